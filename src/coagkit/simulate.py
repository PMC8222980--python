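"""Synthetic-data generators with known ground truth, plus an EC50 fitter.

These generators emulate the three instruments behind the analysis
pipeline — the coagulation analyser (clotting-time concentration
curves), the fluorescence plate reader (zymogen-activation progress
curves) and the TEG analyser (amplitude traces) — so that every analysis
stage can be verified by parameter recovery against known inputs.

Clotting curves follow a four-parameter Hill-type model.  Procoagulant:

    CT(c) = t_floor + (t_spont − t_floor) / (1 + (c / EC50)^h)

falling from the spontaneous clotting time t_spont at c = 0 toward the
maximal-venom floor t_floor; anticoagulant venoms instead multiply the
spontaneous time, CT(c) = t_spont · (1 + (c/EC50)^h), which runs into
the instrument ceiling.  Noise is multiplicative lognormal (clotting
times are positive and replicate SDs scale roughly with the mean) and
censoring at the ceiling is applied after noise.  A treatment with
efficacy e neutralizes a fraction e of the venom, i.e. the curve is
evaluated at the effective concentration c·(1−e); a capacity-limited
variant c_eff = max(0, c − B) is available for treatments that saturate.

All generators take an explicit seed; there is no hidden global random
state, and output is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .activation import FluorescencePlate, FluorescenceTrace
from .assay import (
    DEFAULT_CEILING_S,
    DEFAULT_REPLICATES,
    PLASMA_RECIPE,
    STANDARD_DILUTION_FACTORS,
    ClottingMeasurement,
    ConcentrationCurve,
    build_dilution_series,
    censor_clotting_time,
)
from .errors import CoagKitError
from .teg import TEGTrace


def standard_concentrations(start_stock: float = 100.0) -> tuple[float, ...]:
    """Final concentrations of the standard 8-point dilution design."""
    return build_dilution_series(start_stock, STANDARD_DILUTION_FACTORS,
                                 PLASMA_RECIPE).final_concentrations


@dataclass(frozen=True)
class ClotSimParams:
    """Ground truth for a simulated clotting-time concentration curve.

    Defaults describe a strongly procoagulant viper-like venom measured
    against a spontaneous plasma clotting time of ~645 s, with 5%
    replicate noise.
    """

    direction: Literal["procoagulant", "anticoagulant"] = "procoagulant"
    t_spont_s: float = 645.2
    t_floor_s: float = 16.0
    ec50_ug_ml: float = 0.5
    hill: float = 1.0
    ceiling_s: float = DEFAULT_CEILING_S
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.direction not in ("procoagulant", "anticoagulant"):
            raise CoagKitError(f"unknown direction {self.direction!r}")
        if not self.t_floor_s < self.t_spont_s:
            raise CoagKitError("t_floor must be below t_spont")
        if not self.ec50_ug_ml > 0:
            raise CoagKitError("EC50 must be > 0")
        if not self.hill > 0:
            raise CoagKitError("Hill slope must be > 0")
        if self.noise_cv < 0:
            raise CoagKitError("noise CV must be >= 0")

    def mean_clotting_time(self, conc) -> np.ndarray:
        """Noise-free model clotting time at final concentration(s)."""
        c = np.asarray(conc, dtype=float)
        x = np.power(c / self.ec50_ug_ml, self.hill,
                     where=c > 0, out=np.zeros_like(c))
        if self.direction == "procoagulant":
            return self.t_floor_s + (self.t_spont_s - self.t_floor_s) / (1.0 + x)
        return self.t_spont_s * (1.0 + x)


@dataclass(frozen=True)
class TreatmentSimParams:
    """Neutralizing treatment: fraction ``efficacy`` of venom is removed.

    ``capacity`` switches to the capacity-limited model
    c_eff = max(0, c − capacity) (µg/ml bound, for treatments that are
    overwhelmed at high venom dose).  ``seed`` drives the treated run's
    replicate noise; when ``None`` the venom curve's seed is reused, so
    efficacy 0 reproduces the venom curve bit for bit.
    """

    label: str = "antivenom"
    efficacy: float = 0.0
    capacity: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.efficacy <= 1.0:
            raise CoagKitError("efficacy must lie in [0, 1]")

    def effective_concentration(self, conc: np.ndarray) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        if self.capacity is not None:
            return np.maximum(0.0, c - self.capacity)
        return c * (1.0 - self.efficacy)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    # mean-1 multiplicative noise so the model curve is the expectation
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def simulate_clotting_curve(p: ClotSimParams,
                            concentrations: Sequence[float] | None = None,
                            replicates: int = DEFAULT_REPLICATES,
                            sample_id: str = "synthetic",
                            treatment: str = "none") -> ConcentrationCurve:
    """Simulate a replicated clotting-time concentration curve.

    Noise is applied to the model mean, then the instrument ceiling
    censors the result — so the censored fraction is itself stochastic,
    as on the real analyser.
    """
    conc = np.asarray(standard_concentrations() if concentrations is None
                      else concentrations, dtype=float)
    rng = np.random.default_rng(p.seed)
    mean_ct = p.mean_clotting_time(conc)
    noise = _lognormal_factors(rng, p.noise_cv, (replicates, conc.size))
    measurements = []
    for rep in range(1, replicates + 1):
        for j, c in enumerate(conc):
            t, cens = censor_clotting_time(mean_ct[j] * noise[rep - 1, j],
                                           p.ceiling_s)
            measurements.append(ClottingMeasurement(
                concentration=float(c), replicate=rep, time_s=t, censored=cens))
    return ConcentrationCurve(sample_id=sample_id, treatment=treatment,
                              measurements=measurements, ceiling_s=p.ceiling_s)


def simulate_neutralized_curve(p: ClotSimParams, t: TreatmentSimParams,
                               concentrations: Sequence[float] | None = None,
                               replicates: int = DEFAULT_REPLICATES,
                               sample_id: str = "synthetic") -> ConcentrationCurve:
    """Simulate the venom curve after preincubation with a treatment.

    The model is evaluated at the effective (post-neutralization)
    concentration but the curve is recorded against the nominal
    concentration grid, exactly as a preincubated assay is plotted.
    With efficacy 0 (and no capacity bound) the output distribution is
    identical to :func:`simulate_clotting_curve` at the same seed.
    """
    conc = np.asarray(standard_concentrations() if concentrations is None
                      else concentrations, dtype=float)
    eff = t.effective_concentration(conc)
    p_run = p if t.seed is None else replace(p, seed=t.seed)
    curve = simulate_clotting_curve(p_run, concentrations=eff,
                                    replicates=replicates,
                                    sample_id=sample_id, treatment=t.label)
    relabeled = [replace(m, concentration=float(conc[i % conc.size]))
                 for i, m in enumerate(curve.measurements)]
    curve.measurements = relabeled
    return curve


@dataclass(frozen=True)
class ActivationSimParams:
    """Ground truth for a simulated fluorogenic activation plate.

    First-order activation kinetics: the venom converts zymogen Z0 to
    active enzyme with rate ``k_act`` (enzyme(t) = Z0·(1 − e^(−k_act·t))),
    and active enzyme cleaves substrate producing signal at ``k_sub`` RFU/s
    per unit enzyme.  The activated-enzyme control holds E0 units of
    pre-activated enzyme, giving a linear signal.  ``direct_cleavage``
    models venoms that cleave the substrate without any zymogen — the
    artifact the venom-alone subtraction removes.
    """

    k_act: float = 1e-3          # 1/s
    k_sub: float = 5.0           # RFU/s per unit enzyme
    direct_cleavage: float = 0.0  # RFU/s from venom acting on substrate alone
    blank_drift: float = 0.05    # RFU/s background drift
    e0: float = 1.0              # activated-enzyme control amount (units)
    z0: float = 1.0              # zymogen amount available to the venom (units)
    n_cycles: int = 300
    dt_s: float = 10.0
    noise_sd: float = 0.0        # RFU additive noise
    seed: int = 0

    def __post_init__(self):
        for name in ("k_act", "k_sub", "direct_cleavage", "blank_drift",
                     "e0", "z0", "noise_sd"):
            if getattr(self, name) < 0:
                raise CoagKitError(f"{name} must be >= 0")

    def grid(self) -> np.ndarray:
        return np.arange(self.n_cycles, dtype=float) * self.dt_s

    def integrated_enzyme(self, t: np.ndarray, k_act: float | None = None
                          ) -> np.ndarray:
        """∫₀ᵗ enzyme(u) du for enzyme(u) = Z0·(1 − e^(−k·u))."""
        k = self.k_act if k_act is None else k_act
        if k == 0:
            return np.zeros_like(t)
        return self.z0 * (t - (1.0 - np.exp(-k * t)) / k)


def simulate_fluorescence_plate(
        p: ActivationSimParams,
        venoms: Mapping[str, float | tuple[float, float]],
        replicates: int = DEFAULT_REPLICATES,
        target: str = "FX") -> FluorescencePlate:
    """Simulate a five-role activation plate for several venoms.

    ``venoms`` maps venom id to its activation rate k_act (1/s), or to a
    ``(k_act, direct_cleavage)`` pair; plate-level parameters come from
    ``p``.  One blank and one activated-enzyme control well are produced
    per replicate.
    """
    rng = np.random.default_rng(p.seed)
    t = p.grid()

    def noisy(y: np.ndarray) -> np.ndarray:
        if p.noise_sd == 0:
            return y
        return y + rng.normal(0.0, p.noise_sd, size=y.shape)

    traces: list[FluorescenceTrace] = []
    for rep in range(1, replicates + 1):
        blank = p.blank_drift * t
        traces.append(FluorescenceTrace(well=f"blank-r{rep}", role="blank",
                                        times_s=t, rfu=noisy(blank),
                                        replicate=rep))
        ctrl = blank + p.k_sub * p.e0 * t
        traces.append(FluorescenceTrace(well=f"ctrl-r{rep}",
                                        role="activated_control",
                                        times_s=t, rfu=noisy(ctrl),
                                        replicate=rep))
        zym = blank  # zymogen alone generates no signal in this model
        traces.append(FluorescenceTrace(well=f"zym-r{rep}", role="zymogen_control",
                                        times_s=t, rfu=noisy(zym), replicate=rep))
        for venom_id, spec in venoms.items():
            k_act, direct = (spec if isinstance(spec, tuple)
                             else (spec, p.direct_cleavage))
            alone = blank + direct * t
            traces.append(FluorescenceTrace(
                well=f"{venom_id}-alone-r{rep}", role="venom_alone",
                times_s=t, rfu=noisy(alone), venom_id=venom_id, replicate=rep))
            with_z = alone + p.k_sub * p.integrated_enzyme(t, k_act)
            traces.append(FluorescenceTrace(
                well=f"{venom_id}-zym-r{rep}", role="venom_plus_zymogen",
                times_s=t, rfu=noisy(with_z), venom_id=venom_id, replicate=rep))
    return FluorescencePlate(traces=traces, target=target)


@dataclass(frozen=True)
class TEGSimParams:
    """Ground truth for a simulated TEG amplitude trace.

    Exponential-saturation clot growth after a lag:
    A(t) = MA·(1 − e^(−k(t − t0))) for t > t0, else 0.
    """

    ma_mm: float = 60.0
    rate: float = 0.01   # 1/s
    lag_s: float = 120.0
    duration_s: float = 1800.0
    dt_s: float = 1.0
    noise_sd: float = 0.0  # mm
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ma_mm < 100.0:
            raise CoagKitError("MA must lie in [0, 100) mm")
        if not self.rate > 0:
            raise CoagKitError("rate must be > 0")

    def mean_amplitude(self, t: np.ndarray) -> np.ndarray:
        tau = np.maximum(0.0, t - self.lag_s)
        a = self.ma_mm * (1.0 - np.exp(-self.rate * tau))
        return np.where(t > self.lag_s, a, 0.0)


def simulate_teg_trace(p: TEGSimParams) -> TEGTrace:
    """Simulate one TEG amplitude trace, clipped to the valid [0, 100) mm range."""
    rng = np.random.default_rng(p.seed)
    t = np.arange(0.0, p.duration_s + p.dt_s / 2, p.dt_s)
    a = p.mean_amplitude(t)
    if p.noise_sd > 0:
        a = a + rng.normal(0.0, p.noise_sd, size=a.shape)
    a = np.clip(a, 0.0, np.nextafter(100.0, 0.0))
    return TEGTrace(times_s=t, amplitude_mm=a)


@dataclass(frozen=True)
class FitResult:
    """Estimated clotting-curve parameters with fit diagnostics."""

    t_spont_s: float
    t_floor_s: float
    ec50_ug_ml: float
    hill: float
    converged: bool
    message: str
    rss: float = math.nan


def fit_concentration_response(curve: ConcentrationCurve) -> FitResult:
    """Least-squares fit of the procoagulant Hill model to a curve.

    Fits CT(c) = t_floor + (t_spont − t_floor)/(1 + (c/EC50)^h) to all
    uncensored measurements.  Initialization is deterministic: t_spont
    from the maximum observed time, t_floor from the minimum, EC50 from
    the geometric middle of the positive concentrations, h = 1 — so the
    fit is reproducible given the data.  Fewer than five uncensored
    distinct concentrations yields a flagged (non-converged) result
    rather than an exception.
    """
    pts = [(m.concentration, m.time_s) for m in curve.measurements
           if not m.censored]
    distinct = {c for c, _ in pts}
    if len(distinct) < 5:
        return FitResult(math.nan, math.nan, math.nan, math.nan,
                         converged=False,
                         message=f"only {len(distinct)} uncensored distinct "
                                 "concentrations; need >= 5")
    c = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    pos = c[c > 0]
    ec50_init = math.sqrt(float(pos.min()) * float(pos.max()))
    x0 = np.array([float(y.max()), float(y.min()), ec50_init, 1.0])

    def model(theta, conc):
        t_spont, t_floor, ec50, h = theta
        x = np.power(conc / ec50, h, where=conc > 0,
                     out=np.zeros_like(conc, dtype=float))
        return t_floor + (t_spont - t_floor) / (1.0 + x)

    def residuals(theta):
        return model(theta, c) - y

    eps = 1e-9
    sol = least_squares(residuals, x0,
                        bounds=([eps, eps, eps, 0.05],
                                [np.inf, np.inf, np.inf, 20.0]))
    return FitResult(
        t_spont_s=float(sol.x[0]), t_floor_s=float(sol.x[1]),
        ec50_ug_ml=float(sol.x[2]), hill=float(sol.x[3]),
        converged=bool(sol.success), message=str(sol.message),
        rss=float(2.0 * sol.cost))
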