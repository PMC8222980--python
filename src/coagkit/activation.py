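"""Fluorogenic clotting-factor (zymogen) activation analysis.

A plate-reader assay measures a venom's ability to convert a clotting
zymogen (Factor X or prothrombin) into its active protease: the enzyme
cleaves a fluorogenic peptide substrate, and fluorescence (RFU) is read
on a uniform time grid (every 10 s for 300 cycles by default).  Five
well roles are used:

  blank               buffer + substrate only (background)
  activated_control   the pre-activated enzyme (FXa or thrombin)
  zymogen_control     zymogen without venom
  venom_alone         venom + substrate, no zymogen
  venom_plus_zymogen  venom + zymogen + substrate

Correction proceeds by subtracting the blank from every well and then
subtracting the venom-alone trace from the venom-plus-zymogen trace, so
venoms that cleave the substrate directly (without activating anything)
score zero.  Because the blank cancels in that difference, the corrected
venom trace is simply venom_plus_zymogen − venom_alone.  The corrected
trace is then normalized as a percentage of the activated-enzyme
control; by default the scalar is the ratio of the whole-curve AUCs,
with endpoint and maximum-slope variants selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .errors import GridMismatchError, IncompletePlateError, UndefinedShiftError

ROLES = ("blank", "activated_control", "zymogen_control",
         "venom_alone", "venom_plus_zymogen")

Scalar = Literal["auc", "endpoint", "slope"]


@dataclass(frozen=True)
class FluorescenceTrace:
    """One well's RFU time series."""

    well: str
    role: str
    times_s: np.ndarray
    rfu: np.ndarray
    venom_id: str | None = None
    replicate: int = 1

    def __post_init__(self):
        object.__setattr__(self, "times_s", np.asarray(self.times_s, dtype=float))
        object.__setattr__(self, "rfu", np.asarray(self.rfu, dtype=float))
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}; expected one of {ROLES}")
        t = self.times_s
        if len(t) != len(self.rfu):
            raise GridMismatchError(
                f"well {self.well}: {len(t)} times but {len(self.rfu)} RFU values")
        if len(t) >= 2:
            dt = np.diff(t)
            if (dt <= 0).any():
                raise GridMismatchError(f"well {self.well}: times not strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise GridMismatchError(f"well {self.well}: non-uniform time grid")
        if not np.isfinite(self.rfu).all():
            raise GridMismatchError(f"well {self.well}: non-finite RFU values")


@dataclass
class FluorescencePlate:
    """All wells of one activation assay plate, sharing a time grid."""

    traces: list[FluorescenceTrace]
    target: str = "FX"  # label only: "FX" or "prothrombin"

    def __post_init__(self):
        if self.traces:
            grid = self.traces[0].times_s
            for tr in self.traces[1:]:
                if not np.array_equal(tr.times_s, grid):
                    raise GridMismatchError(
                        f"well {tr.well} is on a different time grid than the plate")

    @property
    def times_s(self) -> np.ndarray:
        return self.traces[0].times_s

    def by_role(self, role: str) -> list[FluorescenceTrace]:
        return [t for t in self.traces if t.role == role]

    def venom_ids(self) -> list[str]:
        seen = dict.fromkeys(t.venom_id for t in self.traces
                             if t.role == "venom_plus_zymogen" and t.venom_id)
        return list(seen)


@dataclass(frozen=True)
class CorrectedTraces:
    """Blank- and venom-alone-corrected traces for one venom replicate."""

    venom_id: str
    replicate: int
    times_s: np.ndarray
    corrected_venom: np.ndarray    # venom_plus_zymogen − venom_alone
    corrected_control: np.ndarray  # activated_control − blank


@dataclass(frozen=True)
class ActivationResult:
    """Activation of one venom as a percentage of the activated-enzyme control."""

    venom_id: str
    target: str
    replicate_percent: tuple[float, ...]
    percent_curves: tuple[np.ndarray, ...] = field(default=(), repr=False)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_percent))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicate_percent, ddof=1)) \
            if len(self.replicate_percent) > 1 else 0.0


def _pick(traces: list[FluorescenceTrace], role: str, replicate: int,
          venom_id: str | None = None) -> FluorescenceTrace:
    pool = [t for t in traces if t.role == role
            and (venom_id is None or t.venom_id == venom_id)]
    if not pool:
        what = f"{role} for venom {venom_id}" if venom_id else role
        raise IncompletePlateError(f"plate has no {what} well")
    for t in pool:
        if t.replicate == replicate:
            return t
    if len(pool) == 1:  # a single shared control well serves all replicates
        return pool[0]
    raise IncompletePlateError(
        f"no {role} well for replicate {replicate} (and several candidates)")


def correct_traces(plate: FluorescencePlate) -> list[CorrectedTraces]:
    """Apply the two-step background correction to every venom on the plate.

    Per time point: corrected venom = (venom_plus_zymogen − blank) −
    (venom_alone − blank) = venom_plus_zymogen − venom_alone; corrected
    control = activated_control − blank.  Negative values are kept (they
    carry drift/quenching information); only the headline percentage
    floors them.
    """
    _pick(plate.traces, "blank", 1)  # fail fast if the plate lacks a blank
    out: list[CorrectedTraces] = []
    for venom_id in plate.venom_ids():
        reps = sorted({t.replicate for t in plate.traces
                       if t.role == "venom_plus_zymogen" and t.venom_id == venom_id})
        for rep in reps:
            vz = _pick(plate.traces, "venom_plus_zymogen", rep, venom_id)
            va = _pick(plate.traces, "venom_alone", rep, venom_id)
            ctrl = _pick(plate.traces, "activated_control", rep)
            blank = _pick(plate.traces, "blank", rep)
            out.append(CorrectedTraces(
                venom_id=venom_id,
                replicate=rep,
                times_s=plate.times_s,
                corrected_venom=vz.rfu - va.rfu,
                corrected_control=ctrl.rfu - blank.rfu,
            ))
    return out


def activation_percent(corrected_venom: np.ndarray,
                       corrected_control: np.ndarray,
                       times_s: np.ndarray,
                       scalar: Scalar = "auc") -> tuple[float, np.ndarray]:
    """Normalize a corrected venom trace against the activated-enzyme control.

    Returns ``(percent, percent_curve)``.  The scalar is
    100 × AUC(venom)/AUC(control) by default ("auc"); "endpoint" uses the
    final RFU values and "slope" the maximum finite-difference slope.
    The headline percent is floored at 0; the per-timepoint percentage
    curve is returned unfloored.
    """
    cv = np.asarray(corrected_venom, dtype=float)
    cc = np.asarray(corrected_control, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if not (len(cv) == len(cc) == len(t)):
        raise GridMismatchError("corrected traces and time grid differ in length")
    if np.allclose(cc, 0.0):
        raise UndefinedShiftError("activated-enzyme control trace is identically zero")

    if scalar == "auc":
        num, den = float(np.trapezoid(cv, t)), float(np.trapezoid(cc, t))
    elif scalar == "endpoint":
        num, den = float(cv[-1]), float(cc[-1])
    elif scalar == "slope":
        num = float(np.max(np.gradient(cv, t)))
        den = float(np.max(np.gradient(cc, t)))
    else:
        raise ValueError(f"unknown scalar {scalar!r}")
    if den == 0:
        raise UndefinedShiftError(f"control {scalar} scalar is zero; cannot normalize")
    percent = max(0.0, 100.0 * num / den)
    with np.errstate(divide="ignore", invalid="ignore"):
        curve = np.where(cc != 0, 100.0 * cv / cc, np.nan)
    return percent, curve


def summarize_plate(plate: FluorescencePlate,
                    scalar: Scalar = "auc") -> list[ActivationResult]:
    """Mean ± SD activation percentage per venom, ranked by mean (descending).

    Ties (e.g. several fully inactive venoms at 0%) keep a stable order:
    the plate's venom order breaks them.
    """
    corrected = correct_traces(plate)
    by_venom: dict[str, list[CorrectedTraces]] = {}
    for c in corrected:
        by_venom.setdefault(c.venom_id, []).append(c)
    results = []
    for venom_id in plate.venom_ids():
        percents, curves = [], []
        for c in sorted(by_venom[venom_id], key=lambda c: c.replicate):
            p, curve = activation_percent(c.corrected_venom, c.corrected_control,
                                          c.times_s, scalar=scalar)
            percents.append(p)
            curves.append(curve)
        results.append(ActivationResult(
            venom_id=venom_id, target=plate.target,
            replicate_percent=tuple(percents), percent_curves=tuple(curves)))
    results.sort(key=lambda r: -r.mean)  # stable: ties keep plate order
    return results
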