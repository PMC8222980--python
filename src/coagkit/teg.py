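"""Thromboelastography (TEG) trace parameterization.

A TEG analyser records clot amplitude A(t) in millimetres over a run
(30 minutes here, 1-s sampling).  Amplitude maps to clot elasticity via
the standard transform

    G = 5000 · A / (100 − A)   [dynes/cm²],

and six parameters summarize a trace:

    SP     split point — first time the amplitude exceeds a small
           detection threshold (clot formation begins) [s]
    R      reaction time — first time a detectable clot (≥ 2 mm) forms [s]
    MA     maximum amplitude of the clot [mm]
    MRTG   maximum rate of thrombus generation, max dG/dt [dynes/cm²/s]
    TMRTG  time to that maximum rate [min]
    TGG    total thrombus generated, terminal elasticity G(end)
           (≡ ∫ dG/dt when G starts at 0) [dynes/cm²]

On a flat negative-control trace the threshold parameters are simply
absent (``None``), not errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InsufficientDataError

#: Amplitude (mm) above which clot formation is considered to have begun.
DEFAULT_SP_THRESHOLD_MM = 0.2
#: Amplitude (mm) defining a detectable clot for the R parameter.
DEFAULT_R_THRESHOLD_MM = 2.0
DEFAULT_SMOOTHING_WINDOW = 5


@dataclass(frozen=True)
class TEGTrace:
    """Amplitude-vs-time trace on a uniform grid."""

    times_s: np.ndarray
    amplitude_mm: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times_s", np.asarray(self.times_s, dtype=float))
        object.__setattr__(self, "amplitude_mm",
                           np.asarray(self.amplitude_mm, dtype=float))
        if len(self.times_s) != len(self.amplitude_mm):
            raise InsufficientDataError("times and amplitudes differ in length")
        if len(self.times_s) >= 2 and (np.diff(self.times_s) <= 0).any():
            raise InsufficientDataError("times must be strictly increasing")
        a = self.amplitude_mm
        if (a < 0).any() or (a >= 100).any():
            raise ValueError("amplitude must lie in [0, 100) mm")


@dataclass(frozen=True)
class TEGParams:
    """The six derived TEG parameters; ``None`` marks an undefined value."""

    SP_s: float | None
    R_s: float | None
    MA_mm: float
    MRTG: float | None        # dynes/cm²/s
    TMRTG_min: float | None
    TGG: float                # dynes/cm²


def amplitude_to_elasticity(amplitude_mm):
    """Clot elasticity G = 5000·A/(100−A), elementwise; G(0) = 0."""
    a = np.asarray(amplitude_mm, dtype=float)
    if (a < 0).any() or (a >= 100).any():
        raise ValueError("amplitude must lie in [0, 100) mm")
    g = 5000.0 * a / (100.0 - a)
    return float(g) if np.isscalar(amplitude_mm) else g


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    # centered window; edges use the partial window so length is preserved
    if window <= 1:
        return y
    kernel = np.ones(window)
    smoothed = np.convolve(y, kernel, mode="same")
    norm = np.convolve(np.ones_like(y), kernel, mode="same")
    return smoothed / norm


def thrombus_velocity(trace: TEGTrace,
                      window: int = DEFAULT_SMOOTHING_WINDOW,
                      on: Literal["elasticity", "amplitude"] = "elasticity"
                      ) -> np.ndarray:
    """Rate of thrombus generation dG/dt along the trace.

    The elasticity curve is smoothed with a centered moving average of
    ``window`` points, then differentiated with central finite
    differences (one-sided at the endpoints).  ``on="amplitude"``
    differentiates the raw amplitude instead (non-standard, for
    comparison with instruments that do so).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be a positive odd integer, got {window}")
    if len(trace.times_s) < window + 1:
        raise InsufficientDataError(
            f"trace has {len(trace.times_s)} samples; needs > window ({window})")
    y = trace.amplitude_mm if on == "amplitude" \
        else amplitude_to_elasticity(trace.amplitude_mm)
    return np.gradient(_moving_average(y, window), trace.times_s)


def extract_teg_params(trace: TEGTrace,
                       sp_threshold_mm: float = DEFAULT_SP_THRESHOLD_MM,
                       r_threshold_mm: float = DEFAULT_R_THRESHOLD_MM,
                       window: int = DEFAULT_SMOOTHING_WINDOW,
                       velocity_on: Literal["elasticity", "amplitude"] = "elasticity"
                       ) -> TEGParams:
    """Compute the six TEG parameters from a trace.

    SP and R are first-crossing times of the detection and 2-mm
    thresholds; when a threshold is never crossed the parameter is
    absent.  MRTG and TMRTG come from the smoothed dG/dt restricted to
    times at or after SP (so baseline noise before clot onset cannot
    masquerade as thrombus generation); TMRTG is reported in minutes.
    TGG is the terminal elasticity.
    """
    t = trace.times_s
    a = trace.amplitude_mm
    above_sp = np.nonzero(a > sp_threshold_mm)[0]
    above_r = np.nonzero(a >= r_threshold_mm)[0]
    sp = float(t[above_sp[0]]) if len(above_sp) else None
    r = float(t[above_r[0]]) if len(above_r) else None
    ma = float(np.max(a))
    g = amplitude_to_elasticity(a)
    tgg = float(g[-1])

    mrtg = tmrtg = None
    if sp is not None:
        vel = thrombus_velocity(trace, window=window, on=velocity_on)
        mask = t >= sp
        i = int(np.argmax(vel[mask]))
        mrtg = float(vel[mask][i])
        tmrtg = float(t[mask][i]) / 60.0
    return TEGParams(SP_s=sp, R_s=r, MA_mm=ma, MRTG=mrtg,
                     TMRTG_min=tmrtg, TGG=tgg)
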