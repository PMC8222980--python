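"""Neutralization statistic: per-curve AUC and the X-fold magnitude of shift.

The efficacy of an antivenom or enzyme inhibitor against a venom is
quantified by comparing the area under the clotting-time concentration
curve (AUC) with and without the treatment:

    shift = AUC(venom + treatment) / AUC(venom) - 1

A shift of 0 means the treated curve is unchanged (no neutralization);
a positive shift means clotting was slowed back toward the spontaneous
time (neutralization).  AUCs are computed per replicate by trapezoid
integration over the concentration axis (linear by default, log10 as an
option) and shifts are paired by replicate index, giving a mean ± SD
across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assay import ConcentrationCurve, require_valid_curve
from .errors import (
    IncompatibleCurvesError,
    InsufficientPointsError,
    UndefinedShiftError,
)

VERDICT_NONE = "none"
VERDICT_NEUTRALIZED = "neutralized"


@dataclass(frozen=True)
class AUCResult:
    """Per-replicate area under one clotting-time concentration curve."""

    sample_id: str
    treatment: str
    replicate_auc: tuple[float, ...]  # s·µg/ml on the linear axis
    censored_fraction: float
    axis: str = "linear"

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_auc))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicate_auc, ddof=1)) \
            if len(self.replicate_auc) > 1 else 0.0


@dataclass(frozen=True)
class ShiftResult:
    """X-fold magnitude of shift of a treated curve against its venom curve."""

    sample_id: str
    treatment: str
    replicate_shift: tuple[float, ...]
    saturated: bool = False  # venom curve entirely at the instrument ceiling
    tolerance: float = 0.0

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_shift))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicate_shift, ddof=1)) \
            if len(self.replicate_shift) > 1 else 0.0

    @property
    def verdict(self) -> str:
        return classify_neutralization(self.mean, self.tolerance)


def _axis_values(conc: np.ndarray, axis: str) -> np.ndarray:
    if axis == "linear":
        return conc
    if axis == "log":
        if (conc <= 0).any():
            raise InsufficientPointsError(
                "log-axis AUC requires strictly positive concentrations")
        return np.log10(conc)
    raise ValueError(f"unknown AUC axis {axis!r} (expected 'linear' or 'log')")


def curve_auc(curve: ConcentrationCurve, axis: str = "linear") -> AUCResult:
    """Trapezoid AUC of clotting time over concentration, per replicate.

    Concentrations are sorted ascending and integration runs only over
    the measured range (no extrapolation).  Censored readings are kept
    at the ceiling value; the returned result carries the curve's
    censored fraction so saturated curves can be flagged downstream.
    """
    conc = curve.concentrations()
    if len(conc) < 2:
        raise InsufficientPointsError(
            f"AUC needs >=2 distinct concentrations, curve has {len(conc)}")
    require_valid_curve(curve)
    x = _axis_values(conc.astype(float), axis)
    aucs = []
    for rep in curve.replicate_indices():
        y = curve.replicate_times(rep)
        if len(y) != len(x):
            raise InsufficientPointsError(
                f"replicate {rep} does not cover the concentration grid")
        aucs.append(float(np.trapezoid(y, x)))
    return AUCResult(
        sample_id=curve.sample_id,
        treatment=curve.treatment,
        replicate_auc=tuple(aucs),
        censored_fraction=curve.censored_fraction,
        axis=axis,
    )


def xfold_shift(auc_venom: float, auc_treated: float) -> float:
    """X-fold magnitude of shift: ``auc_treated / auc_venom - 1``.

    0 means the treatment left the curve unchanged; values above 0 mean
    clotting was slowed (neutralization).
    """
    if not auc_venom > 0:
        raise UndefinedShiftError(
            f"shift undefined for non-positive venom AUC {auc_venom}")
    return auc_treated / auc_venom - 1.0


def shift_with_replicates(venom: ConcentrationCurve,
                          treated: ConcentrationCurve,
                          axis: str = "linear",
                          tolerance: float = 0.0) -> ShiftResult:
    """Per-replicate X-fold shifts of a treated curve vs the venom curve.

    Replicates are paired by index; the two curves must share the same
    concentration grid and replicate count.  A venom curve sitting
    entirely at the instrument ceiling (a fully anticoagulant or
    non-clotting run) yields a ``saturated`` flag: there is nothing left
    to neutralize and the shift against an equally saturated treated
    curve is 0 by construction.
    """
    auc_v = curve_auc(venom, axis=axis)
    auc_t = curve_auc(treated, axis=axis)
    if not np.array_equal(venom.concentrations(), treated.concentrations()):
        raise IncompatibleCurvesError(
            "venom and treated curves measured on different concentration grids")
    if len(auc_v.replicate_auc) != len(auc_t.replicate_auc):
        raise IncompatibleCurvesError(
            f"replicate counts differ: {len(auc_v.replicate_auc)} vs "
            f"{len(auc_t.replicate_auc)}")
    shifts = tuple(xfold_shift(v, t)
                   for v, t in zip(auc_v.replicate_auc, auc_t.replicate_auc))
    saturated = venom.censored_fraction == 1.0
    return ShiftResult(
        sample_id=venom.sample_id,
        treatment=treated.treatment,
        replicate_shift=shifts,
        saturated=saturated,
        tolerance=tolerance,
    )


def classify_neutralization(mean_shift: float, tolerance: float = 0.0) -> str:
    """``"neutralized"`` iff the mean shift exceeds ``tolerance`` (default 0)."""
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    return VERDICT_NEUTRALIZED if mean_shift > tolerance else VERDICT_NONE
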