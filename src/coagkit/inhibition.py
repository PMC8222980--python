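"""Clotting-factor inhibition profiling for anticoagulant venoms.

Anticoagulant venoms can act by inhibiting an activated clotting factor.
The assay preincubates venom with an exogenous factor (thrombin, FIXa,
FXa, FXIa or FXIIa), adds plasma, and measures the clotting time; a
no-venom control gives the baseline.  The readout is the fold shift of
clotting time relative to control,

    shift = time_with_venom / time_control - 1,

the same ratio-minus-one form as the AUC neutralization statistic: 0
means no effect, positive means the factor was inhibited (clotting
slowed).  A difference-based variant (seconds) is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .auc import xfold_shift
from .errors import InvalidControlError

FACTORS = ("thrombin", "FIXa", "FXa", "FXIa", "FXIIa")

#: Mean fold shift above which a factor is called inhibited.  An artifact
#: convention for turning the per-factor shifts into a qualitative call;
#: configurable wherever it is consumed.
DEFAULT_INHIBITION_THRESHOLD = 0.2


@dataclass(frozen=True)
class InhibitionMeasurement:
    """Paired with/without-venom clotting times for one factor."""

    venom_id: str
    factor: str
    times_with_venom_s: tuple[float, ...]
    times_control_s: tuple[float, ...]

    def __post_init__(self):
        if len(self.times_with_venom_s) != len(self.times_control_s):
            raise InvalidControlError(
                f"{self.venom_id}/{self.factor}: replicate counts differ "
                f"({len(self.times_with_venom_s)} vs {len(self.times_control_s)})")
        if any(t <= 0 for t in self.times_with_venom_s):
            raise InvalidControlError(
                f"{self.venom_id}/{self.factor}: non-positive clotting time")


@dataclass(frozen=True)
class InhibitionShift:
    """Per-replicate shift of clotting time relative to the no-venom control."""

    venom_id: str
    factor: str
    replicate_shift: tuple[float, ...]
    mode: str = "ratio"

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_shift))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicate_shift, ddof=1)) \
            if len(self.replicate_shift) > 1 else 0.0


def inhibition_shift(m: InhibitionMeasurement,
                     mode: Literal["ratio", "difference"] = "ratio"
                     ) -> InhibitionShift:
    """Fold shift (default) or absolute shift of clotting time vs control.

    Replicates are paired by position.  The ratio mode reuses the same
    ratio−1 statistic as the AUC shift, so 0 always means "no effect".
    """
    shifts = []
    for with_v, ctrl in zip(m.times_with_venom_s, m.times_control_s):
        if not ctrl > 0:
            raise InvalidControlError(
                f"{m.venom_id}/{m.factor}: non-positive control time {ctrl}")
        if mode == "ratio":
            shifts.append(xfold_shift(ctrl, with_v))
        elif mode == "difference":
            shifts.append(with_v - ctrl)
        else:
            raise ValueError(f"unknown shift mode {mode!r}")
    return InhibitionShift(venom_id=m.venom_id, factor=m.factor,
                           replicate_shift=tuple(shifts), mode=mode)


def inhibition_profile(measurements: Sequence[InhibitionMeasurement],
                       threshold: float = DEFAULT_INHIBITION_THRESHOLD,
                       mode: Literal["ratio", "difference"] = "ratio"
                       ) -> tuple[pd.DataFrame, str | None]:
    """Shift table over factors plus the inhibited-factor call.

    A factor is called inhibited when its mean shift exceeds ``threshold``
    and no other factor does; several factors above threshold yield the
    call ``"ambiguous"`` (all offenders listed in the table); none above
    threshold yields ``None``.
    """
    if not measurements:
        raise InvalidControlError("inhibition profile needs at least one factor")
    rows = []
    for m in measurements:
        s = inhibition_shift(m, mode=mode)
        rows.append({
            "venom_id": s.venom_id,
            "factor": s.factor,
            "shift_mean": s.mean,
            "shift_sd": s.sd,
            "inhibited": s.mean > threshold,
        })
    table = pd.DataFrame(rows)
    hits = table.loc[table["inhibited"], "factor"].tolist()
    if not hits:
        call = None
    elif len(hits) == 1:
        call = hits[0]
    else:
        call = "ambiguous"
    return table, call
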