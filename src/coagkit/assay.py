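"""Data model and deterministic arithmetic of the plasma clotting assay.

The assay mixes a fixed set of components in a cuvette (venom or control,
buffer or treatment, CaCl2, phospholipid, then plasma or fibrinogen),
records the clotting time, and reports results against the FINAL reaction
concentration of venom.  Concentration curves are built from a serial
dilution of a working venom stock; the coagulation analyser stops at an
instrument ceiling (999 s by default), and readings at the ceiling are
retained as right-censored values rather than dropped.

All public concentration values in this package are final reaction
concentrations; working-stock values appear only inside the recipe
arithmetic here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CurveValidationError, MeasurementError, RecipeError

#: Instrument maximum recordable clotting time, in seconds.
DEFAULT_CEILING_S = 999.0

#: Default replicate count for every assay (all tests run in triplicate).
DEFAULT_REPLICATES = 3

#: The 8-point serial dilution of the working stock used for every
#: concentration curve, as fractions of the working stock.
STANDARD_DILUTION_FACTORS = (
    1.0, 1 / 2, 1 / 5, 1 / 12.5, 1 / 30, 1 / 80, 1 / 160, 1 / 400,
)


@dataclass(frozen=True)
class ReactionRecipe:
    """Component volumes (µl) of one clotting reaction.

    The plasma assay adds 50 µl venom stock, 25 µl buffer (replaced by
    antivenom or inhibitor in neutralization runs), 50 µl CaCl2, 50 µl
    phospholipid and finally 75 µl plasma (or fibrinogen), for a 250 µl
    total.
    """

    venom_or_control_ul: float = 50.0
    buffer_or_treatment_ul: float = 25.0
    calcium_ul: float = 50.0
    phospholipid_ul: float = 50.0
    plasma_or_fibrinogen_ul: float = 75.0

    def __post_init__(self) -> None:
        for name, v in self.volumes().items():
            if not (v > 0 and math.isfinite(v)):
                raise RecipeError(f"component volume {name!r} must be > 0, got {v}")

    def volumes(self) -> dict[str, float]:
        return {
            "venom_or_control": self.venom_or_control_ul,
            "buffer_or_treatment": self.buffer_or_treatment_ul,
            "calcium": self.calcium_ul,
            "phospholipid": self.phospholipid_ul,
            "plasma_or_fibrinogen": self.plasma_or_fibrinogen_ul,
        }

    @property
    def total_volume_ul(self) -> float:
        return float(sum(self.volumes().values()))


#: The standard plasma-assay recipe (250 µl total).
PLASMA_RECIPE = ReactionRecipe()


def final_concentration(stock: float, volume_added_ul: float,
                        total_volume_ul: float) -> float:
    """Final reaction concentration after dilution into the cuvette.

    Unit-preserving: a stock in µg/ml yields µg/ml, a stock in % v/v
    yields %, a stock in mM yields mM.

    >>> final_concentration(100.0, 50.0, 250.0)
    20.0
    """
    if not (volume_added_ul > 0 and total_volume_ul > 0):
        raise RecipeError(
            f"volumes must be strictly positive "
            f"(got {volume_added_ul} µl into {total_volume_ul} µl)")
    if volume_added_ul > total_volume_ul:
        raise RecipeError(
            f"added volume {volume_added_ul} µl exceeds total {total_volume_ul} µl")
    if stock < 0:
        raise RecipeError(f"stock concentration must be >= 0, got {stock}")
    return stock * volume_added_ul / total_volume_ul


@dataclass(frozen=True)
class DilutionSeries:
    """A serial dilution of the working stock and its final concentrations.

    ``factors`` are descending fractions of the working stock with the
    first equal to 1; ``final_concentrations`` are the concentrations in
    the assembled reaction, after the venom volume is diluted into the
    total reaction volume.
    """

    start_stock: float
    factors: tuple[float, ...]
    final_concentrations: tuple[float, ...]


def build_dilution_series(start: float, factors: Sequence[float],
                          recipe: ReactionRecipe = PLASMA_RECIPE) -> DilutionSeries:
    """Final reaction concentrations of a serial dilution.

    Each factor scales the working stock; the venom volume / total volume
    ratio of the recipe then dilutes it into the reaction, so a 100 µg/ml
    stock at factor 1 in the standard 50/250 µl recipe gives 20 µg/ml.
    """
    if not start > 0:
        raise RecipeError(f"working-stock concentration must be > 0, got {start}")
    factors = tuple(float(f) for f in factors)
    if not factors:
        raise RecipeError("dilution series needs at least one factor")
    if not math.isclose(factors[0], 1.0):
        raise RecipeError(f"first dilution factor must be 1, got {factors[0]}")
    for f in factors:
        if not (0 < f <= 1):
            raise RecipeError(f"dilution factors must lie in (0, 1], got {f}")
    if any(b >= a for a, b in zip(factors, factors[1:])):
        raise RecipeError(f"dilution factors must be strictly decreasing: {factors}")
    scale = recipe.venom_or_control_ul / recipe.total_volume_ul
    finals = tuple(start * f * scale for f in factors)
    return DilutionSeries(start_stock=start, factors=factors,
                          final_concentrations=finals)


def censor_clotting_time(raw_s: float, ceiling_s: float = DEFAULT_CEILING_S
                         ) -> tuple[float, bool]:
    """Clip a raw clotting time at the instrument ceiling.

    Returns ``(time, censored)``; the censored flag is set exactly when
    the raw time reached or exceeded the ceiling.  Idempotent.
    """
    if not raw_s > 0:
        raise MeasurementError(f"clotting time must be > 0, got {raw_s}")
    if not ceiling_s > 0:
        raise MeasurementError(f"ceiling must be > 0, got {ceiling_s}")
    if raw_s >= ceiling_s:
        return float(ceiling_s), True
    return float(raw_s), False


@dataclass(frozen=True)
class ClottingMeasurement:
    """One clotting-time reading at a final venom concentration."""

    concentration: float  # µg/ml, final reaction concentration
    replicate: int        # 1-based replicate index
    time_s: float
    censored: bool = False


@dataclass
class ConcentrationCurve:
    """An n-point clotting-time concentration curve with replicates.

    ``treatment`` is ``"none"`` for venom alone, otherwise the antivenom
    or inhibitor name used in preincubation.
    """

    sample_id: str
    treatment: str = "none"
    measurements: list[ClottingMeasurement] = field(default_factory=list)
    ceiling_s: float = DEFAULT_CEILING_S

    def concentrations(self) -> np.ndarray:
        """Distinct final concentrations, ascending."""
        return np.unique([m.concentration for m in self.measurements])

    def replicate_indices(self) -> list[int]:
        return sorted({m.replicate for m in self.measurements})

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_indices())

    def replicate_times(self, replicate: int) -> np.ndarray:
        """Clotting times of one replicate, ordered by ascending concentration."""
        rows = sorted((m.concentration, m.time_s) for m in self.measurements
                      if m.replicate == replicate)
        return np.array([t for _, t in rows], dtype=float)

    @property
    def censored_fraction(self) -> float:
        if not self.measurements:
            return 0.0
        return sum(m.censored for m in self.measurements) / len(self.measurements)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per measurement."""
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "treatment": self.treatment,
                "conc_ug_ml": [m.concentration for m in self.measurements],
                "replicate": [m.replicate for m in self.measurements],
                "clot_time_s": [m.time_s for m in self.measurements],
                "censored": [int(m.censored) for m in self.measurements],
            }
        )


def validate_curve(curve: ConcentrationCurve) -> list[str]:
    """Check the structural invariants of a concentration curve.

    Returns an itemized list of violations; an empty list means valid.
    Checked: at least two distinct non-negative concentrations, an equal
    replicate count at every concentration (no ragged replicates),
    strictly positive times, no time above the ceiling, and the censored
    flag set exactly on ceiling readings.
    """
    violations: list[str] = []
    if not curve.measurements:
        return ["curve has no measurements"]
    concs = curve.concentrations()
    if len(concs) < 2:
        violations.append(f"needs >=2 distinct concentrations, has {len(concs)}")
    if (concs < 0).any():
        violations.append("negative concentrations present")
    counts = {}
    for m in curve.measurements:
        counts[m.concentration] = counts.get(m.concentration, 0) + 1
    if len(set(counts.values())) > 1:
        violations.append(f"ragged replicates: counts per concentration {counts}")
    for m in curve.measurements:
        if not m.time_s > 0:
            violations.append(
                f"non-positive time {m.time_s} at {m.concentration} µg/ml")
        if m.time_s > curve.ceiling_s:
            violations.append(
                f"time {m.time_s} above ceiling {curve.ceiling_s}")
        if m.censored and m.time_s < curve.ceiling_s:
            violations.append(
                f"censored flag on sub-ceiling time {m.time_s}")
    return violations


def require_valid_curve(curve: ConcentrationCurve) -> ConcentrationCurve:
    """Raise :class:`CurveValidationError` unless ``curve`` is valid."""
    violations = validate_curve(curve)
    if violations:
        raise CurveValidationError(violations)
    return curve
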