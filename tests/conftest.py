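import numpy as np
import pytest

from coagkit import (
    ClottingMeasurement,
    ConcentrationCurve,
    standard_concentrations,
)


@pytest.fixture
def standard_grid():
    """Final concentrations of the 8-point dilution design (µg/ml)."""
    return np.array(standard_concentrations())


def make_curve(concentrations, times_by_replicate, sample_id="s",
               treatment="none", ceiling=999.0):
    """Build a curve from a list of per-replicate time arrays."""
    measurements = []
    for rep, times in enumerate(times_by_replicate, start=1):
        for c, t in zip(concentrations, times):
            measurements.append(ClottingMeasurement(
                concentration=float(c), replicate=rep, time_s=float(t),
                censored=t >= ceiling))
    return ConcentrationCurve(sample_id=sample_id, treatment=treatment,
                              measurements=measurements, ceiling_s=ceiling)


@pytest.fixture
def curve_factory():
    return make_curve
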