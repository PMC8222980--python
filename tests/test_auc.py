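"""AUC integration and the X-fold neutralization shift statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from coagkit import (
    ClotSimParams,
    TreatmentSimParams,
    classify_neutralization,
    curve_auc,
    shift_with_replicates,
    simulate_clotting_curve,
    simulate_neutralized_curve,
    standard_concentrations,
    xfold_shift,
)
from coagkit.errors import (
    IncompatibleCurvesError,
    InsufficientPointsError,
    UndefinedShiftError,
)
from conftest import make_curve


class TestCurveAUC:
    def test_linear_ramp_closed_form(self):
        curve = make_curve([0.0, 1.0, 2.0], [[10.0, 20.0, 30.0]])
        assert curve_auc(curve).replicate_auc == (40.0,)

    def test_constant_curve_closed_form(self):
        a, b, T = 0.5, 12.5, 77.0
        curve = make_curve([a, 3.0, b], [[T, T, T]] * 3)
        res = curve_auc(curve)
        assert res.mean == pytest.approx(T * (b - a))
        assert res.sd == 0.0

    @pytest.mark.parametrize("ec50, hill, rel", [
        (5.0, 0.7, 0.02),   # shallow curve: grid resolves it to 2%
        (10.0, 1.0, 0.02),
        (0.5, 1.0, 0.10),   # steep default: limited by 8-point resolution
    ])
    def test_hill_curve_matches_quadrature_oracle(self, ec50, hill, rel):
        """8-point trapezoid AUC of a Hill-shaped curve tracks adaptive
        quadrature of the generating function up to grid resolution."""
        p = ClotSimParams(noise_cv=0.0, seed=0, ec50_ug_ml=ec50, hill=hill)
        conc = np.array(standard_concentrations())
        curve = simulate_clotting_curve(p, replicates=1)
        auc = curve_auc(curve).replicate_auc[0]
        oracle, _ = quad(lambda c: p.mean_clotting_time(np.array(c)),
                         conc.min(), conc.max(), limit=500)
        assert auc == pytest.approx(oracle, rel=rel)

    def test_single_concentration_rejected(self):
        with pytest.raises(InsufficientPointsError):
            curve_auc(make_curve([1.0, 1.0], [[5.0]]))

    def test_log_axis_requires_positive_concentrations(self):
        curve = make_curve([0.0, 1.0, 2.0], [[10.0, 20.0, 30.0]])
        with pytest.raises(InsufficientPointsError):
            curve_auc(curve, axis="log")

    def test_log_axis_integrates_over_log10(self):
        curve = make_curve([1.0, 10.0, 100.0], [[5.0, 5.0, 5.0]])
        assert curve_auc(curve, axis="log").mean == pytest.approx(10.0)


class TestXFoldShift:
    @pytest.mark.parametrize("v, t, expected", [
        (100.0, 100.0, 0.0),   # identical AUCs: no neutralization
        (100.0, 250.0, 1.5),
        (50.0, 25.0, -0.5),
    ])
    def test_arithmetic(self, v, t, expected):
        assert xfold_shift(v, t) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(min_value=1e-3, max_value=1e6),
           k=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_relation(self, a, k):
        assert xfold_shift(a, a * k) == pytest.approx(k - 1.0, rel=1e-9)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(UndefinedShiftError):
            xfold_shift(0.0, 10.0)


class TestShiftWithReplicates:
    def test_self_shift_is_exactly_zero(self, standard_grid):
        times = [[100.0 + r] * 8 for r in range(3)]
        venom = make_curve(standard_grid, times)
        treated = make_curve(standard_grid, times, treatment="av")
        res = shift_with_replicates(venom, treated)
        assert res.replicate_shift == (0.0, 0.0, 0.0)
        assert res.sd == 0.0
        assert res.verdict == "none"

    def test_doubled_times_give_shift_one(self, standard_grid):
        times = [list(50.0 + 10 * np.arange(8) + r) for r in range(3)]
        venom = make_curve(standard_grid, times)
        treated = make_curve(standard_grid, [[2 * t for t in row] for row in times],
                             treatment="av")
        res = shift_with_replicates(venom, treated)
        assert res.replicate_shift == pytest.approx((1.0, 1.0, 1.0))

    def test_concentration_axis_rescale_leaves_shift_unchanged(self, standard_grid):
        times_v = [list(np.linspace(600, 30, 8))]
        times_t = [list(np.linspace(620, 200, 8))]
        s1 = shift_with_replicates(make_curve(standard_grid, times_v),
                                   make_curve(standard_grid, times_t, treatment="av"))
        grid10 = standard_grid * 10
        s2 = shift_with_replicates(make_curve(grid10, times_v),
                                   make_curve(grid10, times_t, treatment="av"))
        assert s1.mean == pytest.approx(s2.mean, rel=1e-12)

    def test_mismatched_grids_rejected(self, standard_grid):
        venom = make_curve(standard_grid, [[100.0] * 8])
        treated = make_curve(standard_grid * 2, [[100.0] * 8], treatment="av")
        with pytest.raises(IncompatibleCurvesError):
            shift_with_replicates(venom, treated)

    def test_mismatched_replicate_counts_rejected(self, standard_grid):
        venom = make_curve(standard_grid, [[100.0] * 8] * 3)
        treated = make_curve(standard_grid, [[100.0] * 8] * 2, treatment="av")
        with pytest.raises(IncompatibleCurvesError):
            shift_with_replicates(venom, treated)

    def test_fully_censored_venom_curve_flagged_saturated(self, standard_grid):
        """Anticoagulant venom at the ceiling everywhere: nothing to
        neutralize, shift 0 and a saturated warning."""
        at_ceiling = [[999.0] * 8] * 3
        venom = make_curve(standard_grid, at_ceiling)
        treated = make_curve(standard_grid, at_ceiling, treatment="av")
        res = shift_with_replicates(venom, treated)
        assert res.mean == 0.0
        assert res.saturated

    def test_effective_antivenom_shifts_positive_across_seeds(self):
        """Efficacy-0.9 treatment vs untreated: positive mean shift in at
        least 95% of 50 simulation seeds."""
        positive = 0
        for seed in range(50):
            p = ClotSimParams(seed=seed)
            venom = simulate_clotting_curve(p)
            treated = simulate_neutralized_curve(
                p, TreatmentSimParams(efficacy=0.9, seed=seed + 10_000))
            if shift_with_replicates(venom, treated).mean > 0:
                positive += 1
        assert positive >= 48


class TestClassifyNeutralization:
    @pytest.mark.parametrize("mean, tol, expected", [
        (0.0, 0.0, "none"),
        (1.2, 0.0, "neutralized"),
        (0.005, 0.01, "none"),
        (0.011, 0.01, "neutralized"),
        (-0.3, 0.0, "none"),
    ])
    def test_verdict(self, mean, tol, expected):
        assert classify_neutralization(mean, tol) == expected

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            classify_neutralization(0.5, -0.1)
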