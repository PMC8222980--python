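"""Zymogen-activation corrections and percent-of-control scoring."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from coagkit import (
    ActivationSimParams,
    FluorescencePlate,
    FluorescenceTrace,
    activation_percent,
    correct_traces,
    simulate_fluorescence_plate,
    summarize_plate,
)
from coagkit.errors import GridMismatchError, IncompletePlateError, UndefinedShiftError


def small_plate(**kwargs):
    params = dict(noise_sd=0.0, n_cycles=50, dt_s=10.0, seed=0)
    params.update(kwargs)
    return ActivationSimParams(**params)


class TestCorrectTraces:
    def test_inactive_venom_corrects_to_zero(self):
        plate = simulate_fluorescence_plate(small_plate(), {"v": 0.0},
                                            replicates=1)
        (c,) = correct_traces(plate)
        np.testing.assert_allclose(c.corrected_venom, 0.0, atol=1e-12)

    def test_direct_substrate_cleavage_removed(self):
        """A venom cleaving the substrate without activating the zymogen
        still corrects to zero — the purpose of the venom-alone subtraction."""
        plate = simulate_fluorescence_plate(small_plate(), {"v": (0.0, 3.0)},
                                            replicates=1)
        alone = [t for t in plate.traces if t.role == "venom_alone"][0]
        assert alone.rfu[-1] > alone.rfu[0]  # the artifact itself is present
        (c,) = correct_traces(plate)
        np.testing.assert_allclose(c.corrected_venom, 0.0, atol=1e-12)

    def test_blank_offset_invariance(self):
        plate = simulate_fluorescence_plate(small_plate(), {"v": 1e-3},
                                            replicates=1)
        (base,) = correct_traces(plate)
        offset = 137.5
        shifted = FluorescencePlate(
            traces=[FluorescenceTrace(well=t.well, role=t.role,
                                      times_s=t.times_s, rfu=t.rfu + offset,
                                      venom_id=t.venom_id, replicate=t.replicate)
                    for t in plate.traces])
        (moved,) = correct_traces(shifted)
        np.testing.assert_allclose(moved.corrected_venom, base.corrected_venom,
                                   atol=1e-9)
        np.testing.assert_allclose(moved.corrected_control, base.corrected_control,
                                   atol=1e-9)

    def test_corrected_trace_matches_kinetic_oracle(self):
        """Noise-free corrected trace equals k_sub·∫Z0(1−e^(−k_act·t))dt,
        checked against numeric cumulative integration of the kinetics."""
        p = small_plate(k_act=2e-3, n_cycles=300)
        plate = simulate_fluorescence_plate(p, {"v": p.k_act}, replicates=1)
        (c,) = correct_traces(plate)
        t = p.grid()
        enzyme = p.z0 * (1.0 - np.exp(-p.k_act * t))
        oracle = p.k_sub * cumulative_trapezoid(enzyme, t, initial=0.0)
        # tolerance set by the oracle's own trapezoid discretization error
        np.testing.assert_allclose(c.corrected_venom, oracle, rtol=2e-3,
                                   atol=0.02)

    def test_missing_role_rejected(self):
        plate = simulate_fluorescence_plate(small_plate(), {"v": 1e-3},
                                            replicates=1)
        plate.traces = [t for t in plate.traces if t.role != "blank"]
        with pytest.raises(IncompletePlateError):
            correct_traces(plate)

    def test_grid_mismatch_rejected(self):
        t1 = FluorescenceTrace(well="a", role="blank",
                               times_s=np.arange(5.0), rfu=np.zeros(5))
        t2 = FluorescenceTrace(well="b", role="activated_control",
                               times_s=np.arange(6.0), rfu=np.zeros(6))
        with pytest.raises(GridMismatchError):
            FluorescencePlate(traces=[t1, t2])


class TestActivationPercent:
    def test_self_normalization_is_100(self):
        t = np.arange(0.0, 100.0, 10.0)
        y = t * 2.0
        percent, curve = activation_percent(y, y, t)
        assert percent == pytest.approx(100.0)
        np.testing.assert_allclose(curve[1:], 100.0)

    def test_zero_trace_scores_zero(self):
        t = np.arange(0.0, 100.0, 10.0)
        percent, _ = activation_percent(np.zeros_like(t), t * 2.0, t)
        assert percent == 0.0

    def test_scale_equivariance(self):
        t = np.arange(0.0, 100.0, 10.0)
        cv, cc = t**1.5, t * 3.0
        p1, _ = activation_percent(cv, cc, t)
        p2, _ = activation_percent(cv * 7.0, cc * 7.0, t)
        assert p1 == pytest.approx(p2)

    def test_zero_control_rejected(self):
        t = np.arange(0.0, 100.0, 10.0)
        with pytest.raises(UndefinedShiftError):
            activation_percent(t, np.zeros_like(t), t)

    def test_negative_scalar_floored_but_curve_unfloored(self):
        t = np.arange(0.0, 100.0, 10.0)
        percent, curve = activation_percent(-t, t, t)
        assert percent == 0.0
        assert (curve[1:] < 0).all()

    def test_half_activity_in_saturating_regime_scores_near_50(self):
        """A venom liberating half the control's enzyme activity, with
        activation saturating early in the run, scores ~50%."""
        p = small_plate(k_act=0.05, z0=0.5, e0=1.0, n_cycles=300)
        plate = simulate_fluorescence_plate(p, {"v": p.k_act}, replicates=1)
        (c,) = correct_traces(plate)
        percent, _ = activation_percent(c.corrected_venom, c.corrected_control,
                                        c.times_s)
        assert percent == pytest.approx(50.0, abs=3.0)


class TestSummarizePlate:
    def test_control_equivalent_venom_scores_100(self):
        # k_act so large that activation is effectively instantaneous
        p = small_plate(k_act=50.0, n_cycles=300)
        plate = simulate_fluorescence_plate(p, {"v": p.k_act}, replicates=1)
        (res,) = summarize_plate(plate)
        assert res.mean == pytest.approx(100.0, abs=1.0)

    def test_ranking_preserves_kinetic_order(self):
        """k_act ratio 4:1 in the linear (pre-saturation) regime keeps
        the faster activator ranked first."""
        p = small_plate(n_cycles=300)
        plate = simulate_fluorescence_plate(
            p, {"slow": 2.5e-5, "fast": 1e-4}, replicates=3)
        results = summarize_plate(plate)
        assert [r.venom_id for r in results] == ["fast", "slow"]
        assert results[0].mean > results[1].mean

    def test_activation_monotone_in_k_act(self):
        p = small_plate(n_cycles=300)
        percents = []
        for k in (1e-5, 1e-4, 1e-3):
            plate = simulate_fluorescence_plate(p, {"v": k}, replicates=1)
            (res,) = summarize_plate(plate)
            percents.append(res.mean)
        assert percents[0] < percents[1] < percents[2]

    def test_all_inactive_venoms_stable_zero_ranking(self):
        p = small_plate()
        plate = simulate_fluorescence_plate(p, {"a": 0.0, "b": 0.0, "c": 0.0},
                                            replicates=1)
        results = summarize_plate(plate)
        assert [r.mean for r in results] == [0.0, 0.0, 0.0]
        assert [r.venom_id for r in results] == ["a", "b", "c"]  # stable ties

    def test_replicate_spread_reported(self):
        p = small_plate(noise_sd=5.0, seed=3, n_cycles=300)
        plate = simulate_fluorescence_plate(p, {"v": 1e-3}, replicates=3)
        (res,) = summarize_plate(plate)
        assert len(res.replicate_percent) == 3
        assert res.sd > 0
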