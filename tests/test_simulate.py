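"""Generators: reproducibility, model limits and parameter recovery."""

import numpy as np
import pytest

from coagkit import (
    ActivationSimParams,
    ClotSimParams,
    TEGSimParams,
    TreatmentSimParams,
    fit_concentration_response,
    simulate_clotting_curve,
    simulate_fluorescence_plate,
    simulate_neutralized_curve,
    simulate_teg_trace,
    standard_concentrations,
)
from coagkit.auc import shift_with_replicates
from coagkit.errors import CoagKitError


class TestClottingCurveGenerator:
    def test_bit_reproducible_under_fixed_seed(self):
        c1 = simulate_clotting_curve(ClotSimParams(seed=5))
        c2 = simulate_clotting_curve(ClotSimParams(seed=5))
        assert c1.measurements == c2.measurements
        c3 = simulate_clotting_curve(ClotSimParams(seed=6))
        assert c1.measurements != c3.measurements

    def test_zero_concentration_gives_spontaneous_time(self):
        p = ClotSimParams(noise_cv=0.0, seed=0)
        curve = simulate_clotting_curve(p, concentrations=[0.0, 1.0],
                                        replicates=1)
        t0 = [m.time_s for m in curve.measurements if m.concentration == 0.0][0]
        assert t0 == pytest.approx(p.t_spont_s)

    def test_procoagulant_asymptote_at_high_dose(self):
        p = ClotSimParams(noise_cv=0.0, seed=0)
        curve = simulate_clotting_curve(p, concentrations=[1.0, 1e6],
                                        replicates=1)
        t_hi = max(m.time_s for m in curve.measurements
                   if m.concentration == 1e6)
        assert t_hi == pytest.approx(p.t_floor_s, rel=1e-3)

    def test_anticoagulant_hits_the_instrument_ceiling(self):
        p = ClotSimParams(direction="anticoagulant", t_spont_s=645.0,
                          noise_cv=0.0, seed=0)
        curve = simulate_clotting_curve(p)
        top = [m for m in curve.measurements
               if m.concentration == max(standard_concentrations())]
        assert all(m.time_s == 999.0 and m.censored for m in top)

    @pytest.mark.parametrize("kwargs", [
        dict(t_floor_s=700.0),           # floor above spontaneous
        dict(ec50_ug_ml=0.0),
        dict(hill=0.0),
        dict(noise_cv=-0.1),
        dict(direction="sideways"),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(CoagKitError):
            ClotSimParams(seed=0, **kwargs)


class TestNeutralizedCurveGenerator:
    def test_zero_efficacy_reproduces_venom_curve(self):
        p = ClotSimParams(seed=9)
        venom = simulate_clotting_curve(p)
        treated = simulate_neutralized_curve(p, TreatmentSimParams(efficacy=0.0))
        assert [(m.concentration, m.time_s) for m in venom.measurements] == \
            [(m.concentration, m.time_s) for m in treated.measurements]

    def test_full_neutralization_flattens_to_spontaneous(self):
        p = ClotSimParams(noise_cv=0.0, seed=0)
        treated = simulate_neutralized_curve(p, TreatmentSimParams(efficacy=1.0),
                                             replicates=1)
        for m in treated.measurements:
            assert m.time_s == pytest.approx(p.t_spont_s)

    def test_capacity_limited_variant(self):
        p = ClotSimParams(noise_cv=0.0, seed=0)
        t = TreatmentSimParams(capacity=5.0)
        treated = simulate_neutralized_curve(p, t, concentrations=[1.0, 4.0, 20.0],
                                             replicates=1)
        by_conc = {m.concentration: m.time_s for m in treated.measurements}
        # below capacity: fully neutralized; above: residual venom acts
        assert by_conc[1.0] == pytest.approx(p.t_spont_s)
        assert by_conc[4.0] == pytest.approx(p.t_spont_s)
        assert by_conc[20.0] == pytest.approx(
            p.mean_clotting_time(np.array(15.0)))

    def test_mean_shift_monotone_in_efficacy(self):
        means = []
        for e in (0.5, 0.99):
            vals = []
            for seed in range(5):
                p = ClotSimParams(seed=seed)
                venom = simulate_clotting_curve(p)
                treated = simulate_neutralized_curve(
                    p, TreatmentSimParams(efficacy=e, seed=seed + 500))
                vals.append(shift_with_replicates(venom, treated).mean)
            means.append(np.mean(vals))
        assert means[1] > means[0] > 0

    def test_efficacy_out_of_range_rejected(self):
        with pytest.raises(CoagKitError):
            TreatmentSimParams(efficacy=1.5)


class TestPlateGenerator:
    def test_reproducible_and_grid_shape(self):
        p = ActivationSimParams(noise_sd=2.0, seed=4)
        a = simulate_fluorescence_plate(p, {"v": 1e-3})
        b = simulate_fluorescence_plate(p, {"v": 1e-3})
        assert len(a.traces) == len(b.traces)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.rfu, tb.rfu)
        assert len(a.times_s) == 300
        assert np.diff(a.times_s)[0] == 10.0

    def test_negative_rate_rejected(self):
        with pytest.raises(CoagKitError):
            ActivationSimParams(k_act=-1.0)


class TestTEGGenerator:
    def test_reproducible_and_clipped(self):
        p = TEGSimParams(ma_mm=95.0, noise_sd=5.0, seed=1)
        a = simulate_teg_trace(p)
        b = simulate_teg_trace(p)
        np.testing.assert_array_equal(a.amplitude_mm, b.amplitude_mm)
        assert (a.amplitude_mm >= 0).all() and (a.amplitude_mm < 100).all()

    def test_invalid_ma_rejected(self):
        with pytest.raises(CoagKitError):
            TEGSimParams(ma_mm=100.0)


class TestConcentrationResponseFit:
    def test_noise_free_data_recovered_exactly(self):
        p = ClotSimParams(noise_cv=0.0, seed=0)
        fit = fit_concentration_response(simulate_clotting_curve(p))
        assert fit.converged
        assert fit.ec50_ug_ml == pytest.approx(p.ec50_ug_ml, rel=1e-3)
        assert fit.t_spont_s == pytest.approx(p.t_spont_s, rel=1e-3)
        assert fit.t_floor_s == pytest.approx(p.t_floor_s, rel=1e-3)
        assert fit.hill == pytest.approx(p.hill, rel=1e-3)

    def test_all_censored_curve_flagged_not_raised(self):
        p = ClotSimParams(direction="anticoagulant", t_spont_s=998.0,
                          t_floor_s=1.0, noise_cv=0.0, seed=0)
        curve = simulate_clotting_curve(p)
        assert all(m.censored for m in curve.measurements)
        fit = fit_concentration_response(curve)
        assert not fit.converged
        assert "uncensored" in fit.message

    def test_deterministic_given_data(self):
        curve = simulate_clotting_curve(ClotSimParams(seed=2))
        f1 = fit_concentration_response(curve)
        f2 = fit_concentration_response(curve)
        assert f1 == f2
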