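"""The analysis chain: calibration inversion, stage segmentation,
exponential regression, P and K recovery, replicate aggregation."""

import numpy as np
import pytest

import lipoperm as lp
from lipoperm.fitting import FitError


class TestIntensityToConcentration:
    def test_inverse_of_generator_calibration(self, clean_trace, calib, kin, geom):
        c = lp.intensity_to_concentration(clean_trace, calib)
        # re-apply the calibration: exact round trip (noise-free)
        np.testing.assert_allclose(calib.intensity(c), clean_trace.F, rtol=1e-9)

    def test_intercept_maps_to_zero_and_clipping(self, calib):
        tr = lp.FluorescenceTrace(
            t=np.arange(10.0),
            F=np.full(10, calib.intercept) + np.r_[np.zeros(5), -np.ones(5)],
            T=np.full(10, 25.0),
        )
        c = lp.intensity_to_concentration(tr, calib)
        assert np.all(c[:5] == 0.0)
        assert np.all(c[5:] == 0.0)  # negative excursions clipped

    def test_fully_saturated_trace_rejected(self, calib):
        F = np.full(20, calib.intensity(calib.linear_max * 2))
        tr = lp.FluorescenceTrace(t=np.arange(20.0), F=F, T=np.full(20, 25.0))
        with pytest.raises(FitError):
            lp.intensity_to_concentration(tr, calib)


class TestSegmentation:
    def test_inflection_near_heating_lag_end(self, clean_trace):
        marks = lp.segment_stages(clean_trace)
        ramp_end_idx = int(clean_trace.heat_onset + 60.0)  # dt = 1 s
        assert abs(marks.inflection - ramp_end_idx) <= 5
        assert not marks.release_absent

    def test_flat_trace_release_absent(self, pop, protocol, calib):
        p = lp.KineticParams(P_fluid=0.0, P_gel=0.0, K_app=1e4)
        rec = lp.ExperimentRecipe("flat", noise_sd=0.0)
        tr = lp.generate_trace(rec, p, pop, protocol, calib)
        marks = lp.segment_stages(tr)
        assert marks.release_absent

    def test_triton_jump_detected_without_marker(self, clean_trace):
        from dataclasses import replace

        unmarked = replace(clean_trace, triton_time=None, heat_onset=None)
        marks = lp.segment_stages(unmarked)
        true_idx = int(np.searchsorted(clean_trace.t, clean_trace.triton_time))
        assert abs(marks.triton - true_idx) <= 1

    def test_ethanol_staircase_segments_cleanly(self, kin, pop, protocol, calib):
        """Stepwise lysis traces segment without error; the detergent jump
        is the final one."""
        tr = lp.generate_ethanol_steps(3, 0.3, kin, pop, protocol, calib)
        marks = lp.segment_stages(tr)
        assert tr.t[marks.triton] == pytest.approx(tr.triton_time)

    def test_no_jump_no_marker_raises(self, calib):
        rng = np.random.default_rng(0)
        tr = lp.FluorescenceTrace(
            t=np.arange(200.0),
            F=50.0 + rng.normal(0, 0.5, 200),
            T=np.full(200, 25.0),
        )
        with pytest.raises(lp.SegmentationError):
            lp.segment_stages(tr)


class TestRelativeRelease:
    @pytest.mark.parametrize(
        "c,expected", [(2.0, 0.0), (66.0, 1.0), (34.0, 0.5)]
    )
    def test_anchors(self, c, expected):
        rel = lp.relative_release(np.array([c]), c0=2.0, c_triton=66.0)
        assert rel[0] == pytest.approx(expected)

    def test_degenerate_trace_rejected(self):
        with pytest.raises(ValueError):
            lp.relative_release(np.array([1.0]), c0=5.0, c_triton=5.0)

    def test_bounded_for_noisy_trace(self, kin, pop, protocol, calib, geom):
        rec = lp.ExperimentRecipe("noisy", seed=3)
        tr = lp.generate_trace(rec, kin, pop, protocol, calib)
        c = lp.intensity_to_concentration(tr, calib)
        marks = lp.segment_stages(tr)
        c0 = c[: marks.baseline[1]].mean()
        c_triton = c[marks.triton + 1 :].mean()
        rel = lp.relative_release(c, c0, c_triton)
        noise_c = 0.005 * calib.intensity(c_triton) / calib.slope
        eps = 3 * noise_c / (c_triton - c0)
        assert rel.min() >= -eps and rel.max() <= 1 + eps


class TestExponentialFit:
    def test_recovers_rate_exactly_noise_free(self, geom):
        k = 4.2e-3
        t = np.arange(0.0, 800.0)
        c = lp.closed_form_release(k, geom, 7500.0, 1.0, t)
        fit = lp.fit_exponential(t, c)
        assert fit.b == pytest.approx(k, rel=5e-3)
        assert fit.converged

    def test_noisy_rate_within_ten_percent(self, geom):
        k = 4.2e-3
        t = np.arange(0.0, 800.0)
        rng = np.random.default_rng(11)
        c = lp.closed_form_release(k, geom, 7500.0, 1.0, t) + rng.normal(0, 0.34, t.size)
        fit = lp.fit_exponential(t, c)
        assert fit.b == pytest.approx(k, rel=0.10)

    def test_constant_input_rejected(self):
        with pytest.raises(FitError):
            lp.fit_exponential(np.arange(100.0), np.full(100, 3.0))

    def test_window_restriction(self, geom):
        k = 1e-3
        t = np.arange(0.0, 2000.0)
        c = lp.closed_form_release(k, geom, 7500.0, 1.0, t)
        fit = lp.fit_exponential(t, c, window=(500.0, 1500.0))
        assert fit.b == pytest.approx(k, rel=1e-2)


class TestDerivedQuantities:
    def test_permeability_inverse_pair(self, geom):
        """permeability_from_fit is the exact inverse of rate_constant."""
        for b in (1e-4, 4.2e-3, 3e-2):
            P = lp.permeability_from_fit(b, geom)
            assert lp.rate_constant(P, geom) == pytest.approx(b, rel=1e-9)

    def test_permeability_linearity(self, geom):
        assert lp.permeability_from_fit(8.4e-3, geom) == pytest.approx(
            2 * lp.permeability_from_fit(4.2e-3, geom), rel=1e-12
        )

    def test_thin_shell_permeability_scale(self):
        """P ≈ b·d_Sauter/6 · V_out/V_aq for thin-shell monodisperse vesicles."""
        pop = lp.LiposomePopulation(size_median=200.0, d_mem=0.05, lipid_conc_stock=0.03)
        g = lp.assay_geometry(pop, lp.MixingProtocol())
        b = 4.2e-3
        expected = b * (200e-7) / 6 * g.V_out / g.V_aq
        assert lp.permeability_from_fit(b, g) == pytest.approx(expected, rel=1e-2)

    def test_partition_toy_example(self, geom):
        """c_triton = 6, c_fin = 1 at V_aq/V_lip = 5000 gives K = 25 000."""
        from dataclasses import replace

        g = replace(geom, V_lip=geom.V_aq / 5000.0)
        assert lp.partition_from_plateau(1.0, 6.0, g) == pytest.approx(25000.0, rel=1e-9)

    def test_no_retention_gives_zero(self, geom):
        assert lp.partition_from_plateau(5.0, 5.0, geom) == 0.0

    def test_zero_plateau_rejected(self, geom):
        with pytest.raises(FitError):
            lp.partition_from_plateau(0.0, 5.0, geom)


class TestFullChain:
    def test_noise_free_round_trip(self, clean_trace, calib, geom):
        """The complete chain recovers the generator's P and K within 1%."""
        fit = lp.fit_release(clean_trace, calib, geom)
        assert fit.P == pytest.approx(clean_trace.true_P, rel=1e-2)
        assert fit.K == pytest.approx(clean_trace.true_K, rel=1e-2)
        assert fit.c0 <= fit.c_fin <= fit.c_triton

    def test_condition_aggregation_noise_free(self, kin, pop, protocol, calib, geom):
        rec = lp.ExperimentRecipe("CF alone", noise_sd=0.0, replicates=3)
        traces = [
            lp.generate_trace(rec, kin, pop, protocol, calib, replicate_id=j)
            for j in range(3)
        ]
        s = lp.fit_condition(traces, calib, geom)
        assert s.n == 3
        assert s.P_sd == pytest.approx(0.0, abs=1e-15)
        assert s.K_sd == pytest.approx(0.0, abs=1e-9)

    def test_mixed_success_keeps_good_replicates(self, kin, pop, protocol, calib, geom):
        good = lp.ExperimentRecipe("mix", noise_sd=0.0)
        flat_params = lp.KineticParams(P_fluid=0.0, P_gel=0.0, K_app=2.9e4)
        traces = [
            lp.generate_trace(good, kin, pop, protocol, calib, replicate_id=0),
            lp.generate_trace(good, kin, pop, protocol, calib, replicate_id=1),
            lp.generate_trace(good, flat_params, pop, protocol, calib, replicate_id=2),
        ]
        with pytest.warns(UserWarning, match="replicates failed"):
            s = lp.fit_condition(traces, calib, geom)
        assert s.n == 2
        assert sum(st == "ok" for st in s.statuses) == 2

    def test_all_failing_raises(self, pop, protocol, calib, geom):
        flat = lp.KineticParams(P_fluid=0.0, P_gel=0.0, K_app=2.9e4)
        rec = lp.ExperimentRecipe("flat", noise_sd=0.0)
        traces = [
            lp.generate_trace(rec, flat, pop, protocol, calib, replicate_id=j)
            for j in range(2)
        ]
        with pytest.raises(FitError):
            lp.fit_condition(traces, calib, geom)

    def test_noise_bias_small_and_sd_scales(self, kin, pop, protocol, calib, geom):
        """Across replicates the recovered rate is nearly unbiased and its
        spread grows with the noise level."""
        spreads = {}
        for noise in (0.5, 2.0):
            Ps = []
            for j in range(6):
                rec = lp.ExperimentRecipe("n", noise_sd=noise, seed=17)
                rng = np.random.default_rng(np.random.SeedSequence([17, int(noise * 10), j]))
                tr = lp.generate_trace(rec, kin, pop, protocol, calib, rng=rng)
                Ps.append(lp.fit_release(tr, calib, geom).P)
            Ps = np.array(Ps)
            assert Ps.mean() == pytest.approx(1.4e-8, rel=0.02)
            spreads[noise] = Ps.std()
        assert spreads[2.0] > spreads[0.5]
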