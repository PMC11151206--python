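"""Synthetic-trace generators: four-stage structure, determinism,
mass accounting, enhancer/titration/scan scenarios."""

import numpy as np
import pytest

import lipoperm as lp


class TestGenerateTrace:
    def test_frozen_membrane_flat_until_triton(self, pop, protocol, calib):
        p = lp.KineticParams(P_fluid=0.0, P_gel=0.0, K_app=0.0)
        rec = lp.ExperimentRecipe("flat", noise_sd=0.0, free_fraction=0.0)
        tr = lp.generate_trace(rec, p, pop, protocol, calib)
        pre = tr.F[tr.t < tr.triton_time]
        assert np.ptp(pre) == pytest.approx(0.0, abs=1e-9)
        assert tr.F[-1] > pre[-1]  # single Triton step

    def test_four_stages_present(self, clean_trace, calib):
        """Baseline, release, plateau below the Triton level, dequench."""
        tr = clean_trace
        c = calib.concentration(tr.F)
        base = c[tr.t < tr.heat_onset].mean()
        plateau = c[(tr.t > tr.triton_time - 60) & (tr.t < tr.triton_time)].mean()
        triton = c[tr.t > tr.triton_time].mean()
        assert base < 0.2 * plateau
        assert plateau < 0.25 * triton  # membrane retention: plateau ≪ 100%

    def test_post_inflection_segment_matches_closed_form(
        self, clean_trace, kin, geom, calib
    ):
        """After the heating lag the trace is the exact exponential."""
        tr = clean_trace
        ramp_end = tr.heat_onset + 60.0
        sel = (tr.t >= ramp_end) & (tr.t < tr.triton_time)
        c = calib.concentration(tr.F[sel])
        k = lp.rate_constant(lp.permeability_at(kin, 40.0), geom)
        # closed form anchored at the first post-ramp sample; the aqueous
        # equilibrium is (total aqueous dye)/V_aq with 10% free at t=0
        t_rel = tr.t[sel] - tr.t[sel][0]
        m_aq = geom.V_in * 1e-3 * 7500.0 / 0.9
        c_eq = m_aq / (geom.V_aq * 1e-3)
        expected = c_eq - (c_eq - c[0]) * np.exp(-k * t_rel)
        np.testing.assert_allclose(c, expected, rtol=1e-5)

    def test_determinism(self, kin, pop, protocol, calib):
        rec = lp.ExperimentRecipe("CF alone", seed=33)
        tr1 = lp.generate_trace(rec, kin, pop, protocol, calib)
        tr2 = lp.generate_trace(rec, kin, pop, protocol, calib)
        np.testing.assert_array_equal(tr1.F, tr2.F)

    def test_triton_level_accounts_for_all_dye(self, clean_trace, kin, geom, calib):
        """Triton-level concentration × V_aq equals the dispensed dye mass."""
        tr = clean_trace
        c_triton = calib.concentration(tr.F[tr.t > tr.triton_time]).mean()
        v_in, v_out = geom.V_in * 1e-3, geom.V_out * 1e-3
        m_enc = v_in * 7500.0
        m_aq = m_enc / 0.9  # 10% free dye
        c_fin = m_aq / (v_in + v_out)
        m_total = m_aq + kin.K_app * c_fin * geom.V_lip * 1e-3
        assert c_triton * (geom.V_aq * 1e-3) == pytest.approx(m_total, rel=1e-8)

    def test_ground_truth_attached(self, clean_trace, kin):
        assert clean_trace.true_P == pytest.approx(1.4e-8, rel=1e-12)
        assert clean_trace.true_K == pytest.approx(2.9e4, rel=1e-12)


class TestConditionSet:
    def test_replicates_and_labels(self, kin, pop, protocol, calib):
        recipes = lp.panel_recipes(replicates=3, noise_sd=0.0)
        traces = lp.generate_condition_set(kin, recipes, pop, protocol, calib, 5)
        assert len(traces) == 3 * len(lp.REFERENCE_PANEL)
        labels = {t.condition_label for t in traces}
        assert labels == set(lp.REFERENCE_PANEL)

    def test_seed_reproducibility(self, kin, pop, protocol, calib):
        recipes = lp.panel_recipes(replicates=2)[:3]
        a = lp.generate_condition_set(kin, recipes, pop, protocol, calib, 7)
        b = lp.generate_condition_set(kin, recipes, pop, protocol, calib, 7)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.F, tb.F)

    def test_duplicate_labels_rejected(self, kin, pop, protocol, calib):
        recipes = [
            lp.ExperimentRecipe("same"),
            lp.ExperimentRecipe("same", fP=2.0),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            lp.generate_condition_set(kin, recipes, pop, protocol, calib, 1)

    def test_reference_required(self, kin, pop, protocol, calib):
        recipes = [lp.ExperimentRecipe("only", fP=2.0, fK=2.0)]
        with pytest.raises(ValueError, match="reference"):
            lp.generate_condition_set(kin, recipes, pop, protocol, calib, 1)


class TestEnhancerScenarios:
    def test_ethanol_geometric_release(self, kin, pop, protocol, calib):
        """Three 30% lysis steps release 1 − 0.7³ = 65.7% of encapsulated dye."""
        tr = lp.generate_ethanol_steps(3, 0.3, kin, pop, protocol, calib)
        g = lp.assay_geometry(pop, protocol)
        c = calib.concentration(tr.F)
        pre_triton = c[tr.t < tr.triton_time]
        released = (pre_triton[-1] - c[0]) * g.V_aq * 1e-3
        v_in = g.V_in * 1e-3
        m_enc = v_in * 7500.0
        c_fin = (m_enc / 0.9) / (g.V_aq * 1e-3)
        m_releasable = m_enc + kin.K_app * c_fin * g.V_lip * 1e-3
        assert released / m_releasable == pytest.approx(1 - 0.7**3, rel=1e-9)
        assert len(tr.addition_times) == 3
        assert np.all(np.diff(c) >= -1e-12)  # non-decreasing staircase

    def test_single_total_lysis_reaches_triton_level(self, kin, pop, protocol, calib):
        tr = lp.generate_ethanol_steps(1, 1.0, kin, pop, protocol, calib)
        c = calib.concentration(tr.F)
        after_step = c[(tr.t > tr.addition_times[0]) & (tr.t < tr.triton_time)]
        assert after_step[0] == pytest.approx(c[-1], rel=1e-12)

    def test_oleic_acid_slow_release_still_rising(self, kin, pop, protocol, calib):
        """The printed enhanced permeability releases only partially in 10 h."""
        tr = lp.generate_oleic_acid(6.3e-10, kin, pop, protocol, calib)
        c = calib.concentration(tr.F)
        pre = c[tr.t < tr.triton_time]
        d = np.diff(pre[-100:])
        assert np.all(np.diff(pre) >= -1e-12)
        assert d.mean() > 0  # still rising at the end of the run
        g = lp.assay_geometry(pop, protocol)
        k = lp.rate_constant(6.3e-10, g)
        c_eq = (g.V_in * 7500.0 + g.V_out * pre[0]) / (g.V_in + g.V_out)
        expected = c_eq - (c_eq - pre[0]) * np.exp(-k * (36000.0))
        assert pre[-1] == pytest.approx(expected, rel=1e-3)

    def test_zero_enhancement_is_flat(self, kin, pop, protocol, calib):
        tr = lp.generate_oleic_acid(0.0, kin, pop, protocol, calib)
        pre = tr.F[tr.t < tr.triton_time]
        assert np.ptp(pre) == pytest.approx(0.0, abs=1e-9)


class TestTitration:
    def test_no_partitioning_no_drop(self, pop, calib):
        tr = lp.generate_titration((20.0, 20.0), 5.0, 0.0, pop, calib)
        assert np.ptp(tr.F) == pytest.approx(0.0, abs=1e-9)

    def test_successive_drops_decreasing(self, pop, calib):
        tr = lp.generate_titration((20.0, 20.0, 20.0), 5.0, 2.9e4, pop, calib)
        c = calib.concentration(tr.F)
        levels = [c[0]]
        for t_add in tr.addition_times:
            levels.append(c[np.searchsorted(tr.t, t_add) + 5])
        drops = -np.diff(levels)
        assert np.all(drops > 0)
        assert np.all(np.diff(drops) < 0)
        # bound-fraction formula per step
        g_lip = 20.0 * pop.lipid_conc_stock * 1e-3
        for n, lvl in enumerate(levels[1:], start=1):
            assert lvl == pytest.approx(5.0 * 1200.0 / (1200.0 + 2.9e4 * n * g_lip), rel=1e-9)

    def test_triton_restores_original_intensity(self, pop, calib):
        tr = lp.generate_titration((20.0, 20.0, 20.0), 5.0, 2.9e4, pop, calib)
        assert tr.F[-1] == pytest.approx(tr.F[0], rel=1e-12)


class TestTemperatureScan:
    def test_normalized_maximum(self, kin, pop, protocol, calib):
        tr = lp.generate_temperature_scan(kin, pop, protocol, calib)
        assert tr.F.max() == pytest.approx(1.0)

    def test_tm_shift_moves_half_release(self, kin, pop, protocol, calib):
        """A +3 °C melting shift moves the half-release temperature ≈ +3 °C."""

        def half_T(trace):
            Fn = trace.F / trace.F.max()
            target = (Fn.min() + 1.0) / 2
            return trace.T[np.argmax(Fn >= target)]

        base = lp.generate_temperature_scan(kin, pop, protocol, calib)
        shifted_params = lp.KineticParams(
            P_fluid=kin.P_fluid, P_gel=kin.P_gel, T_m=kin.T_m + 3.0,
            T_width=kin.T_width, K_app=kin.K_app,
        )
        shifted = lp.generate_temperature_scan(shifted_params, pop, protocol, calib)
        assert half_T(shifted) - half_T(base) == pytest.approx(3.0, abs=0.5)

    def test_no_transition_feature_when_P_constant(self, pop, protocol, calib):
        p = lp.KineticParams(P_fluid=1e-8, P_gel=1e-8, K_app=2.9e4)
        tr = lp.generate_temperature_scan(p, pop, protocol, calib)
        c = np.asarray(tr.F, dtype=float)
        d = np.diff(c)
        # release rate decays monotonically: no sigmoidal acceleration
        assert np.argmax(d) < 10
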