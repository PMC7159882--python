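import numpy as np
import pytest

from cardiopufa import effects, synth, tevc
from cardiopufa.synth import PufaEffectProfile


def _iks_family(compound=None, concs=(0.0, 7.0), noise=0.0, seed=0):
    p = synth.default_params("IKs")
    eff = (PufaEffectProfile.from_compound(compound, "IKs") if compound
           else PufaEffectProfile.identity("IKs"))
    return synth.generate_iks_family(p, eff, concs, noise, seed), eff


class TestTailGV:
    def test_curve_matches_generating_boltzmann_up_to_scale(self):
        fam, _ = _iks_family()
        curve = tevc.measure_tail_gv(fam)[0.0]
        p = synth.default_params("IKs")
        po = p.act_po(curve.voltages)
        # affine match (tail deactivates toward the -20 mV steady level)
        A = np.vstack([po, np.ones_like(po)]).T
        resid = np.linalg.lstsq(A, curve.values, rcond=None)[1]
        assert float(resid[0]) < 1e-10 * np.sum(curve.values ** 2)

    def test_lin_taurine_curve_left_shifted_and_larger(self):
        fam, eff = _iks_family("Lin-taurine", concs=(0.0, 20.0))
        curves = tevc.measure_tail_gv(fam)
        from cardiopufa.boltzmann import fit_boltzmann
        f0 = fit_boltzmann(curves[0.0].voltages, curves[0.0].values)
        f20 = fit_boltzmann(curves[20.0].voltages, curves[20.0].values)
        assert f20.v05 < f0.v05
        assert f20.amplitude > f0.amplitude

    def test_window_outside_tail_rejected(self):
        fam, _ = _iks_family()
        with pytest.raises(ValueError):
            tevc.measure_tail_gv(fam, window_ms=(400.0, 600.0))

    def test_window_averaging_consistent_with_midpoint_sample(self):
        fam, _ = _iks_family(noise=0.02, seed=3)
        t0 = fam.segments["tail"][0]
        win = (5.0, 25.0)
        curves = tevc.measure_tail_gv(fam, win)
        t = fam.time_ms
        mid = np.argmin(np.abs(t - (t0 + 15.0)))
        n_win = np.count_nonzero((t >= t0 + win[0]) & (t < t0 + win[1]))
        base_sel = t >= fam.segments["tail"][1] - 50.0
        single = fam.currents[0, :, mid] - fam.currents[0, :, base_sel].mean(axis=0)
        # window mean and single-sample estimates agree within noise scaling
        assert np.all(np.abs(curves[0.0].values - single)
                      < 6.0 * 0.02 / np.sqrt(n_win) + 6.0 * 0.02)


class TestAvailability:
    def test_control_anchor_is_one(self):
        p = synth.default_params("INa")
        fam = synth.generate_nav_family(p, PufaEffectProfile.identity("INa"),
                                        [0.0], 0.0, 0, kind="inactivation")
        curve = tevc.measure_availability(fam)[0.0]
        assert curve.values[0] == pytest.approx(1.0, abs=1e-9)

    def test_mixed_protocol_rejected(self):
        p = synth.default_params("INa")
        fam = synth.generate_nav_family(p, PufaEffectProfile.identity("INa"),
                                        [0.0], 0.0, 0, kind="activation")
        with pytest.raises(ValueError):
            tevc.measure_availability(fam)
        with pytest.raises(ValueError):
            tevc.measure_peak_iv(
                synth.generate_nav_family(p, PufaEffectProfile.identity("INa"),
                                          [0.0], 0.0, 0, kind="inactivation"))


class TestCurrentRatio:
    def test_control_ratio_exactly_one(self):
        fam, _ = _iks_family()
        pts = tevc.current_ratio_at_0mV(fam)
        assert pts[0].concentration_uM == 0.0
        assert pts[0].ratio == 1.0

    def test_ratio_invariant_to_global_gain(self):
        fam, _ = _iks_family("DHA-taurine")
        pts1 = tevc.current_ratio_at_0mV(fam)
        fam.currents = fam.currents * 3.7
        pts2 = tevc.current_ratio_at_0mV(fam)
        for a, b in zip(pts1, pts2):
            assert a.ratio == pytest.approx(b.ratio, rel=1e-12)

    def test_missing_zero_mv_step_rejected(self):
        p = synth.default_params("INa")
        proto = synth.VoltageProtocol(kind="activation", holding_mV=-80,
                                      test_mV=(-35.0, -25.0, -15.0, -5.0, 5.0),
                                      test_ms=50.0)
        fam = synth.generate_nav_family(p, PufaEffectProfile.identity("INa"),
                                        [0.0], 0.0, 0, kind="activation",
                                        protocol=proto)
        with pytest.raises(ValueError):
            tevc.current_ratio_at_0mV(fam)


ALL_COMPOUNDS = list(effects.COMPOUNDS)


class TestForwardInverse:
    @pytest.mark.parametrize("compound", ALL_COMPOUNDS)
    def test_iks_noiseless_recovery(self, compound):
        """Noiseless pipeline recovers every printed 7 uM IKs truth to
        0.5 mV (dV05) and 1% (Gmax ratio)."""
        fam, eff = _iks_family(compound)
        s = tevc.analyze_activation_family(fam)
        row = s.table[s.table.concentration_uM == 7.0].iloc[0]
        assert row.dv05_mV == pytest.approx(eff.dv05(7.0), abs=0.5)
        assert row.gmax_ratio == pytest.approx(eff.gmax_factor(7.0), rel=0.01)

    @pytest.mark.parametrize("compound", ALL_COMPOUNDS)
    def test_nav_noiseless_recovery(self, compound):
        p = synth.default_params("INa")
        eff = PufaEffectProfile.from_compound(compound, "INa")
        fam = synth.generate_nav_family(p, eff, [0.0, 7.0], 0.0, 0,
                                        kind="inactivation")
        s = tevc.analyze_availability_family(fam)
        row = s.table[s.table.concentration_uM == 7.0].iloc[0]
        assert row.dv05_mV == pytest.approx(eff.dv05(7.0), abs=0.5)
        assert row.gmax_ratio == pytest.approx(eff.gmax_factor(7.0), rel=0.01)

    def test_order_preservation_of_shifts(self):
        """A more-left-shifted generating dV05 never yields a less-left-
        shifted estimate on noiseless data."""
        p = synth.default_params("IKs")
        shifts = [-5.0, -15.0, -30.0, -45.0]
        est = []
        for sh in shifts:
            eff = PufaEffectProfile("IKs", km_uM=5.0, dv05_sat_mV=sh / 0.5833,
                                    gmax_sat=1.0)
            fam = synth.generate_iks_family(p, eff, [0.0, 7.0], 0.0, 0)
            s = tevc.analyze_activation_family(fam)
            est.append(s.table[s.table.concentration_uM == 7.0].dv05_mV.iloc[0])
        assert all(a > b for a, b in zip(est, est[1:]))


class TestReplicates:
    def test_sem_across_replicate_families(self):
        p = synth.default_params("IKs")
        eff = PufaEffectProfile.from_compound("Pin-taurine", "IKs")
        summaries = [tevc.analyze_activation_family(
            synth.generate_iks_family(p, eff, [0.0, 7.0], 0.01, seed=s))
            for s in range(4)]
        rep = tevc.summarize_replicates(summaries)
        assert set(rep.n) == {4}
        row = rep[rep.concentration_uM == 7.0].iloc[0]
        assert row.dv05_mV_mean == pytest.approx(eff.dv05(7.0), abs=1.0)
        assert row.dv05_mV_sem > 0
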