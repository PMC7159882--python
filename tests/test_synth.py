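import numpy as np
import pytest

from cardiopufa import synth
from cardiopufa.synth import (CAV_INACTIVATION, IKS_ACTIVATION,
                              NAV_ACTIVATION, NAV_INACTIVATION, CaTParams,
                              PufaEffectProfile, VoltageProtocol,
                              generate_cat_trace, generate_cav_family,
                              generate_iks_family, generate_nav_family)


class TestProtocols:
    def test_iks_steps_match_recording_protocol(self):
        assert IKS_ACTIVATION.holding_mV == -80.0
        assert IKS_ACTIVATION.prepulse_mV == (-140.0,)
        assert list(IKS_ACTIVATION.test_mV) == list(range(-100, 61, 20))
        assert IKS_ACTIVATION.tail_mV == -20.0

    def test_nav_and_cav_steps(self):
        assert list(NAV_ACTIVATION.test_mV) == list(range(-90, 41, 10))
        assert list(NAV_INACTIVATION.prepulse_mV) == list(range(-140, -29, 10))
        assert NAV_INACTIVATION.test_mV == (-30.0,)
        assert list(CAV_INACTIVATION.prepulse_mV) == list(range(-80, 21, 10))
        assert CAV_INACTIVATION.test_mV == (10.0,)
        assert CAV_INACTIVATION.prepulse_ms == 500.0

    def test_tail_voltage_present_iff_tail_kind(self):
        with pytest.raises(ValueError):
            VoltageProtocol(kind="activation", holding_mV=-80,
                            test_mV=(-10.0, 0.0), test_ms=50.0, tail_mV=-20.0)
        with pytest.raises(ValueError):
            VoltageProtocol(kind="tail", holding_mV=-80,
                            test_mV=(-10.0, 0.0), test_ms=50.0)

    def test_swept_voltages_strictly_increasing(self):
        with pytest.raises(ValueError):
            VoltageProtocol(kind="activation", holding_mV=-80,
                            test_mV=(0.0, -10.0), test_ms=50.0)


class TestIKsFamily:
    def test_noiseless_tails_proportional_to_boltzmann(self, iks_params):
        eff = PufaEffectProfile.identity("IKs")
        fam = generate_iks_family(iks_params, eff, [0.0], 0.0, seed=0)
        t0 = fam.segments["tail"][0]
        i_tail0 = fam.currents[0, :, np.searchsorted(fam.time_ms, t0)]
        po = iks_params.act_po(fam.swept_mV)
        scale = i_tail0 / po
        assert np.allclose(scale, scale[0], rtol=1e-6)

    def test_effect_shifts_and_scales_tail_gv(self, iks_params):
        eff = PufaEffectProfile("IKs", km_uM=5.0, dv05_sat_mV=-60.0,
                                gmax_sat=2.5)
        fam = generate_iks_family(iks_params, eff, [0.0, 7.0], 0.0, seed=0)
        truth = fam.truth["per_concentration"][7.0]
        assert truth["dv05_mV"] == pytest.approx(eff.dv05(7.0))
        # shifted curve has larger tail at a mid voltage
        vi = list(fam.swept_mV).index(-20.0)
        t0 = fam.segments["tail"][0]
        k = np.searchsorted(fam.time_ms, t0)
        assert fam.currents[1, vi, k] > fam.currents[0, vi, k]

    def test_seeded_reproducibility(self, iks_params):
        eff = PufaEffectProfile.identity("IKs")
        a = generate_iks_family(iks_params, eff, [0.0, 7.0], 0.05, seed=11)
        b = generate_iks_family(iks_params, eff, [0.0, 7.0], 0.05, seed=11)
        assert np.array_equal(a.currents, b.currents)
        c = generate_iks_family(iks_params, eff, [0.0, 7.0], 0.05, seed=12)
        assert not np.array_equal(a.currents, c.currents)

    def test_negative_noise_rejected(self, iks_params):
        with pytest.raises(ValueError):
            generate_iks_family(iks_params, PufaEffectProfile.identity("IKs"),
                                [0.0], -0.1, seed=0)

    def test_unknown_table_concentration_rejected(self, iks_params):
        eff = PufaEffectProfile("IKs", dv05_table={7.0: -10.0},
                                gmax_table={7.0: 1.5})
        with pytest.raises(KeyError):
            generate_iks_family(iks_params, eff, [0.0, 2.0], 0.0, seed=0)


class TestPeakFamilies:
    def test_nav_peaks_match_closed_form(self, nav_params):
        """Pointwise oracle: the sampled peak equals the closed-form
        g*a(V)*(V - Erev) at every test voltage."""
        eff = PufaEffectProfile.identity("INa")
        fam = generate_nav_family(nav_params, eff, [0.0], 0.0, seed=0,
                                  kind="activation")
        peaks = np.array([fam.currents[0, vi][np.argmax(np.abs(fam.currents[0, vi]))]
                          for vi in range(len(fam.swept_mV))])
        expected = (nav_params.gmax * nav_params.act_po(fam.swept_mV)
                    * (fam.swept_mV - nav_params.Erev))
        assert np.allclose(peaks, expected, rtol=1e-12, atol=1e-12)

    def test_full_availability_at_most_negative_prepulse(self, nav_params):
        eff = PufaEffectProfile("INa", km_uM=2.0, dv05_sat_mV=-40.0)
        fam = generate_nav_family(nav_params, eff, [0.0, 7.0], 0.0, seed=0,
                                  kind="inactivation")
        # at -140 mV prepulse h -> 1: remaining current equals the
        # unconditioned test current for any g_factor = 1 effect
        vtest = fam.protocol.test_mV[0]
        expected = abs(nav_params.gmax * float(nav_params.act_po(vtest))
                       * (vtest - nav_params.Erev)
                       * float(nav_params.avail(-140.0)))
        assert np.abs(fam.currents[0, 0]).max() == pytest.approx(expected, rel=1e-6)
        # the shifted curve still sits in the saturated Boltzmann tail
        assert np.abs(fam.currents[1, 0]).max() == pytest.approx(
            np.abs(fam.currents[0, 0]).max(), rel=0.05)

    def test_cav_identity_availability_matches_boltzmann(self, cav_params):
        eff = PufaEffectProfile.identity("ICaL")
        fam = generate_cav_family(cav_params, eff, [0.0], 0.0, seed=0,
                                  kind="inactivation")
        peaks = np.abs(fam.currents[0]).max(axis=1)
        h = cav_params.avail(fam.swept_mV)
        scale = peaks / h
        assert np.allclose(scale, scale[0], rtol=1e-9)

    def test_kind_protocol_mismatch_rejected(self, nav_params):
        with pytest.raises(ValueError):
            generate_nav_family(nav_params, PufaEffectProfile.identity("INa"),
                                [0.0], 0.0, 0, kind="activation",
                                protocol=NAV_INACTIVATION)


class TestFamilyIO:
    def test_round_trip(self, tmp_path, nav_params):
        eff = PufaEffectProfile("INa", km_uM=2.3, dv05_sat_mV=-35.0,
                                gmax_sat=0.05)
        fam = generate_nav_family(nav_params, eff, [0.0, 7.0], 0.01, seed=5,
                                  kind="inactivation", sampling_ms=0.5)
        csv_path, yaml_path = synth.write_family(fam, tmp_path, stem="nav")
        back = synth.read_family(csv_path, yaml_path)
        assert back.channel_id == "INa"
        assert back.protocol.kind == "inactivation"
        assert np.allclose(back.currents, fam.currents, atol=1e-6)
        assert tuple(back.concentrations_uM) == (0.0, 7.0)


class TestCaT:
    def test_zero_jitter_period_and_frequency(self):
        rec = generate_cat_trace(CaTParams(jitter_sd_s=0.0, noise_sd=0.0),
                                 seed=0)
        beats = rec.truth["beat_times_s"]
        assert np.allclose(np.diff(beats), 1.25)
        assert 1.0 / np.diff(beats)[0] == pytest.approx(0.8)

    def test_duration_must_cover_three_beats(self):
        with pytest.raises(ValueError):
            CaTParams(duration_s=2.0, period_s=1.25)

    def test_decay_slower_than_rise_enforced(self):
        with pytest.raises(ValueError):
            CaTParams(tau_rise_ms=200.0, tau_decay_ms=100.0)

    def test_seeded_reproducibility(self):
        a = generate_cat_trace(CaTParams(), seed=4)
        b = generate_cat_trace(CaTParams(), seed=4)
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.truth["beat_times_s"], b.truth["beat_times_s"])

    def test_cat_io_round_trip(self, tmp_path):
        rec = generate_cat_trace(CaTParams(duration_s=5.0), seed=2)
        path = tmp_path / "cat.txt"
        synth.write_cat(rec, path)
        back = synth.read_cat(path)
        assert back.fs_hz == pytest.approx(rec.fs_hz, rel=1e-3)
        assert np.allclose(back.signal, rec.signal, atol=1e-5)
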