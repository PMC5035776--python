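"""Synaptic templates, convolution, amplitude sampling, modulation."""

import math

import numpy as np
import pytest
from scipy import stats

from sbcsim.model import SimulationConfig, build_default_sbc, resting_state
from sbcsim.synapses import (EndbulbParams, InhibitionParams,
                             MuscarinicCondition, NicotinicParams,
                             apply_muscarinic, events_to_conductance,
                             make_template, nicotinic_timeline,
                             rise_from_time_to_peak,
                             sample_endbulb_amplitudes,
                             template_peak_time_ms)


class TestTemplate:
    @pytest.mark.parametrize("rise,decay", [(0.1, 0.2), (0.4, 2.0),
                                            (27.0, 461.0)])
    def test_unit_peak_and_nonnegative(self, rise, decay):
        tpl = make_template(rise, decay, 1e-5)
        assert tpl.waveform.max() == 1.0
        assert np.all(tpl.waveform >= 0.0)
        assert tpl.waveform[-1] < 2e-4  # decays towards zero

    def test_peak_time_closed_form(self):
        # t_peak = tr*td/(td-tr)*ln(td/tr) = 0.1386 ms for (0.1, 0.2)
        tpl = make_template(0.1, 0.2, 1e-6)
        t_peak_ms = np.argmax(tpl.waveform) * 1e-3
        assert t_peak_ms == pytest.approx(0.1386, abs=0.002)
        assert template_peak_time_ms(0.1, 0.2) == pytest.approx(
            0.2 * math.log(2.0), rel=1e-12)

    def test_slow_kernel_tail_is_single_exponential(self):
        # past the peak the rise term dies out and the kernel decays
        # with the 461 ms constant: one decay constant further along the
        # tail the amplitude drops by exp(-1)
        tau_r = rise_from_time_to_peak(83.0, 461.0)
        tpl = make_template(tau_r, 461.0, 1e-4)
        dt_ms = 0.1
        i0 = int(np.argmax(tpl.waveform)) + int(round(100.0 / dt_ms))
        i1 = i0 + int(round(461.0 / dt_ms))
        assert tpl.waveform[i1] / tpl.waveform[i0] == pytest.approx(
            math.exp(-1.0), rel=0.01)

    def test_degenerate_kernel_rejected(self):
        with pytest.raises(ValueError, match="rise"):
            make_template(0.3, 0.2, 1e-5)
        with pytest.raises(ValueError, match="rise"):
            make_template(0.2, 0.2, 1e-5)


class TestEventsToConductance:
    def test_single_event_is_shifted_template(self, short_cfg):
        tpl = make_template(0.1, 0.2, short_cfg.dt)
        tl = events_to_conductance(np.array([0.01]), [3.0], tpl, 0.0,
                                   short_cfg)
        i0 = int(round(0.01 / short_cfg.dt))
        n = tpl.n_samples
        assert np.allclose(tl.g[i0:i0 + n], 3.0 * tpl.waveform)
        assert np.all(tl.g[:i0] == 0.0)

    def test_disjoint_events_keep_their_amplitudes(self, short_cfg):
        tpl = make_template(0.1, 0.2, short_cfg.dt)
        tl = events_to_conductance(np.array([0.01, 0.03]), [2.0, 5.0], tpl,
                                   0.0, short_cfg)
        assert tl.g[:int(0.02 / short_cfg.dt)].max() == pytest.approx(2.0)
        assert tl.g.max() == pytest.approx(5.0)

    def test_matches_brute_force_summation(self, short_cfg, rng):
        """Overlapping random events equal a direct summation oracle."""
        tpl = make_template(0.1, 0.5, short_cfg.dt)
        events = np.sort(rng.uniform(0.0, 0.04, size=20))
        amps = rng.uniform(10.0, 60.0, size=20)
        tl = events_to_conductance(events, amps, tpl, 0.0, short_cfg)
        nt = short_cfg.n_steps + 1
        t_grid = np.arange(nt) * short_cfg.dt
        oracle = np.zeros(nt)
        for t0, a in zip(events, amps):
            for j, tg in enumerate(t_grid):
                k = int(round((tg - t0) / short_cfg.dt))
                if 0 <= k < tpl.n_samples and \
                        int(round(t0 / short_cfg.dt)) + k == j:
                    oracle[j] += a * tpl.waveform[k]
        assert np.allclose(tl.g, oracle, atol=1e-9)

    def test_linearity_over_event_union(self, short_cfg, rng):
        tpl = make_template(0.1, 0.5, short_cfg.dt)
        ev_a = np.sort(rng.uniform(0.0, 0.04, 7))
        ev_b = np.sort(rng.uniform(0.0, 0.04, 5))
        amp_a = rng.uniform(1, 5, 7)
        amp_b = rng.uniform(1, 5, 5)
        g_a = events_to_conductance(ev_a, amp_a, tpl, 0.0, short_cfg).g
        g_b = events_to_conductance(ev_b, amp_b, tpl, 0.0, short_cfg).g
        g_ab = events_to_conductance(np.concatenate([ev_a, ev_b]),
                                     np.concatenate([amp_a, amp_b]),
                                     tpl, 0.0, short_cfg).g
        assert np.allclose(g_ab, g_a + g_b, atol=1e-12)

    def test_out_of_range_event_warns_and_is_dropped(self, short_cfg):
        tpl = make_template(0.1, 0.2, short_cfg.dt)
        with pytest.warns(UserWarning, match="rejected"):
            tl = events_to_conductance(np.array([0.01, 1.0]), [1.0, 1.0],
                                       tpl, 0.0, short_cfg)
        assert tl.g.max() == pytest.approx(1.0)


class TestEndbulbSampler:
    def test_moments_match_published_distribution(self):
        amps = sample_endbulb_amplitudes(100_000, EndbulbParams(), seed=7)
        assert amps.mean() == pytest.approx(55.0, rel=0.01)
        assert amps.std() == pytest.approx(9.0, rel=0.02)
        assert np.all(amps >= 0.0)

    def test_zero_sd_is_degenerate(self):
        p = EndbulbParams(amp_sd_nS=0.0)
        amps = sample_endbulb_amplitudes(100, p, seed=0)
        assert np.all(amps == 55.0)

    def test_distribution_against_truncated_normal(self):
        amps = sample_endbulb_amplitudes(10_000, EndbulbParams(), seed=3)
        # truncation at 0 is ~6 sigma away: plain normal CDF suffices
        stat, p = stats.kstest(amps, "norm", args=(55.0, 9.0))
        assert p > 0.01

    def test_reproducible_per_seed(self):
        a = sample_endbulb_amplitudes(50, EndbulbParams(), seed=11)
        b = sample_endbulb_amplitudes(50, EndbulbParams(), seed=11)
        assert np.array_equal(a, b)


class TestNicotinic:
    def test_peak_amplitude_and_delay(self):
        cfg = SimulationConfig(dt=1e-4, duration=3.0)
        tl = nicotinic_timeline(0.2, NicotinicParams(), cfg)
        assert tl.g.max() == pytest.approx(2.0, rel=1e-6)
        assert np.all(tl.g[cfg.time_grid() < 0.21] == 0.0)
        t_peak = cfg.time_grid()[np.argmax(tl.g)]
        assert t_peak == pytest.approx(0.21 + 0.083, abs=0.002)

    def test_zero_peak_gives_zero_timeline(self):
        cfg = SimulationConfig(dt=1e-4, duration=1.0)
        tl = nicotinic_timeline(0.0, NicotinicParams(peak_nS=0.0), cfg)
        assert np.all(tl.g == 0.0)

    def test_integral_matches_kernel_closed_form(self):
        # integral of the unit-peak kernel is (tau_d - tau_r)/peak_unnorm
        p = NicotinicParams()
        cfg = SimulationConfig(dt=1e-4, duration=6.0)
        tl = nicotinic_timeline(0.0, p, cfg)
        tau_r = rise_from_time_to_peak(p.rise_ms, p.decay_tau_ms)
        t_pk = template_peak_time_ms(tau_r, p.decay_tau_ms)
        peak_unnorm = (math.exp(-t_pk / p.decay_tau_ms)
                       - math.exp(-t_pk / tau_r))
        expected = p.peak_nS * (p.decay_tau_ms - tau_r) / peak_unnorm * 1e-3
        assert np.trapezoid(tl.g, dx=cfg.dt) == pytest.approx(expected,
                                                              rel=0.01)


class TestMuscarinic:
    @pytest.mark.parametrize("label,erev", [("control", -65.0),
                                            ("plus_ach", -55.0),
                                            ("minus_ach", -75.0)])
    def test_condition_mapping(self, default_model, label, erev):
        m = apply_muscarinic(default_model, label)
        assert m.leak_e_rev_mV == erev
        # nothing else altered
        assert m.c_total_pF == default_model.c_total_pF
        assert m.leak_g_total_nS == default_model.leak_g_total_nS

    def test_unknown_label_rejected(self, default_model):
        with pytest.raises(ValueError, match="unknown muscarinic"):
            apply_muscarinic(default_model, "wash_in")

    def test_resting_potential_ordering(self, default_model):
        rmp = {lab: resting_state(apply_muscarinic(default_model, lab))[0]
               for lab in ("minus_ach", "control", "plus_ach")}
        assert rmp["minus_ach"] < rmp["control"] < rmp["plus_ach"]


class TestInhibition:
    def test_off_mode_zeroes_conductance(self):
        p = InhibitionParams(mode="off")
        assert p.effective_g_nS == 0.0
        assert InhibitionParams().effective_g_nS == 24.0

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            InhibitionParams(mode="plastic")
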