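"""Spike statistics: classification, VS/Rayleigh, PSTH, RLF, FRA, jitter."""

import numpy as np
import pytest
from scipy.special import i0, i1

from sbcsim.analysis import (EventDetectionParams, EventLabel,
                             classify_events, compute_psth,
                             compute_rate_level, cycle_metrics,
                             frequency_response_area, jitter, phases,
                             spike_probability)
from sbcsim.anf import SpikeTrain
from sbcsim.model import VoltageTrace


def synthetic_trace(events, dt=1e-5, dur=0.1, rest=-65.0):
    """Trace with AP-like (tall, fast) or EPSP-like bumps after events.

    ``events`` maps input time -> kind ("ap" | "epsp" | None).
    """
    t = np.arange(int(dur / dt) + 1) * dt
    v = np.full_like(t, rest)
    for t0, kind in events.items():
        if kind is None:
            continue
        delay, width, amp = (5e-4, 3e-4, 80.0) if kind == "ap" else \
            (2e-3, 5e-4, 5.0)
        bump = amp * np.exp(-0.5 * ((t - t0 - delay) / width) ** 2)
        bump[t < t0] = 0.0  # causal response
        v += bump
    return VoltageTrace(t=t, v=v, dt=dt)


class TestClassification:
    def test_three_outcomes(self):
        ev = {0.01: "ap", 0.04: "epsp", 0.07: None}
        tr = synthetic_trace(ev)
        labels = classify_events(tr, np.array(sorted(ev)))
        outcomes = [e.outcome for e in labels]
        assert outcomes == ["AP", "EPSP", "complete_failure"]
        ap = labels[0]
        assert ap.ap_time == pytest.approx(0.0105, abs=1e-4)
        assert ap.latency == pytest.approx(5e-4, abs=1e-4)

    def test_ap_assigned_to_nearest_preceding_input(self):
        # two inputs 2 ms apart, single AP after the second; the first
        # input's window is capped at the second input
        tr = synthetic_trace({0.02: None, 0.022: "ap"})
        labels = classify_events(tr, np.array([0.02, 0.022]))
        assert [e.outcome for e in labels] == ["complete_failure", "AP"]

    def test_flat_trace_is_all_failures(self):
        tr = synthetic_trace({})
        labels = classify_events(tr, np.array([0.02, 0.05]))
        assert all(e.outcome == "complete_failure" for e in labels)

    def test_event_outside_trace_rejected(self):
        tr = synthetic_trace({})
        with pytest.raises(ValueError, match="outside"):
            classify_events(tr, np.array([0.5]))


class TestSpikeProbability:
    def test_definition(self):
        labels = ([EventLabel(0.0, "AP", 0.001, 0.001)] * 10
                  + [EventLabel(0.0, "EPSP")] * 10
                  + [EventLabel(0.0, "complete_failure")] * 5)
        assert spike_probability(labels) == pytest.approx(0.5)

    def test_all_aps(self):
        labels = [EventLabel(0.0, "AP", 0.001, 0.001)] * 7
        assert spike_probability(labels) == 1.0

    def test_matches_counting_oracle_on_random_labels(self, rng):
        kinds = rng.choice(["AP", "EPSP", "complete_failure"], size=1000,
                           p=[0.3, 0.5, 0.2])
        labels = [EventLabel(0.0, k, 0.001 if k == "AP" else None,
                             0.001 if k == "AP" else None) for k in kinds]
        n_ap = sum(k == "AP" for k in kinds)
        n_ep = sum(k == "EPSP" for k in kinds)
        assert spike_probability(labels) == pytest.approx(
            n_ap / (n_ap + n_ep))

    def test_no_successful_events_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            spike_probability([EventLabel(0.0, "complete_failure")])


class TestCycleMetrics:
    def test_perfect_locking(self):
        t = 0.3 + np.arange(50) / 250.0  # one spike per cycle, same phase
        m = cycle_metrics(t, 250.0)
        assert m.vs == pytest.approx(1.0)
        # circular comparison of the preferred phase
        assert np.cos(m.preferred_phase
                      - phases(t[:1], 250.0)[0]) == pytest.approx(1.0)
        assert m.significant

    def test_symmetric_phases_cancel(self):
        t = np.array([0.0, 0.25, 0.5, 0.75]) / 250.0 / 1.0
        m = cycle_metrics(np.array([0.0, 1e-3, 2e-3, 3e-3]), 250.0)
        assert m.vs == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_sample_matches_bessel_ratio(self, rng):
        kappa = 2.0
        n = 200
        th = rng.vonmises(0.5, kappa, size=n)
        t = (th % (2 * np.pi)) / (2 * np.pi * 250.0)
        m = cycle_metrics(t, 250.0)
        expected = i1(kappa) / i0(kappa)  # ~0.698
        assert m.vs == pytest.approx(expected, abs=3.0 / np.sqrt(n))

    def test_rotation_invariance_of_vs(self, rng):
        t = rng.uniform(0, 1, 500)
        vs1 = cycle_metrics(t, 250.0).vs
        vs2 = cycle_metrics(t + 1.234e-3, 250.0).vs
        assert vs1 == pytest.approx(vs2, abs=1e-12)

    def test_bounds_and_empty_error(self, rng):
        m = cycle_metrics(rng.uniform(0, 1, 100), 313.0)
        assert 0.0 <= m.vs <= 1.0
        assert 0.0 < m.rayleigh_p <= 1.0
        with pytest.raises(ValueError, match="no spikes"):
            cycle_metrics(np.empty(0), 250.0)


class TestPSTH:
    def test_empty_input_gives_zero_histogram(self):
        edges, rate = compute_psth([np.empty(0)] * 4, 1e-3, (0.0, 0.1))
        assert np.all(rate == 0.0)

    def test_count_conservation(self, rng):
        trains = [SpikeTrain(i, np.sort(rng.uniform(0, 0.5, 30)))
                  for i in range(10)]
        edges, rate = compute_psth(trains, 1e-3, (0.0, 0.5))
        total = rate.sum() * 1e-3 * 10
        assert total == pytest.approx(300, abs=1e-9)

    def test_constant_rate_recovered(self, rng):
        r, dur, n = 200.0, 0.5, 100
        trains = [SpikeTrain(i, np.sort(rng.uniform(
            0, dur, rng.poisson(r * dur)))) for i in range(n)]
        edges, rate = compute_psth(trains, 10e-3, (0.0, dur))
        se = np.sqrt(r / (n * 10e-3))
        assert rate.mean() == pytest.approx(r, abs=3 * se)


class TestRateLevel:
    def test_empty_trains_give_zero_rlf(self):
        per_level = [[SpikeTrain(0, np.empty(0))] for _ in range(4)]
        rlf = compute_rate_level(per_level, [0, 10, 20, 30], (0.1, 0.6))
        assert np.all(rlf.rates == 0.0)

    def test_rates_match_generator(self, rng):
        levels = [0.0, 20.0]
        window = (0.0, 0.5)
        true_rates = [50.0, 220.0]
        per_level = []
        for r in true_rates:
            per_level.append([SpikeTrain(i, np.sort(rng.uniform(
                0, 0.5, rng.poisson(r * 0.5)))) for i in range(50)])
        rlf = compute_rate_level(per_level, levels, window)
        for est, true in zip(rlf.rates, true_rates):
            assert est == pytest.approx(true,
                                        abs=3 * np.sqrt(true / (50 * 0.5)))


class TestFRA:
    @staticmethod
    def v_shaped_grid(freqs, levels, spont=10.0):
        """Synthetic tuning surface as ready-made spike trains."""
        grid = {}
        rng = np.random.default_rng(0)
        for i, lv in enumerate(levels):
            for j, f in enumerate(freqs):
                octv = abs(np.log2(f / 1000.0))
                drive = max(lv - 60.0 * octv, 0.0)
                r = spont + 4.0 * drive
                grid[(i, j)] = [SpikeTrain(k, np.sort(rng.uniform(
                    0, 0.5, rng.poisson(r * 0.5)))) for k in range(10)]
        return grid

    def test_silent_grid_has_no_contours(self):
        freqs = [500.0, 1000.0, 2000.0]
        levels = [0.0, 20.0]
        grid = {(i, j): [SpikeTrain(0, np.empty(0))]
                for i in range(2) for j in range(3)}
        fra = frequency_response_area(grid, freqs, levels, (0.0, 0.5), 0.0)
        assert all(len(c) == 0 for c in fra.contours.values())

    def test_contour_nesting_on_v_shaped_surface(self):
        freqs = np.geomspace(250, 4000, 21)
        levels = np.arange(0, 81, 10.0)
        grid = self.v_shaped_grid(freqs, levels)
        fra = frequency_response_area(grid, freqs, levels, (0.0, 0.5),
                                      spont_rate=10.0)
        assert fra.rates.shape == (9, 21)
        c5 = fra.contours[5.0]
        c50 = fra.contours[50.0]
        assert c5 and c50
        # the +5 contour encloses the +50 contour: its frequency span at
        # the top level is wider
        span5 = np.ptp(np.concatenate([c[:, 0] for c in c5]))
        span50 = np.ptp(np.concatenate([c[:, 0] for c in c50]))
        assert span5 > span50

    def test_missing_cell_reported(self):
        freqs = [500.0, 1000.0]
        levels = [0.0, 20.0]
        grid = {(i, j): [SpikeTrain(0, np.empty(0))]
                for i in range(2) for j in range(2)}
        del grid[(1, 0)]
        with pytest.raises(ValueError, match=r"\(1, 0\)"):
            frequency_response_area(grid, freqs, levels, (0.0, 0.5), 0.0)


class TestJitter:
    def ap(self, latency):
        return EventLabel(0.1, "AP", 0.1 + latency, latency)

    def test_equal_latencies_give_zero(self):
        labels = [self.ap(1e-3)] * 5
        assert jitter(labels) == 0.0

    def test_hand_computed_sample_sd(self):
        labels = [self.ap(0.9e-3), self.ap(1.1e-3)]
        assert jitter(labels) == pytest.approx(0.1414e-3, rel=1e-3)

    def test_translation_invariance(self):
        base = [self.ap(l) for l in (0.8e-3, 1.0e-3, 1.5e-3)]
        shifted = [self.ap(l + 2e-3) for l in (0.8e-3, 1.0e-3, 1.5e-3)]
        assert jitter(base) == pytest.approx(jitter(shifted), rel=1e-12)

    def test_fewer_than_two_aps_rejected(self):
        with pytest.raises(ValueError, match="two APs"):
            jitter([self.ap(1e-3), EventLabel(0.2, "EPSP")])
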