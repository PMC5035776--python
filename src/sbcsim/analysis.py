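"""Output-side statistics for SBC simulations and recordings.

Covers event classification on voltage traces (action potential /
EPSP-only / complete failure), spike probability, peristimulus time
histograms, rate-level functions, frequency response areas with
iso-rate contours, cycle (period) histogram metrics -- vector strength,
preferred phase, Rayleigh significance -- and spike-time jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from skimage import measure as _skmeasure

from .anf import SpikeTrain
from .model import VoltageTrace

__all__ = [
    "EventLabel",
    "EventDetectionParams",
    "RateLevelFunction",
    "FrequencyResponseArea",
    "CycleMetrics",
    "detect_spikes",
    "classify_events",
    "spike_probability",
    "cycle_metrics",
    "phases",
    "compute_psth",
    "compute_rate_level",
    "frequency_response_area",
    "jitter",
]


@dataclass
class EventDetectionParams:
    """Thresholds separating APs, EPSPs and failures on a trace.

    An event is an action potential when the upstroke exceeds
    ``dvdt_thresh`` and the peak rises at least ``ap_height`` above the
    median trace voltage; a subthreshold depolarization of at least
    ``epsp_min`` above the pre-event baseline is an EPSP; anything else
    is a complete failure.  The values separate the model's bimodal
    event amplitudes cleanly and are configuration-exposed.
    """

    dvdt_thresh_mV_per_ms: float = 10.0
    ap_height_mV: float = 40.0
    epsp_min_mV: float = 1.0
    window_s: float = 4e-3
    refractory_s: float = 0.5e-3


@dataclass
class EventLabel:
    input_time: float
    outcome: str                      # "AP" | "EPSP" | "complete_failure"
    ap_time: Optional[float] = None
    latency: Optional[float] = None

    def __post_init__(self):
        if self.outcome not in ("AP", "EPSP", "complete_failure"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if (self.outcome == "AP") != (self.ap_time is not None):
            raise ValueError("ap_time present iff outcome is AP")


@dataclass
class RateLevelFunction:
    levels_db: np.ndarray
    rates: np.ndarray                 # spikes/s
    spont_rate: float

    def __post_init__(self):
        if len(self.levels_db) != len(self.rates):
            raise ValueError("one rate per level required")


@dataclass
class FrequencyResponseArea:
    freqs_hz: np.ndarray
    levels_db: np.ndarray
    rates: np.ndarray                 # (n_levels, n_freqs)
    spont_rate: float
    #: iso-rate contours {delta_rate: list of (freq_hz, level_db) arrays}
    contours: dict = field(default_factory=dict)


@dataclass
class CycleMetrics:
    vs: float
    preferred_phase: float            # radians in [0, 2*pi)
    rayleigh_p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.rayleigh_p < 1e-3


def detect_spikes(trace: VoltageTrace,
                  params: EventDetectionParams = EventDetectionParams(),
                  ) -> np.ndarray:
    """Action-potential peak times on a soma voltage trace.

    Peaks must rise ``ap_height`` above the median voltage and be
    preceded (within 1 ms) by an upstroke faster than ``dvdt_thresh``.
    """
    v = np.asarray(trace.v, dtype=float)
    dt_ms = trace.dt * 1e3
    baseline = float(np.median(v))
    idx, _ = find_peaks(v, height=baseline + params.ap_height_mV,
                        distance=max(1, int(params.refractory_s / trace.dt)))
    if len(idx) == 0:
        return np.empty(0)
    dvdt = np.diff(v) / dt_ms
    look = max(1, int(1e-3 / trace.dt))
    keep = [i for i in idx
            if dvdt[max(0, i - look):max(1, i)].max()
            >= params.dvdt_thresh_mV_per_ms]
    return trace.t[np.asarray(keep, dtype=int)] if keep else np.empty(0)


def classify_events(trace: VoltageTrace,
                    input_times: np.ndarray,
                    params: EventDetectionParams = EventDetectionParams(),
                    ) -> list[EventLabel]:
    """Label each synaptic input with its postsynaptic outcome.

    APs are detected globally on the trace and assigned to the nearest
    preceding input (this resolves overlapping post-event windows);
    inputs without an assigned AP are labeled EPSP when the voltage
    rises at least ``epsp_min`` above the pre-event baseline inside the
    post-event window, otherwise complete failure.
    """
    input_times = np.sort(np.asarray(input_times, dtype=float))
    if len(input_times) == 0:
        return []
    if input_times[0] < trace.t[0] - 1e-12 or \
            input_times[-1] > trace.t[-1] + 1e-12:
        raise ValueError("input events outside the trace span")
    ap_times = detect_spikes(trace, params)

    assigned: dict[int, float] = {}
    for ap in ap_times:
        k = int(np.searchsorted(input_times, ap + 1e-12) - 1)
        if k < 0:
            continue
        if ap - input_times[k] <= params.window_s and k not in assigned:
            assigned[k] = ap

    v = np.asarray(trace.v, dtype=float)
    labels = []
    for k, t0 in enumerate(input_times):
        if k in assigned:
            ap = assigned[k]
            labels.append(EventLabel(input_time=t0, outcome="AP",
                                     ap_time=ap, latency=ap - t0))
            continue
        i0 = int(round((t0 - trace.t[0]) / trace.dt))
        t_end = t0 + params.window_s
        if k + 1 < len(input_times):
            t_end = min(t_end, input_times[k + 1])
        i1 = min(len(v), int(round((t_end - trace.t[0]) / trace.dt)))
        seg = v[i0:i1]
        if len(seg) and seg.max() - v[i0] >= params.epsp_min_mV:
            labels.append(EventLabel(input_time=t0, outcome="EPSP"))
        else:
            labels.append(EventLabel(input_time=t0,
                                     outcome="complete_failure"))
    return labels


def spike_probability(labels: Sequence[EventLabel]) -> float:
    """P_AP = #AP / (#AP + #EPSP); complete failures are omitted."""
    n_ap = sum(1 for e in labels if e.outcome == "AP")
    n_epsp = sum(1 for e in labels if e.outcome == "EPSP")
    if n_ap + n_epsp == 0:
        raise ValueError("no successful synaptic events; "
                         "spike probability undefined")
    return n_ap / (n_ap + n_epsp)


def phases(spike_times: np.ndarray, freq_hz: float) -> np.ndarray:
    """Stimulus phases of spikes, 2*pi*frac(t*f), in [0, 2*pi)."""
    return 2.0 * np.pi * np.mod(np.asarray(spike_times) * freq_hz, 1.0)


def cycle_metrics(spike_times: np.ndarray, freq_hz: float) -> CycleMetrics:
    """Vector strength, preferred phase and Rayleigh significance.

    ``vs = |sum exp(i*theta)| / n``; the Rayleigh probability uses the
    large-sample approximation ``p = exp(-n * vs^2)`` with significance
    declared at p < 0.001.
    """
    th = phases(spike_times, freq_hz)
    n = len(th)
    if n == 0:
        raise ValueError("no spikes; cycle metrics undefined")
    z = np.exp(1j * th).mean()
    vs = float(np.abs(z))
    pref = float(np.angle(z)) % (2.0 * np.pi)
    if 2.0 * np.pi - pref < 1e-9:  # guard the wrap-around
        pref = 0.0
    p = math.exp(-min(n * vs * vs, 745.0))
    return CycleMetrics(vs=vs, preferred_phase=pref, rayleigh_p=p, n=n)


def compute_psth(trains: Sequence[SpikeTrain] | Sequence[np.ndarray],
                 binwidth: float = 1e-3,
                 window: tuple[float, float] = (0.0, 0.5),
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Peristimulus time histogram pooled over sweeps.

    Returns ``(bin_edges, rate)`` with rate in spikes/s per bin,
    normalized by the number of sweeps times the bin width.
    """
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    times = [tr.times if isinstance(tr, SpikeTrain) else np.asarray(tr)
             for tr in trains]
    n_sweeps = len(times)
    edges = np.arange(window[0], window[1] + binwidth / 2, binwidth)
    pooled = np.concatenate(times) if times else np.empty(0)
    counts, _ = np.histogram(pooled, bins=edges)
    return edges, counts / (n_sweeps * binwidth)


def _pooled_rate(trains, window) -> float:
    n = sum(int(np.count_nonzero(
        (tr.times >= window[0]) & (tr.times < window[1]))) for tr in trains)
    return n / (len(trains) * (window[1] - window[0]))


def compute_rate_level(per_level_trains: Sequence[Sequence[SpikeTrain]],
                       levels_db: Sequence[float],
                       analysis_window: tuple[float, float],
                       spont_window: Optional[tuple[float, float]] = None,
                       ) -> RateLevelFunction:
    """Mean driven rate per sound level, plus the spontaneous rate.

    The driven rate is pooled over sweeps inside ``analysis_window``
    (the tone window); the spontaneous rate comes from ``spont_window``
    (typically a pre-stimulus segment) pooled over all levels.
    """
    if len(per_level_trains) != len(levels_db):
        raise ValueError("one train set per level required")
    rates = np.array([_pooled_rate(tr, analysis_window)
                      for tr in per_level_trains])
    spont = 0.0
    if spont_window is not None:
        spont = float(np.mean([_pooled_rate(tr, spont_window)
                               for tr in per_level_trains]))
    return RateLevelFunction(levels_db=np.asarray(levels_db, float),
                             rates=rates, spont_rate=spont)


def frequency_response_area(grid_trains,
                            freqs_hz: Sequence[float],
                            levels_db: Sequence[float],
                            analysis_window: tuple[float, float],
                            spont_rate: float,
                            contour_deltas: tuple[float, ...] = (5.0, 50.0),
                            ) -> FrequencyResponseArea:
    """Rate surface over level x frequency with iso-rate contours.

    ``grid_trains[(i_level, j_freq)]`` (or a nested sequence) holds the
    sweep set of one grid cell; all cells must be present.  Contours at
    ``spont_rate + delta`` spikes/s are extracted by marching squares
    on the rate surface and mapped to (freq, level) coordinates by
    linear interpolation of the grid axes.
    """
    freqs = np.asarray(freqs_hz, float)
    levels = np.asarray(levels_db, float)
    rates = np.full((len(levels), len(freqs)), np.nan)
    missing = []
    for i in range(len(levels)):
        for j in range(len(freqs)):
            try:
                cell = (grid_trains[(i, j)] if isinstance(grid_trains, dict)
                        else grid_trains[i][j])
            except (KeyError, IndexError):
                cell = None
            if cell is None:
                missing.append((i, j))
                continue
            rates[i, j] = _pooled_rate(cell, analysis_window)
    if missing:
        raise ValueError(f"missing grid cells (level_idx, freq_idx): "
                         f"{missing}")
    contours = {}
    for delta in contour_deltas:
        paths = _skmeasure.find_contours(rates, spont_rate + delta)
        mapped = []
        for path in paths:
            lev = np.interp(path[:, 0], np.arange(len(levels)), levels)
            frq = np.interp(path[:, 1], np.arange(len(freqs)), freqs)
            mapped.append(np.column_stack([frq, lev]))
        contours[delta] = mapped
    return FrequencyResponseArea(freqs_hz=freqs, levels_db=levels,
                                 rates=rates, spont_rate=spont_rate,
                                 contours=contours)


def jitter(labels: Sequence[EventLabel]) -> float:
    """Temporal AP jitter: sample standard deviation of AP latencies."""
    lat = np.array([e.latency for e in labels if e.outcome == "AP"])
    if len(lat) < 2:
        raise ValueError("need at least two APs to estimate jitter")
    return float(np.std(lat, ddof=1))


def summary_frame(metrics: dict) -> pd.DataFrame:
    """Tidy one-row-per-condition table from a {condition: dict} map."""
    return pd.DataFrame.from_dict(metrics, orient="index").rename_axis(
        "condition").reset_index()
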