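"""Synaptic conductance machinery for the SBC model.

Synapses are conductance point sources on the soma.  Conductance
waveforms are built by convolving unit-peak difference-of-exponentials
template kernels with input spike arrival times:

* endbulb of Held excitation -- one template event per auditory-nerve
  spike, amplitudes drawn i.i.d. from a Gaussian (55 +/- 9 nS, reversal
  0 mV) truncated at zero;
* summed glycinergic/GABAergic inhibition -- same event times delayed by
  1 ms, fixed 24 nS per event, reversal -75 mV (``static`` mode), or
  switched off with a compensating reduction of the excitatory mean;
* the slow alpha7-nicotinic event -- a single 2 nS template (time to
  peak 83 ms, decay 461 ms, reversal 0 mV) starting 10 ms after sound
  onset;
* muscarinic modulation -- a static shift of the leak reversal potential
  (-55 mV "+ACh", -75 mV "-ACh"/atropine, -65 mV control), with no
  onset/offset dynamics.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .model import CompartmentModel, ConductanceTimeline, SimulationConfig

__all__ = [
    "PSGTemplate",
    "EndbulbParams",
    "InhibitionParams",
    "NicotinicParams",
    "MuscarinicCondition",
    "MUSCARINIC_LEAK_EREV",
    "ConductanceTimeline",
    "make_template",
    "template_peak_time_ms",
    "rise_from_time_to_peak",
    "events_to_conductance",
    "sample_endbulb_amplitudes",
    "nicotinic_timeline",
    "apply_muscarinic",
    "inhibitory_events",
]


@dataclass
class PSGTemplate:
    """Unit-peak postsynaptic conductance kernel on the simulation grid."""

    rise_ms: float
    decay_ms: float
    dt_s: float
    waveform: np.ndarray  # max exactly 1

    @property
    def n_samples(self) -> int:
        return len(self.waveform)


def template_peak_time_ms(rise_ms: float, decay_ms: float) -> float:
    """Closed-form time to peak of exp(-t/tau_d) - exp(-t/tau_r)."""
    return (rise_ms * decay_ms / (decay_ms - rise_ms)
            * math.log(decay_ms / rise_ms))


def rise_from_time_to_peak(t_peak_ms: float, decay_ms: float) -> float:
    """Invert the peak-time relation: rise constant giving ``t_peak_ms``.

    Used to interpret a reported "rise time" as the kernel's time to
    peak (e.g. the 83 ms nicotinic rise with a 461 ms decay).
    """
    if not 0 < t_peak_ms < decay_ms:
        raise ValueError("time to peak must lie in (0, decay)")
    return brentq(
        lambda tr: template_peak_time_ms(tr, decay_ms) - t_peak_ms,
        1e-9 * decay_ms, decay_ms * (1 - 1e-9))


def make_template(rise_ms: float, decay_ms: float, dt_s: float,
                  cutoff: float = 1e-4) -> PSGTemplate:
    """Difference-of-exponentials kernel, renormalized to unit peak.

    The kernel is truncated once its amplitude falls below ``cutoff``
    of the peak.  ``rise_ms`` must be strictly smaller than
    ``decay_ms``; equal constants make the kernel degenerate.
    """
    if not rise_ms < decay_ms:
        raise ValueError(
            f"rise ({rise_ms} ms) must be < decay ({decay_ms} ms)")
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    dt_ms = dt_s * 1e3
    t_peak = template_peak_time_ms(rise_ms, decay_ms)
    # after the peak the kernel is bounded by exp(-t/decay); pad a little
    t_end = t_peak + decay_ms * math.log(1.0 / cutoff) + 5.0 * rise_ms
    t = np.arange(0.0, t_end, dt_ms)
    w = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    w /= w.max()
    keep = len(w) - np.argmax(w[::-1] >= cutoff)
    w = np.clip(w[:keep], 0.0, None)
    return PSGTemplate(rise_ms=rise_ms, decay_ms=decay_ms, dt_s=dt_s,
                       waveform=w)


@dataclass
class EndbulbParams:
    amp_mean_nS: float = 55.0
    amp_sd_nS: float = 9.0
    e_rev_mV: float = 0.0
    rise_ms: float = 0.1
    decay_ms: float = 0.2

    def __post_init__(self):
        if self.amp_mean_nS <= 0 or self.amp_sd_nS < 0:
            raise ValueError("invalid endbulb amplitude parameters")

    def template(self, dt_s: float) -> PSGTemplate:
        return make_template(self.rise_ms, self.decay_ms, dt_s)


@dataclass
class InhibitionParams:
    g_nS: float = 24.0
    e_rev_mV: float = -75.0
    delay_s: float = 1e-3
    mode: str = "static"       # "static" | "off"
    # glycinergic/GABAergic inputs to SBCs are slow compared to the
    # endbulb EPSG; the sustained inhibitory conductance they build up
    # during driven activity is what the cholinergic depolarization
    # works against
    rise_ms: float = 0.5
    decay_ms: float = 3.0
    #: multiplicative reduction of the excitatory mean amplitude applied
    #: when inhibition is off ("excitation reduced accordingly")
    exc_compensation: float = 0.8

    def __post_init__(self):
        if self.delay_s < 0:
            raise ValueError("inhibitory delay must be >= 0")
        if self.mode not in ("static", "off"):
            raise ValueError(f"unknown inhibition mode {self.mode!r}")

    @property
    def effective_g_nS(self) -> float:
        return 0.0 if self.mode == "off" else self.g_nS

    def template(self, dt_s: float) -> PSGTemplate:
        return make_template(self.rise_ms, self.decay_ms, dt_s)


@dataclass
class NicotinicParams:
    rise_ms: float = 83.0      # time to peak
    peak_nS: float = 2.0
    decay_tau_ms: float = 461.0
    e_rev_mV: float = 0.0
    onset_delay_s: float = 10e-3

    def __post_init__(self):
        for name in ("rise_ms", "decay_tau_ms", "onset_delay_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peak_nS < 0:
            raise ValueError("peak must be >= 0")


MUSCARINIC_LEAK_EREV = {
    "control": -65.0,
    "plus_ach": -55.0,
    "minus_ach": -75.0,
}


@dataclass
class MuscarinicCondition:
    label: str

    def __post_init__(self):
        if self.label not in MUSCARINIC_LEAK_EREV:
            raise ValueError(
                f"unknown muscarinic condition {self.label!r}; "
                f"must be one of {sorted(MUSCARINIC_LEAK_EREV)}")

    @property
    def leak_e_rev_mV(self) -> float:
        return MUSCARINIC_LEAK_EREV[self.label]


def events_to_conductance(events: np.ndarray,
                          amplitudes: Sequence[float] | np.ndarray,
                          template: PSGTemplate,
                          e_rev_mV: float,
                          cfg: SimulationConfig,
                          compartment: str = "soma") -> ConductanceTimeline:
    """Pointwise sum of amplitude-scaled, time-shifted template kernels.

    ``events`` are spike arrival times in seconds; ``amplitudes`` the
    per-event peak conductances (nS), one per event.  Events outside
    ``[0, duration]`` are rejected with a warning.
    """
    events = np.asarray(events, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if len(events) != len(amplitudes):
        raise ValueError("need exactly one amplitude per event")
    nt = cfg.n_steps + 1
    g = np.zeros(nt)
    w = template.waveform
    n_rejected = 0
    for t0, a in zip(events, amplitudes):
        if not (0.0 <= t0 <= cfg.duration):
            n_rejected += 1
            continue
        i0 = int(round(t0 / cfg.dt))
        seg = min(len(w), nt - i0)
        if seg > 0:
            g[i0:i0 + seg] += a * w[:seg]
    if n_rejected:
        warnings.warn(
            f"rejected {n_rejected} event(s) outside [0, {cfg.duration}] s")
    return ConductanceTimeline(t=cfg.time_grid(), g=g, e_rev_mV=e_rev_mV,
                               compartment=compartment)


def sample_endbulb_amplitudes(n: int, p: EndbulbParams,
                              seed: int | np.random.Generator,
                              mean_scale: float = 1.0) -> np.ndarray:
    """i.i.d. Gaussian EPSG amplitudes truncated below at zero.

    The truncation probability at the default (55, 9) nS is ~1e-9, so
    the sample moments are unaffected.  ``mean_scale`` rescales the mean
    (used for the inhibition-off compensation).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mu = p.amp_mean_nS * mean_scale
    out = rng.normal(mu, p.amp_sd_nS, size=n)
    while True:
        bad = out < 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mu, p.amp_sd_nS, size=int(bad.sum()))


def nicotinic_timeline(stim_onset_s: float,
                       p: NicotinicParams,
                       cfg: SimulationConfig) -> ConductanceTimeline:
    """Single slow nicotinic conductance event.

    One template event with the configured peak, starting
    ``onset_delay_s`` (default 10 ms) after sound onset.
    """
    if stim_onset_s < 0:
        raise ValueError("stimulus onset must be >= 0")
    nt = cfg.n_steps + 1
    if p.peak_nS == 0.0:
        return ConductanceTimeline(t=cfg.time_grid(), g=np.zeros(nt),
                                   e_rev_mV=p.e_rev_mV)
    tau_r = rise_from_time_to_peak(p.rise_ms, p.decay_tau_ms)
    template = make_template(tau_r, p.decay_tau_ms, cfg.dt)
    return events_to_conductance(
        np.array([stim_onset_s + p.onset_delay_s]),
        np.array([p.peak_nS]), template, p.e_rev_mV, cfg)


def apply_muscarinic(model: CompartmentModel,
                     cond: MuscarinicCondition | str) -> CompartmentModel:
    """Copy of the model with the leak reversal set for the condition.

    Nothing else is altered; the modulatory effect has no onset or
    offset dynamics and represents the fully developed muscarinic state.
    """
    if isinstance(cond, str):
        cond = MuscarinicCondition(cond)
    m = model.copy()
    m.leak_e_rev_mV = cond.leak_e_rev_mV
    return m


def inhibitory_events(exc_events: np.ndarray,
                      p: InhibitionParams) -> np.ndarray:
    """Inhibitory input spike times: the excitatory times delayed."""
    return np.asarray(exc_events, dtype=float) + p.delay_s
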