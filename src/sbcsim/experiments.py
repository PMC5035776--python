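"""End-to-end in-silico protocols for the SBC model.

Each protocol composes the pipeline

    synthetic ANF spike trains -> synaptic conductances -> SBC membrane
    -> spike detection/statistics

and writes tabular outputs plus a manifest embedding the full
configuration.  Treatment conditions within a protocol are always
paired on identical input spike sets (same seed), so differences
between conditions reflect the modulation, not input sampling.

Protocols
---------
``passive_check``   resting potential / input resistance / capacitance
``nicotinic``       paired PSTH with and without the slow nicotinic input
``muscarinic``      rate-level functions for leak reversals -75/-65/-55 mV
``ivl``             in-vivo-like sweeps: P_AP, jitter, output vector strength
``fra``             frequency response areas with +5/+50 spikes/s contours
``phase_locking``   cycle metrics per condition at one tone frequency
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import analysis, synapses
from .anf import (ANFModelParams, IVLProtocol, SpikeTrain, ToneStimulus,
                  anf_rate_profile, generate_ivl, generate_spike_trains,
                  write_spike_table)
from .model import (CompartmentModel, ConductanceTimeline, SimulationConfig,
                    VoltageTrace, build_default_sbc, integrate_batch,
                    measure_passive)
from .synapses import (EndbulbParams, InhibitionParams, MuscarinicCondition,
                       NicotinicParams, apply_muscarinic,
                       events_to_conductance, nicotinic_timeline,
                       sample_endbulb_amplitudes)

__all__ = ["ProtocolConfig", "ResultBundle", "run_protocol", "PROTOCOLS"]

PROTOCOLS = ("passive_check", "nicotinic", "muscarinic", "ivl", "fra",
             "phase_locking")

MUSCARINIC_ALL = ("minus_ach", "control", "plus_ach")


@dataclass
class ProtocolConfig:
    protocol: str
    seed: int = 1
    n_reps: int = 100
    cf_hz: Optional[float] = None
    freq_hz: Optional[float] = None
    level_db: Optional[float] = None
    freqs_hz: Optional[list] = None
    levels_db: Optional[list] = None
    inhibition_mode: str = "static"
    muscarinic_conditions: list = field(
        default_factory=lambda: list(MUSCARINIC_ALL))
    include_nicotinic: bool = False
    output_dir: str = "results"
    dt: float = 1e-5
    pre_s: float = 0.1          # silent window before tone onset
    post_s: float = 0.1         # silent tail after tone offset
    tone_dur_s: float = 0.5
    anf_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}; "
                             f"choose from {PROTOCOLS}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for lab in self.muscarinic_conditions:
            MuscarinicCondition(lab)  # validates

    def anf_params(self, cf_hz: Optional[float] = None) -> ANFModelParams:
        kw = dict(self.anf_overrides)
        if cf_hz is not None:
            kw["cf_hz"] = cf_hz
        return ANFModelParams(**kw)


@dataclass
class ResultBundle:
    protocol: str
    output_dir: Path
    summary: dict
    tables: dict = field(default_factory=dict)   # name -> DataFrame


# ---------------------------------------------------------------------------
# Pipeline helpers


def _amp_streams(seed: int, n: int):
    return np.random.SeedSequence([seed, 0x5B5]).spawn(n)


def build_synaptic_inputs(trains: Sequence[SpikeTrain],
                          cfg_sim: SimulationConfig,
                          endbulb: EndbulbParams,
                          inhibition: InhibitionParams,
                          seed: int) -> list[ConductanceTimeline]:
    """Per-sweep excitatory and inhibitory conductance batches.

    Endbulb amplitudes are drawn per sweep from streams derived only
    from ``seed``, so repeated calls with the same inputs (different
    treatment conditions) are paired exactly.  When inhibition is off,
    the excitatory mean is reduced by the compensation factor.
    """
    nb = len(trains)
    nt = cfg_sim.n_steps + 1
    t = cfg_sim.time_grid()
    tpl_e = endbulb.template(cfg_sim.dt)
    mean_scale = (inhibition.exc_compensation
                  if inhibition.mode == "off" else 1.0)
    g_exc = np.zeros((nb, nt))
    streams = _amp_streams(seed, nb)
    for i, tr in enumerate(trains):
        ev = tr.times[tr.times <= cfg_sim.duration]
        if len(ev) == 0:
            continue
        rng = np.random.default_rng(streams[i])
        amps = sample_endbulb_amplitudes(len(ev), endbulb, rng, mean_scale)
        g_exc[i] = events_to_conductance(ev, amps, tpl_e,
                                         endbulb.e_rev_mV, cfg_sim).g
    out = [ConductanceTimeline(t=t, g=g_exc, e_rev_mV=endbulb.e_rev_mV)]
    if inhibition.mode == "static":
        tpl_i = inhibition.template(cfg_sim.dt)
        g_inh = np.zeros((nb, nt))
        for i, tr in enumerate(trains):
            ev = tr.times + inhibition.delay_s
            ev = ev[ev <= cfg_sim.duration]
            if len(ev) == 0:
                continue
            g_inh[i] = events_to_conductance(
                ev, np.full(len(ev), inhibition.g_nS), tpl_i,
                inhibition.e_rev_mV, cfg_sim).g
        out.append(ConductanceTimeline(t=t, g=g_inh,
                                       e_rev_mV=inhibition.e_rev_mV))
    return out


def simulate_condition(model: CompartmentModel,
                       trains: Sequence[SpikeTrain],
                       cfg_sim: SimulationConfig,
                       syn_base: Sequence[ConductanceTimeline],
                       nicotinic: Optional[ConductanceTimeline] = None,
                       ) -> np.ndarray:
    """Soma voltage for all sweeps of one condition, shape (nb, nt)."""
    syn = list(syn_base)
    if nicotinic is not None:
        syn.append(nicotinic)
    return integrate_batch(model, syn, cfg_sim, n_batch=len(trains))


def output_spike_trains(v_batch: np.ndarray, cfg_sim: SimulationConfig,
                        det: Optional[analysis.EventDetectionParams] = None,
                        ) -> list[SpikeTrain]:
    det = det or analysis.EventDetectionParams()
    t = cfg_sim.time_grid()
    out = []
    for i in range(v_batch.shape[0]):
        tr = VoltageTrace(t=t, v=v_batch[i], dt=cfg_sim.dt)
        out.append(SpikeTrain(sweep_id=i, times=analysis.detect_spikes(
            tr, det)))
    return out


# ---------------------------------------------------------------------------
# Output plumbing


def _config_hash(cfg: ProtocolConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


class _Runner:
    """Output directory management with a resumable state file."""

    def __init__(self, cfg: ProtocolConfig):
        self.cfg = cfg
        self.out = Path(cfg.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.hash = _config_hash(cfg)
        self.state_path = self.out / "state.json"
        self.done: set[str] = set()
        if self.state_path.exists():
            try:
                st = json.loads(self.state_path.read_text())
                if st.get("config_hash") == self.hash:
                    self.done = set(st.get("completed", []))
            except (json.JSONDecodeError, OSError):
                pass
        self.t0 = time.time()

    def mark(self, stage: str) -> None:
        self.done.add(stage)
        self.state_path.write_text(json.dumps(
            {"config_hash": self.hash, "completed": sorted(self.done)}))

    def finish(self, summary: dict, tables: dict) -> ResultBundle:
        for name, df in tables.items():
            df.to_csv(self.out / f"{name}.csv", index=False)
        (self.out / "summary.json").write_text(
            json.dumps(summary, indent=2, default=float))
        manifest = {
            "protocol": self.cfg.protocol,
            "config": dataclasses.asdict(self.cfg),
            "config_hash": self.hash,
            "seed": self.cfg.seed,
            "wall_time_s": round(time.time() - self.t0, 3),
        }
        (self.out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        if self.state_path.exists():
            self.state_path.unlink()
        return ResultBundle(protocol=self.cfg.protocol, output_dir=self.out,
                            summary=summary, tables=tables)


# ---------------------------------------------------------------------------
# Protocols


def _tone_setup(cfg: ProtocolConfig, freq: float, level: float,
                anf: ANFModelParams):
    stim = ToneStimulus(freq_hz=freq, level_db=level,
                        duration_s=cfg.tone_dur_s, onset_s=cfg.pre_s)
    total = cfg.pre_s + cfg.tone_dur_s + cfg.post_s
    cfg_sim = SimulationConfig(dt=cfg.dt, duration=total, seed=cfg.seed)
    rate = anf_rate_profile(stim, anf, dt=cfg.dt, total_dur=total)
    return stim, cfg_sim, rate


def _run_passive_check(cfg: ProtocolConfig, runner: _Runner) -> ResultBundle:
    pp = measure_passive(build_default_sbc())
    summary = {"rmp_mV": pp.rmp_mV, "r_in_MOhm": pp.r_in_MOhm,
               "c_total_pF": pp.c_total_pF}
    return runner.finish(summary, {})


def _run_nicotinic(cfg: ProtocolConfig, runner: _Runner) -> ResultBundle:
    cf = cfg.cf_hz or 3000.0
    freq = cfg.freq_hz or cf
    level = cfg.level_db if cfg.level_db is not None else 20.0
    anf = cfg.anf_params(cf)
    stim, cfg_sim, rate = _tone_setup(cfg, freq, level, anf)
    trains = generate_spike_trains(rate, freq, anf, cfg.n_reps, cfg.seed,
                                   dt=cfg.dt)
    model = build_default_sbc()
    inh = InhibitionParams(mode=cfg.inhibition_mode)
    syn = build_synaptic_inputs(trains, cfg_sim, EndbulbParams(), inh,
                                cfg.seed)
    nic_tl = nicotinic_timeline(stim.onset_s, NicotinicParams(), cfg_sim)

    tone_win = (stim.onset_s, stim.onset_s + stim.duration_s)
    early_win = (stim.onset_s + 0.01, stim.onset_s + 0.30)
    summary: dict = {"conditions": {}}
    psth_df = None
    for name, nic in (("control", None), ("nicotinic", nic_tl)):
        v = simulate_condition(model, trains, cfg_sim, syn, nic)
        out_trains = output_spike_trains(v, cfg_sim)
        edges, psth = analysis.compute_psth(out_trains, binwidth=1e-3,
                                            window=(0.0, cfg_sim.duration))
        if psth_df is None:
            psth_df = pd.DataFrame({"bin_start_s": edges[:-1]})
        psth_df[f"rate_{name}"] = psth
        pooled = np.concatenate([tr.times for tr in out_trains])
        summary["conditions"][name] = {
            "total_spikes": int(len(pooled)),
            "tone_spikes": int(np.count_nonzero(
                (pooled >= tone_win[0]) & (pooled < tone_win[1]))),
            "early_ongoing_spikes": int(np.count_nonzero(
                (pooled >= early_win[0]) & (pooled < early_win[1]))),
        }
        VoltageTrace(t=cfg_sim.time_grid(), v=v[0], dt=cfg.dt).save_txt(
            runner.out / f"trace_{name}.txt")
        runner.mark(name)
    summary["freq_hz"] = freq
    summary["level_db"] = level
    summary["n_reps"] = cfg.n_reps
    return runner.finish(summary, {"psth": psth_df})


def _run_muscarinic(cfg: ProtocolConfig, runner: _Runner) -> ResultBundle:
    cf = cfg.cf_hz or 1200.0
    freq = cfg.freq_hz or cf
    levels = (cfg.levels_db if cfg.levels_db is not None
              else list(np.arange(-10.0, 76.0, 5.0)))
    anf = cfg.anf_params(cf)
    model0 = build_default_sbc()
    inh = InhibitionParams(mode=cfg.inhibition_mode)
    conditions = list(cfg.muscarinic_conditions)
    models = {lab: apply_muscarinic(model0, lab) for lab in conditions}

    per_level_out: dict[str, list] = {lab: [] for lab in conditions}
    input_rates = []
    tone_win = None
    spont_win = (0.0, cfg.pre_s)
    for il, level in enumerate(levels):
        stim, cfg_sim, rate = _tone_setup(cfg, freq, float(level), anf)
        tone_win = (stim.onset_s, stim.onset_s + stim.duration_s)
        level_seed = int(np.random.SeedSequence(
            [cfg.seed, 0x1F, il]).generate_state(1)[0] % (2 ** 31))
        trains = generate_spike_trains(rate, freq, anf, cfg.n_reps,
                                       level_seed, dt=cfg.dt)
        input_rates.append(analysis._pooled_rate(trains, tone_win))
        syn = build_synaptic_inputs(trains, cfg_sim, EndbulbParams(), inh,
                                    level_seed)
        for lab in conditions:
            v = simulate_condition(models[lab], trains, cfg_sim, syn)
            per_level_out[lab].append(output_spike_trains(v, cfg_sim))
        runner.mark(f"level_{level}")

    df = pd.DataFrame({"level_db": levels, "input_rate": input_rates})
    summary: dict = {"freq_hz": freq, "cf_hz": cf, "n_reps": cfg.n_reps,
                     "spont_rate": {}, "driven_rate": {}}
    for lab in conditions:
        rlf = analysis.compute_rate_level(per_level_out[lab], levels,
                                          tone_win, spont_win)
        df[f"rate_{lab}"] = rlf.rates
        summary["spont_rate"][lab] = rlf.spont_rate
        summary["driven_rate"][lab] = dict(zip(map(float, levels),
                                               map(float, rlf.rates)))
    return runner.finish(summary, {"rlf": df})


def _run_ivl(cfg: ProtocolConfig, runner: _Runner) -> ResultBundle:
    anf = cfg.anf_params(cfg.cf_hz or 1200.0)
    proto = IVLProtocol(n_sweeps=cfg.n_reps if cfg.n_reps != 100 else 25)
    trains = generate_ivl(anf, proto, seed=cfg.seed, dt=cfg.dt)
    write_spike_table(trains, runner.out / "input_spikes.tsv")
    cfg_sim = SimulationConfig(dt=cfg.dt, duration=proto.sweep_dur_s,
                               seed=cfg.seed)
    inh = InhibitionParams(mode=cfg.inhibition_mode)
    syn = build_synaptic_inputs(trains, cfg_sim, EndbulbParams(), inh,
                                cfg.seed)
    model0 = build_default_sbc()
    driven_win = (proto.spont_dur_s, proto.sweep_dur_s)
    rows = []
    summary: dict = {"conditions": {}, "n_sweeps": proto.n_sweeps,
                     "driven_freq_hz": proto.driven_freq_hz}
    for lab in cfg.muscarinic_conditions:
        model = apply_muscarinic(model0, lab)
        v = simulate_condition(model, trains, cfg_sim, syn)
        t = cfg_sim.time_grid()
        labels_all = []
        ap_times = []
        for i, tr in enumerate(trains):
            trace = VoltageTrace(t=t, v=v[i], dt=cfg.dt)
            evs = analysis.classify_events(trace, tr.times)
            labels_all.extend(evs)
            ap_times.extend([e.ap_time for e in evs if e.outcome == "AP"])
            for e in evs:
                rows.append((lab, i, e.input_time, e.outcome,
                             e.ap_time if e.ap_time is not None else np.nan,
                             e.latency if e.latency is not None else np.nan))
        p_ap = analysis.spike_probability(labels_all)
        jit = (analysis.jitter(labels_all)
               if sum(e.outcome == "AP" for e in labels_all) >= 2
               else np.nan)
        ap_times = np.asarray(ap_times)
        driven_aps = ap_times[(ap_times >= driven_win[0])
                              & (ap_times < driven_win[1])]
        cyc = (analysis.cycle_metrics(driven_aps, proto.driven_freq_hz)
               if len(driven_aps) else None)
        summary["conditions"][lab] = {
            "p_ap": p_ap,
            "jitter_ms": float(jit * 1e3) if np.isfinite(jit) else None,
            "vs": cyc.vs if cyc else None,
            "preferred_phase": cyc.preferred_phase if cyc else None,
            "rayleigh_p": cyc.rayleigh_p if cyc else None,
            "n_ap": int(len(ap_times)),
        }
        runner.mark(lab)
    events = pd.DataFrame(rows, columns=[
        "condition", "sweep_id", "input_time_s", "outcome", "ap_time_s",
        "latency_s"])
    return runner.finish(summary, {"events": events})


def _run_fra(cfg: ProtocolConfig, runner: _Runner) -> ResultBundle:
    cf = cfg.cf_hz or 1200.0
    freqs = (np.asarray(cfg.freqs_hz, float) if cfg.freqs_hz is not None
             else np.geomspace(125.0, 4000.0, 21))
    levels = (np.asarray(cfg.levels_db, float) if cfg.levels_db is not None
              else np.arange(-10.0, 71.0, 10.0))
    anf = cfg.anf_params(cf)
    model0 = build_default_sbc()
    inh = InhibitionParams(mode=cfg.inhibition_mode)
    conditions = list(cfg.muscarinic_conditions)
    models = {lab: apply_muscarinic(model0, lab) for lab in conditions}
    grids = {lab: {} for lab in conditions}
    tone_win = None
    spont = {lab: [] for lab in conditions}
    rows = []
    for i, level in enumerate(levels):
        for j, freq in enumerate(freqs):
            stim, cfg_sim, rate = _tone_setup(cfg, float(freq), float(level),
                                              anf)
            tone_win = (stim.onset_s, stim.onset_s + stim.duration_s)
            cell_seed = int(np.random.SeedSequence(
                [cfg.seed, 0xF2A, i, j]).generate_state(1)[0] % (2 ** 31))
            trains = generate_spike_trains(rate, float(freq), anf,
                                           cfg.n_reps, cell_seed, dt=cfg.dt)
            syn = build_synaptic_inputs(trains, cfg_sim, EndbulbParams(),
                                        inh, cell_seed)
            for lab in conditions:
                v = simulate_condition(models[lab], trains, cfg_sim, syn)
                out = output_spike_trains(v, cfg_sim)
                grids[lab][(i, j)] = out
                spont[lab].append(analysis._pooled_rate(
                    out, (0.0, cfg.pre_s)))
                rows.append((lab, float(freq), float(level),
                             analysis._pooled_rate(out, tone_win)))
        runner.mark(f"level_{level}")
    df = pd.DataFrame(rows, columns=["condition", "freq_hz", "level_db",
                                     "rate"])
    summary: dict = {"cf_hz": cf, "n_reps": cfg.n_reps, "contours": {}}
    for lab in conditions:
        fra = analysis.frequency_response_area(
            grids[lab], freqs, levels, tone_win,
            spont_rate=float(np.mean(spont[lab])))
        summary["contours"][lab] = {
            str(d): [c.tolist() for c in cs]
            for d, cs in fra.contours.items()}
        summary.setdefault("spont_rate", {})[lab] = fra.spont_rate
    return runner.finish(summary, {"fra": df})


def _run_phase_locking(cfg: ProtocolConfig, runner: _Runner) -> ResultBundle:
    cf = cfg.cf_hz or 1200.0
    freq = cfg.freq_hz or 1682.0
    level = cfg.level_db if cfg.level_db is not None else 60.0
    anf = cfg.anf_params(cf)
    stim, cfg_sim, rate = _tone_setup(cfg, freq, level, anf)
    trains = generate_spike_trains(rate, freq, anf, cfg.n_reps, cfg.seed,
                                   dt=cfg.dt)
    model0 = build_default_sbc()
    inh = InhibitionParams(mode=cfg.inhibition_mode)
    syn = build_synaptic_inputs(trains, cfg_sim, EndbulbParams(), inh,
                                cfg.seed)
    nic_tl = nicotinic_timeline(stim.onset_s, NicotinicParams(), cfg_sim)
    tone_win = (stim.onset_s, stim.onset_s + stim.duration_s)

    conds: list[tuple[str, CompartmentModel, Optional[ConductanceTimeline]]]
    conds = [(lab, apply_muscarinic(model0, lab), None)
             for lab in cfg.muscarinic_conditions]
    if cfg.include_nicotinic:
        conds.append(("nicotinic", model0, nic_tl))

    rows = []
    summary: dict = {"freq_hz": freq, "level_db": level, "cf_hz": cf,
                     "conditions": {}}
    for lab, model, nic in conds:
        v = simulate_condition(model, trains, cfg_sim, syn, nic)
        out = output_spike_trains(v, cfg_sim)
        pooled = np.concatenate([tr.times for tr in out])
        tone_spikes = pooled[(pooled >= tone_win[0])
                             & (pooled < tone_win[1])]
        if len(tone_spikes) == 0:
            summary["conditions"][lab] = {"vs": None, "n": 0}
            continue
        cyc = analysis.cycle_metrics(tone_spikes, freq)
        summary["conditions"][lab] = {
            "vs": cyc.vs, "preferred_phase": cyc.preferred_phase,
            "rayleigh_p": cyc.rayleigh_p, "n": cyc.n,
            "significant": bool(cyc.significant)}
        rows.append((lab, cyc.vs, cyc.preferred_phase, cyc.rayleigh_p,
                     cyc.n))
        runner.mark(lab)
    cycle = pd.DataFrame(rows, columns=["condition", "vs",
                                        "preferred_phase", "rayleigh_p",
                                        "n"])
    return runner.finish(summary, {"cycle": cycle})


_DISPATCH = {
    "passive_check": _run_passive_check,
    "nicotinic": _run_nicotinic,
    "muscarinic": _run_muscarinic,
    "ivl": _run_ivl,
    "fra": _run_fra,
    "phase_locking": _run_phase_locking,
}


def run_protocol(cfg: ProtocolConfig) -> ResultBundle:
    """Run one named protocol, writing tables and a manifest to disk.

    Deterministic per seed: re-running with the same configuration
    reproduces all output tables.
    """
    runner = _Runner(cfg)
    return _DISPATCH[cfg.protocol](cfg, runner)
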