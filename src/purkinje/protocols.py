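"""The canonical experiments, encoded as parameter-free recipes.

Each protocol bundles stimuli, reversible model edits, a duration and an
analysis step, and returns a :class:`ProtocolResult` with metrics and
qualitative verdicts.  Edits never mutate the input model (copies are made),
and every run asserts that the pristine model's channel-table hash is
unchanged afterwards.

Durations default to desk-scale values chosen so the full battery runs on a
laptop; they can be scaled for longer, lower-variance measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import analysis as an
from .channels import trp
from .solver import Model, SimConfig, Simulation, StimulusSource

#: maximum admissible spontaneous rate (Hz)
MAX_SPONTANEOUS_HZ = 75.0
#: settling window discarded before measurements (ms)
SETTLE_MS = 500.0
#: dendritic TRP leak density emulating the high-rate (Z-) phenotype,
#: calibrated once so the variant fires near 100 Hz
TRP_GMAX_ZMINUS = 6e-5

#: robustness classification cutoffs on the tolerated conductance change
CRITICAL_CUT = 0.15
SUBCRITICAL_CUT = 0.30
NONCRITICAL_CUT = 0.50


@dataclass
class ProtocolResult:
    name: str
    metrics: dict
    verdict: dict
    traces: object = None

    @property
    def passed(self) -> bool:
        return all(bool(v) for v in self.verdict.values())


@dataclass
class Protocol:
    """A named stimulation + model-modification recipe."""

    name: str
    stimuli: list = field(default_factory=list)
    edits: list = field(default_factory=list)
    remove_dendrites: bool = False
    add_channels: list = field(default_factory=list)
    duration: float = 2000.0
    settle: float = SETTLE_MS
    record: list = field(default_factory=lambda: [("soma", "v")])
    analysis: object = None
    dt: float = 0.025
    decim: int = 2

    def run(self, model: Model, keep_traces: bool = False) -> ProtocolResult:
        pristine = model.table_hash()
        m = model
        if self.edits:
            m = m.with_edits(self.edits)
        if self.remove_dendrites:
            m = m.without_dendrites()
        for spec in self.add_channels:
            m = m.with_channel(spec)
        cfg = SimConfig(dt=self.dt, duration=self.duration,
                        record=self.record, decim=self.decim)
        sim = Simulation(m, cfg)
        if self.settle > 0:
            sim.run(duration=self.settle, record=[("soma", "v")])
        tr = sim.run(stimuli=self.stimuli or None, duration=self.duration)
        assert model.table_hash() == pristine, "model edits leaked"
        metrics, verdict = (self.analysis(tr, m, self)
                            if self.analysis else ({}, {}))
        return ProtocolResult(self.name, metrics, verdict,
                              traces=tr if keep_traces else None)


# ---------------------------------------------------------------------------
# spontaneous firing
# ---------------------------------------------------------------------------

def _spont_analysis(tr, model, proto):
    train = an.detect_spikes(tr["soma.v"], tr.t)
    metrics = {"rate_hz": train.rate(tr.t[0], tr.t[-1]),
               "n_spikes": len(train)}
    if len(train) >= 3:
        shape = an.spike_shape(tr["soma.v"], tr.t, train)
        metrics.update(amplitude_mv=shape.amplitude,
                       half_width_ms=shape.half_width,
                       ahp_mv=shape.ahp_depth)
    verdict = {"fires": len(train) >= 3,
               "rate_within_limit": metrics["rate_hz"] <= MAX_SPONTANEOUS_HZ}
    return metrics, verdict


def protocol_spontaneous(duration: float = 2000.0,
                         record_axon: bool = False) -> Protocol:
    """No-stimulus run; reports rate and spike shape, and checks that the
    model fires below the admissible spontaneous maximum."""
    rec = [("soma", "v")]
    if record_axon:
        rec += [("AIS", "v"), ("node3", "v")]
    return Protocol("spontaneous", duration=duration, record=rec,
                    analysis=_spont_analysis)


def spontaneous_battery(model: Model, duration: float = 1500.0) -> dict:
    """The spontaneous-firing test and its three sub-conditions:

    * default model: fires, rate <= 75 Hz;
    * AIS Nav1.6 zeroed: firing must be abolished;
    * dendrites disconnected: rate and spike amplitude must increase;
    * dendritic Cav2.1 zeroed: firing must be abolished.
    """
    base = protocol_spontaneous(duration).run(model)
    out = {"default": base}

    p = protocol_spontaneous(duration)
    p.name = "spontaneous/AIS_Nav16_off"
    p.edits = [("Nav1.6", "AIS", 0.0)]
    r = p.run(model)
    r.verdict = {"silenced": r.metrics["n_spikes"] < 3}
    out["ais_nav_off"] = r

    p = protocol_spontaneous(duration)
    p.name = "spontaneous/dendrites_removed"
    p.remove_dendrites = True
    r = p.run(model)
    r.verdict = {
        "rate_increases": r.metrics["rate_hz"] > base.metrics["rate_hz"],
        "amplitude_increases":
            r.metrics.get("amplitude_mv", 0.0)
            > base.metrics.get("amplitude_mv", np.inf) * 0.999,
    }
    out["dendrites_removed"] = r

    p = protocol_spontaneous(duration)
    p.name = "spontaneous/dend_Cav21_off"
    p.edits = [("Cav2.1", "dendrites", 0.0)]
    r = p.run(model)
    r.verdict = {"silenced": r.metrics["n_spikes"] < 3}
    out["dend_cav_off"] = r
    return out


# ---------------------------------------------------------------------------
# F/I relationships
# ---------------------------------------------------------------------------

def fi_step(model: Model, amplitudes=None, hold: float = 1000.0,
            measure: float = 500.0, record_axon: bool = False) -> dict:
    """Staircase of somatic step currents; steady rate per level from the
    last ``measure`` ms of each ``hold`` window.

    Returns currents, rates, the linear fit, and (optionally) the AIS-to-
    third-node transmission reliability per level.
    """
    amplitudes = np.arange(0.1, 1.61, 0.1) if amplitudes is None \
        else np.asarray(amplitudes, dtype=float)
    rec = [("soma", "v")] + ([("AIS", "v"), ("node3", "v")]
                             if record_axon else [])
    cfg = SimConfig(dt=0.025, duration=hold, record=rec, decim=2)
    sim = Simulation(model, cfg)
    sim.run(duration=SETTLE_MS, record=[("soma", "v")])
    rates, reliab = [], []
    for amp in amplitudes:
        tr = sim.run(stimuli=[StimulusSource.step("soma", amp, 0.0, 1e9)],
                     duration=hold, record=rec)
        sel = tr.t >= tr.t[-1] - measure
        train = an.detect_spikes(tr["soma.v"][sel],
                                 tr.t[sel]).filter_peaks(-10.0)
        rates.append(train.rate(tr.t[sel][0], tr.t[sel][-1]))
        if record_axon:
            ta = an.detect_spikes(tr["AIS.v"][sel], tr.t[sel],
                                  threshold=-10.0)
            tn = an.detect_spikes(tr["node3.v"][sel], tr.t[sel],
                                  threshold=-25.0)
            reliab.append(an.transmission_reliability(ta, tn))
    out = {"currents_na": amplitudes, "rates_hz": np.array(rates)}
    if record_axon:
        out["reliability"] = np.array(reliab)
    if amplitudes.size >= 5:
        out["fit"] = an.fi_curve(amplitudes, rates)
    return out


def fi_ramp(model: Model, peak_na: float = 1.6,
            ramp_ms: float = 2000.0) -> dict:
    """Somatic double ramp 0 -> peak -> 0; instantaneous-rate summary with
    the up/down (hysteresis) branches separated at the ramp apex."""
    cfg = SimConfig(dt=0.025, duration=ramp_ms + 400.0,
                    record=[("soma", "v")], decim=2)
    sim = Simulation(model, cfg)
    sim.run(duration=SETTLE_MS, record=[("soma", "v")])
    t0 = sim.t
    stim = StimulusSource.ramp("soma", 0.0, peak_na, 0.0,
                               t0, t0 + ramp_ms / 2.0, t0 + ramp_ms)
    tr = sim.run(stimuli=[stim], duration=ramp_ms + 400.0)
    # count only full-blown spikes; the apex of a strong ramp produces
    # fading spikelets that are not action potentials
    train = an.detect_spikes(tr["soma.v"], tr.t).filter_peaks(-10.0)
    times, inst = train.instantaneous_rate()
    apex = t0 + ramp_ms / 2.0
    up = inst[times <= apex]
    down = inst[times > apex]
    return {
        "spike_times": train.times,
        "instantaneous_hz": inst,
        "onset_hz": float(up[0]) if up.size else 0.0,
        "peak_hz": float(inst.max()) if inst.size else 0.0,
        "end_hz": float(down[-1]) if down.size else 0.0,
        "up_mean_hz": float(up.mean()) if up.size else 0.0,
        "down_mean_hz": float(down.mean()) if down.size else 0.0,
    }


def protocol_fi(mode: str = "step") -> Protocol:
    """Named recipe wrapper; use :func:`fi_step` / :func:`fi_ramp` for the
    full result dictionaries."""
    if mode not in ("step", "ramp"):
        raise ValueError("mode must be 'step' or 'ramp'")
    p = Protocol(f"fi_{mode}")
    p.analysis = None
    return p


# ---------------------------------------------------------------------------
# bursting and dendritic injection
# ---------------------------------------------------------------------------

def _burst_analysis(tr, model, proto):
    # discard the onset transient: burst classification concerns the
    # sustained response, not the step's adaptation notch
    sel = tr.t >= tr.t[0] + min(400.0, 0.2 * (tr.t[-1] - tr.t[0]))
    train = an.detect_spikes(tr["soma.v"][sel], tr.t[sel])
    metrics = {"rate_hz": train.rate(tr.t[0], tr.t[-1]),
               "n_spikes": len(train)}
    try:
        bm = an.burst_metrics(train)
        metrics.update(bursts_per_s=bm.bursts_per_second,
                       spikes_per_burst=bm.spikes_per_burst,
                       intra_burst_hz=bm.intra_burst_frequency,
                       n_bursts=bm.n_bursts)
        bursting = True
    except an.NoBurstError:
        bursting = False
    metrics["bursting"] = bursting
    return metrics, {"responds": len(train) > 2 or metrics["rate_hz"] == 0}


def protocol_burst(amplitude: float = 2.2,
                   duration: float = 2500.0) -> Protocol:
    """Long somatic step; burst segmentation of the response."""
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    return Protocol(
        f"burst_{amplitude:g}nA",
        stimuli=[StimulusSource.step("soma", amplitude, 0.0, 1e9)],
        duration=duration,
        record=[("soma", "v"), ("terminal", "v"), ("terminal", "cai")],
        analysis=_burst_analysis)


def burst_threshold(model: Model, amplitudes=None,
                    duration: float = 2000.0):
    """Lowest step amplitude classified as bursting by the segmentation
    operator; None when every tested level stays tonic."""
    amplitudes = np.arange(1.8, 3.01, 0.1) if amplitudes is None \
        else np.asarray(amplitudes, dtype=float)
    for amp in amplitudes:
        res = protocol_burst(float(amp), duration).run(model)
        if res.metrics.get("bursting"):
            return float(amp), res
    return None, None


def protocol_dendritic_injection(site: str = "terminal") -> Protocol:
    """Brief strong current into the dendrites: 3 nA / 10 ms in a terminal
    branch (parallel-fibre-like) or 3 nA / 30 ms in the trunk
    (climbing-fibre-like); reports the burst-pause structure."""
    if site not in ("terminal", "trunk"):
        raise ValueError("site must be 'terminal' or 'trunk'")
    width = 10.0 if site == "terminal" else 30.0

    def analyze(tr, model, proto):
        t_on = tr.t[0] + 200.0
        train = an.detect_spikes(tr["soma.v"], tr.t)
        pre = train.times[train.times < t_on]
        dur_burst = train.times[(train.times >= t_on)
                                & (train.times < t_on + width + 15.0)]
        after = train.times[train.times >= t_on + width]
        base_isi = np.median(np.diff(pre)) if pre.size > 2 else np.inf
        pause = (after[0] - (t_on + width)) if after.size else np.inf
        burst_rate = 0.0
        if dur_burst.size > 1:
            burst_rate = 1000.0 / np.median(np.diff(dur_burst))
        metrics = {"baseline_isi_ms": float(base_isi),
                   "burst_spikes": int(dur_burst.size),
                   "burst_rate_hz": float(burst_rate),
                   "pause_ms": float(min(pause, 1e6))}
        verdict = {"burst_then_pause":
                   dur_burst.size >= 2 and pause > base_isi}
        return metrics, verdict

    p = Protocol(f"dendritic_{site}", duration=1200.0,
                 record=[("soma", "v")], analysis=analyze)
    # the simulation clock continues through the settle window, so the
    # onset is expressed on the absolute clock
    p.stimuli = [StimulusSource.step(site, 3.0, 200.0 + SETTLE_MS,
                                     200.0 + SETTLE_MS + width)]
    return p


# ---------------------------------------------------------------------------
# hyperpolarization (sag and rebound)
# ---------------------------------------------------------------------------

def hyperpolarization_response(model: Model, amplitude: float = -0.5,
                               width: float = 800.0) -> dict:
    """Negative somatic step; sag ratio (peak vs steady hyperpolarization
    relative to baseline) and post-offset rebound spikes.  Measured with
    spontaneous firing suppressed by the step itself."""
    cfg = SimConfig(dt=0.025, duration=width + 900.0,
                    record=[("soma", "v")], decim=2)
    sim = Simulation(model, cfg)
    sim.run(duration=SETTLE_MS, record=[("soma", "v")])
    t0 = sim.t
    tr = sim.run(stimuli=[StimulusSource.step("soma", amplitude,
                                              t0 + 100.0, t0 + 100.0 + width)],
                 duration=width + 900.0)
    if amplitude == 0.0:
        return {"sag_ratio": 1.0, "rebound_spikes": 0,
                "v_min": float(tr["soma.v"].min())}
    v, t = tr["soma.v"], tr.t
    on, off = t0 + 100.0, t0 + 100.0 + width
    base = np.median(v[t < on])
    during = v[(t >= on) & (t < off)]
    peak_hyp = during.min()
    steady = np.median(during[-int(100 / tr.dt):])
    sag = (base - peak_hyp) / max(base - steady, 1e-9)
    after = (t >= off) & (t < off + 300.0)
    rebound = an.detect_spikes(v[after], t[after])
    pre_mask = t < on
    pre_rate = an.detect_spikes(v[pre_mask], t[pre_mask]).rate(t[0], on)
    reb_rate = rebound.rate(off, off + 300.0)
    return {"sag_ratio": float(sag), "rebound_spikes": len(rebound),
            "rebound_rate_hz": float(reb_rate),
            "pre_rate_hz": float(pre_rate),
            "v_min": float(peak_hyp), "v_steady": float(steady)}


def protocol_hyperpolarization() -> Protocol:
    return Protocol("hyperpolarization")


# ---------------------------------------------------------------------------
# bistability
# ---------------------------------------------------------------------------

def bistability_test(model: Model, which_ko: str | None = "AIS_Nav16",
                     pulse_gap: float = 1500.0) -> dict:
    """Up/down-state toggling test.

    Applies the chosen knockout, then a +0.2 nA / 200 ms pulse and, later,
    a -0.1 nA / 200 ms pulse.  The up-state verdict requires firing to
    persist >= 1 s after the positive pulse ends; the down-state verdict
    requires silence to persist >= 1 s after the negative pulse ends.  On
    the intact model (``which_ko=None``) neither state change may persist.
    """
    edits = {"AIS_Nav16": [("Nav1.6", "AIS", 0.0)],
             "dend_Cav21": [("Cav2.1", "dendrites", 0.0)],
             None: []}[which_ko]
    m = model.with_edits(edits) if edits else model
    cfg = SimConfig(dt=0.025, duration=100.0, record=[("soma", "v")], decim=2)
    sim = Simulation(m, cfg)
    sim.run(duration=SETTLE_MS, record=[("soma", "v")])
    t0 = sim.t
    pos_on, pos_off = t0 + 100.0, t0 + 300.0
    neg_on = pos_off + pulse_gap
    neg_off = neg_on + 200.0
    total = neg_off + pulse_gap - t0
    stims = [StimulusSource.step("soma", 0.2, pos_on, pos_off),
             StimulusSource.step("soma", -0.1, neg_on, neg_off)]
    tr = sim.run(stimuli=stims, duration=total)
    v, t = tr["soma.v"], tr.t

    def rate_in(a, b):
        m_ = (t >= a) & (t < b)
        return an.detect_spikes(v[m_], t[m_]).rate(a, b)

    baseline = rate_in(t0, pos_on)
    during_pos = rate_in(pos_on, pos_off)
    after_pos = rate_in(pos_off + 200.0, pos_off + 1200.0)
    after_neg = rate_in(neg_off + 200.0, neg_off + 1200.0)
    metrics = {"baseline_hz": baseline, "during_pos_hz": during_pos,
               "after_pos_hz": after_pos, "after_neg_hz": after_neg}
    if which_ko is None:
        verdict = {
            "no_persistent_up": abs(after_pos - baseline) < 0.5 * max(baseline, 1.0),
            "recovers_after_neg": after_neg > 0.5 * baseline,
        }
    else:
        verdict = {
            "silent_at_rest": baseline < 5.0,
            "fires_during_pulse": during_pos > 5.0,
            "up_state_persists": after_pos > 10.0,
            "down_state_persists": after_neg < 5.0,
        }
    return {"metrics": metrics, "verdict": verdict,
            "passed": all(verdict.values())}


def protocol_bistability(which_ko: str = "AIS_Nav16") -> Protocol:
    return Protocol(f"bistability_{which_ko}")


# ---------------------------------------------------------------------------
# knockout battery and variants
# ---------------------------------------------------------------------------

KO_BATTERY = {
    "Nav1.6": [("Nav1.6", None, 0.0)],
    "Cav2.1": [("Cav2.1", None, 0.0)],
    "KCa1.1": [("KCa1.1", None, 0.0)],
    "KCa2.2": [("KCa2.2", None, 0.0)],
    "Kv1.1+Kv1.5": [("Kv1.1", None, 0.0), ("Kv1.5", None, 0.0)],
    "HCN1": [("HCN1", None, 0.0)],
}


def protocol_ko(name: str, spont_ms: float = 1500.0,
                step_ms: float = 1500.0):
    """One knockout: spontaneous run plus a 2 nA evoked run; returns the
    two protocols (run them with :func:`run_ko_battery` for verdicts)."""
    edits = KO_BATTERY[name]
    p1 = protocol_spontaneous(spont_ms)
    p1.name = f"ko_{name}/spontaneous"
    p1.edits = edits
    p2 = protocol_burst(2.0, step_ms)
    p2.name = f"ko_{name}/evoked"
    p2.edits = edits
    return p1, p2


def run_ko_battery(model: Model, spont_ms: float = 1500.0,
                   step_ms: float = 1500.0) -> dict:
    """Run every knockout and compare against the intact model.

    Expected qualitative outcomes: Nav1.6 off abolishes all firing;
    Cav2.1 off abolishes spontaneous firing; KCa1.1, KCa2.2 and
    Kv1.1+Kv1.5 off leave firing intact (rates equal or higher); HCN1 off
    leaves spontaneous firing nearly unchanged.
    """
    base_sp = protocol_spontaneous(spont_ms).run(model)
    base_ev = protocol_burst(2.0, step_ms).run(model)
    out = {"default": {"spont": base_sp, "evoked": base_ev}}
    b_rate = base_sp.metrics["rate_hz"]
    for name in KO_BATTERY:
        p1, p2 = protocol_ko(name, spont_ms, step_ms)
        r1, r2 = p1.run(model), p2.run(model)
        v = {}
        if name == "Nav1.6":
            v["firing_abolished"] = (r1.metrics["n_spikes"] < 3
                                     and r2.metrics["n_spikes"] < 3)
        elif name == "Cav2.1":
            v["spontaneous_abolished"] = r1.metrics["n_spikes"] < 3
        elif name in ("KCa1.1", "KCa2.2", "Kv1.1+Kv1.5"):
            v["firing_preserved"] = r1.metrics["n_spikes"] >= 3
            v["rate_not_decreased"] = (r1.metrics["rate_hz"]
                                       >= 0.85 * b_rate)
        elif name == "HCN1":
            v["nearly_unchanged"] = (abs(r1.metrics["rate_hz"] - b_rate)
                                     <= 0.3 * max(b_rate, 1.0))
        out[name] = {"spont": r1, "evoked": r2, "verdict": v,
                     "passed": all(v.values())}
    return out


def protocol_variants(kind: str) -> Protocol:
    """Firing-phenotype variants: high-basal-rate (dendritic TRP leak),
    continuously-firing (-40% Cav2.1) and pausing (HCN1 -50%, Kv3.4 +8%,
    Kv4.3 -50%)."""
    p = protocol_spontaneous(1500.0)
    if kind == "Zminus":
        p.name = "variant_Zminus"
        p.add_channels = [trp(TRP_GMAX_ZMINUS)]
    elif kind == "CF_PC":
        p.name = "variant_CF_PC"
        p.edits = [("Cav2.1", None, 0.6)]
    elif kind == "P_PC":
        p.name = "variant_P_PC"
        p.edits = [("HCN1", None, 0.5), ("Kv3.4", None, 1.08),
                   ("Kv4.3", None, 0.5)]
    else:
        raise ValueError(f"unknown variant {kind!r}")
    return p


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

@dataclass
class RobustnessResult:
    channel: str
    lower: float   # largest tolerated downward fraction (e.g. 0.15)
    upper: float   # largest tolerated upward fraction
    classification: str
    detail: dict = field(default_factory=dict)

    @staticmethod
    def classify(margin: float) -> str:
        if margin < CRITICAL_CUT:
            return "critical"
        if margin < SUBCRITICAL_CUT:
            return "subcritical"
        return "non_critical"


DEFAULT_SCALE_GRID = (0.5, 0.7, 0.85, 0.9, 0.95, 1.0,
                      1.05, 1.1, 1.15, 1.3, 1.5)


def robustness_scan(model: Model, channel: str,
                    scales=DEFAULT_SCALE_GRID,
                    spont_ms: float = 1200.0,
                    drive_na: float = 1.1, drive_ms: float = 800.0,
                    reference: dict | None = None) -> RobustnessResult:
    """Scale one channel's maximum conductance over a grid and report the
    widest contiguous interval around 1.0 keeping the firing features
    inside their windows: spontaneous rate in (0, 95] Hz and the driven
    rate within +-20 Hz of the canonical model's.

    The classification applies the stated cutoffs to the tighter of the
    two margins.
    """
    scales = sorted(scales)
    if 1.0 not in scales:
        raise ValueError("grid must contain 1.0")
    if min(scales) > 0.5 or max(scales) < 1.5:
        raise ValueError("grid must span at least +-50%")
    if reference is None:
        reference = robustness_reference(model, spont_ms, drive_na, drive_ms)

    def passes(scale: float) -> bool:
        m = model.with_edits([(channel, None, scale)])
        sp = protocol_spontaneous(spont_ms).run(m)
        r = sp.metrics["rate_hz"]
        if not (0.0 < r <= 95.0):
            return False
        ev = protocol_burst(drive_na, drive_ms).run(m)
        if abs(ev.metrics["rate_hz"] - reference["drive_rate"]) > 20.0:
            return False
        return True

    results = {}
    i1 = scales.index(1.0)
    lo_ok = hi_ok = 1.0
    for s in reversed(scales[:i1]):
        if passes(s):
            lo_ok = s
            results[s] = True
        else:
            results[s] = False
            break
    for s in scales[i1 + 1:]:
        if passes(s):
            hi_ok = s
            results[s] = True
        else:
            results[s] = False
            break
    lower = 1.0 - lo_ok
    upper = hi_ok - 1.0
    margin = min(lower, upper)
    return RobustnessResult(channel, lower, upper,
                            RobustnessResult.classify(margin),
                            detail={"grid": results})


def robustness_reference(model: Model, spont_ms: float = 1200.0,
                         drive_na: float = 1.1,
                         drive_ms: float = 800.0) -> dict:
    """Feature values of the canonical model used as robustness windows."""
    sp = protocol_spontaneous(spont_ms).run(model)
    ev = protocol_burst(drive_na, drive_ms).run(model)
    return {"spont_rate": sp.metrics["rate_hz"],
            "drive_rate": ev.metrics["rate_hz"]}
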