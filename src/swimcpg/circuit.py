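"""Swim central-pattern-generator circuit with a two-zone VSI.

The three-interneuron escape-swim CPG (DSI, C2, VSI) is modelled with a
single-side topology in which VSI carries two spike-initiation zones:
one proximal to its soma and one in the distal pedal ganglion, reached
through the pedal commissure (PdN6).  While the commissure is intact the
distal zone can fire the axon antidromically, so the somatic burst count
is insensitive to how excitable the proximal zone is; disconnecting the
commissure removes the distal zone from the recording side and exposes
the proximal zone's excitability — which is set by the hidden
animal-specific balance between recruited polysynaptic excitation and
the delayed inhibitory component (amplitude ``h``) of the direct C2->VSI
synapse.

The simulator is a scheduled generative model.  An exponentially
decaying episode drive, charged by the initiating nerve-stimulus train,
sets the burst scaffold (onset times and cycle count); per-cycle
spike-initiation-zone occupancy follows the calibrated population
mappings in :mod:`swimcpg.cohort`; and membrane/nerve traces are
rendered from templates plus the literal first-order clamp kinetics of
:mod:`swimcpg.synapse`.  The attached dynamic clamp is computed
sample-by-sample from the rendered presynaptic C2 voltage, exactly as
the clamp hardware would.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from . import analysis as _an
from . import cohort as _coh
from . import synapse as _syn
from .io import EpisodeRecording

log = logging.getLogger("swimcpg.circuit")

__all__ = [
    "NeuronUnit",
    "SynapseEdge",
    "CircuitState",
    "CircuitParams",
    "PdN3Stim",
    "C2TrainStim",
    "IntegrationError",
    "build_circuit",
    "apply_lesion",
    "attach_dynamic_clamp",
    "simulate_episode",
    "calibrate_population_model",
    "CalibrationReport",
]


class IntegrationError(RuntimeError):
    """A unit's rendered voltage went non-finite during an episode."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

UNIT_NAMES = ("DSI", "C2", "VSI_proximal", "VSI_distal", "RecruitedPool")
EDGE_SIGNS = ("excitatory", "inhibitory", "biphasic", "multi-component")


@dataclass(frozen=True)
class NeuronUnit:
    name: str
    rest_mv: float
    spike_threshold_mv: float
    refractory_ms: float = 8.0

    def __post_init__(self):
        if self.name not in UNIT_NAMES:
            raise ValueError(f"unknown unit {self.name}")


@dataclass(frozen=True)
class SynapseEdge:
    source: str
    target: str
    sign: str
    weight_ns: float
    delay_ms: float = 0.0
    rise_ms: float = 50.0
    decay_ms: float = 300.0
    # biphasic edges: (fast depolarizing, slow hyperpolarizing) sub-weights
    sub_weights_ns: tuple | None = None

    def __post_init__(self):
        if self.sign not in EDGE_SIGNS:
            raise ValueError(f"invalid synapse sign {self.sign!r}")
        if self.delay_ms < 0:
            raise ValueError("synaptic delay must be >= 0")
        if self.weight_ns < 0:
            raise ValueError(
                f"negative weight on {self.source}->{self.target}; use sign "
                "'inhibitory' instead"
            )
        if self.sign == "biphasic" and self.sub_weights_ns is None:
            raise ValueError("biphasic edges need (fast, slow) sub-weights")


@dataclass(frozen=True)
class CircuitParams:
    """Episode-generation constants (times in the units of their names)."""

    fs_hz: float = 4000.0
    conduction_delay_ms: float = 25.0
    drive_tau_s: float = 25.0          # decay of the episode drive
    first_burst_lag_s: float = 1.5     # stim end -> first dorsal-phase burst
    cycle_period_s: float = 4.5
    cycle_jitter: float = 0.04
    c2_burst_dur_s: float = 2.2
    c2_rate_hz: float = 13.0
    vsi_lag_s: float = 2.3             # ventral phase follows the dorsal phase
    vsi_burst_dur_s: float = 1.5
    vsi_rate_hz: float = 9.5
    dsi_rate_hz: float = 10.0
    # Effective inhibition at the proximal initiation zone per clamp nS;
    # the clamp current enters at the soma, so 1000 nS arrives
    # electrotonically attenuated to ~1.6 mV of natural-synapse
    # equivalent at the zone.
    clamp_coupling_mv_per_ns: float = 0.0016
    subtract_ext_per_mv: float = 0.8          # extra cycles per mV of removed inhibition
    subtract_ext_sd: float = 0.7
    subtract_ext_cap: int = 2
    count_jitter_p: tuple = (0.08, 0.84, 0.08)  # P(n = baseline -1 / 0 / +1)
    noise_mv: float = 0.1
    nerve_noise: float = 0.01
    clamp_display_mv_per_pa: float = 0.001    # somatic deflection per pA injected


@dataclass(frozen=True)
class PdN3Stim:
    """Body-wall nerve train that initiates a swim episode."""

    start_s: float = 2.0
    duration_s: float = 3.0
    rate_hz: float = 5.0


@dataclass(frozen=True)
class C2TrainStim:
    """Direct C2 soma stimulation (current pulses at a fixed rate)."""

    start_s: float = 2.0
    duration_s: float = 4.0
    rate_hz: float = 10.0


@dataclass(frozen=True)
class CircuitState:
    """The assembled single-side CPG plus its switches."""

    units: tuple
    edges: tuple
    animal: _coh.VirtualAnimal
    params: CircuitParams = CircuitParams()
    pdn6_intact: bool = True
    hi_di: bool = False
    clamp_kinetics: _syn.SynapseKinetics | None = None
    clamp_mode: str = "off"
    loss_mapping: _coh.LossMapping = _coh.DEFAULT_LOSS
    zone_mapping: _coh.ZoneMapping = _coh.DEFAULT_ZONES

    @property
    def clamp_g_signed_ns(self) -> float:
        if self.clamp_mode == "off" or self.clamp_kinetics is None:
            return 0.0
        g = abs(self.clamp_kinetics.g_syn_ns)
        return g if self.clamp_mode == "add" else -g


# ---------------------------------------------------------------------------
# circuit construction and switches
# ---------------------------------------------------------------------------

def build_circuit(
    animal: _coh.VirtualAnimal,
    params: CircuitParams | None = None,
    *,
    hi_di: bool = False,
    loss_mapping: _coh.LossMapping = _coh.DEFAULT_LOSS,
    zone_mapping: _coh.ZoneMapping = _coh.DEFAULT_ZONES,
) -> CircuitState:
    """Assemble the CPG for one virtual animal.

    The direct C2->VSI_proximal biphasic edge is scaled so the
    Hi-Di-isolated synaptic potential has hyperpolarization amplitude
    ``h`` and depolarization amplitude ``d``; Hi-Di mode silences the
    recruited polysynaptic pool and raises every unit's firing
    threshold.
    """
    if animal.h_mv < 0 or animal.d_mv < 0:
        raise ValueError("h must be >= 0 and d >= 0")
    p = params or CircuitParams()
    thr_shift = 15.0 if hi_di else 0.0
    units = (
        NeuronUnit("DSI", rest_mv=-48.0, spike_threshold_mv=-35.0 + thr_shift),
        NeuronUnit("C2", rest_mv=-45.0, spike_threshold_mv=-32.0 + thr_shift),
        NeuronUnit("VSI_proximal", rest_mv=-50.0, spike_threshold_mv=-34.0 + thr_shift),
        NeuronUnit("VSI_distal", rest_mv=-50.0, spike_threshold_mv=-34.0 + thr_shift),
        NeuronUnit("RecruitedPool", rest_mv=-55.0, spike_threshold_mv=-40.0 + thr_shift),
    )
    pool_w = 0.0 if hi_di else 60.0
    # conductance scale: 25 nS per mV of Hi-Di PSP amplitude
    per_mv = 25.0
    edges = (
        SynapseEdge("DSI", "C2", "excitatory", 3 * 40.0),  # three DSIs collapsed
        SynapseEdge("C2", "DSI", "biphasic", 30.0, sub_weights_ns=(20.0, 10.0)),
        SynapseEdge("DSI", "VSI_proximal", "multi-component", 15.0),
        SynapseEdge(
            "C2",
            "VSI_proximal",
            "biphasic",
            per_mv * (animal.d_mv + animal.h_mv),
            rise_ms=150.0,
            decay_ms=1000.0,
            sub_weights_ns=(per_mv * animal.d_mv, per_mv * animal.h_mv),
        ),
        SynapseEdge("C2", "VSI_distal", "excitatory", 80.0, delay_ms=p.conduction_delay_ms),
        SynapseEdge("C2", "RecruitedPool", "excitatory", pool_w),
        SynapseEdge("RecruitedPool", "VSI_proximal", "excitatory", pool_w),
        SynapseEdge("VSI_proximal", "C2", "inhibitory", 40.0),
        SynapseEdge("VSI_proximal", "DSI", "inhibitory", 30.0),
    )
    return CircuitState(
        units=units,
        edges=edges,
        animal=animal,
        params=p,
        hi_di=hi_di,
        loss_mapping=loss_mapping,
        zone_mapping=zone_mapping,
    )


def apply_lesion(circuit: CircuitState) -> CircuitState:
    """Disconnect the commissure (transection or TTX block); idempotent."""
    return replace(circuit, pdn6_intact=False)


def attach_dynamic_clamp(
    circuit: CircuitState,
    kinetics: _syn.SynapseKinetics,
    mode: str,
) -> CircuitState:
    """Attach the artificial C2->VSI synapse at the VSI soma.

    ``mode`` is add, subtract or off; subtract mode negates the maximal
    conductance.  The clamp and Hi-Di saline are never combined in
    practice; doing so raises a warning.
    """
    if mode not in ("add", "subtract", "off"):
        raise ValueError(f"clamp mode must be add/subtract/off, got {mode!r}")
    if circuit.hi_di and mode != "off":
        warnings.warn("dynamic clamp attached in Hi-Di saline", stacklevel=2)
    return replace(circuit, clamp_kinetics=kinetics, clamp_mode=mode)


# ---------------------------------------------------------------------------
# episode simulation
# ---------------------------------------------------------------------------

def _exp_kernel_filter(x: np.ndarray, rise_ms: float, decay_ms: float, dt_ms: float):
    """Difference-of-exponentials synaptic filter of an impulse train."""
    a_d = np.exp(-dt_ms / decay_ms)
    a_r = np.exp(-dt_ms / rise_ms)
    y = lfilter([1.0], [1.0, -a_d], x) - lfilter([1.0], [1.0, -a_r], x)
    return y


def _spike_train(onset_s, dur_s, rate_hz, rng, decel=0.25):
    """Spike times of one burst with mild within-burst deceleration."""
    times = []
    t = onset_s + rng.uniform(0.0, 0.03)
    end = onset_s + dur_s
    isi0 = 1.0 / rate_hz
    while t < end:
        times.append(t)
        frac = (t - onset_s) / dur_s
        t += isi0 * (1.0 + decel * frac) * rng.uniform(0.85, 1.15)
    return np.asarray(times)


def _scaffold(circuit: CircuitState, stim: PdN3Stim, rng):
    """Burst scaffold: cycle onsets, counts and zone occupancy."""
    a = circuit.animal
    p = circuit.params
    delta = rng.choice([-1, 0, 1], p=p.count_jitter_p)
    n = int(np.clip(a.baseline_bursts + delta, 2, 9))

    g = circuit.clamp_g_signed_ns
    h_eff = a.h_mv + p.clamp_coupling_mv_per_ns * g

    extra = 0
    if circuit.pdn6_intact and circuit.clamp_mode == "subtract":
        removed = p.clamp_coupling_mv_per_ns * abs(g)
        raw = p.subtract_ext_per_mv * removed + p.subtract_ext_sd * rng.standard_normal()
        extra = int(np.clip(round(raw), 0, p.subtract_ext_cap))
        n += extra

    if circuit.pdn6_intact:
        count = n
        if circuit.clamp_mode == "add":
            m_distal = n  # somatic inhibition silences the proximal zone
        elif circuit.clamp_mode == "subtract":
            m_distal = 0  # subtraction keeps the proximal zone firing
        else:
            m_distal = _coh.zone_switch_cycle(a.h_mv, a.zone_zeta, n, circuit.zone_mapping)
        proximal_cycles = n - m_distal
        loss = 0
    else:
        loss = _coh.burst_loss(h_eff, a.epsilon, n, rng, circuit.loss_mapping)
        count = n - loss
        proximal_cycles = count
        m_distal = 0  # distal zone keeps firing but is unrecorded

    t0 = stim.start_s + stim.duration_s + p.first_burst_lag_s + rng.uniform(0.0, 0.3)
    onsets = []
    t = t0
    for _ in range(n):
        onsets.append(t)
        t += p.cycle_period_s * (1.0 + p.cycle_jitter * rng.standard_normal())
    return {
        "n_cycles": n,
        "count": count,
        "loss": loss,
        "extra": extra,
        "proximal_cycles": proximal_cycles,
        "onsets": np.asarray(onsets),
        "h_eff": h_eff,
    }


def _render_swim(circuit, stim, duration_s, dt_ms, rng, scaffold):
    a, p = circuit.animal, circuit.params
    n_samp = int(round(duration_s * 1000.0 / dt_ms))
    t_s = np.arange(n_samp) * dt_ms / 1000.0
    stim_end = stim.start_s + stim.duration_s

    # --- spike times ---------------------------------------------------
    dsi_times = []
    c2_times = []
    vsi_soma = []
    nerve = []
    vsi_cycle_zone = []  # (cycle index, 'proximal'|'distal')

    if not circuit.hi_di:
        # DSI: tonic firing riding the decaying episode drive
        t = stim.start_s + 0.1
        end_drive = scaffold["onsets"][-1] + p.cycle_period_s if scaffold["n_cycles"] else stim_end
        while t < min(end_drive, duration_s - 0.5):
            frac = max(0.0, 1.0 - (t - stim_end) / (p.drive_tau_s * 1.2)) if t > stim_end else 1.0
            rate = p.dsi_rate_hz * (0.3 + 0.7 * frac)
            t += 1.0 / rate * rng.uniform(0.8, 1.2)
            dsi_times.append(t)

        # a few direct stimulus-locked spikes (not counted as a burst)
        for u in (0.4, 1.1, 2.1):
            vsi_soma.append(stim.start_s + u + rng.uniform(0.0, 0.15))

        for k, onset in enumerate(scaffold["onsets"]):
            c2_times.extend(_spike_train(onset, p.c2_burst_dur_s, p.c2_rate_hz, rng))
            proximal = k < scaffold["proximal_cycles"]
            counted = k < scaffold["count"] if not circuit.pdn6_intact else True
            if not counted:
                continue
            v_times = _spike_train(onset + p.vsi_lag_s, p.vsi_burst_dur_s, p.vsi_rate_hz, rng)
            zone = "proximal" if proximal else "distal"
            vsi_cycle_zone.append((k, zone))
            for ts in v_times:
                if zone == "proximal":
                    vsi_soma.append(ts)
                    if circuit.pdn6_intact:
                        nerve.append(ts + p.conduction_delay_ms / 1000.0)
                else:
                    # distal initiation: impulse reaches the nerve first,
                    # the soma one conduction delay later
                    if circuit.pdn6_intact:
                        vsi_soma.append(ts + p.conduction_delay_ms / 1000.0)
                        nerve.append(ts)
                    # lesioned: distal spikes reach neither recording site

    dsi_times = np.asarray(sorted(ts for ts in dsi_times if ts < duration_s))
    c2_times = np.asarray(sorted(ts for ts in c2_times if ts < duration_s))
    vsi_soma = np.asarray(sorted(ts for ts in vsi_soma if ts < duration_s))
    nerve = np.asarray(sorted(ts for ts in nerve if 0 <= ts < duration_s))

    # --- voltage channels ----------------------------------------------
    spike = _coh.spike_template(dt_ms)
    impulse = np.zeros(n_samp)

    c2_v = np.full(n_samp, -45.0)
    c2_delta = np.zeros(n_samp)
    idx = np.clip((c2_times * 1000.0 / dt_ms).astype(int), 0, n_samp - 1)
    np.add.at(c2_delta, idx, 1.0)
    c2_env = _exp_kernel_filter(c2_delta, 120.0, 900.0, dt_ms)
    c2_v += 6.0 * c2_env / max(c2_env.max(), 1e-9)
    _coh.add_events(c2_v, c2_times, spike, dt_ms)

    dsi_v = np.full(n_samp, -48.0)
    _coh.add_events(dsi_v, dsi_times, spike, dt_ms)

    vsi_v = np.full(n_samp, -50.0)
    # direct synaptic inhibition visible in the soma, scaled to h
    inhib = _exp_kernel_filter(c2_delta, 200.0, 1100.0, dt_ms)
    if inhib.max() > 0:
        vsi_v -= a.h_mv * inhib / inhib.max()
        vsi_v += 0.4 * a.d_mv * inhib / inhib.max()  # fast depolarizing component
    vsi_delta = np.zeros(n_samp)
    if vsi_soma.size:
        vidx = np.clip((vsi_soma * 1000.0 / dt_ms).astype(int), 0, n_samp - 1)
        np.add.at(vsi_delta, vidx, 1.0)
        venv = _exp_kernel_filter(vsi_delta, 100.0, 600.0, dt_ms)
        vsi_v += 5.0 * venv / max(venv.max(), 1e-9)
    _coh.add_events(vsi_v, vsi_soma, spike, dt_ms)

    _coh.add_events(impulse, nerve, _coh.triphasic_template(dt_ms, amp=0.5), dt_ms)

    channels = {"DSI": dsi_v, "C2": c2_v, "VSI_soma": vsi_v, "PdN6": impulse}

    # --- dynamic clamp -------------------------------------------------
    if circuit.clamp_mode != "off" and circuit.clamp_kinetics is not None:
        k = circuit.clamp_kinetics
        if circuit.clamp_mode == "subtract":
            k = k.negated()
        else:
            k = replace(k, g_syn_ns=abs(k.g_syn_ns))
        i_clamp = _syn.clamp_trace(c2_v, k, dt_ms)
        channels["I_clamp_pA"] = i_clamp
        vsi_v += p.clamp_display_mv_per_pa * i_clamp
        channels["VSI_soma"] = vsi_v

    # measurement noise
    for name in ("DSI", "C2", "VSI_soma"):
        channels[name] = channels[name] + rng.normal(0.0, p.noise_mv, n_samp)
    channels["PdN6"] = channels["PdN6"] + rng.normal(0.0, p.nerve_noise, n_samp)

    return t_s, channels, dsi_times, c2_times, vsi_soma, nerve


def _render_c2_train(circuit, stim, duration_s, dt_ms, rng):
    """C2 driven directly at a fixed rate; VSI's synaptic response."""
    a, p = circuit.animal, circuit.params
    n_samp = int(round(duration_s * 1000.0 / dt_ms))
    spike = _coh.spike_template(dt_ms)

    c2_times = stim.start_s + np.arange(0.0, stim.duration_s, 1.0 / stim.rate_hz)
    c2_v = np.full(n_samp, -45.0)
    _coh.add_events(c2_v, c2_times, spike, dt_ms)

    vsi_v = np.full(n_samp, -50.0)
    vsi_soma = np.asarray([])
    nerve = np.asarray([])
    t_ms = np.arange(n_samp) * dt_ms

    if circuit.hi_di:
        # smooth biphasic direct PSP, measured amplitudes (d, h)
        _, psp = _coh.compose_psp(a.d_mv, a.h_mv, dt_ms)
        seg = min(n_samp, psp.size)
        shift = int(round((stim.start_s - _coh.PSP_STIM_ONSET_S) * 1000.0 / dt_ms))
        if shift >= 0:
            m = min(seg, n_samp - shift)
            vsi_v[shift : shift + m] += psp[:m]
        else:
            vsi_v[: seg + shift] += psp[-shift:seg]
    else:
        # polysynaptic barrage of recruited EPSPs riding a slow mound
        mound = _exp_kernel_filter(
            _impulses(c2_times, n_samp, dt_ms), 800.0, 3000.0, dt_ms
        )
        if mound.max() > 0:
            vsi_v += a.dep_norm_mv * mound / mound.max()
        epsp_kernel = _exp_kernel_filter(_unit_impulse(n_samp, dt_ms), 8.0, 60.0, dt_ms)
        epsp_kernel = epsp_kernel[: int(400 / dt_ms)] / max(epsp_kernel.max(), 1e-9)
        t_ev = stim.start_s
        while t_ev < min(stim.start_s + 10.0, duration_s - 0.2):
            inwin = t_ev < stim.start_s + stim.duration_s
            rate = 12.0 if inwin else 12.0 * np.exp(-(t_ev - stim.start_s - stim.duration_s) / 3.0)
            rate = max(rate, 1.0)
            t_ev += rng.exponential(1.0 / rate)
            amp = rng.lognormal(np.log(0.3), 0.4)
            _coh.add_events(vsi_v, [t_ev], amp * epsp_kernel, dt_ms)
        # delayed inhibitory sag from the direct synapse (mostly hidden
        # under the barrage; the latent depolarization model already
        # carries the h dependence of the net response)
        sag = _exp_kernel_filter(_impulses(c2_times, n_samp, dt_ms), 400.0, 1300.0, dt_ms)
        if sag.max() > 0:
            vsi_v -= 0.15 * a.h_mv * sag / sag.max()

        if circuit.pdn6_intact and a.evoked_spikes > 0:
            # C2 excitation of the distal zone drives (mostly antidromic) spikes
            n_ev = a.evoked_spikes
            ts = stim.start_s + 0.3 + np.sort(rng.uniform(0.0, stim.duration_s + 0.5, n_ev))
            antidromic = _coh.zone_switch_cycle(a.h_mv, a.zone_zeta, 1, circuit.zone_mapping) > 0
            if antidromic:
                vsi_soma = ts + p.conduction_delay_ms / 1000.0
                nerve = ts
            else:
                vsi_soma = ts
                nerve = ts + p.conduction_delay_ms / 1000.0
            _coh.add_events(vsi_v, vsi_soma, spike, dt_ms)

    impulse = np.zeros(n_samp)
    _coh.add_events(impulse, nerve, _coh.triphasic_template(dt_ms, amp=0.5), dt_ms)

    channels = {
        "C2": c2_v + rng.normal(0.0, p.noise_mv, n_samp),
        "VSI_soma": vsi_v + rng.normal(0.0, p.noise_mv, n_samp),
        "PdN6": impulse + rng.normal(0.0, p.nerve_noise, n_samp),
    }
    t_s = t_ms / 1000.0
    return t_s, channels, c2_times, vsi_soma, nerve


def _impulses(times_s, n_samp, dt_ms):
    x = np.zeros(n_samp)
    idx = np.clip((np.asarray(times_s) * 1000.0 / dt_ms).astype(int), 0, n_samp - 1)
    np.add.at(x, idx, 1.0)
    return x


def _unit_impulse(n_samp, dt_ms):
    x = np.zeros(n_samp)
    x[0] = 1.0
    return x


def simulate_episode(
    circuit: CircuitState,
    stim: PdN3Stim | C2TrainStim | None = None,
    duration_s: float = 70.0,
    dt_ms: float = 0.25,
    seed: int = 0,
) -> EpisodeRecording:
    """Simulate one episode and return its recording.

    Identical (circuit, stim, duration, dt, seed) give a bit-identical
    recording.  Without stimulation the network is quiescent.  A swim
    episode needs ``duration_s`` of at least 60 s to contain the full
    motor pattern.
    """
    if dt_ms > 0.5:
        raise ValueError("dt_ms must be <= 0.5 ms")
    if isinstance(stim, PdN3Stim) and duration_s < 60.0:
        raise ValueError("swim episodes need duration_s >= 60")
    rng = np.random.default_rng(seed)
    p = circuit.params

    if stim is None or (circuit.hi_di and isinstance(stim, PdN3Stim)):
        # quiescent (or Hi-Di-silenced) network: flat noisy traces
        n_samp = int(round(duration_s * 1000.0 / dt_ms))
        channels = {
            "DSI": -48.0 + rng.normal(0.0, p.noise_mv, n_samp),
            "C2": -45.0 + rng.normal(0.0, p.noise_mv, n_samp),
            "VSI_soma": -50.0 + rng.normal(0.0, p.noise_mv, n_samp),
            "PdN6": rng.normal(0.0, p.nerve_noise, n_samp),
        }
        spike_times = {"DSI": np.asarray([]), "C2": np.asarray([]), "VSI_soma": np.asarray([])}
        nerve = np.asarray([])
        window = (stim.start_s, stim.start_s + stim.duration_s) if stim else (0.0, 0.0)
        scaffold = {"count": 0, "n_cycles": 0, "loss": 0, "extra": 0, "h_eff": circuit.animal.h_mv}
    elif isinstance(stim, PdN3Stim):
        scaffold = _scaffold(circuit, stim, rng)
        _, channels, dsi_t, c2_t, vsi_t, nerve = _render_swim(
            circuit, stim, duration_s, dt_ms, rng, scaffold
        )
        spike_times = {"DSI": dsi_t, "C2": c2_t, "VSI_soma": vsi_t}
        window = (stim.start_s, stim.start_s + stim.duration_s)
    elif isinstance(stim, C2TrainStim):
        _, channels, c2_t, vsi_t, nerve = _render_c2_train(
            circuit, stim, duration_s, dt_ms, rng
        )
        spike_times = {"C2": c2_t, "VSI_soma": vsi_t}
        window = (stim.start_s, stim.start_s + stim.duration_s)
        scaffold = {"count": 0, "n_cycles": 0, "loss": 0, "extra": 0, "h_eff": circuit.animal.h_mv}
    else:
        raise TypeError(f"unknown stimulation protocol: {stim!r}")

    for name, v in channels.items():
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise IntegrationError(
                f"non-finite voltage in unit {name} at t = {bad * dt_ms / 1000.0:.4f} s"
            )

    rec = EpisodeRecording(
        dt_ms=dt_ms,
        channels=channels,
        spike_times=spike_times,
        nerve_impulse_times=nerve,
        stim_window=window,
        condition={
            "animal_id": circuit.animal.id,
            "pdn6_intact": circuit.pdn6_intact,
            "hi_di": circuit.hi_di,
            "clamp_mode": circuit.clamp_mode,
            "clamp_g_ns": circuit.clamp_g_signed_ns,
            "seed": seed,
            "n_cycles": scaffold["n_cycles"],
            "vsi_burst_count": scaffold["count"],
            "burst_loss": scaffold["loss"],
            "h_eff_mv": scaffold["h_eff"],
        },
    )
    log.debug(
        "episode animal=%s intact=%s clamp=%s bursts=%d",
        circuit.animal.id,
        circuit.pdn6_intact,
        circuit.clamp_mode,
        scaffold["count"],
    )
    return rec


# ---------------------------------------------------------------------------
# population calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    chosen: _coh.LossMapping
    achieved: dict
    targets: dict
    ok: bool
    grid_size: int = 0

    def write_config(self, path) -> None:
        import yaml
        from pathlib import Path

        Path(path).write_text(
            yaml.safe_dump(
                {
                    "loss_mapping": {
                        "alpha": self.chosen.alpha,
                        "beta": self.chosen.beta,
                        "gamma": self.chosen.gamma,
                    },
                    "achieved": self.achieved,
                    "targets": self.targets,
                }
            )
        )


DEFAULT_CALIBRATION_TARGETS = {
    "mean_pct_change": -24.7,   # mean % change in burst count after disconnection
    "lesioned_cov": 0.47,       # CoV of the lesioned burst counts
    "r2_pct_vs_h": 0.44,        # regression of % change on h
}


def calibrate_population_model(
    targets: dict | None = None,
    seed: int = 0,
    n_mc: int = 6000,
    grid: tuple | None = None,
    rel_tol: float = 0.2,
) -> CalibrationReport:
    """Grid-search the three burst-loss coefficients against cohort targets.

    Uses one common set of Monte-Carlo draws across the whole grid, so
    the search is deterministic given the seed.  If no grid point lands
    within the relative tolerance on every target, the report is flagged
    (``ok = False``) rather than raising.
    """
    tg = dict(DEFAULT_CALIBRATION_TARGETS)
    if targets:
        tg.update(targets)
    rng = np.random.default_rng(seed)
    cfg = _coh.CohortConfig(n_animals=2)

    h = np.empty(n_mc)
    for i in range(n_mc):
        h[i] = _coh._trunc_normal(rng, cfg.h_mean, cfg.h_sd, cfg.h_floor)
    eps_a = rng.standard_normal(n_mc)
    eps_e = rng.standard_normal(n_mc)
    delta = rng.choice([-1, 0, 1], p=CircuitParams().count_jitter_p, size=n_mc)
    base = np.clip(
        np.round(rng.normal(cfg.burst_baseline_mean, cfg.burst_baseline_sd, n_mc)),
        *cfg.burst_baseline_range,
    )
    n_cycles = np.clip(base + delta, 2, 9)

    # Bounds are physiological priors: the loss slope cannot exceed
    # ~1.2 bursts/mV or an average animal would lose the whole episode,
    # and the intercept keeps loss ~0 at the smallest observed h.
    alphas, betas, gammas = grid or (
        np.linspace(-2.5, 0.5, 13),
        np.linspace(0.4, 1.2, 9),
        np.linspace(0.5, 2.0, 11),
    )
    w_a, w_e = _coh.DEFAULT_LOSS.w_animal, _coh.DEFAULT_LOSS.w_episode
    eps_mix = w_a * eps_a + w_e * eps_e

    best = None
    for alpha in np.atleast_1d(alphas):
        for beta in np.atleast_1d(betas):
            for gamma in np.atleast_1d(gammas):
                loss = np.clip(np.round(alpha + beta * h + gamma * eps_mix), 0, n_cycles)
                counts = n_cycles - loss
                pct = -100.0 * loss / n_cycles
                mpc = pct.mean()
                cv = counts.std(ddof=1) / counts.mean() if counts.mean() > 0 else np.inf
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = np.corrcoef(pct, h)[0, 1]
                r2 = r * r if np.isfinite(r) else 0.0
                err = (
                    ((mpc - tg["mean_pct_change"]) / tg["mean_pct_change"]) ** 2
                    + ((cv - tg["lesioned_cov"]) / tg["lesioned_cov"]) ** 2
                    + ((r2 - tg["r2_pct_vs_h"]) / tg["r2_pct_vs_h"]) ** 2
                )
                if best is None or err < best[0]:
                    best = (err, float(alpha), float(beta), float(gamma), mpc, cv, r2)

    err, alpha, beta, gamma, mpc, cv, r2 = best
    achieved = {"mean_pct_change": float(mpc), "lesioned_cov": float(cv), "r2_pct_vs_h": float(r2)}
    ok = all(
        abs(achieved[k] - tg[k]) <= rel_tol * abs(tg[k]) for k in achieved
    )
    return CalibrationReport(
        chosen=_coh.LossMapping(alpha=alpha, beta=beta, gamma=gamma),
        achieved=achieved,
        targets=tg,
        ok=ok,
        grid_size=len(np.atleast_1d(alphas)) * len(np.atleast_1d(betas)) * len(np.atleast_1d(gammas)),
    )
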