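"""Virtual-animal cohorts and synthetic recordings.

Each virtual animal carries hidden per-animal parameters — chiefly the
hyperpolarization amplitude ``h`` of the direct C2->VSI synaptic
potential (the hidden phenotype) and a depolarization amplitude ``d`` —
drawn from the population distributions measured in high-divalent-cation
(Hi-Di) saline: h ~ N(2.9, 1.3) mV and d ~ N(0.8, 0.36) mV, truncated
at small positive floors.  A latent susceptibility residual ``epsilon``
captures animal-level variation not explained by ``h``; it is shared
between the lesion-loss mapping and the normal-saline depolarization so
that the two express the same underlying physiology.

The lesion-susceptibility mapping — expected burst loss after commissure
disconnection = clip(round(alpha + beta*h + gamma*eps), 0, n) — is the
population model whose three coefficients are set by
``swimcpg.circuit.calibrate_population_model``; the frozen defaults
below are that calibration's output.  The same mapping drives both the
episode simulator and the behavioral flexion-count generator, so
trace-level and count-level cohorts agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from . import synapse as _syn
from . import analysis as _an
from .io import EpisodeRecording

__all__ = [
    "LossMapping",
    "ZoneMapping",
    "VirtualAnimal",
    "CohortConfig",
    "DEFAULT_LOSS",
    "DEFAULT_ZONES",
    "generate_cohort",
    "generate_behavior",
    "generate_hi_di_psp_trace",
    "generate_dual_site_fixture",
    "burst_loss",
    "zone_switch_cycle",
    "spike_template",
    "triphasic_template",
    "biphasic_template",
]


# ---------------------------------------------------------------------------
# population mappings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossMapping:
    """Linear-in-h mapping from hidden inhibition to lesioned burst loss.

    Expected loss = clip(round(alpha + beta*h_eff + gamma*eps), 0, n)
    where eps mixes the animal's susceptibility residual with episode
    noise.  ``h_eff`` is the effective inhibition in mV (the animal's h
    plus any dynamic-clamp contribution).
    """

    alpha: float
    beta: float
    gamma: float
    # split of the eps term between animal-level and episode-level noise
    w_animal: float = 0.9
    w_episode: float = 0.436


@dataclass(frozen=True)
class ZoneMapping:
    """Mapping from h to the intact spike-initiation-zone census.

    The number of terminal antidromic cycles in an intact episode is
    M = clip(round(a + b*h + c*zeta), 0, n); M = 0 gives an
    orthodromic-only animal, M = n an antidromic-only one.  Coefficients
    chosen so the population census reproduces the observed
    24.6% / 68.1% / 7.2% antidromic / mixed / orthodromic split.
    """

    a: float = 0.71
    b: float = 1.10
    c: float = 1.84


# Frozen output of circuit.calibrate_population_model (seed 0); see
# docs/methods.md for the calibration targets.
DEFAULT_LOSS = LossMapping(alpha=-2.5, beta=1.2, gamma=1.55)
DEFAULT_ZONES = ZoneMapping()


def burst_loss(
    h_eff_mv: float,
    eps_animal: float,
    n_cycles: int,
    rng: np.random.Generator,
    mapping: LossMapping = DEFAULT_LOSS,
) -> int:
    """Draw the number of bursts lost to commissure disconnection."""
    eps = mapping.w_animal * eps_animal + mapping.w_episode * rng.standard_normal()
    raw = mapping.alpha + mapping.beta * h_eff_mv + mapping.gamma * eps
    return int(np.clip(round(raw), 0, n_cycles))


def zone_switch_cycle(
    h_mv: float,
    zeta_animal: float,
    n_cycles: int,
    mapping: ZoneMapping = DEFAULT_ZONES,
) -> int:
    """Number of terminal cycles whose spikes are distally initiated."""
    raw = mapping.a + mapping.b * h_mv + mapping.c * zeta_animal
    return int(np.clip(round(raw), 0, n_cycles))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VirtualAnimal:
    """Hidden per-animal parameters plus derived observables."""

    id: int
    h_mv: float                  # hyperpolarization amplitude of the direct PSP
    d_mv: float                  # depolarization amplitude of the direct PSP
    epsilon: float               # latent susceptibility residual, N(0,1)
    zone_zeta: float             # latent for the spike-initiation census, N(0,1)
    baseline_bursts: int         # VSI bursts per intact motor-pattern episode
    flexion_mu: float            # mean flexion count of the intact behavior
    dep_norm_mv: float           # C2-evoked depolarization, normal saline, post-block
    evoked_spikes: int           # VSI spikes evoked by C2 train, intact commissure
    seed_entropy: int            # per-animal reproducible noise seed


@dataclass(frozen=True)
class CohortConfig:
    """Population distribution parameters for a virtual cohort."""

    n_animals: int = 34
    h_mean: float = 2.9
    h_sd: float = 1.3
    h_floor: float = 0.2
    d_mean: float = 0.8
    d_sd: float = 0.36
    d_floor: float = 0.1
    burst_baseline_mean: float = 6.0
    burst_baseline_sd: float = 0.9
    burst_baseline_range: tuple = (4, 8)
    flexion_mean: float = 6.0
    flexion_animal_sd: float = 1.16
    flexion_trial_sd: float = 0.5
    flexion_range: tuple = (2, 10)
    # normal-saline depolarization model: dep = dep0 - dep_h*h - dep_eps*eps + dep_sd*N
    dep0: float = 5.9
    dep_h: float = 1.0
    dep_eps: float = 1.2
    dep_sd: float = 0.9
    dep_floor: float = 0.1
    # C2-evoked spike count with intact commissure: LogNormal, capped
    evoked_log_mean: float = math.log(12.0)
    evoked_log_sd: float = 1.0
    evoked_cap: int = 58
    # complete behavioral failure gate (in vivo only)
    fail_mid_mv: float = 4.2
    fail_slope_mv: float = 0.6
    surgery_effect: float = 0.5   # flexion decrement common to cut and sham arms
    loss: LossMapping = DEFAULT_LOSS
    zones: ZoneMapping = DEFAULT_ZONES

    def __post_init__(self):
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        if self.h_sd <= 0 or self.d_sd <= 0:
            raise ValueError("distribution SDs must be positive")


def _trunc_normal(rng, mean, sd, floor):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= floor:
            return float(x)
    return float(floor)


def generate_cohort(config: CohortConfig | None = None, seed: int = 0):
    """Draw a reproducible cohort of virtual animals.

    Pure function of (config, seed): the same arguments give an
    identical cohort.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    lo, hi = cfg.burst_baseline_range
    animals = []
    for i in range(cfg.n_animals):
        h = _trunc_normal(rng, cfg.h_mean, cfg.h_sd, cfg.h_floor)
        d = _trunc_normal(rng, cfg.d_mean, cfg.d_sd, cfg.d_floor)
        eps = float(rng.standard_normal())
        zeta = float(rng.standard_normal())
        baseline = int(np.clip(round(rng.normal(cfg.burst_baseline_mean, cfg.burst_baseline_sd)), lo, hi))
        flex_mu = float(rng.normal(cfg.flexion_mean, cfg.flexion_animal_sd))
        dep = max(
            cfg.dep0 - cfg.dep_h * h - cfg.dep_eps * eps + cfg.dep_sd * rng.standard_normal(),
            cfg.dep_floor,
        )
        evoked = int(min(round(rng.lognormal(cfg.evoked_log_mean, cfg.evoked_log_sd)), cfg.evoked_cap))
        entropy = int(rng.integers(0, 2**31 - 1))
        animals.append(
            VirtualAnimal(
                id=i,
                h_mv=h,
                d_mv=d,
                epsilon=eps,
                zone_zeta=zeta,
                baseline_bursts=baseline,
                flexion_mu=flex_mu,
                dep_norm_mv=float(dep),
                evoked_spikes=evoked,
                seed_entropy=entropy,
            )
        )
    return animals


def generate_behavior(
    animal: VirtualAnimal,
    lesioned: bool,
    rng: np.random.Generator,
    *,
    surgery: bool = False,
    config: CohortConfig | None = None,
) -> int:
    """Draw one escape-swim flexion count for an animal.

    Intact swims are narrowly distributed around the animal's baseline.
    After commissure transection the count drops by the shared burst-loss
    mapping, and strongly inhibited animals (large h) frequently fail to
    swim at all — a retraction without flexion scores 0.
    """
    cfg = config or CohortConfig()
    lo, hi = cfg.flexion_range
    mu = animal.flexion_mu - (cfg.surgery_effect if surgery else 0.0)
    base = int(np.clip(round(rng.normal(mu, cfg.flexion_trial_sd)), lo, hi))
    if not lesioned:
        return base
    p_fail = 0.5 * (1.0 + math.erf((animal.h_mv - cfg.fail_mid_mv) / (cfg.fail_slope_mv * math.sqrt(2.0))))
    if rng.random() < p_fail:
        return 0
    loss = burst_loss(animal.h_mv, animal.epsilon, base, rng, cfg.loss)
    return max(base - loss, 0)


# ---------------------------------------------------------------------------
# waveform templates
# ---------------------------------------------------------------------------

def spike_template(dt_ms: float, amp_mv: float = 78.0) -> np.ndarray:
    """Intracellular action-potential template (~3 ms, with small AHP)."""
    t = np.arange(0.0, 14.0, dt_ms)
    rise = np.exp(-((t - 1.0) ** 2) / (2 * 0.35**2))
    ahp = -0.06 * np.exp(-(t - 2.2).clip(0) / 4.0) * (t > 2.2)
    return amp_mv * (rise + ahp)


def _gauss(t, mu, sig):
    return np.exp(-((t - mu) ** 2) / (2 * sig**2))


def triphasic_template(dt_ms: float, amp: float = 1.0) -> np.ndarray:
    """Extracellular impulse of a propagating spike: down, up, down."""
    t = np.arange(0.0, 6.0, dt_ms)
    v = -1.0 * _gauss(t, 1.4, 0.35) + 0.85 * _gauss(t, 2.6, 0.4) - 0.7 * _gauss(t, 3.9, 0.45)
    return amp * v


def biphasic_template(dt_ms: float, amp: float = 1.0) -> np.ndarray:
    """Extracellular impulse blocked inside the pipette: down, then up."""
    t = np.arange(0.0, 6.0, dt_ms)
    v = -1.0 * _gauss(t, 1.6, 0.4) + 0.8 * _gauss(t, 3.4, 0.7)
    return amp * v


def add_events(trace: np.ndarray, times_s, template: np.ndarray, dt_ms: float) -> None:
    """Add a waveform template into ``trace`` at each event time (in place)."""
    n = trace.size
    m = template.size
    for ts in np.atleast_1d(times_s):
        i = int(round(ts * 1000.0 / dt_ms))
        if i < 0 or i >= n:
            continue
        j = min(i + m, n)
        trace[i:j] += template[: j - i]


# ---------------------------------------------------------------------------
# Hi-Di PSP traces
# ---------------------------------------------------------------------------

# Standard direct-synapse test: C2 driven at 10 Hz for 4 s.
PSP_STIM_RATE_HZ = 10.0
PSP_STIM_DUR_S = 4.0
PSP_STIM_ONSET_S = 1.0
PSP_TRACE_DUR_S = 16.0
PSP_SMOOTH_MS = 100.0  # moving-average window used when reading slow PSPs


# The inhibitory component is delayed: its release only builds up once
# the train has been running for a while, which is what makes the
# potential visibly biphasic (initial depolarization, delayed
# hyperpolarization).
PSP_INHIB_DELAY_S = 0.8


@lru_cache(maxsize=8)
def _psp_kernels(dt_ms: float):
    """Unit-peak depolarizing and hyperpolarizing PSP kernels.

    The depolarizing lobe is a saturating envelope (300 ms rise) that
    persists through the 10 Hz / 4 s train and decays (500 ms) after
    it.  The hyperpolarizing lobe is the literal two-component
    first-order activation (700/1300 ms decay constants) integrated
    over the presynaptic spikes, whose release starts 0.8 s into the
    train.  Both are normalized to unit peak within the measurement
    window.
    """
    n = int(round(PSP_TRACE_DUR_S * 1000.0 / dt_ms))
    t_s = np.arange(n) * dt_ms / 1000.0
    on = PSP_STIM_ONSET_S
    off = PSP_STIM_ONSET_S + PSP_STIM_DUR_S

    k_d = np.zeros(n)
    during = (t_s >= on) & (t_s < off)
    k_d[during] = 1.0 - np.exp(-(t_s[during] - on) / 0.3)
    after = t_s >= off
    k_d[after] = k_d[during][-1] * np.exp(-(t_s[after] - off) / 0.5)

    # presynaptic command for the delayed inhibitory component
    spike_times_s = np.arange(on + PSP_INHIB_DELAY_S, off, 1.0 / PSP_STIM_RATE_HZ)
    k = _syn.SynapseKinetics(g_syn_ns=1.0, v_post_rest_mv=-50.0)
    v_pre = np.full(n, -45.0)
    add_events(v_pre, spike_times_s, spike_template(dt_ms, amp_mv=75.0), dt_ms)
    i_syn = _syn.clamp_trace(v_pre, k, dt_ms)
    k_h = i_syn / (k.v_syn_mv - k.v_post_rest_mv)  # weighted S(t), peak < 1
    k_h = k_h / k_h.max()
    return t_s, k_d, k_h


def _measure_psp_smoothed(t_s, v, dt_ms):
    w = max(1, int(round(PSP_SMOOTH_MS / dt_ms)))
    vp = np.pad(np.asarray(v, float), (w // 2, w - w // 2 - 1), mode="edge")
    vs = np.convolve(vp, np.ones(w) / w, mode="valid")
    return _an.measure_psp(
        t_s,
        vs,
        PSP_STIM_ONSET_S,
        baseline_window_s=(0.0, PSP_STIM_ONSET_S - 0.05),
        search_window_s=(PSP_STIM_ONSET_S, PSP_STIM_ONSET_S + PSP_STIM_DUR_S),
    )


def compose_psp(d_mv: float, h_mv: float, dt_ms: float = 0.5):
    """Noise-free biphasic PSP whose *measured* amplitudes are (d, h).

    The two unit kernels are rescaled by a short fixed-point iteration
    through the standard amplitude-reading rule, so the residual
    temporal overlap between the lobes is compensated exactly; the
    construction is jointly linear in (d, h).
    """
    t_s, k_d, k_h = _psp_kernels(dt_ms)
    sd, sh = float(d_mv), float(h_mv)
    for _ in range(8):
        v = sd * k_d - sh * k_h
        m = _measure_psp_smoothed(t_s, v, dt_ms)
        if d_mv > 1e-9 and m.depolarization_mv > 1e-9:
            sd *= d_mv / m.depolarization_mv
        if h_mv > 1e-9 and m.hyperpolarization_mv > 1e-9:
            sh *= h_mv / m.hyperpolarization_mv
    return t_s, sd * k_d - sh * k_h


def measure_hi_di_psp(time_s, trace_mv, dt_ms: float) -> _an.PSPMeasure:
    """Standard amplitude reading for slow Hi-Di synaptic potentials.

    Applies the package's standard smoothing before the baseline/peak/
    trough rule, as one would when cursor-reading a slow potential.
    """
    return _measure_psp_smoothed(np.asarray(time_s), np.asarray(trace_mv), dt_ms)


def generate_hi_di_psp_trace(
    animal: VirtualAnimal,
    noise_sd: float = 0.1,
    seed: int = 0,
    dt_ms: float = 0.5,
    baseline_mv: float = -50.0,
):
    """Synthesize the Hi-Di-isolated biphasic PSP of one animal.

    Returns (time_s, trace_mv, meta).  The depolarizing lobe scales to
    the animal's d, the delayed hyperpolarizing lobe to its h; white
    Gaussian noise is added on top.  Stimulus timing (10 Hz, 4 s) is in
    the metadata.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t_s, psp = compose_psp(animal.d_mv, animal.h_mv, dt_ms)
    rng = np.random.default_rng(seed)
    v = baseline_mv + psp
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=v.size)
    meta = {
        "stim_onset_s": PSP_STIM_ONSET_S,
        "stim_rate_hz": PSP_STIM_RATE_HZ,
        "stim_duration_s": PSP_STIM_DUR_S,
        "animal_id": animal.id,
        "hi_di": True,
    }
    return t_s, v, meta


# ---------------------------------------------------------------------------
# dual-site propagation fixtures
# ---------------------------------------------------------------------------

def generate_dual_site_fixture(
    category: str,
    n_bursts: int = 5,
    delay_ms: float = 25.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    dt_ms: float = 0.25,
) -> EpisodeRecording:
    """Soma + nerve recording with a known propagation archetype.

    ``category`` is one of ``antidromic-only``, ``mixed``,
    ``orthodromic-only``.  Orthodromic bursts place the nerve impulse
    one conduction delay after each soma spike; antidromic bursts place
    it one delay before.  The mixed archetype switches from orthodromic
    to antidromic mid-episode, as the motor pattern typically does.
    """
    if category not in ("antidromic-only", "mixed", "orthodromic-only"):
        raise ValueError(f"unknown category: {category}")
    if delay_ms <= 0:
        raise ValueError("delay_ms must be positive")
    rng = np.random.default_rng(seed)

    period_s = 4.0
    first_s = 3.0
    soma_times = []
    burst_zone = []
    for b in range(n_bursts):
        onset = first_s + b * period_s
        n_sp = int(rng.integers(6, 10))
        isi = rng.uniform(0.07, 0.11, size=n_sp).cumsum()
        soma_times.append(onset + isi)
        if category == "antidromic-only":
            zone = "antidromic"
        elif category == "orthodromic-only":
            zone = "orthodromic"
        else:
            zone = "orthodromic" if b < (n_bursts + 1) // 2 else "antidromic"
        burst_zone.append(zone)

    soma = np.concatenate(soma_times)
    nerve = np.concatenate(
        [
            ts + (delay_ms / 1000.0 if z == "orthodromic" else -delay_ms / 1000.0)
            for ts, z in zip(soma_times, burst_zone)
        ]
    )
    nerve.sort()

    duration_s = first_s + n_bursts * period_s + 2.0
    n = int(round(duration_s * 1000.0 / dt_ms))
    v_soma = np.full(n, -50.0)
    add_events(v_soma, soma, spike_template(dt_ms), dt_ms)
    v_nerve = np.zeros(n)
    add_events(v_nerve, nerve, triphasic_template(dt_ms, amp=0.5), dt_ms)
    if noise_sd > 0:
        v_soma += rng.normal(0.0, noise_sd, n)
        v_nerve += rng.normal(0.0, noise_sd / 2, n)

    return EpisodeRecording(
        dt_ms=dt_ms,
        channels={"VSI_soma": v_soma, "PdN6": v_nerve},
        spike_times={"VSI_soma": soma},
        nerve_impulse_times=nerve,
        stim_window=(0.5, 1.0),
        condition={"fixture_category": category, "seed": seed, "pdn6_intact": True},
    )
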