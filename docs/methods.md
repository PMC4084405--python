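# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not emulate.

## The artificial synapse (`swimcpg.synapse`)

The clamp current is the literal first-order kinetic model: `I_syn =
g_syn · S(t) · (V_syn − V_post)`, with `(1 − S_∞)τ dS/dt = S_∞ − S` and
a tanh activation gated at `V_thresh`. Two components (weights 0.5/0.5,
τ = 700 and 1300 ms) share one activation curve; the 50/50 split is a
symmetric default and is configurable, since only the two time
constants and the total conductance are constrained by the clamp
protocol. Defaults: `g_syn` = 1000 nS, `V_syn` = −80 mV, `V_slope` =
20 mV, `V_thresh` = −10 mV (50% height of model C2 spikes that rise
from −45 mV to ≈+30 mV), `V_post` fixed at the VSI rest (−50 mV).

Integration is explicit Euler at the simulation step (default 0.25 ms,
0.1 ms supported), with two guards: `S_∞` is capped at 1 − 10⁻⁶ so the
singular `(1 − S_∞)` factor stays finite, and whenever the effective
time constant `(1 − S_∞)τ` falls below the step the update snaps to
`S_∞` instead of overshooting. A step larger than min(τ)/10 is
rejected. Sub-threshold decay therefore matches `S₀·e^(−t/τ)` to
better than 0.5% at dt = τ/1000, and `S` remains in [0, 1) for any
input. Subtraction mode negates `g_syn` and nothing else.

## The circuit simulator (`swimcpg.circuit`)

The single-side DSI–C2–VSI circuit keeps the classic topology (DSI→C2
excitatory, C2→DSI biphasic, DSI→VSI multi-component, C2→VSI_proximal
biphasic with the 700/1300 ms inhibitory kinetics, C2→VSI_distal
excitatory across the commissure, VSI→C2 and VSI→DSI inhibitory, plus
a recruited polysynaptic pool from C2 onto the proximal zone). The
three DSIs are collapsed into one unit with threefold weight. The
direct C2→VSI edge is scaled per animal so the Hi-Di-isolated PSP has
hyperpolarization amplitude `h` and depolarization `d`.

The simulator is a *scheduled generative model*, not a
conductance-based integrator. An earlier design used adaptive
integrate-and-fire units throughout, but a single adaptation variable
produces spike-frequency adaptation, not the 2–20 s network bursting
this circuit needs, and robustly tuning an emergent slow oscillator
would have put the scientific burden on a component the study does not
constrain. Instead:

- an episode drive, charged by the 5 Hz / 3 s initiating nerve train,
  decays exponentially (τ = 25 s) and schedules the burst scaffold
  (default period 4.5 s with 4% cycle jitter; per-animal baseline of
  5–7 cycles with a small per-episode jitter of ±1 cycle at p = 0.08
  each);
- C2 fires decelerating ~13 Hz bursts on every cycle; VSI bursts follow
  each dorsal phase at a 2.3 s lag;
- per-cycle spike-initiation-zone occupancy and the post-lesion burst
  count follow the two calibrated population mappings below;
- voltage and nerve channels are rendered from spike templates,
  exponential synaptic filters and the literal clamp kinetics, with
  0.1 mV RMS white measurement noise (0.01 on the nerve channel), at
  4 kHz (dt = 0.25 ms).

The dynamic clamp, when attached, is computed sample-by-sample from
the rendered C2 voltage through `synapse.clamp_trace` — exactly the
computation the clamp hardware performs — and the resulting current is
added to the VSI soma channel (0.001 mV/pA display coupling, giving
the characteristically oversized somatic hyperpolarizations of somatic
current injection) and stored as its own channel.

Spike-propagation geometry: a proximally initiated spike reaches the
nerve electrode one conduction delay (25 ms) after the soma; a distally
initiated spike appears on the nerve first and reaches the soma one
delay later. The 25 ms default is chosen to make the ordering
unambiguous at 4 kHz sampling. After disconnection no impulse crosses
the cut: the nerve channel is silent and distal spikes are unrecorded
(the distal zone is assumed to keep firing, but nothing it does reaches
the recording sites). The nerve electrode is idealized as
VSI-selective.

## Population mappings and calibration

Two latent mappings carry the population structure:

- **Lesion susceptibility** — bursts lost after disconnection:
  `L = clip(round(α + β·h_eff + γ·ε), 0, n)`, where `h_eff` is the
  animal's `h` plus the clamp contribution, and `ε` mixes the animal's
  susceptibility residual (weight 0.9) with per-episode noise (0.436).
  `calibrate_population_model` grid-searches (α, β, γ) against three
  cohort targets — mean percent change −24.7%, post-block burst-count
  CoV 0.47, and R² = 0.44 for percent change vs `h` — using common
  Monte-Carlo draws so the search is deterministic. The frozen result
  (seed 0) is α = −2.5, β = 1.2, γ = 1.55. The grid bounds are
  physiological priors: a slope above ~1.2 bursts/mV would cost an
  average animal its entire episode.
- **Zone census** — the number of terminal antidromic cycles in an
  intact episode: `M = clip(round(0.71 + 1.10·h + 1.84·ζ), 0, n)`.
  `M = 0` is an orthodromic-only animal, `M = n` antidromic-only; the
  coefficients place the population at the observed 24.6 / 68.1 / 7.2%
  antidromic / mixed / orthodromic split. Because both mappings grow
  with `h`, antidromic-only animals are the most impaired after the
  lesion, and episodes lose their terminal (antidromic) bursts first.

The clamp couples into `h_eff` at 1.6 mV per 1000 nS: the injected
current enters at the soma, electrotonically distant from the proximal
initiation zone, so a conductance that mimics an average natural
synapse arrives attenuated. Subtraction on the intact circuit also
extends the episode (0.8 cycles per mV of removed inhibition, capped at
2) — the proximal zone stays excitable late in the pattern, shortening
dorsal-phase bursts and letting extra cycles fit under the decaying
drive; this extension is gated to the intact circuit, where both zones
are available.

## The synthetic cohorts (`swimcpg.cohort`)

Per animal: `h ~ N(2.9, 1.3)` truncated at 0.2 mV and `d ~ N(0.8,
0.36)` truncated at 0.1 mV, drawn independently (no depol–hyperpol
correlation is observed in Hi-Di); a susceptibility residual
`ε ~ N(0, 1)` shared between the loss mapping and the normal-saline
depolarization `dep = max(5.9 − 1.0·h − 1.2·ε + 0.9·N, 0.1)` mV, so
that the measured depolarization predicts impairment through both `h`
and the residual physiology, with its R² against the Hi-Di
hyperpolarization near the observed 0.43; a burst baseline
`round(N(6, 0.9))` in [4, 8] (intact CoV ≈ 0.16) and a flexion
baseline `N(6, 1.16)` with 0.5 trial noise in [2, 10] (intact CoV ≈
0.21); and a C2-evoked spike count `LogNormal(ln 12, 1)` capped at 58,
independent of everything else (the intact-condition null).

Behavioral lesions add a complete-failure gate,
`P(failure) = Φ((h − 4.2)/0.6)` — a retraction without flexion scores
0 — reflecting that in vivo the strongly inhibited animals fail
outright; this is what pushes the post-cut flexion CoV to ≈0.64 while
the ex vivo burst CoV stays near 0.47. Both surgical arms carry a fixed
−0.5 flexion surgery effect. Swim episodes are treated as independent
(no habituation across episodes).

The Hi-Di PSP generator composes a saturating fast depolarizing
envelope (300 ms rise, persisting through the 10 Hz / 4 s train) with
the literal two-component activation kernel whose release begins 0.8 s
into the train (the delayed inhibitory component). The two lobes are
rescaled through a short fixed-point iteration *through the measurement
rule itself* (smoothed baseline/peak/trough reading, 100 ms moving
average, window spanning the train), so the measured amplitudes equal
(d, h) exactly at zero noise; the construction is jointly linear in
(d, h). Amplitude reading of slow potentials always goes through
`measure_hi_di_psp`, i.e. the standard smoothing — cursor-reading a
slow PSP off an unsmoothed trace would bias the peak by the noise
envelope.

## Measurement rules (`swimcpg.analysis`)

- Bursts: two or more spikes with inter-spike intervals strictly below
  1 s; an interval of exactly 1 s splits. Spikes inside the stimulation
  window are excluded before clustering; singletons are discarded.
- Propagation: greedy one-to-one soma–nerve pairing within ±50 ms;
  lag = nerve − soma; lag < −0.5 ms antidromic, > +0.5 ms orthodromic,
  the ±0.5 ms band ambiguous and excluded from burst labels. Burst
  labels require unanimity; an animal is antidromic-only /
  orthodromic-only only if every labeled burst is.
- Nerve impulse waveforms: prominence-based extrema; (−, +, −) is a
  propagating (triphasic) impulse, (−, +) a blocked (biphasic) one,
  anything else unknown.
- PSPs: depolarization from the baseline mean to the maximal peak,
  hyperpolarization from that peak to the following trough, both
  floored at 0.
- EPSP barrage: derivative-threshold picker (0.05 mV/ms), amplitude =
  local peak minus preceding trough, events < 0.1 mV excluded,
  analysis restricted to 10 s after stimulation onset; instantaneous
  frequency is the reciprocal inter-event interval.
- Statistics: CoV is sample SD (n−1) over mean; the variance test is
  the Brown–Forsythe (Levene median) form; regressions are OLS with
  the slope t test; paired t and one-way ANOVA with optional
  Holm–Šidák pairwise follow-up; p-values two-tailed. The repeated-
  measures ANOVAs of the original behavioral design are replaced by
  per-timepoint paired comparisons. Note that the Brown–Forsythe test
  is conservative in small samples (empirical level ≈0.037 at n = 20,
  0.047 at n = 50); its level is verified at n = 50.

## Problem sizes

Experiments run at the original sample sizes (N = 19 behavioral pairs,
34 motor-pattern preparations × 4 episodes, 52 correlation animals, 69
census animals, clamp arms of 18/9/20/19), each episode 70 s at 4 kHz.
Uncertainty bands for cohort statistics use 200 count-level cohort
replicates, which are distributionally identical to the trace-level
pipeline because burst detection recovers the scheduled counts exactly
on rendered trains.

## Known limitations

- The rhythm generator is scheduled, not emergent: burst period, phase
  lags and episode length are descriptive parameters, so the package
  cannot make claims about oscillator mechanisms (e.g. how synaptic
  kinetics set the cycle period).
- The lesion mapping is linear in `h` by design; the data constrain
  its first moments and correlations, not its functional form.
- Electrical coupling to the contralateral circuit, serotonergic
  modulation, habituation, and the biophysics of TTX block are out of
  scope; the lesion is a propagation-block flag.
- The synthetic traces carry white measurement noise only; real
  recordings have drift, stimulus artifacts and unit-crosstalk that
  the detectors here are not hardened against. Passing tests therefore
  demonstrate the correctness of the rules and the internal
  consistency of the population model, not robustness to raw
  experimental data.
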