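# swimcpg

Hidden synaptic variability and lesion susceptibility in the *Tritonia
diomedea* escape-swim central pattern generator (CPG), in silico.

## The problem

The *Tritonia* swim CPG — three interneuron types, DSI, C2 and VSI —
produces a rhythmic escape motor pattern that is remarkably uniform
across animals. Yet when the pedal commissure PdN6 (which carries the
C2 and VSI axons between the pedal ganglia) is cut or blocked, some
animals lose most of their swim while others are barely affected. The
source of that differential vulnerability is a *hidden phenotype*: the
animal-to-animal amplitude `h` of the delayed inhibitory component of
the direct C2→VSI synapse. VSI has two spike-initiation zones, one
proximal to its soma and one distal, reached through PdN6; while the
commissure is intact the distal zone backs up the proximal one, so `h`
has no behavioral consequence. After disconnection only the proximal
zone remains, and its excitability — recruited polysynaptic excitation
minus `h` — now determines how many bursts survive.

`swimcpg` packages that whole experimental program as a tested
pipeline: the dynamic-clamp artificial synapse, a circuit simulator
with lesion/Hi-Di/clamp switches, every measurement and statistical
rule, virtual-animal cohorts, and scripted population experiments.

## The model at its core

The dynamic clamp injects, each cycle, the current of a first-order
kinetic synapse:

    I_syn = g_syn · S(t) · (V_syn − V_post)

    (1 − S_∞(V_pre)) · τ_syn · dS/dt = S_∞(V_pre) − S(t)

    S_∞(V_pre) = tanh[(V_pre − V_thresh)/V_slope]   if V_pre > V_thresh,
                 0                                   otherwise

with two inhibitory components (τ_syn = 700 ms and 1300 ms), reversal
potential V_syn = −80 mV, V_post fixed at the VSI resting potential,
and g_syn ≈ 1000 nS. Conductance *subtraction* negates g_syn.
Units are mV / nS / pA / ms throughout.

At the population level, the burst loss caused by PdN6 disconnection
follows a calibrated linear mapping clip(round(α + β·h + γ·ε), 0, n)
whose three coefficients are fitted to the cohort statistics by
`swimcpg.circuit.calibrate_population_model` (see `docs/methods.md`).

## Worked example

```python
from dataclasses import replace
import swimcpg as s
import swimcpg.analysis as an
import swimcpg.circuit as ci
import swimcpg.cohort as co

animals = co.generate_cohort(co.CohortConfig(n_animals=2), seed=0)
weak = replace(animals[0], h_mv=1.2, epsilon=0.0)
strong = replace(animals[0], h_mv=5.0, epsilon=0.0)

for name, a in (("weak", weak), ("strong", strong)):
    circ = ci.build_circuit(a)
    for label, c in (("intact", circ), ("lesioned", ci.apply_lesion(circ))):
        rec = ci.simulate_episode(c, ci.PdN3Stim(), seed=4)
        n = an.detect_bursts(rec.spike_times["VSI_soma"], rec.stim_window).n_bursts
        print(f"{name} inhibition (h={a.h_mv} mV), {label}: {n} VSI bursts")

t, v, _ = co.generate_hi_di_psp_trace(strong, seed=1)
m = co.measure_hi_di_psp(t, v, 0.5)
print(f"Hi-Di PSP of the strong animal: depol {m.depolarization_mv:.2f} mV, "
      f"hyperpol {m.hyperpolarization_mv:.2f} mV")
```

prints

```
weak inhibition (h=1.2 mV), intact: 7 VSI bursts
weak inhibition (h=1.2 mV), lesioned: 7 VSI bursts
strong inhibition (h=5.0 mV), intact: 7 VSI bursts
strong inhibition (h=5.0 mV), lesioned: 4 VSI bursts
Hi-Di PSP of the strong animal: depol 0.75 mV, hyperpol 4.99 mV
```

Both virtual animals swim identically while the commissure is intact —
the synaptic difference is invisible. After the lesion the animal with
the strong inhibitory component loses three of its seven bursts while
the weak one is untouched; the Hi-Di-isolated synaptic potential reads
the hidden amplitudes back directly (a small fast depolarization, a
large delayed hyperpolarization).

## Command line

A thin CLI exposes the main entry points:

```sh
hsc simulate --seed 5 --out episode.tsv        # one swim episode (trace + events)
hsc analyze episode.tsv                        # burst count + propagation labels
hsc population --n 10 --seed 2 --out cohort/   # virtual cohort directory
hsc reproduce --seed 0 --out results/          # all population experiments
```

Traces are plain tab-separated text (time + named voltage channels)
with a JSON event sidecar.

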