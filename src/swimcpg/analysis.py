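"""Measurement and statistics applied to swim-episode recordings.

Burst detection, spike-propagation classification, nerve-impulse
waveform classification, postsynaptic-potential quantification, and the
cohort-level statistics (coefficient of variation, Levene median test,
OLS regression, percent change, paired t, one-way ANOVA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BurstSet",
    "PropagationLabel",
    "PSPMeasure",
    "CohortResult",
    "detect_spikes",
    "detect_bursts",
    "match_and_classify",
    "classify_impulse_waveform",
    "measure_psp",
    "measure_epsp_barrage",
    "cov",
    "levene_median_test",
    "linear_regression",
    "percent_change",
    "paired_t_test",
    "one_way_anova",
    "holm_sidak_pairwise",
]

# Burst rule: a cluster of two or more spikes with inter-spike intervals
# strictly below this gap (s) counts as one burst.
BURST_GAP_S = 1.0

# Propagation lag band (ms): |lag| at or below this is ambiguous.
AMBIGUITY_MS = 0.5


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BurstSet:
    """Ordered, non-overlapping bursts of a single unit's spike train."""

    bursts: list  # of (start_s, end_s, n_spikes)
    excluded_stim_spikes: int = 0

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def spike_counts(self) -> list:
        return [n for _, _, n in self.bursts]


@dataclass
class PropagationLabel:
    """Spike-, burst- and animal-level propagation classification."""

    spike_labels: list            # per soma spike: antidromic|orthodromic|unmatched
    lags_ms: list                 # nerve - soma lag per matched spike, else nan
    burst_labels: list            # per burst: antidromic|orthodromic|mixed|unlabeled
    animal_category: str          # antidromic-only | mixed | orthodromic-only

    def counts(self) -> dict:
        out = {"antidromic": 0, "orthodromic": 0, "unmatched": 0}
        for lab in self.spike_labels:
            out[lab] += 1
        return out


@dataclass
class PSPMeasure:
    """Amplitudes of a biphasic postsynaptic potential.

    Depolarization is measured from the basal resting potential to the
    maximal peak; hyperpolarization from that peak to the trough that
    follows it.
    """

    depolarization_mv: float
    hyperpolarization_mv: float
    baseline_mv: float
    peak_time_s: float
    trough_time_s: float


@dataclass
class CohortResult:
    """Per-animal rows plus derived summary statistics for one experiment."""

    name: str
    rows: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def save(self, out_dir) -> None:
        from pathlib import Path
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / f"{self.name}_rows.csv", index=False)
        (out / f"{self.name}_summary.json").write_text(
            json.dumps(self.summary, indent=1, sort_keys=True, default=float)
        )


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def detect_spikes(
    trace_mv: np.ndarray,
    threshold_mv: float,
    refractory_ms: float,
    dt_ms: float,
) -> np.ndarray:
    """Upward-threshold-crossing spike times (s), peak aligned.

    One event is emitted per refractory window; each event time is moved
    to the local voltage maximum within that window.
    """
    v = np.asarray(trace_mv, float)
    if v.size == 0:
        raise ValueError("empty trace")
    ref_n = max(1, int(round(refractory_ms / dt_ms)))
    crossings = np.flatnonzero((v[1:] >= threshold_mv) & (v[:-1] < threshold_mv)) + 1
    times = []
    last = -ref_n - 1
    for idx in crossings:
        if idx - last < ref_n:
            continue
        peak = idx + int(np.argmax(v[idx : idx + ref_n]))
        times.append(peak * dt_ms / 1000.0)
        last = idx
    return np.asarray(times)


def detect_bursts(spike_times_s, stim_window=None) -> BurstSet:
    """Partition a sorted spike train into bursts.

    Spikes inside ``stim_window`` are removed first (spikes fired during
    nerve stimulation are not counted toward bursts); the remainder is
    split at inter-spike gaps of 1 s or more and singleton groups are
    discarded (a burst needs at least two spikes).
    """
    t = np.asarray(spike_times_s, float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted ascending")
    excluded = 0
    if stim_window is not None:
        lo, hi = stim_window
        inside = (t >= lo) & (t <= hi)
        excluded = int(inside.sum())
        t = t[~inside]
    bursts = []
    start = 0
    for i in range(1, t.size + 1):
        if i == t.size or t[i] - t[i - 1] >= BURST_GAP_S:
            n = i - start
            if n >= 2:
                bursts.append((float(t[start]), float(t[i - 1]), n))
            start = i
    return BurstSet(bursts=bursts, excluded_stim_spikes=excluded)


def match_and_classify(
    soma_spikes_s,
    nerve_impulses_s,
    window_ms: float = 50.0,
    bursts: BurstSet | None = None,
) -> PropagationLabel:
    """Pair soma spikes with nerve impulses and classify propagation.

    Each soma spike is greedily paired one-to-one with the nearest nerve
    impulse within +/- window.  Lag = nerve time - soma time: a nerve
    impulse leading the soma spike (lag < -0.5 ms) marks an antidromic
    spike, a lagging impulse (> +0.5 ms) an orthodromic one; |lag| within
    the ambiguity band, or no impulse in the window, leaves the spike
    unmatched.  Burst labels require unanimity of their labeled spikes;
    the animal is antidromic-only / orthodromic-only when every burst is,
    mixed otherwise.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    soma = np.asarray(soma_spikes_s, float)
    nerve = np.asarray(nerve_impulses_s, float)
    if np.any(np.diff(soma) < 0) or np.any(np.diff(nerve) < 0):
        raise ValueError("event lists must be sorted ascending")

    win_s = window_ms / 1000.0
    # candidate pairs sorted by |lag|, greedy one-to-one assignment
    cand = []
    j0 = 0
    for i, ts in enumerate(soma):
        for j in range(j0, nerve.size):
            lag = nerve[j] - ts
            if lag < -win_s:
                j0 = j + 1
                continue
            if lag > win_s:
                break
            cand.append((abs(lag), i, j, lag))
    cand.sort()
    soma_lag = np.full(soma.size, np.nan)
    used_nerve = set()
    matched_soma = set()
    for _, i, j, lag in cand:
        if i in matched_soma or j in used_nerve:
            continue
        matched_soma.add(i)
        used_nerve.add(j)
        soma_lag[i] = lag

    labels = []
    for lag in soma_lag:
        if np.isnan(lag) or abs(lag) <= AMBIGUITY_MS / 1000.0:
            labels.append("unmatched")
        elif lag < 0:
            labels.append("antidromic")
        else:
            labels.append("orthodromic")

    if bursts is None:
        bursts = detect_bursts(soma)
    burst_labels = []
    for start, end, _ in bursts.bursts:
        in_burst = [
            lab
            for ts, lab in zip(soma, labels)
            if start <= ts <= end and lab != "unmatched"
        ]
        if not in_burst:
            burst_labels.append("unlabeled")
        elif all(l == "antidromic" for l in in_burst):
            burst_labels.append("antidromic")
        elif all(l == "orthodromic" for l in in_burst):
            burst_labels.append("orthodromic")
        else:
            burst_labels.append("mixed")

    labeled = [b for b in burst_labels if b != "unlabeled"]
    if labeled and all(b == "antidromic" for b in labeled):
        category = "antidromic-only"
    elif labeled and all(b == "orthodromic" for b in labeled):
        category = "orthodromic-only"
    else:
        category = "mixed"

    return PropagationLabel(
        spike_labels=labels,
        lags_ms=[lag * 1000.0 if np.isfinite(lag) else float("nan") for lag in soma_lag],
        burst_labels=burst_labels,
        animal_category=category,
    )


def classify_impulse_waveform(snippet, dt_ms: float) -> str:
    """Classify an extracellular impulse snippet by its extrema pattern.

    A propagating impulse recorded en passant is triphasic — two
    downward phases with a positive deflection between them — whereas an
    impulse blocked inside the recording pipette is biphasic, a downward
    deflection followed by an upward one.  Anything else is unknown.
    """
    v = np.asarray(snippet, float)
    if v.size < 5:
        return "unknown"
    span = float(v.max() - v.min())
    if span <= 0:
        return "unknown"
    prom = 0.25 * span
    pos, _ = signal.find_peaks(v, prominence=prom)
    neg, _ = signal.find_peaks(-v, prominence=prom)
    marks = sorted([(int(i), "+") for i in pos] + [(int(i), "-") for i in neg])
    pattern = tuple(s for _, s in marks)
    if pattern == ("-", "+", "-"):
        return "triphasic"
    if pattern == ("-", "+"):
        return "biphasic"
    return "unknown"


# ---------------------------------------------------------------------------
# PSP / EPSP quantification
# ---------------------------------------------------------------------------

def measure_psp(
    time_s,
    trace_mv,
    stim_onset_s: float,
    baseline_window_s,
    search_window_s,
) -> PSPMeasure:
    """Amplitudes of a (possibly biphasic) postsynaptic potential.

    Baseline is the mean over ``baseline_window_s``; depolarization is
    the maximal peak in ``search_window_s`` minus baseline (floored at
    0); hyperpolarization is that peak minus the trough found after it
    within the search window (floored at 0).
    """
    t = np.asarray(time_s, float)
    v = np.asarray(trace_mv, float)
    b0, b1 = baseline_window_s
    s0, s1 = search_window_s
    if b0 < t[0] - 1e-9 or s1 > t[-1] + 1e-9 or b1 > s1 or s0 >= s1:
        raise ValueError("baseline/search windows out of range")
    bmask = (t >= b0) & (t <= b1)
    smask = (t >= s0) & (t <= s1)
    if not bmask.any() or not smask.any():
        raise ValueError("empty baseline or search window")
    baseline = float(v[bmask].mean())
    sidx = np.flatnonzero(smask)
    peak_rel = int(np.argmax(v[sidx]))
    peak_idx = sidx[peak_rel]
    depol = max(float(v[peak_idx] - baseline), 0.0)
    after = sidx[peak_rel:]
    trough_idx = after[int(np.argmin(v[after]))]
    hyper = max(float(v[peak_idx] - v[trough_idx]), 0.0)
    return PSPMeasure(
        depolarization_mv=depol,
        hyperpolarization_mv=hyper,
        baseline_mv=baseline,
        peak_time_s=float(t[peak_idx]),
        trough_time_s=float(t[trough_idx]),
    )


def measure_epsp_barrage(
    time_s,
    trace_mv,
    stim_onset_s: float,
    *,
    window_s: float = 10.0,
    min_amplitude_mv: float = 0.1,
    slope_threshold_mv_per_ms: float = 0.05,
):
    """Detect recruited EPSPs for 10 s after stimulation onset.

    Events are picked where the voltage slope exceeds the derivative
    threshold; each event's amplitude is its local peak minus the
    preceding trough, and events smaller than 0.1 mV are excluded.
    Returns (event_times_s, amplitudes_mv, instantaneous_freq_hz), the
    frequency series being reciprocal inter-event intervals.
    """
    t = np.asarray(time_s, float)
    v = np.asarray(trace_mv, float)
    if t[-1] < stim_onset_s + window_s - 1e-9:
        raise ValueError("trace must span 10 s after stimulation onset")
    dt_ms = (t[1] - t[0]) * 1000.0
    mask = (t >= stim_onset_s) & (t <= stim_onset_s + window_s)
    idx = np.flatnonzero(mask)
    seg = v[idx]
    dv = np.gradient(seg) / dt_ms
    rising = dv > slope_threshold_mv_per_ms
    onsets = np.flatnonzero(rising[1:] & ~rising[:-1]) + 1

    times, amps = [], []
    last_end = 0
    for on in onsets:
        if on < last_end:
            continue
        # peak: first local max while slope stays >= 0
        j = on
        while j + 1 < seg.size and seg[j + 1] >= seg[j]:
            j += 1
        # preceding trough: walk back while decreasing
        k = on
        while k - 1 > last_end and seg[k - 1] <= seg[k]:
            k -= 1
        amp = float(seg[j] - seg[k])
        if amp >= min_amplitude_mv:
            times.append(float(t[idx[j]]))
            amps.append(amp)
            last_end = j
    times = np.asarray(times)
    amps = np.asarray(amps)
    if times.size >= 2:
        freq = 1.0 / np.diff(times)
    else:
        freq = np.asarray([])
    return times, amps, freq


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

def cov(values) -> float:
    """Coefficient of variation: sample SD (n-1) over mean."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("cov needs at least two values")
    m = x.mean()
    if m == 0:
        raise ValueError("cov undefined for zero mean")
    return float(x.std(ddof=1) / m)


def levene_median_test(group_a, group_b):
    """Brown–Forsythe test for equal variances (Levene median form).

    One-way ANOVA F on absolute deviations from the group medians.
    Degenerate all-equal input returns (0, 1).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    da = np.abs(a - np.median(a))
    db = np.abs(b - np.median(b))
    if np.allclose(da, da[0]) and np.allclose(db, db[0]) and np.isclose(da[0], db[0]):
        return 0.0, 1.0
    stat, p = stats.levene(a, b, center="median")
    return float(stat), float(p)


def linear_regression(x, y):
    """Ordinary least squares of y on x -> (slope, intercept, R^2, p).

    p is the two-tailed test of the slope, equivalent to the F test of
    the regression.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("regression needs n >= 3")
    if np.var(x) == 0:
        raise ValueError("var(x) must be positive")
    if np.var(y) == 0:
        # no variance to explain: slope 0, R^2 0 by convention
        return 0.0, float(y.mean()), 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


def percent_change(before: float, after: float) -> float:
    """100 * (after - before) / before."""
    if before == 0:
        raise ValueError("percent change undefined for before = 0")
    return 100.0 * (after - before) / before


def paired_t_test(a, b):
    """Two-tailed paired t test -> (t, p); errors on zero-variance diffs."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.allclose(d, d[0]):
        raise ValueError("zero variance of paired differences")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def one_way_anova(groups):
    """One-way ANOVA across groups -> (F, p)."""
    arrays = [np.asarray(g, float) for g in groups]
    if any(g.size < 2 for g in arrays):
        raise ValueError("each group needs n >= 2")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def holm_sidak_pairwise(groups, labels=None):
    """Pairwise Welch t tests with Holm–Sidak adjustment (ANOVA follow-up)."""
    arrays = [np.asarray(g, float) for g in groups]
    labels = labels or [str(i) for i in range(len(arrays))]
    pairs, raw = [], []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            _, p = stats.ttest_ind(arrays[i], arrays[j], equal_var=False)
            pairs.append((labels[i], labels[j]))
            raw.append(p)
    if not raw:
        return []
    _, adj, _, _ = multipletests(raw, method="holm-sidak")
    return [(a, b, float(p), float(q)) for (a, b), p, q in zip(pairs, raw, adj)]
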