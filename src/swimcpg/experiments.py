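"""Scripted in-silico reproductions of the study's population experiments.

Each ``run_*`` function simulates a cohort under the relevant
conditions, pushes every recording through the measurement pipeline in
:mod:`swimcpg.analysis`, and returns a :class:`CohortResult` with
per-animal rows and summary statistics.  Sample sizes default to the
ones used in the original experiments.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from . import analysis as an
from . import circuit as ci
from . import cohort as co
from . import synapse as sy

log = logging.getLogger("swimcpg.experiments")

__all__ = [
    "ExperimentSpec",
    "run_behavior_lesion",
    "run_motor_lesion",
    "run_correlation_suite",
    "run_propagation_census",
    "run_dynclamp_suite",
    "reproduce_all",
]


@dataclass(frozen=True)
class ExperimentSpec:
    """Cohort size, seed and condition switches for one experiment."""

    name: str = "experiment"
    n: int = 0
    seed: int = 0
    cohort: co.CohortConfig = field(default_factory=co.CohortConfig)
    clamp_g_ns: float = 1000.0
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _result(spec, rows, summary):
    summary = dict(summary)
    summary["config_hash"] = spec.config_hash()
    summary["seed"] = spec.seed
    res = an.CohortResult(name=spec.name, rows=rows, summary=summary)
    if spec.out_dir:
        res.save(spec.out_dir)
    return res


def _burst_count(rec) -> int:
    bs = an.detect_bursts(rec.spike_times["VSI_soma"], rec.stim_window)
    return bs.n_bursts


def _episode(animal, seed, *, lesioned=False, clamp_mode="off", g_ns=1000.0,
             cohort_cfg=None):
    circ = ci.build_circuit(
        animal,
        loss_mapping=(cohort_cfg.loss if cohort_cfg else co.DEFAULT_LOSS),
        zone_mapping=(cohort_cfg.zones if cohort_cfg else co.DEFAULT_ZONES),
    )
    if lesioned:
        circ = ci.apply_lesion(circ)
    if clamp_mode != "off":
        circ = ci.attach_dynamic_clamp(
            circ, sy.SynapseKinetics(g_syn_ns=g_ns), clamp_mode
        )
    return ci.simulate_episode(circ, ci.PdN3Stim(), seed=seed)


# ---------------------------------------------------------------------------
# behavioral lesion experiment
# ---------------------------------------------------------------------------

def run_behavior_lesion(spec: ExperimentSpec | None = None) -> an.CohortResult:
    """Paired cut/sham behavioral cohorts, 3 pre + 1 post timepoints.

    Reports mean flexion counts per timepoint and arm, the CoV time
    course, and the Levene median test on the post-surgery counts.
    """
    spec = spec or ExperimentSpec(name="behavior_lesion", n=19)
    n = spec.n or 19
    rng = np.random.default_rng(spec.seed)
    cut = co.generate_cohort(co_cfg := _with_n(spec.cohort, n), seed=spec.seed)
    sham = co.generate_cohort(co_cfg, seed=spec.seed + 10_000)

    rows = []
    for arm, animals, lesion in (("cut", cut, True), ("sham", sham, False)):
        for a in animals:
            counts = {
                f"pre{k}": co.generate_behavior(a, False, rng, config=co_cfg)
                for k in (1, 2, 3)
            }
            counts["post"] = co.generate_behavior(
                a, lesion, rng, surgery=True, config=co_cfg
            )
            rows.append({"arm": arm, "animal": a.id, "h_mv": a.h_mv, **counts})
    df = pd.DataFrame(rows)

    summary = {}
    for arm in ("cut", "sham"):
        sub = df[df.arm == arm]
        for tp in ("pre1", "pre2", "pre3", "post"):
            summary[f"{arm}_{tp}_mean"] = float(sub[tp].mean())
            summary[f"{arm}_{tp}_cov"] = an.cov(sub[tp])
    stat, p = an.levene_median_test(df[df.arm == "cut"].post, df[df.arm == "sham"].post)
    summary["levene_post_stat"] = stat
    summary["levene_post_p"] = p
    t, p_t = an.paired_t_test(df[df.arm == "cut"].pre3, df[df.arm == "cut"].post)
    summary["cut_pre_vs_post_t"] = t
    summary["cut_pre_vs_post_p"] = p_t
    return _result(spec, df, summary)


def _with_n(cfg: co.CohortConfig, n: int) -> co.CohortConfig:
    from dataclasses import replace

    return replace(cfg, n_animals=n)


# ---------------------------------------------------------------------------
# motor-pattern lesion experiment
# ---------------------------------------------------------------------------

def run_motor_lesion(spec: ExperimentSpec | None = None) -> an.CohortResult:
    """Four swim episodes per preparation; the commissure is blocked
    between the 3rd and 4th.  Reports burst counts, CoV, percent change."""
    spec = spec or ExperimentSpec(name="motor_lesion", n=34)
    n = spec.n or 34
    cfg = _with_n(spec.cohort, n)
    animals = co.generate_cohort(cfg, seed=spec.seed)

    rows = []
    for a in animals:
        seeds = [a.seed_entropy + k for k in range(4)]
        counts = [
            _burst_count(_episode(a, s, lesioned=False, cohort_cfg=cfg))
            for s in seeds[:3]
        ]
        counts.append(_burst_count(_episode(a, seeds[3], lesioned=True, cohort_cfg=cfg)))
        rows.append(
            {
                "animal": a.id,
                "h_mv": a.h_mv,
                "ep1": counts[0],
                "ep2": counts[1],
                "ep3": counts[2],
                "ep4_blocked": counts[3],
                "pct_change": an.percent_change(counts[2], counts[3])
                if counts[2] > 0
                else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "pre_mean": float(df[["ep1", "ep2", "ep3"]].to_numpy().mean()),
        "pre_cov": an.cov(df.ep3),
        "blocked_mean": float(df.ep4_blocked.mean()),
        "blocked_cov": an.cov(df.ep4_blocked),
        "mean_pct_change": float(df["pct_change"].mean()),
    }
    try:
        t, p = an.paired_t_test(df.ep1, df.ep3)
        summary["ep1_vs_ep3_p"] = p
    except ValueError:
        summary["ep1_vs_ep3_p"] = 1.0
    t, p = an.paired_t_test(df.ep3, df.ep4_blocked)
    summary["ep3_vs_blocked_p"] = p
    return _result(spec, df, summary)


# ---------------------------------------------------------------------------
# correlation suite
# ---------------------------------------------------------------------------

def run_correlation_suite(spec: ExperimentSpec | None = None) -> an.CohortResult:
    """Per-animal synaptic measurements vs motor-pattern impairment.

    For each animal: intact and post-block swim episodes; the C2-evoked
    depolarization in normal saline after the block; the direct biphasic
    PSP amplitudes in Hi-Di saline; and the C2-evoked spike count with
    the commissure intact.  Regressions reproduce the correlation
    analyses (impairment vs depolarization and vs hyperpolarization, the
    Hi-Di cross-correlations, and the intact-condition null).
    """
    spec = spec or ExperimentSpec(name="correlation_suite", n=52)
    n = spec.n or 52
    cfg = _with_n(spec.cohort, n)
    animals = co.generate_cohort(cfg, seed=spec.seed)

    rows = []
    for a in animals:
        rec_i = _episode(a, a.seed_entropy, lesioned=False, cohort_cfg=cfg)
        rec_l = _episode(a, a.seed_entropy + 1, lesioned=True, cohort_cfg=cfg)
        bursts_i = _burst_count(rec_i)
        bursts_l = _burst_count(rec_l)

        # C2 train after the block, normal saline: depolarization amplitude
        circ = ci.apply_lesion(ci.build_circuit(a, loss_mapping=cfg.loss, zone_mapping=cfg.zones))
        train = ci.simulate_episode(
            circ, ci.C2TrainStim(), duration_s=16.0, dt_ms=0.5, seed=a.seed_entropy + 2
        )
        t_s = train.time_s
        psp_n = co.measure_hi_di_psp(t_s, train.channels["VSI_soma"], train.dt_ms)

        # Hi-Di: direct biphasic PSP
        t_h, v_h, _ = co.generate_hi_di_psp_trace(a, seed=a.seed_entropy + 3)
        psp_h = co.measure_hi_di_psp(t_h, v_h, 0.5)

        rows.append(
            {
                "animal": a.id,
                "h_mv": a.h_mv,
                "d_mv": a.d_mv,
                "bursts_intact": bursts_i,
                "bursts_blocked": bursts_l,
                "pct_change": an.percent_change(bursts_i, bursts_l) if bursts_i else np.nan,
                "dep_normal_mv": psp_n.depolarization_mv,
                "dep_hidi_mv": psp_h.depolarization_mv,
                "hyp_hidi_mv": psp_h.hyperpolarization_mv,
                "evoked_spikes": a.evoked_spikes,
            }
        )
    df = pd.DataFrame(rows)

    def reg(x, y, nn):
        sub = df.iloc[:nn].dropna(subset=[x, y])
        slope, inter, r2, p = an.linear_regression(sub[x], sub[y])
        return {"slope": slope, "r2": r2, "p": p}

    n50 = min(50, n)
    n26 = min(26, n)
    n24 = min(24, n)
    summary = {
        "r2_bursts_blocked_vs_dep": reg("dep_normal_mv", "bursts_blocked", n50)["r2"],
        "p_bursts_blocked_vs_dep": reg("dep_normal_mv", "bursts_blocked", n50)["p"],
        "r2_pct_vs_dep": reg("dep_normal_mv", "pct_change", n50)["r2"],
        "r2_pct_vs_hyp": reg("hyp_hidi_mv", "pct_change", n26)["r2"],
        "p_pct_vs_hyp": reg("hyp_hidi_mv", "pct_change", n26)["p"],
        "r2_depnorm_vs_dephidi": reg("dep_hidi_mv", "dep_normal_mv", n24)["r2"],
        "r2_depnorm_vs_hyphidi": reg("hyp_hidi_mv", "dep_normal_mv", n24)["r2"],
        "r2_burstsintact_vs_evoked": reg("evoked_spikes", "bursts_intact", n)["r2"],
        "p_burstsintact_vs_evoked": reg("evoked_spikes", "bursts_intact", n)["p"],
        "hyp_mean_mv": float(df.hyp_hidi_mv.iloc[: min(32, n)].mean()),
        "hyp_sd_mv": float(df.hyp_hidi_mv.iloc[: min(32, n)].std(ddof=1)),
        "hyp_cov": an.cov(df.hyp_hidi_mv.iloc[: min(32, n)]),
        "dep_mean_mv": float(df.dep_hidi_mv.iloc[: min(32, n)].mean()),
        "dep_cov": an.cov(df.dep_hidi_mv.iloc[: min(32, n)]),
    }
    lev_stat, lev_p = an.levene_median_test(
        df.hyp_hidi_mv.iloc[: min(32, n)], df.dep_hidi_mv.iloc[: min(32, n)]
    )
    summary["levene_hyp_vs_dep_p"] = lev_p
    return _result(spec, df, summary)


# ---------------------------------------------------------------------------
# propagation census
# ---------------------------------------------------------------------------

def run_propagation_census(spec: ExperimentSpec | None = None) -> an.CohortResult:
    """Classify VSI spike propagation in intact episodes across a cohort,
    then measure per-category impairment after disconnection."""
    spec = spec or ExperimentSpec(name="propagation_census", n=69)
    n = spec.n or 69
    cfg = _with_n(spec.cohort, n)
    animals = co.generate_cohort(cfg, seed=spec.seed)

    rows = []
    for a in animals:
        rec_i = _episode(a, a.seed_entropy, lesioned=False, cohort_cfg=cfg)
        soma = rec_i.spike_times["VSI_soma"]
        bursts = an.detect_bursts(soma, rec_i.stim_window)
        label = an.match_and_classify(
            soma, rec_i.nerve_impulse_times, window_ms=50.0, bursts=bursts
        )
        rec_l = _episode(a, a.seed_entropy + 1, lesioned=True, cohort_cfg=cfg)
        b_i, b_l = bursts.n_bursts, _burst_count(rec_l)
        rows.append(
            {
                "animal": a.id,
                "h_mv": a.h_mv,
                "category": label.animal_category,
                "bursts_intact": b_i,
                "bursts_blocked": b_l,
                "pct_change": an.percent_change(b_i, b_l) if b_i else np.nan,
                "burst_labels": "|".join(label.burst_labels),
            }
        )
    df = pd.DataFrame(rows)
    frac = df.category.value_counts(normalize=True)
    summary = {
        "pct_antidromic_only": 100.0 * float(frac.get("antidromic-only", 0.0)),
        "pct_mixed": 100.0 * float(frac.get("mixed", 0.0)),
        "pct_orthodromic_only": 100.0 * float(frac.get("orthodromic-only", 0.0)),
    }
    groups, labels = [], []
    for cat in ("antidromic-only", "mixed", "orthodromic-only"):
        g = df.loc[df.category == cat, "pct_change"].dropna().to_numpy()
        summary[f"mean_pct_change_{cat.split('-')[0]}"] = (
            float(g.mean()) if g.size else np.nan
        )
        if g.size >= 2:
            groups.append(g)
            labels.append(cat)
    if len(groups) >= 2:
        f, p = an.one_way_anova(groups)
        summary["anova_f"] = f
        summary["anova_p"] = p
        summary["pairwise"] = an.holm_sidak_pairwise(groups, labels)
    return _result(spec, df, summary)


# ---------------------------------------------------------------------------
# dynamic clamp suite
# ---------------------------------------------------------------------------

def run_dynclamp_suite(spec: ExperimentSpec | None = None) -> an.CohortResult:
    """Synaptic-conductance addition/subtraction on intact and blocked
    circuits, each arm paired (clamp off vs on, seed-matched)."""
    spec = spec or ExperimentSpec(name="dynclamp_suite", n=0)
    arms = (
        ("intact_add", False, "add", 18),
        ("intact_subtract", False, "subtract", 9),
        ("lesioned_add", True, "add", 20),
        ("lesioned_subtract", True, "subtract", 19),
    )
    rows = []
    for arm_idx, (arm, lesioned, mode, n_arm) in enumerate(arms):
        n_use = spec.n or n_arm
        cfg = _with_n(spec.cohort, n_use)
        animals = co.generate_cohort(cfg, seed=spec.seed + 1000 * (arm_idx + 1))
        for a in animals:
            ctrl_intact = _episode(a, a.seed_entropy, lesioned=False, cohort_cfg=cfg)
            base_intact = _burst_count(ctrl_intact)
            off = _episode(a, a.seed_entropy + 1, lesioned=lesioned, cohort_cfg=cfg)
            on = _episode(
                a,
                a.seed_entropy + 1,
                lesioned=lesioned,
                clamp_mode=mode,
                g_ns=spec.clamp_g_ns,
                cohort_cfg=cfg,
            )
            n_off, n_on = _burst_count(off), _burst_count(on)
            frac_anti = _fraction_antidromic(on)
            rows.append(
                {
                    "arm": arm,
                    "animal": a.id,
                    "h_mv": a.h_mv,
                    "bursts_intact_ctrl": base_intact,
                    "bursts_off": n_off,
                    "bursts_on": n_on,
                    "diff": n_on - n_off,
                    "pct_off_vs_ctrl": an.percent_change(base_intact, n_off),
                    "pct_on_vs_ctrl": an.percent_change(base_intact, n_on),
                    "frac_antidromic_on": frac_anti,
                }
            )
    df = pd.DataFrame(rows)
    summary = {}
    for arm, *_ in arms:
        sub = df[df.arm == arm]
        summary[f"{arm}_mean_diff"] = float(sub["diff"].mean())
        summary[f"{arm}_mean_pct_off"] = float(sub.pct_off_vs_ctrl.mean())
        summary[f"{arm}_mean_pct_on"] = float(sub.pct_on_vs_ctrl.mean())
        try:
            _, p = an.paired_t_test(sub.bursts_off, sub.bursts_on)
        except ValueError:
            p = 1.0  # no paired difference at all
        summary[f"{arm}_paired_p"] = p
    summary["intact_add_frac_antidromic"] = float(
        df[df.arm == "intact_add"].frac_antidromic_on.mean()
    )
    return _result(spec, df, summary)


def _fraction_antidromic(rec) -> float:
    soma = rec.spike_times["VSI_soma"]
    if soma.size == 0:
        return np.nan
    bursts = an.detect_bursts(soma, rec.stim_window)
    lab = an.match_and_classify(soma, rec.nerve_impulse_times, bursts=bursts)
    counts = lab.counts()
    matched = counts["antidromic"] + counts["orthodromic"]
    return counts["antidromic"] / matched if matched else np.nan


# ---------------------------------------------------------------------------
# count-level cohort replicates (Monte-Carlo uncertainty bands)
# ---------------------------------------------------------------------------
#
# The episode simulator's burst counts are, by construction, a baseline
# count with small episode jitter minus the calibrated loss mapping, and
# burst detection recovers them exactly on noise-free rendered trains.
# These helpers draw the same count distributions directly, so that
# hundreds of cohort replicates are affordable for uncertainty bands.

def _episode_count(animal, rng, params: ci.CircuitParams):
    delta = rng.choice([-1, 0, 1], p=params.count_jitter_p)
    return int(np.clip(animal.baseline_bursts + delta, 2, 9))


def motor_count_replicates(n: int = 34, seed: int = 0, reps: int = 200,
                           cfg: co.CohortConfig | None = None) -> pd.DataFrame:
    """Replicate pre/post-block burst-count statistics at cohort size n."""
    cfg = cfg or co.CohortConfig()
    params = ci.CircuitParams()
    rows = []
    for r in range(reps):
        animals = co.generate_cohort(_with_n(cfg, n), seed=seed + 100_000 + r)
        rng = np.random.default_rng(seed + 200_000 + r)
        pre, post, pct, hs = [], [], [], []
        for a in animals:
            n3 = _episode_count(a, rng, params)
            n4 = _episode_count(a, rng, params)
            loss = co.burst_loss(a.h_mv, a.epsilon, n4, rng, cfg.loss)
            pre.append(n3)
            post.append(n4 - loss)
            pct.append(an.percent_change(n3, n4 - loss))
            hs.append(a.h_mv)
        _, _, r2, _ = an.linear_regression(hs, pct)
        rows.append(
            {
                "pre_cov": an.cov(pre),
                "blocked_cov": an.cov(post),
                "mean_pct_change": float(np.mean(pct)),
                "r2_pct_vs_h": r2,
            }
        )
    return pd.DataFrame(rows)


def behavior_count_replicates(n: int = 19, seed: int = 0, reps: int = 200,
                              cfg: co.CohortConfig | None = None) -> pd.DataFrame:
    """Replicate pre/post-surgery flexion-count CoV at cohort size n."""
    cfg = cfg or co.CohortConfig()
    rows = []
    for r in range(reps):
        animals = co.generate_cohort(_with_n(cfg, n), seed=seed + 300_000 + r)
        rng = np.random.default_rng(seed + 400_000 + r)
        pre = [co.generate_behavior(a, False, rng, config=cfg) for a in animals]
        post = [co.generate_behavior(a, True, rng, surgery=True, config=cfg) for a in animals]
        rows.append(
            {
                "pre_cov": an.cov(pre),
                "post_cov": an.cov(post),
                "pre_mean": float(np.mean(pre)),
                "post_mean": float(np.mean(post)),
            }
        )
    return pd.DataFrame(rows)


def census_count_replicates(n: int = 69, seed: int = 0, reps: int = 200,
                            cfg: co.CohortConfig | None = None) -> pd.DataFrame:
    """Replicate the propagation-category census at cohort size n."""
    cfg = cfg or co.CohortConfig()
    params = ci.CircuitParams()
    rows = []
    for r in range(reps):
        animals = co.generate_cohort(_with_n(cfg, n), seed=seed + 500_000 + r)
        rng = np.random.default_rng(seed + 600_000 + r)
        cats = {"antidromic-only": 0, "mixed": 0, "orthodromic-only": 0}
        for a in animals:
            nc = _episode_count(a, rng, params)
            m = co.zone_switch_cycle(a.h_mv, a.zone_zeta, nc, cfg.zones)
            if m >= nc:
                cats["antidromic-only"] += 1
            elif m == 0:
                cats["orthodromic-only"] += 1
            else:
                cats["mixed"] += 1
        rows.append({k: 100.0 * v / n for k, v in cats.items()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reproduce everything
# ---------------------------------------------------------------------------

def reproduce_all(seed: int = 0, out_dir: str | None = None) -> dict:
    """Run every experiment and collect the headline statistics."""
    results = {
        "behavior": run_behavior_lesion(ExperimentSpec("behavior_lesion", 19, seed, out_dir=out_dir)),
        "motor": run_motor_lesion(ExperimentSpec("motor_lesion", 34, seed + 1, out_dir=out_dir)),
        "correlations": run_correlation_suite(
            ExperimentSpec("correlation_suite", 52, seed + 2, out_dir=out_dir)
        ),
        "census": run_propagation_census(
            ExperimentSpec("propagation_census", 69, seed + 3, out_dir=out_dir)
        ),
        "dynclamp": run_dynclamp_suite(ExperimentSpec("dynclamp_suite", 0, seed + 4, out_dir=out_dir)),
    }
    summary = {name: res.summary for name, res in results.items()}
    if out_dir:
        from pathlib import Path

        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "reproduce_summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True, default=str)
        )
    return summary
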