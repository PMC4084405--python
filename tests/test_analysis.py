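"""Measurement and statistics ops against hand oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import swimcpg.analysis as an
import swimcpg.cohort as co


# ---------------------------------------------------------------------------
# independent textbook oracles
# ---------------------------------------------------------------------------

def oracle_bursts(times, gap=1.0):
    """Brute-force cluster enumeration of the burst rule."""
    groups = []
    cur = []
    for t in times:
        if cur and t - cur[-1] >= gap:
            groups.append(cur)
            cur = []
        cur.append(t)
    if cur:
        groups.append(cur)
    return [g for g in groups if len(g) >= 2]


def oracle_anova(groups):
    """One-way ANOVA from the definitional sums of squares."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_x) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    from scipy.stats import f as fdist

    return f, fdist.sf(f, df_b, df_w)


def oracle_levene_median(a, b):
    da = np.abs(np.asarray(a) - np.median(a))
    db = np.abs(np.asarray(b) - np.median(b))
    return oracle_anova([da, db])


def oracle_ols(x, y):
    """Normal-equation least squares with the slope t test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (slope * x + intercept)
    ss_res = (resid**2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot
    se = np.sqrt(ss_res / (n - 2) / sxx)
    from scipy.stats import t as tdist

    t = slope / se
    return slope, intercept, r2, 2 * tdist.sf(abs(t), n - 2)


def oracle_paired_t(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    from scipy.stats import t as tdist

    return t, 2 * tdist.sf(abs(t), n - 1)


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

class TestDetectSpikes:
    def test_flat_trace_has_no_events(self):
        assert an.detect_spikes(np.full(4000, -60.0), -20.0, 5.0, 0.25).size == 0

    def test_recovers_injected_template_spikes(self):
        dt = 0.25
        v = np.full(40000, -55.0)
        tmpl = co.spike_template(dt)
        inject = [1.0, 2.5, 4.0, 6.2, 8.9]
        co.add_events(v, inject, tmpl, dt)
        peak_offset_s = tmpl.argmax() * dt / 1000.0
        got = an.detect_spikes(v, -20.0, 5.0, dt)
        assert got.size == 5
        np.testing.assert_allclose(got, np.asarray(inject) + peak_offset_s, atol=2 * dt / 1000.0)

    def test_refractory_merges_close_crossings(self):
        dt = 1.0
        v = np.full(100, -60.0)
        v[10] = 0.0
        v[12] = 0.0  # 2 ms later, inside a 5 ms refractory window
        assert an.detect_spikes(v, -20.0, 5.0, dt).size == 1

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            an.detect_spikes(np.array([]), -20.0, 5.0, 0.25)


class TestDetectBursts:
    def test_empty_train(self):
        assert an.detect_bursts([]).n_bursts == 0

    def test_worked_example_with_singleton(self):
        bs = an.detect_bursts([5.0, 5.4, 5.9, 7.5], stim_window=(0.0, 3.0))
        assert bs.n_bursts == 1
        assert bs.bursts[0][2] == 3  # singleton at 7.5 s discarded

    def test_stim_window_spikes_not_counted(self):
        assert an.detect_bursts([1.0, 1.2], stim_window=(0.0, 3.0)).n_bursts == 0

    def test_gap_of_exactly_one_second_splits(self):
        # the rule is intervals strictly less than 1 s
        bs = an.detect_bursts([0.0, 0.5, 1.5, 2.0])
        assert bs.n_bursts == 2

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            an.detect_bursts([2.0, 1.0])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 20))
        times = np.sort(rng.uniform(0.0, 12.0, n))
        got = an.detect_bursts(times)
        want = oracle_bursts(times)
        assert got.n_bursts == len(want)
        assert got.spike_counts == [len(g) for g in want]


class TestMatchAndClassify:
    def test_leading_nerve_impulse_is_antidromic(self):
        lab = an.match_and_classify([10.0, 10.1], [9.975, 10.075])
        assert lab.spike_labels == ["antidromic", "antidromic"]

    def test_lagging_nerve_impulse_is_orthodromic(self):
        lab = an.match_and_classify([10.0, 10.1], [10.025, 10.125])
        assert lab.spike_labels == ["orthodromic", "orthodromic"]

    def test_ambiguous_band_left_unmatched(self):
        lab = an.match_and_classify([10.0], [10.0003])
        assert lab.spike_labels == ["unmatched"]

    def test_no_partner_in_window_unmatched(self):
        lab = an.match_and_classify([10.0], [11.0], window_ms=50.0)
        assert lab.spike_labels == ["unmatched"]

    def test_mixed_burst_taxonomy(self):
        # three all-antidromic bursts plus two all-orthodromic -> mixed animal
        soma, nerve = [], []
        for b in range(5):
            t0 = 2.0 + 3.0 * b
            spikes = [t0, t0 + 0.2, t0 + 0.4]
            soma += spikes
            off = -0.025 if b < 3 else 0.025
            nerve += [t + off for t in spikes]
        lab = an.match_and_classify(soma, sorted(nerve))
        assert lab.burst_labels == ["antidromic"] * 3 + ["orthodromic"] * 2
        assert lab.animal_category == "mixed"

    def test_window_validation(self):
        with pytest.raises(ValueError):
            an.match_and_classify([1.0], [1.0], window_ms=0.0)


class TestImpulseWaveform:
    def test_templates_and_noise(self, rng):
        dt = 0.25
        assert an.classify_impulse_waveform(co.triphasic_template(dt), dt) == "triphasic"
        assert an.classify_impulse_waveform(co.biphasic_template(dt), dt) == "biphasic"
        assert an.classify_impulse_waveform(rng.normal(0, 0.01, 100), dt) == "unknown"


# ---------------------------------------------------------------------------
# PSP / EPSP
# ---------------------------------------------------------------------------

class TestMeasurePsp:
    def test_flat_trace_zero_amplitudes(self):
        t = np.arange(0, 10, 0.001)
        m = an.measure_psp(t, np.full(t.size, -50.0), 1.0, (0.0, 0.9), (1.0, 9.0))
        assert m.depolarization_mv == 0.0
        assert m.hyperpolarization_mv == 0.0

    def test_biphasic_round_trip(self):
        t, v = co.compose_psp(0.8, 2.9, dt_ms=0.5)
        m = co.measure_hi_di_psp(t, v - 50.0, 0.5)
        assert m.depolarization_mv == pytest.approx(0.8, rel=0.05)
        assert m.hyperpolarization_mv == pytest.approx(2.9, rel=0.05)

    def test_monophasic_peak_to_plateau_rule(self):
        # depolarizing step that settles to a plateau: hyperpolarization
        # is read from the peak down to the plateau
        t = np.arange(0, 10, 0.001)
        v = np.full(t.size, -50.0)
        v[(t > 2) & (t <= 3)] = -44.0   # overshoot peak
        v[t > 3] = -46.0                # plateau
        m = an.measure_psp(t, v, 1.0, (0.0, 0.9), (1.0, 9.5))
        assert m.depolarization_mv == pytest.approx(6.0)
        assert m.hyperpolarization_mv == pytest.approx(2.0)
        assert m.trough_time_s > m.peak_time_s

    def test_window_validation(self):
        t = np.arange(0, 2, 0.001)
        with pytest.raises(ValueError):
            an.measure_psp(t, np.zeros(t.size), 1.0, (0.0, 0.9), (1.0, 5.0))


class TestEpspBarrage:
    def _trace(self, events, dt_ms=0.5, dur_s=14.0):
        n = int(dur_s * 1000 / dt_ms)
        v = np.full(n, -50.0)
        kern = np.exp(-np.arange(0, 300, dt_ms) / 30.0) - np.exp(-np.arange(0, 300, dt_ms) / 3.0)
        kern /= kern.max()
        for ts, amp in events:
            co.add_events(v, [ts], amp * kern, dt_ms)
        t = np.arange(n) * dt_ms / 1000.0
        return t, v

    def test_amplitude_floor_excludes_small_events(self):
        t, v = self._trace([(2.0, 0.05), (4.0, 0.30)])
        times, amps, _ = an.measure_epsp_barrage(t, v, 1.0)
        assert times.size == 1
        assert amps[0] == pytest.approx(0.30, rel=0.1)

    def test_no_events(self):
        t, v = self._trace([])
        times, amps, freq = an.measure_epsp_barrage(t, v, 1.0)
        assert times.size == 0 and amps.size == 0 and freq.size == 0

    def test_round_trip_of_injected_events(self):
        inject = 1.5 + 0.45 * np.arange(20)
        t, v = self._trace([(ts, 0.4) for ts in inject])
        times, amps, freq = an.measure_epsp_barrage(t, v, 1.0)
        assert times.size == 20
        np.testing.assert_allclose(np.diff(times), np.diff(inject), atol=0.01)
        np.testing.assert_allclose(freq, 1.0 / np.diff(times))

    def test_requires_ten_seconds_post_onset(self):
        t, v = self._trace([], dur_s=5.0)
        with pytest.raises(ValueError):
            an.measure_epsp_barrage(t, v, 1.0)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

class TestCov:
    def test_constant_values(self):
        assert an.cov([5, 5, 5, 5]) == 0.0

    def test_worked_example(self):
        assert an.cov([2, 4, 6]) == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        x = rng.uniform(1, 10, 20)
        assert an.cov(3.7 * x) == pytest.approx(an.cov(x))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            an.cov([-1.0, 1.0])


class TestLeveneMedian:
    def test_identical_groups_degenerate(self):
        assert an.levene_median_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_matches_anova_on_absolute_deviations(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [-10.0, -5.0, 0.0, 5.0, 10.0]
        stat, p = an.levene_median_test(a, b)
        f_o, p_o = oracle_levene_median(a, b)
        assert stat == pytest.approx(f_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            an.levene_median_test([1, 2], [1, 2, 3])


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r2, p = an.linear_regression(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_response_r2_zero(self):
        _, _, r2, _ = an.linear_regression(np.arange(10.0), np.full(10, 3.0))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        x = [1.0, 2.0, 4.0, 5.0, 7.0]
        y = [2.1, 4.3, 8.0, 9.6, 14.5]
        got = an.linear_regression(x, y)
        want = oracle_ols(x, y)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            an.linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPercentChange:
    @pytest.mark.parametrize(
        "before, after, expected",
        [(5, 3, -40.0), (6, 5, -100.0 / 6.0), (4, 4, 0.0), (4, 5, 25.0)],
    )
    def test_values(self, before, after, expected):
        assert an.percent_change(before, after) == pytest.approx(expected, abs=1e-12)

    def test_zero_before_rejected(self):
        with pytest.raises(ValueError):
            an.percent_change(0, 3)


class TestPairedTAndAnova:
    def test_identical_pairs_rejected(self):
        with pytest.raises(ValueError):
            an.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            an.paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_paired_t_matches_formula_oracle(self):
        a = [5.0, 6.0, 4.0, 7.0, 6.0, 5.0]
        b = [4.0, 6.0, 3.0, 5.0, 6.0, 4.0]
        got = an.paired_t_test(a, b)
        want = oracle_paired_t(a, b)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_anova_matches_sums_of_squares_oracle(self):
        groups = [[4.0, 5.0, 6.0, 5.5], [6.0, 7.0, 8.0], [3.0, 3.5, 4.0, 4.5, 5.0]]
        got = an.one_way_anova(groups)
        want = oracle_anova([np.asarray(g) for g in groups])
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_holm_sidak_adjusts_upward(self, rng):
        groups = [rng.normal(m, 1.0, 12) for m in (0.0, 0.2, 1.5)]
        table = an.holm_sidak_pairwise(groups, labels=["a", "b", "c"])
        assert len(table) == 3
        for _, _, raw, adj in table:
            assert adj >= raw - 1e-12
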