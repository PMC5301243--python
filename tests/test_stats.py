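import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cardioraman.stats import (group_summary, kruskal_wallis, mann_whitney,
                               plateau_time, summary_table, timecourse_compare)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation)

def brute_kw_H(groups):
    pooled = np.concatenate(groups)
    ranks = scipy.stats.rankdata(pooled)
    N = pooled.size
    idx = np.cumsum([0] + [len(g) for g in groups])
    H = 12 / (N * (N + 1)) * sum(
        len(g) * (ranks[idx[i]:idx[i + 1]].mean() - (N + 1) / 2) ** 2
        for i, g in enumerate(groups))
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts)
    if tie:
        H /= 1 - tie / (N ** 3 - N)
    return H


def brute_kw_exact_p(groups):
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    H_obs = brute_kw_H(groups)
    count = total = 0
    for perm in itertools.permutations(range(pooled.size)):
        vals = pooled[list(perm)]
        idx = np.cumsum([0] + sizes)
        gs = [vals[idx[i]:idx[i + 1]] for i in range(len(sizes))]
        total += 1
        count += brute_kw_H(gs) >= H_obs - 1e-9
    return count / total


def brute_mw(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    Ua = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    return min(Ua, len(a) * len(b) - Ua)


def brute_mw_exact_p(a, b):
    pooled = np.concatenate([a, b])
    na = len(a)
    U_obs = brute_mw(a, b)
    count = total = 0
    for combo in itertools.combinations(range(pooled.size), na):
        mask = np.zeros(pooled.size, bool)
        mask[list(combo)] = True
        total += 1
        count += brute_mw(pooled[mask], pooled[~mask]) <= U_obs + 1e-9
    return count / total


# ---------------------------------------------------------------------------
# summaries

def test_group_summary_two_points():
    s = group_summary([2, 4], "SI", 10)
    assert (s.mean, s.sem, s.n) == (3.0, 1.0, 2)


def test_group_summary_singleton_flagged():
    s = group_summary([5], "control", 10)
    assert (s.mean, s.sem, s.n, s.degenerate) == (5.0, 0.0, 1, True)


def test_group_summary_four_points():
    s = group_summary([1, 2, 3, 4], "SI", 10)
    expect_sem = np.std([1, 2, 3, 4], ddof=1) / 2  # oracle: sd/sqrt(n)
    assert s.mean == 2.5
    assert s.sem == pytest.approx(expect_sem)
    assert s.sem == pytest.approx(0.6455, abs=5e-5)


def test_group_summary_empty_rejected():
    with pytest.raises(ValueError):
        group_summary([], "SI", 10)


# ---------------------------------------------------------------------------
# Kruskal-Wallis

def test_kw_two_by_two():
    res = kruskal_wallis([1, 2], [3, 4])
    assert res.statistic == pytest.approx(2.4)


def test_kw_identical_groups():
    res = kruskal_wallis([1, 2, 3], [1, 2, 3])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_kw_all_values_identical():
    res = kruskal_wallis([5, 5], [5, 5, 5])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_kw_matches_scipy_statistic():
    rng = np.random.default_rng(0)
    for _ in range(20):
        gs = [rng.integers(0, 6, size=rng.integers(2, 6)).astype(float)
              for _ in range(3)]
        if np.ptp(np.concatenate(gs)) == 0:
            continue
        res = kruskal_wallis(*gs)
        ref = scipy.stats.kruskal(*gs)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


def test_kw_exact_p_three_groups_of_two():
    gs = [[1.0, 4.0], [2.0, 6.0], [3.0, 5.0]]
    res = kruskal_wallis(*gs)
    assert res.p_exact == pytest.approx(brute_kw_exact_p(gs))


def test_kw_exact_matches_brute_force_randomized():
    rng = np.random.default_rng(1)
    for _ in range(10):
        sizes = rng.integers(2, 4, size=2)
        gs = [rng.integers(0, 5, size=s).astype(float) for s in sizes]
        if np.ptp(np.concatenate(gs)) == 0:
            continue
        res = kruskal_wallis(*gs)
        assert res.p_exact == pytest.approx(brute_kw_exact_p(gs))


def test_kw_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    gs = [rng.normal(size=4), rng.normal(size=5), rng.normal(size=3)]
    H1 = kruskal_wallis(*gs).statistic
    H2 = kruskal_wallis(*[np.exp(g) for g in gs]).statistic
    assert H2 == pytest.approx(H1)


# ---------------------------------------------------------------------------
# Mann-Whitney

def test_mw_separated_pairs():
    res = mann_whitney([1, 2], [3, 4])
    assert res.statistic == 0.0
    assert res.p_exact == pytest.approx(brute_mw_exact_p([1, 2], [3, 4]))


def test_mw_identical_multisets():
    res = mann_whitney([1, 2, 3], [1, 2, 3])
    assert res.statistic == pytest.approx(4.5)  # n^2/2 midpoint
    assert res.p == pytest.approx(1.0)


def test_mw_single_observations():
    assert mann_whitney([37.3], [43.5]).statistic == 0.0


def test_mw_exact_matches_scipy_without_ties():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = rng.permutation(20)[:4].astype(float)
        b = rng.permutation(20)[:5].astype(float) + 0.5
        res = mann_whitney(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="exact")
        assert res.p_exact == pytest.approx(ref.pvalue)


def test_mw_normal_approximation_reasonable():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 1, 10)
    b = rng.normal(1, 1, 10)
    res = mann_whitney(a, b)
    ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic")
    assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)


def test_mw_empty_rejected():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# time-course comparison

def _peaks_frame(values_by_group, t=30.0):
    rows = []
    for g, vals in values_by_group.items():
        for i, v in enumerate(vals):
            rows.append({"heart_id": f"{g}{i}", "group": g,
                         "phase": "ischaemia", "time_min": t, "band": "750",
                         "point_id": "0", "height": v, "ratio_1450": v,
                         "ratio_whole": v})
    return pd.DataFrame(rows)


def test_timecourse_compare_separated_groups_significant():
    peaks = _peaks_frame({"control": [0.0, 0.01, 0.02],
                          "SI": [0.5, 0.6, 0.7, 0.55, 0.65, 0.58, 0.62, 0.61]})
    out = timecourse_compare(peaks, "ratio_1450")
    assert len(out) == 1
    assert out.iloc[0]["p_value"] < 0.05


def test_timecourse_compare_missing_control_time_skipped():
    peaks = pd.concat([
        _peaks_frame({"SI": [1.0, 2.0, 3.0]}, t=10.0),
        _peaks_frame({"control": [0.1, 0.2], "SI": [1.0, 2.0, 3.0]}, t=20.0),
    ])
    out = timecourse_compare(peaks, "ratio_1450")
    assert list(out["time_min"]) == [20.0]


def test_timecourse_compare_no_rows_rejected():
    with pytest.raises(ValueError):
        timecourse_compare(_peaks_frame({"control": [1.0]}), "ratio_1450",
                           band="9999")


def test_summary_table_roundtrips_group_summary():
    peaks = _peaks_frame({"control": [1.0, 2.0], "SI": [3.0, 5.0]})
    out = summary_table(peaks, "ratio_1450")
    si = out[out.group == "SI"].iloc[0]
    assert si["mean"] == 4.0 and si["sem"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# plateau detection

def test_plateau_on_exponential_grid():
    tau = 18.0
    grid = np.array([10, 20, 30, 45, 60, 90, 120], dtype=float)
    v = 1 - np.exp(-grid / tau)
    thr = 0.95 * v[-1]
    # independent interpolation oracle
    k = int(np.argmax(v >= thr))
    expect = grid[k - 1] + (grid[k] - grid[k - 1]) * (thr - v[k - 1]) / (v[k] - v[k - 1])
    got = plateau_time(grid, v)
    assert got == pytest.approx(expect)
    assert got == pytest.approx(54.979, abs=0.01)
    # sanity: the continuous-time crossing is nearby
    assert abs(got - (-tau * math.log(1 - thr))) < 3.0


def test_plateau_constant_series():
    assert plateau_time([0, 10, 20], [2.0, 2.0, 2.0]) == 0.0


def test_plateau_only_final_point():
    t = [0, 10, 20, 30]
    v = [0.0, 0.1, 0.2, 1.0]
    got = plateau_time(t, v, fraction=0.95)
    assert 20.0 < got <= 30.0


def test_plateau_never_reached_is_none():
    # declining negative series: threshold (95% of the final value) sits
    # above the final value itself and is never durably attained
    assert plateau_time([0, 10, 20], [0.0, -1.0, -2.0], fraction=0.95) is None


def test_plateau_validation():
    with pytest.raises(ValueError):
        plateau_time([0, 10], [1, 2])
    with pytest.raises(ValueError):
        plateau_time([0, 10, 5], [1, 2, 3])
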