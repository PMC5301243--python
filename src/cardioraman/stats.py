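"""Group time-course summaries and nonparametric tests.

Hearts are the statistical unit: replicate-point measurements are averaged
per heart before any test.  Group differences at each ischaemia time are
assessed by rank tests (Kruskal-Wallis between each treated group and the
control; Mann-Whitney for two-sample readouts such as TMRE latency), with
exact permutation p-values at the very small sample sizes where the
chi-square / normal approximations are coarse.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

logger = logging.getLogger("cardioraman")

#: Total pooled N up to which an exact permutation p is computed alongside
#: the chi-square approximation for Kruskal-Wallis.
KW_EXACT_N = 8
#: Pooled N up to which the Mann-Whitney p is exact (full enumeration).
MW_EXACT_N = 12


@dataclass
class GroupSummary:
    group: str
    time_min: float
    metric: str
    mean: float
    sem: float
    n: int
    degenerate: bool = False  # n == 1, SEM reported as 0 by convention


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    groups: tuple
    n_per_group: tuple
    p_exact: float | None = None

    @property
    def p(self) -> float:
        """Preferred p: exact when available, else the approximation."""
        return self.p_exact if self.p_exact is not None else self.p_value


def group_summary(values, group: str, time_min: float,
                  metric: str = "") -> GroupSummary:
    """Mean +/- SEM of per-heart values (SEM = sd(ddof=1)/sqrt(n))."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    if v.size == 1:
        logger.warning("group %s t=%s has n=1; SEM set to 0", group, time_min)
        return GroupSummary(group, time_min, metric, float(v[0]), 0.0, 1,
                            degenerate=True)
    sem = float(np.std(v, ddof=1) / math.sqrt(v.size))
    return GroupSummary(group, time_min, metric, float(np.mean(v)), sem, v.size)


def _kw_statistic(groups_ranks, N: int, tie_term: float) -> float:
    H = 12.0 / (N * (N + 1)) * sum(
        len(g) * (np.mean(g) - (N + 1) / 2.0) ** 2 for g in groups_ranks
    )
    if tie_term > 0:
        denom = 1.0 - tie_term / (N ** 3 - N)
        if denom <= 0:
            return 0.0
        H /= denom
    return H


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(*samples) -> StatResult:
    """Kruskal-Wallis H test with midrank tie correction.

    p is from the chi-square approximation with k-1 df; for pooled N <= 8 an
    exact permutation p (probability of H at least as large under random
    group assignment) is computed as well and exposed as ``p_exact``.
    All-identical pooled values give H = 0, p = 1 by convention.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ValueError("need >= 2 nonempty groups")
    sizes = [s.size for s in samples]
    N = sum(sizes)
    if N < 3:
        raise ValueError("need pooled N >= 3")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return StatResult("kruskal_wallis", 0.0, 1.0,
                          tuple(range(len(samples))), tuple(sizes), p_exact=1.0)
    ranks = rankdata(pooled)
    tie = _tie_term(pooled)
    bounds = np.cumsum([0] + sizes)
    groups_ranks = [ranks[bounds[i]:bounds[i + 1]] for i in range(len(sizes))]
    H = _kw_statistic(groups_ranks, N, tie)
    p_approx = float(chi2.sf(H, len(samples) - 1))

    p_exact = None
    if N <= KW_EXACT_N:
        p_exact = _kw_exact_p(ranks, sizes, N, tie, H)
    return StatResult("kruskal_wallis", float(H), p_approx,
                      tuple(range(len(samples))), tuple(sizes), p_exact=p_exact)


def _kw_exact_p(ranks: np.ndarray, sizes, N: int, tie: float,
                H_obs: float) -> float:
    """Exact permutation null of H over all distinct index partitions."""
    count = 0
    total = 0

    def plain(remaining, sizes_left):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rem = [i for i in remaining if i not in combo]
            for tail in plain(rem, sizes_left[1:]):
                yield [combo] + tail

    for part in plain(list(range(N)), list(sizes)):
        gr = [ranks[list(g)] for g in part]
        H = _kw_statistic(gr, N, tie)
        total += 1
        if H >= H_obs - 1e-9:
            count += 1
    return count / total


def mann_whitney(a, b) -> StatResult:
    """Two-sided Mann-Whitney test; statistic U = min(U_a, U_b).

    Exact p by full enumeration of group assignments when pooled N <= 12
    (valid with ties); otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    na, nb = a.size, b.size
    N = na + nb
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    Ra = float(np.sum(ranks[:na]))
    Ua = na * nb + na * (na + 1) / 2.0 - Ra
    Ub = na * nb - Ua
    U = min(Ua, Ub)

    if N <= MW_EXACT_N:
        count = 0
        total = 0
        for combo in itertools.combinations(range(N), na):
            Ra_p = float(np.sum(ranks[list(combo)]))
            Ua_p = na * nb + na * (na + 1) / 2.0 - Ra_p
            U_p = min(Ua_p, na * nb - Ua_p)
            total += 1
            if U_p <= U + 1e-9:
                count += 1
        p = count / total
        return StatResult("mann_whitney", float(U), p, ("a", "b"),
                          (na, nb), p_exact=p)

    mu = na * nb / 2.0
    tie = _tie_term(pooled)
    sigma2 = na * nb / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    if sigma2 <= 0:
        return StatResult("mann_whitney", float(U), 1.0, ("a", "b"), (na, nb))
    z = (U + 0.5 - mu) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * float(norm.cdf(z)))
    return StatResult("mann_whitney", float(U), p, ("a", "b"), (na, nb))


def timecourse_compare(peaks: pd.DataFrame, metric: str, band: str = "750",
                       test: str = "kruskal_wallis",
                       holm: bool = False) -> pd.DataFrame:
    """Per-time comparisons of each treated group against control.

    ``peaks`` is the long-format peak table (one row per spectrum point and
    band).  Values are aggregated per heart first; at each ischaemia time
    with control data, SI-vs-control and IPC-vs-control are tested.  No
    multiple-testing correction by default; ``holm=True`` applies Holm's
    step-down over the whole table.
    """
    sub = peaks[(peaks["band"] == band) & (peaks["phase"] == "ischaemia")]
    if sub.empty:
        raise ValueError(f"no ischaemia-phase rows for band {band!r}")
    per_heart = (sub.groupby(["group", "heart_id", "time_min"])[metric]
                 .mean().reset_index())
    present = set(per_heart["group"])
    for g in ("control",) + tuple(present - {"control"}):
        if g in present and per_heart[per_heart.group == g].empty:
            raise ValueError(f"group {g} has no data")
    rows = []
    for t in sorted(per_heart["time_min"].unique()):
        at_t = per_heart[per_heart.time_min == t]
        ctrl = at_t[at_t.group == "control"][metric].dropna().to_numpy()
        if ctrl.size == 0:
            logger.warning("no control values at t=%s; comparison skipped", t)
            continue
        for g in ("SI", "IPC"):
            other = at_t[at_t.group == g][metric].dropna().to_numpy()
            if other.size == 0:
                if g in present:
                    raise ValueError(f"group {g} empty at t={t}")
                continue
            if test == "kruskal_wallis":
                res = kruskal_wallis(ctrl, other)
            elif test == "mann_whitney":
                res = mann_whitney(ctrl, other)
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append({
                "time_min": t, "comparison": f"{g} vs control",
                "test": res.test, "statistic": res.statistic,
                "p_value": res.p, "n_control": ctrl.size, "n_group": other.size,
            })
    out = pd.DataFrame(rows)
    if holm and not out.empty:
        out["p_holm"] = _holm(out["p_value"].to_numpy())
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def plateau_time(times, values, fraction: float = 0.95) -> float | None:
    """Earliest time (linear interpolation) at which the series reaches
    ``fraction`` of its final value and stays at or above it thereafter.

    Returns None when the threshold is never durably reached.  If only the
    final sample meets the threshold, the final time is returned.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time axis must be strictly increasing")
    thr = fraction * v[-1]
    above = v >= thr
    if not above[-1]:
        return None
    # first index from which the series stays >= threshold
    k = t.size - 1
    while k > 0 and above[k - 1]:
        k -= 1
    if k == 0:
        return float(t[0])
    # interpolate the crossing between k-1 and k
    v0, v1 = v[k - 1], v[k]
    if v1 == v0:
        return float(t[k])
    return float(t[k - 1] + (t[k] - t[k - 1]) * (thr - v0) / (v1 - v0))


def summary_table(peaks: pd.DataFrame, metric: str,
                  band: str = "750") -> pd.DataFrame:
    """Mean +/- SEM per group per time (per-heart aggregated first)."""
    sub = peaks[(peaks["band"] == band) & (peaks["phase"] == "ischaemia")]
    per_heart = (sub.groupby(["group", "heart_id", "time_min"])[metric]
                 .mean().reset_index())
    rows = []
    for (g, t), grp in per_heart.groupby(["group", "time_min"]):
        s = group_summary(grp[metric].dropna(), g, t, metric)
        rows.append({"group": g, "time_min": t, "metric": metric,
                     "mean": s.mean, "sem": s.sem, "n": s.n})
    return pd.DataFrame(rows)
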