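"""Statistical machinery for scalp-level and clinical analyses.

The centrepiece is a cluster-based Monte-Carlo permutation test over scalp
channels (the standard remedy for the multiple-comparison problem across
electrodes): a per-channel statistic is thresholded at an uncorrected
cluster-forming level, suprathreshold channels are grouped into spatially
connected clusters separately per sign, each cluster is scored by the sum of
its member statistics (cluster mass), and the observed masses are referred
to the permutation distribution of the maximum absolute mass.

Also here: first-order partial correlation with its parametric t test,
Benjamini-Hochberg FDR, partial eta squared, pooled-SD Cohen's d, the
>=25%-reduction responder rule with Fisher's exact test, and the classical
2-way mixed ANOVA (time within subjects x group between subjects) used for
the clinical outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Cluster", "ClusterResult", "cluster_permutation",
    "partial_correlation", "bh_fdr",
    "partial_eta_squared", "cohens_d", "explained_variance_pct",
    "classify_responders", "fisher_exact", "mixed_anova",
]


# --------------------------------------------------------------------------
# cluster-based permutation test
# --------------------------------------------------------------------------

@dataclass
class Cluster:
    channels: tuple[str, ...]
    mass: float
    p_mc: float


@dataclass
class ClusterResult:
    """Outcome of a cluster-based permutation test over channels."""

    statistic: pd.Series              # per-channel statistic (NaN = excluded)
    clusters: list[Cluster]           # sorted by |mass|, descending
    threshold: float                  # critical value of the statistic
    alpha_cf: float
    n_perm: int
    seed: int | None
    design: str
    excluded: tuple[str, ...] = ()

    def significant_channels(self, alpha: float = 0.05) -> set[str]:
        out: set[str] = set()
        for cl in self.clusters:
            if cl.p_mc <= alpha:
                out.update(cl.channels)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        ch2cl = {}
        for k, cl in enumerate(self.clusters):
            for ch in cl.channels:
                ch2cl[ch] = (k, cl.p_mc)
        for ch, stat in self.statistic.items():
            cl_id, p = ch2cl.get(ch, (None, np.nan))
            rows.append({"channel": ch, "statistic": stat,
                         "cluster_id": cl_id, "p_mc": p})
        return pd.DataFrame(rows)


def _channel_components(channels: list[str], graph: nx.Graph) -> list[set[str]]:
    sub = graph.subgraph(channels)
    return [set(c) for c in nx.connected_components(sub)]


def _corr_stats(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of y against each column of x; x standardised already."""
    yc = y - y.mean()
    denom = np.sqrt((yc ** 2).sum())
    return (yc @ x) / denom


def _tstat_two_group(data: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    a, b = data[g1], data[g2]
    n1, n2 = len(a), len(b)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a.mean(axis=0) - b.mean(axis=0)) / (sp * np.sqrt(1 / n1 + 1 / n2))


def cluster_permutation(
    data: pd.DataFrame,
    design: str,
    adjacency: nx.Graph,
    *,
    covariate: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    alpha_cf: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """Cluster-corrected Monte-Carlo permutation test over channels.

    Parameters
    ----------
    data : DataFrame, subjects x channels (columns = channel labels).
    design : one of
        ``"correlate"`` — per-channel Pearson r between the channel values
        and ``covariate``; null = random shuffles of the covariate.
        ``"two_group"`` — independent-samples t between the two labels in
        ``groups``; null = random relabelings.
        ``"paired"`` — one-sample t of the rows against zero (rows are
        within-subject change scores); null = random sign flips.
        ``"group_f"`` — one-way F across >=2 labels in ``groups``
        (one-sided, positive clusters only); null = random relabelings.
    adjacency : channel graph covering all columns of ``data``.
    alpha_cf : two-tailed cluster-forming alpha for the channel statistic.
    n_perm : Monte-Carlo permutations; p_mc = (1 + #null >= obs)/(1 + n_perm).
    seed : seed for the permutation RNG (mandatory for reproducible runs).

    Channels with zero variance (statistic undefined) are excluded with a
    warning and reported in ``ClusterResult.excluded``.
    """
    channels = list(data.columns)
    missing = [c for c in channels if c not in adjacency]
    if missing:
        raise ValueError(f"adjacency does not cover channels: {missing}")
    x = data.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects")

    keep = x.std(axis=0, ddof=1) > 0
    if design in ("two_group", "group_f"):
        if groups is None:
            raise ValueError(f"design {design!r} requires group labels")
        groups = np.asarray(groups)
        labels = list(pd.unique(groups))
        for lab in labels:
            keep &= x[groups == lab].std(axis=0, ddof=1) > 0
    if not keep.all():
        dropped = [c for c, k in zip(channels, keep) if not k]
        warnings.warn(f"excluding zero-variance channels: {dropped}")
        channels = [c for c, k in zip(channels, keep) if k]
        x = x[:, keep]

    rng = np.random.default_rng(seed)

    if design == "correlate":
        if covariate is None:
            raise ValueError("design 'correlate' requires a covariate")
        y = np.asarray(covariate, dtype=float)
        if y.shape != (n,):
            raise ValueError("covariate must align with the rows of data")
        if y.std(ddof=1) == 0:
            raise ValueError("covariate has zero variance")
        xs = (x - x.mean(axis=0)) / (x.std(axis=0, ddof=0) * np.sqrt(n))
        t_crit = sps.t.ppf(1 - alpha_cf / 2, n - 2)
        threshold = t_crit / np.sqrt(t_crit ** 2 + n - 2)  # critical |r|

        def stat_fn(perm: np.ndarray) -> np.ndarray:
            return _corr_stats(xs, y[perm])

        def draw() -> np.ndarray:
            return rng.permutation(n)

        identity = np.arange(n)

    elif design == "two_group":
        labels = list(pd.unique(groups))
        if len(labels) != 2:
            raise ValueError("design 'two_group' needs exactly 2 group labels")
        n1 = int((groups == labels[0]).sum())
        threshold = sps.t.ppf(1 - alpha_cf / 2, n - 2)

        def stat_fn(perm: np.ndarray) -> np.ndarray:
            return _tstat_two_group(x, perm[:n1], perm[n1:])

        def draw() -> np.ndarray:
            return rng.permutation(n)

        identity = np.concatenate([np.where(groups == labels[0])[0],
                                   np.where(groups == labels[1])[0]])

    elif design == "paired":
        threshold = sps.t.ppf(1 - alpha_cf / 2, n - 1)

        def stat_fn(signs: np.ndarray) -> np.ndarray:
            xf = x * signs[:, None]
            return xf.mean(axis=0) / (xf.std(axis=0, ddof=1) / np.sqrt(n))

        def draw() -> np.ndarray:
            return rng.choice([-1.0, 1.0], size=n)

        identity = np.ones(n)

    elif design == "group_f":
        labels = list(pd.unique(groups))
        k = len(labels)
        if k < 2:
            raise ValueError("design 'group_f' needs >=2 group labels")
        idx_by_lab = [np.where(groups == lab)[0] for lab in labels]
        sizes = [len(ix) for ix in idx_by_lab]
        bounds = np.cumsum([0] + sizes)
        threshold = sps.f.ppf(1 - alpha_cf, k - 1, n - k)

        def stat_fn(perm: np.ndarray) -> np.ndarray:
            gm = x.mean(axis=0)
            ss_b = np.zeros(x.shape[1])
            ss_w = np.zeros(x.shape[1])
            for j in range(k):
                sub = x[perm[bounds[j]:bounds[j + 1]]]
                mj = sub.mean(axis=0)
                ss_b += sizes[j] * (mj - gm) ** 2
                ss_w += ((sub - mj) ** 2).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                return (ss_b / (k - 1)) / (ss_w / (n - k))

        def draw() -> np.ndarray:
            return rng.permutation(n)

        identity = np.concatenate(idx_by_lab)

    else:
        raise ValueError(f"unknown design {design!r}")

    def max_mass(stat: np.ndarray) -> tuple[float, list[tuple[set[str], float]]]:
        clusters: list[tuple[set[str], float]] = []
        for sign in (1.0, -1.0):
            if design == "group_f" and sign < 0:
                continue
            supra = [c for c, s in zip(channels, stat)
                     if np.isfinite(s) and sign * s > threshold]
            for comp in _channel_components(supra, adjacency):
                mass = float(sum(stat[channels.index(c)] for c in comp))
                clusters.append((comp, mass))
        best = max((abs(m) for _, m in clusters), default=0.0)
        return best, clusters

    obs_stat = stat_fn(identity)
    _, obs_clusters = max_mass(obs_stat)

    null = np.empty(n_perm)
    for p in range(n_perm):
        null[p] = max_mass(stat_fn(draw()))[0]

    result_clusters = [
        Cluster(tuple(sorted(comp)), mass,
                float((1 + np.sum(null >= abs(mass))) / (1 + n_perm)))
        for comp, mass in obs_clusters
    ]
    result_clusters.sort(key=lambda c: -abs(c.mass))

    stat_series = pd.Series(np.nan, index=data.columns, dtype=float)
    stat_series[channels] = obs_stat
    return ClusterResult(
        statistic=stat_series, clusters=result_clusters, threshold=threshold,
        alpha_cf=alpha_cf, n_perm=n_perm, seed=seed, design=design,
        excluded=tuple(c for c in data.columns if c not in channels),
    )


# --------------------------------------------------------------------------
# partial correlation
# --------------------------------------------------------------------------

def partial_correlation(x, y, z) -> tuple[float, float, float]:
    """First-order partial correlation r_xy.z with its parametric test.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),
    t = r sqrt((n - 3)/(1 - r^2)), two-tailed p with df = n - 3.

    Returns (r, t, p). Raises on collinear control (|r_xz| or |r_yz| = 1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = len(x)
    if not (len(y) == len(z) == n):
        raise ValueError("x, y, z must have equal length")
    if n < 4:
        raise ValueError("need n >= 4 for a first-order partial correlation")
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(z).all()):
        raise ValueError("inputs must be finite")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if np.isclose(abs(r_xz), 1.0) or np.isclose(abs(r_yz), 1.0):
        raise ValueError("control variable is collinear with x or y")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if np.isclose(abs(r), 1.0):
        return r, np.inf if r > 0 else -np.inf, 0.0
    t = r * np.sqrt(df / (1 - r ** 2))
    p = 2 * sps.t.sf(abs(t), df)
    return r, float(t), float(p)


# --------------------------------------------------------------------------
# multiple testing, effect sizes
# --------------------------------------------------------------------------

def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected boolean mask, adjusted q-values).

    Rejects all p <= p_(k*) with k* = max{k : p_(k) <= k q / m}; adjusted
    values are the usual monotone min over tail of m p_(k) / k.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    qadj = ranked * m / np.arange(1, m + 1)
    qadj = np.minimum.accumulate(qadj[::-1])[::-1]
    qadj = np.clip(qadj, 0, 1)
    passed = ranked <= np.arange(1, m + 1) * q / m
    k_star = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    rejected_sorted = np.arange(m) < k_star
    rejected = np.zeros(m, bool)
    rejected[order] = rejected_sorted
    adjusted = np.empty(m)
    adjusted[order] = qadj
    return rejected, adjusted


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F ratio: F df1 / (F df1 + df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("require F >= 0 and df >= 1")
    return F * df1 / (F * df1 + df2)


def cohens_d(mean1, sd1, n1, mean2, sd2, n2) -> float:
    """Pooled-SD Cohen's d between two independent groups."""
    if sd1 <= 0 or sd2 <= 0 or n1 < 2 or n2 < 2:
        raise ValueError("require sd > 0 and n >= 2 in both groups")
    sp = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2))
    if sp == 0:
        raise ValueError("pooled SD is zero")
    return float((mean1 - mean2) / sp)


def explained_variance_pct(r: float) -> float:
    """Signed correlation -> explained variance in percent (r^2 * 100)."""
    return float(r * r * 100.0)


# --------------------------------------------------------------------------
# clinical outcome layer
# --------------------------------------------------------------------------

def classify_responders(pre_raw, post_raw) -> tuple[np.ndarray, float]:
    """Responder = >= 25% reduction of the raw total symptom score.

    Returns (boolean flags, response rate in percent).
    """
    pre = np.asarray(pre_raw, float)
    post = np.asarray(post_raw, float)
    if np.any(pre <= 0):
        raise ValueError("pre-treatment raw scores must be positive")
    flags = (pre - post) / pre >= 0.25
    return flags, float(100.0 * flags.mean())


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Two-sided p by the probability-mass convention (sum of hypergeometric
    probabilities of tables no more likely than the observed one,
    conditional on the margins). Returns (p, odds ratio; inf if bc = 0).
    """
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0) or table.sum() == 0:
        raise ValueError("table entries must be non-negative with positive total")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    res = sps.fisher_exact(table, alternative="two-sided")
    odds = np.inf if b * c == 0 else a * d / (b * c)
    return float(res.pvalue), float(odds)


def mixed_anova(values: pd.DataFrame, groups) -> dict[str, pd.DataFrame]:
    """2-way mixed ANOVA: time (pre, post) within x group between subjects.

    Parameters
    ----------
    values : DataFrame with columns ``pre`` and ``post``, one row per subject.
    groups : per-subject group labels aligned with the rows.

    Returns a dict with ``"anova"`` (effects Group, Time, Time x Group with
    F, dfs, p and partial eta squared) and ``"posthoc"`` (per-group
    pre-vs-post F against the within-subject error term, Bonferroni-corrected
    by the number of groups).

    With two time levels the classical decomposition splits exactly into a
    between-subject ANOVA on subject means and a within-subject ANOVA on the
    change scores; group sizes may be unbalanced (weighted-means solution).
    """
    if not {"pre", "post"}.issubset(values.columns):
        raise ValueError("values must have 'pre' and 'post' columns")
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    k = len(labels)
    sizes = np.array([(groups == lab).sum() for lab in labels])
    if np.any(sizes < 2):
        small = [lab for lab, sz in zip(labels, sizes) if sz < 2]
        raise ValueError(f"each group needs >= 2 subjects; too small: {small}")
    pre = values["pre"].to_numpy(float)
    post = values["post"].to_numpy(float)
    n = len(pre)

    subj_mean = (pre + post) / 2.0
    d = post - pre
    grand_mean = subj_mean.mean()
    d_mean = d.mean()

    # between-subject stratum (doubled: two observations per subject)
    ss_group = 2 * sum(sizes[j] * (subj_mean[groups == labels[j]].mean() - grand_mean) ** 2
                       for j in range(k))
    ss_err_b = 2 * sum(((subj_mean[groups == labels[j]]
                         - subj_mean[groups == labels[j]].mean()) ** 2).sum()
                       for j in range(k))
    # within-subject stratum
    ss_time = n * d_mean ** 2 / 2.0
    group_d = np.array([d[groups == lab].mean() for lab in labels])
    ss_txg = sum(sizes[j] * (group_d[j] - d_mean) ** 2 for j in range(k)) / 2.0
    ss_err_w = sum(((d[groups == labels[j]] - group_d[j]) ** 2).sum()
                   for j in range(k)) / 2.0

    df_g, df_eb = k - 1, n - k
    df_t, df_txg, df_ew = 1, k - 1, n - k

    def row(name, ss, df1, ss_err, df2):
        ms, ms_e = ss / df1, ss_err / df2
        F = 0.0 if ms_e == 0 and ms == 0 else ms / ms_e
        p = sps.f.sf(F, df1, df2)
        return {"effect": name, "SS": ss, "df1": df1, "df2": df2, "F": F,
                "p": p, "eta_p_sq": ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0}

    anova = pd.DataFrame([
        row("Group", ss_group, df_g, ss_err_b, df_eb),
        row("Time", ss_time, df_t, ss_err_w, df_ew),
        row("Time x Group", ss_txg, df_txg, ss_err_w, df_ew),
    ])

    ms_err_w = ss_err_w / df_ew
    post_rows = []
    for j, lab in enumerate(labels):
        ss_c = sizes[j] * group_d[j] ** 2 / 2.0
        F = 0.0 if ms_err_w == 0 and ss_c == 0 else ss_c / ms_err_w
        p_unc = sps.f.sf(F, 1, df_ew)
        post_rows.append({"group": lab, "mean_change": group_d[j],
                          "F": F, "df1": 1, "df2": df_ew,
                          "p_uncorrected": p_unc,
                          "p_bonferroni": min(1.0, k * p_unc),
                          "eta_p_sq": ss_c / (ss_c + ss_err_w) if (ss_c + ss_err_w) > 0 else 0.0})
    return {"anova": anova, "posthoc": pd.DataFrame(post_rows)}
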