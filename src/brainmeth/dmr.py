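"""Differentially methylated region discovery and marker-candidate ranking.

All tests run directly on beta-values.  Three per-probe tests are offered:
a two-group Wilcoxon rank-sum with a Benjamini-Hochberg FDR and an
effect-size gate (|mean difference| > 0.30, q < 0.01 by default), a classic
one-way ANOVA F-test with Bonferroni (or BH) adjustment, and a
Kruskal-Wallis H-test with tie correction.  Missing beta-values are handled
per probe with pairwise-complete observations and a minimum of two values
per group; probes below that guard are not tested.

Also here: dichotomization of beta-values into methylated (>= 0.9) /
unmethylated (<= 0.1) calls, deterministic most-variable-probe ranking
(overall variance, or range of class medians), and the low-variance /
large-difference scoring used to pick locus-specific marker candidates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import MethylationMatrix

__all__ = [
    "wilcoxon_dmr",
    "anova_dmr",
    "kruskal_dmr",
    "dichotomize",
    "rank_most_variable",
    "select_marker_candidates",
    "anova_f",
]


def _aligned_labels(matrix: MethylationMatrix, labels) -> pd.Series:
    labels = pd.Series(labels)
    labels = labels.reindex(matrix.sample_ids)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"samples without a class label: {missing[:5]}")
    return labels.astype(str)


def _group_arrays(matrix: MethylationMatrix, labels: pd.Series, min_per_group: int = 2):
    classes = sorted(labels.unique())
    groups = []
    for c in classes:
        cols = labels.index[labels == c]
        if len(cols) < min_per_group:
            raise ValueError(f"group {c!r} has fewer than {min_per_group} samples")
        groups.append(matrix.beta[cols].to_numpy(dtype=float))
    return classes, groups


def _bh(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def _bonferroni(p: np.ndarray) -> np.ndarray:
    return np.minimum(1.0, p * len(p))


def wilcoxon_dmr(
    matrix: MethylationMatrix,
    labels,
    min_delta: float = 0.30,
    q_max: float = 0.01,
    return_all: bool = False,
) -> pd.DataFrame:
    """Two-group rank-sum DMR test with BH-FDR and an effect-size gate.

    Returns the probes with |mean(A) - mean(B)| > ``min_delta`` and BH
    q < ``q_max``, annotated with the hypermethylated group.  With
    ``return_all=True`` all tested probes are returned ungated.
    """
    labels = _aligned_labels(matrix, labels)
    classes, (ga, gb) = _group_arrays(matrix, labels)
    if len(classes) != 2:
        raise ValueError(f"wilcoxon_dmr needs exactly two groups, got {classes}")
    a, b = classes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(ga, axis=1)
        mean_b = np.nanmean(gb, axis=1)
    stat = np.full(matrix.n_probes, np.nan)
    pvals = np.full(matrix.n_probes, np.nan)
    enough = (np.sum(~np.isnan(ga), axis=1) >= 2) & (np.sum(~np.isnan(gb), axis=1) >= 2)
    complete = enough & ~np.isnan(ga).any(axis=1) & ~np.isnan(gb).any(axis=1)
    if complete.any():
        res = stats.mannwhitneyu(ga[complete], gb[complete], alternative="two-sided", axis=1)
        stat[complete] = np.atleast_1d(res.statistic)
        pvals[complete] = np.atleast_1d(res.pvalue)
    for i in np.flatnonzero(enough & ~complete):
        x = ga[i][~np.isnan(ga[i])]
        y = gb[i][~np.isnan(gb[i])]
        r = stats.mannwhitneyu(x, y, alternative="two-sided")
        stat[i], pvals[i] = r.statistic, r.pvalue
    q = np.full_like(pvals, np.nan)
    tested = ~np.isnan(pvals)
    if tested.any():
        q[tested] = _bh(pvals[tested])
    delta = np.abs(mean_a - mean_b)
    records = pd.DataFrame(
        {
            f"mean_{a}": mean_a,
            f"mean_{b}": mean_b,
            "delta": delta,
            "statistic": stat,
            "p_raw": pvals,
            "p_adj": q,
            "adjust_method": "bh_fdr",
            "direction": np.where(mean_a >= mean_b, f"hyper_in_{a}", f"hyper_in_{b}"),
        },
        index=matrix.probe_ids,
    )
    if return_all:
        return records
    keep = tested & (delta > min_delta) & (q < q_max)
    return records.loc[keep]


def anova_f(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p for 1-D group arrays (NaN-free).

    F = (SSB / (k - 1)) / (SSW / (N - k)); zero within-group variance with
    separated means yields F = +inf, p = 0.
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    n_total = ns.sum()
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    dfb, dfw = k - 1, int(n_total) - k
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / dfb) / (ssw / dfw)
    return f, float(stats.f.sf(f, dfb, dfw))


def _per_probe_k_sample(matrix, labels, statfun):
    """Apply a k-sample test per probe with a >=2-per-group NaN guard."""
    labels = _aligned_labels(matrix, labels)
    classes, groups = _group_arrays(matrix, labels)
    n_probes = matrix.n_probes
    stat = np.full(n_probes, np.nan)
    pvals = np.full(n_probes, np.nan)
    means = np.full((n_probes, len(classes)), np.nan)
    for i in range(n_probes):
        rows = [g[i][~np.isnan(g[i])] for g in groups]
        if any(len(r) < 2 for r in rows):
            continue
        means[i] = [r.mean() for r in rows]
        stat[i], pvals[i] = statfun(rows)
    delta = np.nanmax(means, axis=1) - np.nanmin(means, axis=1)
    return classes, means, delta, stat, pvals


def anova_dmr(
    matrix: MethylationMatrix,
    labels,
    adjust: str = "bonferroni",
    alpha: float = 0.05,
    min_delta: float = 0.0,
    return_all: bool = False,
) -> pd.DataFrame:
    """Per-probe one-way ANOVA across k groups with multiplicity adjustment.

    ``adjust`` is ``"bonferroni"`` (p_adj = min(1, p * m), m = probes
    tested) or ``"bh_fdr"``.  Probes with adjusted p < ``alpha`` (and, when
    ``min_delta`` > 0, max pairwise mean difference above it) are returned.
    """
    classes, means, delta, stat, pvals = _per_probe_k_sample(matrix, labels, anova_f)
    if adjust not in ("bonferroni", "bh_fdr"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    tested = ~np.isnan(pvals)
    p_adj = np.full_like(pvals, np.nan)
    if tested.any():
        adjuster = _bonferroni if adjust == "bonferroni" else _bh
        p_adj[tested] = adjuster(pvals[tested])
    records = pd.DataFrame(
        {
            **{f"mean_{c}": means[:, j] for j, c in enumerate(classes)},
            "delta": delta,
            "statistic": stat,
            "p_raw": pvals,
            "p_adj": p_adj,
            "adjust_method": adjust,
        },
        index=matrix.probe_ids,
    )
    if return_all:
        return records
    keep = tested & (p_adj < alpha) & (delta > min_delta)
    return records.loc[keep]


def _kruskal(rows: list[np.ndarray]) -> tuple[float, float]:
    if np.ptp(np.concatenate(rows)) == 0:
        # identical values everywhere: H = 0 by convention, p = 1
        return 0.0, 1.0
    r = stats.kruskal(*rows)
    return float(r.statistic), float(r.pvalue)


def kruskal_dmr(
    matrix: MethylationMatrix,
    labels,
    p_max: float = 1e-4,
    return_all: bool = False,
) -> pd.DataFrame:
    """Per-probe Kruskal-Wallis H-test (tie-corrected, chi-square p).

    Returns probes with raw p < ``p_max`` (no multiplicity adjustment;
    ``p_adj`` mirrors ``p_raw``).
    """
    classes, means, delta, stat, pvals = _per_probe_k_sample(matrix, labels, _kruskal)
    records = pd.DataFrame(
        {
            **{f"mean_{c}": means[:, j] for j, c in enumerate(classes)},
            "delta": delta,
            "statistic": stat,
            "p_raw": pvals,
            "p_adj": pvals,
            "adjust_method": "none",
        },
        index=matrix.probe_ids,
    )
    if return_all:
        return records
    keep = ~np.isnan(pvals) & (pvals < p_max)
    return records.loc[keep]


METHYLATED_MIN = 0.9
UNMETHYLATED_MAX = 0.1


def dichotomize(beta):
    """Map beta-values to 'methylated' (>= 0.9), 'unmethylated' (<= 0.1) or
    'indeterminate'.  Accepts scalars or arrays."""
    arr = np.asarray(beta, dtype=float)
    out = np.where(
        arr >= METHYLATED_MIN,
        "methylated",
        np.where(arr <= UNMETHYLATED_MAX, "unmethylated", "indeterminate"),
    )
    if np.ndim(beta) == 0:
        return out.item()
    return out


def class_median_range(matrix: MethylationMatrix, labels) -> pd.Series:
    """Per-probe range (max - min) of the class medians of beta."""
    labels = _aligned_labels(matrix, labels)
    medians = []
    for c in sorted(labels.unique()):
        cols = labels.index[labels == c]
        medians.append(matrix.beta[cols].median(axis=1))
    med = pd.concat(medians, axis=1)
    return (med.max(axis=1) - med.min(axis=1)).rename("class_median_range")


def rank_most_variable(
    matrix: MethylationMatrix, k: int, mode: str = "variance", labels=None
) -> pd.Index:
    """Top-k probes by overall variance or by range of class medians.

    Deterministic: ties are broken by probe id (lexicographic).
    """
    if mode == "variance":
        score = matrix.beta.var(axis=1, ddof=1)
    elif mode == "class_median_range":
        if labels is None:
            raise ValueError("class_median_range mode requires labels")
        score = class_median_range(matrix, labels)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if k > matrix.n_probes:
        warnings.warn(
            f"requested top {k} of {matrix.n_probes} probes; returning all", stacklevel=2
        )
        k = matrix.n_probes
    order = np.lexsort((matrix.probe_ids.to_numpy(), -score.to_numpy()))
    return matrix.probe_ids[order[:k]]


def select_marker_candidates(
    matrix: MethylationMatrix,
    labels,
    n_per_class: int,
    classes=None,
    lam: float = 1.0,
) -> pd.DataFrame:
    """Score hypermethylated-in-class marker candidates per target class.

    score = (mean in class - mean out of class) - lam * pooled within-class
    SD, favouring probes with a large between-class shift and low scatter.
    Only probes hypermethylated in the target class qualify; the top
    ``n_per_class`` per class are returned.
    """
    labels = _aligned_labels(matrix, labels)
    all_classes, groups = _group_arrays(matrix, labels)
    if classes is None:
        classes = all_classes
    else:
        missing = set(classes) - set(all_classes)
        if missing:
            raise ValueError(f"classes absent from labels: {sorted(missing)}")
    beta = matrix.beta.to_numpy(dtype=float)
    n_total = beta.shape[1]
    # pooled within-class SD across all classes
    ssw = np.zeros(beta.shape[0])
    for g in groups:
        ssw += ((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_sd = np.sqrt(ssw / (n_total - len(all_classes)))
    frames = []
    for c in classes:
        in_cols = labels.index[labels == c]
        out_cols = labels.index[labels != c]
        mean_in = matrix.beta[in_cols].mean(axis=1).to_numpy()
        mean_out = matrix.beta[out_cols].mean(axis=1).to_numpy()
        score = (mean_in - mean_out) - lam * pooled_sd
        df = pd.DataFrame(
            {
                "target_class": c,
                "probe_id": matrix.probe_ids,
                "mean_in": mean_in,
                "mean_out": mean_out,
                "pooled_sd": pooled_sd,
                "score": score,
            }
        )
        df = df[df["mean_in"] > df["mean_out"]]
        order = np.lexsort((df["probe_id"].to_numpy(), -df["score"].to_numpy()))
        frames.append(df.iloc[order[:n_per_class]])
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
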