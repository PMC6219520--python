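"""qMSP quantification (ΔCt → relative level → percent methylation),
composite methylation scores, ROC/AUC and array-concordance statistics.

A qMSP measurement pairs a methylated-allele (M) and an unmethylated-allele
(U) reaction on bisulfite-converted DNA.  ΔCt = mean Ct_M - mean Ct_U and
the relative methylation level is 2^(-ΔCt).  An undetermined Ct (no
amplification) is substituted by a ceiling cycle number (default 40, the
usual qPCR convention) and flagged.  Percent methylation is estimated from
a standard curve of serial dilutions of a fully methylated control in an
unmethylated one, by least-squares fit of pct = a*ln(rel_level) + b
(natural log); calibrated values are clamped to [0, 100].

Composite scores subtract the contrasting types' levels from the target
type's level: score = mean(level over the target's regions) minus, for each
contrasting type, the mean level over that type's regions.  The named
panels of the three-step classifier ship as built-in
:class:`ScoreDefinition` objects.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import PanelError

__all__ = [
    "QmspMeasurement",
    "StandardCurve",
    "ScoreDefinition",
    "RocResult",
    "CT_CEILING",
    "compute_delta_ct",
    "compute_rel_level",
    "fit_standard_curve",
    "calibrate",
    "composite_score",
    "roc_auc",
    "spearman_concordance",
    "measurement_from_table",
    "BUILTIN_SCORES",
]

logger = logging.getLogger(__name__)

CT_CEILING = 40.0


def _clean_ct(ct, ceiling: float) -> tuple[np.ndarray, bool]:
    arr = np.asarray(ct, dtype=float).ravel()
    undetermined = ~np.isfinite(arr)
    if undetermined.all() and len(arr) == 0:
        raise ValueError("need at least one Ct replicate")
    if undetermined.any():
        logger.warning("undetermined Ct replaced by ceiling %.1f", ceiling)
        arr = np.where(undetermined, ceiling, arr)
    if (arr <= 0).any():
        raise ValueError("Ct values must be positive")
    return arr, bool(undetermined.any())


def compute_delta_ct(ct_m, ct_u, ceiling: float = CT_CEILING) -> float:
    """ΔCt = mean(Ct methylated) - mean(Ct unmethylated).

    Undetermined (non-finite) replicates are replaced by ``ceiling``.
    """
    m, _ = _clean_ct(ct_m, ceiling)
    u, _ = _clean_ct(ct_u, ceiling)
    if len(m) == 0 or len(u) == 0:
        raise ValueError("need at least one Ct replicate per reaction")
    return float(m.mean() - u.mean())


def compute_rel_level(delta_ct: float) -> float:
    """Relative methylation level 2^(-ΔCt)."""
    return float(2.0 ** (-delta_ct))


@dataclass
class QmspMeasurement:
    """One region's qMSP quantification for one sample."""

    sample_id: str
    region_id: str
    ct_methylated: tuple
    ct_unmethylated: tuple
    delta_ct: float
    rel_level: float
    pct_methylation: float | None = None
    had_undetermined: bool = False

    @classmethod
    def from_ct(
        cls,
        sample_id: str,
        region_id: str,
        ct_m,
        ct_u,
        curve: "StandardCurve | None" = None,
        ceiling: float = CT_CEILING,
    ) -> "QmspMeasurement":
        m, flag_m = _clean_ct(ct_m, ceiling)
        u, flag_u = _clean_ct(ct_u, ceiling)
        dct = float(m.mean() - u.mean())
        rel = compute_rel_level(dct)
        pct = calibrate(rel, curve) if curve is not None else None
        return cls(
            sample_id=sample_id,
            region_id=region_id,
            ct_methylated=tuple(m),
            ct_unmethylated=tuple(u),
            delta_ct=dct,
            rel_level=rel,
            pct_methylation=pct,
            had_undetermined=flag_m or flag_u,
        )


@dataclass
class StandardCurve:
    """Log-linear calibration pct = a*ln(rel_level) + b from dilution points.

    ``points`` are (known methylated fraction in percent, measured
    rel_level) pairs; ``log_base`` records the natural-log convention.
    """

    points: list[tuple[float, float]]
    a: float
    b: float
    r_squared: float
    log_base: str = "e"

    def predict(self, rel_level) -> np.ndarray:
        rel = np.asarray(rel_level, dtype=float)
        if (rel <= 0).any():
            raise ValueError("rel_level must be positive")
        return np.clip(self.a * np.log(rel) + self.b, 0.0, 100.0)


def fit_standard_curve(points) -> StandardCurve:
    """Least-squares fit of pct = a*ln(rel_level) + b over dilution points.

    ``points``: iterable of (known fraction in percent, rel_level); needs at
    least 3 points with at least 2 distinct rel_levels, all positive.
    """
    pts = [(float(p), float(r)) for p, r in points]
    if len(pts) < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    pct = np.array([p for p, _ in pts])
    rel = np.array([r for _, r in pts])
    if len(np.unique(pct)) != len(pct):
        raise ValueError("known fractions must be distinct")
    if (rel <= 0).any():
        raise ValueError("rel_level must be positive in curve points")
    x = np.log(rel)
    if len(np.unique(x)) < 2:
        raise ValueError("degenerate curve: fewer than 2 distinct rel_levels")
    a, b = np.polyfit(x, pct, 1)
    resid = pct - (a * x + b)
    ss_tot = ((pct - pct.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(points=pts, a=float(a), b=float(b), r_squared=float(r2))


def calibrate(rel_level, curve: StandardCurve) -> float:
    """Percent methylation from a relative level via the fitted curve."""
    out = curve.predict(rel_level)
    return float(out) if np.ndim(rel_level) == 0 else out


# ---------------------------------------------------------------------------
# Composite scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreDefinition:
    """A named composite methylation score.

    ``positive`` lists the target type's region ids (averaged);
    ``negative_groups`` lists, per contrasting type, that type's region ids
    (each group is averaged and then subtracted).
    """

    name: str
    positive: tuple
    negative_groups: tuple  # tuple of tuples of region ids

    def __post_init__(self) -> None:
        if not self.positive:
            raise ValueError("positive region set must be non-empty")
        negatives = set(itertools.chain.from_iterable(self.negative_groups))
        if negatives & set(self.positive):
            raise ValueError("positive and negative region sets must be disjoint")

    @property
    def regions(self) -> tuple:
        return tuple(self.positive) + tuple(itertools.chain.from_iterable(self.negative_groups))

    def swapped(self) -> "ScoreDefinition":
        """Swap positive and negative sets (single-group scores only)."""
        if len(self.negative_groups) != 1:
            raise ValueError("swap is defined only for single-negative-group scores")
        return ScoreDefinition(
            name=f"{self.name} (swapped)",
            positive=tuple(self.negative_groups[0]),
            negative_groups=(tuple(self.positive),),
        )


def composite_score(levels, definition: ScoreDefinition) -> float:
    """Evaluate a composite score on per-region methylation levels.

    ``levels`` maps region id → methylation level.  Missing regions raise
    (no silent imputation).
    """
    missing = [r for r in definition.regions if r not in levels]
    if missing:
        raise PanelError(f"missing region measurements for score {definition.name!r}: {missing}")
    pos = float(np.mean([levels[r] for r in definition.positive]))
    neg = sum(float(np.mean([levels[r] for r in g])) for g in definition.negative_groups)
    return pos - neg


#: The named panels of the three-step classifier.  Class A separates
#: metastases from glioblastoma; class B scores the three tissues of
#: origin; class C scores the three therapeutic subtypes using two regions
#: per subtype.
BUILTIN_SCORES: dict[str, ScoreDefinition] = {
    "BMscore": ScoreDefinition("BMscore", ("BM-C",), (("GBM-A",),)),
    "MBMscore": ScoreDefinition("MBMscore", ("MBM-B",), (("LCBM-C",), ("BCBM-C",))),
    "LCBMscore": ScoreDefinition("LCBMscore", ("LCBM-C",), (("BCBM-C",), ("MBM-B",))),
    "BCBMscore": ScoreDefinition("BCBMscore", ("BCBM-C",), (("LCBM-C",), ("MBM-B",))),
    "HR+/HER2-score": ScoreDefinition(
        "HR+/HER2-score",
        ("HR+/HER2--1", "HR+/HER2--2"),
        (("HER2+-1", "HER2+-2"), ("HR-/HER2--1", "HR-/HER2--2")),
    ),
    "HER2+score": ScoreDefinition(
        "HER2+score",
        ("HER2+-1", "HER2+-2"),
        (("HR+/HER2--1", "HR+/HER2--2"), ("HR-/HER2--1", "HR-/HER2--2")),
    ),
    "HR-/HER2-score": ScoreDefinition(
        "HR-/HER2-score",
        ("HR-/HER2--1", "HR-/HER2--2"),
        (("HR+/HER2--1", "HR+/HER2--2"), ("HER2+-1", "HER2+-2")),
    ),
}

ORIGIN_SCORES = ("MBMscore", "LCBMscore", "BCBMscore")
SUBTYPE_SCORES = ("HR+/HER2-score", "HER2+score", "HR-/HER2-score")


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    auc: float
    ci_lower: float
    ci_upper: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_threshold: float
    n_bootstrap: int

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.auc <= self.ci_upper):
            raise ValueError("CI must bracket the point AUC")


def roc_auc(
    scores, labels, ci_method: str = "stratified_bootstrap", n_bootstrap: int = 2000, seed: int = 0
) -> RocResult:
    """AUC with a stratified percentile-bootstrap CI and Youden threshold.

    The AUC is the Mann-Whitney/trapezoid probability that a positive
    outscores a negative (ties count 1/2).  The 95% CI resamples positives
    and negatives separately; degenerate bootstrap draws are skipped.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present to compute an AUC")
    auc = float(roc_auc_score(y, scores))
    if ci_method != "stratified_bootstrap":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    rng = np.random.default_rng(seed)
    pos = scores[y == 1]
    neg = scores[y == 0]
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        ps = rng.choice(pos, size=len(pos), replace=True)
        ns = rng.choice(neg, size=len(neg), replace=True)
        # pairwise Mann-Whitney estimate, ties at 1/2
        greater = (ps[:, None] > ns[None, :]).mean()
        ties = (ps[:, None] == ns[None, :]).mean()
        boots[b] = greater + 0.5 * ties
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, auc), max(hi, auc)
    fpr, tpr, thresholds = roc_curve(y, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    return RocResult(
        auc=auc,
        ci_lower=float(lo),
        ci_upper=float(hi),
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        youden_threshold=float(thresholds[best]),
        n_bootstrap=n_bootstrap,
    )


# ---------------------------------------------------------------------------
# Concordance with the array
# ---------------------------------------------------------------------------


def spearman_concordance(qmsp_levels, array_beta, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation between paired qMSP and array measurements.

    Tie-adjusted ranks; the p-value uses the t approximation, except for
    small tie-free samples (n <= ``exact_max_n``) where the exact
    permutation null of rho is enumerated.
    """
    x = np.asarray(qmsp_levels, dtype=float)
    y = np.asarray(array_beta, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rho, p_t = stats.spearmanr(x, y)
    rho = float(rho)
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if no_ties and n <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        perms = np.array(list(itertools.permutations(ry)))
        num = ((perms - ry.mean()) * (rx - rx.mean())).sum(axis=1)
        den = math.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
        rho_null = num / den
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
        return rho, p
    return rho, float(p_t)


# ---------------------------------------------------------------------------
# Table-driven quantification
# ---------------------------------------------------------------------------


def curve_from_table(table, region_id: str, ceiling: float = CT_CEILING) -> StandardCurve:
    """Fit a region's standard curve from its dilution rows in a QmspTable."""
    rows = table.curve_rows(region_id)
    if rows.empty:
        raise PanelError(f"no standard-curve rows for region {region_id!r}")
    points = []
    for frac, sub in rows.groupby("known_fraction"):
        m_rows = sub[sub["reaction"] == "M"]
        u_rows = sub[sub["reaction"] == "U"]
        if m_rows.empty or u_rows.empty:
            raise PanelError(
                f"curve point {frac} for region {region_id!r} needs both M and U reactions"
            )
        ct_m = m_rows[table.ct_columns].to_numpy(dtype=float).ravel()
        ct_u = u_rows[table.ct_columns].to_numpy(dtype=float).ravel()
        ct_m = ct_m[~np.isnan(ct_m)] if np.isfinite(ct_m).any() else ct_m
        ct_u = ct_u[~np.isnan(ct_u)] if np.isfinite(ct_u).any() else ct_u
        dct = compute_delta_ct(ct_m, ct_u, ceiling)
        points.append((float(frac) * 100.0, compute_rel_level(dct)))
    return fit_standard_curve(points)


def measurement_from_table(
    table,
    sample_id: str,
    region_id: str,
    curve: StandardCurve | None = None,
    ceiling: float = CT_CEILING,
) -> QmspMeasurement:
    """Quantify one sample/region from a long-format qMSP table."""
    ct_m = table.replicates(sample_id, region_id, "M")
    ct_u = table.replicates(sample_id, region_id, "U")
    ct_m = ct_m[~np.isnan(ct_m)] if np.isfinite(ct_m).any() else ct_m
    ct_u = ct_u[~np.isnan(ct_u)] if np.isfinite(ct_u).any() else ct_u
    return QmspMeasurement.from_ct(sample_id, region_id, ct_m, ct_u, curve=curve, ceiling=ceiling)
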