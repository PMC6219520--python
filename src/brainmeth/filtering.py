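"""Sequential probe-exclusion pipeline for 450K-style beta matrices.

Probes are dropped, in order, when they (1) fail sequence-level quality
checks (SNP overlap, repetitive elements, GC density above 25% of the 50-bp
probe sequence, non-unique mapping, low mapping quality), (2) target sex
chromosomes or cross-react with them, (3) fail detection (detection
p-value > 0.01 in any sample, or any missing beta), (4) were dropped from
the EPIC array design, or (5) show no tumor-vs-normal methylation difference
(two-sided rank-sum p > 0.05, uncorrected).  Exclusion counts are accounted
sequentially: each stage only counts probes that survived all earlier
stages, so the per-stage counts plus the retained count sum to the input
count.  Boundary cases use strict inequalities (a probe at exactly 25% GC,
detection p exactly 0.01, or rank-sum p exactly 0.05 is retained).

The subtype task re-admits X-chromosome probes that pass every quality
check (``FilterConfig(include_x_chromosome=True)``), since that cohort is
gender-homogeneous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import MethylationMatrix, ProbeAnnotation, SEX_CHROMOSOMES

__all__ = [
    "FilterConfig",
    "FilterStep",
    "FilterReport",
    "flag_quality_exclusions",
    "flag_sex_exclusions",
    "flag_detection_failures",
    "flag_epic_dropped",
    "flag_uninformative_vs_normal",
    "run_filter_pipeline",
]

logger = logging.getLogger(__name__)

_KNOWN_CHROMS = frozenset({f"chr{i}" for i in range(1, 23)} | SEX_CHROMOSOMES)

GC_DENSITY_MAX = 0.25
DETECTION_P_MAX = 0.01
VS_NORMAL_ALPHA = 0.05


@dataclass(frozen=True)
class FilterConfig:
    """Switches and thresholds for :func:`run_filter_pipeline`."""

    include_x_chromosome: bool = False
    detection_p_threshold: float = DETECTION_P_MAX
    vs_normal_alpha: float = VS_NORMAL_ALPHA
    skip_detection: bool = False
    skip_vs_normal: bool = False


@dataclass(frozen=True)
class FilterStep:
    criterion: str
    n_excluded: int
    n_remaining: int


@dataclass
class FilterReport:
    """Ordered per-criterion accounting of a filtering run."""

    n_input: int
    steps: list[FilterStep]
    retained: pd.Index
    excluded_ids: dict[str, pd.Index] = field(default_factory=dict)

    def __post_init__(self) -> None:
        remaining = [s.n_remaining for s in self.steps]
        if any(b > a for a, b in zip(remaining, remaining[1:])):
            raise ValueError("remaining counts must be non-increasing")
        total_excluded = sum(s.n_excluded for s in self.steps)
        if total_excluded + len(self.retained) != self.n_input:
            raise ValueError("exclusions plus retained do not sum to the input count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.criterion, s.n_excluded, s.n_remaining) for s in self.steps],
            columns=["criterion", "n_excluded", "n_remaining"],
        )

    def __str__(self) -> str:
        lines = [f"input probes: {self.n_input}"]
        for s in self.steps:
            lines.append(f"  - {s.criterion}: excluded {s.n_excluded}, remaining {s.n_remaining}")
        lines.append(f"retained informative probes: {len(self.retained)}")
        return "\n".join(lines)


def _require_annotated(annotation: ProbeAnnotation, probes: pd.Index) -> pd.DataFrame:
    missing = probes.difference(annotation.table.index)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} probes missing from annotation, e.g. {missing.tolist()[:5]}"
        )
    return annotation.table.loc[probes]


def flag_quality_exclusions(annotation: ProbeAnnotation, probes=None) -> pd.Series:
    """True for probes failing any sequence-level quality criterion."""
    probes = annotation.probe_ids if probes is None else pd.Index(probes)
    t = _require_annotated(annotation, probes)
    mask = (
        t["snp_overlap"]
        | t["repeat_element"]
        | (t["gc_density"] > GC_DENSITY_MAX)
        | ~t["unique_mapping"]
        | ~t["mapping_quality_ok"]
    )
    return mask.rename("quality")


def flag_sex_exclusions(
    annotation: ProbeAnnotation, probes=None, include_x_chromosome: bool = False
) -> pd.Series:
    """True for sex-chromosome probes and autosomal probes cross-reacting
    with sex chromosomes.

    With ``include_x_chromosome=True``, X-chromosome probes passing every
    quality flag are retained (chrY and cross-reactive probes are still
    excluded).  Unrecognized chromosome names pass through unflagged with a
    logged warning.
    """
    probes = annotation.probe_ids if probes is None else pd.Index(probes)
    t = _require_annotated(annotation, probes)
    unknown = ~t["chrom"].isin(_KNOWN_CHROMS)
    if unknown.any():
        logger.warning(
            "%d probes on unrecognized chromosomes (e.g. %r) pass the sex filter unflagged",
            int(unknown.sum()),
            t.loc[unknown, "chrom"].iloc[0],
        )
    mask = t["chrom"].isin(SEX_CHROMOSOMES) | t["cross_reactive_sex"]
    if include_x_chromosome:
        clean = ~flag_quality_exclusions(annotation, probes) & ~t["cross_reactive_sex"]
        mask &= ~((t["chrom"] == "chrX") & clean)
    return mask.rename("sex")


def flag_detection_failures(
    matrix: MethylationMatrix, p_threshold: float = DETECTION_P_MAX
) -> pd.Series:
    """True for probes with detection p > threshold (or missing beta) in any sample."""
    if matrix.detection_p is None:
        raise ValidationError(
            "matrix has no detection p-values; pass skip_detection=True to "
            "omit the detection stage explicitly"
        )
    failed = (matrix.detection_p > p_threshold).any(axis=1)
    failed |= matrix.beta.isna().any(axis=1)
    return failed.rename("detection")


def flag_epic_dropped(annotation: ProbeAnnotation, probes=None) -> pd.Series:
    """True for probes removed from the EPIC BeadChip design."""
    probes = annotation.probe_ids if probes is None else pd.Index(probes)
    t = _require_annotated(annotation, probes)
    return (~t["epic_retained"]).rename("epic")


def flag_uninformative_vs_normal(
    tumor: MethylationMatrix,
    normal: MethylationMatrix,
    alpha: float = VS_NORMAL_ALPHA,
    return_pvalues: bool = False,
):
    """True for probes without significant tumor-vs-normal difference.

    Per probe, a two-sided Wilcoxon rank-sum (Mann-Whitney) test of tumor
    vs normal beta-values; the probe is excluded iff p > ``alpha`` (no
    multiplicity correction).  Probes with fewer than two non-missing values
    on either side are excluded with p = NaN ("insufficient data").
    """
    if not tumor.probe_ids.equals(normal.probe_ids):
        raise ValidationError("tumor and normal matrices must share the same probe set")
    if tumor.n_samples < 2 or normal.n_samples < 2:
        raise ValidationError("need at least 2 samples per side for the rank-sum filter")
    tv = tumor.beta.to_numpy(dtype=float)
    nv = normal.beta.to_numpy(dtype=float)
    pvals = np.full(tv.shape[0], np.nan)
    complete = ~np.isnan(tv).any(axis=1) & ~np.isnan(nv).any(axis=1)
    if complete.any():
        res = stats.mannwhitneyu(tv[complete], nv[complete], alternative="two-sided", axis=1)
        pvals[complete] = np.atleast_1d(res.pvalue)
    for i in np.flatnonzero(~complete):
        x = tv[i][~np.isnan(tv[i])]
        y = nv[i][~np.isnan(nv[i])]
        if len(x) >= 2 and len(y) >= 2:
            pvals[i] = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    pser = pd.Series(pvals, index=tumor.probe_ids, name="p_vs_normal")
    mask = (pser.isna() | (pser > alpha)).rename("vs_normal")
    if return_pvalues:
        return mask, pser
    return mask


def run_filter_pipeline(
    matrix: MethylationMatrix,
    annotation: ProbeAnnotation,
    config: FilterConfig = FilterConfig(),
    normal: MethylationMatrix | None = None,
) -> tuple[MethylationMatrix, FilterReport]:
    """Apply all exclusion stages in order and return the informative matrix.

    Stage order: quality → sex → detection → EPIC → vs-normal.  The
    detection stage requires detection p-values (or ``skip_detection=True``)
    and the vs-normal stage requires a normal-tissue matrix covering the
    same probes (or ``skip_vs_normal=True``).
    """
    _require_annotated(annotation, matrix.probe_ids)
    remaining = matrix
    steps: list[FilterStep] = []
    excluded: dict[str, pd.Index] = {}

    def apply(name: str, mask: pd.Series) -> None:
        nonlocal remaining
        drop = mask.index[mask]
        excluded[name] = drop
        remaining = remaining.subset_probes(mask.index[~mask])
        steps.append(FilterStep(name, len(drop), remaining.n_probes))

    apply("quality", flag_quality_exclusions(annotation, remaining.probe_ids))
    apply(
        "sex",
        flag_sex_exclusions(
            annotation, remaining.probe_ids, include_x_chromosome=config.include_x_chromosome
        ),
    )
    if config.skip_detection:
        steps.append(FilterStep("detection (skipped)", 0, remaining.n_probes))
        excluded["detection (skipped)"] = pd.Index([])
    else:
        apply("detection", flag_detection_failures(remaining, config.detection_p_threshold))
    apply("epic", flag_epic_dropped(annotation, remaining.probe_ids))
    if config.skip_vs_normal:
        steps.append(FilterStep("vs_normal (skipped)", 0, remaining.n_probes))
        excluded["vs_normal (skipped)"] = pd.Index([])
    else:
        if normal is None:
            raise ValidationError(
                "no normal-tissue matrix given; pass skip_vs_normal=True to "
                "omit the vs-normal stage explicitly"
            )
        apply(
            "vs_normal",
            flag_uninformative_vs_normal(
                remaining, normal.subset_probes(remaining.probe_ids), config.vs_normal_alpha
            ),
        )
    report = FilterReport(matrix.n_probes, steps, remaining.probe_ids, excluded)
    return remaining, report
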