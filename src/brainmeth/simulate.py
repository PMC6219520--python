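"""Synthetic methylomes, annotations, sample sheets and qMSP tables.

The generator emulates the statistical structure the pipeline assumes:
beta-values drawn from Beta distributions with class-shifted means on
planted differentially methylated probes, small detection p-values except
for planted detection failures, per-criterion planted annotation failures
(all planted sets mutually disjoint), a normal-tissue matrix that differs
from the tumors at all informative probes, and Ct values derived from true
methylation fractions through a simple exponential-amplification model:

    Ct_M = C0 - log2(m + eps) + noise,   Ct_U = C0 - log2(1 - m + eps) + noise

so that the noise-free relative level 2^(-dCt) equals (m+eps)/(1-m+eps).
Every run is fully determined by the seed, and a ground-truth manifest
sufficient to score any downstream stage is returned with the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import MethylationMatrix, ProbeAnnotation, QmspTable, SampleSheet, NA

__all__ = [
    "SimulationConfig",
    "QmspSimConfig",
    "GroundTruth",
    "SimulatedBundle",
    "simulate_methylomes",
    "simulate_qmsp",
    "panel_truth",
    "PANEL_REGIONS",
]

_QUALITY_FLAGS = ("snp_overlap", "repeat_element", "gc_density", "unique_mapping", "mapping_quality_ok")
FILTER_CRITERIA = ("quality", "sex", "detection", "epic", "vs_normal")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic methylome.

    Defaults are the three-class tissue-of-origin setting used throughout:
    30 samples per class, 10,000 probes, 150 planted class-specific DMRs
    per class with a mean beta shift of 0.4, Beta(2,2) baseline means, a
    within-class Beta concentration of 50 (per-sample SD ~0.07 at beta
    0.5), 20 normal-brain samples shifted by 0.3 at every informative
    probe, and small planted fractions of probes failing each filter
    criterion.
    """

    n_probes: int = 10_000
    classes: tuple = (("BCBM", 30), ("LCBM", 30), ("MBM", 30))
    n_dmr_per_class: int = 150
    effect_size: float = 0.4
    baseline_shape: tuple = (2.0, 2.0)
    concentration: float = 50.0
    n_normal: int = 20
    vs_normal_delta: float = 0.3
    filter_failure_fraction: dict = field(
        default_factory=lambda: {
            "quality": 0.02,
            "sex": 0.02,
            "detection": 0.002,
            "epic": 0.01,
            "vs_normal": 0.005,
        }
    )
    detection_fail_range: tuple = (0.02, 0.5)
    label_kind: str = "origin"  # "origin" or "subtype"
    seed: int = 0

    def filter_failure_counts(self) -> dict:
        return {
            crit: int(round(self.filter_failure_fraction.get(crit, 0.0) * self.n_probes))
            for crit in FILTER_CRITERIA
        }


@dataclass
class GroundTruth:
    """Everything needed to score downstream stages without external data."""

    planted_dmr: dict  # class -> list of probe ids
    true_class_means: pd.DataFrame  # probes x (classes + "normal")
    filter_failures: dict  # criterion -> list of probe ids
    seed: int

    @property
    def all_planted_dmr(self) -> list:
        out: list = []
        for ids in self.planted_dmr.values():
            out.extend(ids)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_dmr": self.planted_dmr,
                "filter_failures": self.filter_failures,
                "seed": self.seed,
                "true_class_means": self.true_class_means.round(6).to_dict(orient="index"),
            },
            indent=1,
        )


@dataclass
class SimulatedBundle:
    matrix: MethylationMatrix  # tumor samples, with detection p-values
    normal: MethylationMatrix  # normal-tissue samples
    annotation: ProbeAnnotation
    sample_sheet: SampleSheet  # tumor + normal samples
    truth: GroundTruth


def _feasible_shift(mu: np.ndarray, delta: float, lo: float = 0.02, hi: float = 0.98) -> np.ndarray:
    """Shifted means mu +/- delta, choosing the direction that stays in (0,1)."""
    up_ok = mu + delta <= hi
    down_ok = mu - delta >= lo
    if not (up_ok | down_ok).all():
        bad = np.flatnonzero(~(up_ok | down_ok))[0]
        raise ValueError(f"mean shift {delta} infeasible for baseline mean {mu[bad]:.3f}")
    return np.where(up_ok, mu + delta, mu - delta)


def _sample_beta(rng: np.random.Generator, means: np.ndarray, concentration: float) -> np.ndarray:
    means = np.clip(means, 1e-3, 1 - 1e-3)
    return rng.beta(means * concentration, (1.0 - means) * concentration)


def simulate_methylomes(config: SimulationConfig = SimulationConfig()) -> SimulatedBundle:
    """Generate a mutually consistent beta matrix, annotation, sample sheet,
    normal-tissue matrix and ground-truth manifest."""
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    width = max(6, len(str(n)))
    probe_ids = np.array([f"cg{i:0{width}d}" for i in range(n)])
    class_names = [c for c, _ in config.classes]

    # --- disjoint planted sets -------------------------------------------
    fail_counts = config.filter_failure_counts()
    n_planted = sum(fail_counts.values()) + config.n_dmr_per_class * len(class_names)
    if n_planted > n:
        raise ValueError("planted failure and DMR counts exceed the probe count")
    pool = rng.permutation(n)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = pool[cursor : cursor + k]
        cursor += k
        return np.sort(out)

    failures = {crit: take(fail_counts[crit]) for crit in FILTER_CRITERIA}
    dmr_idx = {c: take(config.n_dmr_per_class) for c in class_names}

    # --- true means -------------------------------------------------------
    a, b = config.baseline_shape
    mu = np.clip(rng.beta(a, b, size=n), 0.02, 0.98)
    # planted probes need room for the class shift: redraw their baseline
    # uniformly over the feasible band(s); error if no band exists at all
    delta = config.effect_size
    lo_band = (0.02, 0.98 - delta)
    hi_band = (0.02 + delta, 0.98)
    all_dmr = np.concatenate([dmr_idx[c] for c in class_names]) if class_names else np.array([], int)
    if len(all_dmr) and lo_band[1] < lo_band[0] and hi_band[1] < hi_band[0]:
        raise ValueError(f"mean shift {delta} infeasible for any baseline in (0, 1)")
    for i in all_dmr:
        if not (mu[i] + delta <= 0.98 or mu[i] - delta >= 0.02):
            widths = np.array([max(0.0, lo_band[1] - lo_band[0]), max(0.0, hi_band[1] - hi_band[0])])
            band = (lo_band, hi_band)[int(rng.random() < widths[1] / widths.sum())]
            mu[i] = rng.uniform(*band)
    class_means = {c: mu.copy() for c in class_names}
    for c in class_names:
        idx = dmr_idx[c]
        if len(idx):
            class_means[c][idx] = _feasible_shift(mu[idx], config.effect_size)
    # normals differ from tumors at all informative probes; planted
    # "vs_normal" failures share the tumor baseline exactly
    normal_mu = _feasible_shift(mu, config.vs_normal_delta)
    normal_mu[failures["vs_normal"]] = mu[failures["vs_normal"]]

    # --- beta values ------------------------------------------------------
    columns, col_class = [], []
    for c, n_samples in config.classes:
        for j in range(n_samples):
            columns.append(f"{c}_{j + 1:02d}")
            col_class.append(c)
    beta = np.empty((n, len(columns)))
    for j, c in enumerate(col_class):
        beta[:, j] = _sample_beta(rng, class_means[c], config.concentration)
    normal_cols = [f"normal_{j + 1:02d}" for j in range(config.n_normal)]
    normal_beta = np.empty((n, config.n_normal))
    for j in range(config.n_normal):
        normal_beta[:, j] = _sample_beta(rng, normal_mu, config.concentration)

    # --- detection p-values ----------------------------------------------
    detection = rng.uniform(0.0, 0.005, size=beta.shape)
    lo, hi = config.detection_fail_range
    for i in failures["detection"]:
        detection[i, rng.integers(len(columns))] = rng.uniform(lo, hi)

    # --- annotation -------------------------------------------------------
    ann = pd.DataFrame(
        {
            "chrom": [f"chr{(i % 22) + 1}" for i in range(n)],
            "pos": np.arange(1, n + 1) * 100 + 1,
            "gc_density": rng.uniform(0.05, 0.249, size=n),
            "snp_overlap": False,
            "repeat_element": False,
            "unique_mapping": True,
            "mapping_quality_ok": True,
            "cross_reactive_sex": False,
            "epic_retained": True,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    for rank, i in enumerate(failures["quality"]):
        flag = _QUALITY_FLAGS[rank % len(_QUALITY_FLAGS)]
        pid = probe_ids[i]
        if flag == "gc_density":
            ann.loc[pid, "gc_density"] = rng.uniform(0.26, 0.6)
        elif flag in ("unique_mapping", "mapping_quality_ok"):
            ann.loc[pid, flag] = False
        else:
            ann.loc[pid, flag] = True
    for rank, i in enumerate(failures["sex"]):
        pid = probe_ids[i]
        kind = rank % 3
        if kind == 0:
            ann.loc[pid, "chrom"] = "chrX"
        elif kind == 1:
            ann.loc[pid, "chrom"] = "chrY"
        else:
            ann.loc[pid, "cross_reactive_sex"] = True
    ann.loc[probe_ids[failures["epic"]], "epic_retained"] = False

    # --- sample sheet -----------------------------------------------------
    subtype_task = config.label_kind == "subtype"
    rows = []
    for col, c in zip(columns, col_class):
        rows.append(
            {
                "sample_id": col,
                "tumor_class": "BM",
                "origin": "BCBM" if subtype_task else c,
                "bcbm_subtype": c if subtype_task else NA,
                "gender": "F" if subtype_task else ("F", "M")[len(rows) % 2],
                **{k: bool(rng.random() < 0.3) for k in ("pst", "pct", "ptt", "prt")},
            }
        )
    for col in normal_cols:
        rows.append(
            {
                "sample_id": col,
                "tumor_class": "normal",
                "origin": NA,
                "bcbm_subtype": NA,
                "gender": ("F", "M")[len(rows) % 2],
                "pst": False,
                "pct": False,
                "ptt": False,
                "prt": False,
            }
        )
    sheet = SampleSheet(pd.DataFrame(rows).set_index("sample_id"))

    true_means = pd.DataFrame(
        {**{c: class_means[c] for c in class_names}, "normal": normal_mu},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    truth = GroundTruth(
        planted_dmr={c: probe_ids[dmr_idx[c]].tolist() for c in class_names},
        true_class_means=true_means,
        filter_failures={crit: probe_ids[idx].tolist() for crit, idx in failures.items()},
        seed=config.seed,
    )
    matrix = MethylationMatrix(
        pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=columns),
        pd.DataFrame(detection, index=pd.Index(probe_ids, name="probe_id"), columns=columns),
    )
    normal = MethylationMatrix(
        pd.DataFrame(normal_beta, index=pd.Index(probe_ids, name="probe_id"), columns=normal_cols)
    )
    return SimulatedBundle(matrix=matrix, normal=normal, annotation=ProbeAnnotation(ann), sample_sheet=sheet, truth=truth)


# ---------------------------------------------------------------------------
# qMSP simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QmspSimConfig:
    """Generative Ct model parameters.

    ``c0`` is the cycle threshold of an undiluted fully methylated (or
    unmethylated) template; ``epsilon`` is the background amplification
    fraction (the default 2^-12 puts the no-template Ct at the 40-cycle
    ceiling when c0 = 28); ``noise_sd`` is Gaussian per-replicate Ct noise.
    """

    c0: float = 28.0
    epsilon: float = 2.0**-12
    noise_sd: float = 0.2
    replicates: int = 2
    curve_fractions: tuple = (1.0, 0.5, 0.25, 0.125, 0.0625)
    seed: int = 0


def _ct_pair(m: float, cfg: QmspSimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    ct_m = cfg.c0 - np.log2(m + cfg.epsilon) + rng.normal(0.0, cfg.noise_sd, cfg.replicates)
    ct_u = cfg.c0 - np.log2(1.0 - m + cfg.epsilon) + rng.normal(0.0, cfg.noise_sd, cfg.replicates)
    return ct_m, ct_u


def simulate_qmsp(true_fractions, config: QmspSimConfig = QmspSimConfig()) -> tuple[QmspTable, pd.DataFrame]:
    """Emit a long-format qMSP table for true methylated fractions.

    ``true_fractions``: mapping sample id -> {region id -> methylated
    fraction in [0, 1]} (or a samples × regions DataFrame).  Each region
    also gets a two-fold five-point dilution curve of the methylated
    control.  Returns the table and a tidy frame of the true fractions.
    """
    if isinstance(true_fractions, pd.DataFrame):
        true_fractions = {
            s: {r: float(true_fractions.loc[s, r]) for r in true_fractions.columns}
            for s in true_fractions.index
        }
    rng = np.random.default_rng(config.seed)
    regions = sorted({r for per in true_fractions.values() for r in per})
    ct_cols = [f"ct{i + 1}" for i in range(config.replicates)]
    rows = []

    def add_row(sample, region, reaction, known, cts):
        rows.append(
            {
                "sample_id": sample,
                "region_id": region,
                "reaction": reaction,
                "known_fraction": known,
                **dict(zip(ct_cols, np.round(cts, 4))),
            }
        )

    for region in regions:
        for frac in config.curve_fractions:
            ct_m, ct_u = _ct_pair(float(frac), config, rng)
            add_row(f"STD_{region}", region, "M", float(frac), ct_m)
            add_row(f"STD_{region}", region, "U", float(frac), ct_u)
    truth_rows = []
    for sample in sorted(true_fractions):
        for region, m in sorted(true_fractions[sample].items()):
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"true fraction {m} outside [0, 1]")
            ct_m, ct_u = _ct_pair(float(m), config, rng)
            add_row(sample, region, "M", np.nan, ct_m)
            add_row(sample, region, "U", np.nan, ct_u)
            truth_rows.append({"sample_id": sample, "region_id": region, "true_fraction": m})
    table = QmspTable(pd.DataFrame(rows))
    return table, pd.DataFrame(truth_rows)


#: All panel regions of the three-step caller.
PANEL_REGIONS = (
    "BM-C",
    "GBM-A",
    "MBM-B",
    "LCBM-C",
    "BCBM-C",
    "HR+/HER2--1",
    "HR+/HER2--2",
    "HER2+-1",
    "HER2+-2",
    "HR-/HER2--1",
    "HR-/HER2--2",
)


def panel_truth(
    tumor: str, origin: str | None = None, subtype: str | None = None,
    high: float = 0.85, low: float = 0.05,
) -> dict:
    """True panel methylated fractions for a sample of known identity.

    ``tumor`` is ``"GBM"`` or ``"BM"``; for metastases, ``origin`` picks
    which origin region is methylated, and ``subtype`` (BCBM only) which
    subtype region pair is.  Regions specific to the sample's identity sit
    at ``high``, all contrasting regions at ``low``.
    """
    levels = {r: low for r in PANEL_REGIONS}
    if tumor == "GBM":
        levels["GBM-A"] = high
        return levels
    if tumor != "BM":
        raise ValueError(f"tumor must be 'GBM' or 'BM', got {tumor!r}")
    levels["BM-C"] = high
    if origin is not None:
        region = {"MBM": "MBM-B", "LCBM": "LCBM-C", "BCBM": "BCBM-C"}[origin]
        levels[region] = high
    if subtype is not None:
        if origin != "BCBM":
            raise ValueError("subtype regions apply only to BCBM samples")
        levels[f"{subtype}-1"] = high
        levels[f"{subtype}-2"] = high
    return levels
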