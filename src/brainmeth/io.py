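"""Readers and writers for the tables the pipeline touches.

Four external formats are supported, all plain text:

* beta matrix — TSV, probes as rows, first column ``probe_id``, header row of
  sample ids, cells are beta-values in [0, 1] (empty or ``NA`` = missing).
  An optional companion TSV of identical shape holds detection p-values.
* probe annotation — TSV with BED-like leading columns ``chrom``, ``pos``,
  ``probe_id`` followed by per-probe quality flags.
* sample sheet — CSV keyed by ``sample_id`` carrying the class labels of the
  three classification tasks.
* qMSP table — CSV of per-reaction Ct replicates (one row per M or U
  reaction), with standard-curve rows identified by a known methylated
  fraction.

Coordinates are 1-based point positions (the CpG site), as in common 450K
manifests.  All round-trips write→read are the identity, axis order included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "MethylationMatrix",
    "ProbeAnnotation",
    "SampleSheet",
    "QmspTable",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_qmsp_table",
    "write_qmsp_table",
]

NA = "NA"

TUMOR_CLASSES = ("GBM", "BM", "normal")
ORIGINS = ("BCBM", "LCBM", "MBM", "uncertain", NA)
BCBM_SUBTYPES = ("HR+/HER2-", "HER2+", "HR-/HER2-", "unknown", NA)
GENDERS = ("F", "M", NA)
PRIOR_FLAG_COLUMNS = ("pst", "pct", "ptt", "prt")

#: Canonical spellings for category labels seen in the wild.  Unicode minus
#: signs are folded to ASCII before lookup.
LABEL_ALIASES = {
    "HRany/HER2+": "HER2+",
    "HR any/HER2+": "HER2+",
    "HR+/HER2−": "HR+/HER2-",
    "HR−/HER2−": "HR-/HER2-",
}


def _canonical_label(value: str) -> str:
    value = str(value).strip().replace("−", "-")
    return LABEL_ALIASES.get(value, value)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dupes = index[index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dupes[:5]}")


# ---------------------------------------------------------------------------
# MethylationMatrix
# ---------------------------------------------------------------------------


@dataclass
class MethylationMatrix:
    """Probes × samples beta-value matrix, optionally with detection p-values.

    ``beta`` is a :class:`pandas.DataFrame` indexed by probe id with sample
    ids as columns; ``detection_p``, when present, shares both axes exactly.
    All non-missing beta-values must lie in [0, 1].
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.beta.index = self.beta.index.astype(str)
        self.beta.columns = self.beta.columns.astype(str)
        _check_unique(self.beta.index, "probe ids")
        _check_unique(self.beta.columns, "sample ids")
        values = self.beta.to_numpy(dtype=float)
        bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {values[i, j]!r} outside [0, 1] at probe "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )
        if self.detection_p is not None:
            dp = self.detection_p
            dp.index = dp.index.astype(str)
            dp.columns = dp.columns.astype(str)
            if not (dp.index.equals(self.beta.index) and dp.columns.equals(self.beta.columns)):
                raise ValidationError("detection_p axes do not match the beta matrix")
            pv = dp.to_numpy(dtype=float)
            if ((pv < 0.0) | (pv > 1.0)).any():
                raise ValidationError("detection p-values outside [0, 1]")

    # -- convenience -------------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return len(self.beta.index)

    @property
    def n_samples(self) -> int:
        return len(self.beta.columns)

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        probe_ids = pd.Index(probe_ids)
        missing = probe_ids.difference(self.beta.index)
        if len(missing):
            raise KeyError(f"probes not in matrix: {missing.tolist()[:5]}")
        dp = self.detection_p.loc[probe_ids] if self.detection_p is not None else None
        return MethylationMatrix(self.beta.loc[probe_ids], dp)

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        sample_ids = pd.Index(sample_ids)
        missing = sample_ids.difference(self.beta.columns)
        if len(missing):
            raise KeyError(f"samples not in matrix: {missing.tolist()[:5]}")
        dp = self.detection_p[sample_ids] if self.detection_p is not None else None
        return MethylationMatrix(self.beta[sample_ids], dp)


def _read_numeric_tsv(path, value_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected probe_id column plus sample columns")
    df = df.set_index(df.columns[0])
    df.index.name = "probe_id"
    _check_unique(df.index, "probe ids")
    _check_unique(pd.Index(df.columns), "sample ids")
    out = df.replace({"": np.nan, NA: np.nan})
    try:
        out = out.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric {value_name} cell ({exc})") from exc
    return out


def read_beta_matrix(path, detection_path=None) -> MethylationMatrix:
    """Read a beta-value TSV (and optional detection p-value TSV)."""
    beta = _read_numeric_tsv(path, "beta")
    detection = _read_numeric_tsv(detection_path, "detection p") if detection_path else None
    return MethylationMatrix(beta, detection)


def _write_numeric_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index_label="probe_id", lineterminator="\n")


def write_beta_matrix(matrix: MethylationMatrix, path, detection_path=None) -> None:
    _write_numeric_tsv(matrix.beta, path)
    if detection_path is not None:
        if matrix.detection_p is None:
            raise ValueError("matrix has no detection p-values to write")
        _write_numeric_tsv(matrix.detection_p, detection_path)


# ---------------------------------------------------------------------------
# ProbeAnnotation
# ---------------------------------------------------------------------------

_ANNOTATION_BOOL = (
    "snp_overlap",
    "repeat_element",
    "unique_mapping",
    "mapping_quality_ok",
    "cross_reactive_sex",
    "epic_retained",
)
_ANNOTATION_REQUIRED = ("chrom", "pos", "probe_id", "gc_density") + _ANNOTATION_BOOL

SEX_CHROMOSOMES = frozenset({"chrX", "chrY"})


@dataclass
class ProbeAnnotation:
    """Per-probe coordinates and quality flags (one row per probe).

    ``table`` is indexed by probe id with columns ``chrom`` (str), ``pos``
    (1-based int), ``gc_density`` (fraction of the 50-bp probe sequence) and
    the boolean quality flags.  ``sex_chromosome`` is derived from ``chrom``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        t.index = t.index.astype(str)
        _check_unique(t.index, "probe ids")
        missing = [c for c in _ANNOTATION_REQUIRED if c != "probe_id" and c not in t.columns]
        if missing:
            raise FormatError(f"annotation missing mandatory columns: {missing}")
        gc = t["gc_density"].to_numpy(dtype=float)
        if ((gc < 0.0) | (gc > 1.0)).any():
            bad = t.index[(gc < 0.0) | (gc > 1.0)][0]
            raise ValidationError(f"gc_density outside [0, 1] for probe {bad!r}")
        for col in _ANNOTATION_BOOL:
            t[col] = t[col].astype(bool)
        t["pos"] = t["pos"].astype(int)
        t["chrom"] = t["chrom"].astype(str)

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    @property
    def sex_chromosome(self) -> pd.Series:
        return self.table["chrom"].isin(SEX_CHROMOSOMES)

    def subset(self, probe_ids) -> "ProbeAnnotation":
        probe_ids = pd.Index(probe_ids)
        missing = probe_ids.difference(self.table.index)
        if len(missing):
            raise KeyError(f"probes not annotated: {missing.tolist()[:5]}")
        return ProbeAnnotation(self.table.loc[probe_ids].copy())


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOTATION_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing mandatory columns: {missing}")
    df = df.set_index("probe_id")
    for col in _ANNOTATION_BOOL:
        df[col] = df[col].map({"0": False, "1": True, "False": False, "True": True})
        if df[col].isna().any():
            raise FormatError(f"{path}: column {col!r} must be 0/1")
    df["gc_density"] = df["gc_density"].astype(float)
    df["pos"] = df["pos"].astype(int)
    return ProbeAnnotation(df)


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    df = annotation.table.reset_index()
    # BED-like column order: chrom, pos, probe_id, then everything else
    lead = ["chrom", "pos", "probe_id"]
    cols = lead + [c for c in df.columns if c not in lead]
    out = df[cols].copy()
    for col in _ANNOTATION_BOOL:
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

_SHEET_REQUIRED = ("sample_id", "tumor_class", "origin", "bcbm_subtype", "gender") + PRIOR_FLAG_COLUMNS


@dataclass
class SampleSheet:
    """Per-sample class labels for the three classification tasks.

    Category labels are canonical case-sensitive strings (``NA`` denotes not
    applicable); the ``bcbm_subtype`` column may be non-NA only for samples
    whose origin is BCBM.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        t.index = t.index.astype(str)
        _check_unique(t.index, "sample ids")
        missing = [c for c in _SHEET_REQUIRED if c != "sample_id" and c not in t.columns]
        if missing:
            raise FormatError(f"sample sheet missing mandatory columns: {missing}")
        for col, allowed in (
            ("tumor_class", TUMOR_CLASSES),
            ("origin", ORIGINS),
            ("bcbm_subtype", BCBM_SUBTYPES),
            ("gender", GENDERS),
        ):
            t[col] = t[col].map(_canonical_label)
            unknown = t.loc[~t[col].isin(allowed), col]
            if len(unknown):
                raise ValidationError(
                    f"unknown {col} level {unknown.iloc[0]!r} for sample "
                    f"{unknown.index[0]!r} (allowed: {allowed})"
                )
        for col in PRIOR_FLAG_COLUMNS:
            t[col] = t[col].astype(bool)
        bad = (t["bcbm_subtype"] != NA) & (t["origin"] != "BCBM")
        if bad.any():
            raise ValidationError(
                f"bcbm_subtype set for non-BCBM sample {t.index[bad][0]!r}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def labels(self, task: str) -> pd.Series:
        """Class labels for a task: ``tumor_class``, ``origin`` or ``subtype``."""
        col = {"tumor_class": "tumor_class", "origin": "origin", "subtype": "bcbm_subtype"}[task]
        return self.table[col]


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _SHEET_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing mandatory columns: {missing}")
    df = df.set_index("sample_id")
    for col in PRIOR_FLAG_COLUMNS:
        df[col] = df[col].map({"0": False, "1": True, "False": False, "True": True})
        if df[col].isna().any():
            raise FormatError(f"{path}: column {col!r} must be 0/1")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    out = sheet.table.reset_index()
    for col in PRIOR_FLAG_COLUMNS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# qMSP table
# ---------------------------------------------------------------------------

REACTIONS = ("M", "U")


@dataclass
class QmspTable:
    """Long-format qMSP Ct records.

    One row per reaction: ``sample_id``, ``region_id``, ``reaction`` (M for
    the methylated-allele primer set, U for the unmethylated one),
    ``known_fraction`` (methylated fraction in [0, 1] for standard-curve
    rows, NA otherwise) and replicate Ct columns ``ct1``, ``ct2``, ...
    (missing replicates = NA; an undetermined Ct is recorded as NA and
    ceiling-substituted downstream).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "region_id", "reaction"):
            if col not in t.columns:
                raise FormatError(f"qMSP table missing mandatory column {col!r}")
        if not t["reaction"].isin(REACTIONS).all():
            bad = t.loc[~t["reaction"].isin(REACTIONS), "reaction"].iloc[0]
            raise ValidationError(f"unknown reaction {bad!r} (allowed: {REACTIONS})")
        if "known_fraction" not in t.columns:
            t["known_fraction"] = np.nan
        if not self.ct_columns:
            raise FormatError("qMSP table has no ct replicate columns (ct1, ct2, ...)")
        kf = t["known_fraction"].to_numpy(dtype=float)
        ok = np.isnan(kf) | ((kf >= 0.0) & (kf <= 1.0))
        if not ok.all():
            raise ValidationError("known_fraction outside [0, 1]")

    @property
    def ct_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("ct") and c[2:].isdigit()]

    def replicates(self, sample_id: str, region_id: str, reaction: str) -> np.ndarray:
        t = self.table
        row = t[
            (t["sample_id"] == sample_id)
            & (t["region_id"] == region_id)
            & (t["reaction"] == reaction)
            & (t["known_fraction"].isna())
        ]
        if row.empty:
            raise KeyError(f"no {reaction} reaction for sample {sample_id!r}, region {region_id!r}")
        return row[self.ct_columns].to_numpy(dtype=float)[0]

    def curve_rows(self, region_id: str) -> pd.DataFrame:
        t = self.table
        return t[(t["region_id"] == region_id) & (t["known_fraction"].notna())]

    @property
    def region_ids(self) -> list[str]:
        return sorted(self.table["region_id"].unique())


def read_qmsp_table(path) -> QmspTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("sample_id", "region_id", "reaction"):
        if col not in df.columns:
            raise FormatError(f"{path}: qMSP table missing mandatory column {col!r}")
    df = df.replace({"": np.nan, NA: np.nan})
    df["known_fraction"] = df.get("known_fraction", np.nan)
    df["known_fraction"] = df["known_fraction"].astype(float)
    for col in df.columns:
        if col.startswith("ct") and col[2:].isdigit():
            df[col] = df[col].astype(float)
    df["sample_id"] = df["sample_id"].astype(str)
    df["region_id"] = df["region_id"].astype(str)
    return QmspTable(df.reset_index(drop=True))


def write_qmsp_table(table: QmspTable, path) -> None:
    table.table.to_csv(path, index=False, na_rep=NA, lineterminator="\n")
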