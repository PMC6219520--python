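"""Iterative random-forest backward elimination with a permutation null.

The selection protocol: per repeat, samples are split into stratified CV
folds.  Within each fold, the starting feature set (default 10,000 probes)
is chosen on the training samples only, by ranking probes on the range of
their class medians.  A random forest (default 5,000 trees) is trained on
the current feature set, evaluated on the held-out fold, and the feature
set is cut to the top half by Gini importance (mean decrease in impurity);
this is iterated over a ceil-halving schedule of 15 steps ending at a
single probe.  The whole procedure is replicated (default 100 repeats), and
the same machinery run with once-per-repeat permuted class labels provides
the null performance distribution of a random classifier.

Feature sets are strictly nested across steps within a fold, held-out
samples never influence training or feature ranking, and a fixed seed makes
the whole :class:`SelectionResult` bit-identical across runs.  Importance
ties at a halving cut are broken by probe id.  Forest hyperparameters other
than tree count are the library defaults (sqrt(p) features per split, no
depth limit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import MethylationMatrix

__all__ = [
    "SelectionConfig",
    "ModelRecord",
    "SelectionResult",
    "halving_schedule",
    "backward_elimination_cv",
    "permutation_null",
    "aggregate_importance",
    "performance_summary",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the backward-elimination protocol.

    Defaults are the full-scale protocol (10,000 starting regions, 15
    halving steps, 5,000 trees, 3-fold stratified CV, 100 repeats).  For
    unit-scale runs use :meth:`reduced`.
    """

    n_start: int = 10_000
    n_steps: int = 15
    n_trees: int = 5_000
    n_folds: int = 3
    n_repeats: int = 100
    seed: int = 0
    permute: bool = False

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    @classmethod
    def reduced(cls, seed: int = 0, n_trees: int = 500, n_repeats: int = 10, **kw):
        """The documented reduced-scale profile (500 trees, 10 repeats)."""
        return cls(seed=seed, n_trees=n_trees, n_repeats=n_repeats, **kw)


def halving_schedule(n_start: int = 10_000, n_steps: int = 15) -> list[int]:
    """Feature-set sizes: s1 = n_start, s_{i+1} = ceil(s_i / 2), clamped at 1.

    With the defaults the list is [10000, 5000, ..., 2, 1] (length 15).
    When the sequence hits 1 before ``n_steps`` entries, trailing
    duplicates are dropped with a warning.
    """
    if n_start < 1:
        raise ValueError("n_start must be >= 1")
    sizes = [int(n_start)]
    for _ in range(n_steps - 1):
        sizes.append(max(1, -(-sizes[-1] // 2)))
    deduped = []
    for s in sizes:
        if not deduped or s != deduped[-1]:
            deduped.append(s)
    if len(deduped) < n_steps:
        warnings.warn(
            f"halving from {n_start} reaches 1 feature in {len(deduped)} steps "
            f"(< n_steps={n_steps}); schedule truncated",
            stacklevel=2,
        )
    return deduped


@dataclass(frozen=True)
class ModelRecord:
    """One trained forest: (repeat, fold, step) with its evaluation."""

    repeat: int
    fold: int
    step: int
    n_features: int
    features: tuple
    accuracy: float
    y_true: np.ndarray
    y_pred: np.ndarray
    importances: pd.Series  # Gini mean decrease in impurity, indexed by probe


@dataclass
class SelectionResult:
    """All models of a backward-elimination run, with helpers.

    ``records`` holds one :class:`ModelRecord` per (repeat, fold, step);
    ``fold_assignment[(repeat, fold)]`` lists the held-out sample ids.
    """

    config: SelectionConfig
    schedule: list[int]
    classes: list[str]
    records: list[ModelRecord]
    fold_assignment: dict = field(default_factory=dict)

    def accuracy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.repeat, r.fold, r.step, r.n_features, r.accuracy)
                for r in self.records
            ],
            columns=["repeat", "fold", "step", "n_features", "accuracy"],
        )

    def median_accuracy(self, n_features: int) -> float:
        """Median held-out accuracy across all models at a schedule size."""
        acc = [r.accuracy for r in self.records if r.n_features == n_features]
        if not acc:
            raise ValueError(f"no models with {n_features} features (schedule: {self.schedule})")
        return float(np.median(acc))

    def aggregate_importance(self, min_features: int = 40) -> pd.Series:
        return aggregate_importance(self, min_features)

    def performance_summary(self, min_features: int | None = None, per_step: bool = False):
        return performance_summary(self, min_features=min_features, per_step=per_step)

    def summary(self) -> str:
        frame = self.accuracy_frame().groupby("n_features")["accuracy"]
        med = frame.median().sort_index(ascending=False)
        lines = [
            "Backward-elimination cross-validation summary",
            f"  classes: {self.classes}   repeats: {self.config.n_repeats}   "
            f"folds: {self.config.n_folds}   trees: {self.config.n_trees}"
            + ("   (permuted labels)" if self.config.permute else ""),
            "  n_features  median_accuracy",
        ]
        for n, a in med.items():
            lines.append(f"  {n:>10d}  {a:.3f}")
        return "\n".join(lines)


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per sample; within each class, a shuffled round-robin."""
    fold = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def _rank_by_median_range(X: np.ndarray, y: np.ndarray, probe_ids: np.ndarray) -> np.ndarray:
    """Probe order by decreasing range of class medians, ties by probe id."""
    meds = np.stack([np.median(X[y == c], axis=0) for c in np.unique(y)])
    rng_stat = meds.max(axis=0) - meds.min(axis=0)
    return np.lexsort((probe_ids, -rng_stat))


def _top_by_importance(imp: np.ndarray, probe_ids: np.ndarray, k: int) -> np.ndarray:
    """Indices (into the current set) of the top-k importances, ties by probe id."""
    order = np.lexsort((probe_ids, -imp))
    return np.sort(order[:k])


def backward_elimination_cv(
    matrix: MethylationMatrix, labels, config: SelectionConfig = SelectionConfig()
) -> SelectionResult:
    """Run the full repeated, stratified, backward-eliminating CV protocol."""
    labels = pd.Series(labels).reindex(matrix.sample_ids)
    if labels.isna().any():
        raise ValueError("every sample needs a class label")
    y_all = labels.astype(str).to_numpy()
    classes, counts = np.unique(y_all, return_counts=True)
    small = classes[counts < config.n_folds]
    if len(small):
        raise ValueError(
            f"classes smaller than n_folds={config.n_folds}: {small.tolist()}"
        )
    beta = matrix.beta
    nan_probes = beta.index[beta.isna().any(axis=1)]
    if len(nan_probes):
        raise ValueError(
            f"non-finite beta-values for probes {nan_probes.tolist()[:5]}; "
            "run the filter pipeline first"
        )
    X = np.ascontiguousarray(beta.to_numpy(dtype=float).T)  # samples x probes
    probe_ids = beta.index.to_numpy()
    sample_ids = beta.columns.to_numpy()
    n_start = min(config.n_start, len(probe_ids))
    if n_start < config.n_start:
        warnings.warn(
            f"matrix has {len(probe_ids)} probes < n_start={config.n_start}; "
            f"starting from {n_start}",
            stacklevel=2,
        )
    schedule = halving_schedule(n_start, config.n_steps)

    rng = np.random.default_rng(config.seed)
    records: list[ModelRecord] = []
    fold_assignment: dict = {}
    for repeat in range(config.n_repeats):
        y = rng.permutation(y_all) if config.permute else y_all
        folds = _stratified_folds(y, config.n_folds, rng)
        for fold in range(config.n_folds):
            test = folds == fold
            train = ~test
            fold_assignment[(repeat, fold)] = sample_ids[test].tolist()
            order = _rank_by_median_range(X[train], y[train], probe_ids)
            current = np.sort(order[:n_start])  # column indices into X
            imp_prev: np.ndarray | None = None
            for step, size in enumerate(schedule):
                if size < len(current):
                    keep = _top_by_importance(imp_prev, probe_ids[current], size)
                    current = current[keep]
                rf_seed = int(rng.integers(2**31 - 1))
                forest = RandomForestClassifier(
                    n_estimators=config.n_trees, random_state=rf_seed, n_jobs=1
                )
                forest.fit(X[np.ix_(train, current)], y[train])
                y_pred = forest.predict(X[np.ix_(test, current)])
                imp_prev = forest.feature_importances_
                records.append(
                    ModelRecord(
                        repeat=repeat,
                        fold=fold,
                        step=step,
                        n_features=len(current),
                        features=tuple(probe_ids[current]),
                        accuracy=float(np.mean(y_pred == y[test])),
                        y_true=y[test].copy(),
                        y_pred=y_pred,
                        importances=pd.Series(imp_prev, index=probe_ids[current]),
                    )
                )
    return SelectionResult(
        config=config,
        schedule=schedule,
        classes=classes.tolist(),
        records=records,
        fold_assignment=fold_assignment,
    )


def permutation_null(
    matrix: MethylationMatrix, labels, config: SelectionConfig = SelectionConfig()
) -> SelectionResult:
    """The identical selection machinery with labels permuted once per repeat.

    Fold splits are drawn independently of any real-label run (seeded by
    ``config.seed``); the result's accuracies form the null distribution,
    step by step.
    """
    return backward_elimination_cv(matrix, labels, replace(config, permute=True))


def aggregate_importance(result: SelectionResult, min_features: int = 40) -> pd.Series:
    """Mean Gini importance per probe over models with >= ``min_features``.

    A probe contributes to its mean only for models that actually contained
    it (absence is not counted as zero).  Sorted by decreasing importance,
    ties broken by probe id.
    """
    qualifying = [r for r in result.records if r.n_features >= min_features]
    if not qualifying:
        raise ValueError(
            f"no qualifying models with >= {min_features} features "
            f"(schedule: {result.schedule})"
        )
    sums: dict = {}
    counts: dict = {}
    for r in qualifying:
        for probe, v in r.importances.items():
            sums[probe] = sums.get(probe, 0.0) + v
            counts[probe] = counts.get(probe, 0) + 1
    table = pd.Series({p: sums[p] / counts[p] for p in sums}, name="gini_importance")
    order = np.lexsort((table.index.to_numpy(), -table.to_numpy()))
    return table.iloc[order]


def _per_class_rates(y_true: np.ndarray, y_pred: np.ndarray, classes) -> pd.DataFrame:
    rows = []
    for c in classes:
        pos = y_true == c
        hit = y_pred == c
        tp = int(np.sum(pos & hit))
        fn = int(np.sum(pos & ~hit))
        tn = int(np.sum(~pos & ~hit))
        fp = int(np.sum(~pos & hit))
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        rows.append((c, sens, spec))
    return pd.DataFrame(rows, columns=["class", "sensitivity", "specificity"])


def performance_summary(
    result: SelectionResult, min_features: int | None = None, per_step: bool = False
) -> pd.DataFrame:
    """One-vs-rest sensitivity/specificity means with interquartile ranges.

    Rates are computed per model on its held-out fold (sensitivity =
    TP/(TP+FN), specificity = TN/(TN+FP)) and then averaged across models,
    optionally restricted to models with >= ``min_features`` features and/or
    broken out per schedule step.
    """
    records = result.records
    if min_features is not None:
        records = [r for r in records if r.n_features >= min_features]
    if not records:
        raise ValueError(f"no qualifying models with >= {min_features} features")
    frames = []
    for r in records:
        df = _per_class_rates(r.y_true, r.y_pred, result.classes)
        df["step"] = r.step
        df["n_features"] = r.n_features
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    keys = ["step", "n_features", "class"] if per_step else ["class"]
    agg = long.groupby(keys).agg(
        mean_sensitivity=("sensitivity", "mean"),
        iqr_sensitivity=("sensitivity", lambda s: s.quantile(0.75) - s.quantile(0.25)),
        mean_specificity=("specificity", "mean"),
        iqr_specificity=("specificity", lambda s: s.quantile(0.75) - s.quantile(0.25)),
        n_models=("sensitivity", "size"),
    )
    return agg.reset_index()
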