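"""Nearest-shrunken-centroids (PAM-style) region selection and prediction.

Per probe i and class k, the standardized centroid offset is

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),

with s_i the pooled within-class SD, s0 the median of the s_i (a
stabilizer against near-zero SDs), and m_k = sqrt(1/n_k - 1/N).  Soft
thresholding by delta, d'_ik = sign(d_ik) * max(|d_ik| - delta, 0),
shrinks every class centroid toward the overall centroid; probes with any
nonzero shrunken offset are the selected regions.  Prediction assigns the
class minimizing the discriminant

    sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2  -  2 * log(prior_k).

The selected set shrinks monotonically as delta grows; at delta = 0 the
model is plain nearest-centroid classification, and once every probe is
shrunk away predictions collapse to the prior-dominant class.

The original training software also recorded a "minimum correlation" and
"number of bins" setting; those are GUI-side parameters without an
algorithmic role here and are carried in :class:`NscModel.extra_params`
for provenance only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MethylationMatrix

__all__ = ["NscModel", "train_nsc", "predict_nsc", "select_subtype_regions", "NearestShrunkenCentroids"]

SUBTYPE_DELTA = 2.1


@dataclass
class NscModel:
    """A fitted nearest-shrunken-centroids model."""

    classes: list[str]
    probe_ids: pd.Index
    overall_centroid: np.ndarray  # (p,)
    class_centroids: np.ndarray  # (p, k) raw
    shrunken_centroids: np.ndarray  # (p, k)
    d: np.ndarray  # (p, k) standardized offsets
    d_shrunk: np.ndarray  # (p, k) after soft thresholding
    s: np.ndarray  # (p,) pooled within-class SD
    s0: float
    m: np.ndarray  # (k,)
    delta: float
    priors: np.ndarray  # (k,)
    extra_params: dict = field(default_factory=dict)

    @property
    def selected_probes(self) -> pd.Index:
        return self.probe_ids[(self.d_shrunk != 0).any(axis=1)]

    def selection_table(self) -> pd.DataFrame:
        """Selected probes with the classes whose centroid drives each."""
        sel = (self.d_shrunk != 0).any(axis=1)
        rows = []
        for i in np.flatnonzero(sel):
            driving = [self.classes[k] for k in np.flatnonzero(self.d_shrunk[i] != 0)]
            rows.append(
                (
                    self.probe_ids[i],
                    ",".join(driving),
                    float(np.abs(self.d_shrunk[i]).max()),
                )
            )
        df = pd.DataFrame(rows, columns=["probe_id", "driving_classes", "max_abs_d_shrunk"])
        return df.sort_values(
            ["max_abs_d_shrunk", "probe_id"], ascending=[False, True]
        ).reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        """Shrunken centroids as a probes × classes table (for serialization)."""
        return pd.DataFrame(self.shrunken_centroids, index=self.probe_ids, columns=self.classes)


def train_nsc(matrix: MethylationMatrix, labels, delta: float, priors=None) -> NscModel:
    """Fit shrunken centroids on a beta matrix at shrinkage ``delta``.

    Class priors default to the observed class frequencies.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    labels = pd.Series(labels).reindex(matrix.sample_ids)
    if labels.isna().any():
        raise ValueError("every sample needs a class label")
    y = labels.astype(str).to_numpy()
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    X = matrix.beta.to_numpy(dtype=float)  # probes x samples
    if np.isnan(X).any():
        raise ValueError("NSC requires a complete beta matrix (no missing values)")
    n_total = X.shape[1]
    n_k = np.array([(y == c).sum() for c in classes])
    if (n_k < 2).any():
        raise ValueError("need at least two samples per class")
    cents = np.stack([X[:, y == c].mean(axis=1) for c in classes], axis=1)  # p x k
    overall = X.mean(axis=1)
    ssw = np.zeros(X.shape[0])
    for j, c in enumerate(classes):
        ssw += ((X[:, y == c] - cents[:, [j]]) ** 2).sum(axis=1)
    s = np.sqrt(ssw / (n_total - len(classes)))
    s0 = float(np.median(s))
    if s0 == 0.0 and (s == 0.0).any():
        raise ValueError("zero pooled within-class SD with zero stabilizer")
    m = np.sqrt(1.0 / n_k - 1.0 / n_total)
    denom = m[None, :] * (s + s0)[:, None]
    d = (cents - overall[:, None]) / denom
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall[:, None] + denom * d_shrunk
    if priors is None:
        priors = n_k / n_total
    priors = np.asarray(priors, dtype=float)
    if len(priors) != len(classes) or not np.isclose(priors.sum(), 1.0):
        raise ValueError("priors must be one probability per class summing to 1")
    return NscModel(
        classes=classes,
        probe_ids=matrix.probe_ids,
        overall_centroid=overall,
        class_centroids=cents,
        shrunken_centroids=shrunken,
        d=d,
        d_shrunk=d_shrunk,
        s=s,
        s0=s0,
        m=m,
        delta=float(delta),
        priors=priors,
    )


def predict_nsc(model: NscModel, matrix: MethylationMatrix):
    """Classify samples by the shrunken-centroid discriminant.

    Returns ``(labels, scores)`` where ``scores`` is a samples × classes
    DataFrame of discriminant values (lower = closer); ties go to the
    first class in sorted order.
    """
    beta = matrix.beta.reindex(model.probe_ids)
    if beta.isna().any().any():
        raise ValueError("matrix is missing probes (or values) required by the model")
    X = beta.to_numpy(dtype=float)  # p x n
    w = 1.0 / (model.s + model.s0) ** 2
    scores = np.empty((X.shape[1], len(model.classes)))
    for k in range(len(model.classes)):
        diff = X - model.shrunken_centroids[:, [k]]
        scores[:, k] = (diff**2 * w[:, None]).sum(axis=0) - 2.0 * np.log(model.priors[k])
    pred = [model.classes[j] for j in scores.argmin(axis=1)]
    return (
        pd.Series(pred, index=matrix.sample_ids, name="nsc_class"),
        pd.DataFrame(scores, index=matrix.sample_ids, columns=model.classes),
    )


def select_subtype_regions(
    matrix: MethylationMatrix, labels, delta: float = SUBTYPE_DELTA
) -> pd.DataFrame:
    """Regions with any nonzero shrunken centroid offset at ``delta``,
    annotated with the class(es) that drive them."""
    model = train_nsc(matrix, labels, delta)
    return model.selection_table()


class NearestShrunkenCentroids:
    """Thin estimator-style wrapper around :func:`train_nsc` / :func:`predict_nsc`."""

    def __init__(self, delta: float = SUBTYPE_DELTA, priors=None):
        self.delta = delta
        self.priors = priors
        self.model_: NscModel | None = None

    def fit(self, matrix: MethylationMatrix, labels) -> "NearestShrunkenCentroids":
        self.model_ = train_nsc(matrix, labels, self.delta, priors=self.priors)
        return self

    def predict(self, matrix: MethylationMatrix) -> pd.Series:
        if self.model_ is None:
            raise RuntimeError("call fit() first")
        return predict_nsc(self.model_, matrix)[0]

    @property
    def selected_probes(self) -> pd.Index:
        if self.model_ is None:
            raise RuntimeError("call fit() first")
        return self.model_.selected_probes
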