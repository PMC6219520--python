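"""Shared fixtures: small synthetic methylomes and constructed fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from brainmeth import MethylationMatrix
from brainmeth.simulate import SimulationConfig, simulate_methylomes


@pytest.fixture(scope="session")
def small_origin_bundle():
    """A light three-origin methylome: 1,500 probes, 12 samples/class,
    30 planted DMRs/class at a 0.5 mean-beta shift."""
    cfg = SimulationConfig(
        n_probes=1500,
        classes=(("BCBM", 12), ("LCBM", 12), ("MBM", 12)),
        n_dmr_per_class=30,
        effect_size=0.5,
        seed=42,
    )
    return simulate_methylomes(cfg)


def two_class_matrix(
    n_null: int = 200,
    n_planted: int = 5,
    delta: float = 0.5,
    n_per_class: int = 20,
    seed: int = 7,
    concentration: float = 50.0,
):
    """Generic two-class beta matrix with planted class-shifted probes.

    Returns (matrix, labels Series with classes 'A'/'B', planted probe ids).
    """
    rng = np.random.default_rng(seed)
    n = n_null + n_planted
    probes = [f"cg{i:06d}" for i in range(n)]
    samples = [f"s{j:02d}" for j in range(2 * n_per_class)]
    labels = pd.Series(["A"] * n_per_class + ["B"] * n_per_class, index=samples)
    mu = np.clip(rng.beta(2, 2, size=n), 0.02, 0.98)
    lo, hi = 0.45 - delta / 2, 0.45 + delta / 2
    beta = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        m = mu.copy()
        m[:n_planted] = hi if labels[s] == "A" else lo
        beta[:, j] = rng.beta(m * concentration, (1 - m) * concentration)
    matrix = MethylationMatrix(pd.DataFrame(beta, index=probes, columns=samples))
    return matrix, labels, probes[:n_planted]


def disjoint_filter_bundle(seed: int = 5):
    """1,000-probe fixture with disjoint planted filter failures
    100/50/20/10/30 (quality/sex/detection/EPIC/vs-normal).

    The 30 vs-normal probes are made deterministically uninformative by
    giving tumors and normals perfectly interleaved values, so the
    rank-sum p is ~1 and the per-stage exclusion counts are exact.
    """
    cfg = SimulationConfig(
        n_probes=1000,
        classes=(("BCBM", 12), ("LCBM", 12), ("MBM", 12)),
        n_dmr_per_class=0,
        filter_failure_fraction={
            "quality": 0.10,
            "sex": 0.05,
            "detection": 0.02,
            "epic": 0.01,
            "vs_normal": 0.03,
        },
        seed=seed,
    )
    bundle = simulate_methylomes(cfg)
    n_t = bundle.matrix.n_samples
    n_n = bundle.normal.n_samples
    combined = np.linspace(0.3, 0.7, n_t + n_n)
    normal_pos = np.round(np.linspace(0, n_t + n_n - 1, n_n)).astype(int)
    tumor_pos = np.setdiff1d(np.arange(n_t + n_n), normal_pos)
    for pid in bundle.truth.filter_failures["vs_normal"]:
        bundle.matrix.beta.loc[pid] = combined[tumor_pos]
        bundle.normal.beta.loc[pid] = combined[normal_pos]
    return bundle
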