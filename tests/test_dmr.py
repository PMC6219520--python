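"""Differential-methylation tests against hand computations and oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainmeth import MethylationMatrix, anova_dmr, dichotomize, kruskal_dmr, rank_most_variable, select_marker_candidates, wilcoxon_dmr
from brainmeth.dmr import anova_f, class_median_range

from conftest import two_class_matrix


def matrix_from_groups(groups: dict) -> tuple[MethylationMatrix, pd.Series]:
    """One-probe matrix from {class: list of beta values}."""
    values, labels, cols = [], [], []
    for c, vals in groups.items():
        for i, v in enumerate(vals):
            cols.append(f"{c}{i}")
            labels.append(c)
            values.append(v)
    beta = pd.DataFrame([values], index=["cg1"], columns=cols)
    return MethylationMatrix(beta), pd.Series(labels, index=cols)


# --- ANOVA ----------------------------------------------------------------


def test_anova_hand_computation():
    """{0.1,0.2,0.3} vs {0.7,0.8,0.9}: SSB=0.54, SSW=0.04 -> F=54, df (1,4)."""
    f, p = anova_f([np.array([0.1, 0.2, 0.3]), np.array([0.7, 0.8, 0.9])])
    assert f == pytest.approx(54.0)
    assert p == pytest.approx(stats.f.sf(54.0, 1, 4))


def test_anova_matches_library_and_squared_t():
    rng = np.random.default_rng(4)
    for _ in range(5):
        a, b = rng.normal(0.5, 0.1, 8), rng.normal(0.55, 0.1, 9)
        f, p = anova_f([a, b])
        ref = stats.f_oneway(a, b)
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t.statistic**2)


def test_anova_zero_within_variance_gives_inf_sentinel():
    mat, labels = matrix_from_groups({"A": [0.2, 0.2], "B": [0.8, 0.8]})
    rec = anova_dmr(mat, labels, return_all=True)
    assert np.isinf(rec.loc["cg1", "statistic"])
    assert rec.loc["cg1", "p_raw"] == 0.0


def test_bonferroni_arithmetic_and_ordering():
    rng = np.random.default_rng(1)
    n, probes = 6, 50
    beta = pd.DataFrame(
        rng.beta(2, 2, (probes, 2 * n)),
        index=[f"cg{i:03d}" for i in range(probes)],
        columns=[f"s{i}" for i in range(2 * n)],
    )
    labels = pd.Series(["A"] * n + ["B"] * n, index=beta.columns)
    mat = MethylationMatrix(beta)
    bonf = anova_dmr(mat, labels, adjust="bonferroni", return_all=True)
    bh = anova_dmr(mat, labels, adjust="bh_fdr", return_all=True)
    # p_adj = min(1, p * m) with m = 50, e.g. p=0.001 -> 0.05
    assert np.allclose(bonf["p_adj"], np.minimum(1.0, bonf["p_raw"] * probes))
    assert (bonf["p_adj"] >= bh["p_adj"] - 1e-12).all()
    assert (bh["p_adj"] >= bh["p_raw"] - 1e-12).all()
    # BH q monotone non-decreasing in sorted raw p
    srt = bh.sort_values("p_raw")
    assert (np.diff(srt["p_adj"]) >= -1e-12).all()


def test_anova_null_type_one_error_calibrated():
    """k groups from one distribution: raw-alpha rejections ~ alpha (3 binomial SDs)."""
    rng = np.random.default_rng(12)
    probes, n = 1000, 10
    beta = pd.DataFrame(
        rng.beta(2, 2, (probes, 3 * n)),
        index=[f"cg{i:04d}" for i in range(probes)],
        columns=[f"s{i}" for i in range(3 * n)],
    )
    labels = pd.Series(["A"] * n + ["B"] * n + ["C"] * n, index=beta.columns)
    rec = anova_dmr(MethylationMatrix(beta), labels, return_all=True)
    alpha = 0.05
    frac = (rec["p_raw"] < alpha).mean()
    tol = 3 * np.sqrt(alpha * (1 - alpha) / probes)
    assert abs(frac - alpha) < tol


# --- Wilcoxon -------------------------------------------------------------


def test_wilcoxon_identical_groups_empty():
    rng = np.random.default_rng(2)
    beta = pd.DataFrame(
        np.tile(rng.beta(2, 2, 10), (4, 1)).T,
        index=[f"cg{i}" for i in range(10)],
        columns=["a1", "a2", "b1", "b2"],
    )
    labels = pd.Series(["A", "A", "B", "B"], index=beta.columns)
    assert wilcoxon_dmr(MethylationMatrix(beta), labels).empty


def test_wilcoxon_planted_probe_found_and_gated():
    matrix, labels, planted = two_class_matrix(n_null=1000, n_planted=1, delta=0.7, seed=21)
    hits = wilcoxon_dmr(matrix, labels)
    assert planted[0] in hits.index
    assert hits.loc[planted[0], "delta"] > 0.30
    assert hits.loc[planted[0], "direction"] == "hyper_in_A"


def test_wilcoxon_effect_size_gate_blocks_small_delta():
    """A probe with a tiny p but a 0.2 mean shift stays out of the DMR list."""
    matrix, labels, planted = two_class_matrix(
        n_null=50, n_planted=1, delta=0.2, n_per_class=40, seed=22, concentration=400
    )
    all_rec = wilcoxon_dmr(matrix, labels, return_all=True)
    assert all_rec.loc[planted[0], "p_adj"] < 0.01  # highly significant...
    assert all_rec.loc[planted[0], "delta"] < 0.30  # ...but below the gate
    assert planted[0] not in wilcoxon_dmr(matrix, labels).index


def test_wilcoxon_requires_two_per_group():
    mat, labels = matrix_from_groups({"A": [0.1], "B": [0.8, 0.9]})
    with pytest.raises(ValueError, match="fewer than 2"):
        wilcoxon_dmr(mat, labels)


# --- Kruskal-Wallis -------------------------------------------------------


def test_kruskal_identical_and_separated_groups():
    rng = np.random.default_rng(5)
    same = rng.beta(2, 2, 5)
    mat, labels = matrix_from_groups({"A": same, "B": same, "C": same})
    rec = kruskal_dmr(mat, labels, return_all=True)
    assert rec.loc["cg1", "statistic"] == pytest.approx(0.0, abs=1e-10)

    mat2, labels2 = matrix_from_groups(
        {"A": [0.1, 0.12, 0.11, 0.13, 0.09], "B": [0.5, 0.52, 0.51, 0.49, 0.53], "C": [0.9, 0.88, 0.91, 0.89, 0.92]}
    )
    rec2 = kruskal_dmr(mat2, labels2, return_all=True)
    # fully separated ranks: H = 12/(N(N+1)) * sum n_k (rbar_k - rbar)^2 = 12.5
    n = 15
    rbar = (n + 1) / 2
    h_exact = 12 / (n * (n + 1)) * 5 * ((3 - rbar) ** 2 + (8 - rbar) ** 2 + (13 - rbar) ** 2)
    assert rec2.loc["cg1", "statistic"] == pytest.approx(h_exact)
    assert rec2.loc["cg1", "p_raw"] < 0.01


def test_kruskal_two_groups_equals_normalized_rank_sum():
    """For k=2 without ties, H equals the squared standardized rank-sum statistic."""
    rng = np.random.default_rng(6)
    x, y = rng.beta(2, 2, 4), rng.beta(2, 2, 4)
    mat, labels = matrix_from_groups({"A": x, "B": y})
    h = kruskal_dmr(mat, labels, return_all=True).loc["cg1", "statistic"]
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:4].sum()
    n1 = n2 = 4
    n = n1 + n2
    z = (r1 - n1 * (n + 1) / 2) / np.sqrt(n1 * n2 * (n + 1) / 12)
    assert h == pytest.approx(z**2)


# --- dichotomization, variability, candidates -----------------------------


@pytest.mark.parametrize(
    "beta, call",
    [(0.95, "methylated"), (0.9, "methylated"), (0.10, "unmethylated"), (0.5, "indeterminate")],
)
def test_dichotomize(beta, call):
    assert dichotomize(beta) == call


def test_rank_most_variable_modes_and_degenerate():
    beta = pd.DataFrame(
        {
            "s1": [0.5, 0.1, 0.4],
            "s2": [0.5, 0.5, 0.45],
            "s3": [0.5, 0.9, 0.5],
        },
        index=["cg_const", "cg_wild", "cg_mild"],
    )
    mat = MethylationMatrix(beta)
    top = rank_most_variable(mat, 2, mode="variance")
    assert list(top) == ["cg_wild", "cg_mild"]  # constant probe never beats a varying one
    labels = pd.Series(["A", "B", "C"], index=beta.columns)
    med = class_median_range(mat, labels)
    assert med["cg_wild"] == pytest.approx(0.8)
    assert list(rank_most_variable(mat, 1, mode="class_median_range", labels=labels)) == ["cg_wild"]
    with pytest.warns(UserWarning, match="returning all"):
        everything = rank_most_variable(mat, 10, mode="variance")
    assert len(everything) == 3


def test_marker_candidates_prefer_low_variance_and_mirror():
    rng = np.random.default_rng(8)
    n = 20
    cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    labels = pd.Series(["A"] * n + ["B"] * n, index=cols)
    tight_a = np.concatenate([rng.normal(0.9, 0.02, n), rng.normal(0.1, 0.02, n)])
    noisy_a = np.concatenate([rng.normal(0.9, 0.25, n), rng.normal(0.1, 0.25, n)])
    tight_b = np.concatenate([rng.normal(0.1, 0.02, n), rng.normal(0.9, 0.02, n)])
    beta = pd.DataFrame(
        np.clip([tight_a, noisy_a, tight_b], 0, 1),
        index=["cg_tight_a", "cg_noisy_a", "cg_tight_b"],
        columns=cols,
    )
    out = select_marker_candidates(MethylationMatrix(beta), labels, n_per_class=2)
    a = out[out["target_class"] == "A"].set_index("probe_id")
    assert a.index[0] == "cg_tight_a"  # low-variance probe outranks the noisy one
    assert a.loc["cg_tight_a", "score"] > a.loc["cg_noisy_a", "score"]
    b = out[out["target_class"] == "B"].set_index("probe_id")
    assert b.index[0] == "cg_tight_b"
    # symmetric fixture: mirrored candidate scores agree
    assert a.loc["cg_tight_a", "score"] == pytest.approx(b.loc["cg_tight_b", "score"], abs=0.05)


def test_marker_candidates_empty_and_missing_class():
    matrix, labels, _ = two_class_matrix(n_null=20, seed=3)
    assert select_marker_candidates(matrix, labels, n_per_class=0).empty
    with pytest.raises(ValueError, match="absent"):
        select_marker_candidates(matrix, labels, 2, classes=["Z"])


def test_tests_invariant_to_sample_order():
    matrix, labels, _ = two_class_matrix(n_null=30, seed=13)
    perm = np.random.default_rng(0).permutation(matrix.n_samples)
    shuffled = MethylationMatrix(matrix.beta.iloc[:, perm])
    a = wilcoxon_dmr(matrix, labels, return_all=True)
    b = wilcoxon_dmr(shuffled, labels[shuffled.sample_ids], return_all=True)
    pd.testing.assert_frame_equal(a, b)
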