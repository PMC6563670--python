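"""Neutrality regression, ENC null curve, CA and Spearman matrix."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cubkit.bias_analysis import (
    CORRELATION_VARIABLES,
    correspondence_analysis,
    enc_plot_frame,
    expected_enc_curve,
    format_correlation_table,
    neutrality_regression,
    rscu_matrix,
    spearman_matrix,
)
from cubkit.genetic_code import SYNONYMOUS_CODONS
from cubkit.genome_io import CodonCounts, count_codons
from cubkit.indices import gene_indices_frame
from cubkit.synthetic_data import SyntheticGenomeSpec, simulate_genome


# --- neutrality regression ---------------------------------------------------

def test_neutrality_perfect_and_flat_cases():
    g = np.linspace(0.2, 0.8, 20)
    fit = neutrality_regression(g, g)
    assert fit.slope == pytest.approx(1.0)
    assert fit.pearson_r == pytest.approx(1.0)
    assert fit.mutation_pct == pytest.approx(100.0)

    flat = neutrality_regression(np.full(20, 0.5), g)
    assert flat.slope == pytest.approx(0.0, abs=1e-12)
    assert flat.other_pct == pytest.approx(100.0)


def test_neutrality_recovers_generative_slope():
    rng = np.random.default_rng(17)
    gc3 = rng.uniform(0.3, 0.9, 50)
    gc12 = 0.3 * gc3 + rng.normal(0, 0.01, 50)
    fit = neutrality_regression(gc12, gc3)
    assert 0.25 <= fit.slope <= 0.35
    assert fit.r_squared == pytest.approx(fit.pearson_r ** 2, abs=1e-12)
    assert fit.mutation_pct + fit.other_pct == pytest.approx(100.0)


def test_neutrality_scale_consistency_and_degenerate_input():
    rng = np.random.default_rng(3)
    gc3 = rng.uniform(0.3, 0.9, 30)
    gc12 = 0.4 * gc3 + rng.normal(0, 0.02, 30)
    a = neutrality_regression(gc12, gc3)
    b = neutrality_regression(gc12 * 100, gc3 * 100)
    assert b.slope == pytest.approx(a.slope, abs=1e-12)
    assert b.pearson_r == pytest.approx(a.pearson_r, abs=1e-12)

    deg = neutrality_regression(gc12, np.full(30, 0.5))
    assert math.isnan(deg.slope)
    with pytest.raises(ValueError):
        neutrality_regression([0.5, 0.5], [0.4, 0.6])


# --- ENC null curve ----------------------------------------------------------

def test_expected_enc_curve_closed_form_and_symmetry():
    assert expected_enc_curve(0.5) == pytest.approx(60.5)
    for s in (0.1, 0.25, 0.4):
        assert expected_enc_curve(s) - expected_enc_curve(1 - s) == \
            pytest.approx(2 * s - 1, abs=1e-12)
    grid = np.linspace(0.01, 0.99, 99)
    oracle = 2 + grid + 29 / (grid ** 2 + (1 - grid) ** 2)
    np.testing.assert_allclose(expected_enc_curve(grid), oracle, atol=1e-12)
    with pytest.raises(ValueError):
        expected_enc_curve(0.0)


def test_enc_residuals_near_zero_without_selection():
    """Composition-only genes sit on Wright's null curve (median residual
    within ±2 ENC units)."""
    for seed in (1, 2):
        spec = SyntheticGenomeSpec(n_genes=150, length_median_codons=300,
                                   selection_strength=0.0, seed=seed)
        records, _ = simulate_genome(spec)
        frame, _, _ = gene_indices_frame(records)
        plot = enc_plot_frame(frame)
        assert abs(plot["residual"].median()) < 2.0
        assert set(plot["below_curve"]) <= {0, 1}


# --- correspondence analysis -------------------------------------------------

def _ca_oracle_row_coords(N, k=2):
    """Independent CA route: eigendecomposition of S^T S instead of SVD."""
    P = N / N.sum()
    r, c = P.sum(1), P.sum(0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    evals, V = np.linalg.eigh(S.T @ S)
    order = np.argsort(evals)[::-1]
    evals, V = evals[order], V[:, order]
    sv = np.sqrt(np.clip(evals[:k], 0, None))
    U = S @ V[:, :k] / sv
    return (U * sv) / np.sqrt(r)[:, None]


def test_ca_identical_rows_have_zero_inertia():
    row = np.arange(1.0, 60.0)
    mat = pd.DataFrame(np.tile(row, (5, 1)))
    res = correspondence_analysis(mat)
    assert res.rank == 0
    assert np.allclose(res.row_coordinates.to_numpy(), 0.0)
    assert res.eigenvalues.size == 0


def test_ca_axis1_separates_two_codon_preference_clusters():
    rng = np.random.default_rng(5)
    base = np.ones(10)
    cluster_a = base.copy(); cluster_a[:5] = 6.0
    cluster_b = base.copy(); cluster_b[5:] = 6.0
    rows = [cluster_a + rng.uniform(0, .2, 10) for _ in range(6)] + \
           [cluster_b + rng.uniform(0, .2, 10) for _ in range(6)]
    res = correspondence_analysis(pd.DataFrame(rows))
    ax1 = res.row_coordinates["axis1"].to_numpy()
    assert set(np.sign(ax1[:6])) == {np.sign(ax1[0])}
    assert np.sign(ax1[0]) == -np.sign(ax1[6])


def test_ca_matches_independent_eigendecomposition():
    rng = np.random.default_rng(11)
    N = rng.uniform(0.1, 5.0, size=(10, 59))
    res = correspondence_analysis(pd.DataFrame(N))
    oracle = _ca_oracle_row_coords(N)
    ours = res.row_coordinates.to_numpy()
    for j in range(2):
        diff = min(
            np.max(np.abs(ours[:, j] - oracle[:, j])),
            np.max(np.abs(ours[:, j] + oracle[:, j])),
        )
        assert diff < 1e-8


def test_ca_rows_with_identical_profiles_coincide():
    """CA operates on row profiles: a row that is a positive multiple of
    another (same profile, more mass) gets the same coordinates."""
    rng = np.random.default_rng(13)
    N = rng.uniform(0.5, 3.0, size=(8, 20))
    N[5] = 7.5 * N[2]
    res = correspondence_analysis(pd.DataFrame(N))
    a = res.row_coordinates.iloc[2].to_numpy()
    b = res.row_coordinates.iloc[5].to_numpy()
    assert np.allclose(a, b, atol=1e-9)


def test_rscu_matrix_fills_absent_families_neutrally():
    counts = {
        "g1": CodonCounts.from_mapping({"GCC": 10, "GCU": 5, "AAG": 3}),
        "g2": CodonCounts.from_mapping({c: 2 for c in SYNONYMOUS_CODONS}),
        "g3": CodonCounts.from_mapping({"CGC": 8, "CGU": 2}),
    }
    mat, filled = rscu_matrix(counts)
    assert mat.shape == (3, 59)
    assert not mat.isna().any().any()
    assert mat.loc["g1", "GGC"] == 1.0  # Gly absent from g1 -> neutral fill
    assert "GGC" in filled["g1"] and "g2" not in filled


# --- Spearman matrix ---------------------------------------------------------

def test_spearman_trivial_identities():
    rng = np.random.default_rng(23)
    x = rng.normal(size=30)
    df = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(size=30)})
    cm = spearman_matrix(df, variables=["a", "b", "c"])
    assert cm.rho.loc["a", "a"] == 1.0
    assert cm.rho.loc["a", "b"] == pytest.approx(-1.0)
    assert np.allclose(cm.rho.to_numpy(), cm.rho.to_numpy().T,
                       equal_nan=True)
    assert (np.abs(cm.rho.to_numpy()[np.isfinite(cm.rho.to_numpy())])
            <= 1 + 1e-12).all()


def test_spearman_matches_rank_then_pearson_brute_force():
    rng = np.random.default_rng(29)
    df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
    df.iloc[2, 1] = np.nan  # exercise pairwise deletion
    cm = spearman_matrix(df, variables=list("abcd"))
    for i in "abcd":
        for j in "abcd":
            x, y = df[i].to_numpy(), df[j].to_numpy()
            mask = np.isfinite(x) & np.isfinite(y)
            rho = stats.pearsonr(
                stats.rankdata(x[mask]), stats.rankdata(y[mask])
            ).statistic
            assert cm.rho.loc[i, j] == pytest.approx(rho, abs=1e-12)


def test_spearman_exact_small_n_agrees_with_permutation_definition():
    rng = np.random.default_rng(31)
    df = pd.DataFrame(rng.normal(size=(6, 2)), columns=["a", "b"])
    cm = spearman_matrix(df, variables=["a", "b"])
    p = cm.p.loc["a", "b"]
    assert 0.0 <= p <= 1.0
    # exact p of n=6 is a multiple of 1/720
    assert (p * 720) == pytest.approx(round(p * 720), abs=1e-9)


def test_spearman_constant_variable_marked_undefined():
    rng = np.random.default_rng(37)
    df = pd.DataFrame({"a": rng.normal(size=12), "b": np.full(12, 3.0)})
    cm = spearman_matrix(df, variables=["a", "b"])
    assert math.isnan(cm.rho.loc["a", "b"])
    assert cm.rho.loc["b", "b"] == 1.0  # self-correlation stays defined


def test_spearman_on_biased_genome_couples_enc_and_axis1(small_genome):
    """On selection-shaped data the leading CA axis must track ENC
    strongly (|rho| > 0.5), the qualitative signature of genuine bias."""
    records, _ = small_genome
    frame, per_gene, _ = gene_indices_frame(records)
    mat, _ = rscu_matrix(per_gene)
    res = correspondence_analysis(mat)
    frame = frame.set_index("gene_id")
    frame["axis1"] = res.row_coordinates["axis1"]
    frame["axis2"] = res.row_coordinates["axis2"]
    cm = spearman_matrix(frame.reset_index())
    assert abs(cm.rho.loc["enc", "axis1"]) > 0.5
    assert cm.p.loc["enc", "axis1"] < 0.001
    table = format_correlation_table(cm)
    assert table.loc["enc", "axis1"].endswith("**")
    assert set(CORRELATION_VARIABLES) <= set(table.columns)
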