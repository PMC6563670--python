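"""Genome-level analyses over per-gene indices.

* Neutrality regression: OLS of GC12 on GC3 across genes.  Under pure
  mutational (neutral) pressure all three codon positions drift together
  and the slope approaches 1; selective constraint on positions 1-2 pulls
  it toward 0.  The slope is read directly as the mutational share
  (slope x 100 %), the remainder as "other factors".
* ENC-GC3s null curve: the ENC a gene would have if its only bias came
  from third-position composition, ``2 + s + 29 / (s^2 + (1-s)^2)``.
  Genes far below the curve are biased beyond what composition explains.
* Correspondence analysis of the gene x 59-codon RSCU matrix — the
  leading axes of codon-usage variation.
* Spearman correlation matrix between all indices, Table-2 style.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import SYNONYMOUS_CODONS
from .genome_io import CodonCounts
from .indices import compute_rscu

#: Sample size at or below which Spearman p-values are computed by exact
#: enumeration of permutations instead of the t approximation.
EXACT_SPEARMAN_MAX_N = 8


# --- neutrality plot ---------------------------------------------------------

@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float
    n_genes: int

    @property
    def mutation_pct(self) -> float:
        return self.slope * 100.0

    @property
    def other_pct(self) -> float:
        return (1.0 - self.slope) * 100.0


def neutrality_regression(
    gc12: Sequence[float], gc3: Sequence[float]
) -> NeutralityFit:
    """OLS of per-gene GC12 on GC3 with Pearson r and two-sided p.

    NaN pairs are dropped; zero variance in GC3 yields an undefined fit.
    """
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    if x.shape != y.shape:
        raise ValueError("gc12 and gc3 must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = int(x.size)
    if n < 3:
        raise ValueError("neutrality regression requires >= 3 genes")
    if np.ptp(x) == 0:
        return NeutralityFit(math.nan, math.nan, math.nan, math.nan,
                             math.nan, n)
    res = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n_genes=n,
    )


# --- ENC vs GC3s null curve --------------------------------------------------

def expected_enc_curve(gc3s):
    """Composition-only expected ENC at synonymous third-position GC ``s``.

    Accepts a scalar or array in the open interval (0, 1).
    """
    s = np.asarray(gc3s, dtype=float)
    if np.any((s <= 0) | (s >= 1)):
        raise ValueError("gc3s must lie strictly between 0 and 1")
    val = 2.0 + s + 29.0 / (s ** 2 + (1.0 - s) ** 2)
    return float(val) if np.isscalar(gc3s) or val.ndim == 0 else val


def enc_plot_frame(indices: pd.DataFrame) -> pd.DataFrame:
    """Per-gene ENC-plot data: expected ENC, residual, below-curve flag."""
    out = indices[["gene_id", "gc3s", "enc"]].copy()
    s = out["gc3s"].to_numpy(dtype=float)
    expected = np.full_like(s, np.nan)
    ok = np.isfinite(s) & (s > 0) & (s < 1)
    expected[ok] = 2.0 + s[ok] + 29.0 / (s[ok] ** 2 + (1.0 - s[ok]) ** 2)
    out["expected_enc"] = expected
    out["residual"] = out["enc"] - out["expected_enc"]
    out["below_curve"] = (out["residual"] < 0).astype(int)
    return out


# --- correspondence analysis -------------------------------------------------

@dataclass
class CoaResult:
    """Correspondence analysis of a nonnegative gene x codon matrix.

    ``row_coordinates`` / ``column_coordinates`` are principal
    coordinates; ``eigenvalues`` are squared singular values of the
    standardized residual matrix, ``inertia_fractions`` their shares of
    total inertia.  ``rank`` < requested axes flags a degenerate input.
    """

    row_coordinates: pd.DataFrame
    column_coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    inertia_fractions: np.ndarray
    rank: int


def rscu_matrix(
    per_gene_counts: Mapping[str, CodonCounts],
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-gene RSCU over the 59 synonymous sense codons.

    A family absent from a gene has undefined RSCU; those cells are
    filled with the family-neutral value 1 so every row is complete, and
    the filled codons are reported per gene.
    """
    filled: dict[str, list[str]] = {}
    rows = []
    for gene_id, counts in per_gene_counts.items():
        vals = compute_rscu(counts, include_stops=False).values()
        row = []
        fills = []
        for codon in SYNONYMOUS_CODONS:
            v = vals[codon]
            if math.isnan(v):
                v = 1.0
                fills.append(codon)
            row.append(v)
        if fills:
            filled[gene_id] = fills
        rows.append(row)
    frame = pd.DataFrame(rows, index=list(per_gene_counts),
                         columns=list(SYNONYMOUS_CODONS))
    return frame, filled


def correspondence_analysis(
    matrix: pd.DataFrame, n_axes: int = 2
) -> CoaResult:
    """Standard correspondence analysis of a nonnegative matrix.

    The matrix entries are treated as mass; standardized residuals
    ``S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}`` are decomposed by SVD and
    principal coordinates returned for rows (genes) and columns
    (codons).  The sign of each axis is fixed by forcing the column with
    the largest |loading| to be positive.
    """
    if matrix.shape[0] < 3:
        raise ValueError("correspondence analysis requires >= 3 rows")
    N = matrix.to_numpy(dtype=float)
    if np.any(N < 0) or not np.all(np.isfinite(N)):
        raise ValueError("matrix must be nonnegative and finite")
    total = N.sum()
    if total <= 0:
        raise ValueError("matrix has zero total mass")

    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    dr = np.where(r > 0, 1.0 / np.sqrt(np.where(r > 0, r, 1.0)), 0.0)
    dc = np.where(c > 0, 1.0 / np.sqrt(np.where(c > 0, c, 1.0)), 0.0)
    S = dr[:, None] * (P - np.outer(r, c)) * dc[None, :]

    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    tol = max(S.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    rank = int(np.sum(sv > max(tol, 1e-12)))
    k = min(n_axes, rank)

    row = np.zeros((N.shape[0], n_axes))
    col = np.zeros((N.shape[1], n_axes))
    if k:
        row[:, :k] = dr[:, None] * U[:, :k] * sv[:k]
        col[:, :k] = dc[:, None] * Vt[:k].T * sv[:k]
        for j in range(k):
            pivot = int(np.argmax(np.abs(col[:, j])))
            if col[pivot, j] < 0:
                row[:, j] *= -1.0
                col[:, j] *= -1.0

    axes = [f"axis{i + 1}" for i in range(n_axes)]
    eig = sv[:rank] ** 2
    total_inertia = float((sv ** 2).sum())
    inertia = eig / total_inertia if total_inertia > 0 else eig
    return CoaResult(
        row_coordinates=pd.DataFrame(row, index=matrix.index, columns=axes),
        column_coordinates=pd.DataFrame(col, index=matrix.columns,
                                        columns=axes),
        eigenvalues=eig,
        inertia_fractions=inertia,
        rank=rank,
    )


# --- Spearman correlation matrix ---------------------------------------------

CORRELATION_VARIABLES = [
    "length_codons", "gc", "gc1", "gc2", "gc3", "gc3s",
    "a3s", "t3s", "c3s", "g3s", "gravy", "aromo", "enc", "cai",
    "axis1", "axis2",
]


@dataclass
class CorrelationMatrix:
    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (ties via avg ranks)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean())
    denom_x = math.sqrt((rx ** 2).sum())
    count = 0
    total = 0
    for perm in permutations(range(n)):
        ryp = ry[list(perm)]
        ryp = ryp - ryp.mean()
        denom_y = math.sqrt((ryp ** 2).sum())
        rho = float((rx * ryp).sum() / (denom_x * denom_y))
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_matrix(
    indices: pd.DataFrame, variables: Sequence[str] | None = None
) -> CorrelationMatrix:
    """Pairwise Spearman rho and two-sided p over the index columns.

    Undefined entries are pairwise-deleted; a pair with < 3 complete
    observations or a constant variable gets NaN.  P-values use the
    t approximation except at very small n, where the permutation null
    is enumerated exactly.
    """
    variables = list(variables or CORRELATION_VARIABLES)
    missing = [v for v in variables if v not in indices.columns]
    if missing:
        raise ValueError(f"missing index columns: {missing}")
    if len(indices) < 5:
        raise ValueError("spearman_matrix requires >= 5 genes")

    m = len(variables)
    rho = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    nmat = np.zeros((m, m), dtype=int)
    data = {v: indices[v].to_numpy(dtype=float) for v in variables}

    for i in range(m):
        for j in range(i, m):
            x, y = data[variables[i]], data[variables[j]]
            mask = np.isfinite(x) & np.isfinite(y)
            n = int(mask.sum())
            nmat[i, j] = nmat[j, i] = n
            if n < 3:
                continue
            xi, yj = x[mask], y[mask]
            if i == j:
                rho[i, j] = 1.0
                p[i, j] = 0.0
                continue
            if np.ptp(xi) == 0 or np.ptp(yj) == 0:
                continue
            res = stats.spearmanr(xi, yj)
            rho[i, j] = rho[j, i] = float(res.statistic)
            if n <= EXACT_SPEARMAN_MAX_N:
                pv = _exact_spearman_p(xi, yj, float(res.statistic))
            else:
                pv = float(res.pvalue)
            p[i, j] = p[j, i] = pv

    return CorrelationMatrix(
        variables=variables,
        rho=pd.DataFrame(rho, index=variables, columns=variables),
        p=pd.DataFrame(p, index=variables, columns=variables),
        n=pd.DataFrame(nmat, index=variables, columns=variables),
    )


def format_correlation_table(cm: CorrelationMatrix) -> pd.DataFrame:
    """Rho values annotated with significance stars (* p<0.05, ** p<0.01)."""
    out = pd.DataFrame("", index=cm.variables, columns=cm.variables)
    for i in cm.variables:
        for j in cm.variables:
            r = cm.rho.loc[i, j]
            if math.isnan(r):
                out.loc[i, j] = "NA"
                continue
            stars = ""
            pv = cm.p.loc[i, j]
            if i != j and not math.isnan(pv):
                if pv < 0.01:
                    stars = "**"
                elif pv < 0.05:
                    stars = "*"
            out.loc[i, j] = f"{r:.3f}{stars}"
    return out


def benjamini_hochberg(p: pd.DataFrame) -> pd.DataFrame:
    """BH-adjusted p-values for the upper triangle, mirrored back."""
    vars_ = list(p.index)
    pairs = [(i, j) for i in range(len(vars_)) for j in range(i + 1, len(vars_))]
    raw = np.array([p.iloc[i, j] for i, j in pairs])
    adj = np.full_like(raw, np.nan)
    ok = np.isfinite(raw)
    if ok.sum():
        adj[ok] = stats.false_discovery_control(raw[ok], method="bh")
    out = p.copy()
    for (i, j), a in zip(pairs, adj):
        out.iloc[i, j] = out.iloc[j, i] = a
    return out
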