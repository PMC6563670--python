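"""Optimal-codon detection from high- vs low-bias gene pools.

Without expression data, translationally optimal codons are inferred by
contrast: genes are ranked by ENC, the most biased tail is pooled as a
proxy for highly expressed genes and the least biased tail as background,
and a codon is called optimal when it is both preferred in the high pool
(RSCU > 1), substantially more used there (ΔRSCU at least a threshold)
and significantly enriched by a 2x2 chi-square test of codon-vs-family
usage between pools.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats

from .genetic_code import AA_TO_CODONS, SINGLE_CODON_AAS
from .genome_io import CodonCounts, pool_counts
from .indices import compute_rscu

DEFAULT_POOL_FRACTION = 0.05
DEFAULT_DELTA_THRESHOLD = 0.08
DEFAULT_ALPHA = 0.01


@dataclass
class BiasPartition:
    """Disjoint high-bias (lowest ENC) and low-bias (highest ENC) pools."""

    high_genes: list[str]
    low_genes: list[str]
    high_pool: CodonCounts
    low_pool: CodonCounts
    fraction: float
    n_excluded: int = 0

    @property
    def n_codons_high(self) -> int:
        return self.high_pool.n_codons

    @property
    def n_codons_low(self) -> int:
        return self.low_pool.n_codons


def partition_by_enc(
    enc: Mapping[str, float],
    per_gene_counts: Mapping[str, CodonCounts],
    fraction: float = DEFAULT_POOL_FRACTION,
) -> BiasPartition:
    """Split genes into high-/low-bias pools by ENC rank.

    Genes with undefined ENC are excluded before ranking; ties break on
    gene id so the partition is deterministic.  Both tails take
    ``ceil(fraction * N)`` genes and must not overlap.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    usable = sorted(
        (g for g in per_gene_counts
         if not math.isnan(enc.get(g, math.nan))),
        key=lambda g: (enc[g], g),
    )
    n_excluded = len(per_gene_counts) - len(usable)
    k = math.ceil(fraction * len(usable))
    if k == 0 or 2 * k > len(usable):
        raise ValueError(
            f"fraction {fraction} leaves no disjoint pools for "
            f"{len(usable)} usable genes"
        )
    high = usable[:k]
    low = usable[-k:]
    return BiasPartition(
        high_genes=high,
        low_genes=low,
        high_pool=pool_counts([per_gene_counts[g] for g in high]),
        low_pool=pool_counts([per_gene_counts[g] for g in low]),
        fraction=fraction,
        n_excluded=n_excluded,
    )


def _codon_vs_family_test(
    a: int, b: int, c: int, d: int, use_fisher: bool
) -> tuple[float, float]:
    """2x2 test of (codon, rest of family) x (high, low)."""
    if use_fisher:
        res = stats.fisher_exact([[a, b], [c, d]])
        return math.nan, float(res.pvalue)
    total = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if min(row1, row2, col1, col2) == 0:
        # the codon (or its alternatives) is absent from both pools:
        # no contrast to test
        return 0.0, 1.0
    expected_min = min(
        row1 * col1, row1 * col2, row2 * col1, row2 * col2
    ) / total
    chi2, p, _, _ = stats.chi2_contingency(
        [[a, b], [c, d]], correction=expected_min < 5
    )
    return float(chi2), float(p)


def detect_optimal_codons(
    partition: BiasPartition,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    use_fisher: bool = False,
) -> pd.DataFrame:
    """Per-codon high/low RSCU contrast with optimality calls.

    Returns one row per codon (sense codons and stops, for a complete
    report); AUG, UGG and stops are never testable or optimal.  A
    degenerate family absent from either pool is flagged untestable.
    """
    if partition.high_pool.n_codons == 0 or partition.low_pool.n_codons == 0:
        raise ValueError("both pools must be non-empty")
    rscu_high = compute_rscu(partition.high_pool)
    rscu_low = compute_rscu(partition.low_pool)

    rows = []
    for aa, family in AA_TO_CODONS.items():
        degenerate = aa != "*" and aa not in SINGLE_CODON_AAS
        fam_high = sum(partition.high_pool.counts[c] for c in family)
        fam_low = sum(partition.low_pool.counts[c] for c in family)
        for codon in family:
            a = partition.high_pool.counts[codon]
            c_low = partition.low_pool.counts[codon]
            testable = degenerate and fam_high > 0 and fam_low > 0
            if testable:
                chi2, p = _codon_vs_family_test(
                    a, fam_high - a, c_low, fam_low - c_low, use_fisher
                )
            else:
                chi2, p = math.nan, math.nan
            rh = rscu_high[codon].rscu
            rl = rscu_low[codon].rscu
            delta = rh - rl if not (math.isnan(rh) or math.isnan(rl)) \
                else math.nan
            optimal = bool(
                testable
                and not math.isnan(delta)
                and rh > 1.0
                and delta >= delta_threshold
                and p < alpha
            )
            rows.append({
                "amino_acid": aa,
                "codon": codon,
                "rscu_high": rh,
                "n_high": a,
                "rscu_low": rl,
                "n_low": c_low,
                "delta_rscu": delta,
                "chi2": chi2,
                "p": p,
                "testable": int(testable),
                "optimal": int(optimal),
            })
    return pd.DataFrame(rows)
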