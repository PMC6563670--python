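"""Per-gene and pooled codon-usage indices.

RSCU — relative synonymous codon usage: for codon *j* in a family of size
:math:`n_i` with counts :math:`x_{ij}`,

.. math:: \\mathrm{RSCU}_{ij} = n_i \\, x_{ij} / \\sum_j x_{ij}

so 1 means no bias within the family and values sum to the family size.

ENC — Wright's effective number of codons, built from per-family codon
homozygosity :math:`F = (n\\sum \\hat p^2 - 1)/(n-1)` averaged within each
degeneracy class:

.. math:: N_c = 2 + 9/\\bar F_2 + 1/\\bar F_3 + 5/\\bar F_4 + 3/\\bar F_6

ranging from 20 (one codon per amino acid) to 61 (uniform usage).

CAI — the geometric mean of relative-adaptiveness weights
:math:`w_{ij} = \\mathrm{RSCU}_{ij}/\\max_j \\mathrm{RSCU}_{ij}` derived
from a highly-expressed reference pool, over all codons of a gene except
AUG, UGG and stops.

GRAVY and aromaticity are properties of the hypothetical translated
product: mean Kyte–Doolittle hydropathy, and the fraction of F/Y/W.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .composition import composition_profile
from .genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERACY_CLASSES,
    SINGLE_CODON_AAS,
    SYNONYMOUS_CODONS,
)
from .genome_io import CdsRecord, CodonCounts, count_codons, pool_counts, translate

ENC_MAX = 61.0
CAI_WEIGHT_FLOOR = 0.01

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC = frozenset("FYW")


# --- RSCU --------------------------------------------------------------------

@dataclass(frozen=True)
class RscuEntry:
    amino_acid: str
    codon: str
    count: int
    family_size: int
    rscu: float


@dataclass
class RscuTable:
    """Per-codon RSCU with family bookkeeping.

    Entries cover all 61 sense codons (AUG/UGG carry RSCU 1 when observed)
    and, when ``include_stops``, the 3-member stop family.  Families with
    zero total have NaN RSCU.
    """

    entries: dict[str, RscuEntry]

    def __getitem__(self, codon: str) -> RscuEntry:
        return self.entries[codon]

    def values(self) -> dict[str, float]:
        return {c: e.rscu for c, e in self.entries.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.amino_acid, e.codon, e.count, e.family_size, e.rscu)
            for e in self.entries.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["amino_acid", "codon", "total_count", "family_size",
                     "rscu"],
        )


def compute_rscu(counts: CodonCounts, include_stops: bool = True) -> RscuTable:
    """RSCU for every family of a count table.

    Stop-family RSCU is reported for completeness but stops never enter
    ENC, CAI, GC3s or the optimal-codon analysis.
    """
    entries: dict[str, RscuEntry] = {}
    for aa, family in AA_TO_CODONS.items():
        if aa == "*" and not include_stops:
            continue
        size = len(family)
        total = sum(counts.counts[c] for c in family)
        for codon in family:
            x = counts.counts[codon]
            if size == 1:
                rscu = 1.0 if x > 0 else math.nan
            elif total == 0:
                rscu = math.nan
            else:
                rscu = size * x / total
            entries[codon] = RscuEntry(
                amino_acid=aa, codon=codon, count=x, family_size=size,
                rscu=rscu,
            )
    return RscuTable(entries=entries)


# --- ENC ---------------------------------------------------------------------

@dataclass(frozen=True)
class EncValue:
    """Wright's ENC plus the per-class diagnostics behind it.

    ``f_bar`` maps degeneracy class (2, 3, 4, 6) to the mean family
    homozygosity; ``n_informative`` counts families with total >= 2 per
    class.  ``capped`` flags raw estimates above 61 (sampling noise)
    that were clipped.
    """

    enc: float
    f_bar: dict[int, float]
    n_informative: dict[int, int]
    capped: bool = False
    raw_enc: float = math.nan


def _family_homozygosity(counts: CodonCounts, family: Sequence[str]) -> float:
    """F = (n * sum(p^2) - 1) / (n - 1); NaN for n < 2."""
    ns = [counts.counts[c] for c in family]
    n = sum(ns)
    if n < 2:
        return math.nan
    sum_p2 = sum((x / n) ** 2 for x in ns)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def compute_enc(counts: CodonCounts) -> EncValue:
    """Wright's effective number of codons for one count table.

    Per-class means are taken over informative families only (total >= 2).
    A class with no informative family makes ENC undefined, except the
    3-fold class (Ile alone), for which Wright's fallback
    ``F3 = (F2 + F4) / 2`` is used; classes 2, 4 and 6 additionally
    require at least half of their families to be informative so that a
    class mean is never extrapolated from a stray family or two.
    Estimates above 61 are capped (and flagged).
    """
    f_bar: dict[int, float] = {}
    n_informative: dict[int, int] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = []
        for aa in aas:
            f = _family_homozygosity(counts, AA_TO_CODONS[aa])
            if not math.isnan(f):
                fs.append(f)
        n_informative[k] = len(fs)
        if fs and (k == 3 or len(fs) >= len(aas) / 2):
            f_bar[k] = sum(fs) / len(fs)
        else:
            f_bar[k] = math.nan

    if math.isnan(f_bar[3]) and not (
        math.isnan(f_bar[2]) or math.isnan(f_bar[4])
    ):
        f_bar = dict(f_bar)
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0

    if any(math.isnan(f_bar[k]) for k in (2, 3, 4, 6)):
        return EncValue(enc=math.nan, f_bar=f_bar,
                        n_informative=n_informative)

    def contrib(n_fam: int, f: float) -> float:
        return n_fam / f if f > 0 else math.inf

    raw = 2.0 + contrib(9, f_bar[2]) + contrib(1, f_bar[3]) \
        + contrib(5, f_bar[4]) + contrib(3, f_bar[6])
    capped = raw > ENC_MAX
    return EncValue(enc=min(raw, ENC_MAX), f_bar=f_bar,
                    n_informative=n_informative, capped=capped, raw_enc=raw)


# --- CAI ---------------------------------------------------------------------

@dataclass
class CaiWeights:
    """Relative adaptiveness w in (0, 1] per synonymous sense codon.

    ``floored`` lists codons unobserved in the reference that received the
    floor weight instead of an impossible log(0).
    """

    weights: dict[str, float]
    provenance: str
    floored: tuple[str, ...] = ()


def derive_cai_weights(
    pooled_reference: CodonCounts,
    provenance: str = "user",
    floor: float = CAI_WEIGHT_FLOOR,
) -> CaiWeights:
    """w_ij = RSCU_ij / max_j RSCU_ij on the reference pool.

    Codons unobserved in the reference (or whole families with zero
    total) get the floor weight; within every observed family the best
    codon has w == 1.
    """
    if pooled_reference.n_codons == 0:
        raise ValueError("empty CAI reference pool")
    rscu = compute_rscu(pooled_reference, include_stops=False)
    weights: dict[str, float] = {}
    floored: list[str] = []
    for aa, family in AA_TO_CODONS.items():
        if aa == "*" or aa in SINGLE_CODON_AAS:
            continue
        vals = {c: rscu[c].rscu for c in family}
        finite = [v for v in vals.values() if not math.isnan(v) and v > 0]
        best = max(finite) if finite else math.nan
        for codon in family:
            v = vals[codon]
            if math.isnan(v) or v <= 0 or math.isnan(best):
                weights[codon] = floor
                floored.append(codon)
            else:
                weights[codon] = v / best
    return CaiWeights(weights=weights, provenance=provenance,
                      floored=tuple(sorted(floored)))


def compute_cai(gene: CodonCounts, weights: CaiWeights) -> float:
    """Geometric mean of weights over the gene's synonymous sense codons.

    AUG, UGG and stops are excluded; a gene with no includable codon
    yields NaN.
    """
    log_sum = 0.0
    n = 0
    for codon in SYNONYMOUS_CODONS:
        x = gene.counts[codon]
        if x:
            log_sum += x * math.log(weights.weights[codon])
            n += x
    if n == 0:
        return math.nan
    return math.exp(log_sum / n)


# --- protein-level indices ---------------------------------------------------

def compute_gravy(protein: str) -> float:
    """Mean Kyte–Doolittle hydropathy, ignoring '*' and 'X'."""
    vals = [KYTE_DOOLITTLE[aa] for aa in protein if aa in KYTE_DOOLITTLE]
    if not vals:
        return math.nan
    return sum(vals) / len(vals)


def compute_aromo(protein: str) -> float:
    """Fraction of aromatic residues (F, Y, W), ignoring '*' and 'X'."""
    residues = [aa for aa in protein if aa in KYTE_DOOLITTLE]
    if not residues:
        return math.nan
    return sum(1 for aa in residues if aa in AROMATIC) / len(residues)


# --- per-gene assembly -------------------------------------------------------

GENE_INDEX_COLUMNS = [
    "gene_id", "length_nt", "length_codons", "n_codons", "n_skipped",
    "gc", "gc1", "gc2", "gc12", "gc3", "gc3s", "a3s", "t3s", "c3s", "g3s",
    "enc", "enc_capped", "cai", "gravy", "aromo", "axis1", "axis2",
]


def derive_auto_reference(
    per_gene_counts: Mapping[str, CodonCounts],
    enc: Mapping[str, float],
    fraction: float = 0.05,
) -> tuple[CodonCounts, str, list[str]]:
    """Pool the lowest-ENC fraction of genes as the CAI reference.

    The most biased genes stand proxy for highly expressed genes when no
    expression data exist; ties break on gene id for determinism.
    """
    usable = sorted(
        (g for g in per_gene_counts if not math.isnan(enc.get(g, math.nan))),
        key=lambda g: (enc[g], g),
    )
    if not usable:
        raise ValueError("no gene has a defined ENC; cannot build reference")
    k = max(1, math.ceil(fraction * len(usable)))
    chosen = usable[:k]
    pooled = pool_counts([per_gene_counts[g] for g in chosen])
    provenance = f"auto-enc: pooled {k} lowest-ENC genes of {len(usable)}"
    return pooled, provenance, chosen


def gene_indices_frame(
    records: Sequence[CdsRecord],
    cai_weights: CaiWeights | None = None,
    cai_reference_fraction: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, CodonCounts], CaiWeights]:
    """Compute the full per-gene index table.

    When no CAI weights are supplied they are derived from the pooled
    lowest-ENC ``cai_reference_fraction`` of the input genes.  Axis1/axis2
    columns are NaN placeholders filled later by correspondence analysis.
    Returns (frame, per-gene counts, the weights actually used).
    """
    per_gene: dict[str, CodonCounts] = {r.id: count_codons(r) for r in records}
    enc_by_gene = {g: compute_enc(c).enc for g, c in per_gene.items()}

    if cai_weights is None:
        pooled_ref, provenance, _ = derive_auto_reference(
            per_gene, enc_by_gene, cai_reference_fraction
        )
        cai_weights = derive_cai_weights(pooled_ref, provenance)

    rows = []
    for rec in records:
        counts = per_gene[rec.id]
        if counts.n_codons == 0:
            continue
        prof = composition_profile(counts)
        enc_val = compute_enc(counts)
        protein = translate(rec)
        rows.append({
            "gene_id": rec.id,
            "length_nt": len(rec.seq),
            "length_codons": len(rec.seq) // 3,
            "n_codons": counts.n_codons,
            "n_skipped": counts.n_skipped,
            "gc": prof.gc, "gc1": prof.gc1, "gc2": prof.gc2,
            "gc12": prof.gc12, "gc3": prof.gc3, "gc3s": prof.gc3s,
            "a3s": prof.a3s, "t3s": prof.t3s, "c3s": prof.c3s,
            "g3s": prof.g3s,
            "enc": enc_val.enc,
            "enc_capped": int(enc_val.capped),
            "cai": compute_cai(counts, cai_weights),
            "gravy": compute_gravy(protein),
            "aromo": compute_aromo(protein),
            "axis1": math.nan, "axis2": math.nan,
        })
    frame = pd.DataFrame(rows, columns=GENE_INDEX_COLUMNS)
    return frame, per_gene, cai_weights
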