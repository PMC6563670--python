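"""Standard nuclear genetic code bookkeeping shared by every analysis stage.

All codon keys throughout the package are in the RNA alphabet ("CUC", not
"CTC"); FASTA input is DNA and is re-keyed when codons are counted.  The
code is fixed to the standard nuclear table (NCBI translation table 1),
which is the correct table for ascomycete nuclear CDS.
"""
from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable

RNA_BASES: tuple[str, ...] = ("U", "C", "A", "G")

#: All 64 codons in lexicographic (A<C<G<U) order — the canonical column
#: order of every wide count table the package writes.
ALL_CODONS: tuple[str, ...] = tuple(
    sorted("".join(p) for p in product("ACGU", repeat=3))
)

_TABLE = CodonTable.unambiguous_rna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: codon -> one-letter amino acid; stop codons map to "*".
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in STOP_CODONS})

SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if c not in STOP_CODONS
)

_aa_to_codons: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    _aa_to_codons.setdefault(CODON_TO_AA[_codon], []).append(_codon)
_aa_to_codons["*"] = sorted(STOP_CODONS)

#: amino acid -> synonymous family (sorted codons); "*" is the stop family.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(codons) for aa, codons in _aa_to_codons.items()
}

#: family size (degeneracy) per codon; stops count as a 3-member family.
FAMILY_SIZE: dict[str, int] = {
    codon: len(AA_TO_CODONS[CODON_TO_AA[codon]]) for codon in ALL_CODONS
}

#: Met and Trp: single-codon amino acids, excluded from every synonymous
#: statistic (RSCU is trivially 1, no third-position choice exists).
SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, fam in AA_TO_CODONS.items() if aa != "*" and len(fam) == 1
)

#: The 59 synonymous sense codons: sense codons minus AUG and UGG.
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c
    for c in SENSE_CODONS
    if CODON_TO_AA[c] not in SINGLE_CODON_AAS
)

#: Degenerate amino acids grouped by family size, as used by Wright's
#: effective-number-of-codons estimator: nine 2-fold families, Ile as the
#: sole 3-fold family, five 4-fold families, three 6-fold families.
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _fam in AA_TO_CODONS.items():
    if _aa == "*" or len(_fam) == 1:
        continue
    DEGENERACY_CLASSES.setdefault(len(_fam), [])
for _aa, _fam in AA_TO_CODONS.items():
    if _aa == "*" or len(_fam) == 1:
        continue
    DEGENERACY_CLASSES[len(_fam)].append(_aa)
DEGENERACY_CLASSES = {
    k: tuple(sorted(v)) for k, v in DEGENERACY_CLASSES.items()
}


def to_rna(codon: str) -> str:
    """Re-key a codon from DNA to RNA alphabet (T -> U)."""
    return codon.replace("T", "U").replace("t", "u")


def to_dna(codon: str) -> str:
    """Re-key a codon from RNA to DNA alphabet (U -> T)."""
    return codon.replace("U", "T").replace("u", "t")
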