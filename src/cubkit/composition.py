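"""Nucleotide composition at each codon position.

Two conventions coexist and are kept explicit throughout:

* ``gc`` / ``gc1`` / ``gc2`` / ``gc3`` are computed over *all* counted
  codons, including stop codons — they describe the CDS as a nucleotide
  sequence.
* ``gc3s`` and the per-base ``a3s/t3s/c3s/g3s`` are computed over
  *synonymous* third positions only: all sense codons except AUG and UGG
  (no synonymous choice exists there) and the stops.  With this
  definition ``a3s + t3s + c3s + g3s == 1`` and ``gc3s == c3s + g3s``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .genetic_code import SYNONYMOUS_CODONS
from .genome_io import CodonCounts

_GC = frozenset("GC")


@dataclass(frozen=True)
class CompositionProfile:
    """Composition fractions in [0, 1]; undefined values are NaN."""

    gc: float
    gc1: float
    gc2: float
    gc12: float
    gc3: float
    gc3s: float
    a3s: float
    t3s: float
    c3s: float
    g3s: float


def composition_profile(counts: CodonCounts) -> CompositionProfile:
    """Count-weighted composition profile of a codon count table.

    When no synonymous codon was counted (e.g. a gene of only Met/Trp),
    the synonymous-third-position fields are NaN, never fabricated zeros.
    """
    if counts.n_codons < 1:
        raise ValueError("composition_profile requires at least one codon")

    gc_pos = [0, 0, 0]
    total = 0
    for codon, n in counts.counts.items():
        if n == 0:
            continue
        total += n
        for k in range(3):
            if codon[k] in _GC:
                gc_pos[k] += n

    gc1 = gc_pos[0] / total
    gc2 = gc_pos[1] / total
    gc3 = gc_pos[2] / total
    gc = (gc_pos[0] + gc_pos[1] + gc_pos[2]) / (3 * total)

    third = {"A": 0, "U": 0, "C": 0, "G": 0}
    syn_total = 0
    for codon in SYNONYMOUS_CODONS:
        n = counts.counts[codon]
        if n:
            third[codon[2]] += n
            syn_total += n

    if syn_total == 0:
        a3s = t3s = c3s = g3s = gc3s = math.nan
    else:
        a3s = third["A"] / syn_total
        t3s = third["U"] / syn_total
        c3s = third["C"] / syn_total
        g3s = third["G"] / syn_total
        gc3s = (third["C"] + third["G"]) / syn_total

    return CompositionProfile(
        gc=gc, gc1=gc1, gc2=gc2, gc12=(gc1 + gc2) / 2, gc3=gc3,
        gc3s=gc3s, a3s=a3s, t3s=t3s, c3s=c3s, g3s=g3s,
    )
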