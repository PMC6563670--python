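"""Synthetic CDS generation and packaged count fixtures.

The generator emulates the two forces the downstream analyses are built
to separate:

* mutational pressure — each gene carries its own probability ``m`` that
  a synonymous third position ends in G or C (drawn from a Beta prior
  whose default matches a GC-rich ascomycete gene set), and
* translational selection — a fraction of genes is marked highly
  expressed and uses one preferred codon per family with probability
  ``s``, mixing selection on top of the mutational background.

A coupling parameter ``k`` tilts each gene's amino-acid composition with
its ``m`` so that first/second-position GC co-varies with third-position
GC, inducing a non-zero neutrality-plot slope; at ``k = 0`` the slope is
zero in expectation.

The packaged fixtures are genome-wide and high/low-bias-pool codon count
tables for *Beauveria bassiana*, transcribed from a published study of
assembly ASM28067v1, so the index arithmetic is testable against printed
values with no download.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genetic_code import (
    AA_TO_CODONS,
    SINGLE_CODON_AAS,
    STOP_CODONS,
    to_dna,
)
from .genome_io import CdsRecord, CodonCounts

#: Gain applied to the amino-acid tilt at coupling k = 1; sets how much
#: first/second-position GC can respond to a gene's third-position bias.
COUPLING_GAIN = 6.0

_AMINO_ACIDS = tuple(sorted(aa for aa in AA_TO_CODONS if aa != "*"))
_STOPS = tuple(sorted(STOP_CODONS))


def default_preferred_codons() -> tuple[str, ...]:
    """One preferred codon per degenerate family: C-ending if available,
    else G-ending; alphabetical tie-break (Ser has two C-ending codons)."""
    chosen = []
    for aa in _AMINO_ACIDS:
        family = AA_TO_CODONS[aa]
        if len(family) == 1:
            continue
        c_ending = [c for c in family if c[2] == "C"]
        g_ending = [c for c in family if c[2] == "G"]
        chosen.append(sorted(c_ending or g_ending)[0])
    return tuple(chosen)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Generation parameters; defaults emulate a GC-rich fungal gene set.

    ``gc3_beta_a``/``gc3_beta_b`` give per-gene mutational GC3 bias
    ``m ~ Beta(a, b)`` (default mean 0.667, sd 0.108, matching the wide
    per-gene GC3s spread of an ascomycete genome); gene lengths are
    log-normal with a 400-codon median.
    """

    n_genes: int = 500
    length_median_codons: float = 400.0
    length_sigma: float = 0.45
    aa_freqs: Mapping[str, float] | None = None
    gc3_beta_a: float = 12.0
    gc3_beta_b: float = 6.0
    coupling_k: float = 0.0
    highly_expressed_fraction: float = 0.1
    selection_strength: float = 0.0
    preferred_codons: tuple[str, ...] = field(
        default_factory=default_preferred_codons
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("coupling_k", "highly_expressed_fraction",
                     "selection_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.selection_strength > 0 and not self.preferred_codons:
            raise ValueError(
                "selection_strength > 0 requires a preferred codon set"
            )
        seen_aas = set()
        for codon in self.preferred_codons:
            aa = _codon_aa(codon)
            if aa in seen_aas:
                raise ValueError(
                    f"two preferred codons for amino acid {aa}"
                )
            seen_aas.add(aa)


def _codon_aa(codon: str) -> str:
    from .genetic_code import CODON_TO_AA
    return CODON_TO_AA[codon]


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    per_gene: pd.DataFrame  # gene_id, m, highly_expressed, length_codons
    preferred_codons: tuple[str, ...]
    selection_strength: float
    coupling_k: float


# amino-acid-level constants used by the sampler -----------------------------

def _family_subsets() -> dict[str, tuple[list[str], list[str]]]:
    """Per amino acid: (G/C-ending codons, A/U-ending codons).

    For Ile the G-ending codon does not exist, so the G/C outcome maps to
    AUC alone; single-codon amino acids have one subset empty or trivial.
    """
    subsets = {}
    for aa in _AMINO_ACIDS:
        family = AA_TO_CODONS[aa]
        gc = sorted(c for c in family if c[2] in "GC")
        au = sorted(c for c in family if c[2] in "AU")
        subsets[aa] = (gc, au)
    return subsets


_SUBSETS = _family_subsets()


def _gc12_per_aa() -> np.ndarray:
    """Mean G+C fraction at codon positions 1-2 per amino acid (family
    average)."""
    out = []
    for aa in _AMINO_ACIDS:
        fam = AA_TO_CODONS[aa]
        vals = [sum(b in "GC" for b in c[:2]) / 2.0 for c in fam]
        out.append(sum(vals) / len(vals))
    return np.asarray(out)


_AA_GC12 = _gc12_per_aa()


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based substream: gene i's draws never depend on n_genes
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    )


def simulate_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[list[CdsRecord], GroundTruth]:
    """Generate stop-terminated ORFs under the spec; deterministic per seed."""
    if spec.aa_freqs is None:
        base_freqs = np.full(len(_AMINO_ACIDS), 1.0 / len(_AMINO_ACIDS))
    else:
        base_freqs = np.array(
            [spec.aa_freqs.get(aa, 0.0) for aa in _AMINO_ACIDS], dtype=float
        )
        if base_freqs.sum() <= 0:
            raise ValueError("aa_freqs must have positive total mass")
        base_freqs = base_freqs / base_freqs.sum()

    preferred_by_aa = {_codon_aa(c): c for c in spec.preferred_codons}
    records: list[CdsRecord] = []
    truth_rows = []
    mean_gc12 = float((base_freqs * _AA_GC12).sum())

    for i in range(spec.n_genes):
        rng = _gene_rng(spec.seed, i)
        length = max(
            10,
            int(round(spec.length_median_codons
                      * math.exp(spec.length_sigma * rng.standard_normal()))),
        )
        m = float(rng.beta(spec.gc3_beta_a, spec.gc3_beta_b))
        highly_expressed = bool(
            rng.random() < spec.highly_expressed_fraction
        )

        if spec.coupling_k > 0:
            tilt = np.exp(
                spec.coupling_k * COUPLING_GAIN * (m - 0.5)
                * (_AA_GC12 - mean_gc12)
            )
            freqs = base_freqs * tilt
            freqs = freqs / freqs.sum()
        else:
            freqs = base_freqs

        aa_idx = rng.choice(len(_AMINO_ACIDS), size=length, p=freqs)
        s = spec.selection_strength if highly_expressed else 0.0
        use_pref = (
            rng.random(length) < s if s > 0
            else np.zeros(length, dtype=bool)
        )
        gc_outcome = rng.random(length) < m
        subset_pick = rng.random(length)

        codons = []
        for pos in range(length):
            aa = _AMINO_ACIDS[aa_idx[pos]]
            if use_pref[pos] and aa in preferred_by_aa:
                codons.append(preferred_by_aa[aa])
                continue
            gc_set, au_set = _SUBSETS[aa]
            subset = gc_set if (gc_outcome[pos] and gc_set) else (
                au_set or gc_set
            )
            codons.append(subset[int(subset_pick[pos] * len(subset))])

        stop = _STOPS[int(rng.integers(len(_STOPS)))]
        seq = "".join(to_dna(c) for c in codons) + to_dna(stop)
        gene_id = f"gene{i:05d}"
        records.append(CdsRecord(id=gene_id, seq=seq))
        truth_rows.append({
            "gene_id": gene_id,
            "m": m,
            "highly_expressed": int(highly_expressed),
            "length_codons": length + 1,
        })

    truth = GroundTruth(
        per_gene=pd.DataFrame(truth_rows),
        preferred_codons=spec.preferred_codons,
        selection_strength=spec.selection_strength,
        coupling_k=spec.coupling_k,
    )
    return records, truth


def write_ground_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "wt") as out:
        out.write("gene_id\tm\thighly_expressed\tlength_codons\n")
        for row in truth.per_gene.itertuples(index=False):
            out.write(
                f"{row.gene_id}\t{row.m:.8f}\t{row.highly_expressed}"
                f"\t{row.length_codons}\n"
            )


# --- packaged fixtures -------------------------------------------------------

def _read_fixture(name: str) -> pd.DataFrame:
    path = resources.files("cubkit").joinpath("data", name)
    with path.open("rt") as handle:
        return pd.read_csv(handle, sep="\t", comment="#")


def bassiana_genome_counts() -> CodonCounts:
    """Genome-wide pooled codon counts of the B. bassiana CDS set."""
    frame = _read_fixture("bassiana_genome_counts.tsv")
    return CodonCounts.from_mapping(
        dict(zip(frame["codon"], frame["count"]))
    )


def bassiana_genome_printed_rscu() -> dict[str, float]:
    """RSCU values printed alongside the genome-wide counts."""
    frame = _read_fixture("bassiana_genome_counts.tsv")
    return dict(zip(frame["codon"], frame["printed_rscu"].astype(float)))


def bassiana_pool_counts() -> tuple[CodonCounts, CodonCounts]:
    """(high-bias, low-bias) pooled codon counts of the B. bassiana set."""
    frame = _read_fixture("bassiana_pool_counts.tsv")
    high = frame[frame["pool"] == "high"]
    low = frame[frame["pool"] == "low"]
    return (
        CodonCounts.from_mapping(dict(zip(high["codon"], high["count"]))),
        CodonCounts.from_mapping(dict(zip(low["codon"], low["count"]))),
    )


def bassiana_pool_printed() -> pd.DataFrame:
    """Full pool fixture with printed RSCU and ambiguity flags."""
    return _read_fixture("bassiana_pool_counts.tsv")
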