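"""Reading, validating and codon-tokenizing coding sequences.

Codon count tables (:class:`CodonCounts`) are the common currency of every
downstream module: per-gene tables feed the per-gene indices, and pooled
tables feed genome-wide RSCU and the high/low-bias contrasts.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from Bio import SeqIO

from .genetic_code import ALL_CODONS, CODON_TO_AA, to_rna

_DNA_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence; the unit of per-gene analysis.

    ``seq`` is stored uppercase in the DNA alphabet (U mapped to T on
    read); IUPAC ambiguity letters are kept and handled at codon counting.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("CdsRecord requires a non-empty id")
        if len(self.seq) < 3:
            raise ValueError(
                f"record {self.id!r}: sequence shorter than one codon"
            )


@dataclass
class CodonCounts:
    """A 64-slot codon count vector (per gene or pooled).

    ``n_skipped`` tallies in-frame triplets dropped because they contain a
    non-ACGT base; it keeps totals auditable: for an in-frame gene,
    ``n_codons + n_skipped == len(seq) // 3``.
    """

    counts: dict[str, int]
    n_codons: int
    n_skipped: int = 0

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, int], n_skipped: int = 0
    ) -> "CodonCounts":
        """Build a full 64-slot table from a (possibly sparse) mapping.

        Keys may be DNA or RNA codons; they are re-keyed to RNA.
        """
        counts = {c: 0 for c in ALL_CODONS}
        for codon, n in mapping.items():
            key = to_rna(codon.upper())
            if key not in counts:
                raise ValueError(f"not a codon: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon!r}")
            counts[key] += int(n)
        return cls(counts=counts, n_codons=sum(counts.values()),
                   n_skipped=n_skipped)

    @classmethod
    def zero(cls) -> "CodonCounts":
        return cls(counts={c: 0 for c in ALL_CODONS}, n_codons=0)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        counts = {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        return CodonCounts(
            counts=counts,
            n_codons=self.n_codons + other.n_codons,
            n_skipped=self.n_skipped + other.n_skipped,
        )

    def __getitem__(self, codon: str) -> int:
        return self.counts[to_rna(codon.upper())]


@dataclass(frozen=True)
class QcConfig:
    """Gene-level quality filters.

    Length-multiple-of-3 is always enforced; the other two filters are off
    by default so that whole annotated CDS sets pass untouched.
    """

    min_codons: int | None = None
    reject_internal_stops: bool = False


@dataclass
class QcReport:
    n_input: int
    n_kept: int
    reasons: dict[str, int] = field(default_factory=dict)


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    """Read a (plain or gzipped) CDS FASTA into a list of records.

    Sequences are uppercased and U is mapped to T; record ids must be
    unique and sequences non-empty.
    """
    records: list[CdsRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq:
                raise ValueError(f"record {rec.id!r} has an empty sequence")
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append(CdsRecord(id=rec.id, seq=seq))
    return records


def write_cds_fasta(records: Iterable[CdsRecord], path: str | Path,
                    width: int = 70) -> None:
    """Write records as FASTA with fixed line wrapping (deterministic)."""
    with open(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i:i + width] + "\n")


def qc_filter(
    records: Sequence[CdsRecord], config: QcConfig | None = None
) -> tuple[list[CdsRecord], QcReport]:
    """Filter genes; never raises — every rejection lands in the report.

    A gene is counted under the first filter it fails, in the order:
    length_not_multiple_of_3, too_few_codons, internal_stop.
    """
    config = config or QcConfig()
    kept: list[CdsRecord] = []
    reasons: dict[str, int] = {}

    def reject(reason: str) -> None:
        reasons[reason] = reasons.get(reason, 0) + 1

    for rec in records:
        if len(rec.seq) % 3 != 0:
            reject("length_not_multiple_of_3")
            continue
        n_codons = len(rec.seq) // 3
        if config.min_codons is not None and n_codons < config.min_codons:
            reject("too_few_codons")
            continue
        if config.reject_internal_stops and _has_internal_stop(rec.seq):
            reject("internal_stop")
            continue
        kept.append(rec)
    return kept, QcReport(n_input=len(records), n_kept=len(kept),
                          reasons=reasons)


def _has_internal_stop(seq: str) -> bool:
    for i in range(0, len(seq) - 3, 3):
        codon = seq[i:i + 3]
        if set(codon) <= _DNA_BASES and CODON_TO_AA[to_rna(codon)] == "*":
            return True
    return False


def count_codons(record: CdsRecord) -> CodonCounts:
    """Tokenize an in-frame CDS into non-overlapping codons.

    Triplets containing any non-ACGT base (N or other IUPAC ambiguity
    letters) are skipped and tallied in ``n_skipped`` rather than imputed.
    """
    seq = record.seq
    if len(seq) % 3 != 0:
        raise ValueError(
            f"record {record.id!r}: length {len(seq)} is not a multiple of 3"
        )
    counts = {c: 0 for c in ALL_CODONS}
    n_skipped = 0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if set(codon) <= _DNA_BASES:
            counts[to_rna(codon)] += 1
        else:
            n_skipped += 1
    return CodonCounts(counts=counts, n_codons=len(seq) // 3 - n_skipped,
                       n_skipped=n_skipped)


def pool_counts(tables: Iterable[CodonCounts]) -> CodonCounts:
    """Elementwise sum of count tables (associative, commutative)."""
    total = CodonCounts.zero()
    for t in tables:
        total = total + t
    return total


def translate(record: CdsRecord) -> str:
    """Translate an in-frame CDS with the standard code.

    Stops render as ``*`` and ambiguous codons as ``X``, so the protein
    length always equals the in-frame codon count.
    """
    seq = record.seq
    if len(seq) % 3 != 0:
        raise ValueError(
            f"record {record.id!r}: length {len(seq)} is not a multiple of 3"
        )
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if set(codon) <= _DNA_BASES:
            out.append(CODON_TO_AA[to_rna(codon)])
        else:
            out.append("X")
    return "".join(out)


# --- count-table TSV dialects ------------------------------------------------

def read_counts_tsv(path: str | Path) -> CodonCounts:
    """Read a two-column ``codon<TAB>count`` TSV (RNA or DNA codons).

    Lines starting with ``#`` are comments; an optional header line with
    non-numeric second field is skipped.
    """
    mapping: dict[str, int] = {}
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed counts line: {line!r}")
            try:
                n = int(parts[1])
            except ValueError:
                continue  # header line
            key = to_rna(parts[0].upper())
            mapping[key] = mapping.get(key, 0) + n
    if not mapping:
        raise ValueError(f"no codon counts found in {path}")
    return CodonCounts.from_mapping(mapping)


def write_counts_tsv(counts: CodonCounts, path: str | Path) -> None:
    with open(path, "wt") as out:
        out.write("codon\tcount\n")
        for codon in ALL_CODONS:
            out.write(f"{codon}\t{counts.counts[codon]}\n")


def write_gene_counts_tsv(
    per_gene: Mapping[str, CodonCounts], path: str | Path
) -> None:
    """Wide per-gene table: gene_id, 64 codon columns, n_skipped."""
    with open(path, "wt") as out:
        out.write("gene_id\t" + "\t".join(ALL_CODONS) + "\tn_skipped\n")
        for gene_id in per_gene:
            c = per_gene[gene_id]
            row = "\t".join(str(c.counts[codon]) for codon in ALL_CODONS)
            out.write(f"{gene_id}\t{row}\t{c.n_skipped}\n")
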