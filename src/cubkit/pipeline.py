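"""End-to-end analysis pipeline and report assembly.

``run_pipeline`` takes a CDS FASTA through QC, per-gene counting,
composition and indices, correspondence analysis, Spearman correlations,
the neutrality regression, ENC-plot data, the ENC-ranked partition and
optimal-codon detection, writing one TSV per result plus a JSON manifest
that records everything needed to reproduce the run bit-exactly.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bias_analysis import (
    correspondence_analysis,
    enc_plot_frame,
    format_correlation_table,
    neutrality_regression,
    rscu_matrix,
    spearman_matrix,
)
from .genome_io import (
    QcConfig,
    pool_counts,
    read_cds_fasta,
    qc_filter,
    write_gene_counts_tsv,
)
from .indices import compute_rscu, derive_cai_weights, gene_indices_frame
from .genome_io import read_counts_tsv
from .optimal_codons import (
    DEFAULT_ALPHA,
    DEFAULT_DELTA_THRESHOLD,
    DEFAULT_POOL_FRACTION,
    detect_optimal_codons,
    partition_by_enc,
)

HIGH_BIAS_ENC_CUTOFF = 35.0

TSV_OUTPUTS = [
    "codon_counts.tsv",
    "gene_indices.tsv",
    "rscu_pooled.tsv",
    "neutrality_fit.tsv",
    "enc_plot.tsv",
    "coa_genes.tsv",
    "coa_codons.tsv",
    "correlation_spearman.tsv",
    "optimal_codons.tsv",
]


class PipelineError(RuntimeError):
    """Raised with a stage-named message when a stage cannot proceed."""


@dataclass
class PipelineConfig:
    input: Path
    outdir: Path
    min_codons: int | None = None
    reject_internal_stops: bool = False
    pool_fraction: float = DEFAULT_POOL_FRACTION
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    cai_reference: str = "auto"  # "auto" or a codon/count TSV path
    enc_bias_cutoff: float = HIGH_BIAS_ENC_CUTOFF
    plots: bool = False
    n_axes: int = 2

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["input"] = str(self.input)
        d["outdir"] = str(self.outdir)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_frame(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f",
                 lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        records = read_cds_fasta(config.input)
    except (OSError, ValueError) as exc:
        raise PipelineError(f"read: {exc}") from exc

    qc = QcConfig(min_codons=config.min_codons,
                  reject_internal_stops=config.reject_internal_stops)
    kept, report = qc_filter(records, qc)
    if not kept:
        raise PipelineError(
            f"qc: no genes left after filtering "
            f"({report.n_input} read, reasons {report.reasons})"
        )

    if config.cai_reference == "auto":
        frame, per_gene, weights = gene_indices_frame(kept)
    else:
        ref_counts = read_counts_tsv(config.cai_reference)
        weights = derive_cai_weights(
            ref_counts, provenance=f"file: {config.cai_reference}"
        )
        frame, per_gene, weights = gene_indices_frame(
            kept, cai_weights=weights
        )

    write_gene_counts_tsv(per_gene, outdir / "codon_counts.tsv")

    pooled = pool_counts(per_gene.values())
    rscu_frame = compute_rscu(pooled).to_frame()
    _write_frame(rscu_frame.drop(columns=["family_size"]),
                 outdir / "rscu_pooled.tsv")

    # correspondence analysis, axes written back into the index table
    matrix, filled = rscu_matrix(per_gene)
    try:
        coa = correspondence_analysis(matrix, n_axes=config.n_axes)
    except ValueError as exc:
        raise PipelineError(f"coa: {exc}") from exc
    frame = frame.set_index("gene_id")
    frame.loc[coa.row_coordinates.index, "axis1"] = \
        coa.row_coordinates["axis1"]
    frame.loc[coa.row_coordinates.index, "axis2"] = \
        coa.row_coordinates["axis2"]
    frame = frame.reset_index()
    _write_frame(frame, outdir / "gene_indices.tsv")
    _write_frame(coa.row_coordinates.reset_index(names="gene_id"),
                 outdir / "coa_genes.tsv")
    _write_frame(coa.column_coordinates.reset_index(names="codon"),
                 outdir / "coa_codons.tsv")

    # neutrality regression
    try:
        fit = neutrality_regression(frame["gc12"], frame["gc3"])
    except ValueError as exc:
        raise PipelineError(f"neutrality: {exc}") from exc
    fit_frame = pd.DataFrame([{
        "slope": fit.slope, "intercept": fit.intercept,
        "pearson_r": fit.pearson_r, "r_squared": fit.r_squared,
        "p_value": fit.p_value, "mutation_pct": fit.mutation_pct,
        "other_pct": fit.other_pct, "n_genes": fit.n_genes,
    }])
    _write_frame(fit_frame, outdir / "neutrality_fit.tsv")

    _write_frame(enc_plot_frame(frame), outdir / "enc_plot.tsv")

    # Spearman correlation matrix (rho block, then p block)
    try:
        cm = spearman_matrix(frame)
    except ValueError as exc:
        raise PipelineError(f"correlation: {exc}") from exc
    with open(outdir / "correlation_spearman.tsv", "wt") as out:
        out.write("# block: rho\n")
        cm.rho.to_csv(out, sep="\t", float_format="%.6f",
                      index_label="variable", lineterminator="\n")
        out.write("# block: p\n")
        cm.p.to_csv(out, sep="\t", float_format="%.6g",
                    index_label="variable", lineterminator="\n")

    # optimal codons from the ENC-ranked partition
    enc_by_gene = dict(zip(frame["gene_id"], frame["enc"]))
    try:
        partition = partition_by_enc(enc_by_gene, per_gene,
                                     config.pool_fraction)
        optimal = detect_optimal_codons(
            partition, delta_threshold=config.delta_threshold,
            alpha=config.alpha,
        )
    except ValueError as exc:
        raise PipelineError(f"optimal_codons: {exc}") from exc
    _write_frame(optimal, outdir / "optimal_codons.tsv")

    if config.plots:
        _write_plots(frame, fit, outdir)

    manifest = {
        "tool": "cubkit",
        "version": __version__,
        "config": config.to_dict(),
        "input_sha256": _sha256(Path(config.input)),
        "cai_reference": weights.provenance,
        "stages": {
            "genes_read": report.n_input,
            "genes_kept": report.n_kept,
            "qc_reasons": report.reasons,
            "genes_indexed": int(len(frame)),
            "coa_rank": coa.rank,
            "partition_high": len(partition.high_genes),
            "partition_low": len(partition.low_genes),
            "partition_excluded": partition.n_excluded,
            "n_codons_high": partition.n_codons_high,
            "n_codons_low": partition.n_codons_low,
        },
        "outputs": TSV_OUTPUTS,
    }
    with open(outdir / "manifest.json", "wt") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
        out.write("\n")

    with open(outdir / "summary.txt", "wt") as out:
        out.write(summarize(outdir))

    return manifest


def _write_plots(frame: pd.DataFrame, fit, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(frame["gc3"], frame["gc12"], s=4, alpha=0.4)
    xs = np.linspace(frame["gc3"].min(), frame["gc3"].max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "k-")
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    fig.savefig(outdir / "neutrality_plot.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(frame["gc3s"], frame["enc"], s=4, alpha=0.4)
    xs = np.linspace(0.01, 0.99, 200)
    ax.plot(xs, 2 + xs + 29 / (xs ** 2 + (1 - xs) ** 2), "k-")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    fig.savefig(outdir / "enc_plot.png", dpi=150)
    plt.close(fig)


def summarize(outdir: str | Path,
              enc_cutoff: float = HIGH_BIAS_ENC_CUTOFF) -> str:
    """One-page text summary recomputed entirely from the bundle TSVs."""
    outdir = Path(outdir)
    missing = [f for f in TSV_OUTPUTS if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete bundle, missing: {', '.join(missing)}"
        )

    idx = pd.read_csv(outdir / "gene_indices.tsv", sep="\t")
    rscu = pd.read_csv(outdir / "rscu_pooled.tsv", sep="\t")
    fit = pd.read_csv(outdir / "neutrality_fit.tsv", sep="\t").iloc[0]
    opt = pd.read_csv(outdir / "optimal_codons.tsv", sep="\t")

    sense = rscu[rscu["amino_acid"] != "*"]
    n_rscu_gt1 = int((sense["rscu"] > 1.0 + 1e-9).sum())
    opt_codons = opt[opt["optimal"] == 1]["codon"].tolist()
    n_gc_ending = sum(1 for c in opt_codons if c[2] in "GC")
    n_high_bias = int((idx["enc"] < enc_cutoff).sum())

    lines = [
        "codon usage bias summary",
        "========================",
        f"genes analyzed: {len(idx)}",
        "",
        "per-gene statistics (mean±sd):",
    ]
    for col in ["gc", "gc1", "gc2", "gc3", "gc3s", "a3s", "t3s", "c3s",
                "g3s", "enc", "cai", "gravy", "aromo"]:
        vals = idx[col].dropna()
        if len(vals):
            lines.append(f"  {col:6s} {vals.mean():8.4f} ± {vals.std():.4f}")
    lines += [
        "",
        f"sense codons with RSCU > 1: {n_rscu_gt1}",
        f"optimal codons: {len(opt_codons)}"
        f" (G/C-ending: {n_gc_ending})",
        f"neutrality slope: {fit['slope']:.4f}"
        f" (mutation {fit['mutation_pct']:.2f}%, "
        f"other {fit['other_pct']:.2f}%)",
        f"genes with ENC < {enc_cutoff:g}: {n_high_bias}",
        "",
    ]
    if opt_codons:
        lines.insert(-1, "optimal codon set: " + " ".join(sorted(opt_codons)))
    return "\n".join(lines) + "\n"
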