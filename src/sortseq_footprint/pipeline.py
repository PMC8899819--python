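"""End-to-end orchestration: simulate -> preprocess -> footprint, with manifests.

A run is driven by a single :class:`PipelineConfig` and a single top-level
seed; per-stage seeds are derived deterministically, so an identical
config + seed reproduces byte-identical artifacts.  Artifacts are written
as plain TSV/FASTQ/FASTA plus a JSON manifest carrying SHA-256 checksums
of every output and of the serialized configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as seqio
from .footprint import (
    FootprintOptions,
    enrichment_map,
    information_footprint,
    rank_positions,
)
from .preprocess import (
    collapse_unique,
    count_bases,
    filter_ambiguous,
    filter_by_length,
    filter_hypermutated,
    mutation_frequency,
    substitution_spectrum,
    trim_counts,
)
from .reference import ReferenceAmplicon, bmo_reference
from .simulate import (
    EpPCRModel,
    SortGates,
    default_expression_model,
    emit_reads,
    mutagenize_library,
    sort_cells,
)

logger = logging.getLogger(__name__)

MODES = ("simulate", "analyze", "end_to_end")
BIN_FILES = {"unsorted": "unsorted.fastq", "low": "low.fastq", "high": "high.fastq"}


@dataclass
class PipelineConfig:
    """Everything a run needs: stage selection, model parameters, paths."""

    mode: str = "end_to_end"
    seed: int = 0
    outdir: str = "sortseq_run"
    # analyze-mode inputs (ignored when simulating)
    reference_fasta: str | None = None
    unsorted_reads: str | None = None
    low_reads: str | None = None
    high_reads: str | None = None
    # simulator parameters
    n_variants: int = 10_000
    per_position_rate: float = 0.05
    n_cells: int = 100_000
    high_fraction: float = 0.05
    low_fraction: float = 0.10
    noise_sd: float = 0.3
    seq_error_rate: float = 0.001
    n_reads_per_bin: int | None = None  # None: one read per sorted cell
    # preprocessing parameters
    trim_width: int = 20
    max_hamming: int = 20
    weighting: str = "unique"
    # footprint parameters
    bin_weighting: str = "equal"
    pseudocount_mi: float = 0.0
    pseudocount_enrichment: float = 1.0
    make_figures: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "analyze":
            missing = [
                name
                for name, path in [
                    ("unsorted_reads", self.unsorted_reads),
                    ("low_reads", self.low_reads),
                    ("high_reads", self.high_reads),
                ]
                if path is None
            ]
            if missing:
                raise ValueError(f"analyze mode requires read paths: {missing}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def derive_stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds (< 2**31) from one top-level seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def _load_reference(config: PipelineConfig) -> ReferenceAmplicon:
    if config.reference_fasta:
        return ReferenceAmplicon(
            seqio.read_reference_fasta(config.reference_fasta),
            trim_width=config.trim_width,
        )
    return bmo_reference(trim_width=config.trim_width)


def simulate_stage(
    config: PipelineConfig, reference: ReferenceAmplicon
) -> dict:
    """Generate the library, sort it, and sequence the three pools."""
    seeds = derive_stage_seeds(config.seed)
    ep = EpPCRModel(per_position_rate=config.per_position_rate)
    expr = default_expression_model(reference, noise_sd=config.noise_sd)
    gates = SortGates(config.high_fraction, config.low_fraction)
    library = mutagenize_library(reference, ep, config.n_variants, seed=seeds[0])
    pools = sort_cells(library, expr, gates, config.n_cells, seed=seeds[1])
    reads = {}
    for i, (label, pool) in enumerate(
        [("unsorted", pools.unsorted), ("low", pools.low), ("high", pools.high)]
    ):
        reads[label] = emit_reads(
            pool,
            config.seq_error_rate,
            seed=seeds[2 + i],
            n_reads=config.n_reads_per_bin,
        )
    return {"library": library, "pools": pools, "reads": reads, "expression_model": expr}


def preprocess_reads(
    raw_reads: list[str],
    reference: ReferenceAmplicon,
    bin_label: str,
    max_hamming: int = 20,
    weighting: str = "unique",
    trim_width: int | None = None,
) -> dict:
    """Run the full filter/collapse/count chain on one bin's reads.

    Returns the retained unique-read set, the trimmed count matrix, and a
    filter report of survivor counts after each step.
    """
    tw = reference.trim_width if trim_width is None else trim_width
    unambiguous = filter_ambiguous(raw_reads)
    sized = filter_by_length(unambiguous, min_length=len(reference), strict=True)
    readset = collapse_unique(sized, bin_label)
    readset, n_hyper = filter_hypermutated(readset, reference, max_distance=max_hamming)
    counts_full = count_bases(readset, reference, weighting=weighting)
    counts = trim_counts(counts_full, trim_width=tw) if tw else counts_full
    report = {
        "bin": bin_label,
        "raw": len(raw_reads),
        "post_ambiguity": len(unambiguous),
        "post_length": len(sized),
        "unique": readset.n_unique + n_hyper,
        "post_hamming": readset.n_unique,
        "hypermutated_removed": n_hyper,
    }
    return {
        "readset": readset,
        "counts": counts,
        "counts_untrimmed": counts_full,
        "report": report,
    }


def analyze_stage(
    reads_by_bin: dict[str, list[str]],
    reference: ReferenceAmplicon,
    config: PipelineConfig,
) -> dict:
    """Preprocess every bin and compute footprint + enrichment statistics."""
    options = FootprintOptions(
        bin_weighting=config.bin_weighting, pseudocount=config.pseudocount_mi
    )
    processed = {
        label: preprocess_reads(
            reads,
            reference,
            label,
            max_hamming=config.max_hamming,
            weighting=config.weighting,
            trim_width=config.trim_width,
        )
        for label, reads in reads_by_bin.items()
    }
    warnings: list[str] = []
    result: dict = {"processed": processed, "warnings": warnings, "options": options}
    empty = [lbl for lbl, p in processed.items() if p["counts"].library_total == 0]
    for lbl in empty:
        warnings.append(f"bin '{lbl}' has no reads surviving the filters")
    if {"low", "high"} - set(empty) == {"low", "high"}:
        result["footprint"] = information_footprint(
            processed["low"]["counts"], processed["high"]["counts"], options
        )
    else:
        warnings.append("footprint omitted: an expression bin is empty")
    if "unsorted" in processed and "unsorted" not in empty:
        uns = processed["unsorted"]
        result["mutation_frequency"] = mutation_frequency(
            uns["counts_untrimmed"], reference
        )
        result["spectrum"] = substitution_spectrum(uns["readset"], reference)
        result["enrichment"] = {}
        for lbl in ("low", "high"):
            if lbl not in empty and lbl in processed:
                result["enrichment"][lbl] = enrichment_map(
                    processed[lbl]["counts"],
                    uns["counts"],
                    pseudocount=config.pseudocount_enrichment,
                    bin_label=lbl,
                )
    return result


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write artifacts plus a manifest.

    Returns the manifest (also written to ``<outdir>/manifest.json``):
    config echo + checksum, per-file SHA-256 checksums, filter reports and
    any warnings.  Identical config + seed reproduce identical checksums.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = _load_reference(config)
    files: list[str] = []
    warnings: list[str] = []
    reports: list[dict] = []

    reads_by_bin: dict[str, list[str]] | None = None
    if config.mode in ("simulate", "end_to_end"):
        sim = simulate_stage(config, reference)
        seqio.write_fasta([reference.sequence], outdir / "reference.fasta", "reference")
        files.append("reference.fasta")
        for label, fname in BIN_FILES.items():
            seqio.write_fastq(sim["reads"][label], outdir / fname, prefix=label)
            files.append(fname)
        reads_by_bin = sim["reads"]

    if config.mode == "analyze":
        reads_by_bin = {
            "unsorted": seqio.read_sequences(config.unsorted_reads),
            "low": seqio.read_sequences(config.low_reads),
            "high": seqio.read_sequences(config.high_reads),
        }

    if config.mode in ("analyze", "end_to_end"):
        analysis = analyze_stage(reads_by_bin, reference, config)
        warnings.extend(analysis["warnings"])
        for label, proc in analysis["processed"].items():
            fname = f"counts_{label}.tsv"
            proc["counts"].to_tsv(outdir / fname)
            files.append(fname)
            reports.append(proc["report"])
        if "footprint" in analysis:
            fname = "footprint.tsv"
            analysis["footprint"].to_frame().to_csv(outdir / fname, sep="\t")
            files.append(fname)
        if "mutation_frequency" in analysis:
            mf = analysis["mutation_frequency"].rename_axis("position")
            mf.to_csv(outdir / "mutation_frequency.tsv", sep="\t")
            files.append("mutation_frequency.tsv")
            analysis["spectrum"].to_frame().rename_axis("substitution").to_csv(
                outdir / "substitution_spectrum.tsv", sep="\t"
            )
            files.append("substitution_spectrum.tsv")
        for lbl, emap in analysis.get("enrichment", {}).items():
            fname = f"enrichment_{lbl}.tsv"
            emap.to_long().to_csv(outdir / fname, sep="\t", index=False)
            files.append(fname)
        if config.make_figures and "footprint" in analysis:
            from .plotting import plot_enrichment_heatmap, plot_footprint

            plot_footprint(analysis["footprint"], outdir / "footprint.png")
            files.append("footprint.png")
            for lbl, emap in analysis.get("enrichment", {}).items():
                plot_enrichment_heatmap(emap, outdir / f"enrichment_{lbl}.png")
                files.append(f"enrichment_{lbl}.png")
        pd.DataFrame(reports).to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        files.append("filter_report.tsv")

    config.to_yaml(outdir / "config.yaml")
    files.append("config.yaml")
    config_blob = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True).encode()
    manifest = {
        "mode": config.mode,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_sha256": hashlib.sha256(config_blob).hexdigest(),
        "files": {f: _sha256(outdir / f) for f in sorted(files)},
        "filter_reports": reports,
        "warnings": warnings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def summarize_run(manifest: dict, outdir: str | Path | None = None, top_k: int = 15) -> str:
    """Human-readable report of one pipeline run.

    Lists survivor counts per filter, mean mutation frequency, the top-k MI
    positions and the most extreme enrichment entries.  Missing artifacts
    are flagged rather than fatal.
    """
    outdir = Path(outdir if outdir is not None else manifest["config"]["outdir"])
    lines = [
        "sort-seq run summary",
        f"  mode: {manifest['mode']}   seed: {manifest['seed']}",
        f"  config checksum: {manifest['config_sha256'][:12]}",
    ]
    for warning in manifest.get("warnings", []):
        lines.append(f"  WARNING: {warning}")
    for report in manifest.get("filter_reports", []):
        lines.append(
            "  [{bin}] raw={raw} unambiguous={post_ambiguity} "
            "full-length={post_length} unique={unique} "
            "kept={post_hamming} (hypermutated removed: {hypermutated_removed})".format(
                **report
            )
        )
    mf_path = outdir / "mutation_frequency.tsv"
    if mf_path.exists():
        mf = pd.read_csv(mf_path, sep="\t", index_col=0)["mutation_frequency"]
        lines.append(f"  mean mutation frequency (unsorted): {mf.mean():.4f}")
    fp_path = outdir / "footprint.tsv"
    if fp_path.exists():
        fp = pd.read_csv(fp_path, sep="\t", index_col=0)["mi_bits"]
        top = fp.sort_values(ascending=False).head(top_k)
        ranked = ", ".join(f"P{p}={v:.3g}" for p, v in top.items())
        lines.append(f"  top-{top_k} MI positions (bits): {ranked}")
    else:
        lines.append("  footprint: not available")
    for lbl in ("low", "high"):
        epath = outdir / f"enrichment_{lbl}.tsv"
        if epath.exists():
            em = pd.read_csv(epath, sep="\t")
            hi = em.loc[em["log2_ratio"].idxmax()]
            lo = em.loc[em["log2_ratio"].idxmin()]
            lines.append(
                f"  enrichment [{lbl}]: most enriched P{int(hi['position'])}"
                f"{hi['base']} ({hi['log2_ratio']:+.2f}), most depleted "
                f"P{int(lo['position'])}{lo['base']} ({lo['log2_ratio']:+.2f})"
            )
    return "\n".join(lines)
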