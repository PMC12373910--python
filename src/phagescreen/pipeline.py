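"""End-to-end screen pipelines with run manifests.

Two orchestrations over the library modules:

* the accessory-gene (AG) screen: FASTQ -> barcode counts -> fitness
  scores -> representation flags -> paired t-tests -> hit calls;
* the Tn5 screen: characterization FASTQ -> fragment parsing ->
  duplicate collapse -> barcode/insertion-site map (dominance and
  vector filters) -> BarSeq counting -> gene aggregation -> the same
  fitness procedure with two replicates.

Every run writes TSV tables, a plain-text log with per-stage record
counts (a whole-pipeline conservation audit) and a machine-readable
``manifest.json`` recording the package version, thresholds, seed and
SHA-256 digests of all inputs and outputs.  Runs contain no hidden
randomness, so identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import read_design, read_fasta, read_fastq_sequences, sha256_file
from .library import BarcodeLibrary
from .quant import count_barcodes
from .fitness import score_screen
from .tables import CountTable
from .tnmap import build_map, dedupe, gene_counts, parse_fragments

__all__ = [
    "Thresholds",
    "AGConfig",
    "TnseqConfig",
    "PipelineError",
    "run_ag_pipeline",
    "run_tnseq_pipeline",
]


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class Thresholds:
    """The screen-analysis thresholds, centralized.

    Defaults are the screen procedure's: pseudocount 1 before
    normalization, low-read cutoff 100, MAD multiplier 3, P <= 0.2
    reproducibility gate, 4-fold effect gate, >0.9 insertion-site
    dominance.
    """

    pseudocount: float = 1.0
    read_cutoff: int = 100
    mad_k: float = 3.0
    p_cutoff: float = 0.2
    fold_cutoff: float = 4.0
    dominance: float = 0.9

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"threshold {name} must be positive, got {v}")


def _require(path: str | Path, what: str, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"[{stage}] {what} not found: {p}")
    return p


@dataclass
class AGConfig:
    library: str
    design: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    paired: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AGConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


@dataclass
class TnseqConfig:
    genome: str
    annotation: str
    refmap_fastq: str
    design: str
    vector: str | None = None
    barseq_counts: str | None = None  # precomputed counts TSV instead of per-sample FASTQ
    thresholds: Thresholds = field(default_factory=Thresholds)
    paired: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TnseqConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


def _load_design_with_fastq(path: Path, need_fastq: bool, stage: str) -> pd.DataFrame:
    design = read_design(path)
    if need_fastq:
        if "fastq" not in design.columns:
            raise PipelineError(f"[{stage}] design lacks a 'fastq' column")
        for _, row in design.iterrows():
            _require(row["fastq"], f"FASTQ for sample {row['sample_id']}", stage)
    return design


def _count_samples(design: pd.DataFrame, library: BarcodeLibrary, log: list[str]) -> CountTable:
    table: CountTable | None = None
    for _, row in design.iterrows():
        reads = read_fastq_sequences(row["fastq"])
        col = count_barcodes(reads, library, sample_id=row["sample_id"])
        log.append(
            f"count[{row['sample_id']}]: total={len(reads)} "
            + " ".join(f"{k}={int(col.audit.iloc[0][k])}" for k in col.audit.columns)
        )
        table = col if table is None else table.join(col)
    assert table is not None
    return table


def _write_manifest(
    outdir: Path,
    pipeline: str,
    config,
    inputs: dict[str, str],
    outputs: list[Path],
    log: list[str],
) -> Path:
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    manifest = {
        "pipeline": pipeline,
        "package": "phagescreen",
        "version": __version__,
        "seed": config.seed,
        "thresholds": asdict(config.thresholds),
        "inputs": {k: sha256_file(k) for k in sorted(inputs)},
        "outputs": {p.name: sha256_file(p) for p in sorted(outputs)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_ag_pipeline(config: AGConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the AG screen end to end; returns paths of the written outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"phagescreen {__version__} ag pipeline"]

    # fail-fast validation before any compute
    lib_path = _require(config.library, "library manifest", "validate")
    design_path = _require(config.design, "design table", "validate")
    design = _load_design_with_fastq(design_path, need_fastq=True, stage="validate")

    library = BarcodeLibrary.from_tsv(lib_path)
    log.append(f"library: {len(library)} members, dialect {library.dialect}")

    counts = _count_samples(design, library, log)
    thr = config.thresholds
    effects = score_screen(
        counts,
        design,
        pseudocount=thr.pseudocount,
        read_cutoff=thr.read_cutoff,
        mad_k=thr.mad_k,
        fold_cutoff=thr.fold_cutoff,
        p_cutoff=thr.p_cutoff,
        paired=config.paired,
    )
    hits = effects[effects["hit"]].sort_values("delta_inf")
    log.append(f"effects: {len(effects)} members, {len(hits)} hits")

    out = {
        "counts": outdir / "counts.tsv",
        "audit": outdir / "audit.tsv",
        "effects": outdir / "effects.tsv",
        "hits": outdir / "hits.tsv",
    }
    counts.to_tsv(out["counts"], out["audit"])
    effects.to_csv(out["effects"], sep="\t", index_label="member_id", float_format="%.10g")
    hits.to_csv(out["hits"], sep="\t", index_label="member_id", float_format="%.10g")
    inputs = {str(lib_path): "", str(design_path): "", **{str(f): "" for f in design["fastq"]}}
    out["manifest"] = _write_manifest(
        outdir, "ag", config, inputs, list(out.values()), log
    )
    out["log"] = outdir / "run.log"
    return out


def run_tnseq_pipeline(config: TnseqConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the Tn5 screen: map construction, gene aggregation, depletion."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"phagescreen {__version__} tnseq pipeline"]

    genome_path = _require(config.genome, "genome FASTA", "validate")
    ann_path = _require(config.annotation, "annotation TSV", "validate")
    refmap_path = _require(config.refmap_fastq, "characterization FASTQ", "validate")
    design_path = _require(config.design, "design table", "validate")
    need_fastq = config.barseq_counts is None
    design = _load_design_with_fastq(design_path, need_fastq=need_fastq, stage="validate")
    if not need_fastq:
        _require(config.barseq_counts, "BarSeq counts TSV", "validate")

    genome = "".join(read_fasta(genome_path).values())
    vector = "".join(read_fasta(config.vector).values()) if config.vector else ""
    annotation = pd.read_csv(ann_path, sep="\t", comment="#")
    if len(annotation) == 0:
        log.append("WARNING: annotation has zero genes; all insertions are intergenic")

    reads = read_fastq_sequences(refmap_path)
    fragments, audit = parse_fragments(reads)
    log.append(
        "refmap parse: " + " ".join(f"{k}={v}" for k, v in audit.items())
    )
    unique = dedupe(fragments)
    log.append(f"dedupe: {len(fragments)} fragments -> {len(unique)} unique")
    imap = build_map(
        unique, genome, vector, annotation, dominance=config.thresholds.dominance
    )
    log.append(
        f"map: {len(imap.entries)} barcodes retained, {len(imap.discarded)} discarded"
    )

    if need_fastq:
        whitelist = BarcodeLibrary(
            members=[(bc, bc) for bc in pd.concat(
                [imap.entries["barcode"], imap.discarded["barcode"]]
            )],
            dialect="TN5",
        )
        counts = _count_samples(design, whitelist, log)
    else:
        counts = CountTable.from_tsv(config.barseq_counts)
        log.append(f"barseq counts loaded: {counts.counts.shape}")

    genes, gc_audit = gene_counts(imap, counts)
    for s in gc_audit.index:
        log.append(
            f"gene_counts[{s}]: mapped={gc_audit.loc[s, 'mapped']} "
            f"discarded={gc_audit.loc[s, 'discarded']} unknown={gc_audit.loc[s, 'unknown']}"
        )

    thr = config.thresholds
    effects = score_screen(
        genes,
        design,
        pseudocount=thr.pseudocount,
        read_cutoff=thr.read_cutoff,
        mad_k=thr.mad_k,
        fold_cutoff=thr.fold_cutoff,
        p_cutoff=thr.p_cutoff,
        paired=config.paired,
    ).sort_values("delta_inf")
    log.append(f"gene effects: {len(effects)} genes, {int(effects['hit'].sum())} depleted hits")

    out = {
        "map": outdir / "insertion_map.tsv",
        "gene_counts": outdir / "gene_counts.tsv",
        "gene_audit": outdir / "gene_audit.tsv",
        "gene_effects": outdir / "gene_effects.tsv",
    }
    imap.to_tsv(out["map"])
    genes.to_csv(out["gene_counts"], sep="\t", index_label="gene_id")
    gc_audit.to_csv(out["gene_audit"], sep="\t", index_label="sample_id")
    effects.to_csv(out["gene_effects"], sep="\t", index_label="gene_id", float_format="%.10g")

    inputs = {str(p): "" for p in [genome_path, ann_path, refmap_path, design_path]}
    if config.vector:
        inputs[str(config.vector)] = ""
    if config.barseq_counts:
        inputs[str(config.barseq_counts)] = ""
    elif "fastq" in design.columns:
        inputs.update({str(f): "" for f in design["fastq"]})
    out["manifest"] = _write_manifest(
        outdir, "tnseq", config, inputs, list(out.values()), log
    )
    out["log"] = outdir / "run.log"
    return out
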