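"""Synthetic Tn5 mutant libraries: genome, annotation, insertions, fragments.

The reference generator replaces read alignment (out of scope for this
package) with a guarantee: the genome segment downstream of every
insertion point is unique in the genome, so exact substring matching
localizes each insertion unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..library import BarcodeLibrary
from ..tnmap import INTERGENIC, Fragment, assign_gene
from ..layouts import TN5_REFMAP_LAYOUT, ReadLayout
from .barcodes import random_barcode_set
from .truth import SimTruth
from .screens import even_abundance

__all__ = [
    "TnReference",
    "make_tn5_reference",
    "make_barseq_library",
    "make_tnseq_truth",
    "simulate_refmap_fragments",
    "fragments_to_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PROBE_LEN = 50  # uniqueness is guaranteed for this downstream window


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


@dataclass
class TnReference:
    """A synthetic host genome with a Tn5 insertion library.

    ``insertions`` columns: barcode, position (1-based), gene_id — the
    ground-truth map that :func:`phagescreen.tnmap.build_map` should
    reconstruct.
    """

    genome: str
    vector: str
    annotation: pd.DataFrame
    insertions: pd.DataFrame

    def true_barcode_to_gene(self) -> dict[str, str]:
        return dict(zip(self.insertions["barcode"], self.insertions["gene_id"]))

    def write(self, outdir: str | Path, prefix: str = "tn5") -> None:
        outdir = Path(outdir)
        SeqIO.write(
            [SeqRecord(Seq(self.genome), id="chr1", description="synthetic genome")],
            outdir / f"{prefix}_genome.fasta",
            "fasta",
        )
        SeqIO.write(
            [SeqRecord(Seq(self.vector), id="vector", description="synthetic Tn5 donor vector")],
            outdir / f"{prefix}_vector.fasta",
            "fasta",
        )
        with open(outdir / f"{prefix}_annotation.tsv", "w") as fh:
            fh.write("# coordinates are 1-based inclusive\n")
            self.annotation.to_csv(fh, sep="\t", index=False)
        self.insertions.to_csv(outdir / f"{prefix}_true_map.tsv", sep="\t", index=False)


def make_tn5_reference(
    genome_len: int,
    n_genes: int,
    n_insertions: int,
    seed: int,
    gene_len: int = 1000,
    vector_len: int = 400,
    max_redraws: int = 1000,
) -> TnReference:
    """Random genome + non-overlapping genes + uniquely-localizable insertions.

    Genes of ``gene_len`` nt are placed one per equal-width slot at a
    random offset, so they never overlap.  Insertion positions are drawn
    uniformly; a position is redrawn if its downstream 50-mer is not
    unique in the genome, or if the position was already used.  Each
    insertion receives a unique 20 nt barcode (pairwise Hamming >= 3).
    """
    if n_insertions < 1:
        raise ValueError("n_insertions must be >= 1")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if n_genes > 0 and n_genes * gene_len > genome_len:
        raise ValueError("genes do not fit in the genome without overlap")
    if genome_len < _PROBE_LEN:
        raise ValueError(f"genome_len must be >= {_PROBE_LEN}")

    rng = np.random.default_rng(seed)
    genome = _random_dna(rng, genome_len)
    vector = _random_dna(rng, vector_len)

    rows = []
    if n_genes > 0:
        slot = genome_len // n_genes
        for i in range(n_genes):
            off = int(rng.integers(0, slot - gene_len + 1))
            start = i * slot + off + 1
            rows.append((f"gene{i + 1:03d}", start, start + gene_len - 1))
    annotation = pd.DataFrame(rows, columns=["gene_id", "start", "end"])

    # multiplicity of every 50-mer, for the uniqueness guarantee
    probe_counts: dict[str, int] = {}
    for i in range(genome_len - _PROBE_LEN + 1):
        probe = genome[i : i + _PROBE_LEN]
        probe_counts[probe] = probe_counts.get(probe, 0) + 1

    positions: list[int] = []
    used: set[int] = set()
    for _ in range(n_insertions):
        for _attempt in range(max_redraws):
            pos = int(rng.integers(1, genome_len - _PROBE_LEN + 2))  # 1-based
            probe = genome[pos - 1 : pos - 1 + _PROBE_LEN]
            if pos not in used and probe_counts[probe] == 1 and probe not in vector:
                break
        else:
            raise RuntimeError(
                f"could not draw a uniquely-localizable insertion after {max_redraws} tries"
            )
        used.add(pos)
        positions.append(pos)

    barcodes = random_barcode_set(n_insertions, length=20, min_dist=3, seed=rng)
    insertions = pd.DataFrame(
        {
            "barcode": barcodes,
            "position": positions,
            "gene_id": [assign_gene(p, annotation) for p in positions],
        }
    )
    return TnReference(genome=genome, vector=vector, annotation=annotation, insertions=insertions)


def make_barseq_library(reference: TnReference) -> BarcodeLibrary:
    """BarSeq whitelist for a Tn5 library: member ids are the barcodes
    themselves (the natural key for insertion mutants)."""
    return BarcodeLibrary(
        members=[(bc, bc) for bc in reference.insertions["barcode"]], dialect="TN5"
    )


def make_tnseq_truth(
    reference: TnReference, depleted_gene: str, effect: float = -4.0, seed: int = 0
) -> SimTruth:
    """Screen truth where every insertion in ``depleted_gene`` shares the
    same log2 infection effect and all other insertions are neutral."""
    genes = set(reference.insertions["gene_id"])
    if depleted_gene not in genes:
        raise KeyError(f"{depleted_gene!r} has no insertions")
    effects = {
        row.barcode: float(effect) if row.gene_id == depleted_gene else 0.0
        for row in reference.insertions.itertuples()
    }
    abundance = even_abundance(list(effects), seed)
    return SimTruth(depletion_effect=effects, abundance=abundance, seed=seed)


def _unique_is_segment(
    genome: str, vector: str, pos: int, length: int, max_len: int = _PROBE_LEN
) -> str:
    """Genome segment downstream of ``pos``, lengthened until it maps
    uniquely (the full 50-mer is unique by construction)."""
    for L in range(length, max_len + 1):
        seg = genome[pos - 1 : pos - 1 + L]
        if vector and seg in vector:
            continue
        first = genome.find(seg)
        if first != -1 and genome.find(seg, first + 1) == -1:
            return seg
    return genome[pos - 1 : pos - 1 + max_len]


def simulate_refmap_fragments(
    reference: TnReference,
    fragments_per_insertion: int = 10,
    dup_rate: float = 0.0,
    chimera_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[Fragment], pd.DataFrame]:
    """Characterization fragments for every insertion.

    Each genuine fragment carries its insertion's barcode, a random
    4 nt PCR tag and a genome segment starting at the insertion point
    (length uniform on 16-50 nt, lengthened if needed so it localizes
    uniquely).  With probability ``chimera_rate`` a fragment instead
    carries the IS of a *different* insertion (a chimeric PCR artifact);
    with probability ``dup_rate`` the emitted fragment is re-emitted
    verbatim (a PCR duplicate).  Returns the fragment list and a truth
    table flagging chimeric and duplicate records.
    """
    for name, rate in (("dup_rate", dup_rate), ("chimera_rate", chimera_rate)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ins = reference.insertions
    n_ins = len(ins)
    is_lo, is_hi = TN5_REFMAP_LAYOUT.is_len_range

    fragments: list[Fragment] = []
    rows = []
    seen: set[Fragment] = set()
    for i, row in enumerate(ins.itertuples()):
        for _ in range(fragments_per_insertion):
            chimeric = n_ins > 1 and rng.random() < chimera_rate
            if chimeric:
                j = int(rng.integers(0, n_ins - 1))
                j = j if j < i else j + 1  # any insertion but this one
                src_pos = int(ins.iloc[j]["position"])
            else:
                src_pos = int(row.position)
            length = int(rng.integers(is_lo, is_hi + 1))
            is_seq = _unique_is_segment(reference.genome, reference.vector, src_pos, length)
            # genuine fragments are distinct molecules: redraw the tag on
            # the rare (barcode, tag, IS) collision so only dup_rate
            # produces duplicate triples
            for _try in range(100):
                frag = Fragment(row.barcode, _random_dna(rng, 4), is_seq)
                if frag not in seen:
                    break
            seen.add(frag)
            fragments.append(frag)
            rows.append((*frag, src_pos, chimeric, False))
            if rng.random() < dup_rate:
                fragments.append(frag)
                rows.append((*frag, src_pos, chimeric, True))
    truth = pd.DataFrame(
        rows, columns=["barcode", "tag", "is_seq", "source_position", "chimeric", "duplicate"]
    )
    return fragments, truth


def fragments_to_reads(
    fragments: list[Fragment],
    layout: ReadLayout = TN5_REFMAP_LAYOUT,
    substitution_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Render fragments as characterization reads
    (``up_flank + barcode + down_flank + tag + IS``) with iid
    substitution errors."""
    if not 0.0 <= substitution_rate < 0.25:
        raise ValueError("substitution_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    reads = []
    for frag in fragments:
        seq = layout.up_flank + frag.barcode + layout.down_flank + frag.tag + frag.is_seq
        if substitution_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            mask = rng.random(arr.shape) < substitution_rate
            if mask.any():
                idx = np.searchsorted(_BASES, arr[mask])
                arr[mask] = _BASES[(idx + rng.integers(1, 4, size=idx.shape)) % 4]
            seq = bytes(arr).decode()
        reads.append(seq)
    return reads
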