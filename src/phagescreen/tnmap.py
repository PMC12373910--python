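"""Tn5 barcode -> insertion site -> gene mapping.

Characterization reads pair each 20 bp transposon barcode with a 4 nt
PCR tag and a 16-50 nt genome-derived insertion-site (IS) segment.
After collapsing PCR duplicates (identical barcode/tag/IS triples), the
IS is localized by unique exact substring match in the host genome;
fragments whose IS matches the transposon donor vector are discarded.
A barcode is entered in the map only if its modal insertion position
accounts for *strictly more than* 90% of its fragments (the dominance
rule), which suppresses chimeric PCR artifacts.  Retained insertions
are assigned to the gene whose annotated interval contains the
position, else pooled as intergenic.

Coordinates are 1-based inclusive throughout (annotation and
positions); strand is ignored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .layouts import TN5_REFMAP_LAYOUT, ReadLayout
from .quant import hamming
from .tables import AUDIT_COLUMNS, CountTable

__all__ = [
    "Fragment",
    "VECTOR",
    "UNLOCATED",
    "INTERGENIC",
    "parse_fragments",
    "dedupe",
    "locate",
    "assign_gene",
    "InsertionMap",
    "build_map",
    "gene_counts",
]

# sentinels for non-genomic localization outcomes / unannotated positions
VECTOR = "VECTOR"
UNLOCATED = "UNLOCATED"
INTERGENIC = "INTERGENIC"

_VALID = set("ACGTN")


class Fragment(NamedTuple):
    """One distinct DNA fragment from the characterization library."""

    barcode: str
    tag: str
    is_seq: str


def parse_fragments(
    reads: Iterable[str], layout: ReadLayout = TN5_REFMAP_LAYOUT
) -> tuple[list[Fragment], dict[str, int]]:
    """Parse characterization reads into fragments, with a fate audit.

    The barcode is extracted under the layout's flank budgets, the PCR
    tag is read from its fixed position after the downstream flank, and
    the IS is the trailing segment (clipped to the layout maximum;
    reads whose trailing segment is shorter than the layout minimum are
    rejected).  The audit partitions the input reads.
    """
    if layout.tag_len == 0 or layout.is_len_range == (0, 0):
        raise ValueError("layout must define a PCR tag and an IS segment")
    u = len(layout.up_flank)
    bl = layout.barcode_len
    d = len(layout.down_flank)
    is_lo, is_hi = layout.is_len_range
    audit = dict.fromkeys(AUDIT_COLUMNS, 0)
    fragments: list[Fragment] = []
    for read in reads:
        if not set(read) <= _VALID:
            audit["rejected_other"] += 1
            continue
        placed = None
        stage = "other"
        for off in range(layout.n_prefix_range[0], layout.n_prefix_range[1] + 1):
            if off + u + bl + d > len(read):
                continue
            if hamming(read[off : off + u], layout.up_flank) > layout.up_max_mismatch:
                stage = "flank" if stage == "other" else stage
                continue
            if (
                hamming(read[off + u + bl : off + u + bl + d], layout.down_flank)
                <= layout.down_max_mismatch
            ):
                placed = off
                break
            stage = "flank"
        if placed is None:
            audit["rejected_flank" if stage == "flank" else "rejected_other"] += 1
            continue
        tail = read[placed + u + bl + d :]
        if len(tail) < layout.tag_len + is_lo:
            audit["rejected_other"] += 1
            continue
        tag = tail[: layout.tag_len]
        is_seq = tail[layout.tag_len : layout.tag_len + is_hi]
        fragments.append(Fragment(read[placed + u : placed + u + bl], tag, is_seq))
        audit["assigned"] += 1
    return fragments, audit


def dedupe(fragments: Iterable[Fragment]) -> list[Fragment]:
    """Collapse PCR duplicates: one representative per distinct
    (barcode, tag, IS) triple, first-seen order preserved."""
    return list(dict.fromkeys(fragments))


def locate(is_seq: str, genome: str, vector_seq: str = "") -> int | str:
    """Localize an IS segment by exact substring match.

    Returns :data:`VECTOR` if the segment occurs in the donor-vector
    sequence, the 1-based genome start coordinate if it occurs at
    exactly one genomic locus, and :data:`UNLOCATED` otherwise (absent
    or multi-mapping).
    """
    if not is_seq:
        return UNLOCATED
    if vector_seq and is_seq in vector_seq:
        return VECTOR
    first = genome.find(is_seq)
    if first == -1:
        return UNLOCATED
    if genome.find(is_seq, first + 1) != -1:
        return UNLOCATED
    return first + 1


def assign_gene(position: int, annotation: pd.DataFrame) -> str:
    """Gene whose [start, end] interval (1-based inclusive) contains the
    position, else :data:`INTERGENIC`."""
    hit = annotation[(annotation["start"] <= position) & (position <= annotation["end"])]
    if len(hit) == 0:
        return INTERGENIC
    return str(hit.iloc[0]["gene_id"])


@dataclass
class InsertionMap:
    """Retained barcode -> insertion entries plus discarded barcodes.

    ``entries`` columns: barcode, position, gene_id, support (fragments
    at the modal position), dominant_fraction.  ``discarded`` columns:
    barcode, reason (AMBIGUOUS_DOMINANCE / VECTOR / UNLOCATED).
    """

    entries: pd.DataFrame
    discarded: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.entries):
            if (self.entries["dominant_fraction"] <= 0.9).any():
                raise ValueError("retained entry with dominant_fraction <= 0.9")
            if (self.entries["support"] < 1).any():
                raise ValueError("retained entry with support < 1")
        overlap = set(self.entries["barcode"]) & set(self.discarded["barcode"])
        if overlap:
            raise ValueError(f"barcodes both retained and discarded: {sorted(overlap)[:3]}")

    def barcode_to_gene(self) -> dict[str, str]:
        return dict(zip(self.entries["barcode"], self.entries["gene_id"]))

    def to_tsv(self, path: str | Path) -> None:
        kept = self.entries.assign(status="RETAINED")
        disc = self.discarded.assign(
            position=pd.NA, gene_id=pd.NA, support=pd.NA, dominant_fraction=pd.NA
        ).rename(columns={"reason": "status"})
        cols = ["barcode", "position", "gene_id", "support", "dominant_fraction", "status"]
        parts = [df[cols] for df in (kept, disc) if len(df)]
        merged = (
            pd.concat(parts, ignore_index=True) if parts else kept[cols]
        )
        merged.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InsertionMap":
        df = pd.read_csv(path, sep="\t")
        kept = df[df["status"] == "RETAINED"].drop(columns="status").reset_index(drop=True)
        kept = kept.astype({"position": "int64", "support": "int64"})
        disc = df[df["status"] != "RETAINED"][["barcode", "status"]].rename(
            columns={"status": "reason"}
        ).reset_index(drop=True)
        return cls(entries=kept, discarded=disc)


def build_map(
    unique_fragments: Sequence[Fragment],
    genome: str,
    vector: str,
    annotation: pd.DataFrame,
    dominance: float = 0.9,
    include_vector_in_denominator: bool = True,
) -> InsertionMap:
    """Build the barcode/IS map from deduplicated fragments.

    Per barcode, fragments are grouped by located genome position; the
    barcode is retained iff its modal position's fragment share
    *strictly* exceeds ``dominance`` (default 0.9, i.e. "over 90%").
    Vector-matching fragments count toward the denominator (set
    ``include_vector_in_denominator`` False to exclude them) but can
    never be the retained position.  UNLOCATED fragments are excluded
    from the denominator: under exact-match localization they are the
    analogue of unmappable reads, which are discarded before the
    dominance rule is applied.
    """
    loc_cache: dict[str, int | str] = {}
    by_barcode: dict[str, list[Fragment]] = {}
    for frag in unique_fragments:
        by_barcode.setdefault(frag.barcode, []).append(frag)

    kept_rows, disc_rows = [], []
    for barcode, frags in by_barcode.items():
        positions: Counter[int] = Counter()
        n_vector = n_unlocated = 0
        for frag in frags:
            loc = loc_cache.get(frag.is_seq)
            if loc is None:
                loc = locate(frag.is_seq, genome, vector)
                loc_cache[frag.is_seq] = loc
            if loc == VECTOR:
                n_vector += 1
            elif loc == UNLOCATED:
                n_unlocated += 1
            else:
                positions[loc] += 1
        if not positions:
            reason = VECTOR if n_vector >= n_unlocated and n_vector else UNLOCATED
            disc_rows.append((barcode, reason))
            continue
        denom = sum(positions.values()) + (n_vector if include_vector_in_denominator else 0)
        pos, support = positions.most_common(1)[0]
        fraction = support / denom
        if fraction > dominance:
            kept_rows.append(
                (barcode, pos, assign_gene(pos, annotation), support, fraction)
            )
        else:
            disc_rows.append((barcode, "AMBIGUOUS_DOMINANCE"))

    entries = pd.DataFrame(
        kept_rows,
        columns=["barcode", "position", "gene_id", "support", "dominant_fraction"],
    )
    discarded = pd.DataFrame(disc_rows, columns=["barcode", "reason"])
    return InsertionMap(entries=entries, discarded=discarded)


def gene_counts(
    imap: InsertionMap, barseq_counts: CountTable | pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate BarSeq barcode counts to genes.

    Per sample, a gene's total is the sum of counts of retained
    barcodes assigned to it; intergenic insertions pool under
    ``INTERGENIC``.  Returns ``(gene_table, audit)`` where the audit
    reports mapped / discarded / unknown read mass per sample
    (``mapped + discarded + unknown = total``).
    """
    counts = barseq_counts.counts if isinstance(barseq_counts, CountTable) else barseq_counts
    b2g = imap.barcode_to_gene()
    discarded_set = set(imap.discarded["barcode"])

    gene_of = counts.index.map(lambda bc: b2g.get(bc))
    mapped_mask = gene_of.notna()
    discarded_mask = counts.index.isin(discarded_set)
    unknown_mask = ~mapped_mask & ~discarded_mask

    mapped = counts[mapped_mask].groupby(gene_of[mapped_mask]).sum()
    mapped.index.name = "gene_id"
    genes = sorted(set(imap.entries["gene_id"]))
    mapped = mapped.reindex(genes, fill_value=0).astype("int64")

    audit = pd.DataFrame(
        {
            "mapped": counts[mapped_mask].sum(),
            "discarded": counts[discarded_mask].sum(),
            "unknown": counts[unknown_mask].sum(),
        }
    )
    audit.index.name = "sample_id"
    return mapped, audit
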