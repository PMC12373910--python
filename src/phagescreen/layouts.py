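"""Read layouts: where the barcode sits inside an amplicon read.

A barcoded amplicon read is laid out as

    [random prefix] [upstream invariant flank] [barcode] [downstream
    invariant context] [optional 4 nt PCR tag] [optional genome-derived
    insertion-site sequence]

Three dialects are used by the screens:

* ``AG`` -- 10 bp strain barcodes between two 20 bp primer-derived
  invariant flanks that must match *exactly*; a 5-7 nt random stagger
  prefix keeps replicate amplicon pools out of phase on the sequencer.
* ``TN5 refmap`` -- 20 bp transposon barcodes flanked by a 23 bp
  invariant sequence upstream (up to 3 mismatches tolerated) and a 50 bp
  invariant sequence downstream (up to 6 mismatches), followed by a 4 nt
  PCR-duplicate tag and 16-50 nt of genomic sequence at the insertion
  site.
* ``TN5 barseq`` -- the same 20 bp barcodes, quantified between 18 bp
  invariant flanks with 3 / 4 mismatches allowed up- / downstream.

All mismatch comparisons are plain Hamming distances; ``N`` in a read
counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ReadLayout",
    "AG_LAYOUT",
    "TN5_REFMAP_LAYOUT",
    "TN5_BARSEQ_LAYOUT",
    "LAYOUTS",
]

_DNA = set("ACGT")


@dataclass(frozen=True)
class ReadLayout:
    """Geometry and mismatch budgets of one amplicon dialect.

    Parameters
    ----------
    n_prefix_range
        ``(min, max)`` number of random leading nucleotides.
    up_flank, down_flank
        Invariant sequences immediately up- and downstream of the
        barcode.
    up_max_mismatch, down_max_mismatch
        Hamming-distance budgets for the two flanks (0 = exact match).
    barcode_len
        Barcode length in nt.
    tag_len
        Length of the PCR-duplicate tag following the downstream flank
        (0 if the dialect has none).
    is_len_range
        ``(min, max)`` length of the trailing genome-derived
        insertion-site segment, ``(0, 0)`` if absent.
    """

    name: str
    n_prefix_range: tuple[int, int]
    up_flank: str
    up_max_mismatch: int
    barcode_len: int
    down_flank: str
    down_max_mismatch: int
    tag_len: int = 0
    is_len_range: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not set(self.up_flank) <= _DNA or not set(self.down_flank) <= _DNA:
            raise ValueError("flank sequences must be ACGT only")
        if self.up_max_mismatch < 0 or self.down_max_mismatch < 0:
            raise ValueError("mismatch budgets must be >= 0")
        if self.barcode_len <= 0:
            raise ValueError("barcode_len must be positive")
        lo, hi = self.n_prefix_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid n_prefix_range")
        lo, hi = self.is_len_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid is_len_range")
        if self.tag_len < 0:
            raise ValueError("tag_len must be >= 0")

    @property
    def down_flank_span(self) -> int:
        return len(self.down_flank)

    @property
    def core_len(self) -> int:
        """Length of flank + barcode + flank (no prefix, tag or IS)."""
        return len(self.up_flank) + self.barcode_len + len(self.down_flank)

    @property
    def min_read_len(self) -> int:
        """Shortest read that can contain a complete barcode cassette."""
        return (
            self.n_prefix_range[0]
            + self.core_len
            + self.tag_len
            + self.is_len_range[0]
        )


# AG dialect: flanks are the primer-derived 20-mers of the barcode
# amplicon; both must match exactly.  The 5-7 nt stagger prefix encodes
# the biological replicate.
AG_LAYOUT = ReadLayout(
    name="ag",
    n_prefix_range=(5, 7),
    up_flank="TGATGTCGTTGTTGCCATCG",
    up_max_mismatch=0,
    barcode_len=10,
    down_flank="AGCAACACTGGCTCAGAAAG",
    down_max_mismatch=0,
)

# Tn5 characterization (barcode -> insertion-site mapping) reads:
# 23 bp / <=3 mismatches upstream, 50 bp / <=6 downstream, then a 4 nt
# PCR tag and 16-50 nt of genomic insertion-site sequence.
TN5_REFMAP_LAYOUT = ReadLayout(
    name="tn5-refmap",
    n_prefix_range=(0, 0),
    up_flank="GATGTGTCGACCTGCAGCGTACG",
    up_max_mismatch=3,
    barcode_len=20,
    down_flank="AGAGACCTCGTGGACATCAAGATCTGGCCTTAATTAAGGCGCGCCTTCTA",
    down_max_mismatch=6,
    tag_len=4,
    is_len_range=(16, 50),
)

# Tn5 BarSeq (abundance quantification) reads: 18 bp flanks with
# 3 / 4 mismatches allowed.
TN5_BARSEQ_LAYOUT = ReadLayout(
    name="tn5-barseq",
    n_prefix_range=(0, 0),
    up_flank="GTCGACCTGCAGCGTACG",
    up_max_mismatch=3,
    barcode_len=20,
    down_flank="AGAGACCTCGTGGACATC",
    down_max_mismatch=4,
)

LAYOUTS: dict[str, ReadLayout] = {
    l.name: l for l in (AG_LAYOUT, TN5_REFMAP_LAYOUT, TN5_BARSEQ_LAYOUT)
}
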