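"""Barcode extraction and counting.

Reads are demultiplexed against a whitelist by locating the invariant
flanks around the barcode under per-dialect Hamming budgets (see
:mod:`phagescreen.layouts`).  Candidate prefix offsets are scanned in
ascending order and the first placement whose two flanks both fit their
budgets wins; whitelist matching is exact (no error correction), which
is safe because libraries are built with pairwise barcode distance >= 3.

Every read is assigned exactly one fate, so the audit categories
partition the input (``assigned + rejected = total``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .layouts import ReadLayout
from .library import BarcodeLibrary
from .tables import AUDIT_COLUMNS, CountTable

__all__ = [
    "hamming",
    "Reason",
    "ReadFate",
    "extract_barcode",
    "extract_barcodes_batch",
    "count_barcodes",
    "ConcordanceResult",
    "concordance",
]

_VALID = set("ACGTN")


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length strings differ."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


class Reason(str, Enum):
    """Fate of a single read in the extractor/counter."""

    OK = "OK"
    FLANK_UP = "FLANK_UP"
    FLANK_DOWN = "FLANK_DOWN"
    NO_WHITELIST_MATCH = "NO_WHITELIST_MATCH"
    MALFORMED = "MALFORMED"


@dataclass(frozen=True)
class ReadFate:
    reason: Reason
    barcode: str | None = None

    def __post_init__(self) -> None:
        has_bc = self.barcode is not None
        wants_bc = self.reason in (Reason.OK, Reason.NO_WHITELIST_MATCH)
        if has_bc != wants_bc:
            raise ValueError(
                f"barcode must be present iff OK/NO_WHITELIST_MATCH, got "
                f"{self.reason} with barcode={self.barcode!r}"
            )


# fate precedence when no placement succeeds: report the furthest stage
# any candidate offset reached
_STAGE_RANK = {Reason.MALFORMED: 0, Reason.FLANK_UP: 1, Reason.FLANK_DOWN: 2}


def extract_barcode(read: str, layout: ReadLayout) -> ReadFate:
    """Locate and return the barcode of one read.

    Scans candidate prefix offsets in ascending order; at each offset
    the upstream flank is checked against its mismatch budget, then the
    next ``barcode_len`` nt are taken as the barcode and the downstream
    context validated.  The first acceptable placement wins.  On
    failure the fate is the furthest stage reached across offsets
    (``FLANK_DOWN`` beats ``FLANK_UP``).  ``N`` counts as a mismatch;
    characters outside ``ACGTN`` make the read ``MALFORMED``.
    """
    if not set(read) <= _VALID:
        return ReadFate(Reason.MALFORMED)
    u = len(layout.up_flank)
    bl = layout.barcode_len
    d = len(layout.down_flank)
    need = u + bl + d
    stage = Reason.MALFORMED  # no offset even fits in the read
    for off in range(layout.n_prefix_range[0], layout.n_prefix_range[1] + 1):
        if off + need > len(read):
            continue
        if hamming(read[off : off + u], layout.up_flank) > layout.up_max_mismatch:
            if _STAGE_RANK[stage] < _STAGE_RANK[Reason.FLANK_UP]:
                stage = Reason.FLANK_UP
            continue
        down = read[off + u + bl : off + u + bl + d]
        if hamming(down, layout.down_flank) <= layout.down_max_mismatch:
            return ReadFate(Reason.OK, read[off + u : off + u + bl])
        stage = Reason.FLANK_DOWN
    return ReadFate(stage)


def _to_byte_matrix(reads: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pack variable-length reads into a 0-padded uint8 matrix."""
    lengths = np.fromiter((len(r) for r in reads), dtype=np.int64, count=len(reads))
    width = int(lengths.max()) if len(reads) else 0
    mat = np.zeros((len(reads), width), dtype=np.uint8)
    for i, r in enumerate(reads):
        mat[i, : lengths[i]] = np.frombuffer(r.encode("ascii"), dtype=np.uint8)
    return mat, lengths


def extract_barcodes_batch(
    reads: Sequence[str], layout: ReadLayout
) -> tuple[list[str | None], list[Reason]]:
    """Vectorized equivalent of :func:`extract_barcode` over many reads.

    Semantically identical to calling :func:`extract_barcode` per read
    (property-tested); used by :func:`count_barcodes` for throughput.
    """
    n = len(reads)
    if n == 0:
        return [], []
    mat, lengths = _to_byte_matrix(reads)
    valid_chars = np.isin(mat, np.frombuffer(b"ACGTN\x00", dtype=np.uint8)).all(axis=1)

    up = np.frombuffer(layout.up_flank.encode(), dtype=np.uint8)
    down = np.frombuffer(layout.down_flank.encode(), dtype=np.uint8)
    u, bl, d = len(up), layout.barcode_len, len(down)
    need = u + bl + d

    stage = np.zeros(n, dtype=np.int8)  # 0 = MALFORMED so far
    bc_off = np.full(n, -1, dtype=np.int64)
    for off in range(layout.n_prefix_range[0], layout.n_prefix_range[1] + 1):
        if off + need > mat.shape[1]:
            break
        cand = (bc_off < 0) & valid_chars & (lengths >= off + need)
        if not cand.any():
            continue
        up_mm = (mat[:, off : off + u] != up).sum(axis=1)
        up_ok = cand & (up_mm <= layout.up_max_mismatch)
        np.maximum(stage, np.where(cand & ~up_ok, 1, 0).astype(np.int8), out=stage)
        if not up_ok.any():
            continue
        lo = off + u + bl
        down_mm = (mat[:, lo : lo + d] != down).sum(axis=1)
        hit = up_ok & (down_mm <= layout.down_max_mismatch)
        np.maximum(stage, np.where(up_ok & ~hit, 2, 0).astype(np.int8), out=stage)
        bc_off[hit] = off + u

    barcodes: list[str | None] = [None] * n
    reasons: list[Reason] = [Reason.MALFORMED] * n
    stage_map = {0: Reason.MALFORMED, 1: Reason.FLANK_UP, 2: Reason.FLANK_DOWN}
    for i in range(n):
        if not valid_chars[i]:
            continue
        if bc_off[i] >= 0:
            o = int(bc_off[i])
            barcodes[i] = reads[i][o : o + bl]
            reasons[i] = Reason.OK
        else:
            reasons[i] = stage_map[int(stage[i])]
    return barcodes, reasons


def count_barcodes(
    reads: Iterable[str],
    library: BarcodeLibrary,
    sample_id: str,
    layout: ReadLayout | None = None,
) -> CountTable:
    """Count whitelist barcodes in one sample's reads.

    Extracted barcodes are matched to the library by exact equality;
    non-whitelist barcodes are audited as ``rejected_unknown_barcode``.
    Returns a single-column :class:`~phagescreen.tables.CountTable`
    whose audit partitions the input reads exactly.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    layout = layout or library.layout
    reads = reads if isinstance(reads, (list, tuple)) else list(reads)
    barcodes, reasons = extract_barcodes_batch(reads, layout)

    whitelist = library.barcode_to_member()
    counts = dict.fromkeys(library.member_ids, 0)
    audit = dict.fromkeys(AUDIT_COLUMNS, 0)
    for bc, reason in zip(barcodes, reasons):
        if reason is Reason.OK:
            member = whitelist.get(bc)  # type: ignore[arg-type]
            if member is None:
                audit["rejected_unknown_barcode"] += 1
            else:
                counts[member] += 1
                audit["assigned"] += 1
        elif reason in (Reason.FLANK_UP, Reason.FLANK_DOWN):
            audit["rejected_flank"] += 1
        else:
            audit["rejected_other"] += 1

    counts_df = pd.DataFrame({sample_id: pd.Series(counts, dtype="int64")})
    counts_df.index.name = "member_id"
    audit_df = pd.DataFrame([audit], index=pd.Index([sample_id], name="sample_id"))
    return CountTable(counts=counts_df, audit=audit_df[AUDIT_COLUMNS])


@dataclass(frozen=True)
class ConcordanceResult:
    pearson_r_log10: float
    spearman_rho: float
    n_used: int
    n_zero_excluded: int


def concordance(a: pd.Series, b: pd.Series) -> ConcordanceResult:
    """Abundance concordance between two count columns.

    Counts are converted to proportions; members with zero proportion in
    either column are excluded from the log10-scale Pearson statistic
    (their number is reported).  Used as library QC: two sequencing
    routes over the same pool should agree (r close to 1).
    """
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared members")
    pa = a.loc[shared] / a.loc[shared].sum()
    pb = b.loc[shared] / b.loc[shared].sum()
    nonzero = (pa > 0) & (pb > 0)
    n_used = int(nonzero.sum())
    if n_used < 3:
        raise ValueError(f"fewer than 3 shared nonzero members ({n_used})")
    la, lb = np.log10(pa[nonzero]), np.log10(pb[nonzero])
    r = float(stats.pearsonr(la, lb).statistic)
    rho = float(stats.spearmanr(pa[nonzero], pb[nonzero]).statistic)
    return ConcordanceResult(r, rho, n_used, int(len(shared) - n_used))
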