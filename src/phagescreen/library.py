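"""Barcode library manifests.

A :class:`BarcodeLibrary` is the whitelist that links each library
member (an accessory-gene strain or a Tn5 insertion mutant) to its DNA
barcode, together with the read layout its amplicons follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .layouts import AG_LAYOUT, TN5_BARSEQ_LAYOUT, LAYOUTS, ReadLayout

__all__ = ["BarcodeLibrary"]

_DNA = set("ACGT")
_BARCODE_LEN = {"AG": 10, "TN5": 20}


@dataclass
class BarcodeLibrary:
    """Manifest of library members and their barcodes.

    Parameters
    ----------
    members
        ``(member_id, barcode)`` pairs.
    dialect
        ``"AG"`` (10 nt barcodes) or ``"TN5"`` (20 nt barcodes).
    layout
        The :class:`~phagescreen.layouts.ReadLayout` the amplicon reads
        follow; defaults to the dialect's standard quantification
        layout.
    """

    members: list[tuple[str, str]]
    dialect: str = "AG"
    layout: ReadLayout | None = None

    def __post_init__(self) -> None:
        if self.dialect not in _BARCODE_LEN:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.layout is None:
            self.layout = AG_LAYOUT if self.dialect == "AG" else TN5_BARSEQ_LAYOUT
        want = _BARCODE_LEN[self.dialect]
        seen_ids: set[str] = set()
        seen_bcs: set[str] = set()
        for mid, bc in self.members:
            if len(bc) != want:
                raise ValueError(
                    f"{mid}: barcode length {len(bc)} != {want} for {self.dialect}"
                )
            if not set(bc) <= _DNA:
                raise ValueError(f"{mid}: barcode has non-ACGT characters")
            if mid in seen_ids:
                raise ValueError(f"duplicate member id {mid!r}")
            if bc in seen_bcs:
                raise ValueError(f"duplicate barcode {bc!r}")
            seen_ids.add(mid)
            seen_bcs.add(bc)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [mid for mid, _ in self.members]

    @property
    def barcodes(self) -> list[str]:
        return [bc for _, bc in self.members]

    def barcode_to_member(self) -> dict[str, str]:
        return {bc: mid for mid, bc in self.members}

    def member_to_barcode(self) -> dict[str, str]:
        return dict(self.members)

    def min_pairwise_hamming(self) -> int:
        """Smallest pairwise Hamming distance (exhaustive; O(n^2))."""
        from .quant import hamming

        bcs = self.barcodes
        if len(bcs) < 2:
            raise ValueError("need >= 2 barcodes")
        return min(
            hamming(bcs[i], bcs[j])
            for i in range(len(bcs))
            for j in range(i + 1, len(bcs))
        )

    # -- TSV manifest (member_id, barcode) ---------------------------------
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.members, columns=["member_id", "barcode"])
        with open(path, "w") as fh:
            fh.write(f"# dialect={self.dialect}\tlayout={self.layout.name}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeLibrary":
        dialect, layout = "AG", None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for part in first[1:].split():
                    k, _, v = part.partition("=")
                    if k == "dialect":
                        dialect = v
                    elif k == "layout":
                        layout = LAYOUTS[v]
                df = pd.read_csv(fh, sep="\t")
            else:
                df = pd.read_csv(path, sep="\t")
        return cls(
            members=list(zip(df["member_id"].astype(str), df["barcode"])),
            dialect=dialect,
            layout=layout,
        )
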