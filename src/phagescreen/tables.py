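"""Count tables with read-fate audits.

Every read entering the counter ends up in exactly one audit category,
so ``assigned + rejected_* = total`` holds per sample by construction
and is re-checked by :meth:`CountTable.validate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["CountTable", "AUDIT_COLUMNS"]

AUDIT_COLUMNS = [
    "assigned",
    "rejected_flank",
    "rejected_unknown_barcode",
    "rejected_other",
]


@dataclass
class CountTable:
    """member x sample integer read counts plus a per-sample audit.

    ``counts`` is indexed by member id with one column per sample;
    ``audit`` is indexed by sample id with the four fate categories as
    columns.  Simulated tables (no reads involved) carry an audit in
    which every count is ``assigned``.
    """

    counts: pd.DataFrame
    audit: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = self.counts.astype("int64")
        if self.audit is None:
            self.audit = pd.DataFrame(
                0, index=self.counts.columns, columns=AUDIT_COLUMNS, dtype="int64"
            )
            self.audit["assigned"] = self.counts.sum(axis=0)
        self.audit = self.audit.astype("int64")
        self.validate()

    def validate(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if list(self.audit.columns) != AUDIT_COLUMNS:
            raise ValueError(f"audit columns must be {AUDIT_COLUMNS}")
        missing = set(self.counts.columns) - set(self.audit.index)
        if missing:
            raise ValueError(f"samples missing from audit: {sorted(missing)}")
        per_sample = self.counts.sum(axis=0)
        for s in self.counts.columns:
            if per_sample[s] != self.audit.loc[s, "assigned"]:
                raise ValueError(
                    f"sample {s}: counts sum {per_sample[s]} != "
                    f"assigned {self.audit.loc[s, 'assigned']}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def members(self) -> list[str]:
        return list(self.counts.index)

    def total_reads(self, sample: str) -> int:
        return int(self.audit.loc[sample].sum())

    def join(self, other: "CountTable") -> "CountTable":
        """Column-wise concatenation of two tables over the same members."""
        if list(other.counts.index) != list(self.counts.index):
            raise ValueError("member sets differ")
        return CountTable(
            counts=pd.concat([self.counts, other.counts], axis=1),
            audit=pd.concat([self.audit, other.audit], axis=0),
        )

    # -- TSV round trip ----------------------------------------------------
    def to_tsv(self, counts_path: str | Path, audit_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="member_id")
        if audit_path is not None:
            self.audit.to_csv(audit_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, audit_path: str | Path | None = None
    ) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="member_id")
        audit = None
        if audit_path is not None:
            audit = pd.read_csv(audit_path, sep="\t", index_col="sample_id")
        return cls(counts=counts, audit=audit)
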