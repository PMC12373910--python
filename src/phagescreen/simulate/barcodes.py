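"""Barcode set generation.

Library barcodes are drawn by rejection sampling under a minimum
pairwise Hamming distance of 3, so that a single sequencing
substitution can never turn one library barcode into another.
"""

from __future__ import annotations

import numpy as np

from ..library import BarcodeLibrary

__all__ = ["random_barcode_set", "make_ag_library"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_barcode_set(
    n: int,
    length: int,
    min_dist: int = 3,
    seed: int | np.random.Generator = 0,
    max_attempts_per_barcode: int = 2000,
) -> list[str]:
    """Draw ``n`` distinct barcodes with pairwise Hamming distance >= ``min_dist``.

    Raises ``RuntimeError`` if rejection sampling cannot place a new
    barcode within ``max_attempts_per_barcode`` draws (the requested set
    is too dense for the sequence space).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accepted = np.empty((0, length), dtype=np.uint8)
    while accepted.shape[0] < n:
        for attempt in range(max_attempts_per_barcode):
            cand = _BASES[rng.integers(0, 4, size=length)]
            if accepted.shape[0] == 0:
                break
            dists = (accepted != cand).sum(axis=1)
            if int(dists.min()) >= min_dist:
                break
        else:
            raise RuntimeError(
                f"could not place barcode {accepted.shape[0] + 1}/{n} with "
                f"min distance {min_dist} after {max_attempts_per_barcode} attempts"
            )
        accepted = np.vstack([accepted, cand])
    return [bytes(row).decode() for row in accepted]


def make_ag_library(n_members: int, seed: int) -> BarcodeLibrary:
    """An accessory-gene library: ``n_members`` strains with unique 10 bp
    barcodes (pairwise distance >= 3), AG read layout."""
    barcodes = random_barcode_set(n_members, length=10, min_dist=3, seed=seed)
    members = [(f"ag{i + 1:03d}", bc) for i, bc in enumerate(barcodes)]
    return BarcodeLibrary(members=members, dialect="AG")
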