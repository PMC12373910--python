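"""Pooled-screen count and read simulation.

The sampling model: each sample is a multinomial draw of ``depth`` reads
over the library members.  Uninfected and baseline samples draw from the
library's baseline abundances; infected samples draw from abundances
re-weighted by ``2**effect`` (so a member with effect -4 is depleted
16-fold relative to the pool) and renormalized.  Replicate-to-replicate
variation comes only from the multinomial sampling itself.

Baseline abundances follow an "even library" model: log2 proportions
uniform on ``[-spread, +spread]`` (default spread 1, i.e. at most a
4-fold range between the best- and worst-represented member), matching
a pooled library that passed evenness QC.  See docs/methods.md for why
a bounded spread matters to the representation filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..library import BarcodeLibrary
from ..tables import CountTable
from .truth import SimTruth

__all__ = [
    "even_abundance",
    "make_screen_truth",
    "simulate_screen_counts",
    "ScreenCounts",
    "reads_from_counts",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def even_abundance(
    member_ids: list[str], seed: int | np.random.Generator, log2_spread: float = 1.0
) -> dict[str, float]:
    """Baseline proportions with log2 values uniform on +-``log2_spread``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = 2.0 ** rng.uniform(-log2_spread, log2_spread, size=len(member_ids))
    w /= w.sum()
    return dict(zip(member_ids, w))


def make_screen_truth(
    library: BarcodeLibrary,
    depleted: dict[str, float] | None = None,
    seed: int = 0,
    log2_spread: float = 1.0,
) -> SimTruth:
    """Build a :class:`SimTruth` for a screen simulation.

    ``depleted`` maps member ids to true log2 infection effects
    (e.g. ``{"ag001": -4}`` for 16-fold depletion); all other members
    are neutral.
    """
    depleted = depleted or {}
    unknown = set(depleted) - set(library.member_ids)
    if unknown:
        raise KeyError(f"effects for unknown members: {sorted(unknown)}")
    effects = {m: float(depleted.get(m, 0.0)) for m in library.member_ids}
    abundance = even_abundance(library.member_ids, seed, log2_spread)
    return SimTruth(depletion_effect=effects, abundance=abundance, seed=seed)


@dataclass
class ScreenCounts:
    """The three condition tables of one simulated screen."""

    baseline: CountTable
    uninfected: CountTable
    infected: CountTable

    def combined(self) -> CountTable:
        return self.baseline.join(self.uninfected).join(self.infected)


def simulate_screen_counts(
    library: BarcodeLibrary,
    truth: SimTruth,
    depth: int,
    n_reps: int,
    seed: int,
) -> ScreenCounts:
    """Draw baseline / uninfected / infected count tables.

    Per replicate, baseline and uninfected counts are
    ``multinomial(depth, abundance)`` and infected counts are
    ``multinomial(depth, renormalize(abundance * 2**effect))``.
    Column names are ``{condition}_r{replicate}``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    members = library.member_ids
    if set(truth.abundance) != set(members) or set(truth.depletion_effect) != set(members):
        raise KeyError("truth abundance/effect keys do not match the library")

    p0 = np.array([truth.abundance[m] for m in members])
    eff = np.array([truth.depletion_effect[m] for m in members])
    p_inf = p0 * 2.0**eff
    p_inf /= p_inf.sum()

    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for cond, p in (("baseline", p0), ("uninfected", p0), ("infected", p_inf)):
        for r in range(1, n_reps + 1):
            cols[f"{cond}_r{r}"] = rng.multinomial(depth, p)
    counts = pd.DataFrame(cols, index=pd.Index(members, name="member_id"))
    return ScreenCounts(
        baseline=CountTable(counts[[c for c in cols if c.startswith("baseline")]]),
        uninfected=CountTable(counts[[c for c in cols if c.startswith("uninfected")]]),
        infected=CountTable(counts[[c for c in cols if c.startswith("infected")]]),
    )


def reads_from_counts(
    counts: "pd.Series | dict[str, int]",
    library: BarcodeLibrary,
    substitution_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Expand one sample's counts into synthetic amplicon reads.

    Each read is ``random prefix + up_flank + barcode + down_flank``
    (prefix length drawn uniformly from the layout's range) with iid
    substitution errors at ``substitution_rate``; a substitution always
    changes the base.  Emits exactly ``sum(counts)`` reads.  Quality is
    not modelled (nothing downstream consumes it); FASTQ writers emit a
    constant placeholder quality string.
    """
    if not 0.0 <= substitution_rate < 0.25:
        raise ValueError("substitution_rate must be in [0, 0.25)")
    layout = library.layout
    m2b = library.member_to_barcode()
    items = counts.items() if hasattr(counts, "items") else counts
    rng = np.random.default_rng(seed)
    plo, phi = layout.n_prefix_range
    reads: list[str] = []
    for member, n in items:
        if member not in m2b:
            raise KeyError(f"unknown member id {member!r}")
        n = int(n)
        if n < 0:
            raise ValueError("negative count")
        if n == 0:
            continue
        core = layout.up_flank + m2b[member] + layout.down_flank
        core_b = np.frombuffer(core.encode(), dtype=np.uint8)
        plens = rng.integers(plo, phi + 1, size=n)
        for plen in range(plo, phi + 1):
            k = int((plens == plen).sum())
            if k == 0:
                continue
            mat = np.empty((k, plen + len(core)), dtype=np.uint8)
            if plen:
                mat[:, :plen] = _BASES[rng.integers(0, 4, size=(k, plen))]
            mat[:, plen:] = core_b
            if substitution_rate > 0:
                mask = rng.random(mat.shape) < substitution_rate
                if mask.any():
                    # map byte -> base index (A<C<G<T sorts ascending),
                    # then shift by 1-3 so the base always changes
                    idx = np.searchsorted(_BASES, mat[mask])
                    shift = rng.integers(1, 4, size=idx.shape)
                    mat[mask] = _BASES[(idx + shift) % 4]
            reads.extend(bytes(row).decode() for row in mat)
    return reads
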