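"""Poisson apparent-MOI model for liquid killing assays.

If every infected cell dies, the surviving fraction is the Poisson zero
class, so the apparent multiplicity of infection is

    MOI_a = -ln(surviving fraction).

Plotting MOI_a against the expected MOI (phage added per cell, MOI_e)
and fitting a line through the origin, ``MOI_a = m * MOI_e``, measures
adsorption efficiency: ``1/m`` is the fold reduction between expected
and apparent MOI under the assay conditions (~26x in dilute cultures in
the original characterization).  Screens are then dosed to a *target
apparent* MOI by scaling the expected MOI up by the fold reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["apparent_moi", "MOIFit", "fit_adsorption", "plan_inoculum", "read_moi_tsv"]


def apparent_moi(survival_fraction: "float | np.ndarray") -> "float | np.ndarray":
    """Poisson zero-class apparent MOI, ``-ln(survival_fraction)``.

    Defined for survival in (0, 1]; a fraction of exactly 0 (no
    survivors) has no finite apparent MOI — rather than silently
    substituting a value, the caller must floor such rows explicitly,
    e.g. at ``0.5 / n_cells``.
    """
    sf = np.asarray(survival_fraction, dtype=float)
    if (sf <= 0).any():
        raise ValueError(
            "survival_fraction must be > 0; floor zero-survivor rows "
            "explicitly (e.g. at 0.5 / n_cells) before calling"
        )
    if (sf > 1).any():
        raise ValueError("survival_fraction must be <= 1")
    out = -np.log(sf)
    return float(out) if np.isscalar(survival_fraction) else out


@dataclass
class MOIFit:
    """Origin-constrained fit of apparent vs expected MOI."""

    points: pd.DataFrame  # moie, moia, residual
    slope: float
    fold_reduction: float


def fit_adsorption(assay: pd.DataFrame) -> MOIFit:
    """Fit ``MOI_a = m * MOI_e`` by least squares through the origin.

    ``m = sum(moie * moia) / sum(moie**2)``; the fold reduction is
    ``1/m``.  ``assay`` needs columns ``moie`` and ``survival_fraction``
    (or a precomputed ``moia``); at least two rows with ``moie > 0``
    are required.
    """
    df = assay.copy()
    if "moia" not in df.columns:
        df["moia"] = apparent_moi(df["survival_fraction"].to_numpy())
    used = df[df["moie"] > 0]
    if len(used) < 2:
        raise ValueError("need >= 2 rows with moie > 0")
    moie = used["moie"].to_numpy(dtype=float)
    moia = used["moia"].to_numpy(dtype=float)
    m = float((moie * moia).sum() / (moie**2).sum())
    if m <= 0:
        raise ValueError("non-positive slope: assay shows no net killing")
    df["residual"] = df["moia"] - m * df["moie"]
    return MOIFit(points=df, slope=m, fold_reduction=1.0 / m)


def plan_inoculum(
    target_moia: float,
    fold_reduction: float,
    cfu_per_ml: float,
    titer_pfu_per_ml: float,
    culture_volume_ml: float,
) -> float:
    """Lysate volume (ml) that achieves a target *apparent* MOI.

    The required expected MOI is ``target_moia * fold_reduction`` (the
    screens target MOI_a ~ 100 so adsorption is saturating), and the
    volume follows from cell density, culture volume and lysate titer.
    """
    args = (target_moia, fold_reduction, cfu_per_ml, titer_pfu_per_ml, culture_volume_ml)
    if any(a <= 0 for a in args):
        raise ValueError("all inputs must be positive")
    moie = target_moia * fold_reduction
    return moie * cfu_per_ml * culture_volume_ml / titer_pfu_per_ml


def read_moi_tsv(path) -> pd.DataFrame:
    """Read an assay table (moie, survivors, n_cells) and derive the
    survival fraction."""
    df = pd.read_csv(path, sep="\t")
    for col in ("moie", "survivors", "n_cells"):
        if col not in df.columns:
            raise ValueError(f"MOI table lacks column {col!r}")
    if ((df["survivors"] < 0) | (df["survivors"] > df["n_cells"])).any():
        raise ValueError("survivors must lie in [0, n_cells]")
    df["survival_fraction"] = df["survivors"] / df["n_cells"]
    return df
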