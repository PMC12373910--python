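"""Synthetic liquid-killing MOI assays.

Survival follows the Poisson zero class with attenuated adsorption:
cells survive with probability ``exp(-moie / k)`` where ``k`` is the
fold reduction between expected and apparent MOI, and survivor counts
are binomial over ``n_cells`` plated cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_moi_assay"]


def simulate_moi_assay(
    k: float, moie_grid: list[float], n_cells: int, seed: int = 0
) -> pd.DataFrame:
    """Rows of (moie, survivors, n_cells, survival_fraction)."""
    if k <= 0:
        raise ValueError("adsorption factor k must be > 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    moie = np.asarray(moie_grid, dtype=float)
    if (moie < 0).any():
        raise ValueError("expected MOI values must be >= 0")
    rng = np.random.default_rng(seed)
    p_survive = np.exp(-moie / k)
    survivors = rng.binomial(n_cells, p_survive)
    return pd.DataFrame(
        {
            "moie": moie,
            "survivors": survivors,
            "n_cells": n_cells,
            "survival_fraction": survivors / n_cells,
        }
    )
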