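"""Synthetic AP-MS intensity matrices.

Baseline protein intensities are log-normal (a stylized MaxLFQ-style
abundance distribution); designated bait interactors are multiplied by
``2**effect_log2`` in the test (bait) samples of designated hosts;
replicate noise is log-normal with a given coefficient of variation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .truth import SimTruth

__all__ = ["simulate_apms"]


def simulate_apms(
    n_proteins: int,
    hosts: list[str],
    spiked: set[str] | None = None,
    effect_log2: float = 3.0,
    cv: float = 0.2,
    seed: int = 0,
    n_reps: int = 3,
    bait: str = "bait",
    control: str = "orf74",
    spiked_hosts: list[str] | None = None,
    dropout_rate: float = 0.0,
    log2_mean: float = 20.0,
    log2_sd: float = 2.0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate test/control triplicate intensity matrices per host.

    Returns ``(intensities, truth)``: a protein x sample DataFrame with
    columns ``{host}.{bait}.r{i}`` and ``{host}.{control}.r{i}``, and
    the truth sidecar recording which proteins were spiked where.
    Protein ids are ``P0001``...; ``spiked`` may name explicit ids or be
    None for no spikes.  ``cv=0`` gives noiseless replicates.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    spiked = spiked or set()
    spiked_hosts = hosts if spiked_hosts is None else spiked_hosts
    proteins = [f"P{i + 1:04d}" for i in range(n_proteins)]
    unknown = spiked - set(proteins)
    if unknown:
        raise KeyError(f"spiked ids not in protein universe: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))  # log-normal sd giving CV=cv
    spike_mask = np.isin(proteins, sorted(spiked))

    cols: dict[str, np.ndarray] = {}
    for host in hosts:
        base = 2.0 ** rng.normal(log2_mean, log2_sd, size=n_proteins)
        for group in (bait, control):
            mean = base.copy()
            if group == bait and host in spiked_hosts:
                mean[spike_mask] *= 2.0**effect_log2
            for r in range(1, n_reps + 1):
                noise = rng.lognormal(0.0, sigma, size=n_proteins) if cv > 0 else 1.0
                values = mean * noise
                if dropout_rate > 0:
                    values = np.where(rng.random(n_proteins) < dropout_rate, 0.0, values)
                cols[f"{host}.{group}.r{r}"] = values

    df = pd.DataFrame(cols, index=pd.Index(proteins, name="protein_id"))
    truth = SimTruth(
        spiked_interactors={(h, bait): set(spiked) for h in spiked_hosts},
        seed=seed,
    )
    return df, truth
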