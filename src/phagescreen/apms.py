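"""AP-MS bait-prey enrichment scoring.

Each host-bait triplicate is quantile normalized jointly with the
matched control triplicate from the same host (the control bait is a
phenotypically neutral gene, *orf74* in the original screens): proteins
are ranked by intensity within each sample, the mean intensity at each
rank across the samples is computed, and every protein's value is
replaced by the mean for its rank.  Enrichment is the log2 ratio of
mean normalized test to control intensity with a two-sample Student t
on the replicate values.  Within each host the positively enriched
proteins are ranked by fold change (rank 1 = most enriched), and a
protein's summed rank across all hosts where the bait was tested makes
consistent interactors float to the top (small summed rank = strong
candidate).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "quantile_normalize",
    "enrichment",
    "summed_rank",
    "run_apms",
    "parse_sample_columns",
]


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Joint quantile normalization over the given sample columns.

    After normalization the sorted value vector of every sample is
    identical and equals the vector of per-rank means.  Tied intensities
    within a sample receive the mean of the tied ranks' means.  Zeros
    (unobserved proteins) participate as the smallest values, keeping
    the protein universe constant across samples.
    """
    if df.isna().any().any():
        raise ValueError("intensity matrix contains NaN")
    values = df.to_numpy(dtype=float)
    rank_means = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = rank_means.copy()
        # average rank means over tied groups
        sorted_col = col[order]
        start = 0
        for end in range(1, len(col) + 1):
            if end == len(col) or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    assigned[start:end] = rank_means[start:end].mean()
                start = end
        out[order, j] = assigned
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def enrichment(
    normalized: pd.DataFrame,
    test_cols: list[str],
    control_cols: list[str],
    eps: float | None = None,
) -> pd.DataFrame:
    """Per-protein log2 fold change and Student t P-value.

    ``log2fc = log2(mean(test) / mean(control))`` with a floor ``eps``
    on both means (default: half the smallest positive normalized value,
    so fully-absent proteins do not produce infinities); ``p_value``
    from a two-sided two-sample t on the replicate values.  Proteins
    absent from all test and control samples are excluded and reported
    in the ``all_missing`` column of the result.
    """
    t = normalized[test_cols].to_numpy(dtype=float)
    c = normalized[control_cols].to_numpy(dtype=float)
    if eps is None:
        positive = normalized.to_numpy()[normalized.to_numpy() > 0]
        eps = float(positive.min()) / 2 if positive.size else 1.0
    mean_t, mean_c = t.mean(axis=1), c.mean(axis=1)
    all_missing = (t == 0).all(axis=1) & (c == 0).all(axis=1)
    log2fc = np.log2(np.maximum(mean_t, eps) / np.maximum(mean_c, eps))
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical replicate sets (quantile-tie plateaus) trigger a
        # harmless precision warning inside the t statistic
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(t, c, axis=1).pvalue
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "mean_test": mean_t,
            "mean_control": mean_c,
            "all_missing": all_missing,
        },
        index=normalized.index,
    )
    return out[~out["all_missing"]].drop(columns="all_missing")


def summed_rank(enrichments_by_host: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cross-host summed enrichment ranks for one bait.

    Within each host, proteins with positive fold change are ranked
    descending by fold change (rank 1 = most enriched); proteins outside
    a host's positive set contribute that host's worst rank + 1 to the
    sum, so absence penalizes but does not disqualify.  Returns one row
    per protein with per-host ranks and ``summed_rank``, sorted
    ascending (best candidates first).
    """
    if not enrichments_by_host:
        raise ValueError("need >= 1 host")
    proteins = sorted(set().union(*(e.index for e in enrichments_by_host.values())))
    out = pd.DataFrame(index=pd.Index(proteins, name="protein_id"))
    total = np.zeros(len(proteins))
    for host, enr in enrichments_by_host.items():
        pos = enr[enr["log2fc"] > 0].sort_values("log2fc", ascending=False)
        ranks = pd.Series(np.arange(1, len(pos) + 1), index=pos.index, dtype=float)
        worst_plus_one = float(len(pos) + 1)
        col = ranks.reindex(proteins).fillna(worst_plus_one)
        out[f"rank_{host}"] = col
        total += col.to_numpy()
    out["summed_rank"] = total
    return out.sort_values("summed_rank", kind="stable")


_SAMPLE_RE = re.compile(r"^(?P<host>[^.]+)\.(?P<bait>[^.]+)\.(?P<rep>r?\d+)$")


def parse_sample_columns(columns: list[str]) -> pd.DataFrame:
    """Parse ``host.bait.rep`` column names into a metadata table."""
    rows = []
    for col in columns:
        m = _SAMPLE_RE.match(col)
        if not m:
            raise ValueError(f"column {col!r} does not follow host.bait.rep naming")
        rows.append((col, m["host"], m["bait"], m["rep"]))
    return pd.DataFrame(rows, columns=["sample_id", "host", "bait", "replicate"])


@dataclass
class ApmsResult:
    """Per-(host, bait) enrichment tables and per-bait summed ranks."""

    enrichment: dict[tuple[str, str], pd.DataFrame]
    summed_ranks: dict[str, pd.DataFrame]


def run_apms(intensities: pd.DataFrame, control_bait: str = "orf74") -> ApmsResult:
    """Score every bait against the per-host control triplicates.

    For each (host, bait != control) set, the six samples (test and
    control triplicates of that host) are quantile normalized jointly,
    enrichment is computed, and per-bait summed ranks are taken across
    all hosts where the bait was tested.
    """
    meta = parse_sample_columns(list(intensities.columns))
    if control_bait not in set(meta["bait"]):
        raise ValueError(f"no {control_bait!r} control samples found")
    enr: dict[tuple[str, str], pd.DataFrame] = {}
    for (host, bait), grp in meta.groupby(["host", "bait"], sort=True):
        if bait == control_bait:
            continue
        ctrl = meta[(meta["host"] == host) & (meta["bait"] == control_bait)]
        if ctrl.empty:
            raise ValueError(f"host {host!r} lacks {control_bait!r} control samples")
        test_cols = grp["sample_id"].tolist()
        control_cols = ctrl["sample_id"].tolist()
        norm = quantile_normalize(intensities[test_cols + control_cols])
        enr[(host, bait)] = enrichment(norm, test_cols, control_cols)
    baits = sorted({b for _, b in enr})
    ranks = {
        bait: summed_rank({h: e for (h, b), e in enr.items() if b == bait})
        for bait in baits
    }
    return ApmsResult(enrichment=enr, summed_ranks=ranks)
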