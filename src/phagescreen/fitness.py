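"""Fitness scores, representation filters, effect sizes, hit calls.

The scoring model: per sample, each member's count (plus a pseudocount)
is divided by the per-sample median over all library members — the
median represents neutral fitness in a pooled screen — and log2
transformed.  The infection effect of a member is the mean difference
between its infected and uninfected scores across replicates
(``delta_inf``); the direct host-fitness effect is uninfected minus
baseline (``delta_host``).  Reproducibility is assessed with a paired
t-test across replicates (P <= 0.2 gate), and hits additionally need a
>= 4-fold effect and clean representation flags.

The same procedure serves the accessory-gene screens (3 replicates) and
the Tn5 gene-depletion screens (2 replicates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CountTable

__all__ = [
    "ScoreTable",
    "make_design",
    "normalize_log2",
    "flag_representation",
    "effect_and_test",
    "call_hits",
    "score_screen",
    "infection_score",
]

DESIGN_COLUMNS = ["sample_id", "condition", "replicate"]
CONDITIONS = ("baseline", "uninfected", "infected")


@dataclass
class ScoreTable:
    """Log2 median-normalized fitness scores plus the raw counts."""

    score: pd.DataFrame
    raw: pd.DataFrame


def make_design(
    n_reps: int, conditions: Sequence[str] = CONDITIONS, sep: str = "_r"
) -> pd.DataFrame:
    """Design table for the simulator's ``{condition}_r{rep}`` naming."""
    rows = [
        (f"{cond}{sep}{r}", cond, r)
        for cond in conditions
        for r in range(1, n_reps + 1)
    ]
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def _check_design(design: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design lacks columns {missing}")
    absent = set(design["sample_id"]) - set(columns)
    if absent:
        raise ValueError(f"design references missing samples: {sorted(absent)}")
    bad = set(design["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")


def normalize_log2(
    counts: CountTable | pd.DataFrame, pseudocount: float = 1.0
) -> ScoreTable:
    """score = log2((count + pseudocount) / per-sample median(count + pseudocount)).

    The median is taken over all library members of each sample, so for
    an odd member count the per-sample median score is exactly 0.  The
    pseudocount (default 1) keeps fully-depleted members finite.
    """
    raw = counts.counts if isinstance(counts, CountTable) else counts
    if raw.empty:
        raise ValueError("empty count table")
    if pseudocount == 0 and (raw.sum(axis=0) == 0).any():
        raise ValueError("a sample has no nonzero counts")
    shifted = raw + pseudocount
    score = np.log2(shifted / shifted.median(axis=0))
    return ScoreTable(score=score, raw=raw.copy())


def _mad(x: np.ndarray) -> float:
    """Unscaled median absolute deviation (no 1.4826 consistency factor)."""
    return float(np.median(np.abs(x - np.median(x))))


def flag_representation(
    scores: ScoreTable,
    design: pd.DataFrame,
    read_cutoff: int = 100,
    mad_k: float = 3.0,
    mad_condition: str = "uninfected",
    low_read_conditions: Sequence[str] = ("baseline", "uninfected"),
) -> pd.DataFrame:
    """Flag poorly represented members.

    ``LOW_READS``: raw count below ``read_cutoff`` in any sample of
    ``low_read_conditions`` (a count of exactly ``read_cutoff`` passes).
    ``MAD_OUTLIER``: the member's mean score across the replicates of
    ``mad_condition`` lies more than ``mad_k`` unscaled MADs below the
    median of those means.  Default conditions are the pre-infection
    ones — hits must be well represented *to begin with*; depletion in
    the infected samples is signal, not a representation problem.
    Returns boolean columns ``LOW_READS`` / ``MAD_OUTLIER`` per member.
    """
    _check_design(design, scores.raw.columns)
    low_samples = design.loc[
        design["condition"].isin(low_read_conditions), "sample_id"
    ].tolist()
    low = (
        (scores.raw[low_samples] < read_cutoff).any(axis=1)
        if low_samples
        else pd.Series(False, index=scores.raw.index)
    )

    mad_samples = design.loc[design["condition"] == mad_condition, "sample_id"].tolist()
    if mad_samples:
        means = scores.score[mad_samples].mean(axis=1)
        med = float(means.median())
        mad = _mad(means.to_numpy())
        mad_flag = means < med - mad_k * mad
    else:
        mad_flag = pd.Series(False, index=scores.score.index)

    flags = pd.DataFrame({"LOW_READS": low, "MAD_OUTLIER": mad_flag})
    flags.index.name = scores.raw.index.name
    return flags


def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-sample t on per-replicate differences (df = n-1).

    Zero-variance rows: all-zero differences give t = 0, p = 1 (no
    evidence of change); identical nonzero differences are degenerate
    (p undefined, flagged) rather than manufactured certainty.
    Returns (p, mean, degenerate).
    """
    n = diffs.shape[1]
    if n < 2:
        raise ValueError("need >= 2 replicates for a t-test")
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    p = np.ones(diffs.shape[0])
    degenerate = np.zeros(diffs.shape[0], dtype=bool)
    ok = sd > 0
    t = np.zeros_like(mean)
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    zero_var_nonzero = (~ok) & (mean != 0)
    p[zero_var_nonzero] = np.nan
    degenerate[zero_var_nonzero] = True
    return p, mean, degenerate


def effect_and_test(
    scores: ScoreTable, design: pd.DataFrame, paired: bool = True
) -> pd.DataFrame:
    """Per-member effects and reproducibility P-values.

    ``delta_inf`` = mean infected score - mean uninfected score;
    ``delta_host`` = mean uninfected - mean baseline (NaN without
    baseline samples).  ``paired`` (default) pairs samples by replicate
    and tests the per-replicate differences with a one-sample t
    (df = n - 1); ``paired=False`` uses a two-sample Student t instead.
    """
    _check_design(design, scores.score.columns)

    def _cols(cond: str) -> list[str]:
        sub = design[design["condition"] == cond].sort_values("replicate")
        return sub["sample_id"].tolist()

    inf_cols, uninf_cols, base_cols = _cols("infected"), _cols("uninfected"), _cols("baseline")
    if not inf_cols or not uninf_cols:
        raise ValueError("design must include infected and uninfected samples")
    if len(inf_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")

    out = pd.DataFrame(index=scores.score.index)

    def _contrast(a_cols: list[str], b_cols: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = scores.score[a_cols].to_numpy()
        b = scores.score[b_cols].to_numpy()
        if paired:
            if len(a_cols) != len(b_cols):
                raise ValueError("paired design needs equal replicate counts")
            return _paired_t(a - b)
        with warnings.catch_warnings():
            # near-identical replicate vectors trigger a harmless
            # precision warning inside the t statistic
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(a, b, axis=1)
        return np.asarray(res.pvalue), a.mean(axis=1) - b.mean(axis=1), np.zeros(a.shape[0], bool)

    p_inf, d_inf, degen = _contrast(inf_cols, uninf_cols)
    out["delta_inf"], out["p_inf"] = d_inf, p_inf
    if base_cols:
        p_host, d_host, degen_h = _contrast(uninf_cols, base_cols)
        degen = degen | degen_h
    else:
        d_host = np.full(len(out), np.nan)
        p_host = np.full(len(out), np.nan)
    out["delta_host"], out["p_host"] = d_host, p_host
    out["DEGENERATE"] = degen
    return out


def call_hits(
    effects: pd.DataFrame,
    flags: pd.DataFrame | None = None,
    fold_cutoff: float = 4.0,
    p_cutoff: float = 0.2,
) -> pd.DataFrame:
    """Hit = unflagged, reproducible (p <= cutoff) and >= ``fold_cutoff``
    infection effect in either direction (negative ``delta_inf`` =
    sensitizing).  Adds an informational BH-adjusted column; the gate
    itself uses the raw P, as a reproducibility filter, not an FDR
    procedure."""
    out = effects.copy()
    if flags is not None:
        out = out.join(flags)
    flag_cols = [c for c in ("LOW_READS", "MAD_OUTLIER", "DEGENERATE") if c in out.columns]
    unflagged = ~out[flag_cols].any(axis=1) if flag_cols else pd.Series(True, index=out.index)
    p = out["p_inf"].to_numpy()
    with np.errstate(invalid="ignore"):
        out["p_inf_bh"] = stats.false_discovery_control(np.nan_to_num(p, nan=1.0))
        passes = (
            unflagged
            & (pd.Series(p, index=out.index) <= p_cutoff)
            & (out["delta_inf"].abs() >= np.log2(fold_cutoff))
        )
    out["hit"] = passes.fillna(False)
    return out


def score_screen(
    counts: CountTable | pd.DataFrame,
    design: pd.DataFrame,
    pseudocount: float = 1.0,
    read_cutoff: int = 100,
    mad_k: float = 3.0,
    fold_cutoff: float = 4.0,
    p_cutoff: float = 0.2,
    paired: bool = True,
) -> pd.DataFrame:
    """Full scoring chain: normalize -> flag -> test -> call.

    Convenience wrapper used by both screen pipelines; returns the
    EffectTable with flags and hit calls.
    """
    scores = normalize_log2(counts, pseudocount=pseudocount)
    flags = flag_representation(scores, design, read_cutoff=read_cutoff, mad_k=mad_k)
    effects = effect_and_test(scores, design, paired=paired)
    return call_hits(effects, flags, fold_cutoff=fold_cutoff, p_cutoff=p_cutoff)


def infection_score(clearing: Sequence[bool]) -> int | None:
    """Last 10-fold dilution still clearing the lawn.

    ``clearing[k]`` is whether the ``10**-k`` dilution cleared; returns
    the largest ``k`` with a clearing, or None if no dilution cleared.
    A clearing pattern with gaps (non-monotone) is tolerated but
    warned about, since it usually indicates a scoring mistake.
    """
    if len(clearing) == 0:
        raise ValueError("empty clearing series")
    trues = [k for k, c in enumerate(clearing) if c]
    if not trues:
        return None
    score = trues[-1]
    if trues != list(range(trues[0], score + 1)) or trues[0] != 0:
        warnings.warn(
            f"non-monotone clearing pattern {list(clearing)}; "
            "score taken as last clearing dilution",
            stacklevel=2,
        )
    return score
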