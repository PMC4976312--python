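"""Copy-dosage effects on normalized transcript expression.

Expression is measured by qRT-PCR, normalized against two housekeeping
genes, and related to the diploid CNV copy number per transcript with
non-parametric group tests (Kruskal-Wallis across copy groups 2-6,
Mann-Whitney U for low {2,3} vs high {4,5,6}), a high/low fold change, the
Spearman rank correlation with copies, and an OLS slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kruskal, linregress, mannwhitneyu, spearmanr

from .synthetic import ExpressionSample

__all__ = ["TrendResult", "normalize_expression", "dosage_trend"]

LOW_SET_DEFAULT = frozenset({2, 3})
COPY_GROUPS = (2, 3, 4, 5, 6)


@dataclass
class TrendResult:
    transcript_id: str
    n: int
    kruskal_p: float | None
    mw_low_high_p: float | None
    fold_change: float | None  # high-group / low-group central tendency
    spearman_rho: float | None
    spearman_p: float | None
    ols_slope: float | None
    ols_intercept: float | None


def normalize_expression(
    target_ct: float,
    reference_cts: Sequence[float],
    efficiency: float,
) -> float:
    """Relative expression against the mean of two reference-gene Cts.

    rel_expr = E^-(Ct_target - mean(Ct_refs)); averaging reference Cts is
    equivalent to normalizing to the geometric mean of the reference
    quantities.  A target crossing one cycle earlier than the reference
    mean doubles rel_expr when E = 2.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    refs = [float(c) for c in reference_cts]
    if len(refs) < 1:
        raise ValueError("at least one reference-gene Ct is required")
    return float(efficiency ** (-(float(target_ct) - sum(refs) / len(refs))))


def _to_frame(samples: Iterable[ExpressionSample] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "transcript": s.transcript_id,
                    "rel_expr": s.rel_expr,
                    "total_copies": s.total_copies,
                }
                for s in samples
            ]
        )
    missing = {"rel_expr", "total_copies"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return df


def dosage_trend(
    samples: Iterable[ExpressionSample] | pd.DataFrame,
    transcript_id: str | None = None,
    low_set: frozenset[int] | set[int] = LOW_SET_DEFAULT,
    use_median: bool = False,
) -> TrendResult:
    """Quantify how one transcript's expression tracks CNV copy number.

    Statistics whose group requirements are unmet (e.g. an empty low or
    high group for the fold change) are reported as None while the others
    are still computed.  Kruskal-Wallis uses the copy groups with at least
    two samples; it needs at least two such groups.  The fold change
    divides the high-group mean by the low-group mean (medians with
    ``use_median``).
    """
    df = _to_frame(samples)
    if transcript_id is not None:
        df = df[df["transcript"] == transcript_id] if "transcript" in df.columns else df
    elif "transcript" in df.columns:
        ids = df["transcript"].unique()
        if len(ids) > 1:
            raise ValueError("multiple transcripts present; pass transcript_id")
        transcript_id = ids[0] if len(ids) else None
    if df.empty:
        raise ValueError("no expression samples for the requested transcript")

    values = df["rel_expr"].to_numpy(float)
    copies = df["total_copies"].to_numpy(int)

    groups = [values[copies == k] for k in COPY_GROUPS]
    usable = [g for g in groups if len(g) >= 2]
    kruskal_p = None
    if len(usable) >= 2:
        if len(np.unique(np.concatenate(usable))) == 1:
            kruskal_p = 1.0  # every observation tied: no evidence either way
        else:
            kruskal_p = float(kruskal(*usable).pvalue)

    low_mask = np.isin(copies, list(low_set))
    low, high = values[low_mask], values[~low_mask]
    mw_p = fold = None
    if len(low) >= 1 and len(high) >= 1:
        center = np.median if use_median else np.mean
        denom = float(center(low))
        fold = float(center(high)) / denom if denom != 0 else math.inf
        if len(low) >= 2 and len(high) >= 2:
            mw_p = float(mannwhitneyu(low, high, alternative="two-sided").pvalue)

    rho = rho_p = slope = intercept = None
    if len(values) >= 3 and len(np.unique(copies)) >= 2:
        if len(np.unique(values)) > 1:
            sp = spearmanr(copies, values)
            rho, rho_p = float(sp.statistic), float(sp.pvalue)
        ols = linregress(copies, values)
        slope, intercept = float(ols.slope), float(ols.intercept)

    return TrendResult(
        transcript_id=transcript_id or "",
        n=int(len(values)),
        kruskal_p=kruskal_p,
        mw_low_high_p=mw_p,
        fold_change=fold,
        spearman_rho=rho,
        spearman_p=rho_p,
        ols_slope=slope,
        ols_intercept=intercept,
    )
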