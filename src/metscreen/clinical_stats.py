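"""Clinical statistics downstream of the screen.

Covers the four analyses that connect a candidate marker to patient data:

* immunohistochemistry (IHC) score binning on the 0-4 half-point grid into
  negative (0) / weak positive (0.5-2.5) / strong positive (3-4), with
  Mann-Whitney comparison of score distributions between tissues or groups;
* lymph-node-ratio stratification: patients split at a 30% ratio of
  positive to examined lymph nodes (no positive nodes forms its own group);
* Kaplan-Meier survival curves with the two-group log-rank test;
* marker-marker correlation (Spearman or Pearson).

Survival machinery is delegated to ``lifelines``; the exact small-sample
Mann-Whitney test is enumerated here because the screen needs it for group
sizes where the normal approximation is poor.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .io_model import (  # noqa: F401  (re-exported data model)
    IHC_GRID,
    IHCRecord,
    LNCountRecord,
    SurvivalRecord,
    ValidationError,
    _check_grid,
)

BIN_NEGATIVE = "negative"
BIN_WEAK = "weak_positive"
BIN_STRONG = "strong_positive"
IHC_BINS = (BIN_NEGATIVE, BIN_WEAK, BIN_STRONG)

#: maximum pooled sample size for the exact Mann-Whitney enumeration
EXACT_MW_LIMIT = 12


# ---------------------------------------------------------------------------
# IHC scores
# ---------------------------------------------------------------------------

def bin_ihc(score: float) -> str:
    """Map an IHC score to its expression bin.

    0 -> negative; 0.5-2.5 -> weak_positive; 3-4 -> strong_positive.
    Off-grid scores raise.
    """
    score = _check_grid(score)
    if score == 0:
        return BIN_NEGATIVE
    if score <= 2.5:
        return BIN_WEAK
    return BIN_STRONG


def ihc_bin_table(records: Sequence[IHCRecord]) -> pd.DataFrame:
    """Counts and within-tissue proportions of IHC bins per tissue."""
    rows = [
        {"tissue": r.tissue, "bin": bin_ihc(r.score)} for r in records
    ]
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["tissue", "bin"]).size().rename("count").reset_index()
    )
    totals = counts.groupby("tissue")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group A: pairs with a > b, ties counting one half."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U of group A, p).

    ``mode='exact'`` enumerates all C(nA+nB, nA) assignments of the pooled
    values (feasible for nA+nB <= 12 without ties; otherwise it falls back
    to the asymptotic test with a warning).  The exact two-sided p is twice
    the smaller tail probability, capped at 1.  ``mode='asymptotic'`` uses
    the normal approximation with tie and continuity corrections;
    ``mode='auto'`` picks exact whenever it is feasible.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValidationError(f"unknown mode {mode!r}")

    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    feasible = pooled.size <= EXACT_MW_LIMIT and not has_ties
    if mode == "exact" and not feasible:
        warnings.warn(
            "exact Mann-Whitney infeasible (ties or pooled n > "
            f"{EXACT_MW_LIMIT}); falling back to asymptotic",
            stacklevel=2,
        )
    use_exact = feasible if mode in ("auto", "exact") else False

    u_obs = _u_statistic(a, b)
    if use_exact:
        n_a = a.size
        total = comb(pooled.size, n_a)
        le = ge = 0
        idx = np.arange(pooled.size)
        for combo in combinations(idx, n_a):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if u <= u_obs:
                le += 1
            if u >= u_obs:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return u_obs, p

    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), min(1.0, float(res.pvalue))


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def km_estimate(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve as a (time, survival) step table.

    Right-censored records shrink the risk set without dropping the curve.
    The first row is (0, 1).
    """
    if not records:
        raise ValidationError("need at least one survival record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    out = pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    ).reset_index(drop=True)
    if out.iloc[0]["time"] != 0:
        out = pd.concat(
            [pd.DataFrame({"time": [0.0], "survival": [1.0]}), out],
            ignore_index=True,
        )
    return out


def survival_at(curve: pd.DataFrame, t: float) -> float:
    """Evaluate a km_estimate step table at time t (right-continuous)."""
    below = curve[curve["time"] <= t]
    if below.empty:
        return 1.0
    return float(below["survival"].iloc[-1])


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    Uses the standard (O-E)^2/V form with the hypergeometric variance at
    each event time (ties handled by that variance).  Requires at least one
    event overall.
    """
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    ev_a = [r.event for r in group_a]
    ev_b = [r.event for r in group_b]
    if not (any(ev_a) or any(ev_b)):
        raise ValidationError("log-rank test needs at least one event")
    res = _ll_logrank(
        [r.time for r in group_a],
        [r.time for r in group_b],
        event_observed_A=ev_a,
        event_observed_B=ev_b,
    )
    return float(res.test_statistic), float(res.p_value)


def dichotomize(
    values: Sequence[float], labels: tuple[str, str] = ("low", "high")
) -> list[str]:
    """Median-split group labels: strictly above the median -> high."""
    x = np.asarray(values, dtype=float)
    med = float(np.median(x))
    return [labels[1] if v > med else labels[0] for v in x]


# ---------------------------------------------------------------------------
# Lymph-node ratio
# ---------------------------------------------------------------------------

GROUP_NO_LN = "no_ln_met"
GROUP_LOW = "low_ratio"
GROUP_HIGH = "high_ratio"
LN_GROUPS = (GROUP_NO_LN, GROUP_LOW, GROUP_HIGH)


def ln_ratio_group(record: LNCountRecord, cutoff: float = 0.30) -> str:
    """Stratify a patient by the positive/examined lymph-node ratio.

    Zero positive nodes -> ``no_ln_met``; ratio strictly above the cutoff
    (default 30%) -> ``high_ratio``; otherwise ``low_ratio`` (a ratio of
    exactly the cutoff goes to the low group).
    """
    if record.positive_ln == 0:
        return GROUP_NO_LN
    ratio = record.positive_ln / record.examined_ln
    return GROUP_HIGH if ratio > cutoff else GROUP_LOW


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def marker_correlation(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> tuple[float, float]:
    """Spearman or Pearson correlation between two marker profiles."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValidationError("need equal-length vectors with >= 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    if method == "spearman":
        r, p = stats.spearmanr(xa, ya)
    elif method == "pearson":
        r, p = stats.pearsonr(xa, ya)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(r), float(p)
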