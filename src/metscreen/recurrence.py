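"""Cross-case recurrence: tallies, k-of-n selection and leading genes.

A gene that satisfies the per-case rule in a single patient may reflect
patient-specific biology or noise; the screen therefore keeps genes whose
call recurs in at least ``k_select`` of the n cases (default 4 of 8) and
highlights "leading" genes recurring in at least ``k_leading`` cases
(default 6 of 8), truncated to the top ``m_up_leading`` / ``m_down_leading``
(defaults 3 and 2).

Ranking is deterministic: recurrence count (descending), then the median
per-case LN/T fold change over evaluable cases (descending for up genes,
ascending for down genes), then gene ID.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .case_filter import CALL_DOWN, CALL_NOT_EVALUABLE, CALL_UP
from .io_model import CaseTrio, ExpressionMatrix, ValidationError

MAX_VENN_CASES = 12


@dataclass(frozen=True)
class RecurrenceParams:
    k_select: int = 4
    k_leading: int = 6
    m_up_leading: int = 3
    m_down_leading: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.k_select <= self.k_leading):
            raise ValidationError(
                "need 1 <= k_select <= k_leading, got "
                f"k_select={self.k_select}, k_leading={self.k_leading}"
            )
        if self.m_up_leading < 0 or self.m_down_leading < 0:
            raise ValidationError("leading-list sizes must be non-negative")


def count_recurrence(
    calls: pd.DataFrame,
    matrix: ExpressionMatrix | None = None,
    trios: Sequence[CaseTrio] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Tally per-gene up/down calls into a recurrence table.

    Columns: ``up_count``, ``down_count``, ``n_evaluable``, and — when the
    expression matrix and trios are supplied — ``median_fold_ln_t`` and
    ``median_fold_ln_n``, the median pseudocounted (LN+c)/(T+c) and
    (LN+c)/(N+c) over the gene's evaluable cases.  Without expression data
    the fold columns are NaN (ranking then falls back to gene ID).
    """
    if calls.shape[1] == 0:
        raise ValidationError("empty call matrix: no cases")
    values = calls.to_numpy()
    table = pd.DataFrame(
        {
            "up_count": (values == CALL_UP).sum(axis=1),
            "down_count": (values == CALL_DOWN).sum(axis=1),
            "n_evaluable": (values != CALL_NOT_EVALUABLE).sum(axis=1),
            "median_fold_ln_t": np.nan,
            "median_fold_ln_n": np.nan,
        },
        index=calls.index,
    )
    if matrix is not None and trios is not None:
        by_case = {t.case_id: t for t in trios}
        ordered = [by_case[c] for c in calls.columns]
        data = matrix.data.loc[calls.index]
        n = data[[t.n_sample for t in ordered]].to_numpy(dtype=float)
        t_ = data[[t.t_sample for t in ordered]].to_numpy(dtype=float)
        ln = data[[t.ln_sample for t in ordered]].to_numpy(dtype=float)
        c = pseudocount
        fold_t = (ln + c) / (t_ + c)
        fold_n = (ln + c) / (n + c)
        evaluable = values != CALL_NOT_EVALUABLE
        fold_t = np.where(evaluable, fold_t, np.nan)
        fold_n = np.where(evaluable, fold_n, np.nan)
        any_eval = evaluable.any(axis=1)
        med_t = np.full(len(table), np.nan)
        med_n = np.full(len(table), np.nan)
        med_t[any_eval] = np.nanmedian(fold_t[any_eval], axis=1)
        med_n[any_eval] = np.nanmedian(fold_n[any_eval], axis=1)
        table["median_fold_ln_t"] = med_t
        table["median_fold_ln_n"] = med_n
    return table


def _rank(table: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Order genes by (count desc, direction-consistent median fold, gene id)."""
    if direction not in (CALL_UP, CALL_DOWN):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    count_col = "up_count" if direction == CALL_UP else "down_count"
    fold = table["median_fold_ln_t"].to_numpy(dtype=float)
    if direction == CALL_UP:
        fold_key = np.where(np.isnan(fold), -np.inf, fold)  # larger fold first
        fold_key = -fold_key
    else:
        fold_key = np.where(np.isnan(fold), np.inf, fold)  # smaller fold first
    order = pd.DataFrame(
        {
            "_neg_count": -table[count_col].to_numpy(),
            "_fold_key": fold_key,
            "_gene_key": table.index.astype(str),
        }
    ).sort_values(["_neg_count", "_fold_key", "_gene_key"], kind="mergesort")
    return table.iloc[order.index]


def select_recurrent(
    table: pd.DataFrame,
    params: RecurrenceParams = RecurrenceParams(),
    direction: str = CALL_UP,
    k: int | None = None,
) -> list[str]:
    """Genes called in ``direction`` in at least ``k`` cases (default
    ``params.k_select``), ranked deterministically."""
    k = params.k_select if k is None else k
    count_col = "up_count" if direction == CALL_UP else "down_count"
    hits = table[table[count_col] >= k]
    return list(_rank(hits, direction).index)


def leading_genes(
    table: pd.DataFrame, params: RecurrenceParams = RecurrenceParams()
) -> tuple[list[str], list[str]]:
    """Top recurrent genes at the leading threshold (default 6 of 8 cases),
    truncated to ``m_up_leading`` up and ``m_down_leading`` down genes."""
    up = select_recurrent(table, params, CALL_UP, k=params.k_leading)
    down = select_recurrent(table, params, CALL_DOWN, k=params.k_leading)
    return up[: params.m_up_leading], down[: params.m_down_leading]


def discordant_genes(
    table: pd.DataFrame, params: RecurrenceParams = RecurrenceParams()
) -> list[str]:
    """Genes reaching ``k_select`` recurrent calls in *both* directions
    (across different cases); flagged rather than silently assigned."""
    mask = (table["up_count"] >= params.k_select) & (
        table["down_count"] >= params.k_select
    )
    return list(table.index[mask])


def venn_summary(calls: pd.DataFrame, direction: str = CALL_UP) -> pd.DataFrame:
    """Exact-membership partition of called genes over case subsets.

    For every non-empty subset of cases, counts the genes called in exactly
    that subset (so subset counts sum to the number of genes with >= 1
    call).  Exponential in the number of cases; refuses more than
    ``MAX_VENN_CASES``.
    """
    cases = list(calls.columns)
    if len(cases) > MAX_VENN_CASES:
        raise ValidationError(
            f"venn_summary supports at most {MAX_VENN_CASES} cases, got {len(cases)}"
        )
    hit = calls.to_numpy() == direction
    counts: dict[tuple[str, ...], int] = {
        tuple(c for c in combo): 0
        for r in range(1, len(cases) + 1)
        for combo in combinations(cases, r)
    }
    for row in hit:
        members = tuple(c for c, h in zip(cases, row) if h)
        if members:
            counts[members] += 1
    rows = [
        {
            "cases": "|".join(members),
            "n_cases": len(members),
            "bitmask": sum(1 << cases.index(c) for c in members),
            "count": count,
        }
        for members, count in counts.items()
    ]
    out = pd.DataFrame(rows).sort_values(["n_cases", "bitmask"]).reset_index(drop=True)
    return out


def write_recurrence_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")
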