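"""Per-case up-/down-regulation calls over matched (N, T, LN) trios.

For each gene in each patient trio the screen asks whether the metastatic
lymph node (LN) expression stands out against the matched primary tumor (T)
and adjacent non-tumor tissue (N):

* **up**: LN is at least ``up_ln_vs_t``-fold (default 2) above T *and* at
  least ``up_ln_vs_n``-fold (default 2) above N, with T additionally higher
  than N (the gene is already rising in the primary tumor);
* **down**: N exceeds T, and LN has dropped to at most ``down_ln_vs_n``
  (default 0.5) of N and at most ``down_ln_vs_t`` (default 0.8) of T.

Fold comparisons are inclusive at the stated thresholds; the within-primary
comparisons (T vs N and N vs T) are strict.  A pseudocount is added to all
three values before the comparisons so that zeros never divide; comparisons
are evaluated multiplicatively (``L >= f * T``), so no division occurs even
with a zero pseudocount.  Gene/case pairs whose maximum raw value across the
three sites falls below ``min_expr`` are marked ``not_evaluable``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import CaseTrio, ExpressionMatrix, ValidationError

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NEITHER = "neither"
CALL_NOT_EVALUABLE = "not_evaluable"
CALLS = (CALL_UP, CALL_DOWN, CALL_NEITHER, CALL_NOT_EVALUABLE)


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the per-case dysregulation rule.

    Defaults encode the screen as run: 2-fold LN enrichment over both T and
    N (with T > N) for "up"; LN at <= 0.5 x N and <= 0.8 x T (with N > T)
    for "down"; pseudocount 1 on the normalized (CPM) scale; evaluability
    floor 1 CPM.
    """

    up_ln_vs_t: float = 2.0
    up_ln_vs_n: float = 2.0
    require_t_gt_n_up: bool = True
    down_ln_vs_n: float = 0.5
    down_ln_vs_t: float = 0.8
    require_n_gt_t_down: bool = True
    pseudocount: float = 1.0
    min_expr: float = 1.0

    def __post_init__(self) -> None:
        if not (self.up_ln_vs_t > 1 and self.up_ln_vs_n > 1):
            raise ValidationError("up-fold thresholds must exceed 1")
        if not (0 < self.down_ln_vs_n < 1 and 0 < self.down_ln_vs_t < 1):
            raise ValidationError("down-fold thresholds must lie in (0, 1)")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be non-negative")
        if self.min_expr < 0:
            raise ValidationError("min_expr must be non-negative")


def classify_gene_in_case(
    n_val: float, t_val: float, ln_val: float,
    th: FilterThresholds = FilterThresholds(),
) -> str:
    """Classify one gene in one trio as up / down / neither / not_evaluable.

    Scalar reference form of the rule; :func:`call_all` is the vectorized
    equivalent over a whole matrix.
    """
    if min(n_val, t_val, ln_val) < 0:
        raise ValidationError(
            f"expression values must be non-negative, got "
            f"(N={n_val}, T={t_val}, LN={ln_val})"
        )
    if max(n_val, t_val, ln_val) < th.min_expr:
        return CALL_NOT_EVALUABLE
    c = th.pseudocount
    n, t, ln = n_val + c, t_val + c, ln_val + c
    up = (
        ln >= th.up_ln_vs_t * t
        and ln >= th.up_ln_vs_n * n
        and (t > n or not th.require_t_gt_n_up)
    )
    if up:
        return CALL_UP
    down = (
        (n > t or not th.require_n_gt_t_down)
        and ln <= th.down_ln_vs_n * n
        and ln <= th.down_ln_vs_t * t
    )
    if down:
        return CALL_DOWN
    return CALL_NEITHER


def call_all(
    matrix: ExpressionMatrix,
    trios: Sequence[CaseTrio],
    th: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Apply the per-case rule to every (gene, trio) pair.

    Returns a gene x case DataFrame of call strings, with genes in matrix
    order and cases in trio order.  The matrix is assumed to be on a
    cross-sample-comparable scale (CPM or equivalent).
    """
    gene_ids = matrix.gene_ids
    case_ids = [trio.case_id for trio in trios]
    if not trios:
        return pd.DataFrame(index=gene_ids, columns=[], dtype=object)

    known = set(matrix.sample_ids)
    for trio in trios:
        missing = [s for s in trio.samples if s not in known]
        if missing:
            raise ValidationError(
                f"trio {trio.case_id!r} references missing sample(s): {missing}"
            )

    n = matrix.data[[t.n_sample for t in trios]].to_numpy(dtype=float)
    t = matrix.data[[t.t_sample for t in trios]].to_numpy(dtype=float)
    ln = matrix.data[[t.ln_sample for t in trios]].to_numpy(dtype=float)

    c = th.pseudocount
    np_, tp, lp = n + c, t + c, ln + c
    up = (lp >= th.up_ln_vs_t * tp) & (lp >= th.up_ln_vs_n * np_)
    if th.require_t_gt_n_up:
        up &= tp > np_
    down = (lp <= th.down_ln_vs_n * np_) & (lp <= th.down_ln_vs_t * tp)
    if th.require_n_gt_t_down:
        down &= np_ > tp
    not_eval = np.maximum(np.maximum(n, t), ln) < th.min_expr

    calls = np.select(
        [not_eval, up, down],
        [CALL_NOT_EVALUABLE, CALL_UP, CALL_DOWN],
        default=CALL_NEITHER,
    )
    return pd.DataFrame(calls, index=gene_ids, columns=case_ids)


def write_call_matrix(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_call_matrix(path: str | Path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    bad = sorted(set(np.unique(calls.to_numpy())) - set(CALLS))
    if bad:
        raise ValidationError(f"unknown call value(s) in {path}: {bad}")
    return calls


def write_case_gene_lists(calls: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Write per-case up/down gene lists (``case<id>_up.txt`` etc.)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for case_id in calls.columns:
        for direction in (CALL_UP, CALL_DOWN):
            genes = calls.index[calls[case_id] == direction]
            path = outdir / f"case{case_id}_{direction}.txt"
            path.write_text("".join(g + "\n" for g in genes), encoding="utf-8")
            written.append(path)
    return written
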