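from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, chisquare

from metscreen import (
    RecurrenceParams,
    SimulationConfig,
    ValidationError,
    assemble_trios,
    call_all,
    cpm_normalize,
    count_recurrence,
    leading_genes,
    select_recurrent,
    simulate_trios,
    venn_summary,
)
from metscreen.recurrence import discordant_genes


def calls_frame(rows, cases=None):
    cases = cases or [f"c{i + 1}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cases)


def table_with_counts(counts, direction="up"):
    col = f"{direction}_count"
    other = "down_count" if direction == "up" else "up_count"
    return pd.DataFrame(
        {
            col: list(counts.values()),
            other: 0,
            "n_evaluable": 8,
            "median_fold_ln_t": np.nan,
            "median_fold_ln_n": np.nan,
        },
        index=list(counts),
    )


class TestCounting:
    def test_direct_tally(self):
        calls = calls_frame(
            {"g1": ["up", "up", "neither", "neither", "up", "neither",
                    "neither", "neither"]}
        )
        table = count_recurrence(calls)
        assert table.loc["g1", "up_count"] == 3
        assert table.loc["g1", "down_count"] == 0
        assert table.loc["g1", "n_evaluable"] == 8

    def test_all_neither_gives_zero_counts(self):
        calls = calls_frame({"g1": ["neither"] * 4, "g2": ["neither"] * 4})
        table = count_recurrence(calls)
        assert (table[["up_count", "down_count"]] == 0).all().all()

    def test_single_case_counts_bounded(self):
        calls = calls_frame({"g1": ["up"], "g2": ["neither"]})
        table = count_recurrence(calls)
        assert set(table["up_count"]) <= {0, 1}

    def test_empty_call_matrix_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            count_recurrence(pd.DataFrame(index=["g1"]))

    def test_median_folds_over_evaluable_cases(self, small_calls):
        calls, norm, trios, _ = small_calls
        table = count_recurrence(calls, norm, trios, pseudocount=1.0)
        gene = calls.index[0]
        evaluable = calls.loc[gene] != "not_evaluable"
        folds = []
        for trio in trios:
            if not evaluable[trio.case_id]:
                continue
            t = norm.data.loc[gene, trio.t_sample]
            ln = norm.data.loc[gene, trio.ln_sample]
            folds.append((ln + 1) / (t + 1))
        assert table.loc[gene, "median_fold_ln_t"] == pytest.approx(
            np.median(folds)
        )


class TestSelection:
    def test_threshold_membership(self):
        table = table_with_counts({"g1": 5, "g2": 4, "g3": 3})
        assert select_recurrent(table, RecurrenceParams(), "up") == ["g1", "g2"]

    def test_unattainable_threshold_gives_empty_list(self):
        table = table_with_counts({"g1": 8})
        assert select_recurrent(table, k=9, direction="up") == []

    def test_k_one_selects_every_called_gene(self):
        table = table_with_counts({"g1": 1, "g2": 0, "g3": 3})
        assert set(select_recurrent(table, k=1, direction="up")) == {"g1", "g3"}

    def test_fold_breaks_count_ties(self):
        table = table_with_counts({"a": 5, "b": 5, "c": 5})
        table["median_fold_ln_t"] = [2.5, 4.0, 3.0]
        assert select_recurrent(table, k=4, direction="up") == ["b", "c", "a"]
        # for down genes the smaller LN/T fold ranks first
        down = table_with_counts({"a": 5, "b": 5}, direction="down")
        down["median_fold_ln_t"] = [0.4, 0.2]
        assert select_recurrent(down, k=4, direction="down") == ["b", "a"]

    def test_gene_id_breaks_remaining_ties(self):
        table = table_with_counts({"z": 5, "a": 5})
        assert select_recurrent(table, k=4, direction="up") == ["a", "z"]

    def test_selection_invariant_to_orderings(self, small_calls):
        calls, norm, trios, _ = small_calls
        table = count_recurrence(calls, norm, trios)
        sel = select_recurrent(table, RecurrenceParams(), "up")
        shuffled_calls = calls.sample(frac=1, axis=0, random_state=5).sample(
            frac=1, axis=1, random_state=6
        )
        table2 = count_recurrence(shuffled_calls, norm, trios)
        assert select_recurrent(table2, RecurrenceParams(), "up") == sel

    def test_anti_monotone_in_k(self, small_calls):
        calls, norm, trios, _ = small_calls
        table = count_recurrence(calls, norm, trios)
        sizes = [
            len(select_recurrent(table, k=k, direction="up")) for k in range(1, 10)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == 0  # k = 9 on 8 cases

    def test_discordant_genes_flagged(self):
        table = table_with_counts({"g1": 4, "g2": 4})
        table.loc["g1", "down_count"] = 4
        assert discordant_genes(table) == ["g1"]


class TestLeading:
    def test_rank_and_truncate(self):
        table = table_with_counts({"a": 6, "b": 7, "c": 6, "d": 8, "e": 6})
        table["median_fold_ln_t"] = [3.0, 2.0, 5.0, 2.0, 4.0]
        up, down = leading_genes(table, RecurrenceParams(m_up_leading=3))
        assert up == ["d", "b", "c"]
        assert down == []

    def test_no_gene_reaches_leading_threshold(self):
        table = table_with_counts({"a": 5, "b": 4})
        assert leading_genes(table) == ([], [])

    def test_exactly_m_genes_returned_regardless_of_folds(self):
        table = table_with_counts({"a": 6, "b": 6, "c": 6})
        up, _ = leading_genes(table, RecurrenceParams(m_up_leading=3))
        assert set(up) == {"a", "b", "c"}


class TestVenn:
    def test_exact_membership_partition_two_cases(self):
        calls = calls_frame({"g1": ["up", "up"]}, cases=["c1", "c2"])
        venn = venn_summary(calls, "up").set_index("cases")["count"]
        assert venn["c1|c2"] == 1
        assert venn["c1"] == 0 and venn["c2"] == 0

    def test_counts_match_manual_enumeration(self):
        calls = calls_frame(
            {
                "g1": ["up", "neither", "up"],
                "g2": ["up", "up", "up"],
                "g3": ["neither", "up", "neither"],
                "g4": ["up", "neither", "up"],
                "g5": ["down", "down", "neither"],
            },
            cases=["c1", "c2", "c3"],
        )
        # brute force: membership pattern per gene
        expected = {}
        for subset in [
            s for r in (1, 2, 3) for s in
            __import__("itertools").combinations(["c1", "c2", "c3"], r)
        ]:
            expected["|".join(subset)] = 0
        for gene in calls.index:
            members = tuple(c for c in calls.columns if calls.loc[gene, c] == "up")
            if members:
                expected["|".join(members)] += 1
        venn = venn_summary(calls, "up").set_index("cases")["count"].to_dict()
        assert venn == expected

    def test_subset_counts_sum_to_called_genes(self, small_calls):
        calls, _, _, _ = small_calls
        venn = venn_summary(calls, "up")
        n_called = ((calls == "up").any(axis=1)).sum()
        assert venn["count"].sum() == n_called

    def test_too_many_cases_rejected(self):
        calls = pd.DataFrame(
            [["neither"] * 13], index=["g1"], columns=[f"c{i}" for i in range(13)]
        )
        with pytest.raises(ValidationError, match="at most 12"):
            venn_summary(calls)


class TestRecurrenceDistribution:
    def test_up_counts_binomial_across_seeds(self):
        """Per-case up calls for spiked-up genes behave like independent
        Bernoulli trials: the recurrence count fits Binomial(8, p) with p
        estimated from the realized per-case detection rate (chi-square
        goodness of fit per seed, alpha 0.01, at most 2 of 20 rejections)."""
        rejections = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_genes=2000, n_up_spiked=50, n_down_spiked=50, seed=100 + seed
            )
            matrix, annot, truth = simulate_trios(cfg)
            calls = call_all(cpm_normalize(matrix), assemble_trios(matrix, annot))
            up_genes = truth.genes_with_label("up_spiked")
            counts = (calls.loc[up_genes].to_numpy() == "up").sum(axis=1)
            p_detect = counts.mean() / cfg.n_cases
            obs = np.bincount(counts, minlength=cfg.n_cases + 1).astype(float)
            exp = binom.pmf(np.arange(cfg.n_cases + 1), cfg.n_cases, p_detect)
            exp = exp * len(up_genes)
            # pool sparse tail bins (expected < 5) before the chi-square
            o, e = list(obs), list(exp)
            while len(e) > 2 and e[0] < 5:
                o[1] += o[0]; e[1] += e[0]; o.pop(0); e.pop(0)
            while len(e) > 2 and e[-1] < 5:
                o[-2] += o[-1]; e[-2] += e[-1]; o.pop(); e.pop()
            o, e = np.array(o), np.array(e)
            _, p = chisquare(o, e * o.sum() / e.sum(), ddof=1)
            if p < 0.01:
                rejections += 1
        assert rejections <= 2
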