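from __future__ import annotations

import itertools
import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germline_banner.cohort_analysis import (
    ancestry_disparity_tests,
    bh_adjust,
    decomposition_disparity_tests,
    filter_decomposition,
    fisher_exact_2x2,
    gene_ppgv_counts,
    prevalence_by,
    prevalence_compare,
    prevalence_disparity_tests,
)
from germline_banner.ppgv_caller import (
    Ancestry,
    SampleMeta,
    Specimen,
    call_ppgv_batch,
    sample_ppgv_status,
)

from test_ppgv_caller import PLP_SNAPSHOT, call_at


def meta(sid, ancestry=Ancestry.EUR, cancer="breast"):
    return SampleMeta(sample_id=sid, specimen=Specimen.TISSUE, cancer_type=cancer,
                      ancestry=ancestry)


def status_frame(cohort, positives):
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in cohort],
            "ppgv_positive": [m.sample_id in positives for m in cohort],
            "n_calls": 0,
            "n_pass": 0,
        }
    )


# ---------------------------------------------------------------------------
# Independent enumeration oracle for the exact test


def fisher_oracle(table):
    (a, b), (c, d) = table
    n, row1, col1 = a + b + c + d, a + b, a + c
    denom = comb(n, col1)

    def point(x):
        return comb(row1, x) * comb(n - row1, col1 - x) / denom

    p_obs = point(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs * (1 + 1e-12))


class TestFisherExact:
    def test_enumeration_example(self):
        # [[1,3],[3,1]]: 5 admissible tables; p = 34/70.
        _, p = fisher_exact_2x2([[1, 3], [3, 1]])
        assert p == pytest.approx(34 / 70, rel=1e-12)

    def test_symmetric_table(self):
        odds, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_extreme_table(self):
        _, p = fisher_exact_2x2([[0, 10], [10, 0]])
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    def test_negative_cell_fatal(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 3], [3, 1]])

    def test_odds_ratio_sentinels(self):
        odds, _ = fisher_exact_2x2([[5, 0], [3, 2]])
        assert math.isinf(odds)
        odds, _ = fisher_exact_2x2([[0, 5], [0, 2]])
        assert math.isnan(odds)

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            table = rng.integers(0, 15, size=(2, 2)).tolist()
            if sum(itertools.chain(*table)) == 0:
                continue
            _, p = fisher_exact_2x2(table)
            assert p == pytest.approx(fisher_oracle(table), rel=1e-10, abs=1e-14)

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(11)
        for _ in range(100):
            table = rng.integers(0, 40, size=(2, 2)).tolist()
            if min(sum(r) for r in table) == 0:
                continue
            _, p = fisher_exact_2x2(table)
            assert p == pytest.approx(scipy_fisher(table)[1], rel=1e-9)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_ties(self):
        assert bh_adjust([0.5, 0.5, 0.5, 0.5]) == pytest.approx([0.5] * 4)

    def test_mixed_hand_case(self):
        # m=3: sorted (0.01, 0.04, 0.9) -> (0.03, 0.06, 0.9).
        assert bh_adjust([0.04, 0.9, 0.01]) == pytest.approx([0.06, 0.9, 0.03])

    def test_invalid_p_fatal(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_never_below_raw_and_permutation_invariant(self, ps):
        adj = bh_adjust(ps)
        assert all(q >= p - 1e-15 for p, q in zip(ps, adj))
        assert all(q <= 1.0 for q in adj)
        perm = list(reversed(ps))
        assert sorted(bh_adjust(perm)) == pytest.approx(sorted(adj))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(50):
            ps = rng.uniform(0, 1, size=rng.integers(1, 12)).tolist()
            _, sm_adj, _, _ = multipletests(ps, method="fdr_bh")
            assert bh_adjust(ps) == pytest.approx(sm_adj.tolist(), rel=1e-12)


class TestPrevalence:
    def test_all_negative(self):
        cohort = [meta(f"s{i}") for i in range(5)]
        table = prevalence_by(status_frame(cohort, set()), cohort, "cancer_type")
        assert (table["prevalence"] == 0).all()

    def test_direct_ratio(self):
        cohort = [meta(f"s{i}") for i in range(10)]
        table = prevalence_by(status_frame(cohort, {"s0", "s1", "s2"}), cohort, "overall")
        assert table.iloc[-1]["prevalence"] == pytest.approx(0.30)

    def test_two_stratum_toy(self):
        cohort = [meta(f"a{i}", cancer="breast") for i in range(3)] + [
            meta(f"b{i}", cancer="lung") for i in range(3)
        ]
        table = prevalence_by(status_frame(cohort, {"a0", "a1", "b0"}), cohort, "cancer_type")
        by = table.set_index("cancer_type")["prevalence"]
        assert by["breast"] == pytest.approx(2 / 3)
        assert by["lung"] == pytest.approx(1 / 3)

    def test_stratum_sizes_sum_to_cohort(self):
        cohort = [meta(f"s{i}", cancer="breast" if i % 2 else "lung") for i in range(9)]
        table = prevalence_by(status_frame(cohort, set()), cohort, "cancer_type")
        strata = table[table["cancer_type"] != "overall"]
        assert strata["n_samples"].sum() == len(cohort)

    def test_unknown_stratum_fatal(self):
        cohort = [meta("s0")]
        with pytest.raises(ValueError):
            prevalence_by(status_frame(cohort, set()), cohort, "shoe_size")

    def test_compare_pp_change(self):
        cohort = [meta(f"s{i}") for i in range(10)]
        out = prevalence_compare(
            status_frame(cohort, {"s0"}), status_frame(cohort, {"s0", "s1"}), cohort, "overall"
        )
        row = out.iloc[-1]
        assert row["pp_change"] == pytest.approx(10.0)
        assert row["rel_change_percent"] == pytest.approx(100.0)


class TestFilterDecomposition:
    def test_all_pass_zero_excluded(self):
        cohort = [meta("t")]
        decisions = call_ppgv_batch([call_at(100, sid="t")], cohort, PLP_SNAPSHOT)
        decomp = filter_decomposition(decisions, cohort)
        assert decomp["frac_excluded"].iloc[0] == 0.0

    def test_hand_counted_mix(self):
        # 4 eligible calls: 2 PASS, 1 FAIL_VUS, 1 FAIL_NOT_IN_CLINVAR.
        cohort = [meta("t")]
        calls = [call_at(100, sid="t"), call_at(100, sid="t"),
                 call_at(300, sid="t"), call_at(999, sid="t")]
        decomp = filter_decomposition(call_ppgv_batch(calls, cohort, PLP_SNAPSHOT), cohort)
        row = decomp.iloc[0]
        assert row["n_eligible"] == 4
        assert row["frac_excluded"] == pytest.approx(0.5)
        assert row["frac_FAIL_VUS"] == pytest.approx(0.25)
        assert row["frac_FAIL_NOT_IN_CLINVAR"] == pytest.approx(0.25)

    def test_gene_and_vaf_failures_not_eligible(self):
        cohort = [meta("t")]
        calls = [call_at(100, sid="t", gene="TP53"), call_at(100, sid="t", vaf=0.01),
                 call_at(100, sid="t")]
        decomp = filter_decomposition(call_ppgv_batch(calls, cohort, PLP_SNAPSHOT), cohort)
        assert decomp.iloc[0]["n_eligible"] == 1

    def test_fractions_sum_to_one(self):
        cohort = [meta("t")]
        calls = [call_at(p, sid="t") for p in (100, 200, 300, 400, 999)]
        decomp = filter_decomposition(call_ppgv_batch(calls, cohort, PLP_SNAPSHOT), cohort)
        frac_cols = [c for c in decomp.columns if c.startswith("frac_") and c != "frac_excluded"]
        assert decomp[frac_cols].iloc[0].sum() == pytest.approx(1.0)

    def test_unknown_ancestry_excluded_and_reported(self):
        cohort = [meta("t"), meta("u", ancestry=Ancestry.UNKNOWN)]
        calls = [call_at(100, sid="t"), call_at(100, sid="u")]
        decomp = filter_decomposition(call_ppgv_batch(calls, cohort, PLP_SNAPSHOT), cohort)
        assert set(decomp["ancestry"]) == {"EUR"}
        assert decomp.attrs["n_unknown_ancestry_calls_excluded"] == 1


class TestDisparityTests:
    def test_identical_prevalence_not_significant(self):
        counts = {a: (50, 450) for a in ("EUR", "AFR", "AMR", "EAS", "SAS")}
        results = ancestry_disparity_tests(counts)
        assert not any(r.significant for r in results)
        assert all(r.p_raw == pytest.approx(1.0) for r in results)

    def test_toy_counts_against_oracle(self):
        counts = {"EUR": (600, 4400), "AFR": (450, 4550),
                  "AMR": (600, 4400), "EAS": (600, 4400), "SAS": (600, 4400)}
        results = ancestry_disparity_tests(counts)
        afr = next(r for r in results if r.comparison == "AFR vs EUR")
        expected_p = fisher_oracle(((450, 4550), (600, 4400)))
        assert afr.p_raw == pytest.approx(expected_p, rel=1e-10)
        raws = [r.p_raw for r in results]
        assert [r.p_adj for r in results] == pytest.approx(bh_adjust(raws))

    def test_p_adj_at_least_p_raw(self):
        counts = {"EUR": (100, 900), "AFR": (80, 920), "AMR": (90, 910),
                  "EAS": (110, 890), "SAS": (70, 930)}
        for r in ancestry_disparity_tests(counts):
            assert r.p_adj >= r.p_raw - 1e-15

    def test_empty_stratum_not_computable(self):
        counts = {"EUR": (100, 900), "AFR": (80, 920)}
        results = ancestry_disparity_tests(counts)
        by_label = {r.comparison: r for r in results}
        assert by_label["AFR vs EUR"].computable
        assert not by_label["EAS vs EUR"].computable
        assert by_label["EAS vs EUR"].p_raw is None

    def test_empty_reference_fatal(self):
        with pytest.raises(ValueError):
            ancestry_disparity_tests({"AFR": (10, 90)})

    def test_prevalence_wrapper(self):
        cohort = [meta(f"e{i}") for i in range(20)] + [
            meta(f"a{i}", ancestry=Ancestry.AFR) for i in range(20)
        ]
        positives = {f"e{i}" for i in range(10)} | {f"a{i}" for i in range(2)}
        results = prevalence_disparity_tests(status_frame(cohort, positives), cohort)
        afr = next(r for r in results if r.comparison == "AFR vs EUR")
        assert afr.contingency == ((2, 18), (10, 10))

    def test_decomposition_wrapper(self):
        cohort = [meta("t"), meta("a", ancestry=Ancestry.AFR)]
        calls = [call_at(100, sid="t"), call_at(300, sid="t"),
                 call_at(100, sid="a"), call_at(999, sid="a")]
        decisions = call_ppgv_batch(calls, cohort, PLP_SNAPSHOT)
        results = decomposition_disparity_tests(decisions, cohort)
        afr = next(r for r in results if r.comparison == "AFR vs EUR")
        assert afr.contingency == ((1, 1), (1, 1))


class TestGenePpgvCounts:
    def test_counts_pass_only(self):
        cohort = [meta("t")]
        calls = [call_at(100, sid="t"), call_at(100, sid="t"), call_at(300, sid="t")]
        table = gene_ppgv_counts(call_ppgv_batch(calls, cohort, PLP_SNAPSHOT))
        assert table.set_index("gene")["n_ppgv"]["BRCA1"] == 2
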