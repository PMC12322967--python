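"""Cohort-level PPGV statistics: prevalence, filter decomposition, and
ancestry-disparity testing (Fisher exact with Benjamini-Hochberg correction).

Sample-level counts feed the prevalence comparisons; call-level counts feed
the filtered-variant decomposition comparisons.  Both percent-of-baseline and
percentage-point changes are reported under distinct names because the two
senses of "% change" are easy to conflate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .ppgv_caller import (
    Ancestry,
    FilterReason,
    PPGVDecision,
    SampleMeta,
    CLINVAR_STAGE_REASONS,
)

__all__ = [
    "prevalence_by",
    "prevalence_compare",
    "gene_ppgv_counts",
    "filter_decomposition",
    "fisher_exact_2x2",
    "bh_adjust",
    "DisparityTestResult",
    "ancestry_disparity_tests",
    "prevalence_disparity_tests",
    "decomposition_disparity_tests",
]

_STRATA = {"cancer_type", "ancestry", "specimen", "overall"}

#: Non-reference ancestries compared against EUR, in reporting order.
_NON_EUR = (Ancestry.AFR, Ancestry.AMR, Ancestry.EAS, Ancestry.SAS)

#: Relative tolerance for hypergeometric point-probability ties.
_TIE_RTOL = 1e-12


def _cohort_frame(cohort: Sequence[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in cohort],
            "specimen": [m.specimen.value for m in cohort],
            "cancer_type": [m.cancer_type for m in cohort],
            "ancestry": [m.ancestry.value for m in cohort],
        }
    )


def prevalence_by(
    status: pd.DataFrame,
    cohort: Sequence[SampleMeta],
    stratum: str,
    min_positive: int = 0,
) -> pd.DataFrame:
    """PPGV prevalence per stratum level, plus an ``overall`` row.

    ``status`` is the per-sample table from :func:`sample_ppgv_status` and must
    cover every cohort sample.  ``min_positive`` drops strata with fewer
    positives (a rendering option; default reports all observed strata).
    """
    if stratum not in _STRATA:
        raise ValueError(f"unknown grouping key {stratum!r}; expected one of {sorted(_STRATA)}")
    meta = _cohort_frame(cohort)
    merged = meta.merge(status[["sample_id", "ppgv_positive"]], on="sample_id", how="left")
    if merged["ppgv_positive"].isna().any():
        missing = merged.loc[merged["ppgv_positive"].isna(), "sample_id"].tolist()
        raise ValueError(f"status table does not cover cohort samples {missing[:5]}")

    rows = []
    if stratum != "overall":
        for level, grp in merged.groupby(stratum, sort=True):
            n, k = len(grp), int(grp["ppgv_positive"].sum())
            if k < min_positive:
                continue
            rows.append({stratum: level, "n_samples": n, "n_positive": k, "prevalence": k / n})
    n, k = len(merged), int(merged["ppgv_positive"].sum())
    rows.append({stratum: "overall", "n_samples": n, "n_positive": k,
                 "prevalence": k / n if n else 0.0})
    return pd.DataFrame(rows, columns=[stratum, "n_samples", "n_positive", "prevalence"])


def prevalence_compare(
    status_a: pd.DataFrame,
    status_b: pd.DataFrame,
    cohort: Sequence[SampleMeta],
    stratum: str,
) -> pd.DataFrame:
    """Two-snapshot prevalence comparison per stratum.

    Adds ``pp_change`` (percentage points, 100 * (prev_b - prev_a)) and
    ``rel_change_percent`` (percent of the snapshot-A baseline).
    """
    ta = prevalence_by(status_a, cohort, stratum).rename(
        columns={"n_positive": "n_positive_a", "prevalence": "prevalence_a"}
    )
    tb = prevalence_by(status_b, cohort, stratum).rename(
        columns={"n_positive": "n_positive_b", "prevalence": "prevalence_b"}
    )
    out = ta.merge(tb, on=[stratum, "n_samples"], how="outer")
    out["pp_change"] = 100.0 * (out["prevalence_b"] - out["prevalence_a"])
    out["rel_change_percent"] = np.where(
        out["prevalence_a"] > 0,
        100.0 * (out["prevalence_b"] - out["prevalence_a"]) / out["prevalence_a"],
        np.nan,
    )
    return out


def gene_ppgv_counts(decisions: Sequence[PPGVDecision]) -> pd.DataFrame:
    """Number of PASS decisions per gene (variant-call units, as in per-gene
    PPGV count reporting)."""
    counts: dict[str, int] = {}
    for dec in decisions:
        if dec.reason is FilterReason.PASS:
            counts[dec.call.gene] = counts.get(dec.call.gene, 0) + 1
    rows = [{"gene": g, "n_ppgv": n} for g, n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["gene", "n_ppgv"])


def filter_decomposition(
    decisions: Sequence[PPGVDecision],
    cohort: Sequence[SampleMeta],
) -> pd.DataFrame:
    """Per-ancestry breakdown of ClinVar-stage outcomes among eligible calls.

    Eligible calls are those that already passed the gene and VAF filters
    (reason not in {FAIL_GENE, FAIL_VAF}).  Samples of UNKNOWN ancestry are
    excluded; their eligible-call count is reported on a separate row with
    ancestry ``UNKNOWN_EXCLUDED``.
    """
    anc_by_sample = {m.sample_id: m.ancestry for m in cohort}
    reasons = [r.value for r in CLINVAR_STAGE_REASONS]
    counts: dict[str, dict[str, int]] = {}
    n_unknown = 0
    for dec in decisions:
        if dec.reason not in CLINVAR_STAGE_REASONS:
            continue
        anc = anc_by_sample.get(dec.call.sample_id)
        if anc is None:
            raise KeyError(f"decision references unknown sample {dec.call.sample_id!r}")
        if anc is Ancestry.UNKNOWN:
            n_unknown += 1
            continue
        cell = counts.setdefault(anc.value, {r: 0 for r in reasons})
        cell[dec.reason.value] += 1

    order = [
        FilterReason.PASS, FilterReason.FAIL_NOT_IN_CLINVAR, FilterReason.FAIL_VUS,
        FilterReason.FAIL_PLP_INSUFFICIENT, FilterReason.FAIL_BLB,
    ]
    rows = []
    for anc in sorted(counts):
        cell = counts[anc]
        n_eligible = sum(cell.values())
        row: dict[str, object] = {"ancestry": anc, "n_eligible": n_eligible}
        for r in order:
            row[f"frac_{r.value}"] = cell[r.value] / n_eligible if n_eligible else 0.0
        row["frac_excluded"] = (
            (n_eligible - cell[FilterReason.PASS.value]) / n_eligible if n_eligible else 0.0
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_unknown_ancestry_calls_excluded"] = n_unknown
    return df


# ---------------------------------------------------------------------------
# Exact tests


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric point probabilities (conditional on the
    margins) that do not exceed the observed table's probability, with a
    relative tie tolerance of 1e-12.  The odds ratio is the cross-product
    ratio a*d / (b*c); ``inf`` when only b*c is zero and ``nan`` when the
    ratio is 0/0.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(int(x) != x for x in cells):
        raise ValueError(f"table cells must be integers: {table!r}")
    a, b, c, d = (int(x) for x in cells)
    if min(a, b, c, d) < 0:
        raise ValueError(f"table cells must be non-negative: {table!r}")
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0:
        raise ValueError("empty 2x2 table")

    if b * c == 0:
        odds_ratio = math.nan if a * d == 0 else math.inf
    else:
        odds_ratio = (a * d) / (b * c)

    # Degenerate margins: only one table is possible.
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = float(hypergeom.pmf(a, n, row1, col1))
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return odds_ratio, min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError(f"p-values must lie in [0, 1]: {p_values!r}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out.tolist()


@dataclass(frozen=True, slots=True)
class DisparityTestResult:
    comparison: str
    contingency: tuple[tuple[int, int], tuple[int, int]] | None
    odds_ratio: float | None
    p_raw: float | None
    p_adj: float | None
    significant: bool
    computable: bool

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "contingency": [list(r) for r in self.contingency] if self.contingency else None,
            "odds_ratio": None if self.odds_ratio is None or not math.isfinite(self.odds_ratio)
            else self.odds_ratio,
            "odds_ratio_repr": repr(self.odds_ratio),
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "significant": self.significant,
            "computable": self.computable,
        }


def ancestry_disparity_tests(
    counts: Mapping[str, tuple[int, int]],
    alpha: float = 0.05,
    reference: str = Ancestry.EUR.value,
) -> list[DisparityTestResult]:
    """Each non-reference ancestry vs the reference, Fisher + BH.

    ``counts`` maps an ancestry code to an (event, non-event) pair — e.g.
    (PPGV-positive, PPGV-negative) samples, or (excluded, retained) eligible
    calls.  The BH family is the set of computable comparisons (at most 4).
    """
    ref = counts.get(reference)
    if ref is None or sum(ref) == 0:
        raise ValueError(f"reference stratum {reference!r} is empty")
    comparisons = []
    for anc in _NON_EUR:
        label = f"{anc.value} vs {reference}"
        pair = counts.get(anc.value)
        if pair is None or sum(pair) == 0:
            comparisons.append((label, None))
        else:
            table = ((int(pair[0]), int(pair[1])), (int(ref[0]), int(ref[1])))
            comparisons.append((label, table))

    computable = [(lbl, t) for lbl, t in comparisons if t is not None]
    raw = []
    ors = []
    for _, table in computable:
        odds, p = fisher_exact_2x2(table)
        ors.append(odds)
        raw.append(p)
    adj = bh_adjust(raw) if raw else []

    by_label = {
        lbl: (table, odds, p, q)
        for (lbl, table), odds, p, q in zip(computable, ors, raw, adj)
    }
    results = []
    for lbl, table in comparisons:
        if table is None:
            results.append(
                DisparityTestResult(lbl, None, None, None, None, significant=False, computable=False)
            )
        else:
            table, odds, p, q = by_label[lbl]
            results.append(
                DisparityTestResult(
                    lbl, table, odds, p, q, significant=bool(q < alpha), computable=True
                )
            )
    return results


def prevalence_disparity_tests(
    status: pd.DataFrame,
    cohort: Sequence[SampleMeta],
    alpha: float = 0.05,
) -> list[DisparityTestResult]:
    """Sample-level PPGV-positive vs -negative counts per ancestry vs EUR."""
    table = prevalence_by(status, cohort, "ancestry")
    counts = {
        row["ancestry"]: (int(row["n_positive"]), int(row["n_samples"] - row["n_positive"]))
        for _, row in table.iterrows()
        if row["ancestry"] not in ("overall", Ancestry.UNKNOWN.value)
    }
    return ancestry_disparity_tests(counts, alpha=alpha)


def decomposition_disparity_tests(
    decisions: Sequence[PPGVDecision],
    cohort: Sequence[SampleMeta],
    alpha: float = 0.05,
) -> list[DisparityTestResult]:
    """Call-level excluded vs retained eligible-call counts per ancestry vs EUR."""
    decomp = filter_decomposition(decisions, cohort)
    counts = {}
    for _, row in decomp.iterrows():
        n = int(row["n_eligible"])
        excluded = int(round(row["frac_excluded"] * n))
        counts[row["ancestry"]] = (excluded, n - excluded)
    return ancestry_disparity_tests(counts, alpha=alpha)
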