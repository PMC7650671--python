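"""Contingency and rank statistics with explicit test selection.

The cohort analyses report raw two-sided p-values from a small inventory
of non-parametric tests: plain chi-square, Yates-corrected chi-square,
two-sided Fisher exact (two qualitative variables), and Kruskal–Wallis /
Mann–Whitney (one qualitative, one quantitative).  Which contingency
test applies is decided from the minimum expected cell count:

* every expected count >= 5  -> plain chi-square;
* every expected count >= 3  -> chi-square with Yates correction;
* otherwise                  -> Fisher exact.

The thresholds are configurable (``select_and_run_test``).  The Yates
term floors ``|O - E| - 0.5`` at zero so the correction can never
overshoot.  Fisher's two-sided p sums hypergeometric point
probabilities no larger than the observed table's (the point-probability
method, not tail doubling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SELECT_PLAIN_MIN_EXPECTED = 5.0
SELECT_YATES_MIN_EXPECTED = 3.0


@dataclass(frozen=True)
class ContingencyResult:
    """Outcome of one contingency test.

    ``statistic`` is ``None`` for the Fisher exact test (which has no
    chi-square statistic); ``degenerate`` flags tables with a zero
    margin or other untestable structure, for which ``p_value`` is 1 by
    convention.
    """

    test_used: str  # "chi2" | "chi2_yates" | "fisher"
    p_value: float
    statistic: float | None = None
    df: int | None = None
    min_expected: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _as_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError(f"contingency table must be at least 2x2, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("contingency table entries must be non-negative integers")
    return t.astype(float)


def expected_counts(table) -> np.ndarray:
    """Expected counts under independence: E_ij = rowsum_i * colsum_j / N.

    Rejects tables with a zero row or column margin — such a table
    cannot be tested (a structural zero makes the expected count 0).
    """
    t = _as_table(table)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if t.sum() == 0:
        raise ValueError("empty contingency table")
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row/column margin: table untestable")
    return np.outer(rows, cols) / t.sum()


def chi_square_test(table, yates: bool = False) -> ContingencyResult:
    """Pearson chi-square test, optionally with the Yates correction.

    The Yates-corrected statistic is sum((max(|O-E| - 0.5, 0))^2 / E);
    without correction the standard sum((O-E)^2 / E).  The p-value is
    the chi-square upper tail with (r-1)(c-1) degrees of freedom.
    Yates applies to 2x2 tables only.
    """
    t = _as_table(table)
    if yates and t.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables only")
    e = expected_counts(t)
    dev = np.abs(t - e)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / e).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return ContingencyResult(
        test_used="chi2_yates" if yates else "chi2",
        p_value=float(sps.chi2.sf(stat, df)),
        statistic=stat,
        df=df,
        min_expected=float(e.min()),
    )


def fisher_exact_two_sided(table) -> ContingencyResult:
    """Two-sided Fisher exact test on a 2x2 table.

    p is the sum of hypergeometric probabilities of all tables with the
    observed margins whose point probability does not exceed the
    observed table's.  A zero margin gives p = 1, flagged degenerate.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return ContingencyResult(test_used="fisher", p_value=1.0, degenerate=True)
    p = float(sps.fisher_exact(t.astype(int), alternative="two-sided")[1])
    e = expected_counts(t)
    return ContingencyResult(
        test_used="fisher", p_value=min(p, 1.0), min_expected=float(e.min())
    )


def select_and_run_test(
    table,
    plain_min_expected: float = SELECT_PLAIN_MIN_EXPECTED,
    yates_min_expected: float = SELECT_YATES_MIN_EXPECTED,
) -> ContingencyResult:
    """Run the contingency test the expected counts call for (2x2).

    Selection on the minimum expected count: plain chi-square when it is
    at least *plain_min_expected* (default 5), Yates-corrected
    chi-square when at least *yates_min_expected* (default 3), Fisher
    exact otherwise.  Degenerate tables (zero margin) go to Fisher,
    which flags them.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("test selection is defined for 2x2 tables")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return fisher_exact_two_sided(t)
    min_e = float(expected_counts(t).min())
    if min_e >= plain_min_expected:
        return chi_square_test(t, yates=False)
    if min_e >= yates_min_expected:
        return chi_square_test(t, yates=True)
    return fisher_exact_two_sided(t)


def cooccurrence_table(calls_a: np.ndarray, calls_b: np.ndarray) -> np.ndarray:
    """2x2 WT/M cross-table of two binary call vectors (WT row/col first)."""
    a = np.asarray(calls_a, dtype=int)
    b = np.asarray(calls_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("call vectors differ in length")
    return np.array(
        [
            [int(((a == 0) & (b == 0)).sum()), int(((a == 0) & (b == 1)).sum())],
            [int(((a == 1) & (b == 0)).sum()), int(((a == 1) & (b == 1)).sum())],
        ]
    )


def pairwise_cooccurrence(matrix, loci_subset: list[str] | None = None) -> pd.DataFrame:
    """Co-occurrence tests for every unordered pair of loci.

    *matrix* is a :class:`palinsig.cohort.CohortMatrix`.  Returns a tidy
    frame with one row per pair: the four WT/M cell counts (orientation:
    rows = first locus WT/M, columns = second locus WT/M), the selected
    test, statistic, df and p-value.  Pairs where either locus is
    constant across samples (all WT or all mutated) are flagged
    untestable with p = NaN.  A Bonferroni-adjusted column is included
    for reporting; significance calls elsewhere use raw p-values.
    """
    loci = list(loci_subset) if loci_subset is not None else list(matrix.locus_ids)
    if len(loci) < 2:
        raise ValueError("need at least two loci for pairwise co-occurrence")
    rows = []
    n_pairs = len(loci) * (len(loci) - 1) // 2
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            a = matrix.calls_for(loci[i])
            b = matrix.calls_for(loci[j])
            t = cooccurrence_table(a, b)
            rec = {
                "locus_a": loci[i],
                "locus_b": loci[j],
                "a_wt_b_wt": t[0, 0],
                "a_wt_b_m": t[0, 1],
                "a_m_b_wt": t[1, 0],
                "a_m_b_m": t[1, 1],
            }
            if a.min() == a.max() or b.min() == b.max():
                rec.update(test_used="untestable", statistic=np.nan, df=np.nan,
                           p_value=np.nan, untestable=True)
            else:
                res = select_and_run_test(t)
                rec.update(
                    test_used=res.test_used,
                    statistic=np.nan if res.statistic is None else res.statistic,
                    df=np.nan if res.df is None else res.df,
                    p_value=res.p_value,
                    untestable=res.degenerate,
                )
            rows.append(rec)
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p_value"] * n_pairs, 1.0)
    return out


def categorical_association(groups: pd.Series, covariate: pd.Series) -> ContingencyResult:
    """Plain chi-square of a categorical covariate against signature groups.

    Samples with a missing covariate are excluded for this test only
    (pairwise deletion).  Empty covariate levels are dropped with a
    warning; a covariate constant over the remaining samples is
    untestable and raises.
    """
    df = pd.DataFrame({"g": groups, "c": covariate}).dropna()
    table = pd.crosstab(df["c"], df["g"])
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2:
        raise ValueError("covariate has fewer than two observed levels")
    if table.shape[1] < 2:
        raise ValueError("fewer than two signature groups observed")
    return chi_square_test(table.to_numpy())


def rank_group_test(values, groups) -> tuple[float, float, str]:
    """Kruskal–Wallis (3+ groups) or Mann–Whitney (2 groups) on ranks.

    Returns ``(statistic, p_value, test_name)``.  Kruskal–Wallis uses
    the tie-corrected chi-square approximation; Mann–Whitney is
    two-sided with normal approximation, tie and continuity correction.
    Missing values are dropped pairwise; an empty group raises.  All
    values identical gives the degenerate p = 1.
    """
    df = pd.DataFrame({"v": pd.Series(values, dtype=float), "g": pd.Series(groups)}).dropna()
    samples = [sub["v"].to_numpy() for _, sub in df.groupby("g", observed=True)]
    if len(samples) < 2:
        raise ValueError("need at least two non-empty groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if df["v"].nunique() == 1:
        return 0.0, 1.0, "degenerate"
    if len(samples) == 2:
        stat, p = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
        return float(stat), float(p), "mannwhitney"
    stat, p = sps.kruskal(*samples)
    return float(stat), float(p), "kruskalwallis"
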