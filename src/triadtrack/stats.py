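"""Inferential toolkit for the bias analysis.

Implements the tests the analysis relies on: an exact two-sided binomial
test for subgenome asymmetry, the Yates-corrected two-sample proportion
test (matching R's prop.test for 2x2 tables), Wilcoxon rank-sum with an
exact small-sample path, upper-tail hypergeometric enrichment with
Benjamini-Hochberg FDR, and Pearson correlation.  The decision rules
(two-sided minimum-likelihood tail, pooled chi-square with capped
continuity correction, exact rank-sum distribution, BH step-up) are
implemented here; scipy supplies only distribution functions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("triadtrack")


@dataclass
class TestResult:
    """A single test outcome: method, statistic, p (and optional q)."""

    method: str
    statistic: float
    p_value: float
    n: tuple
    q_value: float | None = None
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# exact binomial asymmetry test
# ---------------------------------------------------------------------------

def binom_asymmetry(n_a_gt_b: int, n_a_lt_b: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test of A-biased vs B-biased triad counts.

    Under the null, a biased triad is A>B or A<B with equal probability.
    The two-sided p sums P(X = i) over all outcomes no more likely than
    the observed one (the minimum-likelihood rule, as the conventional
    exact test is run).
    """
    if n_a_gt_b < 0 or n_a_lt_b < 0:
        raise ValueError("counts must be non-negative")
    n = n_a_gt_b + n_a_lt_b
    if n == 0:
        raise ValueError("no biased triads: binomial test undefined")
    k = n_a_gt_b
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    # small relative slack guards against float noise in pmf comparisons
    p = float(pmf[pmf <= pmf[k] * (1 + 1e-7)].sum())
    return TestResult("binom_asymmetry", float(k), min(p, 1.0), (n,))


# ---------------------------------------------------------------------------
# two-sample proportion test (prop.test-style)
# ---------------------------------------------------------------------------

def two_proportion_test(x1: int, n1: int, x2: int, n2: int,
                        correction: bool = True) -> TestResult:
    """Chi-square test (1 df) of H0: p1 = p2 for two binomial samples.

    With ``correction`` the Yates continuity correction
    (1/n1 + 1/n2)/2, capped at |p1 - p2|, is subtracted from the
    absolute difference — the standard corrected two-proportion test.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n and n >= 1")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        logger.warning("degenerate pooled proportion %s: p set to 1", pooled)
        return TestResult("two_proportion", float("nan"), 1.0, (n1, n2))
    diff = abs(p1 - p2)
    cc = (1 / n1 + 1 / n2) / 2 if correction else 0.0
    cc = min(cc, diff)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    stat = (diff - cc) ** 2 / var
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult("two_proportion", float(stat), p, (n1, n2))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney)
# ---------------------------------------------------------------------------

def _exact_rank_sum_counts(n1: int, n2: int) -> np.ndarray:
    """Number of n1-subsets of ranks 1..n1+n2 per rank-sum value.

    Dynamic programme over ranks; index r of the result counts subsets
    whose rank sum is r.  Exact distribution of the rank-sum statistic
    under H0 when there are no ties.
    """
    n = n1 + n2
    max_sum = n1 * n + 1
    counts = np.zeros((n1 + 1, max_sum), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, n + 1):
        for j in range(min(rank, n1), 0, -1):
            counts[j, rank:] += counts[j - 1, :-rank or None]
    return counts[n1]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      exact_threshold: int = 16) -> TestResult:
    """Two-sided Wilcoxon rank-sum test; U statistic reported for x.

    Exact p by enumerating the rank-sum distribution when
    len(x)+len(y) <= exact_threshold and there are no ties; otherwise a
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if n1 + n2 <= exact_threshold and not has_ties:
        dist = _exact_rank_sum_counts(n1, n2)
        total = dist.sum()
        r1 = int(round(r1))
        lower = dist[: r1 + 1].sum() / total
        upper = dist[r1:].sum() / total
        p = min(1.0, 2 * min(lower, upper))
        return TestResult("wilcoxon_rank_sum_exact", float(u), float(p),
                          (n1, n2))

    mu = n1 * n2 / 2
    n = n1 + n2
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
                if n > 1 else 0.0)
    var = n1 * n2 / 12 * (n + 1 - tie_term)
    if var == 0:
        return TestResult("wilcoxon_rank_sum", float(u), 1.0, (n1, n2))
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var) if u != mu else 0.0
    p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    return TestResult("wilcoxon_rank_sum", float(u), p, (n1, n2))


# ---------------------------------------------------------------------------
# hypergeometric enrichment + BH
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_enrichment(selection: Iterable[str],
                         annotation: pd.DataFrame,
                         universe: Iterable[str],
                         q_threshold: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of GO terms in a gene set.

    For each term with K annotated genes in a universe of N, and a
    selection of n genes of which k carry the term, p = P(X >= k) for
    X ~ Hypergeom(N, K, n).  q-values are BH-adjusted over all tested
    terms; ``significant`` flags q < q_threshold.
    """
    universe = set(universe)
    selection = set(selection)
    if not universe:
        raise ValueError("empty universe")
    if not selection:
        raise ValueError("empty selection")
    if not selection <= universe:
        raise ValueError("selection must be a subset of the universe")
    ann = annotation[annotation["gene_id"].isin(universe)]
    rows = []
    big_n = len(universe)
    n = len(selection)
    for term_id, grp in ann.groupby("term_id", sort=True):
        term_genes = set(grp["gene_id"])
        big_k = len(term_genes)
        k = len(term_genes & selection)
        p = float(sps.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term_id": term_id,
                     "term_name": grp["term_name"].iloc[0],
                     "k": k, "K": big_k, "n": n, "N": big_n,
                     "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_value"] = bh_adjust(out["p_value"].values)
    out["significant"] = out["q_value"] < q_threshold
    return out.sort_values(["p_value", "term_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation between two equal-length value lists."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult("pearson", float(r), float(p), (len(x),))


def results_table(results: Mapping[str, TestResult]) -> pd.DataFrame:
    """Flatten named TestResults into a tidy output table."""
    rows = []
    for name, res in results.items():
        rows.append({"comparison": name, "method": res.method,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "q_value": res.q_value,
                     "n": ";".join(str(v) for v in res.n)})
    return pd.DataFrame(rows)
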