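"""Fisher-exact enrichment machinery and genomic-feature tabulation.

Covers the 2x2 contrasts used across the pipeline: epigenetic-clock CpG
enrichment per category, DHS (open chromatin) enrichment of age-varying vs
age-associated CpGs, and the risk-factor significant-count contrast.  Also
tabulates the distribution of CpG categories over the 8 genomic feature
classes with a Pearson chi-square independence test.

Odds ratios use the Haldane-Anscombe +0.5 correction when any cell is zero
(for the OR and its Wald CI only); the exact p is always computed on the raw
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .simulate import GENOMIC_FEATURES

__all__ = ["ContingencyTable", "EnrichmentResult", "fisher_exact_2x2",
           "clock_enrichment", "dhs_enrichment", "feature_distribution",
           "bh_adjust"]


@dataclass
class ContingencyTable:
    """2x2 cell counts [[a, b], [c, d]] with optional axis labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple = ("row1", "row2")
    col_labels: tuple = ("col1", "col2")

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers: {cells}")
        if sum(cells) == 0:
            raise ValueError("empty contingency table")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class EnrichmentResult:
    """Sample odds ratio with Wald CI and two-sided Fisher exact p."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    adj_pvalue: Optional[float] = None
    zero_cell: bool = False
    degenerate_margin: bool = False

    @property
    def log2_or(self) -> float:
        return float(np.log2(self.odds_ratio))


def _hypergeom_pmf(ks: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    lg = gammaln
    logp = (lg(K + 1) - lg(ks + 1) - lg(K - ks + 1)
            + lg(N - K + 1) - lg(n - ks + 1) - lg(N - K - n + ks + 1)
            - (lg(N + 1) - lg(n + 1) - lg(N - n + 1)))
    return np.exp(logp)


def _fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Sum of hypergeometric probabilities of all margin-preserving tables
    whose probability does not exceed the observed one (1e-7 relative
    slack)."""
    N, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = _hypergeom_pmf(ks, N, c1, r1)
    return float(min(pmf[pmf <= pmf[a - lo] * (1 + 1e-7)].sum(), 1.0))


def fisher_exact_2x2(table: ContingencyTable) -> EnrichmentResult:
    """Two-sided Fisher exact test with sample odds ratio and 95% CI.

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed one
    (within a 1e-7 relative slack) — the minimum-likelihood definition also
    used by ``scipy.stats.fisher_exact``.  OR = ad/bc; when a cell is zero,
    0.5 is added to every cell for the OR and the Wald CI on log OR, never
    for p.
    """
    arr = table.array
    degenerate = bool((arr.sum(axis=0) == 0).any() or
                      (arr.sum(axis=1) == 0).any())
    p = 1.0 if degenerate else _fisher_two_sided_p(table.a, table.b,
                                                   table.c, table.d)
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    zero = min(a, b, c, d) == 0
    if zero:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(odds) + np.array([-1.96, 1.96]) * se)
    return EnrichmentResult(float(odds), float(lo), float(hi), p,
                            zero_cell=zero, degenerate_margin=degenerate)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = sps.false_discovery_control(p[mask], method="bh")
    return out


def clock_enrichment(calls, clock_lists: Mapping[str, Iterable[str]],
                     universe: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Enrichment of each CpG category in each epigenetic clock's CpGs.

    Clock lists are intersected with the analyzed universe first.  For each
    (clock, category): a = clock CpGs in the category, b = clock CpGs
    outside it, c = category CpGs outside the clock, d = the rest.  The
    category sets are inclusive ('both' CpGs belong to age_associated and
    age_varying alike).  p-values are BH-adjusted across the whole
    clock x category grid; log2(OR) and the CI are exported for forest
    plots.
    """
    uni = pd.Index(calls.universe if universe is None else universe)
    cat_sets = {
        "age_associated": set(calls.members("age_associated", inclusive=True)),
        "age_varying": set(calls.members("age_varying", inclusive=True)),
    }
    rows = []
    for clock, cpgs in clock_lists.items():
        in_clock = set(cpgs) & set(uni)
        for cat, members in cat_sets.items():
            if not in_clock:
                rows.append((clock, cat, 0, np.nan, np.nan, np.nan, np.nan,
                             np.nan, True))
                continue
            a = len(in_clock & members)
            b = len(in_clock) - a
            c = len(members) - a
            d = len(uni) - a - b - c
            res = fisher_exact_2x2(ContingencyTable(a, b, c, d))
            rows.append((clock, cat, len(in_clock), res.odds_ratio,
                         res.log2_or, np.log2(res.ci_low),
                         np.log2(res.ci_high), res.pvalue, False))
    out = pd.DataFrame(rows, columns=["clock", "category", "n_clock_cpgs",
                                      "odds_ratio", "log2_or", "log2_ci_low",
                                      "log2_ci_high", "p", "empty"])
    out["p_adj"] = bh_adjust(out["p"])
    return out


def dhs_enrichment(calls, dhs_flags: Mapping[str, int]) -> EnrichmentResult:
    """DHS enrichment of age-varying relative to age-associated CpGs.

    2x2 of the two exclusive categories x DHS status; OR > 1 means the
    age-varying category sits in open chromatin more often.
    """
    flags = pd.Series(dhs_flags)
    missing = calls.universe.difference(flags.index)
    if len(missing):
        raise ValueError(
            f"DHS flag missing for {len(missing)} CpGs (e.g. {missing[0]!r})")
    av = calls.members("age_varying")
    aa = calls.members("age_associated")
    a = int(flags[av].sum())
    b = len(av) - a
    c = int(flags[aa].sum())
    d = len(aa) - c
    return fisher_exact_2x2(ContingencyTable(
        a, b, c, d, row_labels=("age_varying", "age_associated"),
        col_labels=("dhs", "non_dhs")))


def feature_distribution(calls, features: Mapping[str, str],
                         categories: Sequence[str] = ("age_associated",
                                                      "age_varying")
                         ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Category x genomic-feature counts, proportions and chi-square p.

    Every CpG must map to one of the 8 feature classes; unknown labels raise
    with the offending values listed.  Returns (counts, row-normalized
    proportions, Pearson chi-square p for independence).
    """
    feats = pd.Series(features)
    bad = sorted(set(feats.unique()) - set(GENOMIC_FEATURES))
    if bad:
        raise ValueError(f"unknown genomic feature labels: {bad}")
    frames = []
    for cat in categories:
        idx = calls.members(cat)
        frames.append(pd.DataFrame({"category": cat, "feature": feats[idx]}))
    long = pd.concat(frames)
    counts = (pd.crosstab(long["category"], long["feature"])
              .reindex(index=categories, fill_value=0)
              .reindex(columns=list(GENOMIC_FEATURES), fill_value=0))
    props = counts.div(counts.sum(axis=1), axis=0)
    nonzero = counts.loc[:, counts.sum(axis=0) > 0]
    chi2_p = float(sps.chi2_contingency(nonzero.to_numpy()).pvalue)
    return counts, props, chi2_p
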