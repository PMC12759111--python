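"""Genome-wide two-step CpG classification and PCA diagnostics.

For every CpG the two nested mixed models are fitted (random intercept;
random intercept + slope).  A CpG is called *age-varying* when the
boundary-mixture likelihood-ratio test of the random-slope components beats
the Bonferroni threshold family_alpha / M, and *age-associated* when the
fixed age effect of the best-AIC model beats the same threshold.  The
Model-2 subject-level slope BLUPs are kept as each CpG's per-subject
longitudinal rate of methylation change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lmm import (DegenerateDesignError, LongitudinalDesign, fit_lmm,
                  lrt_random_slope, wald_age_p)

logger = logging.getLogger("methylopace.scan")

__all__ = ["CpGCallTable", "PCAResult", "classify_cpgs", "pca_scores",
           "pc_age_association", "loading_contrast"]

CATEGORIES = ("age_associated", "age_varying", "both", "neither")


@dataclass
class CpGCallTable:
    """Per-CpG category calls plus the statistics behind them.

    ``table`` columns: category, lam (LRT statistic), p_slope, delta_aic,
    best_model, beta_age, p_fixed, threshold, converged, degenerate.
    ``slopes`` holds Model-2 per-subject slope BLUPs (subject x CpG,
    beta-units/year).
    """

    table: pd.DataFrame
    slopes: pd.DataFrame
    family_alpha: float
    criterion: str
    n_tests: int

    @property
    def counts(self) -> pd.Series:
        ok = self.table[self.table["converged"] & ~self.table["degenerate"]]
        return ok["category"].value_counts().reindex(CATEGORIES, fill_value=0)

    def members(self, category: str, inclusive: bool = False) -> pd.Index:
        """CpGs called ``category``; with ``inclusive=True`` the 'both' CpGs
        count toward age_associated and age_varying as well."""
        t = self.table
        mask = t["category"] == category
        if inclusive and category in ("age_associated", "age_varying"):
            mask |= t["category"] == "both"
        return t.index[mask]

    @property
    def universe(self) -> pd.Index:
        """All analyzed CpGs (the enrichment universe)."""
        return self.table.index

    def reclassify(self, family_alpha: Optional[float] = None,
                   criterion: Optional[str] = None) -> "CpGCallTable":
        """Re-threshold the stored statistics without refitting."""
        alpha = self.family_alpha if family_alpha is None else family_alpha
        crit = self.criterion if criterion is None else criterion
        t = self.table.copy()
        thr = alpha / self.n_tests
        varying = (t["delta_aic"] > 0 if crit == "delta_aic"
                   else t["p_slope"] < thr)
        assoc = t["p_fixed"] < thr
        t["category"] = np.select(
            [assoc & varying, varying, assoc],
            ["both", "age_varying", "age_associated"], default="neither")
        t.loc[~t["converged"] | t["degenerate"], "category"] = "excluded"
        t["threshold"] = thr
        return replace(self, table=t, family_alpha=alpha, criterion=crit)


def classify_cpgs(methylation: pd.DataFrame, design: LongitudinalDesign,
                  family_alpha: float = 0.05, criterion: str = "lrt_mixture",
                  force_model1_fixed: bool = False) -> CpGCallTable:
    """Run the two-step classification over a CpG x sample matrix.

    The family size M is the number of CpGs attempted (converged or not), so
    the Bonferroni threshold family_alpha / M does not depend on fit
    outcomes.  Non-converged or constant CpGs are flagged and excluded from
    the category counts.
    """
    if criterion not in ("lrt_mixture", "delta_aic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if methylation.shape[1] != len(design):
        raise ValueError(
            f"methylation has {methylation.shape[1]} samples but the design "
            f"has {len(design)} observations")
    M = methylation.shape[0]
    thr = family_alpha / M
    values = methylation.to_numpy(dtype=float)
    rows = []
    slope_blups = np.full((design.n_subjects, M), np.nan)
    for j in range(M):
        y = values[j]
        degenerate = bool(np.var(y) < 1e-14)
        try:
            f1 = fit_lmm(design, y, "intercept_only")
            f2 = fit_lmm(design, y, "intercept_slope",
                         start=np.array([f1.theta[0]]))
            test = lrt_random_slope(f1, f2)
            best = f2 if f2.aic < f1.aic else f1
            if force_model1_fixed:
                best = f1
            p_fixed = wald_age_p(best)
            converged = f1.converged and f2.converged and not f1.degenerate
            slope_blups[:, j] = f2.blup_slopes
            rows.append((test.statistic, test.pvalue, test.delta_aic,
                         best.model_kind, best.beta_age, p_fixed,
                         converged, degenerate))
        except DegenerateDesignError:
            rows.append((np.nan, np.nan, np.nan, "", np.nan, np.nan,
                         False, True))
    table = pd.DataFrame(
        rows, index=methylation.index,
        columns=["lam", "p_slope", "delta_aic", "best_model", "beta_age",
                 "p_fixed", "converged", "degenerate"])
    table.index.name = "cpg"
    n_bad = int((~table["converged"] | table["degenerate"]).sum())
    if n_bad:
        logger.warning("%d of %d CpGs flagged (non-converged or degenerate) "
                       "and excluded from category counts", n_bad, M)
    table["threshold"] = thr
    table["category"] = "neither"
    calls = CpGCallTable(
        table=table,
        slopes=pd.DataFrame(slope_blups, index=design.subjects,
                            columns=methylation.index),
        family_alpha=family_alpha, criterion=criterion, n_tests=M)
    return calls.reclassify()


# ---------------------------------------------------------------------------
# PCA diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """PCA of the sample x CpG matrix (CpGs centered, not scaled)."""

    scores: pd.DataFrame              # sample x component
    loadings: pd.DataFrame            # CpG x component, unit-norm columns
    explained_variance_ratio: np.ndarray


def pca_scores(methylation: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Principal components of methylation across samples.

    CpG columns are centered but not variance-scaled (beta-values share a
    common scale).  Each component's sign is oriented so its
    largest-magnitude loading is positive.
    """
    X = methylation.to_numpy(dtype=float).T      # samples x CpGs
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 samples and 2 CpGs")
    if n_components > min(n, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_cpgs)="
            f"{min(n, m)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((s ** 2).sum())
    evr = (s[:n_components] ** 2) / total_var
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=methylation.columns, columns=comp),
        loadings=pd.DataFrame(loadings, index=methylation.index, columns=comp),
        explained_variance_ratio=evr,
    )


def pc_age_association(pca: PCAResult, design: LongitudinalDesign
                       ) -> pd.DataFrame:
    """Mixed-model age association of each principal component.

    Fits both nested models per component (full covariate adjustment) and
    reports the fixed age effect from the random-slope model together with
    the boundary LRT of slope heterogeneity.
    """
    if len(pca.scores) != len(design):
        raise ValueError("scores do not align with the design")
    out = []
    for comp in pca.scores.columns:
        y = pca.scores[comp].to_numpy(dtype=float)
        f1 = fit_lmm(design, y, "intercept_only")
        f2 = fit_lmm(design, y, "intercept_slope",
                     start=np.array([f1.theta[0]]))
        test = lrt_random_slope(f1, f2)
        out.append((comp, f2.beta_age, wald_age_p(f2), test.statistic,
                    test.pvalue, test.delta_aic))
    return pd.DataFrame(out, columns=["component", "beta_age", "p_fixed",
                                      "lam", "p_slope", "delta_aic"]
                        ).set_index("component")


def loading_contrast(pca: PCAResult, calls: CpGCallTable,
                     min_cpgs: int = 10) -> pd.DataFrame:
    """Within-category paired contrast of |PC1| vs |PC2| loadings.

    Two-sided Wilcoxon signed-rank test per CpG category; a positive median
    difference means the category loads more heavily on PC1.
    """
    if not {"PC1", "PC2"}.issubset(pca.loadings.columns):
        raise ValueError("loadings for PC1 and PC2 are required")
    l1 = pca.loadings["PC1"].abs()
    l2 = pca.loadings["PC2"].abs()
    rows = []
    for cat in CATEGORIES:
        idx = calls.members(cat).intersection(pca.loadings.index)
        n = len(idx)
        if n < min_cpgs:
            warnings.warn(f"category {cat!r} has {n} < {min_cpgs} CpGs; "
                          "contrast reported as NA", UserWarning, stacklevel=2)
            rows.append((cat, n, np.nan, np.nan))
            continue
        d = (l1[idx] - l2[idx]).to_numpy()
        med = float(np.median(d))
        if np.all(d == 0):
            p = 1.0
        else:
            p = float(sps.wilcoxon(d, alternative="two-sided",
                                   zero_method="wilcox").pvalue)
        rows.append((cat, n, med, p))
    return pd.DataFrame(rows, columns=["category", "n", "median_diff", "p"]
                        ).set_index("category")
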