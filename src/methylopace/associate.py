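"""Associations between CpG change rates, organ paces and risk factors.

The CpG-organ analysis is a covariate-adjusted Pearson partial correlation
at the subject level: both the CpG's per-subject methylation change rate
(its random-slope BLUP) and the organ pace are residualized on the subject
covariates, and the residuals are correlated.  Time-varying covariates are
collapsed to subject level first (baseline age/smoking/drinking, mean
leukocyte proportions across waves).

Baseline risk factors (BMI, socioeconomic status) are related to the change
rates by per-CpG least squares, followed by a 2x2 Fisher contrast of the
significant-CpG counts between the age-varying and age-associated
categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enrich import ContingencyTable, EnrichmentResult, fisher_exact_2x2

__all__ = ["AssociationRecord", "partial_correlation", "subject_covariates",
           "cpg_organ_scan", "riskfactor_scan"]


class CollinearityError(ValueError):
    """Covariate matrix is rank deficient."""


@dataclass
class AssociationRecord:
    """One covariate-adjusted association."""

    x_name: str
    y_name: str
    r: float
    t: float
    df: int
    p: float
    n: int
    k: int                       # number of adjustment covariates
    degenerate: bool = False


def _check_full_rank(Z: np.ndarray, names) -> None:
    X = np.column_stack([np.ones(len(Z)), Z]) if Z.size else \
        np.ones((len(Z), 1))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for j in range(Z.shape[1]):
            keep = np.delete(np.arange(Z.shape[1]), j)
            Xs = np.column_stack([np.ones(len(Z)), Z[:, keep]])
            if np.linalg.matrix_rank(Xs) == Xs.shape[1]:
                bad.append(names[j] if names is not None else f"col{j}")
        raise CollinearityError(
            f"covariate matrix is rank deficient; collinear columns: "
            f"{bad or 'multiple'}")


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v)), Z]) if Z.size else \
        np.ones((len(v), 1))
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ coef


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        Z: Optional[np.ndarray] = None,
                        names=("x", "y"), z_names=None) -> AssociationRecord:
    """Pearson partial correlation of x and y given covariates Z.

    r is the Pearson correlation of the residuals after regressing x and y
    on [1, Z]; the test statistic is t = r * sqrt((n-2-k) / (1-r^2)) on
    n-2-k degrees of freedom.  With no covariates this reduces to the
    textbook Pearson r and its t-test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.empty((len(x), 0)) if Z is None else np.atleast_2d(
        np.asarray(Z, dtype=float))
    if Z.shape[0] != len(x) or len(y) != len(x):
        raise ValueError("x, y and Z must share the subject dimension")
    n, k = len(x), Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 subjects (n={n}, k={k})")
    for v, nm in ((x, names[0]), (y, names[1])):
        if np.ptp(v) == 0:
            raise ValueError(f"input vector {nm!r} is constant")
    _check_full_rank(Z, z_names)
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    sx, sy = rx.std(), ry.std()
    if sx < 1e-12 * max(x.std(), 1.0) or sy < 1e-12 * max(y.std(), 1.0):
        # one variable fully explained by the covariates
        return AssociationRecord(names[0], names[1], 0.0, 0.0, n - 2 - k,
                                 1.0, n, k, degenerate=True)
    r = float(np.clip((rx @ ry) / (n * sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return AssociationRecord(names[0], names[1], r, float(t), df, p, n, k)


def subject_covariates(sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Collapse the per-wave sample sheet to one row per subject.

    Baseline (first-wave) age, sex, smoking and drinking; leukocyte
    proportions averaged across waves.
    """
    sheet = sample_sheet.sort_values(["subject_id", "wave"])
    first = sheet.groupby("subject_id").first()
    out = first[["age", "sex", "smoking", "drinking"]].copy()
    for col in ("cd8t", "cd4t", "nk", "bcell"):
        out[col] = sheet.groupby("subject_id")[col].mean()
    return out


def _residualize_matrix(Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(Y.shape[0]), Z])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ coef


def cpg_organ_scan(slopes: pd.DataFrame, organ_paces: pd.DataFrame,
                   covariates: pd.DataFrame, alpha: float = 0.05,
                   bh: bool = False) -> tuple[pd.DataFrame, pd.Series]:
    """Partial correlations of every (CpG change rate, organ pace) pair.

    Parameters
    ----------
    slopes : subject x CpG change-rate matrix (restricted to age-varying
        CpGs by the caller, per the two-step approach)
    organ_paces : subject x organ composite pace
    covariates : subject x k adjustment covariates
    alpha : significance cutoff on the (raw, by default) p-values

    Returns the long record table and the per-organ count of significant
    CpGs.
    """
    if not slopes.index.equals(organ_paces.index):
        raise ValueError("subject mismatch between slopes and organ paces")
    if not slopes.index.equals(covariates.index):
        raise ValueError("subject mismatch between slopes and covariates")
    Z = covariates.to_numpy(dtype=float)
    _check_full_rank(Z, list(covariates.columns))
    n, k = Z.shape
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough subjects for the covariate count")
    RX = _residualize_matrix(slopes.to_numpy(dtype=float), Z)
    RY = _residualize_matrix(organ_paces.to_numpy(dtype=float), Z)
    RX = RX - RX.mean(axis=0)
    RY = RY - RY.mean(axis=0)
    sx = RX.std(axis=0)
    sy = RY.std(axis=0)
    sx[sx == 0] = np.nan
    sy[sy == 0] = np.nan
    r = (RX.T @ RY) / n / np.outer(sx, sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1, 0.0, p))
    rec = pd.DataFrame({
        "cpg": np.repeat(slopes.columns, organ_paces.shape[1]),
        "organ": np.tile(organ_paces.columns, slopes.shape[1]),
        "r": r.ravel(), "t": t.ravel(), "df": df, "p": p.ravel(),
        "n": n, "k": k,
    })
    pcol = "p"
    if bh:
        mask = rec["p"].notna()
        rec["p_adj"] = np.nan
        rec.loc[mask, "p_adj"] = sps.false_discovery_control(
            rec.loc[mask, "p"], method="bh")
        pcol = "p_adj"
    rec["significant"] = rec[pcol] < alpha
    counts = (rec[rec["significant"]].groupby("organ").size()
              .reindex(organ_paces.columns, fill_value=0))
    return rec, counts


def riskfactor_scan(factor: pd.Series, slopes: pd.DataFrame,
                    covariates: pd.DataFrame, categories: pd.Series,
                    alpha: float = 0.05
                    ) -> tuple[pd.DataFrame, EnrichmentResult]:
    """Baseline risk factor vs per-CpG change rates, with category contrast.

    For each CpG, least-squares regression of the change rate on the factor
    plus covariates; the factor's two-sided t-test p is recorded.  The
    significant counts are then contrasted between the age_varying and
    age_associated categories with a two-sided Fisher exact test.
    """
    if not slopes.index.equals(covariates.index):
        raise ValueError("subject mismatch between slopes and covariates")
    f = factor.reindex(slopes.index).to_numpy(dtype=float)
    if np.ptp(f) == 0:
        raise ValueError("risk factor is constant across subjects")
    Z = covariates.to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(f)), f, Z])
    _check_full_rank(X[:, 1:], ["factor"] + list(covariates.columns))
    Y = slopes.to_numpy(dtype=float)
    n, pdim = X.shape
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = n - pdim
    sigma2 = (resid ** 2).sum(axis=0) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef[1] / se
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    rec = pd.DataFrame({"coef": coef[1], "se": se, "t": t, "df": dof, "p": p,
                        "significant": p < alpha}, index=slopes.columns)
    cats = categories.reindex(slopes.columns)
    sig = rec["significant"]
    a = int(((cats == "age_varying") & sig).sum())
    b = int(((cats == "age_varying") & ~sig).sum())
    c = int(((cats == "age_associated") & sig).sum())
    d = int(((cats == "age_associated") & ~sig).sum())
    contrast = fisher_exact_2x2(ContingencyTable(
        a, b, c, d, row_labels=("age_varying", "age_associated"),
        col_labels=("significant", "not_significant")))
    return rec, contrast
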