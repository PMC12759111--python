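"""Phenotype-specific and organ-composite pace-of-aging scores.

Each macro-phenotype is fitted with a random-intercept/random-slope mixed
model (same covariate adjustment as the methylome scan); the per-subject
slope BLUP is that subject's phenotype-specific pace of aging, in phenotype
units per year.  Organ composites average the direction-aligned,
across-subject standardized phenotype paces within each of eight organ
systems, yielding a z-scaled rate per subject and organ.

Missing phenotype cells are completed deterministically: phenotypes with too
many holes are dropped, interior holes are linearly interpolated on age
within subject, remaining holes take the subject mean, then the cohort mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .lmm import LongitudinalDesign, fit_lmm

logger = logging.getLogger("methylopace.pace")

__all__ = ["OrganConfig", "PacePanel", "impute_phenotypes", "phenotype_pace",
           "organ_composite", "DEFAULT_ORGANS"]

DEFAULT_ORGANS = ("brain", "cardiovascular", "immune", "kidney", "liver",
                  "metabolic", "musculoskeletal", "physical")


@dataclass
class OrganConfig:
    """Organ system -> [(phenotype, direction)] with directions +/-1.

    The direction codes how the phenotype moves with aging, so aligned paces
    d_k * s_ik all point in the 'faster aging' direction before averaging.
    """

    systems: Mapping[str, List[Tuple[str, int]]] = field(default_factory=dict)

    def __post_init__(self):
        seen: Dict[str, str] = {}
        for organ, phens in self.systems.items():
            for name, d in phens:
                if d not in (-1, 1):
                    raise ValueError(
                        f"direction for {name!r} must be +1 or -1, got {d}")
                if name in seen:
                    raise ValueError(
                        f"phenotype {name!r} appears in both {seen[name]!r} "
                        f"and {organ!r}")
                seen[name] = organ

    @classmethod
    def from_simulation(cls, organ_config) -> "OrganConfig":
        """Strip the coupling column of a simulator organ mapping."""
        return cls({o: [(n, d) for (n, d, *_r) in phens]
                    for o, phens in organ_config.items()})

    @property
    def directions(self) -> pd.Series:
        return pd.Series({name: d for phens in self.systems.values()
                          for name, d in phens}, name="direction")


@dataclass
class PacePanel:
    """Per-subject phenotype paces and organ composites."""

    phenotype_pace: pd.DataFrame      # subject x phenotype (units/year)
    organ_pace: pd.DataFrame          # subject x organ (z-units/year)
    directions: pd.Series
    standardized: bool
    dropped_phenotypes: List[str] = field(default_factory=list)


def impute_phenotypes(panel: pd.DataFrame, design: LongitudinalDesign,
                      max_missing_fraction: float = 0.2) -> pd.DataFrame:
    """Complete a sample x phenotype panel deterministically.

    Phenotypes missing in more than ``max_missing_fraction`` of cells are
    dropped (logged).  Remaining holes that lie strictly inside a subject's
    observed age range are linearly interpolated on age; other holes take the
    subject mean, and subjects with no observation take the cohort mean.
    """
    if len(panel) != len(design):
        raise ValueError("phenotype panel does not align with the design")
    out = panel.copy()
    frac = out.isna().mean()
    drop = list(frac.index[frac > max_missing_fraction])
    for name in drop:
        logger.warning("dropping phenotype %r: %.0f%% missing (> %.0f%%)",
                       name, 100 * frac[name], 100 * max_missing_fraction)
    out = out.drop(columns=drop)
    if out.isna().to_numpy().any():
        age = design.age
        idx = design.subject_index
        for col in out.columns:
            v = out[col].to_numpy(dtype=float)
            if not np.isnan(v).any():
                continue
            cohort_mean = float(np.nanmean(v))
            for s in range(design.n_subjects):
                rows = np.flatnonzero(idx == s)
                vs = v[rows]
                obs = ~np.isnan(vs)
                if obs.all():
                    continue
                if not obs.any():
                    v[rows] = cohort_mean
                    continue
                a_obs = age[rows][obs]
                hole = rows[~obs]
                inner = (age[hole] > a_obs.min()) & (age[hole] < a_obs.max())
                if inner.any():
                    order = np.argsort(a_obs)
                    v[hole[inner]] = np.interp(age[hole[inner]],
                                               a_obs[order], vs[obs][order])
                if (~inner).any():
                    v[hole[~inner]] = float(vs[obs].mean())
            out[col] = v
    return out


def phenotype_pace(panel: pd.DataFrame, design: LongitudinalDesign
                   ) -> pd.DataFrame:
    """Per-phenotype subject slope BLUPs s_ik (phenotype units per year).

    Fits the random-intercept/random-slope model per phenotype with full
    covariate adjustment; non-converged phenotypes are excluded with a
    warning.
    """
    if len(panel) != len(design):
        raise ValueError("phenotype panel does not align with the design")
    if panel.isna().to_numpy().any():
        raise ValueError("panel has missing values; run impute_phenotypes first")
    paces = {}
    for col in panel.columns:
        y = panel[col].to_numpy(dtype=float)
        fit = fit_lmm(design, y, "intercept_slope")
        if not fit.converged:
            warnings.warn(f"phenotype {col!r} did not converge; excluded",
                          UserWarning, stacklevel=2)
            continue
        paces[col] = fit.blup_slopes
    return pd.DataFrame(paces, index=pd.Index(design.subjects,
                                              name="subject_id"))


def organ_composite(paces: pd.DataFrame, config: OrganConfig,
                    standardize: bool = True) -> PacePanel:
    """Direction-aligned arithmetic mean of phenotype paces per organ.

    With ``standardize=True`` (default) each phenotype pace is z-scored
    across subjects before aligning, so phenotypes with incommensurable
    units contribute equally; with ``standardize=False`` the raw aligned
    paces are averaged.
    """
    directions = config.directions
    organ_cols = {}
    dropped = []
    for organ, phens in config.systems.items():
        cols = []
        for name, d in phens:
            if name not in paces.columns:
                dropped.append(name)
                logger.warning("phenotype %r configured for organ %r is "
                               "absent from the pace panel", name, organ)
                continue
            s = paces[name].to_numpy(dtype=float)
            if standardize:
                sd = s.std()
                if sd == 0:
                    dropped.append(name)
                    logger.warning("phenotype %r has zero pace variance; "
                                   "excluded from organ %r", name, organ)
                    continue
                s = (s - s.mean()) / sd
            cols.append(d * s)
        if not cols:
            warnings.warn(f"organ {organ!r} has no surviving phenotypes; "
                          "composite is NA", UserWarning, stacklevel=2)
            organ_cols[organ] = np.full(len(paces), np.nan)
        else:
            organ_cols[organ] = np.mean(cols, axis=0)
    organ_df = pd.DataFrame(organ_cols, index=paces.index)
    return PacePanel(phenotype_pace=paces, organ_pace=organ_df,
                     directions=directions, standardized=standardize,
                     dropped_phenotypes=dropped)
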