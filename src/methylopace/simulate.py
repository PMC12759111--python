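"""Synthetic longitudinal methylation cohorts with known ground truth.

The generator reproduces the statistical structure the package's models
assume: 135 subjects measured at 3 waves over 5 years (405 observations),
baseline ages 70-81, per-CpG Gaussian random-intercept/random-slope
trajectories on the beta scale, covariates including a 5-part leukocyte
proportion simplex, and organ phenotypes whose per-subject slopes are coupled
to latent organ-level aging rates.  Every stochastic draw flows from a single
integer seed, so identical configurations are bit-reproducible.

CpG sites fall into four planted classes:

``null``            no age trend, no slope heterogeneity
``age_associated``  fixed age trend beta_age, no slope heterogeneity
``age_varying``     per-subject slopes b1_i ~ N(0, slope_sd^2), no mean trend
``both``            fixed trend plus slope heterogeneity

Ground truth (class labels, per-subject slopes, latent organ rates, fixed
effects) is returned alongside the data for recovery testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lmm import LongitudinalDesign

logger = logging.getLogger("methylopace.simulate")

__all__ = [
    "ConfigurationError",
    "CohortConfig",
    "TruthTables",
    "SimulatedCohort",
    "DEFAULT_ORGAN_CONFIG",
    "GENOMIC_FEATURES",
    "CLOCK_SIZES",
    "simulate_cohort",
    "planted_class_config",
    "inject_missing",
    "simulate_annotation",
    "simulate_clock_lists",
    "simulate_gene_sets",
    "simulate_ontology_edges",
    "design_covariate_columns",
]


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


#: Eight organ systems with (phenotype, direction of change with aging,
#: coupling of the phenotype's slope to the latent organ rate).
DEFAULT_ORGAN_CONFIG: Dict[str, List[Tuple[str, int, float]]] = {
    "brain": [("cognition", -1, 0.7), ("depression", +1, 0.7)],
    "cardiovascular": [("pulse_pressure", +1, 0.7), ("heart_rate", +1, 0.7)],
    "immune": [("wbc_count", +1, 0.7), ("lymphocyte_pct", -1, 0.7)],
    "kidney": [("creatinine", +1, 0.7), ("egfr", -1, 0.7)],
    "liver": [("alt", -1, 0.7), ("albumin", -1, 0.7)],
    "metabolic": [("bmi", +1, 0.7), ("hba1c", +1, 0.7)],
    "musculoskeletal": [("grip_strength", -1, 0.7), ("walking_speed", -1, 0.7)],
    "physical": [("frailty_index", +1, 0.7), ("tug_time", +1, 0.7)],
}

GENOMIC_FEATURES = ("First Exon", "5'UTR", "Exon Boundary", "TSS1500",
                    "3'UTR", "Body", "IGR", "TSS200")

#: Per-clock CpG counts present in a typical EPIC dataset after QC
#: (HannumAge, GrimAge, Zhang, PhenoAge, DunedinPACE).
CLOCK_SIZES = {"hannum": 64, "grimage": 327, "zhang": 508,
               "phenoage": 510, "dunedinpace": 169}

CPG_CLASSES = ("null", "age_associated", "age_varying", "both")

#: Covariate columns entering the fixed-effect design (monocyte proportion is
#: the omitted reference level of the leukocyte simplex).
DESIGN_COVARIATES = ("sex", "smoking", "drinking", "cd8t", "cd4t", "nk", "bcell")


def design_covariate_columns() -> Tuple[str, ...]:
    return DESIGN_COVARIATES


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Variance components are on the beta-value scale: ``intercept_sd``
    (sigma_b0), ``slope_sd`` (sigma_b1, beta-units/year) and ``residual_sd``
    (sigma_e).  ``beta_age_mean`` is the magnitude of the fixed age trend for
    the age-associated classes (random sign per CpG).
    """

    n_subjects: int = 135
    wave_offsets: Tuple[float, ...] = (0.0, 2.5, 5.0)
    baseline_age_range: Tuple[float, float] = (70.0, 81.0)
    female_fraction: float = 0.615
    n_cpgs: int = 2000
    class_fractions: Mapping[str, float] = field(default_factory=lambda: {
        "null": 0.70, "age_associated": 0.15, "age_varying": 0.10, "both": 0.05})
    beta_age_mean: float = 0.005
    slope_sd: float = 0.004
    intercept_sd: float = 0.02
    residual_sd: float = 0.005
    intercept_slope_corr: float = 0.0
    cell_type_concentration: Tuple[float, ...] = (6.0, 10.0, 3.0, 4.0, 4.0)
    cell_effect: float = 0.02
    organ_config: Mapping[str, List[Tuple[str, int, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in
                                 DEFAULT_ORGAN_CONFIG.items()})
    cpg_organ_coupling: Mapping[str, Tuple[int, float]] = field(
        default_factory=dict)
    pheno_trend: float = 0.3
    pheno_slope_sd: float = 0.5
    pheno_intercept_sd: float = 2.0
    pheno_residual_sd: float = 0.5
    class_overrides: Optional[Mapping[str, Mapping[str, float]]] = None
    missing_rate: float = 0.0
    m_values: bool = False
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_fractions sum to {total}, expected 1")
        unknown = set(self.class_fractions) - set(CPG_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown CpG classes {sorted(unknown)}")
        off = np.asarray(self.wave_offsets, dtype=float)
        if off[0] != 0 or np.any(np.diff(off) <= 0):
            raise ConfigurationError(
                "wave_offsets must start at 0 and increase strictly")
        for name in ("slope_sd", "intercept_sd", "residual_sd",
                     "pheno_slope_sd", "pheno_intercept_sd",
                     "pheno_residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if abs(self.intercept_slope_corr) > 1:
            raise ConfigurationError("|intercept_slope_corr| must be <= 1")
        for organ, phens in self.organ_config.items():
            for (_, d, rho) in phens:
                if d not in (-1, 1):
                    raise ConfigurationError(
                        f"direction must be +/-1 in organ {organ!r}")
                if abs(rho) > 1:
                    raise ConfigurationError(
                        f"|coupling| must be <= 1 in organ {organ!r}")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.class_overrides:
            for cls, over in self.class_overrides.items():
                if cls in ("null", "age_associated") and \
                        over.get("slope_sd", 0) > 0:
                    raise ConfigurationError(
                        f"slope_sd > 0 requested for class {cls!r}")
                if cls in ("null", "age_varying") and \
                        over.get("beta_age_mean", 0) != 0:
                    raise ConfigurationError(
                        f"nonzero beta_age_mean requested for class {cls!r}")

    def class_param(self, cls: str, name: str) -> float:
        if self.class_overrides and cls in self.class_overrides:
            if name in self.class_overrides[cls]:
                return float(self.class_overrides[cls][name])
        return float(getattr(self, name))


@dataclass
class TruthTables:
    """Ground truth emitted alongside a simulated cohort."""

    cpg_class: pd.Series                 # CpG -> class label
    true_subject_slopes: pd.DataFrame    # subject x CpG, b1_i (beta/yr)
    true_organ_rate: pd.DataFrame        # subject x organ, latent z-rate
    true_fixed_effects: pd.DataFrame     # CpG -> beta0, beta_age
    true_phenotype_slopes: pd.DataFrame  # subject x phenotype slope deviation


@dataclass
class SimulatedCohort:
    sample_sheet: pd.DataFrame           # one row per observation
    design: LongitudinalDesign
    methylation: pd.DataFrame            # CpG x sample
    phenotypes: pd.DataFrame             # sample x phenotype
    truth: TruthTables
    clamped_fraction: float = 0.0


def _beta_to_m(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    b = np.clip(beta, eps, 1 - eps)
    return np.log2(b / (1 - b))


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate one longitudinal cohort.

    Per CpG j and observation (i, t), on the beta scale:

        m_ijt = beta0_j + beta_age_j * age_c + sum_c gamma_cj * x_c
                + b0_ij + b1_ij * age_c + eps_ijt

    with (b0, b1) bivariate normal and age centered at the cohort mean
    baseline age; values are clamped to [0, 1] and the clamped fraction is
    logged.  Organ phenotypes get per-subject slopes coupled to a latent
    standard-normal organ rate with the configured coupling.
    """
    rng = np.random.default_rng(config.seed)
    S = config.n_subjects
    waves = np.asarray(config.wave_offsets, dtype=float)
    W = len(waves)
    n_obs = S * W

    subjects = np.array([f"S{i + 1:04d}" for i in range(S)])
    lo, hi = config.baseline_age_range
    base_age = rng.uniform(lo, hi, S)
    sex = (rng.random(S) < config.female_fraction).astype(int)  # 1 = female
    smoking = rng.choice(3, size=S, p=[0.60, 0.25, 0.15])
    drinking = rng.choice(3, size=S, p=[0.50, 0.35, 0.15])
    ses = rng.choice([1, 2, 3], size=S, p=[0.5, 0.3, 0.2])

    subj_idx = np.repeat(np.arange(S), W)
    wave_no = np.tile(np.arange(1, W + 1), S)
    age = base_age[subj_idx] + waves[wave_no - 1]
    cells = rng.dirichlet(config.cell_type_concentration, size=n_obs)

    sample_ids = np.array([f"{subjects[s]}_w{w}" for s, w in
                           zip(subj_idx, wave_no)])
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": subjects[subj_idx],
        "wave": wave_no,
        "age": age,
        "sex": sex[subj_idx],
        "smoking": smoking[subj_idx],
        "drinking": drinking[subj_idx],
        "ses": ses[subj_idx],
        "cd8t": cells[:, 0], "cd4t": cells[:, 1], "nk": cells[:, 2],
        "bcell": cells[:, 3], "mono": cells[:, 4],
    }).set_index("sample_id")

    design = LongitudinalDesign(
        subject_ids=sheet["subject_id"].to_numpy(),
        age=sheet["age"].to_numpy(),
        covariates=sheet[list(DESIGN_COVARIATES)].to_numpy(dtype=float),
        covariate_names=DESIGN_COVARIATES,
    )
    age_c = design.age_centered

    # ---- CpG classes -----------------------------------------------------
    n_cpg = config.n_cpgs
    counts = {c: int(round(config.class_fractions.get(c, 0.0) * n_cpg))
              for c in CPG_CLASSES}
    drift = n_cpg - sum(counts.values())
    counts["null"] += drift
    classes = np.concatenate([[c] * counts[c] for c in CPG_CLASSES])
    cpg_ids = np.array([f"cg{j + 1:07d}" for j in range(n_cpg)])

    has_trend = np.isin(classes, ("age_associated", "both"))
    has_slope = np.isin(classes, ("age_varying", "both"))

    beta0 = rng.uniform(0.15, 0.85, n_cpg)
    sign = rng.choice([-1.0, 1.0], size=n_cpg)
    beta_age = np.where(
        has_trend,
        sign * np.array([config.class_param(c, "beta_age_mean")
                         for c in classes]),
        0.0)

    # latent organ rates (shared with the phenotype block below)
    organs = list(config.organ_config)
    latent = rng.standard_normal((S, len(organs)))

    # per-CpG random effects
    sig_b0 = config.intercept_sd
    r01 = config.intercept_slope_corr
    b0_mat = rng.standard_normal((S, n_cpg)) * sig_b0
    slope_sd_j = np.where(
        has_slope,
        np.array([config.class_param(c, "slope_sd") for c in classes]), 0.0)
    raw_u = rng.standard_normal((S, n_cpg))
    # correlated with the intercept draw where requested
    u = r01 * (b0_mat / sig_b0 if sig_b0 > 0 else 0.0) + \
        np.sqrt(max(1 - r01 ** 2, 0.0)) * raw_u
    b1_mat = u * slope_sd_j[None, :]

    # optional coupling of age-varying CpG slopes to latent organ rates
    coupled_organ = np.full(n_cpg, "", dtype=object)
    varying_pool = list(np.flatnonzero(has_slope))
    for organ, (n_c, rho) in config.cpg_organ_coupling.items():
        if organ not in config.organ_config:
            raise ConfigurationError(f"unknown organ {organ!r} in coupling")
        take = varying_pool[:n_c]
        varying_pool = varying_pool[n_c:]
        if len(take) < n_c:
            raise ConfigurationError(
                "not enough age-varying CpGs to satisfy cpg_organ_coupling")
        o = organs.index(organ)
        mix = rho * latent[:, [o]] + \
            np.sqrt(1 - rho ** 2) * rng.standard_normal((S, len(take)))
        b1_mat[:, take] = mix * slope_sd_j[take][None, :]
        coupled_organ[take] = organ

    gamma_cells = np.full(4, config.cell_effect)  # cd8t, cd4t, nk, bcell
    cell_term = design.covariates[:, 3:7] @ gamma_cells

    meth = (beta0[None, :] + np.outer(age_c, beta_age)
            + cell_term[:, None]
            + b0_mat[subj_idx, :] + b1_mat[subj_idx, :] * age_c[:, None]
            + rng.standard_normal((n_obs, n_cpg)) * config.residual_sd)
    clamped = float(np.mean((meth < 0) | (meth > 1)))
    meth = np.clip(meth, 0.0, 1.0)
    logger.info("clamped %.4f%% of methylation values to [0, 1]",
                100 * clamped)
    if config.m_values:
        meth = _beta_to_m(meth)
    meth_df = pd.DataFrame(meth.T, index=pd.Index(cpg_ids, name="cpg"),
                           columns=sample_ids)

    # ---- organ phenotypes -----------------------------------------------
    phen_cols, phen_truth = {}, {}
    for o, organ in enumerate(organs):
        for (name, d, rho) in config.organ_config[organ]:
            dev = config.pheno_slope_sd * (
                rho * latent[:, o]
                + np.sqrt(1 - rho ** 2) * rng.standard_normal(S))
            slope_i = d * (config.pheno_trend + dev)
            b0p = rng.standard_normal(S) * config.pheno_intercept_sd
            vals = (50.0 + slope_i[subj_idx] * age_c + b0p[subj_idx]
                    + rng.standard_normal(n_obs) * config.pheno_residual_sd)
            phen_cols[name] = vals
            phen_truth[name] = d * dev    # deviation part = true pace
    phen_df = pd.DataFrame(phen_cols, index=pd.Index(sample_ids,
                                                     name="sample_id"))
    if config.missing_rate > 0:
        phen_df = inject_missing(phen_df, config.missing_rate,
                                 seed=config.seed + 1)

    truth = TruthTables(
        cpg_class=pd.Series(classes, index=cpg_ids, name="class"),
        true_subject_slopes=pd.DataFrame(b1_mat, index=subjects,
                                         columns=cpg_ids),
        true_organ_rate=pd.DataFrame(latent, index=subjects, columns=organs),
        true_fixed_effects=pd.DataFrame(
            {"beta0": beta0, "beta_age": beta_age,
             "coupled_organ": coupled_organ}, index=cpg_ids),
        true_phenotype_slopes=pd.DataFrame(phen_truth, index=subjects),
    )
    return SimulatedCohort(sample_sheet=sheet.reset_index(), design=design,
                           methylation=meth_df, phenotypes=phen_df,
                           truth=truth, clamped_fraction=clamped)


def planted_class_config(seed: int = 1, n_per_class: int = 500,
                         n_subjects: int = 135) -> CohortConfig:
    """Strong-effect recovery fixture with equal planted classes.

    Effects are set relative to the noise level: the fixed trend moves a CpG
    by 5 residual SDs over the 5-year follow-up, and the slope SD is well
    above the per-subject slope standard error (sigma_e / sqrt(J) with
    J = sum of squared centered wave offsets), so each class is separable at
    a Bonferroni threshold.
    """
    residual_sd = 0.005
    span = 5.0
    return CohortConfig(
        n_subjects=n_subjects,
        n_cpgs=4 * n_per_class,
        class_fractions={c: 0.25 for c in CPG_CLASSES},
        beta_age_mean=5 * residual_sd / span,
        slope_sd=0.004,
        intercept_sd=0.02,
        residual_sd=residual_sd,
        seed=seed,
    )


def inject_missing(panel: pd.DataFrame, missing_rate: float,
                   seed: int = 0) -> pd.DataFrame:
    """Mask each cell independently with probability ``missing_rate``."""
    if not (0 <= missing_rate < 1):
        raise ConfigurationError("missing_rate must be in [0, 1)")
    if missing_rate == 0:
        return panel.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(panel.shape) < missing_rate
    out = panel.copy()
    out[mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# Synthetic annotation resources (fixture-scale stand-ins for array manifests,
# clock CpG lists, gene-set collections and ontologies)
# ---------------------------------------------------------------------------

_FEATURE_PROBS = (0.05, 0.08, 0.03, 0.12, 0.04, 0.35, 0.25, 0.08)


def simulate_annotation(cpg_ids: Sequence[str], seed: int = 0,
                        genes_per_cpg: float = 3.0,
                        dhs_fraction: float = 0.25) -> pd.DataFrame:
    """Synthetic CpG annotation: gene, genomic feature and DHS flag."""
    rng = np.random.default_rng(seed)
    n = len(cpg_ids)
    n_genes = max(int(n / genes_per_cpg), 1)
    genes = np.array([f"GENE{i + 1:05d}" for i in range(n_genes)])
    return pd.DataFrame({
        "cpg": list(cpg_ids),
        "gene": genes[rng.integers(0, n_genes, n)],
        "feature": rng.choice(GENOMIC_FEATURES, size=n, p=_FEATURE_PROBS),
        "dhs": (rng.random(n) < dhs_fraction).astype(int),
    })


def simulate_clock_lists(cpg_ids: Sequence[str], seed: int = 0,
                         sizes: Optional[Mapping[str, int]] = None
                         ) -> Dict[str, List[str]]:
    """Synthetic epigenetic-clock CpG lists drawn from the universe."""
    rng = np.random.default_rng(seed)
    sizes = dict(CLOCK_SIZES if sizes is None else sizes)
    ids = np.asarray(cpg_ids)
    out = {}
    for clock, size in sizes.items():
        k = min(int(size), len(ids))
        out[clock] = sorted(rng.choice(ids, size=k, replace=False).tolist())
    return out


def simulate_gene_sets(genes: Sequence[str], seed: int = 0,
                       n_terms: int = 25, size_range: Tuple[int, int] = (10, 50),
                       sources: Sequence[str] = ("GO", "KEGG", "Reactome")
                       ) -> Dict[str, Dict[str, set]]:
    """Random gene sets per source, GMT-style (term -> set of genes)."""
    rng = np.random.default_rng(seed)
    genes = np.asarray(genes)
    out: Dict[str, Dict[str, set]] = {}
    for src in sources:
        terms = {}
        for t in range(n_terms):
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            size = min(size, len(genes))
            term_id = f"{src.upper()}:{t + 1:04d}"
            terms[term_id] = set(rng.choice(genes, size=size, replace=False))
        out[src] = terms
    return out


def simulate_ontology_edges(term_ids: Sequence[str], seed: int = 0,
                            part_of_fraction: float = 0.2) -> pd.DataFrame:
    """A random tree over ``term_ids`` (child, parent, relation) plus a root."""
    rng = np.random.default_rng(seed)
    terms = list(term_ids)
    root = "GO:ROOT"
    rows = []
    placed = [root]
    for t in terms:
        parent = placed[int(rng.integers(0, len(placed)))]
        rel = "part_of" if rng.random() < part_of_fraction else "is_a"
        rows.append((t, parent, rel))
        placed.append(t)
    return pd.DataFrame(rows, columns=["child", "parent", "relation"])
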