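"""File formats, configuration and the end-to-end pipeline driver.

All tables are tab-separated UTF-8 with '.' decimals and 'NA' for missing
values; writers put a commented metadata header (tool version, seed, the
analysis decisions in force) above the column header.  The methylation
matrix is CpG x sample; the reader transposes (and logs) when it recognizes
a sample-oriented header token.  Outputs contain no timestamps, so repeated
runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associate import cpg_organ_scan, subject_covariates
from .enrich import clock_enrichment, dhs_enrichment, feature_distribution
from .lmm import LongitudinalDesign
from .pace import OrganConfig, impute_phenotypes, organ_composite, phenotype_pace
from .pathways import OntologyGraph, enrich_terms, reduce_terms
from .scan import classify_cpgs, loading_contrast, pc_age_association, pca_scores
from .simulate import (CohortConfig, DESIGN_COVARIATES, simulate_annotation,
                       simulate_clock_lists, simulate_cohort,
                       simulate_gene_sets, simulate_ontology_edges)

logger = logging.getLogger("methylopace.io")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_table",
           "read_table", "read_metadata", "read_sample_sheet",
           "read_methylation", "read_phenotypes", "read_annotation",
           "read_clock_list", "read_gmt", "write_gmt", "read_organ_config",
           "read_ontology_edges", "design_from_sample_sheet", "setup_logging"]

_FLOAT_FMT = "%.15g"
SAMPLE_SHEET_COLUMNS = ("sample_id", "subject_id", "wave", "age", "sex",
                        "smoking", "drinking", "cd8t", "cd4t", "nk", "bcell",
                        "mono")
_CPG_TOKENS = {"cpg", "cpg_id", "probe", "probe_id"}
_SAMPLE_TOKENS = {"sample", "sample_id"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path, metadata: Optional[Mapping] = None,
                index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# methylopace {__version__}\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, sep="\t", na_rep="NA", index=index,
                     float_format=_FLOAT_FMT, lineterminator="\n")


def read_metadata(path) -> Dict[str, str]:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_table(path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col,
                       na_values=["NA"], keep_default_na=False)


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = read_table(path)
    _require_columns(sheet, SAMPLE_SHEET_COLUMNS, path)
    return sheet


def read_methylation(path) -> pd.DataFrame:
    meth = read_table(path, index_col=0)
    token = (meth.index.name or "").lower()
    if token in _SAMPLE_TOKENS:
        logger.info("methylation matrix at %s is sample-oriented; transposing",
                    path)
        meth = meth.T
        meth.index.name = "cpg"
    elif token not in _CPG_TOKENS:
        logger.warning("unrecognized methylation index token %r at %s; "
                       "assuming rows are CpGs", token, path)
    return meth


def read_phenotypes(path) -> pd.DataFrame:
    return read_table(path, index_col=0)


def read_annotation(path) -> pd.DataFrame:
    ann = read_table(path)
    _require_columns(ann, ("cpg", "gene", "feature", "dhs"), path)
    return ann


def read_clock_list(path) -> List[str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"clock list not found: {path}")
    out = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gmt(path) -> Dict[str, Set[str]]:
    """GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    sets: Dict[str, Set[str]] = {}
    for ln, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs term, description "
                             "and at least one gene")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(gene_sets: Mapping[str, Set[str]], path,
              description: str = "synthetic") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[term]))
            fh.write(f"{term}\t{description}\t{genes}\n")


def read_organ_config(path) -> OrganConfig:
    frame = read_table(path)
    _require_columns(frame, ("organ", "phenotype", "direction"), path)
    systems: Dict[str, list] = {}
    for row in frame.itertuples(index=False):
        systems.setdefault(row.organ, []).append(
            (row.phenotype, int(row.direction)))
    return OrganConfig(systems)


def read_ontology_edges(path) -> pd.DataFrame:
    frame = read_table(path)
    _require_columns(frame, ("child", "parent", "relation"), path)
    return frame


def design_from_sample_sheet(sheet: pd.DataFrame) -> LongitudinalDesign:
    """Build the fitting design from a sample sheet.

    Covariates: sex, smoking, drinking and four leukocyte proportions (the
    monocyte fraction is the omitted simplex reference).
    """
    return LongitudinalDesign(
        subject_ids=sheet["subject_id"].to_numpy(),
        age=sheet["age"].to_numpy(dtype=float),
        covariates=sheet[list(DESIGN_COVARIATES)].to_numpy(dtype=float),
        covariate_names=DESIGN_COVARIATES,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for a full pipeline run."""

    outdir: str = "methylopace_out"
    simulate: bool = True
    n_subjects: int = 135
    n_cpgs: int = 2000
    sample_sheet: Optional[str] = None
    methylation: Optional[str] = None
    phenotypes: Optional[str] = None
    annotation: Optional[str] = None
    clock_lists: Dict[str, str] = field(default_factory=dict)
    gene_sets: Dict[str, str] = field(default_factory=dict)  # source -> GMT
    ontology: Optional[str] = None
    organ_config: Optional[str] = None
    family_alpha: float = 0.05
    criterion: str = "lrt_mixture"
    alpha: float = 0.05
    standardize: bool = True
    similarity_threshold: float = 0.5
    terms_per_source: int = 15
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _meta(config: PipelineConfig, **extra) -> Dict[str, object]:
    base = {
        "seed": config.seed,
        "family_alpha": config.family_alpha,
        "criterion": config.criterion,
        "slope_test_null": "0.5*chi2(1) + 0.5*chi2(2)",
        "fixed_effect_test": "Wald z from best-AIC model",
        "covariate_collapse": ("baseline age/sex/smoking/drinking, "
                               "mean leukocyte proportions"),
        "pace_standardized": config.standardize,
    }
    base.update(extra)
    return base


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Execute simulate (optional) -> scan -> pace -> associate -> enrich ->
    reduce, writing one or more TSV artifacts per stage under
    ``config.outdir``.  Raises :class:`PipelineError` naming the failing
    stage."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, index=True, **extra) -> None:
        path = out / name
        write_table(frame, path, metadata=_meta(config, **extra), index=index)
        artifacts[name] = path

    # ---- stage: simulate / load -----------------------------------------
    stage = "simulate" if config.simulate else "load"
    try:
        if config.simulate:
            cohort = simulate_cohort(CohortConfig(
                n_subjects=config.n_subjects, n_cpgs=config.n_cpgs,
                seed=config.seed))
            sheet = cohort.sample_sheet
            meth = cohort.methylation
            phen = cohort.phenotypes
            design = cohort.design
            ann = simulate_annotation(meth.index, seed=config.seed + 2)
            clocks = simulate_clock_lists(meth.index, seed=config.seed + 3)
            genes = sorted(ann["gene"].unique())
            sets = simulate_gene_sets(genes, seed=config.seed + 4)
            onto_edges = simulate_ontology_edges(sorted(sets["GO"]),
                                                 seed=config.seed + 5)
            organ_cfg = OrganConfig.from_simulation(
                CohortConfig().organ_config)
            emit("sample_sheet.tsv", sheet, index=False)
            emit("methylation.tsv", meth)
            emit("phenotypes.tsv", phen)
            emit("annotation.tsv", ann, index=False)
            emit("truth_cpg_class.tsv", cohort.truth.cpg_class.to_frame())
            for clock, cpgs in sorted(clocks.items()):
                p = out / f"{clock}.txt"
                p.write_text("\n".join(cpgs) + "\n", encoding="utf-8")
                artifacts[p.name] = p
            for src, s in sorted(sets.items()):
                p = out / f"gene_sets_{src.lower()}.gmt"
                write_gmt(s, p)
                artifacts[p.name] = p
            emit("ontology_edges.tsv", onto_edges, index=False)
            rows = [(o, n, d) for o, phens in organ_cfg.systems.items()
                    for n, d in phens]
            emit("organ_config.tsv",
                 pd.DataFrame(rows, columns=["organ", "phenotype",
                                             "direction"]), index=False)
        else:
            sheet = read_sample_sheet(_require(config.sample_sheet,
                                               "sample_sheet", stage))
            meth = read_methylation(_require(config.methylation,
                                             "methylation", stage))
            phen = read_phenotypes(_require(config.phenotypes, "phenotypes",
                                            stage))
            phen = phen.reindex(sheet["sample_id"])
            ann = (read_annotation(config.annotation)
                   if config.annotation else None)
            clocks = {name: read_clock_list(p)
                      for name, p in config.clock_lists.items()}
            sets = {src: read_gmt(p)
                    for src, p in config.gene_sets.items()}
            onto_edges = (read_ontology_edges(config.ontology)
                          if config.ontology else None)
            organ_cfg = (read_organ_config(config.organ_config)
                         if config.organ_config else
                         OrganConfig.from_simulation(
                             CohortConfig().organ_config))
            design = design_from_sample_sheet(sheet)
            if meth.shape[1] != len(design):
                raise ValueError(
                    f"methylation has {meth.shape[1]} samples but the sample "
                    f"sheet has {len(design)} rows")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: scan -----------------------------------------------------
    try:
        calls = classify_cpgs(meth, design, family_alpha=config.family_alpha,
                              criterion=config.criterion)
        emit("calls.tsv", calls.table)
        emit("slopes.tsv", calls.slopes.rename_axis("subject_id"))
        n_comp = min(2, min(meth.shape) - 1)
        pca = pca_scores(meth, n_components=max(n_comp, 1))
        pc_assoc = pc_age_association(pca, design)
        emit("pca_age.tsv", pc_assoc,
             explained_variance=",".join(
                 f"{v:.6g}" for v in pca.explained_variance_ratio))
        if "PC2" in pca.loadings.columns:
            emit("pca_loading_contrast.tsv", loading_contrast(pca, calls))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("scan", str(exc)) from exc

    # ---- stage: pace -----------------------------------------------------
    try:
        completed = impute_phenotypes(phen, design)
        paces = phenotype_pace(completed, design)
        panel = organ_composite(paces, organ_cfg,
                                standardize=config.standardize)
        both = paces.join(panel.organ_pace, rsuffix="_organ")
        emit("paces.tsv", both)
        emit("organ_pace_matrix.tsv", panel.organ_pace.T.rename_axis("organ"))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("pace", str(exc)) from exc

    # ---- stage: associate ------------------------------------------------
    try:
        varying = calls.members("age_varying", inclusive=True)
        covars = subject_covariates(sheet)
        subj = panel.organ_pace.index
        if len(varying):
            slopes = calls.slopes.loc[subj, varying]
            rec, counts = cpg_organ_scan(slopes, panel.organ_pace,
                                         covars.loc[subj],
                                         alpha=config.alpha)
        else:
            rec = pd.DataFrame(columns=["cpg", "organ", "r", "t", "df", "p",
                                        "n", "k", "significant"])
            counts = pd.Series(0, index=panel.organ_pace.columns)
        emit("assoc.tsv", rec, index=False)
        emit("assoc_counts.tsv", counts.rename("n_significant").to_frame())
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("associate", str(exc)) from exc

    # ---- stage: enrich ---------------------------------------------------
    try:
        if ann is not None:
            ann_idx = ann.set_index("cpg")
            if clocks:
                emit("clock_enrichment.tsv",
                     clock_enrichment(calls, clocks), index=False)
            dhs = dhs_enrichment(calls, ann_idx["dhs"])
            emit("dhs_enrichment.tsv", pd.DataFrame([{
                "odds_ratio": dhs.odds_ratio, "ci_low": dhs.ci_low,
                "ci_high": dhs.ci_high, "p": dhs.pvalue}]), index=False)
            counts_t, props, chi_p = feature_distribution(
                calls, ann_idx["feature"])
            emit("feature_counts.tsv", counts_t, chi2_p=f"{chi_p:.6g}")
            emit("feature_proportions.tsv", props)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("enrich", str(exc)) from exc

    # ---- stage: reduce ---------------------------------------------------
    try:
        if ann is not None and sets:
            ann_idx = ann.set_index("cpg")
            sig_cpgs = set(rec.loc[rec["significant"], "cpg"]) \
                if len(rec) else set()
            if not sig_cpgs:
                sig_cpgs = set(varying)
            universe = set(ann_idx["gene"])
            query = set(ann_idx.loc[ann_idx.index.intersection(
                pd.Index(sorted(sig_cpgs))), "gene"])
            all_terms = []
            for src in sorted(sets):
                if not query:
                    break
                recs = enrich_terms(query, sets[src], universe, source=src)
                recs.sort(key=lambda r: (r.raw_p, r.term))
                all_terms.extend(recs[:config.terms_per_source])
            if all_terms:
                onto = (OntologyGraph.from_frame(onto_edges)
                        if onto_edges is not None else None)
                graph = reduce_terms(all_terms,
                                     threshold=config.similarity_threshold,
                                     ontology=onto,
                                     jaccard_fallback=onto is None)
                emit("terms.tsv", graph.to_frame(), index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("reduce", str(exc)) from exc

    return artifacts


def _require(value, name, stage):
    if value is None:
        raise PipelineError(stage, f"required input {name!r} not configured")
    path = Path(value)
    if not path.exists():
        raise PipelineError(stage, f"missing input file for {name!r}: {path}")
    return path
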