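"""End-to-end orchestration, cohort summary tables, and purity confounding.

``run`` executes the stages in dependency order from a single
:class:`RunConfig` (inputs read from disk, or a cohort simulated inline),
writes every result table as TSV into the output directory, and records a
manifest with the parameters actually used. With a fixed seed two runs
produce byte-identical tables.

``cohort_summary`` reproduces the pipeline's patient-level bookkeeping: per
tumor type, how many patients carry at least one matrisome CNA, and how many
carry at least one matrisome mutation, with integer percentages and a totals
row. ``purity_confounding`` regresses per-patient alteration counts on the
consensus purity estimate (CPE) per tumor with a GLM, to gauge whether tumor
purity confounds the alteration burden.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from ._errors import ConfigError
from . import io_formats as io
from . import cna_analysis, domain_impact, mutation_analysis, survival_screen
from .synthetic_cohort import CohortConfig, SyntheticCohort, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("cna", "mutations", "domains", "survival", "summary")


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def _pct_half_up(count: int, total: int) -> int:
    """Integer percentage with round-half-up (773/1236 -> 63)."""
    if total == 0:
        return 0
    return int(math.floor(100.0 * count / total + 0.5))


def cohort_summary(cna: pd.DataFrame, mutations: pd.DataFrame,
                   clinical: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Patients per tumor with >=1 matrisome CNA and >=1 matrisome mutation."""
    mat_genes = set(annotation.loc[annotation["division"] != "non-matrisome",
                                   "gene_symbol"])
    cna_mat = cna.loc[cna.index.isin(mat_genes)]
    has_cna = set(cna_mat.columns[(cna_mat != 0).any(axis=0)])
    has_mut = set(mutations.loc[mutations["gene_symbol"].isin(mat_genes), "sample"])
    counts = (clinical.groupby("tumor_type", sort=True)
              .agg(n_patients=("sample", "size"),
                   n_matrisome_cna=("sample", lambda s: s.isin(has_cna).sum()),
                   n_matrisome_mutation=("sample", lambda s: s.isin(has_mut).sum()))
              .reset_index())
    return summary_from_counts(counts)


def summary_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Add integer percentages and the totals row to per-tumor patient counts.

    Expects columns tumor_type, n_patients, n_matrisome_cna,
    n_matrisome_mutation (e.g. from :func:`cohort_summary` or a published
    per-cohort tally).
    """
    out = counts.copy()
    total = pd.DataFrame([{
        "tumor_type": "Total",
        "n_patients": int(out["n_patients"].sum()),
        "n_matrisome_cna": int(out["n_matrisome_cna"].sum()),
        "n_matrisome_mutation": int(out["n_matrisome_mutation"].sum()),
    }])
    out = pd.concat([out, total], ignore_index=True)
    out["pct_matrisome_cna"] = [
        _pct_half_up(c, n) for c, n in zip(out["n_matrisome_cna"], out["n_patients"])]
    out["pct_matrisome_mutation"] = [
        _pct_half_up(c, n) for c, n in zip(out["n_matrisome_mutation"], out["n_patients"])]
    return out[["tumor_type", "n_patients", "n_matrisome_cna", "pct_matrisome_cna",
                "n_matrisome_mutation", "pct_matrisome_mutation"]]


def load_reference_counts() -> pd.DataFrame:
    """Published per-cohort patient counts bundled with the package."""
    with resources.files("matrisome_scan.data").joinpath(
            "tcga_cohort_counts.tsv").open("rb") as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_incidence() -> pd.DataFrame:
    """Published per-cancer-type incidence/mortality figures bundled with the package."""
    with resources.files("matrisome_scan.data").joinpath(
            "tcga_incidence.tsv").open("rb") as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# purity confounding
# ---------------------------------------------------------------------------

def alteration_counts(cna: pd.DataFrame, mutations: pd.DataFrame,
                      clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-patient counts of altered genes (CNA) and mutation records."""
    cna_count = (cna != 0).sum(axis=0)
    mut_count = mutations.groupby("sample").size()
    return pd.DataFrame({
        "sample": clinical["sample"],
        "tumor_type": clinical["tumor_type"],
        "cna_count": clinical["sample"].map(cna_count).fillna(0).astype(int),
        "mutation_count": clinical["sample"].map(mut_count).fillna(0).astype(int),
    })


def purity_confounding(counts: pd.DataFrame, clinical: pd.DataFrame,
                       family: str = "gaussian", min_patients: int = 10) -> pd.DataFrame:
    """Per-tumor GLM of alteration counts on consensus purity (CPE).

    Default family is Gaussian on log1p(count); ``family="poisson"`` or
    ``"negative_binomial"`` fit the raw counts instead. Tumors with fewer than
    ``min_patients`` CPE measurements, or constant CPE, are skipped (logged).
    Returns one row per (tumor, count kind) with coefficient, SE and p-value.
    """
    table = counts.merge(clinical[["sample", "cpe"]], on="sample")
    rows = []
    for tumor, grp in table.groupby("tumor_type", sort=True):
        grp = grp.dropna(subset=["cpe"])
        if len(grp) < min_patients:
            logger.info("tumor %s skipped: only %d patients with CPE", tumor, len(grp))
            continue
        if grp["cpe"].nunique() < 2:
            logger.info("tumor %s skipped: constant CPE (degenerate design)", tumor)
            continue
        design = sm.add_constant(grp["cpe"].to_numpy())
        for kind in ("cna_count", "mutation_count"):
            if family == "gaussian":
                y = np.log1p(grp[kind].to_numpy(dtype=float))
                model = sm.GLM(y, design, family=sm.families.Gaussian())
            elif family == "poisson":
                model = sm.GLM(grp[kind].to_numpy(dtype=float), design,
                               family=sm.families.Poisson())
            elif family == "negative_binomial":
                model = sm.GLM(grp[kind].to_numpy(dtype=float), design,
                               family=sm.families.NegativeBinomial())
            else:
                raise ConfigError(f"unknown GLM family {family!r}")
            fit = model.fit()
            rows.append({
                "tumor_type": tumor, "kind": kind, "family": family,
                "n": len(grp), "coef": float(fit.params[1]),
                "se": float(fit.bse[1]), "p_value": float(fit.pvalues[1]),
                "ci_low": float(fit.conf_int()[1][0]),
                "ci_high": float(fit.conf_int()[1][1]),
            })
    return pd.DataFrame(rows, columns=["tumor_type", "kind", "family", "n",
                                       "coef", "se", "p_value", "ci_low", "ci_high"])


# ---------------------------------------------------------------------------
# run orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One config to drive the whole pipeline.

    Exactly one of ``simulate`` (inline cohort parameters) or ``inputs``
    (paths to annotation/cna/expression/maf/clinical/domains files) must be
    given. ``seed`` overrides the simulation seed and seeds the randomization
    suite.
    """

    outdir: str | Path = "results"
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    stages: tuple[str, ...] = ALL_STAGES
    cna_directions: tuple[str, ...] = ("any", "gain", "loss")
    randomization_reps: int = 1000
    expression_threshold: float = 0.5
    survival: dict = field(default_factory=dict)
    top_k_domains: int = 20
    glm_family: str = "gaussian"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' or 'inputs' must be set")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "cna_directions" in raw:
            raw["cna_directions"] = tuple(raw["cna_directions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        return d


def _load_cohort(config: RunConfig) -> SyntheticCohort:
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim["seed"] = config.seed
        return generate_cohort(CohortConfig.from_dict(sim))
    paths = config.inputs
    return SyntheticCohort(
        annotation=io.read_gene_list(paths["annotation"]),
        cna=io.read_matrix(paths["cna"], "cna"),
        expression=io.read_matrix(paths["expression"], "expression"),
        mutations=io.read_maf(paths["maf"]),
        clinical=io.read_clinical(paths["clinical"]),
        domains=io.read_domains(paths["domains"]) if "domains" in paths
        else pd.DataFrame(columns=list(io.DOMAIN_COLUMNS)),
        truth={},
    )


def run(config: RunConfig) -> dict:
    """Execute the enabled stages and write all result tables plus a manifest.

    Returns the manifest dict. A stage failure is recorded in the manifest
    and aborts that stage's outputs without touching the others.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = _load_cohort(config)
    if config.simulate is not None:
        write_cohort(cohort, outdir / "cohort")

    manifest: dict = {"config": config.to_dict(), "seed": config.seed,
                      "stages": {}, "outputs": []}
    runners = {"cna": _stage_cna, "mutations": _stage_mutations,
               "domains": _stage_domains, "survival": _stage_survival,
               "summary": _stage_summary}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        start = time.perf_counter()
        try:
            files = runners[stage](cohort, config, outdir)
            manifest["stages"][stage] = {
                "status": "ok", "runtime_s": round(time.perf_counter() - start, 3)}
            manifest["outputs"].extend(str(f) for f in files)
        except Exception as exc:
            logger.exception("stage %s failed", stage)
            manifest["stages"][stage] = {
                "status": "failed", "error": f"{type(exc).__name__}: {exc}",
                "runtime_s": round(time.perf_counter() - start, 3)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_cna(cohort: SyntheticCohort, config: RunConfig, outdir: Path) -> list[Path]:
    freqs = pd.concat(
        [cna_analysis.cna_frequency(cohort.cna, cohort.clinical, d)
         for d in config.cna_directions], ignore_index=True)
    comparison = cna_analysis.compare_bins(freqs, cohort.annotation)
    effects = cna_analysis.expression_effect(
        cohort.cna, cohort.expression, cohort.clinical, cohort.annotation,
        threshold=config.expression_threshold)
    effect_summary = cna_analysis.summarize_effects(effects)
    files = {
        outdir / "cna_frequency.tsv": (freqs, ["tumor_type", "direction", "gene_symbol"]),
        outdir / "bin_comparison.tsv": (comparison, ["tumor_type", "direction"]),
        outdir / "expression_effects.tsv": (effects, ["tumor_type", "gene_symbol"]),
        outdir / "expression_effect_summary.tsv": (effect_summary,
                                                   ["tumor_type", "division"]),
    }
    for path, (table, keys) in files.items():
        io.write_result_table(table, path, sort_by=keys)
    return list(files)


def _stage_mutations(cohort: SyntheticCohort, config: RunConfig, outdir: Path) -> list[Path]:
    burden = mutation_analysis.gene_burden(cohort.mutations, cohort.annotation,
                                           scope="pan_cancer")
    rand_cfg = mutation_analysis.RandomizationConfig(
        n_reps=config.randomization_reps, seed=config.seed)
    tests = mutation_analysis.randomization_suite(burden, cohort.annotation, rand_cfg)
    hotspots = mutation_analysis.detect_hotspots(cohort.mutations)
    hist = mutation_analysis.recurrence(cohort.mutations)
    spectrum = mutation_analysis.composition(cohort.mutations, cohort.annotation)
    files = {
        outdir / "burden.tsv": (burden, ["tumor_type", "gene_symbol"]),
        outdir / "hotspots.tsv": (hotspots, ["gene_symbol", "chrom", "pos"]),
        outdir / "recurrence.tsv": (hist, ["tumor_type", "n_patients"]),
        outdir / "composition_classes.tsv": (spectrum.class_counts,
                                             ["tumor_type", "category", "variant_class"]),
        outdir / "composition_titv.tsv": (spectrum.titv, ["tumor_type", "category"]),
    }
    for path, (table, keys) in files.items():
        io.write_result_table(table, path, sort_by=keys)
    tests_path = outdir / "burden_tests.json"
    tests_path.write_text(json.dumps(tests.to_dict(), indent=2, sort_keys=True))
    return list(files) + [tests_path]


def _stage_domains(cohort: SyntheticCohort, config: RunConfig, outdir: Path) -> list[Path]:
    mapped = domain_impact.map_to_domains(cohort.mutations, cohort.domains)
    counts = domain_impact.domain_counts(mapped)
    tops = domain_impact.top_domains(mapped, k=config.top_k_domains)
    impact = domain_impact.impact_summary(cohort.mutations, cohort.annotation)
    files = {
        outdir / "domain_counts.tsv": (counts, ["tumor_type", "domain_name"]),
        outdir / "top_domains.tsv": (tops.per_tumor, ["tumor_type", "rank"]),
        outdir / "top_domains_union.tsv": (tops.union, ["domain_name"]),
        outdir / "impact_summary.tsv": (impact.by_stratum, ["tumor_type", "group"]),
    }
    for path, (table, keys) in files.items():
        io.write_result_table(table, path, sort_by=keys)
    chi2_path = outdir / "impact_chi2.json"
    chi2_path.write_text(json.dumps(
        {"chi2_stat": impact.chi2_stat, "p_value": impact.p_value,
         "contingency": impact.contingency.to_dict()}, indent=2, sort_keys=True))
    return list(files) + [chi2_path]


def _stage_survival(cohort: SyntheticCohort, config: RunConfig, outdir: Path) -> list[Path]:
    surv_cfg = survival_screen.SurvivalConfig(**config.survival)
    result = survival_screen.screen(cohort.mutations, cohort.clinical,
                                    cohort.annotation, surv_cfg, return_all=True)
    reported = result[result["concordant"]]
    curves = []
    for _, row in reported.iterrows():
        cohort_clin = cohort.clinical[cohort.clinical["tumor_type"] == row["tumor_type"]]
        flags = survival_screen.carrier_status(
            row["gene_symbol"], cohort.mutations, cohort_clin, surv_cfg.carrier_rule)
        km, _, _ = survival_screen.km_logrank(flags, cohort_clin)
        km.insert(0, "gene_symbol", row["gene_symbol"])
        km.insert(0, "tumor_type", row["tumor_type"])
        curves.append(km)
    curve_table = (pd.concat(curves, ignore_index=True) if curves else
                   pd.DataFrame(columns=["tumor_type", "gene_symbol",
                                         "group", "time", "survival"]))
    files = {
        outdir / "survival_screen.tsv": (result, ["tumor_type", "os_difference"]),
        outdir / "km_curves.tsv": (curve_table,
                                   ["tumor_type", "gene_symbol", "group", "time"]),
    }
    for path, (table, keys) in files.items():
        io.write_result_table(table, path, sort_by=keys)
    return list(files)


def _stage_summary(cohort: SyntheticCohort, config: RunConfig, outdir: Path) -> list[Path]:
    summary = cohort_summary(cohort.cna, cohort.mutations,
                             cohort.clinical, cohort.annotation)
    counts = alteration_counts(cohort.cna, cohort.mutations, cohort.clinical)
    glm = purity_confounding(counts, cohort.clinical, family=config.glm_family)
    files = {
        outdir / "cohort_summary.tsv": (summary, None),
        outdir / "purity_glm.tsv": (glm, ["tumor_type", "kind"]),
    }
    for path, (table, keys) in files.items():
        io.write_result_table(table, path, sort_by=keys)
    return list(files)
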