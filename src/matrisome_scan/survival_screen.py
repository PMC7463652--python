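"""Mutation-carrier survival screen: Kaplan-Meier log-rank + adjusted Cox.

For each tumor type and each gene with enough mutation carriers, overall
survival of carriers versus non-carriers is compared twice:

* univariate — Kaplan-Meier curves and the two-group log-rank test;
* multivariate — Cox proportional-hazards fit of carrier status adjusted for
  age at diagnosis, gender and ethnicity (Efron tie handling).

A gene is *reported* only when both tests are significant at alpha and agree
in direction ("concordant"). The reported effect size, ``os_difference``, is
the negated carrier log-hazard coefficient (-beta): negative values mean
carriers fare worse (hazard ratio > 1, shorter survival), positive values
mean a protective association.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time
from statsmodels.stats.multitest import multipletests

from ._errors import ConfigError, EmptyGroupError
from .domain_impact import map_to_domains

logger = logging.getLogger(__name__)

#: variant classes that qualify a sample as carrier under "nonsilent_only"
NONSILENT_CLASSES = frozenset(
    ("missense", "nonsense", "nonstop", "frame_shift_del", "frame_shift_ins",
     "in_frame_del", "in_frame_ins", "splice_site", "other"))

RESULT_COLUMNS = ["tumor_type", "gene_symbol", "category", "n_carriers",
                  "os_difference", "p_univariate", "p_multivariate",
                  "fdr_multivariate", "concordant"]


@dataclass(frozen=True)
class SurvivalConfig:
    """Screen settings; defaults mirror the pipeline's reporting rules."""

    min_carriers: int = 10
    alpha: float = 0.05
    covariates: tuple[str, ...] = ("age", "gender", "ethnicity")
    carrier_rule: str = "any_mutation"

    def __post_init__(self) -> None:
        if self.min_carriers < 1:
            raise ConfigError("min_carriers must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.carrier_rule not in ("any_mutation", "nonsilent_only"):
            raise ConfigError(f"unknown carrier_rule {self.carrier_rule!r}")


def carrier_status(gene: str, mutations: pd.DataFrame, clinical: pd.DataFrame,
                   rule: str = "any_mutation") -> pd.Series:
    """Boolean carrier flag per clinical sample for one gene.

    ``any_mutation`` counts every record; ``nonsilent_only`` requires at least
    one protein-affecting mutation (silent and non-coding classes excluded).
    """
    hits = mutations[mutations["gene_symbol"] == gene]
    if rule == "nonsilent_only":
        hits = hits[hits["variant_class"].isin(NONSILENT_CLASSES)]
    elif rule != "any_mutation":
        raise ConfigError(f"unknown carrier rule {rule!r}")
    carriers = set(hits["sample"])
    return pd.Series(clinical["sample"].isin(carriers).to_numpy(),
                     index=pd.Index(clinical["sample"], name="sample"), name=gene)


def km_logrank(carriers: pd.Series, clinical: pd.DataFrame
               ) -> tuple[pd.DataFrame, float, float]:
    """Kaplan-Meier curves per carrier group and the two-group log-rank test.

    Returns (curves, statistic, p). ``curves`` holds the product-limit step
    functions in long form (group, time, survival). Raises
    :class:`EmptyGroupError` if either group is empty or no events occurred at
    all; a single event-free group is fine (complete separation is the
    strongest possible signal, not a degenerate case).
    """
    flags = carriers.reindex(clinical["sample"]).to_numpy()
    t = clinical["os_months"].to_numpy(dtype=float)
    e = clinical["os_event"].to_numpy(dtype=bool)
    if e.sum() == 0:
        raise EmptyGroupError("no events; log-rank undefined")
    curves = []
    for label, mask in (("carrier", flags), ("noncarrier", ~flags)):
        if mask.sum() == 0:
            raise EmptyGroupError(f"{label} group is empty")
        km = KaplanMeierFitter().fit(t[mask], e[mask], label=label)
        sf = km.survival_function_
        curves.append(pd.DataFrame({
            "group": label,
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf[label].to_numpy(dtype=float),
        }))
    res = logrank_test(t[flags], t[~flags], e[flags], e[~flags])
    return pd.concat(curves, ignore_index=True), float(res.test_statistic), float(res.p_value)


def _km_direction(carriers: pd.Series, clinical: pd.DataFrame) -> float:
    """Sign of the carrier-minus-noncarrier restricted-mean survival difference."""
    flags = carriers.reindex(clinical["sample"]).to_numpy()
    t = clinical["os_months"].to_numpy(dtype=float)
    e = clinical["os_event"].to_numpy(dtype=bool)
    horizon = float(t.max())
    rmst = {}
    for label, mask in (("carrier", flags), ("noncarrier", ~flags)):
        km = KaplanMeierFitter().fit(t[mask], e[mask], label=label)
        rmst[label] = float(restricted_mean_survival_time(km, t=horizon))
    return float(np.sign(rmst["carrier"] - rmst["noncarrier"]))


def cox_multivariate(carriers: pd.Series, clinical: pd.DataFrame,
                     covariates: tuple[str, ...] = ("age", "gender", "ethnicity"),
                     ) -> tuple[float, float, pd.DataFrame]:
    """Cox proportional-hazards fit of carrier status with covariates.

    Categorical covariates are one-hot encoded against their most frequent
    level; covariates constant within the data are dropped; patients missing a
    covariate are dropped from this fit only (logged). Ties are handled with
    the Efron approximation (lifelines default); convergence failures
    propagate as :class:`EmptyGroupError` so callers can skip and log.

    Returns (carrier log-hazard beta, Wald p-value, full coefficient table).
    """
    df = clinical.set_index("sample")[["os_months", "os_event"]].copy()
    df["carrier"] = carriers.reindex(df.index).astype(float)
    design_cols = ["carrier"]
    for cov in covariates:
        col = clinical.set_index("sample")[cov]
        if pd.api.types.is_numeric_dtype(col):
            df[cov] = col.astype(float)
            design_cols.append(cov)
        else:
            levels = col.value_counts()
            reference = levels.index[0]
            for level in levels.index[1:]:
                name = f"{cov}_{level}"
                df[name] = (col == level).astype(float)
                design_cols.append(name)
            logger.debug("covariate %s encoded against reference %r", cov, reference)
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.info("cox fit: dropped %d patients with missing covariates",
                    n_before - len(df))
    # constant columns make the design singular
    design_cols = [c for c in design_cols if df[c].nunique() > 1]
    if "carrier" not in design_cols:
        raise EmptyGroupError("carrier status is constant; nothing to fit")
    if df["os_event"].sum() == 0:
        raise EmptyGroupError("no events; Cox model undefined")
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df[["os_months", "os_event"] + design_cols],
                       duration_col="os_months", event_col="os_event")
    except Exception as exc:  # convergence failure / separation
        raise EmptyGroupError(f"Cox fit failed: {exc}") from exc
    summary = fitter.summary
    beta = float(summary.loc["carrier", "coef"])
    p = float(summary.loc["carrier", "p"])
    return beta, p, summary.reset_index()


def screen(mutations: pd.DataFrame, clinical: pd.DataFrame,
           annotation: pd.DataFrame, config: SurvivalConfig | None = None,
           genes: list[str] | None = None, return_all: bool = False) -> pd.DataFrame:
    """Per-tumor gene screen for concordant carrier survival effects.

    Genes with at least ``min_carriers`` carriers in a tumor are tested with
    :func:`km_logrank` and :func:`cox_multivariate`; a record is concordant
    when both p-values fall below alpha and the univariate direction matches
    the sign of ``os_difference`` (= -beta). By default only concordant
    records are returned, ordered by (tumor, os_difference); ``return_all``
    keeps every tested gene with its ``concordant`` flag. A Benjamini-
    Hochberg ``fdr_multivariate`` column is emitted for reference and not
    used for filtering.
    """
    config = config or SurvivalConfig()
    category = annotation.set_index("gene_symbol")["category"]
    carrier_sets = _carrier_sets(mutations, config.carrier_rule)
    rows = []
    for tumor, cohort in clinical.groupby("tumor_type", sort=True):
        tumor_samples = set(cohort["sample"])
        candidates = genes if genes is not None else sorted(carrier_sets)
        for gene in candidates:
            members = carrier_sets.get(gene, set()) & tumor_samples
            if len(members) < config.min_carriers:
                continue
            flags = pd.Series(cohort["sample"].isin(members).to_numpy(),
                              index=pd.Index(cohort["sample"]), name=gene)
            try:
                _, _, p_uni = km_logrank(flags, cohort)
                beta, p_multi, _ = cox_multivariate(flags, cohort, config.covariates)
            except EmptyGroupError as exc:
                logger.info("tumor %s gene %s skipped: %s", tumor, gene, exc)
                continue
            os_difference = -beta
            direction = _km_direction(flags, cohort)
            concordant = (p_uni < config.alpha and p_multi < config.alpha
                          and direction != 0.0
                          and np.sign(os_difference) == direction)
            rows.append({
                "tumor_type": tumor, "gene_symbol": gene,
                "category": category.get(gene, "none"),
                "n_carriers": len(members), "os_difference": os_difference,
                "p_univariate": p_uni, "p_multivariate": p_multi,
                "concordant": bool(concordant),
            })
    result = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS
                                         if c != "fdr_multivariate"])
    if len(result):
        fdr = np.empty(len(result))
        for tumor, idx in result.groupby("tumor_type").groups.items():
            fdr[np.asarray(idx)] = multipletests(
                result.loc[idx, "p_multivariate"], method="fdr_bh")[1]
        result["fdr_multivariate"] = fdr
    else:
        result["fdr_multivariate"] = pd.Series(dtype=float)
    result = result[RESULT_COLUMNS]
    if not return_all:
        result = result[result["concordant"]]
    return result.sort_values(["tumor_type", "os_difference"],
                              kind="mergesort").reset_index(drop=True)


def screen_domains(mutations: pd.DataFrame, domains: pd.DataFrame,
                   clinical: pd.DataFrame, config: SurvivalConfig | None = None,
                   return_all: bool = False) -> pd.DataFrame:
    """Domain-level variant of :func:`screen`.

    A patient is a carrier of a domain when at least one of their mutations
    maps inside any interval bearing that domain name. Reuses the gene
    engine by rewriting mapped mutations to their domain identity.
    """
    mapped = map_to_domains(mutations, domains)
    hits = mapped.dropna(subset=["domain_name"]).copy()
    hits["gene_symbol"] = hits["domain_name"]
    pseudo_annotation = pd.DataFrame({
        "gene_symbol": sorted(hits["gene_symbol"].unique()),
        "length_bp": 1, "division": "core matrisome", "category": "collagens",
    })
    result = screen(hits, clinical, pseudo_annotation, config, return_all=return_all)
    return result.rename(columns={"gene_symbol": "domain_name"}).drop(columns=["category"])


def _carrier_sets(mutations: pd.DataFrame, rule: str) -> dict[str, set]:
    table = mutations
    if rule == "nonsilent_only":
        table = table[table["variant_class"].isin(NONSILENT_CLASSES)]
    return {g: set(grp["sample"]) for g, grp in table.groupby("gene_symbol")}
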