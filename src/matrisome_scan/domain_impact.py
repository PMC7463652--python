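"""Protein-domain mutation mapping, ranking, and functional-impact tabulation.

A coding mutation maps to a domain iff it lies in the same gene and its
protein position falls inside the domain's amino-acid interval (1-based,
inclusive on both ends). Mutations without a protein position — UTR, splice
site, intron — are unmappable by construction; if overlapping intervals are
supplied, each receives the mutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import io_formats as io

logger = logging.getLogger(__name__)

_MUT_ID = "_mutation_id"


def map_to_domains(mutations: pd.DataFrame, domains: pd.DataFrame) -> pd.DataFrame:
    """Assign each mutation to the domain interval(s) containing it.

    Returns the mutation table with a ``domain_name`` column; unmapped
    mutations keep a single row with ``domain_name`` missing, mutations inside
    k overlapping domains appear k times. Idempotent in the sense that the
    assignment depends only on (gene, protein_pos) and the domain table.
    """
    domains = io.validate_domains(domains)
    muts = mutations.reset_index(drop=True)
    muts[_MUT_ID] = np.arange(len(muts))
    candidates = muts.dropna(subset=["protein_pos"]).merge(
        domains, on="gene_symbol", how="inner")
    inside = candidates[
        (candidates["protein_pos"] >= candidates["aa_start"])
        & (candidates["protein_pos"] <= candidates["aa_end"])
    ]
    mapped = muts.merge(
        inside[[_MUT_ID, "domain_name", "aa_start", "aa_end"]],
        on=_MUT_ID, how="left")
    return mapped.drop(columns=[_MUT_ID])


def domain_counts(mapped: pd.DataFrame) -> pd.DataFrame:
    """Per-(tumor, domain) mutation counts and frequencies.

    ``frequency`` is the domain's share of that tumor's *mapped* mutations
    (so per tumor the frequencies sum to 1 when overlap-free); a raw count
    and a per-amino-acid rate over the domain's total annotated extent are
    also emitted.
    """
    hits = mapped.dropna(subset=["domain_name"])
    counts = hits.groupby(["tumor_type", "domain_name"], sort=True).agg(
        n_mutations=("gene_symbol", "size"),
        n_genes_contributing=("gene_symbol", "nunique"),
    ).reset_index()
    total_mapped = counts.groupby("tumor_type")["n_mutations"].transform("sum")
    counts["frequency"] = counts["n_mutations"] / total_mapped
    extent = (hits.drop_duplicates(["gene_symbol", "domain_name", "aa_start", "aa_end"])
              .assign(aa=lambda d: d["aa_end"] - d["aa_start"] + 1)
              .groupby("domain_name")["aa"].sum())
    counts["rate_per_aa"] = counts["n_mutations"] / counts["domain_name"].map(extent)
    return counts


@dataclass
class TopDomains:
    """Per-tumor top-k domains and their cross-tumor union."""

    per_tumor: pd.DataFrame   # tumor_type, rank, domain_name, n_mutations, frequency
    union: pd.DataFrame       # domain_name x tumor_type frequency matrix


def top_domains(mapped: pd.DataFrame, k: int = 20) -> TopDomains:
    """Rank domains by mutation count within each tumor and take the top k.

    Ties at the cut are broken lexicographically by domain name. Tumors with
    fewer than k mutated domains contribute all of them (logged). The union
    table reports each selected domain's frequency in every tumor.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = domain_counts(mapped)
    tops = []
    for tumor, grp in counts.groupby("tumor_type", sort=True):
        ranked = grp.sort_values(["n_mutations", "domain_name"],
                                 ascending=[False, True], kind="mergesort")
        if len(ranked) < k:
            logger.info("tumor %s has only %d mutated domains (< k=%d)",
                        tumor, len(ranked), k)
        top = ranked.head(k).copy()
        top["rank"] = np.arange(1, len(top) + 1)
        tops.append(top)
    per_tumor = (pd.concat(tops, ignore_index=True)
                 if tops else counts.assign(rank=pd.Series(dtype=int)))
    per_tumor = per_tumor[["tumor_type", "rank", "domain_name",
                           "n_mutations", "n_genes_contributing", "frequency"]]
    union_domains = sorted(per_tumor["domain_name"].unique())
    union = (counts[counts["domain_name"].isin(union_domains)]
             .pivot_table(index="domain_name", columns="tumor_type",
                          values="frequency", fill_value=0.0)
             .reindex(union_domains))
    union.columns.name = None
    return TopDomains(per_tumor=per_tumor, union=union.reset_index())


@dataclass
class ImpactSummary:
    """PolyPhen label tabulation plus the damaging-vs-not chi-square."""

    by_stratum: pd.DataFrame   # tumor_type, group, counts + proportions per label
    contingency: pd.DataFrame  # 2x2: damaging / not x matrisome / non-matrisome
    chi2_stat: float
    p_value: float


def impact_summary(mutations: pd.DataFrame, annotation: pd.DataFrame) -> ImpactSummary:
    """Tabulate predicted functional impact of mutations by matrisome status.

    Counts PolyPhen labels per (tumor, matrisome-vs-non) stratum, and tests
    the pooled 2x2 of damaging (possibly + probably) versus not-damaging
    against matrisome status with a two-sided chi-square (no continuity
    correction).
    """
    division = annotation.set_index("gene_symbol")["division"]
    table = mutations.assign(
        group=np.where(mutations["gene_symbol"].map(division) == "non-matrisome",
                       "non-matrisome", "matrisome"))
    counts = (table.groupby(["tumor_type", "group"], sort=True)["polyphen"]
              .value_counts().unstack(fill_value=0)
              .reindex(columns=list(io.POLYPHEN_LABELS), fill_value=0)
              .reset_index())
    counts.columns.name = None
    label_cols = list(io.POLYPHEN_LABELS)
    totals = counts[label_cols].sum(axis=1)
    for label in label_cols:
        counts[f"prop_{label}"] = counts[label] / totals.where(totals > 0)

    damaging = table["polyphen"].isin(["possibly_damaging", "probably_damaging"])
    contingency = pd.crosstab(damaging, table["group"]).reindex(
        index=[True, False], columns=["matrisome", "non-matrisome"], fill_value=0)
    contingency.index = pd.Index(["damaging", "not_damaging"], name="impact")
    obs = contingency.to_numpy(dtype=float)
    if (obs.sum(axis=0) > 0).all() and (obs.sum(axis=1) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    else:
        chi2, p = 0.0, 1.0
    return ImpactSummary(by_stratum=counts, contingency=contingency,
                         chi2_stat=float(chi2), p_value=float(p))
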