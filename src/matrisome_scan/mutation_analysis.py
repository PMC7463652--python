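"""Length-normalized mutation burden, randomization nulls, hotspots and spectra.

The central statistic is the per-gene mutation burden: mutation count divided
by gene length in bp. Matrisome genes are systematically long, so raw counts
overstate their mutation load; burden removes the first-order length effect
and the comparison against non-matrisome genes is then made twice over —
a two-sided Mann-Whitney U test against all non-matrisome genes, and a suite
of randomization nulls that re-draw non-matrisome comparison sets:

1. ``frac33`` — a random ~33% of non-matrisome genes per repetition;
2. ``size_matched`` — random sets the size of the mutated matrisome set;
3. ``length_matched`` — same-size sets drawn only from non-matrisome genes
   longer than the mean matrisome gene length (the sharpest control for the
   length disparity).

Also here: recurrence histograms (how many patients share an identical
mutation), the hotspot rule (same mutation in >=5 patients per tumor type in
>=2 tumor types), transition/transversion classification and mutation-type
composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigError, EmptyGroupError, MatrisomeScanError

GENOMIC_KEY = ["gene_symbol", "chrom", "pos", "ref", "alt"]
PROTEIN_KEY = ["gene_symbol", "protein_pos", "alt"]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


# ---------------------------------------------------------------------------
# burden
# ---------------------------------------------------------------------------

def gene_burden(mutations: pd.DataFrame, annotation: pd.DataFrame,
                scope: str = "pan_cancer") -> pd.DataFrame:
    """Per-gene mutation counts and per-bp burden.

    ``scope="pan_cancer"`` aggregates over all samples (one row per annotated
    gene); ``scope="per_tumor"`` yields one row per (tumor, gene) over the
    tumor types present in the mutation table. Unmutated genes appear with
    burden 0.
    """
    if scope not in ("pan_cancer", "per_tumor"):
        raise ValueError(f"scope must be 'pan_cancer' or 'per_tumor', got {scope!r}")
    known = set(annotation["gene_symbol"])
    stray = sorted(set(mutations["gene_symbol"]) - known)
    if stray:
        raise MatrisomeScanError(
            f"{len(stray)} mutated genes missing from the annotation: {stray[:10]}")
    lengths = annotation.set_index("gene_symbol")["length_bp"]

    if scope == "pan_cancer":
        counts = mutations.groupby("gene_symbol").size()
        out = pd.DataFrame({
            "gene_symbol": lengths.index,
            "tumor_type": "pan_cancer",
            "n_mutations": counts.reindex(lengths.index, fill_value=0).to_numpy(),
        })
    else:
        tumors = sorted(pd.unique(mutations["tumor_type"].dropna()))
        counts = mutations.groupby(["tumor_type", "gene_symbol"]).size()
        grid = pd.MultiIndex.from_product([tumors, lengths.index],
                                          names=["tumor_type", "gene_symbol"])
        out = counts.reindex(grid, fill_value=0).rename("n_mutations").reset_index()
    out["length_bp"] = out["gene_symbol"].map(lengths)
    out["burden"] = out["n_mutations"] / out["length_bp"]
    return out[["gene_symbol", "tumor_type", "n_mutations", "length_bp", "burden"]]


def burden_mwu(burden: pd.DataFrame, annotation: pd.DataFrame,
               include_zero: bool = False) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on burden, matrisome vs non-matrisome genes.

    By default only mutated genes (burden > 0) enter the comparison;
    ``include_zero=True`` keeps unmutated genes as zeros.
    """
    is_mat = annotation.set_index("gene_symbol")["division"] != "non-matrisome"
    table = burden if include_zero else burden[burden["n_mutations"] > 0]
    mat = table.loc[table["gene_symbol"].map(is_mat).fillna(False), "burden"]
    non = table.loc[~table["gene_symbol"].map(is_mat).fillna(True), "burden"]
    if len(mat) < 2 or len(non) < 2:
        raise EmptyGroupError(
            f"need >=2 genes per group for the Mann-Whitney test "
            f"(matrisome {len(mat)}, non-matrisome {len(non)})")
    stat, p = stats.mannwhitneyu(mat, non, alternative="two-sided",
                                 use_continuity=False)
    return float(stat), float(p)


@dataclass(frozen=True)
class RandomizationConfig:
    """Settings for the randomization null suite."""

    schemes: tuple[str, ...] = ("frac33", "size_matched", "length_matched")
    n_reps: int = 1000
    alpha: float = 0.05
    frac: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        unknown = set(self.schemes) - {"frac33", "size_matched", "length_matched"}
        if unknown:
            raise ConfigError(f"unknown randomization schemes: {sorted(unknown)}")


@dataclass
class BurdenTestResult:
    """Global Mann-Whitney result plus per-scheme randomization summaries."""

    mwu_stat: float
    mwu_p: float
    n_matrisome: int
    n_non_matrisome: int
    schemes: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"mwu_stat": self.mwu_stat, "mwu_p": self.mwu_p,
                "n_matrisome": self.n_matrisome,
                "n_non_matrisome": self.n_non_matrisome, "schemes": self.schemes}


def randomization_suite(burden: pd.DataFrame, annotation: pd.DataFrame,
                        config: RandomizationConfig | None = None,
                        include_zero: bool = False) -> BurdenTestResult:
    """Run the randomization nulls against the matrisome burden distribution.

    Per repetition a non-matrisome gene set is drawn according to the scheme
    and compared to the matrisome set with a two-sided Mann-Whitney U test.
    Reported per scheme:

    * ``fraction_significant`` — share of repetitions with p < alpha and the
      matrisome median above the drawn set's median;
    * ``empirical_p`` — add-one-smoothed share of repetitions whose set median
      reached the matrisome median, ``(k + 1) / (n_reps + 1)``;
    * ``direction`` — ``"higher"`` if the matrisome median exceeded the median
      random-set median.
    """
    config = config or RandomizationConfig()
    rng = np.random.default_rng(config.seed)
    is_mat = annotation.set_index("gene_symbol")["division"] != "non-matrisome"
    table = burden if include_zero else burden[burden["n_mutations"] > 0]
    mat_mask = table["gene_symbol"].map(is_mat).fillna(False)
    mat = table.loc[mat_mask, "burden"].to_numpy()
    pool_tbl = table.loc[~mat_mask]
    if len(mat) < 2 or len(pool_tbl) < 2:
        raise EmptyGroupError(
            f"need >=2 genes per group (matrisome {len(mat)}, pool {len(pool_tbl)})")
    mat_median = float(np.median(mat))
    mean_mat_length = float(
        annotation.loc[annotation["division"] != "non-matrisome", "length_bp"].mean())

    stat, p = stats.mannwhitneyu(mat, pool_tbl["burden"], alternative="two-sided",
                                 use_continuity=False)
    result = BurdenTestResult(float(stat), float(p), len(mat), len(pool_tbl))

    for scheme in config.schemes:
        if scheme == "length_matched":
            pool = pool_tbl.loc[pool_tbl["length_bp"] > mean_mat_length, "burden"].to_numpy()
            size = len(mat)
        elif scheme == "size_matched":
            pool = pool_tbl["burden"].to_numpy()
            size = len(mat)
        else:  # frac33
            pool = pool_tbl["burden"].to_numpy()
            size = int(np.floor(config.frac * len(pool)))
        size = max(size, 1)
        if len(pool) < size:
            raise ConfigError(
                f"scheme {scheme!r}: pool of {len(pool)} non-matrisome genes "
                f"cannot supply sets of size {size}")
        n_sig = 0
        n_ge = 0
        set_medians = np.empty(config.n_reps)
        for rep in range(config.n_reps):
            drawn = rng.choice(pool, size=size, replace=False)
            _, rep_p = stats.mannwhitneyu(mat, drawn, alternative="two-sided",
                                          use_continuity=False)
            med = float(np.median(drawn))
            set_medians[rep] = med
            if rep_p < config.alpha and mat_median > med:
                n_sig += 1
            if med >= mat_median:
                n_ge += 1
        result.schemes[scheme] = {
            "set_size": size,
            "fraction_significant": n_sig / config.n_reps,
            "empirical_p": (n_ge + 1) / (config.n_reps + 1),
            "direction": "higher" if mat_median > float(np.median(set_medians)) else "lower",
        }
    return result


# ---------------------------------------------------------------------------
# recurrence and hotspots
# ---------------------------------------------------------------------------

def _key_columns(key: str) -> list[str]:
    if key == "genomic":
        return GENOMIC_KEY
    if key == "protein":
        return PROTEIN_KEY
    raise ValueError(f"key must be 'genomic' or 'protein', got {key!r}")


def recurrence_counts(mutations: pd.DataFrame, key: str = "genomic") -> pd.DataFrame:
    """Distinct-patient count per (tumor, mutation identity)."""
    cols = _key_columns(key)
    table = mutations.dropna(subset=cols)
    counts = (table.groupby(["tumor_type"] + cols, sort=True)["sample"]
              .nunique().rename("n_patients").reset_index())
    return counts


def recurrence(mutations: pd.DataFrame, key: str = "genomic") -> pd.DataFrame:
    """Per-tumor histogram: number of identical-mutation keys by patient count."""
    counts = recurrence_counts(mutations, key)
    hist = (counts.groupby(["tumor_type", "n_patients"], sort=True)
            .size().rename("n_keys").reset_index())
    return hist


def detect_hotspots(mutations: pd.DataFrame, min_patients: int = 5,
                    min_tumors: int = 2, key: str = "genomic") -> pd.DataFrame:
    """Identical mutations seen in >= min_patients patients per tumor type in
    >= min_tumors tumor types."""
    cols = _key_columns(key)
    counts = recurrence_counts(mutations, key)
    qualifying = counts[counts["n_patients"] >= min_patients]
    per_key = qualifying.groupby(cols, sort=True).agg(
        n_tumors_qualifying=("tumor_type", "nunique"),
        max_patients_per_tumor=("n_patients", "max"),
        total_patients_qualifying=("n_patients", "sum"),
    ).reset_index()
    hotspots = per_key[per_key["n_tumors_qualifying"] >= min_tumors]
    return hotspots.reset_index(drop=True)


# ---------------------------------------------------------------------------
# substitution spectra and composition
# ---------------------------------------------------------------------------

def classify_substitution(ref: str, alt: str) -> str:
    """Classify an allele pair as transition, transversion or not_snv.

    Only single-base A/C/G/T pairs are SNVs; A<->G and C<->T are transitions,
    the other eight ordered single-base pairs transversions.
    """
    if not ref or not alt:
        raise ValueError("allele strings must be nonempty")
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return "not_snv"
    if ref not in "ACGT" or alt not in "ACGT":
        return "not_snv"
    if (ref in _PURINES) == (alt in _PURINES):
        return "transition"
    return "transversion"


def classify_substitutions(mutations: pd.DataFrame) -> pd.Series:
    """Vectorized substitution class for each mutation record."""
    ref = mutations["ref"].astype(str)
    alt = mutations["alt"].astype(str)
    snv = (ref.str.len() == 1) & (alt.str.len() == 1) & \
        ref.isin(list("ACGT")) & alt.isin(list("ACGT")) & (ref != alt)
    ti = snv & (ref.isin(["A", "G"]) == alt.isin(["A", "G"]))
    out = pd.Series(np.where(ti, "transition",
                             np.where(snv, "transversion", "not_snv")),
                    index=mutations.index)
    return out


@dataclass
class SpectrumSummary:
    """Mutation-type composition and Ti/Tv counts per tumor x matrisome category."""

    class_counts: pd.DataFrame   # tumor_type, category, variant_class, n, proportion
    titv: pd.DataFrame           # tumor_type, category, n_transitions, n_transversions, n_snv


def composition(mutations: pd.DataFrame, annotation: pd.DataFrame) -> SpectrumSummary:
    """Tabulate variant-class proportions and Ti/Tv per tumor and category.

    Proportions sum to 1 within each (tumor, category) stratum; transitions
    plus transversions equal the SNV count in every stratum.
    """
    category = annotation.set_index("gene_symbol")["category"]
    table = mutations.assign(category=mutations["gene_symbol"].map(category))

    counts = (table.groupby(["tumor_type", "category", "variant_class"], sort=True)
              .size().rename("n").reset_index())
    totals = counts.groupby(["tumor_type", "category"])["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals

    sub = table.assign(substitution=classify_substitutions(table))
    titv = (sub.groupby(["tumor_type", "category"], sort=True)["substitution"]
            .value_counts().unstack(fill_value=0)
            .reindex(columns=["transition", "transversion"], fill_value=0)
            .rename(columns={"transition": "n_transitions",
                             "transversion": "n_transversions"})
            .reset_index())
    titv.columns.name = None
    titv["n_snv"] = titv["n_transitions"] + titv["n_transversions"]
    return SpectrumSummary(class_counts=counts, titv=titv)
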