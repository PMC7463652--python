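"""Synthetic multi-tumor cohort generator with known planted structure.

Every downstream stage of the pipeline (CNA frequency binning, CNA-to-
expression effects, length-normalized mutation burden, domain mapping,
survival screening) is exercised against cohorts produced here, where the
ground truth — which genes are matrisome, which are CNA-enriched, which are
expression-coupled, which carry a survival hazard — is known by construction.

The statistical structure emulated:

* a gene universe split into matrisome (core + associated, partitioned into
  the six canonical categories) and non-matrisome genes, with matrisome genes
  drawn from longer log-normal length distributions;
* GISTIC-like thresholded CNA calls in {-2,-1,1,2}, with a configurable
  matrisome enrichment multiplier;
* log2(norm+1) expression with a multiplicative fold-change applied to CNA
  carriers of a chosen set of coupled genes;
* per-gene, per-sample Poisson mutation counts proportional to gene length,
  with variant classes, transition/transversion-aware alleles, protein
  positions (coding classes only) and PolyPhen labels;
* exponential overall survival with planted per-gene log hazard ratios for
  mutation carriers, independent uniform censoring, and standard covariates;
* protein-domain intervals (non-overlapping, amino-acid coordinates) for
  matrisome genes, named from a fixed vocabulary of matrisome-defining
  domains.

All draws descend from a single integer seed; an identical config reproduces
a byte-identical cohort.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigError
from . import io_formats as io

#: the 14 solid-tumor cohorts of the study, used round-robin
TUMOR_TYPES = (
    "BRCA", "CESC", "COAD", "ESCA", "LUAD", "LUSC", "OV",
    "PAAD", "PRAD", "READ", "SKCM", "STAD", "UCEC", "UCS",
)

#: matrisome-defining domain names used for synthetic domain tables
DOMAIN_VOCABULARY = (
    "Collagen triple helix repeat", "EGF-like", "EGF-like calcium-binding",
    "Fibronectin type III", "VWF type A", "VWF type C", "Laminin G",
    "Laminin EGF-like", "Thrombospondin type 1", "Kazal-type inhibitor",
    "Ig-like C2", "Sushi/CCP", "C-type lectin", "Fibrillar collagen NC1",
    "Link domain", "Peptidase M10", "TIMP-like", "Cystine knot",
)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}

# per-stage children of the master seed, so adding a stage never reshuffles others
_STAGE = {"annotation": 1, "cna": 2, "expression": 3, "mutations": 4,
          "clinical": 5, "domains": 6}


def _category_defaults() -> dict[str, float]:
    # proportions of the 1027-gene human matrisome:
    # 44 collagens, 195 glycoproteins, 35 proteoglycans (core);
    # 171 affiliated, 238 regulators, 344 secreted factors (associated)
    n = {"collagens": 44, "ECM glycoproteins": 195, "proteoglycans": 35,
         "ECM-affiliated": 171, "ECM regulators": 238, "secreted factors": 344}
    return {k: v / 1027 for k, v in n.items()}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort; defaults give a desk-scale study.

    Proportion maps must sum to 1 (checked to 1e-9). ``length_params`` maps
    each division to ``(median_bp, sigma)`` of a log-normal; matrisome genes
    default to markedly longer lengths than the rest of the genome, since
    length disparity is what the burden normalization and the length-matched
    randomization scheme exist to handle.
    """

    n_genes: int = 1000
    frac_matrisome: float = 0.10
    category_weights: dict[str, float] = field(default_factory=_category_defaults)
    length_params: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "core matrisome": (6000.0, 0.8),
        "matrisome-associated": (4500.0, 0.8),
        "non-matrisome": (3000.0, 1.0),
    })
    n_tumor_types: int = 4
    samples_per_tumor: int = 50
    cna_rate: float = 0.20
    matrisome_cna_multiplier: float = 2.0
    cna_state_weights: dict[int, float] = field(
        default_factory=lambda: {-2: 0.25, -1: 0.25, 1: 0.25, 2: 0.25})
    expr_coupled_genes: int = 20
    expr_effect: float = 2.0
    expr_noise_sd: float = 0.5          # sd of log2-scale multiplicative noise
    mutation_rate_per_bp: float = 3e-6  # per sample: ~3 mutations per Mb
    matrisome_mut_multiplier: float = 2.0
    variant_class_weights: dict[str, float] = field(default_factory=lambda: {
        "missense": 0.50, "silent": 0.25, "nonsense": 0.04, "splice_site": 0.03,
        "frame_shift_del": 0.04, "frame_shift_ins": 0.02, "in_frame_del": 0.01,
        "in_frame_ins": 0.01, "nonstop": 0.005, "3'UTR": 0.05, "5'UTR": 0.02,
        "intron": 0.02, "other": 0.005,
    })
    transition_prob: float = 0.70
    polyphen_weights: dict[str, float] = field(default_factory=lambda: {
        "benign": 0.40, "possibly_damaging": 0.25, "probably_damaging": 0.35})
    planted_survival_genes: tuple[tuple[str, float], ...] = ()
    censor_rate: float = 0.5
    baseline_hazard: float = 1.0 / 36.0  # per month; median OS ~= 25 months
    seed: int = 0

    def __post_init__(self) -> None:
        for name, weights in (("category_weights", self.category_weights),
                              ("cna_state_weights", self.cna_state_weights),
                              ("variant_class_weights", self.variant_class_weights),
                              ("polyphen_weights", self.polyphen_weights)):
            total = float(sum(weights.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1, got {total!r}")
            if any(w < 0 for w in weights.values()):
                raise ConfigError(f"{name} contains negative weights")
        for name, value in (("frac_matrisome", self.frac_matrisome),
                            ("transition_prob", self.transition_prob),
                            ("censor_rate", self.censor_rate)):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.n_genes < 10:
            raise ConfigError("n_genes must be at least 10")
        unknown = set(self.category_weights) - set(io.MATRISOME_CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown matrisome categories: {sorted(unknown)}")
        unknown_vc = set(self.variant_class_weights) - set(io.VARIANT_CLASSES)
        if unknown_vc:
            raise ConfigError(f"unknown variant classes: {sorted(unknown_vc)}")
        if set(self.cna_state_weights) - {-2, -1, 1, 2}:
            raise ConfigError("cna_state_weights keys must be in {-2,-1,1,2}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_survival_genes"] = [list(g) for g in self.planted_survival_genes]
        d["cna_state_weights"] = {str(k): v for k, v in self.cna_state_weights.items()}
        d["length_params"] = {k: list(v) for k, v in self.length_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "cna_state_weights" in d:
            d["cna_state_weights"] = {int(k): v for k, v in d["cna_state_weights"].items()}
        if "length_params" in d:
            d["length_params"] = {k: tuple(v) for k, v in d["length_params"].items()}
        if "planted_survival_genes" in d:
            d["planted_survival_genes"] = tuple(
                (g, float(b)) for g, b in d["planted_survival_genes"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """A fully generated cohort plus the record of its planted effects."""

    annotation: pd.DataFrame
    cna: pd.DataFrame
    expression: pd.DataFrame
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    domains: pd.DataFrame
    truth: dict


def _rng(config: CohortConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STAGE[stage]])


def sample_roster(config: CohortConfig) -> pd.DataFrame:
    """Sample identifiers and round-robin tumor-type assignment.

    Deterministic given the config alone, so the mutation and clinical stages
    can agree on the cohort roster without a data dependency.
    """
    n = config.n_tumor_types * config.samples_per_tumor
    tumors = [TUMOR_TYPES[i % len(TUMOR_TYPES)] for i in range(config.n_tumor_types)]
    return pd.DataFrame({
        "sample": [f"S{i + 1:05d}" for i in range(n)],
        "tumor_type": [tumors[i % len(tumors)] for i in range(n)],
    })


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def generate_annotation(config: CohortConfig) -> pd.DataFrame:
    """Gene universe: symbols, divisions, categories and log-normal lengths."""
    rng = _rng(config, "annotation")
    n_mat = round(config.n_genes * config.frac_matrisome)
    n_non = config.n_genes - n_mat

    cats = list(config.category_weights)
    probs = np.array([config.category_weights[c] for c in cats])
    mat_cats = rng.choice(cats, size=n_mat, p=probs) if n_mat else np.array([], dtype=object)

    records = []
    for i, cat in enumerate(mat_cats):
        records.append((f"MXG{i + 1:04d}", io.CATEGORY_DIVISION[cat], cat))
    for i in range(n_non):
        records.append((f"NMG{i + 1:05d}", "non-matrisome", "none"))
    annotation = pd.DataFrame(records, columns=["gene_symbol", "division", "category"])

    lengths = np.empty(len(annotation))
    for division, (median, sigma) in config.length_params.items():
        mask = (annotation["division"] == division).to_numpy()
        lengths[mask] = rng.lognormal(math.log(median), sigma, mask.sum())
    annotation["length_bp"] = np.maximum(np.round(lengths), 90).astype(int)
    annotation = annotation[list(io.ANNOTATION_COLUMNS)]
    return io.validate_annotation(annotation)


def generate_cna(annotation: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Thresholded CNA calls: Bernoulli alteration, then a nonzero state."""
    rng = _rng(config, "cna")
    roster = sample_roster(config)
    is_mat = (annotation["division"] != "non-matrisome").to_numpy()
    p = np.where(is_mat, config.cna_rate * config.matrisome_cna_multiplier, config.cna_rate)
    if (p > 1).any():
        raise ConfigError(
            f"cna_rate * matrisome_cna_multiplier = {p.max():g} exceeds 1")
    n_genes, n_samples = len(annotation), len(roster)
    altered = rng.random((n_genes, n_samples)) < p[:, None]
    states = list(config.cna_state_weights)
    weights = [config.cna_state_weights[s] for s in states]
    drawn = rng.choice(np.array(states, dtype=np.int8), size=(n_genes, n_samples), p=weights)
    calls = np.where(altered, drawn, 0).astype(np.int8)
    matrix = pd.DataFrame(calls, index=pd.Index(annotation["gene_symbol"], name="gene_symbol"),
                          columns=roster["sample"])
    return io.validate_cna_matrix(matrix)


def coupled_genes(annotation: pd.DataFrame, config: CohortConfig) -> list[str]:
    """The matrisome genes whose expression is coupled to CNA carrier status."""
    rng = _rng(config, "expression")
    mat = annotation.loc[annotation["division"] != "non-matrisome", "gene_symbol"]
    k = min(config.expr_coupled_genes, len(mat))
    return sorted(rng.choice(mat.to_numpy(), size=k, replace=False)) if k else []


def generate_expression(annotation: pd.DataFrame, cna: pd.DataFrame,
                        config: CohortConfig) -> pd.DataFrame:
    """log2(norm+1) expression; coupled genes' carriers get an expr_effect fold-change."""
    rng = _rng(config, "expression")
    # consume the same draw used by coupled_genes() so gene choice is shared
    mat = annotation.loc[annotation["division"] != "non-matrisome", "gene_symbol"]
    k = min(config.expr_coupled_genes, len(mat))
    chosen = set(rng.choice(mat.to_numpy(), size=k, replace=False)) if k else set()

    n_genes, n_samples = cna.shape
    base = rng.lognormal(math.log(100.0), 1.0, n_genes)          # per-gene baseline, linear scale
    noise = rng.normal(0.0, config.expr_noise_sd, (n_genes, n_samples))
    linear = base[:, None] * np.exp2(noise)
    coupled_mask = cna.index.isin(chosen)
    carriers = (cna.to_numpy() != 0) & coupled_mask[:, None]
    linear = np.where(carriers, linear * config.expr_effect, linear)
    values = np.log2(linear + 1.0)
    matrix = pd.DataFrame(values, index=cna.index.copy(), columns=cna.columns.copy())
    return io.validate_expression_matrix(matrix)


def generate_mutations(annotation: pd.DataFrame, clinical: pd.DataFrame,
                       config: CohortConfig) -> pd.DataFrame:
    """Somatic mutation records from length-proportional Poisson counts.

    ``clinical`` needs only ``sample`` and ``tumor_type`` columns (the roster);
    the full clinical table also works.
    """
    rng = _rng(config, "mutations")
    samples = clinical["sample"].to_numpy()
    tumor_of = clinical.set_index("sample")["tumor_type"]
    lengths = annotation["length_bp"].to_numpy(dtype=float)
    is_mat = (annotation["division"] != "non-matrisome").to_numpy()
    rate = lengths * config.mutation_rate_per_bp
    rate = np.where(is_mat, rate * config.matrisome_mut_multiplier, rate)

    counts = rng.poisson(rate[:, None], size=(len(annotation), len(samples)))
    gene_idx, sample_idx = np.nonzero(counts)
    reps = counts[gene_idx, sample_idx]
    gene_idx = np.repeat(gene_idx, reps)
    sample_idx = np.repeat(sample_idx, reps)
    n = len(gene_idx)
    if n == 0:
        empty = pd.DataFrame(columns=list(io.MUTATION_COLUMNS))
        empty["pos"] = empty["pos"].astype(int)
        empty["protein_pos"] = empty["protein_pos"].astype("Int64")
        return empty

    genes = annotation["gene_symbol"].to_numpy()[gene_idx]
    glen = lengths[gene_idx].astype(int)
    # stable fake loci: one chromosome slot and a 10-Mb stride per gene
    chrom = np.array([f"chr{(i % 22) + 1}" for i in gene_idx])
    gene_start = (gene_idx // 22 + 1) * 10_000_000
    pos = gene_start + rng.integers(0, np.maximum(glen, 1))

    classes = list(config.variant_class_weights)
    probs = [config.variant_class_weights[c] for c in classes]
    vclass = rng.choice(np.array(classes, dtype=object), size=n, p=probs)

    ref, alt = _draw_alleles(rng, vclass, config.transition_prob)

    protein_len = np.maximum(glen // 3, 1)
    protein_pos = rng.integers(1, protein_len + 1)
    coding = np.isin(vclass, list(io.CODING_CLASSES))
    protein_pos = pd.array(np.where(coding, protein_pos, 0), dtype="Int64")
    protein_pos[~coding] = pd.NA

    pp_labels = list(config.polyphen_weights)
    pp_probs = [config.polyphen_weights[l] for l in pp_labels]
    polyphen = np.where(
        vclass == "missense",
        rng.choice(np.array(pp_labels, dtype=object), size=n, p=pp_probs),
        "unknown",
    )

    table = pd.DataFrame({
        "sample": samples[sample_idx],
        "gene_symbol": genes,
        "tumor_type": tumor_of.loc[samples[sample_idx]].to_numpy(),
        "chrom": chrom,
        "pos": pos.astype(int),
        "ref": ref,
        "alt": alt,
        "variant_class": vclass,
        "protein_pos": protein_pos,
        "polyphen": polyphen,
    })
    return io.validate_mutations(table)


_INDEL_CLASSES = {"frame_shift_del": ("del", 1), "frame_shift_ins": ("ins", 1),
                  "in_frame_del": ("del", 3), "in_frame_ins": ("ins", 3)}


def _draw_alleles(rng: np.random.Generator, vclass: np.ndarray,
                  transition_prob: float) -> tuple[np.ndarray, np.ndarray]:
    n = len(vclass)
    bases = np.array(["A", "C", "G", "T"])
    ref = rng.choice(bases, size=n)
    is_ti = rng.random(n) < transition_prob
    which_tv = rng.integers(0, 2, size=n)
    alt = np.empty(n, dtype=object)
    for i in range(n):
        b = ref[i]
        alt[i] = _TRANSITION[b] if is_ti[i] else _TRANSVERSIONS[b][which_tv[i]]
    ref = ref.astype(object)
    filler = rng.choice(bases, size=n)
    for i in range(n):
        kind = _INDEL_CLASSES.get(vclass[i])
        if kind is None:
            continue
        op, width = kind
        anchor = ref[i]
        run = str(filler[i]) * width
        if op == "del":
            ref[i], alt[i] = anchor + run, anchor
        else:
            ref[i], alt[i] = anchor, anchor + run
    return ref, alt


def generate_clinical(config: CohortConfig, mutations: pd.DataFrame) -> pd.DataFrame:
    """Clinical covariates and exponential OS with planted carrier hazards."""
    rng = _rng(config, "clinical")
    roster = sample_roster(config)
    n = len(roster)

    age = np.clip(np.round(rng.normal(62.0, 11.0, n)), 20, 90).astype(int)
    gender = rng.choice(np.array(["female", "male"], dtype=object), size=n, p=[0.52, 0.48])
    ethnicity = rng.choice(
        np.array(["white", "black", "asian", "other"], dtype=object),
        size=n, p=[0.70, 0.12, 0.10, 0.08])
    cpe = np.round(rng.beta(5.0, 2.0, n), 4)

    log_hr = np.zeros(n)
    for gene, beta in config.planted_survival_genes:
        carriers = set(mutations.loc[mutations["gene_symbol"] == gene, "sample"])
        log_hr += np.where(roster["sample"].isin(carriers), float(beta), 0.0)
    hazard = config.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < config.censor_rate
    os_months = np.where(censored, t_event * rng.random(n), t_event)

    clinical = roster.assign(
        os_months=np.round(os_months, 4),
        os_event=~censored,
        age=age,
        gender=gender,
        ethnicity=ethnicity,
        cpe=cpe,
    )[list(io.CLINICAL_COLUMNS)]
    return io.validate_clinical(clinical)


def generate_domains(annotation: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """1-5 non-overlapping amino-acid domain intervals per matrisome gene."""
    rng = _rng(config, "domains")
    records = []
    mat = annotation[annotation["division"] != "non-matrisome"]
    for gene, length in zip(mat["gene_symbol"], mat["length_bp"]):
        protein_len = max(int(length) // 3, 1)
        n_dom = int(rng.integers(1, 6))
        n_dom = min(n_dom, protein_len // 2)  # need 2 distinct coords per interval
        if n_dom < 1:
            continue
        cuts = np.sort(rng.choice(np.arange(1, protein_len + 1), size=2 * n_dom, replace=False))
        names = rng.choice(np.array(DOMAIN_VOCABULARY, dtype=object), size=n_dom, replace=False)
        for j in range(n_dom):
            records.append((gene, names[j], int(cuts[2 * j]), int(cuts[2 * j + 1])))
    domains = pd.DataFrame(records, columns=list(io.DOMAIN_COLUMNS))
    return io.validate_domains(domains)


# ---------------------------------------------------------------------------
# whole-cohort assembly and serialization
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Run every stage in dependency order and bundle the ground truth."""
    annotation = generate_annotation(config)
    cna = generate_cna(annotation, config)
    expression = generate_expression(annotation, cna, config)
    roster = sample_roster(config)
    mutations = generate_mutations(annotation, roster, config)
    clinical = generate_clinical(config, mutations)
    domains = generate_domains(annotation, config)
    truth = {
        "matrisome_genes": annotation.loc[
            annotation["division"] != "non-matrisome", "gene_symbol"].tolist(),
        "coupled_genes": coupled_genes(annotation, config),
        "hazard_genes": {g: b for g, b in config.planted_survival_genes},
        "config": config.to_dict(),
    }
    return SyntheticCohort(annotation, cna, expression, mutations, clinical, domains, truth)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write all cohort tables plus the truth sidecar; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.tsv",
        "cna": outdir / "cna.tsv",
        "expression": outdir / "expression.tsv",
        "mutations": outdir / "mutations.maf",
        "clinical": outdir / "clinical.tsv",
        "domains": outdir / "domains.tsv",
        "truth": outdir / "truth.json",
    }
    io.write_gene_list(cohort.annotation, paths["annotation"])
    io.write_matrix(cohort.cna, paths["cna"])
    io.write_matrix(cohort.expression.round(6), paths["expression"])
    io.write_maf(cohort.mutations, paths["mutations"])
    io.write_clinical(cohort.clinical, paths["clinical"])
    io.write_domains(cohort.domains, paths["domains"])
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2, sort_keys=True))
    return paths


def read_cohort(indir: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    return SyntheticCohort(
        annotation=io.read_gene_list(indir / "annotation.tsv"),
        cna=io.read_matrix(indir / "cna.tsv", "cna"),
        expression=io.read_matrix(indir / "expression.tsv", "expression"),
        mutations=io.read_maf(indir / "mutations.maf"),
        clinical=io.read_clinical(indir / "clinical.tsv"),
        domains=io.read_domains(indir / "domains.tsv"),
        truth=json.loads((indir / "truth.json").read_text()),
    )
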