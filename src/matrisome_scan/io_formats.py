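"""Readers, writers and validators for the tabular dialects the pipeline touches.

Conventions enforced here, once:

* genomic coordinates are 1-based inclusive (MAF convention);
* protein-domain coordinates are 1-based inclusive amino-acid positions;
* gene-by-sample matrices are Xena-style TSV — first column gene symbols,
  header row sample identifiers, first header cell ignored;
* CNA call matrices hold GISTIC-thresholded integers in {-2, -1, 0, 1, 2}
  (homozygous deletion, single-copy deletion, diploid, low-level gain,
  high-level amplification) and may not contain missing values;
* expression matrices are log2(normalized value + 1) and may contain missing
  values, which are treated as absent;
* tumor-type assignment lives only in the clinical table (matrices never
  encode it); the MAF dialect written by the simulator carries a tumor_type
  column as a convenience, and the reader keeps it when present.

Readers reject invariant violations with :class:`FormatError`; they never
silently repair. Every writer produces a file its paired reader accepts.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import FormatError

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

CNA_STATES = (-2, -1, 0, 1, 2)

DIVISIONS = ("core matrisome", "matrisome-associated", "non-matrisome")
CORE_CATEGORIES = ("collagens", "ECM glycoproteins", "proteoglycans")
ASSOCIATED_CATEGORIES = ("ECM-affiliated", "ECM regulators", "secreted factors")
MATRISOME_CATEGORIES = CORE_CATEGORIES + ASSOCIATED_CATEGORIES
CATEGORIES = MATRISOME_CATEGORIES + ("none",)
#: category -> division implied by the matrisome nomenclature
CATEGORY_DIVISION = {
    **{c: "core matrisome" for c in CORE_CATEGORIES},
    **{c: "matrisome-associated" for c in ASSOCIATED_CATEGORIES},
    "none": "non-matrisome",
}

VARIANT_CLASSES = (
    "missense", "silent", "nonsense", "nonstop",
    "frame_shift_del", "frame_shift_ins", "in_frame_del", "in_frame_ins",
    "splice_site", "3'UTR", "5'UTR", "intron", "other",
)
#: variant classes that fall in the coding sequence and may carry a protein position
CODING_CLASSES = frozenset(
    ("missense", "silent", "nonsense", "nonstop",
     "frame_shift_del", "frame_shift_ins", "in_frame_del", "in_frame_ins")
)

POLYPHEN_LABELS = ("benign", "possibly_damaging", "probably_damaging", "unknown")

#: MAF Variant_Classification -> canonical class
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Silent": "silent",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "nonstop",
    "Frame_Shift_Del": "frame_shift_del",
    "Frame_Shift_Ins": "frame_shift_ins",
    "In_Frame_Del": "in_frame_del",
    "In_Frame_Ins": "in_frame_ins",
    "Splice_Site": "splice_site",
    "3'UTR": "3'UTR",
    "5'UTR": "5'UTR",
    "Intron": "intron",
}
# canonical labels are accepted as-is so our own writer round-trips
MAF_CLASS_MAP.update({c: c for c in VARIANT_CLASSES})

MUTATION_COLUMNS = (
    "sample", "gene_symbol", "tumor_type", "chrom", "pos",
    "ref", "alt", "variant_class", "protein_pos", "polyphen",
)
CLINICAL_COLUMNS = (
    "sample", "tumor_type", "os_months", "os_event",
    "age", "gender", "ethnicity", "cpe",
)
ANNOTATION_COLUMNS = ("gene_symbol", "length_bp", "division", "category")
DOMAIN_COLUMNS = ("gene_symbol", "domain_name", "aa_start", "aa_end")

_MAF_RENAME = {
    "Tumor_Sample_Barcode": "sample",
    "Hugo_Symbol": "gene_symbol",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Variant_Classification": "variant_class",
    "Protein_position": "protein_pos",
    "PolyPhen": "polyphen",
}


# ---------------------------------------------------------------------------
# Validators
# ---------------------------------------------------------------------------

def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a gene annotation table against the matrisome vocabulary.

    Raises :class:`FormatError` on duplicate symbols, non-positive lengths,
    unknown division/category labels, or category/division mismatches
    (e.g. collagens listed under matrisome-associated).
    """
    _require_columns(annotation, ANNOTATION_COLUMNS, "annotation")
    dup = annotation["gene_symbol"][annotation["gene_symbol"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate gene symbols in annotation: {sorted(set(dup))[:5]}")
    if (annotation["length_bp"] <= 0).any():
        bad = annotation.loc[annotation["length_bp"] <= 0, "gene_symbol"]
        raise FormatError(f"non-positive gene lengths for: {list(bad[:5])}")
    bad_div = set(annotation["division"]) - set(DIVISIONS)
    if bad_div:
        raise FormatError(f"unknown division labels: {sorted(bad_div)}")
    bad_cat = set(annotation["category"]) - set(CATEGORIES)
    if bad_cat:
        raise FormatError(f"unknown category labels: {sorted(bad_cat)}")
    implied = annotation["category"].map(CATEGORY_DIVISION)
    mism = annotation[implied != annotation["division"]]
    if len(mism):
        row = mism.iloc[0]
        raise FormatError(
            f"category/division mismatch for gene {row['gene_symbol']!r}: "
            f"category {row['category']!r} cannot occur under {row['division']!r}"
        )
    return annotation


def validate_cna_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a genes-by-samples CNA call matrix (integers in {-2..2}, no NA)."""
    _check_matrix_ids(matrix)
    if matrix.isna().any().any():
        gene, sample = _first_offender(matrix.isna())
        raise FormatError(f"missing CNA call at gene {gene!r}, sample {sample!r}")
    values = matrix.to_numpy()
    if not np.array_equal(values, np.round(values)):
        gene, sample = _first_offender(matrix != np.round(matrix))
        raise FormatError(f"non-integer CNA call at gene {gene!r}, sample {sample!r}")
    out_of_range = ~matrix.isin(CNA_STATES)
    if out_of_range.any().any():
        gene, sample = _first_offender(out_of_range)
        raise FormatError(
            f"CNA call {matrix.loc[gene, sample]!r} outside {{-2..2}} "
            f"at gene {gene!r}, sample {sample!r}"
        )
    return matrix.astype(np.int8)


def validate_expression_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a genes-by-samples log2(norm+1) expression matrix (values >= 0, NA allowed)."""
    _check_matrix_ids(matrix)
    negative = matrix.lt(0)
    if negative.any().any():
        gene, sample = _first_offender(negative)
        raise FormatError(
            f"negative expression value at gene {gene!r}, sample {sample!r}; "
            "expected log2(norm+1) scale"
        )
    return matrix.astype(float)


def validate_mutations(mutations: pd.DataFrame) -> pd.DataFrame:
    """Check a canonical mutation table (MAF subset)."""
    _require_columns(mutations, MUTATION_COLUMNS, "mutation table")
    bad_class = set(mutations["variant_class"]) - set(VARIANT_CLASSES)
    if bad_class:
        raise FormatError(f"unknown variant classes: {sorted(bad_class)}")
    same = mutations["ref"] == mutations["alt"]
    if same.any():
        row = mutations[same].iloc[0]
        raise FormatError(
            f"ref == alt ({row['ref']!r}) for gene {row['gene_symbol']!r} "
            f"at {row['chrom']}:{row['pos']}"
        )
    has_pos = mutations["protein_pos"].notna()
    noncoding = ~mutations["variant_class"].isin(CODING_CLASSES)
    bad = has_pos & noncoding
    if bad.any():
        row = mutations[bad].iloc[0]
        raise FormatError(
            f"protein position on non-coding class {row['variant_class']!r} "
            f"(gene {row['gene_symbol']!r})"
        )
    bad_pp = set(mutations["polyphen"]) - set(POLYPHEN_LABELS)
    if bad_pp:
        raise FormatError(f"unknown PolyPhen labels: {sorted(bad_pp)}")
    out = mutations.copy()
    out["protein_pos"] = out["protein_pos"].astype("Int64")
    out["pos"] = out["pos"].astype(int)
    return out


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check a per-sample clinical table (unique samples, os_months >= 0, cpe in [0,1])."""
    _require_columns(clinical, CLINICAL_COLUMNS, "clinical table")
    dup = clinical["sample"][clinical["sample"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate sample identifiers: {sorted(set(dup))[:5]}")
    if (clinical["os_months"] < 0).any():
        raise FormatError("negative overall-survival times present")
    cpe = clinical["cpe"].dropna()
    if ((cpe < 0) | (cpe > 1)).any():
        raise FormatError("CPE purity values must lie in [0, 1]")
    out = clinical.copy()
    out["os_event"] = out["os_event"].astype(bool)
    return out


def validate_domains(domains: pd.DataFrame) -> pd.DataFrame:
    """Check a protein-domain interval table (1 <= aa_start <= aa_end)."""
    _require_columns(domains, DOMAIN_COLUMNS, "domain table")
    bad = (domains["aa_start"] < 1) | (domains["aa_start"] > domains["aa_end"])
    if bad.any():
        row = domains[bad].iloc[0]
        raise FormatError(
            f"invalid domain interval [{row['aa_start']}, {row['aa_end']}] "
            f"for gene {row['gene_symbol']!r}"
        )
    out = domains.copy()
    out[["aa_start", "aa_end"]] = out[["aa_start", "aa_end"]].astype(int)
    return out


# ---------------------------------------------------------------------------
# Matrix I/O (Xena-style TSV)
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a Xena-style gene-by-sample TSV.

    Parameters
    ----------
    path
        TSV file: first column gene symbols, header row sample identifiers
        (the first header cell is ignored).
    kind
        ``"cna"`` for thresholded copy-number calls or ``"expression"`` for
        log2(norm+1) expression.
    """
    if kind not in ("cna", "expression"):
        raise ValueError(f"kind must be 'cna' or 'expression', got {kind!r}")
    # pandas silently renames duplicate header cells, so check them up front
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dup = next(s for s in header if header.count(s) > 1)
        raise FormatError(f"duplicate sample identifier {dup!r}")
    matrix = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    matrix.index.name = "gene_symbol"
    if kind == "cna":
        return validate_cna_matrix(matrix)
    return validate_expression_matrix(matrix)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a gene-by-sample matrix as Xena-style TSV (genes in row order)."""
    matrix.to_csv(path, sep="\t", index_label="Gene", na_rep="NA")


# ---------------------------------------------------------------------------
# MAF I/O
# ---------------------------------------------------------------------------

def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a MAF-style mutation file into the canonical mutation table.

    Accepts either standard MAF column names (Hugo_Symbol, Tumor_Sample_Barcode,
    Variant_Classification, ...) or the canonical lower-case names this package
    writes. Unknown variant classifications map to ``"other"`` with a logged
    count; PolyPhen strings such as ``"probably damaging(0.98)"`` are reduced
    to their label.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str, "Chromosome": str})
    raw = raw.rename(columns=_MAF_RENAME)
    required = ["sample", "gene_symbol", "chrom", "pos", "ref", "alt", "variant_class"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"MAF file {path} lacks required columns: {missing}")

    mapped = raw["variant_class"].map(MAF_CLASS_MAP)
    unknown = raw["variant_class"][mapped.isna()]
    if len(unknown):
        counts = unknown.value_counts()
        logger.info("mapping %d records with unknown variant classes to 'other': %s",
                    len(unknown), counts.to_dict())
    raw["variant_class"] = mapped.fillna("other")

    if "tumor_type" not in raw.columns:
        raw["tumor_type"] = pd.NA
    if "protein_pos" not in raw.columns:
        raw["protein_pos"] = pd.NA
    raw["protein_pos"] = pd.to_numeric(raw["protein_pos"], errors="coerce").astype("Int64")
    # protein positions only make sense for coding classes; MAF files sometimes
    # carry residuals on UTR records — strip rather than reject third-party files
    raw.loc[~raw["variant_class"].isin(CODING_CLASSES), "protein_pos"] = pd.NA
    if "polyphen" not in raw.columns:
        raw["polyphen"] = "unknown"
    raw["polyphen"] = _normalize_polyphen(raw["polyphen"])

    return validate_mutations(raw[list(MUTATION_COLUMNS)].copy())


def write_maf(mutations: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical mutation table as a minimum-column MAF."""
    validate_mutations(mutations).to_csv(path, sep="\t", index=False)


def _normalize_polyphen(labels: pd.Series) -> pd.Series:
    clean = (labels.fillna("unknown").astype(str)
             .str.replace(r"\(.*\)$", "", regex=True)
             .str.strip().str.lower().str.replace(" ", "_"))
    return clean.where(clean.isin(POLYPHEN_LABELS), "unknown")


# ---------------------------------------------------------------------------
# Annotation / clinical / domain I/O
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation table (TSV or CSV by extension) and validate it."""
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep)
    _require_columns(table, ANNOTATION_COLUMNS, "gene list")
    return validate_annotation(table[list(ANNOTATION_COLUMNS)].copy())


def write_gene_list(annotation: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(annotation).to_csv(path, sep="\t", index=False)


def merge_gene_universe(
    matrisome: pd.DataFrame, gene_lengths: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Merge a matrisome gene list into a genome-wide length table.

    Matching is exact on gene symbol. Genes in ``gene_lengths`` absent from the
    matrisome list are appended as non-matrisome; matrisome symbols with no
    length entry are dropped and returned as the unmatched list (logged), the
    way a symbol-level merge of curated lists against TCGA tables loses a few
    genes.
    """
    _require_columns(gene_lengths, ("gene_symbol", "length_bp"), "gene length table")
    known = set(gene_lengths["gene_symbol"])
    unmatched = sorted(set(matrisome["gene_symbol"]) - known)
    if unmatched:
        logger.warning("%d matrisome symbols had no length entry and were dropped: %s",
                       len(unmatched), unmatched[:10])
    kept = matrisome[matrisome["gene_symbol"].isin(known)]
    merged = gene_lengths[["gene_symbol", "length_bp"]].merge(
        kept[["gene_symbol", "division", "category"]], on="gene_symbol", how="left"
    )
    merged["division"] = merged["division"].fillna("non-matrisome")
    merged["category"] = merged["category"].fillna("none")
    return validate_annotation(merged), unmatched


def read_clinical(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    return validate_clinical(table)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    validate_clinical(clinical).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_domains(path: str | Path) -> pd.DataFrame:
    return validate_domains(pd.read_csv(path, sep="\t"))


def write_domains(domains: pd.DataFrame, path: str | Path) -> None:
    validate_domains(domains).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_result_table(table: pd.DataFrame, path: str | Path,
                       sort_by: list[str] | None = None) -> None:
    """Write an analysis result table as TSV with deterministic row order.

    ``sort_by`` names the sort keys for the result type; column order is the
    DataFrame's column order, which each stage fixes. An empty table yields a
    header-only file.
    """
    out = table.sort_values(sort_by, kind="mergesort") if sort_by and len(table) else table
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _require_columns(table: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise FormatError(f"{what} lacks required columns: {missing}")


def _check_matrix_ids(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise FormatError(f"duplicate gene identifier {dup!r}")
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise FormatError(f"duplicate sample identifier {dup!r}")


def _first_offender(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    gene, sample = stacked[stacked].index[0]
    return gene, sample
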