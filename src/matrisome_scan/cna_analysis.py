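"""Copy-number alteration frequencies, quartile binning, and expression effects.

Per tumor type, each gene's CNA frequency is the percentage of that tumor's
samples carrying a qualifying call. Frequencies are binned into quartile
classes Q0-Q4 (Q0 is exactly 0%, then half-open quarters (0,25], (25,50],
(50,75], (75,100]) and the bin distributions of matrisome versus non-matrisome
genes are compared with a two-sided chi-square test on the 2x5 contingency
table of gene counts.

The CNA-to-expression stage classifies, per tumor and gene, whether CNA
carriers express the gene at least 50% higher (up) or lower (down) than
non-carriers, on the back-transformed linear scale (the matrices are
log2(norm+1)).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import EmptyGroupError
from . import io_formats as io

logger = logging.getLogger(__name__)

BINS = ("Q0", "Q1", "Q2", "Q3", "Q4")

#: direction name -> predicate on a call array
DIRECTIONS = {
    "any": lambda c: c != 0,
    "gain": lambda c: c > 0,
    "loss": lambda c: c < 0,
    "high_amp": lambda c: c == 2,
    "low_amp": lambda c: c == 1,
    "homo_del": lambda c: c == -2,
    "single_del": lambda c: c == -1,
}


def bin_frequency(pct: float) -> str:
    """Quartile bin of a CNA sample-frequency percentage.

    Q0 iff pct == 0; Q1 iff 0 < pct <= 25; Q2 iff 25 < pct <= 50;
    Q3 iff 50 < pct <= 75; Q4 iff 75 < pct <= 100.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentage must lie in [0, 100], got {pct}")
    if pct == 0.0:
        return "Q0"
    return BINS[int(np.ceil(pct / 25.0))]


def bin_frequencies(pct: pd.Series | np.ndarray) -> np.ndarray:
    """Vectorized :func:`bin_frequency`."""
    pct = np.asarray(pct, dtype=float)
    if ((pct < 0) | (pct > 100)).any():
        bad = pct[(pct < 0) | (pct > 100)][0]
        raise ValueError(f"percentage must lie in [0, 100], got {bad}")
    idx = np.ceil(pct / 25.0).astype(int)
    idx[pct == 0.0] = 0
    return np.array(BINS, dtype=object)[idx]


def cna_frequency(cna: pd.DataFrame, clinical: pd.DataFrame,
                  direction: str = "any") -> pd.DataFrame:
    """Per-(tumor, gene) CNA frequency and quartile bin.

    ``direction`` selects which calls qualify: ``any`` (call != 0), ``gain``,
    ``loss``, ``high_amp`` (+2), ``low_amp`` (+1), ``homo_del`` (-2) or
    ``single_del`` (-1). Tumor types with no samples in the matrix are
    excluded with a log entry.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}; choose from {sorted(DIRECTIONS)}")
    predicate = DIRECTIONS[direction]
    sample_tumor = clinical.set_index("sample")["tumor_type"]
    frames = []
    for tumor, samples in sample_tumor.groupby(sample_tumor).groups.items():
        cols = [s for s in samples if s in cna.columns]
        if not cols:
            logger.info("tumor %s has no samples in the CNA matrix; excluded", tumor)
            continue
        counts = predicate(cna[cols].to_numpy()).sum(axis=1)
        pct = 100.0 * counts / len(cols)
        frames.append(pd.DataFrame({
            "tumor_type": tumor,
            "gene_symbol": cna.index,
            "direction": direction,
            "n_altered": counts,
            "n_samples": len(cols),
            "pct_samples": pct,
            "bin": bin_frequencies(pct),
        }))
    if not frames:
        return pd.DataFrame(columns=["tumor_type", "gene_symbol", "direction",
                                     "n_altered", "n_samples", "pct_samples", "bin"])
    return pd.concat(frames, ignore_index=True)


def compare_bins(freqs: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Chi-square comparison of matrisome vs non-matrisome bin distributions.

    One row per (tumor_type, direction) with the 2x5 gene-count contingency
    table (columns ``mat_Q0..mat_Q4``, ``non_Q0..non_Q4``), the chi-square
    statistic (no continuity correction, all-zero bins dropped), degrees of
    freedom and two-sided p-value.
    """
    is_mat = annotation.set_index("gene_symbol")["division"] != "non-matrisome"
    freqs = freqs.assign(_mat=freqs["gene_symbol"].map(is_mat))
    rows = []
    for (tumor, direction), grp in freqs.groupby(["tumor_type", "direction"], sort=True):
        mat = grp[grp["_mat"] == True]        # noqa: E712 - NaN-safe comparison
        non = grp[grp["_mat"] == False]       # noqa: E712
        if len(mat) == 0 or len(non) == 0:
            raise EmptyGroupError(
                f"tumor {tumor}: matrisome and non-matrisome groups must both be "
                f"nonempty ({len(mat)} vs {len(non)} genes)")
        table = np.array([
            [(mat["bin"] == b).sum() for b in BINS],
            [(non["bin"] == b).sum() for b in BINS],
        ], dtype=float)
        chi2, p, dof = _chi2_drop_zero(table)
        row = {"tumor_type": tumor, "direction": direction}
        row.update({f"mat_{b}": int(table[0, i]) for i, b in enumerate(BINS)})
        row.update({f"non_{b}": int(table[1, i]) for i, b in enumerate(BINS)})
        row.update({"chi2_stat": chi2, "df": dof, "p_value": p})
        rows.append(row)
    return pd.DataFrame(rows)


def _chi2_drop_zero(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square after dropping all-zero columns; degenerate -> (0, 1, 0)."""
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, 0
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), int(dof)


def expression_effect(cna: pd.DataFrame, expression: pd.DataFrame,
                      clinical: pd.DataFrame, annotation: pd.DataFrame,
                      threshold: float = 0.5, min_group: int = 3,
                      direction: str = "any") -> pd.DataFrame:
    """Classify per-(tumor, gene) CNA effects on expression.

    Carriers are samples with a qualifying call (default: any nonzero).
    Means are taken on the back-transformed linear scale ``2**v - 1``;
    ``fold_ratio`` is carrier mean / non-carrier mean, and the effect is
    ``up`` iff fold_ratio >= 1 + threshold, ``down`` iff <= 1 - threshold,
    else ``none``. Gene-tumor pairs with fewer than ``min_group`` carriers or
    non-carriers are excluded (logged), as are pairs whose non-carrier mean is
    not positive.
    """
    predicate = DIRECTIONS[direction]
    genes = cna.index.intersection(expression.index)
    samples = cna.columns.intersection(expression.columns)
    samples = samples.intersection(pd.Index(clinical["sample"]))
    info = annotation.set_index("gene_symbol")[["division", "category"]]
    sample_tumor = clinical.set_index("sample")["tumor_type"]

    calls = cna.loc[genes, samples].to_numpy()
    linear = np.exp2(expression.loc[genes, samples].to_numpy()) - 1.0
    observed = ~np.isnan(linear)
    carrier = predicate(calls) & observed
    noncarrier = (calls == 0) & observed

    rows = []
    n_excluded = 0
    tumor_of = sample_tumor.loc[samples].to_numpy()
    for tumor in pd.unique(tumor_of):
        cols = tumor_of == tumor
        n_c = carrier[:, cols].sum(axis=1)
        n_n = noncarrier[:, cols].sum(axis=1)
        safe = np.nan_to_num(linear[:, cols])
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_c = (safe * carrier[:, cols]).sum(axis=1) / n_c
            mean_n = (safe * noncarrier[:, cols]).sum(axis=1) / n_n
        ok = (n_c >= min_group) & (n_n >= min_group) & (mean_n > 0)
        n_excluded += int((~ok).sum())
        fold = mean_c[ok] / mean_n[ok]
        # boundaries inclusive; tolerance absorbs the log2/exp2 round trip
        eps = 1e-9
        effect = np.where(fold >= 1.0 + threshold - eps, "up",
                          np.where(fold <= 1.0 - threshold + eps, "down", "none"))
        sub = pd.DataFrame({
            "tumor_type": tumor,
            "gene_symbol": genes[ok],
            "n_carriers": n_c[ok],
            "n_noncarriers": n_n[ok],
            "fold_ratio": fold,
            "effect": effect,
        })
        rows.append(sub)
    if n_excluded:
        logger.info("expression_effect: %d gene-tumor pairs excluded "
                    "(group < %d or degenerate baseline)", n_excluded, min_group)
    if not rows:
        return pd.DataFrame(columns=["tumor_type", "gene_symbol", "division", "category",
                                     "n_carriers", "n_noncarriers", "fold_ratio", "effect"])
    out = pd.concat(rows, ignore_index=True)
    out = out.join(info, on="gene_symbol")
    cols = ["tumor_type", "gene_symbol", "division", "category",
            "n_carriers", "n_noncarriers", "fold_ratio", "effect"]
    return out[cols]


def summarize_effects(effects: pd.DataFrame) -> pd.DataFrame:
    """Per-tumor, per-matrisome-division counts and shares of up/down genes.

    ``pct_of_up`` (resp. ``pct_of_down``) is the division's percentage of that
    tumor's up- (down-) regulated matrisome genes, so core + associated sum to
    100 per tumor wherever any such gene exists.
    """
    mat = effects[effects["division"].isin(["core matrisome", "matrisome-associated"])]
    rows = []
    for tumor, grp in mat.groupby("tumor_type", sort=True):
        n_up_total = int((grp["effect"] == "up").sum())
        n_down_total = int((grp["effect"] == "down").sum())
        for division in ("core matrisome", "matrisome-associated"):
            sub = grp[grp["division"] == division]
            n_up = int((sub["effect"] == "up").sum())
            n_down = int((sub["effect"] == "down").sum())
            rows.append({
                "tumor_type": tumor,
                "division": division,
                "n_genes_classified": len(sub),
                "n_up": n_up,
                "n_down": n_down,
                "pct_of_up": 100.0 * n_up / n_up_total if n_up_total else np.nan,
                "pct_of_down": 100.0 * n_down / n_down_total if n_down_total else np.nan,
            })
    return pd.DataFrame(rows, columns=["tumor_type", "division", "n_genes_classified",
                                       "n_up", "n_down", "pct_of_up", "pct_of_down"])
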