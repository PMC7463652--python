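"""Burden arithmetic, exact rank statistics, hotspot rules, and spectra."""

import itertools

import numpy as np
import pandas as pd
import pytest

from matrisome_scan import ConfigError, MatrisomeScanError
from matrisome_scan import mutation_analysis as ma
from matrisome_scan import synthetic_cohort as sc
from matrisome_scan import CohortConfig, generate_cohort

from conftest import make_annotation, make_mutations


# ---------------------------------------------------------------------------
# burden
# ---------------------------------------------------------------------------

def test_gene_burden_arithmetic():
    ann = make_annotation([{"gene_symbol": "G1", "length_bp": 4000},
                           {"gene_symbol": "G2", "length_bp": 1000}])
    muts = make_mutations([{"gene_symbol": "G1", "sample": f"S{i}", "pos": 100 + i}
                           for i in range(12)])
    burden = ma.gene_burden(muts, ann).set_index("gene_symbol")
    assert burden.loc["G1", "burden"] == pytest.approx(0.003)
    assert burden.loc["G2", "n_mutations"] == 0
    assert burden.loc["G2", "burden"] == 0.0


def test_gene_burden_unknown_gene_errors():
    ann = make_annotation([{"gene_symbol": "G1"}])
    muts = make_mutations([{"gene_symbol": "GHOST"}])
    with pytest.raises(MatrisomeScanError, match="GHOST"):
        ma.gene_burden(muts, ann)


def test_gene_burden_matches_group_and_count_oracle():
    """Per-tumor burden equals an explicit dict-based tally."""
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(12)]
    ann = make_annotation([{"gene_symbol": g, "length_bp": int(l)} for g, l in
                           zip(genes, rng.integers(500, 9000, len(genes)))])
    rows = [{"gene_symbol": rng.choice(genes), "sample": f"S{rng.integers(40)}",
             "tumor_type": rng.choice(["T0", "T1", "T2"]), "pos": int(p)}
            for p in rng.integers(1, 10_000, 300)]
    muts = make_mutations(rows)
    burden = ma.gene_burden(muts, ann, scope="per_tumor")
    tally: dict = {}
    for row in rows:
        key = (row["tumor_type"], row["gene_symbol"])
        tally[key] = tally.get(key, 0) + 1
    lookup = burden.set_index(["tumor_type", "gene_symbol"])["n_mutations"]
    for tumor in ["T0", "T1", "T2"]:
        for gene in genes:
            assert lookup.loc[(tumor, gene)] == tally.get((tumor, gene), 0)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def exact_mwu_two_sided(x, y):
    """Two-sided MWU p by full enumeration of group-label assignments."""
    pooled = list(x) + list(y)
    n_x = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    mean_u = n_x * len(y) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for xi in xs for yj in ys if xi > yj) \
            + 0.5 * sum(1 for xi in xs for yj in ys if xi == yj)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def _burden_table(mat_values, non_values, non_length=1000):
    ann = make_annotation(
        [{"gene_symbol": f"M{i}", "division": "core matrisome",
          "category": "collagens", "length_bp": 1000} for i in range(len(mat_values))]
        + [{"gene_symbol": f"N{i}", "length_bp": non_length}
           for i in range(len(non_values))])
    burden = pd.DataFrame({
        "gene_symbol": [f"M{i}" for i in range(len(mat_values))]
        + [f"N{i}" for i in range(len(non_values))],
        "tumor_type": "pan_cancer",
        "n_mutations": 1,
        "length_bp": [1000] * len(mat_values) + [non_length] * len(non_values),
        "burden": list(mat_values) + list(non_values),
    })
    return burden, ann


def test_burden_mwu_matches_exact_enumeration():
    mat = [0.003, 0.004, 0.005]
    non = [0.001, 0.002]
    burden, ann = _burden_table(mat, non)
    stat, p = ma.burden_mwu(burden, ann)
    assert stat == 6.0  # every matrisome value exceeds every non-matrisome value
    assert p == pytest.approx(exact_mwu_two_sided(mat, non))


@pytest.mark.parametrize("seed", range(6))
def test_burden_mwu_exact_for_small_groups(seed):
    """Agreement with enumeration for random tie-free groups of size <= 8."""
    rng = np.random.default_rng(seed)
    n_mat, n_non = rng.integers(2, 9, size=2)
    values = rng.permutation(np.arange(1, n_mat + n_non + 1) * 1e-3)
    mat, non = values[:n_mat], values[n_mat:]
    burden, ann = _burden_table(mat, non)
    _, p = ma.burden_mwu(burden, ann)
    assert p == pytest.approx(exact_mwu_two_sided(mat, non))


def test_burden_mwu_symmetry_and_identity():
    mat = [0.003, 0.004, 0.005]
    non = [0.001, 0.002]
    burden_a, ann_a = _burden_table(mat, non)
    burden_b, ann_b = _burden_table(non, mat)
    assert ma.burden_mwu(burden_a, ann_a)[1] == pytest.approx(
        ma.burden_mwu(burden_b, ann_b)[1])
    same = [0.001, 0.002, 0.003]
    burden_c, ann_c = _burden_table(same, same)
    assert ma.burden_mwu(burden_c, ann_c)[1] == pytest.approx(1.0)


def test_burden_mwu_include_zero_flag():
    burden, ann = _burden_table([0.003, 0.004], [0.001, 0.002, 0.0025])
    burden.loc[burden["gene_symbol"] == "N2", ["n_mutations", "burden"]] = 0
    _, p_default = ma.burden_mwu(burden, ann)        # N2 excluded by default
    _, p_all = ma.burden_mwu(burden, ann, include_zero=True)
    assert p_default != p_all


# ---------------------------------------------------------------------------
# randomization suite
# ---------------------------------------------------------------------------

def test_randomization_deterministic_and_reports_all_schemes():
    rng = np.random.default_rng(3)
    mat = rng.uniform(1e-3, 5e-3, 12)
    non = rng.uniform(1e-3, 5e-3, 60)
    burden, ann = _burden_table(mat, non, non_length=2000)  # pool longer than matrisome
    cfg = ma.RandomizationConfig(n_reps=10, seed=5)
    a = ma.randomization_suite(burden, ann, cfg)
    b = ma.randomization_suite(burden, ann, cfg)
    assert a.to_dict() == b.to_dict()
    assert set(a.schemes) == {"frac33", "size_matched", "length_matched"}
    for scheme in a.schemes.values():
        assert 0.0 <= scheme["fraction_significant"] <= 1.0
        assert 0.0 < scheme["empirical_p"] <= 1.0


def test_randomization_length_matched_pool_too_small():
    """Scheme 3 needs enough long non-matrisome genes."""
    ann = make_annotation(
        [{"gene_symbol": f"M{i}", "division": "core matrisome",
          "category": "collagens", "length_bp": 9000} for i in range(5)]
        + [{"gene_symbol": f"N{i}", "length_bp": 1000} for i in range(20)])
    burden = ma.gene_burden(make_mutations(
        [{"gene_symbol": g, "pos": i} for i, g in enumerate(ann["gene_symbol"])]), ann)
    with pytest.raises(ConfigError, match="length_matched"):
        ma.randomization_suite(burden, ann, ma.RandomizationConfig(n_reps=5, seed=0))


def test_randomization_null_empirical_p_centered(null_config_factory):
    """On exchangeable null cohorts the matrisome median is typical of random
    sets: empirical_p covers (0,1) with mean near 0.5."""
    emps = []
    for seed in range(100):
        cohort = generate_cohort(null_config_factory(seed))
        burden = ma.gene_burden(cohort.mutations, cohort.annotation)
        res = ma.randomization_suite(
            burden, cohort.annotation,
            ma.RandomizationConfig(schemes=("size_matched",), n_reps=50,
                                   seed=seed + 40_000))
        emps.append(res.schemes["size_matched"]["empirical_p"])
    emps = np.array(emps)
    assert 0.4 <= emps.mean() <= 0.6
    assert emps.min() < 0.2 and emps.max() > 0.8


# ---------------------------------------------------------------------------
# recurrence / hotspots
# ---------------------------------------------------------------------------

def test_recurrence_histogram():
    muts = make_mutations(
        [{"sample": f"S{i}", "pos": 100 + i} for i in range(4)]       # unique
        + [{"sample": f"S{i}", "pos": 999} for i in range(3)])        # shared by 3
    hist = ma.recurrence(muts).set_index("n_patients")["n_keys"]
    assert hist.loc[1] == 4 and hist.loc[3] == 1


def test_recurrence_matches_bruteforce():
    rng = np.random.default_rng(11)
    rows = [{"sample": f"S{rng.integers(15)}", "gene_symbol": f"G{rng.integers(4)}",
             "tumor_type": rng.choice(["T0", "T1"]), "pos": int(rng.integers(1, 20))}
            for _ in range(200)]
    muts = make_mutations(rows)
    counts = ma.recurrence_counts(muts)
    brute: dict = {}
    for row in rows:
        key = (row["tumor_type"], row["gene_symbol"], "chr1", row["pos"], "A", "G")
        brute.setdefault(key, set()).add(row["sample"])
    assert len(counts) == len(brute)
    for _, rec in counts.iterrows():
        key = (rec["tumor_type"], rec["gene_symbol"], rec["chrom"],
               rec["pos"], rec["ref"], rec["alt"])
        assert rec["n_patients"] == len(brute[key])


def test_hotspot_thresholds_are_sharp():
    """>=5 patients in >=2 tumors reports; 5-in-1 plus 4-in-another does not."""
    hot = [{"sample": f"A{i}", "tumor_type": "T0", "pos": 7} for i in range(5)] + \
          [{"sample": f"B{i}", "tumor_type": "T1", "pos": 7} for i in range(5)]
    cold = [{"sample": f"C{i}", "tumor_type": "T0", "pos": 8} for i in range(5)] + \
           [{"sample": f"D{i}", "tumor_type": "T1", "pos": 8} for i in range(4)]
    result = ma.detect_hotspots(make_mutations(hot + cold))
    assert result["pos"].tolist() == [7]
    assert result["n_tumors_qualifying"].iloc[0] == 2


def test_hotspots_subset_of_recurrence_keys(default_cohort):
    hotspots = ma.detect_hotspots(default_cohort.mutations, min_patients=2)
    keys = set(map(tuple, ma.recurrence_counts(default_cohort.mutations)
                   [ma.GENOMIC_KEY].itertuples(index=False)))
    for row in hotspots[ma.GENOMIC_KEY].itertuples(index=False):
        assert tuple(row) in keys


# ---------------------------------------------------------------------------
# substitution spectra
# ---------------------------------------------------------------------------

ALL_PAIRS = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]


def test_exactly_four_transitions():
    labels = {pair: ma.classify_substitution(*pair) for pair in ALL_PAIRS}
    transitions = {pair for pair, lab in labels.items() if lab == "transition"}
    assert transitions == {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    assert sum(1 for lab in labels.values() if lab == "transversion") == 8


@pytest.mark.parametrize("ref, alt, expected", [
    ("A", "G", "transition"), ("C", "A", "transversion"), ("AT", "A", "not_snv"),
    ("A", "AT", "not_snv"), ("N", "A", "not_snv"),
])
def test_classify_substitution_examples(ref, alt, expected):
    assert ma.classify_substitution(ref, alt) == expected


def test_classify_substitution_rejects_empty():
    with pytest.raises(ValueError):
        ma.classify_substitution("", "A")


def test_composition_proportions_and_conservation(default_cohort):
    muts = make_mutations(
        [{"sample": f"S{i}", "variant_class": "missense"} for i in range(8)]
        + [{"sample": f"S{i+8}", "variant_class": "silent"} for i in range(2)])
    ann = make_annotation([{"gene_symbol": "G1"}])
    spectrum = ma.composition(muts, ann)
    props = spectrum.class_counts.set_index("variant_class")["proportion"]
    assert props["missense"] == pytest.approx(0.8)
    assert props["silent"] == pytest.approx(0.2)
    # conservation on a full synthetic cohort: Ti + Tv = #SNV in every stratum
    titv = ma.composition(default_cohort.mutations, default_cohort.annotation).titv
    snv = ma.classify_substitutions(default_cohort.mutations) != "not_snv"
    assert titv["n_snv"].sum() == int(snv.sum())
    assert (titv["n_transitions"] + titv["n_transversions"]).equals(titv["n_snv"])


def test_composition_recovers_configured_weights(default_cohort):
    """Class proportions and the transition share match the generator's
    configuration within 3 multinomial SEs."""
    muts = default_cohort.mutations
    cfg = CohortConfig()
    n = len(muts)
    counts = muts["variant_class"].value_counts()
    for cls in ("missense", "silent"):
        w = cfg.variant_class_weights[cls]
        se = np.sqrt(w * (1 - w) / n)
        assert abs(counts[cls] / n - w) <= 3 * se
    sub = ma.classify_substitutions(muts)
    n_snv = int((sub != "not_snv").sum())
    ti = int((sub == "transition").sum())
    se = np.sqrt(0.7 * 0.3 / n_snv)
    assert abs(ti / n_snv - cfg.transition_prob) <= 3 * se
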