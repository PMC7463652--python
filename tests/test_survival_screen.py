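"""KM/log-rank against hand computation, Cox recovery, concordance filtering."""

import numpy as np
import pandas as pd
import pytest

from matrisome_scan import CohortConfig, EmptyGroupError, generate_cohort
from matrisome_scan import survival_screen as ss

from conftest import EQUAL_LENGTHS, make_annotation, make_clinical, make_mutations


# ---------------------------------------------------------------------------
# carrier status
# ---------------------------------------------------------------------------

def test_carrier_status_rules():
    muts = make_mutations(
        [{"sample": "S1", "pos": p} for p in (10, 20, 30)]
        + [{"sample": "S2", "variant_class": "silent"}])
    clinical = make_clinical([{"sample": s} for s in ("S1", "S2", "S3")])
    any_rule = ss.carrier_status("G1", muts, clinical)
    assert any_rule.tolist() == [True, True, False]
    nonsilent = ss.carrier_status("G1", muts, clinical, rule="nonsilent_only")
    assert nonsilent.tolist() == [True, False, False]


def test_carrier_status_matches_membership_scan():
    rng = np.random.default_rng(31)
    rows = [{"sample": f"S{rng.integers(25)}", "gene_symbol": f"G{rng.integers(5)}",
             "pos": int(p)} for p in rng.integers(1, 1000, 120)]
    muts = make_mutations(rows)
    clinical = make_clinical([{"sample": f"S{i}"} for i in range(25)])
    for gene in [f"G{i}" for i in range(5)]:
        flags = ss.carrier_status(gene, muts, clinical)
        expected = {r["sample"] for r in rows if r["gene_symbol"] == gene}
        for sample, flag in flags.items():
            assert flag == (sample in expected)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def hand_logrank(times, events, group):
    """Two-group log-rank statistic from first principles (O - E with the
    hypergeometric variance), independent of lifelines."""
    observed = expected = variance = 0.0
    for t in sorted({t for t, e in zip(times, events) if e}):
        at_risk = [(ti, ei, gi) for ti, ei, gi in zip(times, events, group) if ti >= t]
        n = len(at_risk)
        n1 = sum(1 for _, _, gi in at_risk if gi)
        d = sum(1 for ti, ei, _ in at_risk if ti == t and ei)
        d1 = sum(1 for ti, ei, gi in at_risk if ti == t and ei and gi)
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (observed - expected) ** 2 / variance


def test_logrank_matches_hand_computation():
    """Six-patient fixture: the statistic equals the explicit O-E calculation."""
    clinical = make_clinical([
        {"sample": "S1", "os_months": 2.0, "os_event": True},
        {"sample": "S2", "os_months": 4.0, "os_event": True},
        {"sample": "S3", "os_months": 5.0, "os_event": False},
        {"sample": "S4", "os_months": 6.0, "os_event": True},
        {"sample": "S5", "os_months": 8.0, "os_event": True},
        {"sample": "S6", "os_months": 9.0, "os_event": False},
    ])
    carriers = pd.Series([True, True, True, False, False, False],
                         index=pd.Index(clinical["sample"], name="sample"))
    curves, stat, p = ss.km_logrank(carriers, clinical)
    expected_stat = hand_logrank(clinical["os_months"], clinical["os_event"],
                                 [True, True, True, False, False, False])
    assert stat == pytest.approx(expected_stat)
    from scipy import stats as sps
    assert p == pytest.approx(sps.chi2.sf(expected_stat, df=1))


def test_km_curves_are_proper_step_functions():
    clinical = make_clinical([
        {"sample": f"S{i}", "os_months": t, "os_event": e}
        for i, (t, e) in enumerate([(1, True), (2, False), (3, True), (4, True),
                                    (5, False), (6, True)])])
    carriers = pd.Series([True, True, True, False, False, False],
                         index=pd.Index(clinical["sample"], name="sample"))
    curves, _, _ = ss.km_logrank(carriers, clinical)
    for _, grp in curves.groupby("group"):
        surv = grp.sort_values("time")["survival"].to_numpy()
        assert surv[0] == pytest.approx(1.0)   # S(t)=1 before the first event
        assert (np.diff(surv) <= 1e-12).all()  # nonincreasing


def test_extreme_separation():
    """All carriers die at t=1, all non-carriers censored at t=10."""
    clinical = make_clinical(
        [{"sample": f"C{i}", "os_months": 1.0, "os_event": True} for i in range(10)]
        + [{"sample": f"N{i}", "os_months": 10.0, "os_event": False}
           for i in range(10)])
    carriers = pd.Series([True] * 10 + [False] * 10,
                         index=pd.Index(clinical["sample"], name="sample"))
    curves, _, p = ss.km_logrank(carriers, clinical)
    assert p < 1e-4
    carrier_curve = curves[curves["group"] == "carrier"].sort_values("time")
    assert carrier_curve["survival"].iloc[-1] == pytest.approx(0.0)


def test_km_requires_some_events_and_nonempty_groups():
    clinical = make_clinical([
        {"sample": "S1", "os_event": False}, {"sample": "S2", "os_event": False}])
    carriers = pd.Series([True, False], index=pd.Index(clinical["sample"],
                                                       name="sample"))
    with pytest.raises(EmptyGroupError, match="no events"):
        ss.km_logrank(carriers, clinical)
    clinical2 = make_clinical([
        {"sample": "S1", "os_event": True}, {"sample": "S2", "os_event": True}])
    all_carriers = pd.Series([True, True], index=pd.Index(clinical2["sample"],
                                                          name="sample"))
    with pytest.raises(EmptyGroupError, match="empty"):
        ss.km_logrank(all_carriers, clinical2)


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def _hazard_cohort(beta):
    return generate_cohort(CohortConfig(
        n_genes=50, frac_matrisome=0.2, n_tumor_types=1, samples_per_tumor=500,
        mutation_rate_per_bp=2e-5, matrisome_mut_multiplier=3.0,
        planted_survival_genes=(("MXG0001", beta),), seed=7))


def test_cox_recovers_planted_hazard():
    cohort = _hazard_cohort(1.0)
    flags = ss.carrier_status("MXG0001", cohort.mutations, cohort.clinical)
    assert flags.sum() >= 50
    beta, p, table = ss.cox_multivariate(flags, cohort.clinical)
    assert 0.7 <= beta <= 1.3
    assert p < 0.01
    # no covariate effect was planted: well-supported covariates stay near
    # zero, sparse categorical levels at least keep 0 inside their CI
    table = table.set_index("covariate")
    gender_col = next(c for c in table.index if c.startswith("gender_"))
    assert abs(table.loc["age", "coef"]) < 0.3
    assert abs(table.loc[gender_col, "coef"]) < 0.3
    others = table.drop(index=["carrier", "age", gender_col])
    assert ((others["coef lower 95%"] <= 0) & (others["coef upper 95%"] >= 0)).all()


def test_cox_mean_bias_small_over_planted_effects():
    """Over repeated cohorts with planted log-HR in +/-{0.5, 1, 1.5}, the mean
    estimation bias stays below 0.1."""
    betas = [0.5, -0.5, 1.0, -1.0, 1.5, -1.5]
    errors = []
    for i in range(30):
        beta = betas[i % len(betas)]
        cohort = generate_cohort(CohortConfig(
            n_genes=50, frac_matrisome=0.2, n_tumor_types=1, samples_per_tumor=500,
            mutation_rate_per_bp=2e-5, matrisome_mut_multiplier=3.0,
            planted_survival_genes=(("MXG0001", beta),), seed=100 + i))
        flags = ss.carrier_status("MXG0001", cohort.mutations, cohort.clinical)
        est, _, _ = ss.cox_multivariate(flags, cohort.clinical)
        errors.append(est - beta)
    assert abs(np.mean(errors)) < 0.1


def test_cox_requires_events():
    clinical = make_clinical([{"sample": f"S{i}", "os_event": False}
                              for i in range(10)])
    flags = pd.Series([True] * 5 + [False] * 5,
                      index=pd.Index(clinical["sample"], name="sample"))
    with pytest.raises(EmptyGroupError, match="no events"):
        ss.cox_multivariate(flags, clinical)


def test_cox_drops_patients_missing_covariates():
    rng = np.random.default_rng(5)
    clinical = make_clinical([
        {"sample": f"S{i}", "os_months": float(rng.exponential(20)),
         "os_event": bool(rng.random() < 0.7),
         "age": None if i < 3 else 50 + i % 20} for i in range(60)])
    flags = pd.Series(rng.random(60) < 0.4,
                      index=pd.Index(clinical["sample"], name="sample"))
    beta, p, table = ss.cox_multivariate(flags, clinical)
    assert np.isfinite(beta) and 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def test_screen_reports_protective_gene_with_positive_os_difference():
    cohort = _hazard_cohort(-1.0)
    result = ss.screen(cohort.mutations, cohort.clinical, cohort.annotation,
                       ss.SurvivalConfig(), return_all=True)
    rec = result[result["gene_symbol"] == "MXG0001"]
    assert len(rec) == 1
    assert rec["os_difference"].iloc[0] > 0
    assert rec["concordant"].iloc[0]
    # and the harmful planting flips the sign
    harmful = _hazard_cohort(1.0)
    res2 = ss.screen(harmful.mutations, harmful.clinical, harmful.annotation,
                     ss.SurvivalConfig(), return_all=True)
    rec2 = res2[res2["gene_symbol"] == "MXG0001"]
    assert rec2["os_difference"].iloc[0] < 0


def test_screen_min_carrier_filter_is_sharp():
    """A gene with 9 carriers is never tested at min_carriers=10."""
    rng = np.random.default_rng(9)
    clinical = make_clinical([
        {"sample": f"S{i}", "os_months": float(rng.exponential(20)),
         "os_event": bool(rng.random() < 0.7)} for i in range(80)])
    muts = make_mutations(
        [{"sample": f"S{i}", "gene_symbol": "NINE", "pos": 5} for i in range(9)]
        + [{"sample": f"S{i}", "gene_symbol": "TEN", "pos": 6} for i in range(10)])
    ann = make_annotation([{"gene_symbol": "NINE"}, {"gene_symbol": "TEN"}])
    result = ss.screen(muts, clinical, ann, ss.SurvivalConfig(), return_all=True)
    assert "NINE" not in set(result["gene_symbol"])
    assert "TEN" in set(result["gene_symbol"])


def test_screen_concordance_is_a_subset_property(default_cohort):
    """Reported genes are exactly those passing both tests with matching sign."""
    cfg = ss.SurvivalConfig(min_carriers=5, alpha=0.5)  # loose alpha to get records
    full = ss.screen(default_cohort.mutations, default_cohort.clinical,
                     default_cohort.annotation, cfg, return_all=True)
    reported = ss.screen(default_cohort.mutations, default_cohort.clinical,
                         default_cohort.annotation, cfg)
    assert len(full) > 0
    assert set(map(tuple, reported[["tumor_type", "gene_symbol"]].itertuples(
        index=False))) == set(map(tuple, full.loc[full["concordant"],
                                                  ["tumor_type", "gene_symbol"]]
                                  .itertuples(index=False)))
    both_pass = full[(full["p_univariate"] < cfg.alpha)
                     & (full["p_multivariate"] < cfg.alpha)]
    assert full["concordant"].sum() <= len(both_pass)


def test_domain_screen_runs_on_synthetic_cohort():
    cohort = generate_cohort(CohortConfig(
        n_genes=40, frac_matrisome=0.5, n_tumor_types=1, samples_per_tumor=150,
        mutation_rate_per_bp=5e-5, seed=17))
    result = ss.screen_domains(cohort.mutations, cohort.domains, cohort.clinical,
                               ss.SurvivalConfig(min_carriers=5), return_all=True)
    assert {"tumor_type", "domain_name", "os_difference", "concordant"} <= \
        set(result.columns)
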