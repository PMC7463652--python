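"""Screen genes whose mutation carriers show concordant survival effects.

A planted gene with log-hazard ratio +1 (carriers die faster) should be the
screen's one confident hit: significant in both the Kaplan-Meier log-rank
and the covariate-adjusted Cox model, with a negative OS difference
(os_difference = -beta, so negative means carriers fare worse).
"""

from matrisome_scan import CohortConfig, generate_cohort
from matrisome_scan import survival_screen as ss

cohort = generate_cohort(CohortConfig(
    n_genes=50, frac_matrisome=0.2, n_tumor_types=1, samples_per_tumor=500,
    mutation_rate_per_bp=2e-5, matrisome_mut_multiplier=3.0,
    planted_survival_genes=(("MXG0001", 1.0),), seed=7))

result = ss.screen(cohort.mutations, cohort.clinical, cohort.annotation,
                   ss.SurvivalConfig(), return_all=True)
print(f"genes tested (>=10 carriers): {len(result)}")
print(result[["gene_symbol", "n_carriers", "os_difference",
              "p_univariate", "p_multivariate", "concordant"]]
      .sort_values("p_multivariate").head(5).to_string(index=False))

reported = result[result["concordant"]]
print(f"\nreported (concordant in both analyses): "
      f"{reported['gene_symbol'].tolist()}")
# MXG0001 should appear with os_difference near -1 (the planted log-HR),
# while unplanted genes only rarely clear both 0.05 thresholds with matching
# direction.
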