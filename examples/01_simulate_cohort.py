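"""Generate a synthetic pan-cancer cohort and look at its planted structure.

The generator emulates a TCGA-like study: matrisome genes (here 10% of the
universe) are longer than the rest of the genome, accumulate CNAs and
mutations at an elevated rate, and a subset is expression-coupled to CNA
carrier status.
"""

from matrisome_scan import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=1))

ann = cohort.annotation
mat = ann[ann["division"] != "non-matrisome"]
print(f"genes: {len(ann)} total, {len(mat)} matrisome")
print(f"median length: matrisome {mat['length_bp'].median():.0f} bp, "
      f"rest {ann.loc[ann['division'] == 'non-matrisome', 'length_bp'].median():.0f} bp")
print(f"samples: {cohort.clinical.groupby('tumor_type').size().to_dict()}")
print(f"mutation records: {len(cohort.mutations)}")
print(f"planted expression-coupled genes: {len(cohort.truth['coupled_genes'])}")
# The length disparity is the reason every burden statistic downstream is
# normalized per bp; the coupled genes are what the expression-effect stage
# should rediscover.
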