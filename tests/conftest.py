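"""Shared fixtures and table builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from matrisome_scan import CohortConfig, generate_cohort

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

#: equal, nearly constant gene lengths: the exchangeable design for null cohorts
EQUAL_LENGTHS = {
    "core matrisome": (3000.0, 0.05),
    "matrisome-associated": (3000.0, 0.05),
    "non-matrisome": (3000.0, 0.05),
}

MUT_DEFAULTS = dict(sample="S1", gene_symbol="G1", tumor_type="BRCA", chrom="chr1",
                    pos=100, ref="A", alt="G", variant_class="missense",
                    protein_pos=10, polyphen="unknown")


def make_mutations(rows: list[dict]) -> pd.DataFrame:
    """Mutation table from sparse row dicts; unspecified fields take defaults."""
    table = pd.DataFrame([{**MUT_DEFAULTS, **row} for row in rows])
    table["protein_pos"] = table["protein_pos"].astype("Int64")
    return table


def make_annotation(rows: list[dict]) -> pd.DataFrame:
    defaults = dict(gene_symbol="G1", length_bp=3000,
                    division="non-matrisome", category="none")
    return pd.DataFrame([{**defaults, **row} for row in rows])


def make_clinical(rows: list[dict]) -> pd.DataFrame:
    defaults = dict(sample="S1", tumor_type="BRCA", os_months=12.0, os_event=True,
                    age=60, gender="female", ethnicity="white", cpe=0.7)
    return pd.DataFrame([{**defaults, **row} for row in rows])


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def null_config_factory():
    """Exchangeable null cohorts: no enrichment, equal near-constant lengths."""
    def factory(seed: int, **overrides) -> CohortConfig:
        params = dict(
            n_genes=240, frac_matrisome=0.2, n_tumor_types=2, samples_per_tumor=20,
            mutation_rate_per_bp=3e-5, matrisome_mut_multiplier=1.0,
            matrisome_cna_multiplier=1.0, length_params=EQUAL_LENGTHS, seed=seed)
        params.update(overrides)
        return CohortConfig(**params)
    return factory
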