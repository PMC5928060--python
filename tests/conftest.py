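import numpy as np
import pytest

from mutload import (
    CohortConfig,
    MutationMatrix,
    VariantRecord,
    VariantType,
    build_mutation_matrix,
    filter_nonsynonymous,
    generate_cohort,
)


def make_record(
    gene="TP53",
    classification="missense_mutation",
    vtype=VariantType.SNP,
    patient="P0001",
):
    return VariantRecord(
        gene_symbol=gene,
        variant_classification=classification,
        variant_type=vtype,
        sample_barcode=patient,
        patient_id=patient,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Compact seeded cohort reused across unit tests."""
    config = CohortConfig(
        n_patients=80,
        n_genes=40,
        n_signal_genes=3,
        n_background_genes=300,
        seed=42,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return build_mutation_matrix(filter_nonsynonymous(small_cohort.maf_records))


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def random_matrix(rng):
    """20 genes x 10 patients of small random counts."""
    counts = rng.integers(0, 5, size=(20, 10))
    return MutationMatrix(
        genes=[f"G{i:02d}" for i in range(20)],
        patients=[f"P{j:02d}" for j in range(10)],
        counts=counts,
    )
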