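import numpy as np
import pytest

from cernet import CohortSpec, simulate_cohort, random_mirnas, simulate_sequences


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at default study conditions, shared across tests."""
    matrix, truth = simulate_cohort(CohortSpec(seed=42))
    return matrix, truth


@pytest.fixture(scope="session")
def default_sequences(default_cohort):
    matrix, truth = default_cohort
    mirnas = random_mirnas(matrix.features_of_class("miRNA"), seed=421)
    lnc_seqs, utr_seqs = simulate_sequences(
        truth, mirnas, seed=422,
        lnc_ids=matrix.features_of_class("lncRNA"),
        mrna_ids=matrix.features_of_class("mRNA"))
    return mirnas, lnc_seqs, utr_seqs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rna(rng, length):
    return "".join(rng.choice(np.array(list("ACGU")), size=length))
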