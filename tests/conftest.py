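"""Shared fixtures: the reference model bank and a corpus-derived prior.

The expensive objects (large synthetic corpus, fitted models, overlap prior)
are built once per session and shared; every test that needs ground truth
uses the reference models as the generating world.
"""

import pytest

from bamorc import build_reference_models, compute_overlap_matrix, fit_model_set
from bamorc.simulate import generate_corpus

CORPUS_SEED = 11
CORPUS_N_PER_CLASS = 2000


@pytest.fixture(scope="session")
def reference_models():
    return build_reference_models()


@pytest.fixture(scope="session")
def corpus(reference_models):
    """Large matched corpus (records, entry qualities) drawn from the models."""
    return generate_corpus(
        reference_models, n_per_class=CORPUS_N_PER_CLASS, seed=CORPUS_SEED
    )


@pytest.fixture(scope="session")
def overlap_prior(reference_models, corpus):
    records, _ = corpus
    return compute_overlap_matrix(records, reference_models)


@pytest.fixture(scope="session")
def fitted_models(corpus):
    """E-revised models fitted from a half-decorrelated corpus."""
    records, qualities = generate_corpus(
        n_per_class=600, seed=23, n_entries=40, decorrelated_fraction=0.5
    )
    return fit_model_set(records, qualities, variant="E_revised")
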