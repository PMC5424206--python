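"""Shared fixtures: the shipped-seed synthetic datasets, generated once."""

import numpy as np
import pytest

from sepmine.synthetic_data import protein_preset
from sepmine.synthetic_data.metagenome import (
    default_models,
    generate_metagenome,
    default_presets,
)

SHIPPED_SEED = 1


@pytest.fixture(scope="session")
def default_metagenome():
    rng = np.random.default_rng(SHIPPED_SEED)
    models = default_models(rng)
    return generate_metagenome(default_presets(), models, rng)


@pytest.fixture(scope="session")
def pipeline_result(default_metagenome):
    from sepmine.pipeline import run_pipeline

    mg = default_metagenome
    return run_pipeline(
        mg.contigs, mg.depth, mg.annotations, mg.proteins, mg.trnas,
        mg.references,
    )


@pytest.fixture(scope="session")
def seprs_preset():
    return protein_preset("seprs_default", np.random.default_rng(SHIPPED_SEED))


@pytest.fixture(scope="session")
def sepcyss_preset():
    return protein_preset("sepcyss_default", np.random.default_rng(SHIPPED_SEED))


@pytest.fixture(scope="session")
def pylrs_preset():
    return protein_preset("pylrs_default", np.random.default_rng(SHIPPED_SEED))
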