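import logging

import numpy as np
import pandas as pd
import pytest

from phenoselect.synthetic import GeneratorConfig, generate_study

# MCMC-length warnings are expected at test scale
logging.getLogger("phenoselect").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_study():
    return generate_study(GeneratorConfig(n_seasons=5, n_breeding_females=8, n_breeding_males=6), seed=12345)


@pytest.fixture(scope="session")
def study():
    """Full-scale synthetic study (~330 females, ~1,400 records, 16 seasons)."""
    return generate_study(seed=2)


@pytest.fixture(scope="session")
def prepared(study):
    from phenoselect.records import prepare_dataset

    return prepare_dataset(study.records, study.temperatures)


@pytest.fixture(scope="session")
def prepared_tiny(tiny_study):
    from phenoselect.records import prepare_dataset

    return prepare_dataset(tiny_study.records, tiny_study.temperatures)


def small_pedigree():
    """Founder pair, two full sibs, and an offspring of the sib mating."""
    from phenoselect.pedigree import Pedigree

    return Pedigree.from_triples(
        [("d", None, None), ("s", None, None), ("a", "d", "s"), ("b", "d", "s"), ("c", "a", "b")]
    )
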