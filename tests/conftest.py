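"""Shared fixtures: a calibrated synthetic panel, reference cohort and index.

The full-size panel (62 targets, 10 species over four series) is built once
per session; most unit tests use smaller purpose-built panels instead.
"""

from __future__ import annotations

import numpy as np
import pytest

from amplityper import (
    SpeciesAssigner,
    build_index,
    simulate_cohort,
    simulate_panel,
)

PANEL_SEED = 101
REF_SEED = 202
QUERY_SEED = 303


@pytest.fixture(scope="session")
def panel():
    return simulate_panel(seed=PANEL_SEED)


@pytest.fixture(scope="session")
def taxonomy(panel):
    return panel.taxonomy()


@pytest.fixture(scope="session")
def ref_cohort(panel):
    return simulate_cohort(panel, n_per_species=5, seed=REF_SEED)


@pytest.fixture(scope="session")
def index_and_report(panel, taxonomy, ref_cohort):
    return build_index(
        ref_cohort,
        taxonomy,
        version="NNsim1",
        geo_structure_species={"An_geminus"},
    )


@pytest.fixture(scope="session")
def index(index_and_report):
    return index_and_report[0]


@pytest.fixture(scope="session")
def query_cohort(panel):
    return simulate_cohort(panel, n_per_species=3, seed=QUERY_SEED, id_prefix="q")


@pytest.fixture(scope="session")
def assigner(index):
    return SpeciesAssigner().fit(index)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
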