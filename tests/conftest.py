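"""Shared fixtures: one toy lineage and one planted scenario per session.

Everything is generated programmatically at test time; no data files ship
with the repository.
"""

from __future__ import annotations

import pytest

from orthoassess.fixtures import make_toy_lineage, render_paf_fixture, standard_scenario
from orthoassess.lineage import load_lineage
from orthoassess.orthology import PyhmmerBackend

SEED = 11


@pytest.fixture(scope="session")
def toy_lineage_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("lineage") / "toy_odb"
    return make_toy_lineage(out, n_groups=10, proteins_per_group=3, seed=SEED)


@pytest.fixture(scope="session")
def toy_lineage(toy_lineage_dir):
    return load_lineage(toy_lineage_dir)


@pytest.fixture(scope="session")
def scenario(toy_lineage):
    """10 planted genes: 4 single (introns/frameshifts/substitutions mixed in),
    2 duplicated, 2 fragmented, 2 missing."""
    return standard_scenario(toy_lineage, n_single=4, n_duplicated=2, n_fragmented=2, n_missing=2, seed=SEED)


@pytest.fixture(scope="session")
def scenario_paf(scenario):
    return render_paf_fixture(scenario)


@pytest.fixture(scope="session")
def hmm_backend():
    return PyhmmerBackend()
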