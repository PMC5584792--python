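import warnings

import pytest

import riboregulon as rb
from riboregulon.synthetic_data import packaged_seed_alignment

# branch-length clamping chatter from bootstrap replicates is expected noise
warnings.filterwarnings("ignore", message="negative branch length")


@pytest.fixture(scope="session")
def seed_alignment():
    rows, structure = packaged_seed_alignment()
    return rows, structure


@pytest.fixture(scope="session")
def aptamer_model(seed_alignment):
    rows, _ = seed_alignment
    return rb.build_phmm(rows)


@pytest.fixture(scope="session")
def consensus_structure(seed_alignment, aptamer_model):
    _, structure = seed_alignment
    return structure.project(aptamer_model.match_columns)


@pytest.fixture(scope="session")
def catalog():
    return rb.FunctionCatalog.default()


@pytest.fixture(scope="session")
def species_tree_12():
    tree, taxonomy = rb.make_species_tree(12, seed=3)
    return tree, taxonomy
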