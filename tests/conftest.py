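import numpy as np
import pytest

from phylotestis import SpeciesTree


@pytest.fixture(scope="session")
def species_tree() -> SpeciesTree:
    return SpeciesTree.default()


@pytest.fixture()
def fresh_tree() -> SpeciesTree:
    """A mutable copy of the default tree (branch lengths may be set)."""
    return SpeciesTree.default()


from phylotestis.scenarios import (  # noqa: F401  (re-exported for tests)
    omega_shift_locus_params as arhgap28_like_params,
    study_branch_lengths,
)
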