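import pytest

from tddkit.synthetic import NodeShape, PhantomSpec, table2_fixture


@pytest.fixture(scope="session")
def cohort():
    """The packaged 28-patient table of relative TDD scores."""
    return table2_fixture()


@pytest.fixture(scope="session")
def small_phantom():
    """Compact phantom parcellation used by the simulation-heavy tests:
    a 512-voxel deficit component plus two eligible 125-voxel nodes and a
    64-voxel fragment below the eligibility cutoff."""
    return PhantomSpec(shape=(24, 24, 24), nodes=(
        NodeShape(label=1, corner=(2, 2, 2), size=(8, 8, 8)),
        NodeShape(label=1, corner=(15, 15, 15), size=(5, 5, 5)),
        NodeShape(label=2, corner=(2, 15, 2), size=(5, 5, 5)),
        NodeShape(label=2, corner=(15, 2, 15), size=(4, 4, 4)),
    ))
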