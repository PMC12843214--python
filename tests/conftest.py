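import pytest

from alveomech import PhenotypeParams, build_outline, generate_mesh
from alveomech.scenarios import run_comparison


@pytest.fixture(scope="session")
def default_params():
    return PhenotypeParams()


@pytest.fixture(scope="session")
def default_outline(default_params):
    return build_outline(default_params)


@pytest.fixture(scope="session")
def coarse_mesh(default_outline):
    """Coarse mesh for solver plumbing tests (fast, not for field accuracy)."""
    return generate_mesh(default_outline, h_pdl=0.2, h_far=1.0)


@pytest.fixture(scope="session")
def comparison_results():
    """The six production runs (3 protocols x 2 cortical moduli) at the
    default mesh; shared by the scenario-level assertions."""
    return run_comparison()


@pytest.fixture(scope="session")
def comparison_by_key(comparison_results):
    return {(r.spec.name, r.cortical_E): r for r in comparison_results}
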