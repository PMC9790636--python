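import pytest

from phkin.keq import load_packaged_tables
from phkin.schemes import load_all_schemes


@pytest.fixture(scope="session")
def keq_tables():
    return load_packaged_tables()


@pytest.fixture(scope="session")
def schemes(keq_tables):
    """All packaged assay schemes with Keq references resolved at their pH."""
    return {e: s.resolve_keq(keq_tables) for e, s in load_all_schemes().items()}


@pytest.fixture(scope="session")
def eno_study():
    """Small noisy single-enzyme study shared by estimator tests."""
    from phkin.synth import StudyDesign, generate_study

    design = StudyDesign(dilution_factors=(1, 2), replicates=3, sigma_au=0.002)
    return generate_study(seed=11, enzymes=["ENO"], design=design)
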