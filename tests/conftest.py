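import pytest

from edemascore import default_rubric
from edemascore import fixtures as fx


@pytest.fixture(scope="session")
def rubric():
    return default_rubric()


@pytest.fixture(scope="session")
def paper_study():
    """The reconstructed seven-reader study: (standard, score-based, reference)."""
    return fx.standard_calls(), fx.score_based_calls(), fx.reference_standard()


@pytest.fixture(scope="session")
def point_table():
    """Independent literal copy of the published point table, for oracle sums."""
    return {
        "hilar_enlarged": (0, 1, 2, 3),
        "hilar_density": (0, 2, 4, 6),
        "hilar_blurred": (0, 3, 6, 9),
        "kerley_b": (0, 4, 8),
        "micronoduli": (0, 4, 8),
        "fissure_widening": (0, 4, 8, 12),
        "cuffs": (0, 4, 8, 12),
        "perihilar_haze": (0, 5, 10, 15),
        "diffuse_density": (0, 5, 10, 15),
    }
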