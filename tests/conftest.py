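import numpy as np
import pytest

from epirange.io_formats import ChecklistEntry
from epirange.synthetic_data import make_toy_atlas


@pytest.fixture(scope="session")
def toy_atlas():
    """(RegionAtlas, ref_points) with 8 rectangular equatorial regions."""
    return make_toy_atlas()


@pytest.fixture()
def small_checklist():
    return [
        ChecklistEntry("Aster alpinus", "terrestrial", "Asteraceae",
                       frozenset({"R01"})),
        ChecklistEntry("Vanda caerulea", "epiphyte", "Orchidaceae",
                       frozenset({"R02", "R03"})),
    ]


def lifeform_design(scenario):
    """Intercept + epiphyte-indicator design matrix for a scenario."""
    x = np.array(
        [1.0 if scenario.lifeform[t] == "epiphyte" else 0.0 for t in scenario.taxa]
    )
    return np.column_stack([np.ones_like(x), x])


@pytest.fixture(scope="session")
def design_for():
    return lifeform_design
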