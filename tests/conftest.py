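"""Shared fixtures.

Heavy artifacts (the worst-case implant's neck-width database and the
cylindrical reference detector) are session-scoped so the accuracy tests
share one build.
"""

import numpy as np
import pytest

from hiprom.fixtures import (
    cylindrical_assembly,
    trapezoidal_assembly,
    worst_case_assembly,
)
from hiprom.neckwidth import NeckWidthDatabase
from hiprom.rom import ROMTarget


@pytest.fixture(scope="session")
def target30():
    """The reference combined target: 30 IR @ 90 FL and 10 ER @ 10 EX."""
    return ROMTarget(30.0, 90.0, 10.0, 10.0)


@pytest.fixture(scope="session")
def cylindrical():
    """Constant 12 mm circular neck, 32 mm head, hemispherical liner."""
    return cylindrical_assembly()


@pytest.fixture(scope="session")
def cylindrical_n10():
    """10 mm neck on a 32 mm head: the closed-form reference geometry."""
    return cylindrical_assembly(neck_width_mm=10.0)


@pytest.fixture(scope="session")
def trapezoidal():
    return trapezoidal_assembly()


@pytest.fixture(scope="session")
def worst_case():
    return worst_case_assembly()


@pytest.fixture(scope="session")
def worst_case_db(worst_case):
    """Neck-width database for the validation experiment: stem anteversion
    slices -40..60 step 20, cup grid 0-60 x 0-60 step 10."""
    return NeckWidthDatabase.build(worst_case)


@pytest.fixture(scope="session")
def cylindrical_db(cylindrical):
    """Single-slice database for the cylindrical reference at b = 15."""
    grid = np.arange(0.0, 61.0, 10.0)
    return NeckWidthDatabase.build(
        cylindrical, slices=(15.0,), alphas=grid, betas=grid
    )
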