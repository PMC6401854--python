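import numpy as np
import pytest

from paacs.ionization import ACID, BASE, IonizableGroup, PolymerSpec


@pytest.fixture
def amphoteric_spec() -> PolymerSpec:
    """A generic amphoteric polymer with mild cooperativity on both groups."""
    return PolymerSpec(
        name="test-polymer",
        repeat_unit_mass=243.26,
        acid_group=IonizableGroup(ACID, pka=2.3, beta=1.1),
        base_group=IonizableGroup(BASE, pka=7.5, beta=1.3),
    )


@pytest.fixture
def ideal_spec() -> PolymerSpec:
    """Ideal (beta = 1) amphoteric polymer for closed-form checks."""
    return PolymerSpec(
        name="ideal-polymer",
        repeat_unit_mass=243.26,
        acid_group=IonizableGroup(ACID, pka=2.3, beta=1.0),
        base_group=IonizableGroup(BASE, pka=7.5, beta=1.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
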