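import pytest

from puresol import ActivityContext, CompoundSpec


@pytest.fixture
def ctx37():
    return ActivityContext(temperature=37.0, ionic_strength=0.15)


@pytest.fixture
def acetaminophen_worked():
    """Acetaminophen with the worked-example constants (pS0_ref known)."""
    return CompoundSpec(name="Acetaminophen", compound_class="acid",
                        pKa_ref=(9.41,), max_cation_charge=0, T=37.0,
                        pS0_ref=0.87, k_salt=0.117, MW=151.16)
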