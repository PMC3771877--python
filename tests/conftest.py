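import pytest

from cisweep import PopState, SingleStrainParams, TwoStrainParams


@pytest.fixture
def strain_a_params() -> SingleStrainParams:
    """Point estimates for the non-CI strain (F from the equilibrium
    inversion at p-hat = 0.6, mu = 0.023)."""
    return SingleStrainParams(F=1.061, mu=0.023)


@pytest.fixture
def strain_r_params() -> SingleStrainParams:
    """CI-strain parameters at the low-fecundity end (bistable regime)."""
    return SingleStrainParams(F=0.95, mu=0.045, H=0.55)


@pytest.fixture
def two_strain_params() -> TwoStrainParams:
    """Displacement-scenario parameters."""
    return TwoStrainParams(F_A=1.061, mu_A=0.023, F_R=1.08, mu_R=0.045, H=0.55)


@pytest.fixture
def displacement_start() -> PopState:
    return PopState(p_A=0.54, p_R=0.09, p_O=0.37)
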