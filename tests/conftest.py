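import pytest

import tundraphys as tp


@pytest.fixture(scope="session")
def kinetics():
    return tp.KineticParams()


@pytest.fixture(scope="session")
def noiseless_truth():
    """Generator configuration with every noise source switched off."""
    return tp.default_truth(seed=11, sigma_A=0.0, sigma_rd=0.0,
                            tussock_cv=0.0, ratio_sd=0.0)


@pytest.fixture(scope="session")
def noisy_truth():
    return tp.default_truth(seed=11)


@pytest.fixture(scope="session")
def clean_curve(noiseless_truth):
    """One noiseless 25 degC curve (CF ambient at the TL garden)."""
    return tp.generate_aci_curve(noiseless_truth, "TL", "CF", "ambient",
                                 1, 25.0)


@pytest.fixture(scope="session")
def tl_dataset(noisy_truth):
    """The TL garden's full synthetic dataset (90 curves + traits)."""
    return tp.generate_garden_dataset(noisy_truth, "TL")
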