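import pytest

from glycoprofiler.simulate import FIXTURES, NoiseModel, generate_glyco_run


@pytest.fixture(scope="session")
def ftst78_zero_noise_run():
    """Synthetic line-78 run at zero noise (shared; generators are pure)."""
    return generate_glyco_run(FIXTURES["ftst78"], noise=NoiseModel.zero(), seed=7)


@pytest.fixture(scope="session")
def ftst78_noisy_run():
    """Same fixture at the default noise model, with decoy MS2 spectra."""
    return generate_glyco_run(
        FIXTURES["ftst78"], noise=NoiseModel(decoy_spectra=100), seed=7
    )
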