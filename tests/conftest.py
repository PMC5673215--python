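import pytest
from hypothesis import settings

from chitoseq import MONOISOTOPIC

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")
from chitoseq.chos import ChosPattern, Label
from chitoseq.simulate import SpectrumNoise, synth_spectrum


@pytest.fixture
def table():
    return MONOISOTOPIC


@pytest.fixture
def noiseless_spectrum():
    """Factory: full noiseless Y+B ladder spectrum of one labeled pattern."""

    def make(residues: str):
        return synth_spectrum(
            {str(ChosPattern(residues, Label.AMAC)): 1.0},
            noise=SpectrumNoise(),
        )

    return make
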