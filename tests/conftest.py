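import numpy as np
import pytest

from soilmend import FixedParams, MicrobialParams, SoilInit


@pytest.fixture(scope="session")
def fp():
    return FixedParams()


@pytest.fixture(scope="session")
def mp():
    return MicrobialParams()


@pytest.fixture(scope="session")
def soil():
    """A mid-range loam-like soil case."""
    return SoilInit(site="TN", ecosystem="forest", poc=8.0, moc=18.0,
                    doc=0.12, mbc=0.45)


@pytest.fixture(scope="session")
def cellulose_soil(soil):
    from dataclasses import replace
    return replace(soil, substrate="cellulose")
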