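import pytest

from epibarrier import ChamberConfig, TissueGeometry


@pytest.fixture
def chamber() -> ChamberConfig:
    """Conventional chamber run: 10 mL half-chambers, 0.95 cm², 100 μmol/L
    apical dose, 0.5 mL samples at 0/30/60 min."""
    return ChamberConfig()


@pytest.fixture
def geometry() -> TissueGeometry:
    """Porcine Peyer's-patch morphometry defaults."""
    return TissueGeometry()
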