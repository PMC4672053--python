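import numpy as np
import pytest

from photolim.fvcb import FvCBParams
from photolim.types import ACiCurve, FluorescenceRecord, GasExchangeRecord


@pytest.fixture
def params():
    """Kinetic constants used throughout: chloroplastic basis, 25 °C."""
    return FvCBParams(V_cmax=33.71, J_max=144.59, R_d=1.0)


@pytest.fixture
def make_curve():
    """Factory for bare curves from columnar arrays (no fluorescence)."""

    def _make(c_a, c_i, a_n, g_sw=0.4, ppfd=1000.0, leaf_id="leafA",
              treatment="control", day=0, fluor=None):
        points = []
        for k in range(len(c_a)):
            gas = GasExchangeRecord(
                A_N=float(a_n[k]), C_a=float(c_a[k]), C_i=float(c_i[k]),
                g_sw=g_sw, PPFD=ppfd,
            )
            fl = None
            if fluor is not None:
                fl = FluorescenceRecord(**{k2: v[k] for k2, v in fluor.items()})
            points.append((gas, fl))
        return ACiCurve(leaf_id=leaf_id, treatment=treatment, day=day, points=points)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)
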