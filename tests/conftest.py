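import numpy as np
import pandas as pd
import pytest

from orbidelta.chem import make_target
from orbidelta.scandata import RunTable


@pytest.fixture(scope="session")
def mh_target():
    """Protonated methyl stearate monitoring M0 and 13C1."""
    return make_target("C19H38O2", "proton", 1, labels=("M0", "13C1"))


@pytest.fixture(scope="session")
def mna_target():
    """Sodiated methyl stearate monitoring the four key isotopologues."""
    return make_target("C19H38O2", "sodium", 1, labels=("M0", "13C1", "13C2", "18O1"))


def build_run(
    s_m0,
    s_13c1,
    n_m0=None,
    n_13c1=None,
    times=None,
    tic=None,
    resolution=60000.0,
    microscans=2,
) -> RunTable:
    """Assemble a RunTable from per-scan arrays (noise defaults to 1)."""
    s_m0 = np.asarray(s_m0, float)
    s_13c1 = np.asarray(s_13c1, float)
    n = len(s_m0)
    frame = pd.DataFrame(
        {
            "scan": np.arange(n),
            "time_min": np.arange(n) / 60.0 if times is None else np.asarray(times, float),
            "tic": s_m0 + s_13c1 if tic is None else np.asarray(tic, float),
            "S_M0": s_m0,
            "N_M0": np.ones(n) if n_m0 is None else np.asarray(n_m0, float),
            "S_13C1": s_13c1,
            "N_13C1": np.ones(n) if n_13c1 is None else np.asarray(n_13c1, float),
        }
    )
    return RunTable(frame, {"resolution": resolution, "microscans": microscans})
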