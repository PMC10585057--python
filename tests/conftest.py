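import numpy as np
import pandas as pd
import pytest

from pedrecon import StudyArea, VitalRateTable, simulate_study


@pytest.fixture(scope="session")
def rates():
    return VitalRateTable.default()


@pytest.fixture(scope="session")
def study():
    """Default desk-scale study: 659 founders, 20-year burn-in, 5 sampling years."""
    return simulate_study(seed=101)


@pytest.fixture(scope="session")
def ministudy():
    """Small, fast trajectory for integration tests."""
    return simulate_study(n0=250, burn_in=8, years=3, seed=7,
                          area=StudyArea.rectangle(30.0, 22.0))


@pytest.fixture()
def toy_pedigree_frames():
    """Six adults and two calves mirroring the worked pedigree example.

    Sampled: both parents of calf K1, a childless adult S1, calf K1,
    calf K2 and K2's dam P2 (shared with K1).  K2's sire U1 is unsampled
    (inferred); X1 and X2 are unsampled and unmatched (invisible).
    Expected segments: (linked, unlinked, inferred) = (2, 1, 1).
    """
    ped = pd.DataFrame({
        "id": ["P1", "P2", "S1", "U1", "X1", "X2", "K1", "K2"],
        "sire": ["0", "0", "0", "0", "0", "0", "P1", "U1"],
        "dam": ["0", "0", "0", "0", "0", "0", "P2", "P2"],
    })
    attrs = pd.DataFrame({
        "id": ["P1", "P2", "S1", "U1", "X1", "X2", "K1", "K2"],
        "sex": ["M", "F", "F", "M", "M", "F", "F", "M"],
        "birth_year": [2010, 2010, 2011, 2010, 2012, 2012, 2020, 2020],
        "sampled": [True, True, True, False, False, False, True, True],
        "sample_year": [2020, 2020, 2020, np.nan, np.nan, np.nan, 2020, 2020],
        "known_dead": [False] * 8,
    })
    return ped, attrs
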