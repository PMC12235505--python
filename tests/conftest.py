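import pandas as pd
import pytest

from oligoscreen import enumerate_database, component_catalogue


@pytest.fixture(scope="session")
def db() -> pd.DataFrame:
    """Default predicted oligoester database (enumerated once per session)."""
    return enumerate_database()


@pytest.fixture(scope="session")
def catalogue() -> pd.DataFrame:
    return component_catalogue()


@pytest.fixture()
def reference_nmr_table() -> pd.DataFrame:
    """Signal table reproducing the film's blend composition.

    Integrals are generated noiselessly from the reported molar composition
    (PBA 35, PBT 40, PLA 13, PBSe 12 mol%) with the assigned proton counts
    and average repeat-unit weights.
    """
    from oligoscreen import simulate_nmr_integrals

    return simulate_nmr_integrals(
        {"PBA": 35.0, "PBT": 40.0, "PLA": 13.0, "PBSe": 12.0},
        {"PBA": 4, "PBT": 4, "PLA": 1, "PBSe": 4},
        mws={"PBA": 200.23, "PBT": 220.22, "PLA": 72.06, "PBSe": 256.34},
    )
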