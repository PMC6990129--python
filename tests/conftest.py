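import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rhizonet.tables_io import CountTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_table() -> CountTable:
    """3 OTUs x 4 samples with simple structure."""
    return CountTable(
        pd.DataFrame(
            {
                "s1": [10, 5, 0],
                "s2": [8, 6, 1],
                "s3": [0, 20, 30],
                "s4": [2, 18, 25],
            },
            index=["otuA", "otuB", "otuC"],
        )
    )


@pytest.fixture
def site_metadata() -> pd.DataFrame:
    """One site, rhizosphere + bulk, 3 replicates each."""
    rows = []
    for habitat in ("rhizosphere", "bulk"):
        for rep in (1, 2, 3):
            rows.append(
                {"sample_id": f"QS.{habitat}.{rep}", "site": "QS",
                 "habitat": habitat, "year": 2015, "replicate": rep}
            )
    return pd.DataFrame(rows).set_index("sample_id")


def make_table(counts: dict[str, list[int]], otus: list[str]) -> CountTable:
    return CountTable(pd.DataFrame(counts, index=otus))
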