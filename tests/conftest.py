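import numpy as np
import pandas as pd
import pytest

from sedtaph.profiles_io import SampleMetadata, TaxonCountTable, TaxonRecord


@pytest.fixture
def toy_table() -> TaxonCountTable:
    """4 samples x 4 taxa with two perfectly co-occurring pairs."""
    counts = pd.DataFrame(
        {
            "alder": [10, 40, 20, 30],
            "willow": [20, 80, 40, 60],      # alder x2: pmcc +1 with alder
            "zostera": [60, 10, 50, 20],
            "eelgrass_kin": [30, 5, 25, 10],  # zostera/2
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return TaxonCountTable(counts)


@pytest.fixture
def toy_metadata() -> list[SampleMetadata]:
    return [
        SampleMetadata("s1", "coreA", 10.0, "silt", True, 9000.0, 50.0, "secure", "terrestrial"),
        SampleMetadata("s2", "coreA", 20.0, "silt", True, 9500.0, 50.0, "secure", "terrestrial"),
        SampleMetadata("s3", "coreA", 30.0, "coarse_sand", False, 10000.0, 80.0, "insecure", "unknown"),
        SampleMetadata("s4", "coreB", 15.0, "clay", True, 9200.0, 60.0, "secure", "marine"),
    ]


@pytest.fixture
def taxonomy() -> dict[str, TaxonRecord]:
    return {
        "alder": TaxonRecord("alder", "genus", True),
        "willow": TaxonRecord("willow", "genus", True),
        "zostera": TaxonRecord("zostera", "genus", True),
        "eelgrass_kin": TaxonRecord("eelgrass_kin", "family", True),
        "eucalyptus": TaxonRecord("eucalyptus", "genus", False),
    }
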