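import numpy as np
import pandas as pd
import pytest

from applegap.data_io import GenotypeMatrix, MarkerDef
from applegap.simdata import default_config, make_study


@pytest.fixture(scope="session")
def small_panel():
    return [
        MarkerDef("SIZE0001", "Chr01", 1_000_000, "C", "A"),
        MarkerDef("SIZE0002", "Chr02", 2_000_000, "A", "G"),
        MarkerDef("SIZE0003", "Chr03", 3_000_000, "G", "T"),
    ]


@pytest.fixture
def tiny_matrix(small_panel):
    # 4 individuals x 3 markers: codes 0=hom-ref, 1=het, 2=hom-alt, -1=missing
    calls = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, -1],
            [0, 2, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        individual_ids=["ind001", "ind002", "ind003", "ind004"],
        markers=small_panel,
        calls=calls,
    )


@pytest.fixture
def tiny_phenotypes():
    return pd.Series(
        [165.04, 142.5, 201.3, 188.8],
        index=pd.Index(["ind001", "ind002", "ind003", "ind004"], name="individual_id"),
        name="fruit_weight",
    )


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic six-population study at a fixed seed."""
    return make_study(default_config(seed=1))
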