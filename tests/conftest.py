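import numpy as np
import pandas as pd
import pytest

from copresence.io import IntensityTable


@pytest.fixture
def small_intensity_table() -> IntensityTable:
    """4 proteins x 3 fractions x 5 replicates with a few missing cells."""
    rng = np.random.default_rng(7)
    cols = pd.MultiIndex.from_tuples(
        [(f, f"r{r}") for f in ("Opt1015", "Opt1520", "Opt2030") for r in range(1, 6)],
        names=["fraction", "replicate"],
    )
    data = pd.DataFrame(
        rng.uniform(18, 30, size=(4, 15)),
        index=[f"prot{i}" for i in range(1, 5)],
        columns=cols,
    )
    data.iloc[0, 0] = np.nan
    data.iloc[2, 7] = np.nan
    data.index.name = "protein"
    return IntensityTable(data, is_log2=True)
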