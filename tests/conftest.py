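import numpy as np
import pandas as pd
import pytest

from lipidfa.nomenclature import LIPID_CLASSES


def random_panel_matrix(rng: np.random.Generator, n_samples: int = 6):
    """A random species panel and positive concentration matrix (no missing)."""
    names = []
    codes = list(LIPID_CLASSES)
    fas = ["12:0", "14:0", "16:0", "18:0", "18:1", "18:2", "20:0", "24:1"]
    for code in rng.choice(codes, size=rng.integers(3, 8), replace=False):
        arity = LIPID_CLASSES[code].chains_per_molecule
        for _ in range(rng.integers(1, 5)):
            chains = "/".join(rng.choice(fas, size=arity))
            name = f"{code}({chains})"
            if name not in names:
                names.append(name)
    values = rng.lognormal(0.0, 1.0, size=(n_samples, len(names)))
    return pd.DataFrame(values, columns=names,
                        index=[f"S{i}" for i in range(n_samples)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_matrix():
    """4 samples x 3 species with controlled missingness."""
    return pd.DataFrame(
        {
            "DAG(16:0/16:0)": [1.0, np.nan, np.nan, np.nan],  # 75% missing
            "DAG(16:0/14:0)": [2.0, 1.5, np.nan, np.nan],  # 50% missing
            "CE(18:0)": [0.5, 0.6, 0.7, 0.8],  # complete
        },
        index=["A", "B", "C", "D"],
    )
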