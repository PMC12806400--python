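import numpy as np
import pandas as pd
import pytest

from syncomscreen import (
    AbundanceTable,
    CompoundTable,
    GeneratorConfig,
    SampleMetadata,
    generate_dataset,
)

#: a light config for unit tests: noiseless proportions, fewer taxa
FAST_CONFIG = dict(
    n_bacteria=14,
    n_fungi=7,
    n_producers=2,
    n_hubs=2,
    partners_per_hub=4,
    depth=0,
)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(GeneratorConfig(**FAST_CONFIG, seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the study-design defaults (slower, shared per session)."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture
def toy_tables():
    """Hand-built 3-taxon x 6-sample tables sharing one sample universe."""
    samples = [f"S{i}" for i in range(1, 7)]
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "group": ["CK"] * 3 + ["Lpscw"] * 3,
                "day": [0, 3, 10, 0, 3, 10],
                "replicate": [1, 1, 1, 1, 1, 1],
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    abund = AbundanceTable(
        pd.DataFrame(
            np.array(
                [
                    [2.0, 1.0, 4.0, 2.0, 3.0, 1.0],
                    [8.0, 6.0, 4.0, 5.0, 5.0, 2.0],
                    [0.0, 3.0, 2.0, 3.0, 2.0, 7.0],
                ]
            ),
            index=["Lacto", "Kazach", "Pichia"],
            columns=samples,
        ),
        pd.Series(["bacteria", "fungi", "fungi"], index=["Lacto", "Kazach", "Pichia"]),
    )
    comp = CompoundTable(
        pd.DataFrame(
            np.array(
                [
                    [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                    [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
                ]
            ),
            index=["ethyl_acetate", "glutamate"],
            columns=samples,
        ),
        pd.Series(["ester", "amino_acid"], index=["ethyl_acetate", "glutamate"]),
    )
    return abund, comp, meta
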