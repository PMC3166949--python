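import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pkaglucose import Condition, ExpressionMatrix, SampleDescriptor, Strain

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_matrix(values, genes=None, samples=None, scaled=False):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{i+1}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        scaled=scaled,
    )


@pytest.fixture
def duplicate_design():
    """3 strains x (ethanol, glucose 30 min) x duplicates = 12 arrays."""
    samples = []
    for strain in Strain:
        for cond in (Condition.ETHANOL, Condition.GLUCOSE_30MIN):
            for rep in (1, 2):
                samples.append(
                    SampleDescriptor(f"{strain.name}.{cond.name}.r{rep}", strain, cond, rep)
                )
    return samples
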