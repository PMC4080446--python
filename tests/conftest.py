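import numpy as np
import pandas as pd
import pytest

from epinet import pipeline
from epinet.types import GeneProfileMatrix


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One end-to-end demonstration run on generated data with planted
    structure; shared by the pipeline and recovery tests."""
    outdir = tmp_path_factory.mktemp("demo")
    report = pipeline.run(pipeline.demo_config(rng_seed=0, B=200), outdir)
    return report, outdir


def make_matrix(values, n_control, n_case, genes=None):
    """Small GeneProfileMatrix helper: first n_control columns are controls."""
    values = np.asarray(values, float)
    n_genes = values.shape[0]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = [f"c{i}" for i in range(n_control)] + [f"t{i}" for i in range(n_case)]
    groups = pd.Series(["control"] * n_control + ["case"] * n_case, index=samples)
    return GeneProfileMatrix(pd.DataFrame(values, index=genes, columns=samples), groups)


@pytest.fixture
def tiny_matrix():
    """2 genes x 4 samples (2 control, 2 case) with hand-checkable numbers."""
    return make_matrix([[0.1, 0.3, 0.5, 0.7], [0.4, 0.4, 0.4, 0.4]], 2, 2)
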