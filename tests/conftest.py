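import numpy as np
import pandas as pd
import pytest

from modrepo import synth
from modrepo.io import ExpressionMatrix


def make_em(values, genes, samples, tissue, status) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from plain arrays/lists."""
    vals = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=pd.Index(genes, name="gene"),
        columns=samples,
    )
    meta = pd.DataFrame(
        {"tissue": tissue, "status": status}, index=pd.Index(samples, name="sample")
    )
    return ExpressionMatrix(vals, meta)


def random_em(rng, n_genes=10, n_per_group=4, tissues=("T1",)) -> ExpressionMatrix:
    """One random matrix with case/control groups per tissue."""
    samples, tissue, status = [], [], []
    for t in tissues:
        for st in ("case", "control"):
            for i in range(n_per_group):
                samples.append(f"{t}_{st}_{i}")
                tissue.append(t)
                status.append(st)
    values = rng.normal(size=(n_genes, len(samples)))
    genes = [f"G{i:03d}" for i in range(n_genes)]
    return make_em(values, genes, samples, tissue, status)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_bundle():
    return synth.generate(synth.SynthConfig(seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    return synth.generate(synth.SynthConfig(seed=3, block_size=30, n_drugs=15))
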