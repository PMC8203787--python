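import numpy as np
import pandas as pd
import pytest

from yloss.datatypes import ExpressionMatrix
from yloss.simulate import SyntheticConfig, generate_cohort


def make_expression(values: np.ndarray, transcripts=None, samples=None,
                    chromosomes=None, symbols=None) -> ExpressionMatrix:
    """Small ExpressionMatrix with compliant default annotations."""
    n, m = values.shape
    transcripts = transcripts or [f"T{i:03d}" for i in range(n)]
    samples = samples or [f"S{j:03d}" for j in range(m)]
    ann = pd.DataFrame({
        "chromosome": chromosomes or ["1"] * n,
        "gene_symbol": symbols or [f"G{i:03d}" for i in range(n)],
        "cross_hybridisation": 1,
        "mrna_assigned": True,
        "probe_category": "main",
    }, index=pd.Index(transcripts, name="transcript_id"))
    return ExpressionMatrix(pd.DataFrame(values, index=transcripts,
                                         columns=samples), ann)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort: fast enough for unit tests, same structure."""
    cfg = SyntheticConfig(n_patients=60, n_transcripts=500,
                          module_sizes=(39, 40, 45), n_cpgs=1200, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size study cohort used by the acceptance checks."""
    return generate_cohort(SyntheticConfig(seed=1))
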