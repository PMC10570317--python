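import numpy as np
import pandas as pd
import pytest

from stressgcn.synthetic_data import (
    CountExperiment,
    SimulationParams,
    generate_experiment,
)


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(n_genes=300, n_conditions=2, n_modules=2, seed=42)


@pytest.fixture(scope="session")
def small_experiment(small_params):
    """A 300-gene, 2-condition experiment with planted truth."""
    return generate_experiment(small_params)


@pytest.fixture(scope="session")
def study_experiment():
    """An experiment at the planted-recovery study conditions."""
    params = SimulationParams(
        n_genes=600,
        n_conditions=3,
        n_modules=3,
        module_size_range=(20, 20),
        de_log2fc_range=(2.0, 2.0),
        n_replicates=5,
        seed=7,
    )
    return generate_experiment(params)


def make_experiment(counts: np.ndarray, lengths=None, n_conditions=1) -> CountExperiment:
    """Wrap a raw count array in a minimal CountExperiment.

    Samples are split evenly over conditions, half mock / half treated
    within each, one time point.
    """
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    genes = [f"g{i}" for i in range(n_genes)]
    per_cond = n_samples // n_conditions
    rows = []
    for s in range(n_samples):
        cond = f"c{s // per_cond + 1}" if n_conditions > 1 else "c1"
        within = s % per_cond if n_conditions > 1 else s
        arm = "mock" if within < per_cond // 2 else "treated"
        rows.append(
            {
                "sample_id": f"s{s}",
                "condition": cond,
                "time_point": "t0",
                "replicate": within + 1,
                "arm": arm,
            }
        )
    samples = pd.DataFrame(rows).set_index("sample_id")
    if lengths is None:
        lengths = np.full(n_genes, 1000)
    return CountExperiment(
        counts=pd.DataFrame(counts, index=genes, columns=samples.index),
        samples=samples,
        gene_lengths=pd.Series(lengths, index=genes),
    )
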