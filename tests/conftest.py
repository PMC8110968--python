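import numpy as np
import pandas as pd
import pytest

from ecmatlas import expression as expr
from ecmatlas import matrisome
from ecmatlas.simulate import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def catalogue():
    return matrisome.load_default_catalogue()


@pytest.fixture(scope="session")
def sim_dataset(catalogue):
    """Default-config simulated study: counts, truth, and derived matrices."""
    cfg = SimulationConfig(seed=11)
    cm, truth = simulate_counts(cfg, catalogue)
    factors = expr.compute_size_factors(cm)
    nm = expr.normalize_counts(cm, factors)
    logged = expr.log_transform(nm)
    z = expr.zscore_genes(logged)
    return {
        "cfg": cfg,
        "cm": cm,
        "truth": truth,
        "factors": factors,
        "nm": nm,
        "log": logged,
        "z": z,
    }


def make_count_matrix(counts, populations, genes=None):
    """Small CountMatrix helper: counts is genes × samples array-like."""
    counts = np.asarray(counts)
    reps = {}
    samples = []
    for pop in populations:
        reps[pop] = reps.get(pop, 0) + 1
        samples.append(expr.SampleMeta(f"{pop}_{reps[pop]}", pop, reps[pop]))
    if genes is None:
        genes = [f"g{i}" for i in range(counts.shape[0])]
    frame = pd.DataFrame(
        counts.astype(np.int64),
        index=pd.Index(genes, name="gene"),
        columns=[s.sample_id for s in samples],
    )
    return expr.CountMatrix(counts=frame, samples=tuple(samples))
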