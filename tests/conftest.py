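import numpy as np
import pandas as pd
import pytest

from mbmm import ModelSpec, SampleMeta, SimTruth, build_design, simulate_nbmm


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_meta():
    """12 samples, 4 subjects x 3, one binary and one continuous covariate."""
    rng = np.random.default_rng(7)
    n_s, k = 4, 3
    subj = np.repeat([f"s{i}" for i in range(n_s)], k)
    df = pd.DataFrame(
        {
            "subject": subj,
            "time": np.tile(np.arange(k, dtype=float), n_s),
            "group": np.repeat([0, 1, 0, 1], k).astype(float),
            "age": np.repeat(rng.normal(size=n_s), k),
            "total_reads": rng.uniform(1e3, 1e4, n_s * k),
        },
        index=[f"{s}_t{t}" for s, t in zip(subj, np.tile(np.arange(k), n_s))],
    )
    return SampleMeta(df)


@pytest.fixture
def nb_dataset():
    """Standard longitudinal NB simulation at moderate size."""
    return simulate_nbmm(SimTruth(n_subjects=40, seed=101))


def design_for(meta, y, method="nb", **kw):
    spec = ModelSpec(fixed_formula=kw.pop("fixed", "group + time + age"),
                     random_formula=kw.pop("random", "1 | subject"),
                     method=method, **kw)
    return build_design(meta, spec, y), spec
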