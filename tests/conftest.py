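import numpy as np
import pandas as pd
import pytest

from teb.experiment import TimeCourseExperiment
from teb.expression import cpm_normalize


def make_experiment(values, times, n_reps=2, to_counts=True):
    """Build a small experiment from a genes x (time, rep) value array.

    ``values`` may be counts (to_counts=True) or any non-negative matrix.
    Column order is time-major: (t0,r1), (t0,r2), (t1,r1), ...
    """
    values = np.asarray(values)
    cols, meta_rows = [], []
    for t in times:
        for r in range(1, n_reps + 1):
            sid = f"T{t:g}_R{r}"
            cols.append(sid)
            meta_rows.append((sid, float(t), str(r)))
    counts = pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])], columns=cols
    )
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "time_hours", "replicate"])
    return TimeCourseExperiment(counts.astype(int if to_counts else float), meta.set_index("sample_id"))


def profile_experiment(profiles, times, noise_sd=0.0, seed=0, scale=1000.0):
    """Experiment whose log2 replicate-mean profiles approximate ``profiles``.

    Counts are round(scale * 2^profile) per replicate with optional log-scale
    noise, large enough that log2(CPM+0.5) preserves shape.
    """
    rng = np.random.default_rng(seed)
    profiles = np.asarray(profiles, dtype=float)
    n_genes, n_t = profiles.shape
    cols = []
    for j in range(n_t):
        for r in range(2):
            noise = rng.normal(0, noise_sd, n_genes) if noise_sd > 0 else 0.0
            cols.append(np.round(scale * np.power(2.0, profiles[:, j] + noise)))
    return make_experiment(np.column_stack(cols), times)


@pytest.fixture(scope="session")
def times21():
    return np.arange(21) * 6.0


@pytest.fixture(scope="session")
def norm_small():
    """Normalized 4-gene, 3-time-point toy used across modules."""
    counts = np.array(
        [
            [10, 12, 30, 28, 60, 62],
            [100, 90, 100, 110, 100, 95],
            [0, 0, 0, 0, 0, 0],
            [5, 5, 50, 55, 5, 6],
        ]
    )
    return cpm_normalize(make_experiment(counts, [0.0, 6.0, 12.0]))
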