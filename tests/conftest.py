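import numpy as np
import pandas as pd
import pytest

from plastevo.containers import CountMatrix


def make_design_frame(groups):
    """Design DataFrame from a list of (sample, population, garden[, days]) tuples."""
    rows = []
    for entry in groups:
        sample, pop, garden = entry[:3]
        days = entry[3] if len(entry) > 3 else 40
        rows.append({"sample": sample, "population": pop, "garden": garden,
                     "acclimation_days": days, "tissue": "liver", "batch": "b1"})
    return pd.DataFrame(rows)


@pytest.fixture
def two_sample_cm():
    design = make_design_frame([("a", "L1", "l"), ("b", "L1", "l")])
    counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]},
                          index=["g1", "g2", "g3"])
    return CountMatrix(counts, design)


@pytest.fixture(scope="session")
def nb_two_group_cm():
    """Two groups of 20 samples, NB counts with a mean-dispersion trend; the
    first 100 genes are 4-fold up in group A, the next 100 are 4-fold down
    (sign-balanced so normalization stays unbiased), the rest are null."""
    rng = np.random.default_rng(42)
    g, per = 2000, 20
    mu_b = np.exp(rng.normal(4.5, 1.0, g))
    alpha = (3.0 / mu_b + 0.05) * np.exp(rng.normal(0, 0.3, g))
    mu_a = mu_b.copy()
    mu_a[:100] *= 4.0
    mu_a[100:200] /= 4.0
    ya = rng.negative_binomial((1 / alpha)[:, None],
                               (1 / (1 + alpha * mu_a))[:, None], (g, per))
    yb = rng.negative_binomial((1 / alpha)[:, None],
                               (1 / (1 + alpha * mu_b))[:, None], (g, per))
    design = make_design_frame(
        [(f"a{i}", "L1", "l") for i in range(per)]
        + [(f"b{i}", "L2", "l") for i in range(per)])
    counts = pd.DataFrame(np.hstack([ya, yb]),
                          index=[f"g{i:04d}" for i in range(g)],
                          columns=design["sample"])
    cm = CountMatrix(counts, design)
    return cm, [f"a{i}" for i in range(per)], [f"b{i}" for i in range(per)]


@pytest.fixture(scope="session")
def planted_partition():
    """Two 50-gene modules with graded latent loadings over 80 samples."""
    rng = np.random.default_rng(7)
    n_s = 80
    f1, f2 = rng.standard_normal(n_s), rng.standard_normal(n_s)
    loading = rng.uniform(0.4, 1.2, 100)
    expr = np.empty((100, n_s))
    expr[:50] = loading[:50, None] * f1 + 0.4 * rng.standard_normal((50, n_s))
    expr[50:] = loading[50:, None] * f2 + 0.4 * rng.standard_normal((50, n_s))
    df = pd.DataFrame(expr, index=[f"g{i:03d}" for i in range(100)])
    truth = np.array([1] * 50 + [2] * 50)
    return df, truth, loading
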