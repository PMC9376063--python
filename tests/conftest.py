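import numpy as np
import pytest

from mutevol import simulate as sim


@pytest.fixture(scope="session")
def small_genome():
    return sim.gen_genome(200_000, gc_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def ma_fixture(small_genome):
    """A clean+artifact MA simulation shared across filter/rate tests.

    12 lines so a single inflated line can exceed the |Z| > 2.5 cutoff
    (max attainable |Z| for one outlier among n lines is (n-1)/sqrt(n)).
    """
    truth = sim.MATruth(
        snm_rate=2e-7,
        sim_rate=4e-8,
        svm_rate=2e-4,
        n_lines=12,
        generations_per_line=1500.0,
    )
    plan = sim.ArtifactPlan(
        n_shared_snm=3,
        shared_in_lines=4,
        n_lowdepth=6,
        n_outlier_lines=1,
        inflation_factor=12.0,
    )
    calls, lines = sim.simulate_ma(truth, small_genome, plan, seed=23)
    return truth, plan, calls, lines


@pytest.fixture(scope="session")
def pattern_truth():
    """Three well-separated ground-truth 96-class patterns + sampled counts."""
    rng = np.random.default_rng(5)
    truth = np.zeros((96, 3))
    truth[0:32, 0] = rng.random(32)
    truth[32:64, 1] = rng.random(32)
    truth[64:96, 2] = rng.random(32)
    truth /= truth.sum(axis=0)
    n_samples = 24
    exposures = np.empty((3, n_samples))
    for j in range(n_samples):
        e = np.full(3, 0.1)
        e[j % 3] = 0.8
        exposures[:, j] = e
    V = np.vstack(
        [
            rng.multinomial(1500, truth @ exposures[:, j])
            for j in range(n_samples)
        ]
    ).T.astype(float)
    return truth, exposures, V
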