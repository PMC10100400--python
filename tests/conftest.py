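import numpy as np
import pytest

import orbimet as om


@pytest.fixture(scope="session")
def benchmark_cohort():
    """Two-class spike-in cohort: 20 sites/region, 200 features, 20 spiked
    at standardized effect 2, 10% detection-limited missingness, 1 ppm jitter."""
    cfg = om.SyntheticConfig(
        n_patients=4,
        regions=("necrotic", "viable"),
        sites_per_region=5,
        n_background_compounds=180,
        n_discriminative_compounds=20,
        effect_size=2.0,
        mass_jitter_ppm=1.0,
        missing_rate=0.10,
        seed=42,
    )
    spectra, truth, compounds = om.generate_cohort(cfg)
    return cfg, spectra, truth, compounds


@pytest.fixture(scope="session")
def benchmark_preprocessed(benchmark_cohort):
    _, spectra, _, _ = benchmark_cohort
    return om.preprocess(spectra)


@pytest.fixture(scope="session")
def benchmark_model(benchmark_preprocessed):
    tic = benchmark_preprocessed.tic
    return om.fit_oplsda(tic, tic.regions(), n_orthogonal=1, scale="pareto")


def nipals_pls1(X, y, tol=1e-12):
    """Independent single-component NIPALS PLS1 on centred data (test oracle)."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    w = Xc.T @ yc
    w = w / np.linalg.norm(w)
    t = Xc @ w
    p = Xc.T @ t / (t @ t)
    c = yc @ t / (t @ t)
    return w, t, p, c


def bh_stepup(p):
    """Hand-written Benjamini-Hochberg step-up rule (test oracle)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
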