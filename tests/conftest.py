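import numpy as np
import pytest

from k2tax import ExpressionMatrix, RunConfig, SimulationSpec, run_taxonomy, simulate_hierarchy


@pytest.fixture(scope="session")
def two_blob_matrix():
    """20 observations in two well-separated Gaussian blobs, 60 features."""
    rng = np.random.default_rng(11)
    a = rng.normal(0.0, 0.3, (60, 10))
    b = rng.normal(0.0, 0.3, (60, 10))
    b[:20, :] += 4.0
    values = np.concatenate([a, b], axis=1)
    obs = [f"o{j}" for j in range(20)]
    return ExpressionMatrix(values, [f"g{i}" for i in range(60)], obs), set(obs[:10])


@pytest.fixture(scope="session")
def paired_groups_matrix():
    """4 groups whose centroids form two well-separated pairs."""
    rng = np.random.default_rng(5)
    centers = {"gA": 0.0, "gB": 0.4, "gC": 6.0, "gD": 6.4}
    cols, obs, labels = [], [], {}
    for g, c in centers.items():
        for k in range(6):
            cols.append(rng.normal(c, 0.2, 30))
            name = f"{g}_{k}"
            obs.append(name)
            labels[name] = g
    values = np.stack(cols, axis=1)
    return ExpressionMatrix(values, [f"f{i}" for i in range(30)], obs, labels)


@pytest.fixture(scope="session")
def sim_taxonomy():
    """A fitted group-level taxonomy on simulated 4-cluster data plus truth."""
    spec = SimulationSpec(n_observations=60, n_features=500, n_terminal_clusters=4,
                          signal_fraction=0.2, noise_sd=0.5, seed=3)
    matrix, truth, labels = simulate_hierarchy(spec)
    config = RunConfig(mode="group", p=25, seed=3)
    tax = run_taxonomy(matrix, config)
    return {"matrix": matrix, "truth": truth, "labels": labels,
            "taxonomy": tax, "config": config}
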