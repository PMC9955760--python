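import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from temporalign import (DecayConfig, EmbedConfig, SimConfig, SnapshotSeries,
                         build_snapshots, embed_series, simulate_dynamic_sbm)

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sbm_graph():
    """Small growing planted-partition graph (60 nodes, 3 communities)."""
    return simulate_dynamic_sbm(SimConfig(n=60, k=3, T=6, p_in=0.12,
                                          p_out=0.01, seed=11))


@pytest.fixture(scope="session")
def snapshots(sbm_graph):
    return build_snapshots(sbm_graph, T=6)


@pytest.fixture(scope="session")
def small_series(snapshots):
    """d=12 embedding series on the small fixture (fresh weights/step)."""
    return embed_series(snapshots, EmbedConfig(d=12, weight_seed_base=3),
                        DecayConfig())


@pytest.fixture(scope="session")
def constant_snapshots():
    """A time-constant snapshot series: same adjacency at every step."""
    rng = np.random.default_rng(5)
    n, T = 40, 5
    A = (rng.random((n, n)) < 0.15).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    E = np.where(A > 0, 0.0, np.nan)
    return SnapshotSeries(A=[A.copy() for _ in range(T)],
                          edge_time=[E.copy() for _ in range(T)],
                          boundaries=np.arange(T + 1, dtype=float),
                          cumulative=True, directed=False)
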