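import numpy as np
import pytest

from pedprio.intervals import IbdTrack, RegionSet
from pedprio.network import GeneNetwork, build_network
from pedprio.simulate import SimConfig, simulate_bundle


def random_region_set(rng, chroms=("chrA", "chrB"), max_pos=10_000, max_ivs=8) -> RegionSet:
    out = {}
    for chrom in chroms:
        n = rng.integers(0, max_ivs + 1)
        ivs = []
        for _ in range(n):
            s = int(rng.integers(0, max_pos))
            e = int(rng.integers(s + 1, max_pos + 1))
            ivs.append((s, e))
        out[chrom] = ivs
    return RegionSet(out)


def region_mask(regions: RegionSet, chrom: str, size: int) -> np.ndarray:
    """Per-base membership oracle: bool array over [0, size)."""
    mask = np.zeros(size, dtype=bool)
    for s, e in regions.intervals(chrom):
        mask[s:min(e, size)] = True
    return mask


def random_track(rng, n_chroms=2, max_markers=60, max_pos=10_000) -> IbdTrack:
    markers = {}
    for c in range(n_chroms):
        m = int(rng.integers(1, max_markers + 1))
        pos = np.sort(rng.choice(np.arange(1, max_pos + 1), size=m, replace=False))
        raw = rng.dirichlet(np.ones(3), size=m)
        markers[f"chr{c}"] = np.column_stack([pos.astype(float), raw])
    return IbdTrack(("S1", "S2"), markers)


def random_network(rng, n_max=200) -> tuple[GeneNetwork, np.ndarray]:
    """Random weighted ER graph; returns the network and its dense W."""
    n = int(rng.integers(5, n_max + 1))
    p = rng.uniform(0.02, 0.3)
    W = np.zeros((n, n))
    genes = [f"g{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = float(rng.uniform(0.1, 5.0))
                W[i, j] = W[j, i] = w
                edges.append((genes[i], genes[j], w))
    net = build_network(edges, extra_nodes=genes)
    # align dense matrix with the network's node order
    order = [int(g[1:]) for g in net.nodes]
    return net, W[np.ix_(order, order)]


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic study, shared across tests (read-only)."""
    return simulate_bundle(SimConfig(), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
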