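import numpy as np
import pytest

from npdosim import CascadeModel, CellModel


@pytest.fixture
def hela() -> CellModel:
    return CellModel(r_cell=8.6, r_nucleus=5.5, name="Hela")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20211218)


@pytest.fixture
def cascade() -> CascadeModel:
    return CascadeModel()


def brute_force_proximity(tracks, edges):
    """O(N^2) double-loop reference for the binned proximity estimator."""
    edges = np.asarray(edges, dtype=float)
    mass = np.zeros(edges.size - 1)
    overflow = 0.0
    for pos, en in tracks:
        pos = np.atleast_2d(np.asarray(pos, float))
        en = np.asarray(en, float)
        t_total = en.sum()
        for i in range(en.size):
            for j in range(en.size):
                if i == j:
                    continue
                d = float(np.linalg.norm(pos[i] - pos[j]))
                w = en[i] * en[j] / t_total
                if edges[0] <= d < edges[-1]:
                    mass[np.searchsorted(edges, d, side="right") - 1] += w
                else:
                    overflow += w
    n = len(tracks)
    return mass / np.diff(edges) / n, overflow / n


def random_tracks(rng, n_tracks, max_deposits, scale=0.1):
    tracks = []
    for _ in range(n_tracks):
        n = int(rng.integers(1, max_deposits + 1))
        tracks.append((rng.normal(scale=scale, size=(n, 3)), rng.uniform(0.1, 5.0, n)))
    return tracks
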