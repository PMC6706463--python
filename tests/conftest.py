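"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-implement quantities by the most
literal route available (per-sample loops, Floyd-Warshall, triangle
enumeration) so that the package's vectorised/library-backed paths are
checked against something that cannot share their mistakes.
"""

import numpy as np
import pytest

from plinet.preprocessing import EpochSet


def brute_force_pli(phase_a, phase_b):
    """Literal per-epoch PLI: loop over epochs and samples.

    For each epoch, average sign(wrap(dphi)) over time with the
    difference wrapped to (-pi, pi] and sign(0) = 0; return the mean of
    the per-epoch magnitudes.
    """
    a = np.atleast_2d(phase_a)
    b = np.atleast_2d(phase_b)
    per_epoch = []
    for ea, eb in zip(a, b):
        total = 0.0
        for x, y in zip(ea, eb):
            d = x - y
            while d <= -np.pi:
                d += 2 * np.pi
            while d > np.pi:
                d -= 2 * np.pi
            total += 0.0 if d == 0 else (1.0 if d > 0 else -1.0)
        per_epoch.append(abs(total / len(ea)))
    return float(np.mean(per_epoch))


def floyd_warshall_oracle(weight_matrix):
    """All-pairs shortest paths by the textbook triple loop, distance 1/w."""
    W = np.asarray(weight_matrix, float)
    n = W.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                dist[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def onnela_clustering_oracle(weight_matrix):
    """Per-node weighted clustering: geometric mean of triangle weights."""
    W = np.asarray(weight_matrix, float)
    n = W.shape[0]
    wmax = W.max() if W.max() > 0 else 1.0
    Wn = W / wmax
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        tri = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = nbrs[a], nbrs[b]
                tri += (Wn[i, j] * Wn[i, h] * Wn[j, h]) ** (1.0 / 3.0)
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


def triangle_count_oracle(edges, n_nodes):
    """Number of triangles in a binary graph, by enumeration."""
    adj = np.zeros((n_nodes, n_nodes), bool)
    for a, b in edges:
        adj[a, b] = adj[b, a] = True
    count = 0
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if not adj[i, j]:
                continue
            for k in range(j + 1, n_nodes):
                if adj[i, k] and adj[j, k]:
                    count += 1
    return count


def make_epochset(data, sampling_rate=1000.0, band=(8.0, 13.0),
                  subject_id="T001"):
    """Wrap an (epochs, channels, samples) array as an analysis-ready EpochSet."""
    data = np.asarray(data, float)
    return EpochSet(
        subject_id=subject_id,
        sampling_rate=sampling_rate,
        channel_labels=tuple(f"E{i + 1}" for i in range(data.shape[1])),
        data=data,
        epoch_length=data.shape[2] / sampling_rate,
        trim=0.0,
        band=band,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
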