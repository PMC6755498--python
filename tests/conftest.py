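"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from phageflux.alignio import SnpHaplotypes
from phageflux.painting import CoancestryMatrix


def planted_coancestry(
    seed: int,
    n_per: int = 8,
    n_blocks: int = 3,
    within: float = 30.0,
    between: float = 5.0,
    noise: float = 2.0,
) -> tuple[CoancestryMatrix, dict[str, int]]:
    """Block-structured co-ancestry matrix with known cluster labels."""
    rng = np.random.default_rng(seed)
    N = n_per * n_blocks
    X = np.full((N, N), between) + rng.random((N, N)) * noise
    for k in range(n_blocks):
        sl = slice(k * n_per, (k + 1) * n_per)
        X[sl, sl] = within + rng.random((n_per, n_per)) * noise
    np.fill_diagonal(X, 0)
    ids = [f"p{k}_i{i}" for k in range(n_blocks) for i in range(n_per)]
    truth = {sid: int(sid[1]) for sid in ids}
    return CoancestryMatrix(ids, X), truth


def brute_force_painting(snps: SnpHaplotypes, recipient: int, params):
    """Exact copy posterior and expected chunks by enumerating donor paths."""
    n = snps.n_samples
    donors = [i for i in range(n) if i != recipient]
    k = len(donors)
    L = snps.n_snps
    d = snps.distances
    switch = 1.0 - np.exp(-params.switch_scale * d)
    recv = snps.matrix[recipient]
    post = np.zeros((L, k))
    chunks = np.zeros(k)
    total = 0.0
    for path in itertools.product(range(k), repeat=L):
        p = 1.0 / k
        for l in range(1, L):
            p *= (1.0 - switch[l - 1]) * (path[l] == path[l - 1]) + switch[l - 1] / k
        for l in range(L):
            match = snps.matrix[donors[path[l]], l] == recv[l]
            p *= (1.0 - params.miscopy) if match else params.miscopy
        total += p
        for l in range(L):
            post[l, path[l]] += p
        chunks[path[0]] += p
        for l in range(L - 1):
            if path[l + 1] != path[l]:
                chunks[path[l + 1]] += p
    return chunks / total, post / total


def exhaustive_rmin(matrix: np.ndarray) -> int:
    """Minimum breakpoints by brute force: smallest set of inter-site gaps
    stabbing every four-gamete-incompatible open interval."""
    n_sites = matrix.shape[1]
    pairs = []
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            if len(set(zip(matrix[:, i].tolist(), matrix[:, j].tolist()))) == 4:
                pairs.append((i, j))
    if not pairs:
        return 0
    gaps = range(n_sites - 1)  # gap g lies between sites g and g+1
    for k in range(1, n_sites):
        for chosen in itertools.combinations(gaps, k):
            if all(any(a <= g < b for g in chosen) for a, b in pairs):
                return k
    return n_sites - 1


def enumerate_ranksum_p(a, b) -> float:
    """Two-sided exact Wilcoxon rank-sum p by full enumeration (no ties)."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle requires untied values"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n = len(a), len(pooled)
    w_obs = sum(rank[v] for v in a)
    mu = n1 * (n + 1) / 2
    hits = 0
    combos = list(itertools.combinations(range(1, n + 1), n1))
    for combo in combos:
        if abs(sum(combo) - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / len(combos)


@pytest.fixture
def tiny_snps() -> SnpHaplotypes:
    """Three samples, three SNPs; recipient 0 mixes the two donors."""
    matrix = np.array([[0, 1, 1], [0, 1, 0], [1, 0, 1]], dtype=np.int8)
    return SnpHaplotypes(["r", "d1", "d2"], matrix, [0, 100, 250])
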