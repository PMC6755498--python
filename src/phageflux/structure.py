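"""Model-based clustering of individuals from the co-ancestry matrix.

Individuals are partitioned into populations by a Dirichlet-multinomial
model on their donated chunk counts.  For a recipient *r* and a partition
with donor clusters *b = 1..B*, the counts aggregated by donor cluster
``x_rb`` carry a symmetric-Dirichlet marginal

    log ML_dm(r) = log G(B*beta) - log G(n_r + B*beta)
                   + sum_b [ log G(x_rb + beta) - log G(beta) ]

with ``G`` the gamma function and ``n_r = sum_b x_rb``.  To compare
partitions with different numbers of clusters the score must be the
probability of the *full* donor-resolved count vector, not just of its
cluster aggregate: the aggregate is drawn Dirichlet-multinomially
(including the multinomial normalization ``n_r! / prod_b x_rb!``) and is
then spread uniform-multinomially over each cluster's ``m_b`` donors (the
recipient excluded from its own cluster).  The composite per-row score
simplifies to

    log ML(r) = log ML_dm(r) + log G(n_r + 1)
                - sum_b x_rb * log m_b - sum_d log G(x_rd + 1)

and the partition score is its sum over recipients.  Without the
normalization and spread factors, aggregation can only lose information
and the one-cluster partition would always be optimal.  Chunk counts are
expectations (real-valued), handled throughout via the continuous gamma
extension.

A Metropolis-Hastings chain explores partitions with single-individual
reassignment and merge/split moves; the highest-scoring partition visited
is retained as the MAP estimate.  A greedy agglomeration of the MAP
clusters yields the merge tree displayed alongside co-ancestry heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from phageflux.errors import ConfigError, InputError
from phageflux.painting import CoancestryMatrix


@dataclass
class Partition:
    """Assignment of samples to clusters with its marginal-likelihood score."""

    assignment: dict[str, int]
    log_ml: float = float("nan")
    tree: str | None = None  # Newick over cluster labels

    @property
    def K(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, c in self.assignment.items():
            out.setdefault(c, []).append(sid)
        return out

    def as_sets(self) -> frozenset[frozenset[str]]:
        """Label-free view, for comparing partitions."""
        return frozenset(frozenset(m) for m in self.clusters().values())

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tcluster\n")
            for sid, c in self.assignment.items():
                fh.write(f"{sid}\t{c}\n")


@dataclass
class McmcConfig:
    """Chain settings; defaults follow the published analysis protocol."""

    burn_in: int = 100_000
    iterations: int = 100_000
    seed: int = 0
    dirichlet_beta: float = 1.0
    thin: int = 100

    def __post_init__(self) -> None:
        if self.burn_in <= 0 or self.iterations <= 0:
            raise ConfigError("burn_in and iterations must be positive")
        if self.dirichlet_beta <= 0:
            raise ConfigError("dirichlet_beta must be positive")
        if self.thin <= 0:
            raise ConfigError("thin must be positive")


def _labels_to_partition(sample_ids, labels, log_ml=float("nan")) -> Partition:
    return Partition({sid: int(c) for sid, c in zip(sample_ids, labels)}, log_ml=log_ml)


def _log_ml_from_labels(X: np.ndarray, labels: np.ndarray, beta: float) -> float:
    """Partition score (Dirichlet-multinomial + uniform spread) from labels."""
    N = X.shape[0]
    uniq = np.unique(labels)
    B = len(uniq)
    member = np.stack([labels == c for c in uniq], axis=1)  # (N, B)
    agg = X @ member  # (N, B) counts aggregated by donor cluster
    n_r = agg.sum(axis=1)
    score = gammaln(B * beta) - gammaln(n_r + B * beta)
    score += (gammaln(agg + beta) - gammaln(beta)).sum(axis=1)
    # multinomial normalization + uniform spread over each cluster's donors
    sizes = member.sum(axis=0)[None, :] - member.astype(int)  # recipient excluded
    log_m = np.where(sizes > 0, np.log(np.maximum(sizes, 1)), 0.0)
    score += gammaln(n_r + 1.0) - (agg * log_m).sum(axis=1)
    score -= gammaln(X + 1.0).sum(axis=1)
    return float(score.sum())


def partition_log_ml(X: CoancestryMatrix, partition: Partition, beta: float = 1.0) -> float:
    """Log marginal likelihood of a partition under the Dirichlet-multinomial model."""
    if beta <= 0:
        raise ConfigError("beta must be positive")
    if set(partition.assignment) != set(X.sample_ids):
        raise InputError("partition does not cover the co-ancestry samples")
    if np.any(X.X < 0):
        raise InputError("negative counts in co-ancestry matrix")
    labels = np.array([partition.assignment[sid] for sid in X.sample_ids])
    return _log_ml_from_labels(X.X, labels, beta)


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by first appearance so label vectors compare cleanly."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, c in enumerate(labels):
        if c not in mapping:
            mapping[c] = len(mapping)
        out[i] = mapping[c]
    return out


def run_mcmc(
    X: CoancestryMatrix, cfg: McmcConfig
) -> tuple[list[Partition], Partition]:
    """Metropolis-Hastings over partitions of the co-ancestry samples.

    Moves: (i) reassign one uniformly chosen individual to a uniformly
    chosen cluster, including a fresh singleton; (ii) merge two random
    clusters or split one cluster by a random bipartition, with the
    appropriate Hastings correction.  Post-burn-in states are thinned into
    ``samples``; the highest-scoring partition ever visited is the MAP.
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = X.sample_ids
    N = len(ids)
    beta = cfg.dirichlet_beta
    labels = np.zeros(N, dtype=int)  # start from one cluster
    cur_ml = _log_ml_from_labels(X.X, labels, beta)
    if not np.isfinite(cur_ml):
        raise FloatingPointError("non-finite likelihood at initial state")
    best_labels, best_ml = labels.copy(), cur_ml

    samples: list[Partition] = []
    total = cfg.burn_in + cfg.iterations
    for it in range(total):
        if rng.random() < 0.5:
            prop, log_hastings = _propose_reassign(labels, rng)
        else:
            prop, log_hastings = _propose_merge_split(labels, rng)
        if prop is None:
            new_labels, new_ml = labels, cur_ml  # null proposal: ratio 1, accept
        else:
            new_ml = _log_ml_from_labels(X.X, prop, beta)
            if not np.isfinite(new_ml):
                raise FloatingPointError("non-finite likelihood during chain")
            log_ratio = (new_ml - cur_ml) + log_hastings
            if np.log(rng.random()) < log_ratio:
                new_labels = prop
            else:
                new_labels, new_ml = labels, cur_ml
        labels, cur_ml = new_labels, new_ml
        if cur_ml > best_ml:
            best_ml, best_labels = cur_ml, labels.copy()
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            samples.append(_labels_to_partition(ids, _canonical(labels), cur_ml))

    map_partition = _labels_to_partition(ids, _canonical(best_labels), best_ml)
    return samples, map_partition


def _propose_reassign(labels: np.ndarray, rng) -> tuple[np.ndarray | None, float]:
    """Move one individual to an existing cluster or a new singleton."""
    N = len(labels)
    i = int(rng.integers(N))
    clusters = np.unique(labels)
    K = len(clusters)
    new_label = int(labels.max()) + 1  # fresh singleton option
    choices = list(clusters) + [new_label]
    target = int(choices[rng.integers(len(choices))])
    if target == labels[i]:
        return None, 0.0
    prop = labels.copy()
    prop[i] = target
    K_new = len(np.unique(prop))
    # forward: 1/N * 1/(K+1); reverse: 1/N * 1/(K_new+1)
    log_hastings = np.log(K + 1) - np.log(K_new + 1)
    return prop, float(log_hastings)


def _propose_merge_split(labels: np.ndarray, rng) -> tuple[np.ndarray | None, float]:
    """Merge two random clusters, or split one by a uniform bipartition."""
    clusters = np.unique(labels)
    K = len(clusters)
    do_merge = rng.random() < 0.5
    if do_merge:
        if K < 2:
            return None, 0.0
        a, b = rng.choice(K, size=2, replace=False)
        ca, cb = clusters[a], clusters[b]
        prop = labels.copy()
        prop[prop == cb] = ca
        m = int(np.sum(prop == ca))
        K_big = np.sum([np.sum(prop == c) >= 2 for c in np.unique(prop)])
        # forward: pick unordered pair, 1/C(K,2); reverse: split that cluster
        # into exactly this bipartition: 1/K_big * 2/(2^m - 2)
        log_fwd = -np.log(K * (K - 1) / 2)
        log_rev = -np.log(K_big) + np.log(2.0) - np.log(2.0**m - 2.0)
        return prop, float(log_rev - log_fwd)
    else:
        sizes = {c: int(np.sum(labels == c)) for c in clusters}
        splittable = [c for c in clusters if sizes[c] >= 2]
        if not splittable:
            return None, 0.0
        c = splittable[rng.integers(len(splittable))]
        members = np.where(labels == c)[0]
        m = len(members)
        while True:
            side = rng.random(m) < 0.5
            if 0 < side.sum() < m:
                break
        prop = labels.copy()
        prop[members[side]] = int(labels.max()) + 1
        K_new = K + 1
        log_fwd = -np.log(len(splittable)) + np.log(2.0) - np.log(2.0**m - 2.0)
        log_rev = -np.log(K_new * (K_new - 1) / 2)
        return prop, float(log_rev - log_fwd)


def merge_tree(
    X: CoancestryMatrix, map_partition: Partition, beta: float = 1.0
) -> Partition:
    """Greedy agglomeration of MAP clusters into a rooted merge tree.

    Repeatedly merges the cluster pair whose merge loses the least log
    marginal likelihood until one cluster remains; ties break on the
    lexicographically smallest cluster-label pair.  The merge order is
    recorded as a Newick string whose leaves are the MAP cluster labels.
    """
    ids = X.sample_ids
    labels = np.array([map_partition.assignment[sid] for sid in ids])
    newick: dict[int, str] = {int(c): f"c{int(c)}" for c in np.unique(labels)}
    current = labels.copy()
    while len(np.unique(current)) > 1:
        clusters = sorted(int(c) for c in np.unique(current))
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                trial = current.copy()
                trial[trial == clusters[j]] = clusters[i]
                ml = _log_ml_from_labels(X.X, trial, beta)
                key = (-ml, clusters[i], clusters[j])
                if best is None or key < best[0]:
                    best = (key, clusters[i], clusters[j], trial)
        _, ci, cj, merged = best
        newick[ci] = f"({newick[ci]},{newick[cj]})"
        del newick[cj]
        current = merged
    root = int(np.unique(current)[0])
    tree = newick[root] + ";"
    return Partition(
        assignment=dict(map_partition.assignment),
        log_ml=partition_log_ml(X, map_partition, beta),
        tree=tree,
    )
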