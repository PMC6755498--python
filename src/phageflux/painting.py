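"""Haplotype-copying ("chromosome painting") hidden Markov model.

Each recipient genome is modelled as a mosaic copied from a leave-one-out
panel of donor haplotypes, in the Li & Stephens tradition.  The hidden
state at SNP *l* is the donor being copied.  The chain starts uniform over
the *k* donors; between adjacent SNPs at alignment distance ``d`` it
switches with probability ``1 - exp(-switch_scale * d)``, and conditional
on a switch the new donor is uniform over all *k* donors (switching back
to the same donor is allowed -- the standard simplification that keeps
transitions closed-form).  Emissions match the donor allele with
probability ``1 - miscopy``.

Forward-backward gives the per-site copy posterior, and the expected
number of *chunks* (maximal copied segments) from each donor:

    chunks[d] = P(state_0 = d) + sum_l P(state_l != d, state_{l+1} = d).

Because a chunk is counted on entry into a donor, self-switches do not
inflate counts.  Painting every sample against all others yields the
co-ancestry matrix: recipients in rows, donors in columns, entries the
expected chunk counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from phageflux.alignio import SnpHaplotypes
from phageflux.errors import ConfigError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PaintingParams:
    """Copying-model parameters.

    ``switch_scale`` is the switch intensity per bp (an Ne-like scale:
    larger values mean shorter copied chunks); ``miscopy`` is the per-site
    probability of emitting an allele different from the copied donor's.
    """

    switch_scale: float
    miscopy: float

    def __post_init__(self) -> None:
        if not self.switch_scale > 0:
            raise ConfigError("switch_scale must be positive")
        if not (0.0 < self.miscopy < 0.5):
            raise ConfigError("miscopy must lie in (0, 0.5)")


@dataclass
class CoancestryMatrix:
    """Recipient x donor matrix of expected chunk counts.

    ``X[r, d]`` is the expected number of chunks recipient ``r`` copied
    from donor ``d``; the diagonal is zero (self-copying is excluded).
    """

    sample_ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.sample_ids)
        if self.X.shape != (n, n):
            raise InputError("co-ancestry matrix must be N x N")
        if np.any(self.X < 0):
            raise InputError("co-ancestry entries must be non-negative")
        if np.any(np.diag(self.X) != 0):
            raise InputError("co-ancestry diagonal must be zero")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row_sums(self) -> np.ndarray:
        return self.X.sum(axis=1)

    def write_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.X, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", float_format="%.6f"
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CoancestryMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(sample_ids=[str(s) for s in df.index], X=df.to_numpy(dtype=float))


def estimate_params(
    snps: SnpHaplotypes,
    switch_scale: float | None = None,
    miscopy: float | None = None,
) -> PaintingParams:
    """Default copying parameters, overridable per argument.

    ``miscopy`` follows the Watterson-style convention
    ``theta_w / (theta_w + 2k)`` with ``theta_w = 1 / sum_{m=1}^{k-1} 1/m``
    for a panel of ``k`` donors, clipped to ``(1e-4, 0.49)``.
    ``switch_scale`` is set so the expected number of switches across the
    painted region is of order 10.
    """
    if snps.n_samples < 2:
        raise InputError("need at least two samples")
    k = snps.n_samples - 1  # leave-one-out donor panel size
    if miscopy is None:
        if k >= 2:
            theta_w = 1.0 / sum(1.0 / m for m in range(1, k))
        else:
            theta_w = 1.0
        miscopy = theta_w / (theta_w + 2.0 * k)
        miscopy = float(np.clip(miscopy, 1e-4, 0.49))
    if switch_scale is None:
        if snps.n_snps >= 2:
            span = float(snps.positions[-1] - snps.positions[0])
        else:
            span = 1.0
        switch_scale = 10.0 / max(span, 1.0)
    params = PaintingParams(switch_scale=switch_scale, miscopy=miscopy)
    logger.info("painting params: switch_scale=%.3g miscopy=%.3g", params.switch_scale, params.miscopy)
    return params


def paint_recipient(
    snps: SnpHaplotypes, recipient_index: int, params: PaintingParams
) -> tuple[np.ndarray, np.ndarray]:
    """Paint one recipient against the leave-one-out donor panel.

    Returns ``(expected_chunks, copy_posterior)`` where ``expected_chunks``
    has one entry per donor (panel order = sample order with the recipient
    removed) and ``copy_posterior`` is an ``(L_snps, k)`` matrix whose rows
    sum to 1.  Scaled forward-backward keeps outputs finite for long SNP
    tracks.
    """
    n = snps.n_samples
    if not 0 <= recipient_index < n:
        raise InputError("recipient index out of range")
    donor_rows = [i for i in range(n) if i != recipient_index]
    k = len(donor_rows)
    if k == 0:
        raise InputError("empty donor panel")
    L = snps.n_snps
    if L == 0:
        return np.zeros(k), np.zeros((0, k))

    recipient = snps.matrix[recipient_index]
    donors = snps.matrix[donor_rows]  # (k, L)
    match = donors == recipient[None, :]
    emit = np.where(match, 1.0 - params.miscopy, params.miscopy).T  # (L, k)

    d = snps.distances.astype(float)
    switch = 1.0 - np.exp(-params.switch_scale * d)  # (L-1,)

    # scaled forward pass
    alpha = np.empty((L, k))
    scale = np.empty(L)
    a = emit[0] / k
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for l in range(1, L):
        s = switch[l - 1]
        pred = (1.0 - s) * alpha[l - 1] + s / k  # sum_i alpha[i] T(i,j)
        a = pred * emit[l]
        scale[l] = a.sum()
        alpha[l] = a / scale[l]

    # scaled backward pass
    beta = np.empty((L, k))
    beta[L - 1] = 1.0
    for l in range(L - 2, -1, -1):
        s = switch[l]
        w = beta[l + 1] * emit[l + 1]
        beta[l] = ((1.0 - s) * w + s / k * w.sum()) / scale[l + 1]

    posterior = alpha * beta
    posterior /= posterior.sum(axis=1, keepdims=True)

    # expected chunks: entry at SNP 0 plus expected switch-into events
    expected = posterior[0].copy()
    for l in range(L - 1):
        s = switch[l]
        # joint P(state_l = d, state_{l+1} = d) from the pair marginal
        stay = alpha[l] * ((1.0 - s) + s / k) * emit[l + 1] * beta[l + 1] / scale[l + 1]
        expected += np.maximum(posterior[l + 1] - stay, 0.0)

    if not (np.all(np.isfinite(posterior)) and np.all(np.isfinite(expected))):
        raise FloatingPointError("non-finite painting output")
    return expected, posterior


def coancestry(
    snps: SnpHaplotypes,
    params: PaintingParams | None = None,
    statistic: str = "chunks",
) -> CoancestryMatrix:
    """Paint every sample as recipient and assemble the co-ancestry matrix.

    ``statistic="chunks"`` (default) fills the matrix with expected chunk
    counts -- the number of donated fragments.  ``statistic="lengths"``
    fills it with expected copied-site totals (posterior mass summed over
    SNPs).  Chunk counts split a segment copied from an interchangeable
    donor group across that group's members, so count shares drift toward
    larger donor populations; copied-length shares estimate the genome
    fraction donated without that panel-size effect.
    """
    n = snps.n_samples
    if n < 3:
        raise InputError("co-ancestry needs at least 3 samples")
    if statistic not in ("chunks", "lengths"):
        raise InputError("statistic must be 'chunks' or 'lengths'")
    if params is None:
        params = estimate_params(snps)
    X = np.zeros((n, n))
    for r in range(n):
        expected, posterior = paint_recipient(snps, r, params)
        donor_rows = [i for i in range(n) if i != r]
        X[r, donor_rows] = expected if statistic == "chunks" else posterior.sum(axis=0)
    return CoancestryMatrix(sample_ids=list(snps.sample_ids), X=X)
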