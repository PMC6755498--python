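"""Gene-level recombination: Hudson-Kaplan minimum recombination events
and a diversity-controlled regression of recombination intensity.

Under the infinite-sites assumption, a pair of biallelic sites at which
all four gametic types (00, 01, 10, 11) occur cannot be explained without
at least one crossover between them (the four-gamete test).  The
Hudson-Kaplan bound R_min collects every incompatible site pair as an open
interval and counts a maximal set of pairwise non-overlapping intervals --
each such interval must contain its own breakpoint, so the count is a
lower bound on the number of recombination events in the gene's history.

To compare genes with different diversity, R_min per nucleotide ``y`` is
regressed on nucleotide diversity ``x1`` and the number of aligned
sequences ``x2``:

    y_i = b0 + b1 * x1_i + b2 * x2_i + e_i

and the residual ``e_i`` scores each gene's recombination intensity after
accounting for its diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from phageflux.alignio import GeneStats, HaplotypeAlignment, gap_filter, nucleotide_diversity
from phageflux.errors import InputError

NT_PLAIN = frozenset("ACGT")


@dataclass
class RegressionFit:
    """OLS fit of R_min per nucleotide on diversity and sample count."""

    beta0: float
    beta1: float
    beta2: float | None  # None when x2 was dropped for rank deficiency
    residuals: np.ndarray
    r_squared: float
    bse: np.ndarray  # standard errors, in (b0, b1[, b2]) order
    mean_n: float
    gene_ids: list[str]

    def line_at_mean_n(self, x1: float | np.ndarray) -> np.ndarray:
        """Predicted y as a function of diversity, holding x2 at the mean n."""
        x1 = np.asarray(x1, dtype=float)
        b2 = self.beta2 if self.beta2 is not None else 0.0
        return self.beta0 + self.beta1 * x1 + b2 * self.mean_n


def incompatible(site_a: np.ndarray, site_b: np.ndarray) -> bool:
    """Four-gamete test on two biallelic, gap-free allele columns.

    True iff all four gametic types occur among the haplotypes.
    """
    site_a = np.asarray(site_a)
    site_b = np.asarray(site_b)
    if site_a.shape != site_b.shape:
        raise InputError("columns cover different samples")
    for col in (site_a, site_b):
        if len(np.unique(col)) != 2:
            raise InputError("four-gamete test requires biallelic columns")
    gametes = {(int(x), int(y)) for x, y in zip(_binarize(site_a), _binarize(site_b))}
    return len(gametes) == 4


def _binarize(col: np.ndarray) -> np.ndarray:
    alleles = np.unique(col)
    return (col == alleles[1]).astype(int)


def _biallelic_columns(aln: HaplotypeAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Gap-filtered biallelic 0/1 columns and their (filtered) positions."""
    arr = gap_filter(aln)
    cols = []
    pos = []
    for j in range(arr.shape[1]):
        uniq = set(arr[:, j].tolist())
        if len(uniq) == 2 and uniq <= NT_PLAIN:
            a, _ = sorted(uniq)
            cols.append((arr[:, j] != a).astype(np.int8))
            pos.append(j)
    if not cols:
        return np.zeros((arr.shape[0], 0), dtype=np.int8), np.asarray([], dtype=int)
    return np.column_stack(cols), np.asarray(pos, dtype=int)


def rmin(gene_aln: HaplotypeAlignment) -> tuple[int, list[tuple[int, int]]]:
    """Hudson-Kaplan minimum number of recombination events.

    Gap-containing columns are removed first; multiallelic sites are
    excluded from pairing.  All incompatible site pairs become open
    intervals; scanning them by right endpoint and greedily accepting each
    interval that starts at or after the last accepted right endpoint
    yields a maximal non-overlapping set, whose size is R_min.  Breakpoint
    intervals are returned half-open in 0-based gap-filtered coordinates.
    """
    matrix, positions = _biallelic_columns(gene_aln)
    n_sites = matrix.shape[1]
    if gene_aln.n_samples <= 2 or n_sites < 2:
        return 0, []
    intervals = []
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            gametes = set(zip(matrix[:, i].tolist(), matrix[:, j].tolist()))
            if len(gametes) == 4:
                intervals.append((int(positions[i]), int(positions[j])))
    intervals.sort(key=lambda iv: (iv[1], iv[0]))
    accepted: list[tuple[int, int]] = []
    last_end = -1
    for start, end in intervals:
        if start >= last_end:
            accepted.append((start, end))
            last_end = end
    return len(accepted), accepted


def gene_stats(gene_id: str, gene_aln: HaplotypeAlignment) -> GeneStats:
    """Per-gene statistics feeding the regression: pi, L, S and R_min."""
    pi, L, S = nucleotide_diversity(gene_aln)
    r, _ = rmin(gene_aln)
    return GeneStats(gene_id=gene_id, n=gene_aln.n_samples, L=L, S=S, pi=pi, rmin=r)


def regress(stats: list[GeneStats]) -> RegressionFit:
    """OLS of R_min per nucleotide on (nucleotide diversity, sample count).

    Requires at least four genes.  If the design is rank deficient (for
    example every gene has the same number of sequences), the sample-count
    term is dropped with a warning and the model refit.
    """
    if len(stats) < 4:
        raise InputError("regression needs at least 4 genes")
    return ols_fit(
        y=np.array([s.rmin_per_nt for s in stats]),
        x1=np.array([s.pi for s in stats]),
        x2=np.array([float(s.n) for s in stats]),
        gene_ids=[s.gene_id for s in stats],
    )


def ols_fit(
    y: np.ndarray, x1: np.ndarray, x2: np.ndarray, gene_ids: list[str] | None = None
) -> RegressionFit:
    """Fit ``y = b0 + b1*x1 + b2*x2`` by ordinary least squares."""
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(len(y))]
    X = sm.add_constant(np.column_stack([x1, x2]), has_constant="add")
    drop_x2 = np.linalg.matrix_rank(X) < X.shape[1]
    if drop_x2:
        import warnings

        warnings.warn("design rank deficient; dropping the sample-count term", stacklevel=2)
        X = sm.add_constant(x1.reshape(-1, 1), has_constant="add")
    model = sm.OLS(y, X).fit()
    params = model.params
    return RegressionFit(
        beta0=float(params[0]),
        beta1=float(params[1]),
        beta2=None if drop_x2 else float(params[2]),
        residuals=np.asarray(model.resid),
        r_squared=float(model.rsquared),
        bse=np.asarray(model.bse),
        mean_n=float(x2.mean()),
        gene_ids=list(gene_ids),
    )


def intensity_report(stats: list[GeneStats], fit: RegressionFit) -> pd.DataFrame:
    """Per-gene recombination-intensity table ranked by deviation.

    Standardized residuals use the residual standard deviation; genes with
    |z| > 2 are flagged as deviating from the diversity-controlled trend.
    """
    if [s.gene_id for s in stats] != fit.gene_ids:
        raise InputError("fit was computed on a different gene set")
    resid = fit.residuals
    sd = resid.std(ddof=1) if len(resid) > 1 else 0.0
    z = resid / sd if sd > 0 else np.zeros_like(resid)
    df = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in stats],
            "rmin": [s.rmin for s in stats],
            "rmin_per_nt": [s.rmin_per_nt for s in stats],
            "pi": [s.pi for s in stats],
            "n": [s.n for s in stats],
            "residual": resid,
            "std_residual": z,
            "deviating": np.abs(z) > 2,
        }
    )
    return df.reindex(df.std_residual.abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
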