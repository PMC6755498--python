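"""Inter-population genetic flux from the co-ancestry matrix.

For each recipient genome the donated chunk counts are converted into the
fraction of its painting attributed to each donor population; the
denominator is the recipient's full painting (all donor populations,
including its own), so per-recipient fractions sum to one.  Group medians
over recipient x donor-population pairs quantify imports (fix the
recipient populations) and exports (fix the donor populations), and group
contrasts are tested with the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from phageflux.errors import DegenerateInputError, InputError, SelectionError
from phageflux.painting import CoancestryMatrix


@dataclass
class FluxTable:
    """Per-recipient donor-population fractions.

    ``rows`` has one entry per (recipient, donor population) pair with
    donor population different from the recipient's own; ``own_fraction``
    keeps the complementary within-population share so fractions can be
    checked to sum to one.
    """

    rows: pd.DataFrame  # columns: recipient_id, recipient_pop, donor_pop, fraction
    own_fraction: dict[str, float]

    def write_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class WilcoxonResult:
    statistic: float  # rank sum W of the first sample
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int
    medians: tuple[float, float]


def import_fractions(
    X: CoancestryMatrix,
    labels: Mapping[str, str],
    denominator: str = "all",
) -> FluxTable:
    """Fraction of each recipient's chunks attributed to each donor population.

    ``fraction(r, P) = sum_{d in P, d != r} X[r, d] / sum_{d != r} X[r, d]``.
    With ``denominator="all"`` (default) the denominator includes the
    recipient's own population, so fractions over all donor populations sum
    to 1; ``denominator="other"`` restricts it to foreign populations.
    """
    missing = [sid for sid in X.sample_ids if sid not in labels]
    if missing:
        raise InputError(f"unlabeled samples: {missing}")
    if denominator not in ("all", "other"):
        raise InputError("denominator must be 'all' or 'other'")
    pops = sorted(set(labels[sid] for sid in X.sample_ids))
    idx_by_pop = {
        p: [i for i, sid in enumerate(X.sample_ids) if labels[sid] == p] for p in pops
    }
    records = []
    own: dict[str, float] = {}
    for r, sid in enumerate(X.sample_ids):
        row = X.X[r]
        total = row.sum()
        if total <= 0:
            raise DegenerateInputError(f"recipient {sid!r} has zero donated chunks")
        own_pop = labels[sid]
        pop_sums = {p: row[idx_by_pop[p]].sum() for p in pops}
        denom = total if denominator == "all" else total - pop_sums[own_pop]
        own[sid] = pop_sums[own_pop] / total
        for p in pops:
            if p == own_pop:
                continue
            if denom <= 0:
                raise DegenerateInputError(
                    f"recipient {sid!r} has no foreign chunks for 'other' denominator"
                )
            records.append((sid, own_pop, p, pop_sums[p] / denom))
    rows = pd.DataFrame(
        records, columns=["recipient_id", "recipient_pop", "donor_pop", "fraction"]
    )
    return FluxTable(rows=rows, own_fraction=own)


def group_flux(
    table: FluxTable,
    recipient_pops: Iterable[str],
    donor_pops: Iterable[str],
) -> tuple[list[float], float]:
    """Select flux rows by recipient/donor population and return (values, median).

    An import view fixes ``recipient_pops``; an export view fixes
    ``donor_pops``.  Both are slices of the same table.
    """
    rp, dp = set(recipient_pops), set(donor_pops)
    if not rp or not dp:
        raise SelectionError("population sets must be non-empty")
    sel = table.rows[
        table.rows.recipient_pop.isin(rp) & table.rows.donor_pop.isin(dp)
    ]
    if sel.empty:
        raise SelectionError(f"no flux rows for recipients {sorted(rp)} x donors {sorted(dp)}")
    values = sel.fraction.tolist()
    return values, float(np.median(values))


def ranksum_test(a: Sequence[float], b: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Uses the exact null distribution whenever ``n1 + n2 <= 20`` and the
    pooled values carry no ties; otherwise a normal approximation with tie
    and continuity corrections.  The statistic reported is the rank sum of
    the first sample.
    """
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    n1, n2 = len(a), len(b)
    if n1 < 1 or n2 < 1:
        raise InputError("both samples must be non-empty")
    pooled = a + b
    has_ties = len(set(pooled)) < len(pooled)
    if len(set(pooled)) == 1:
        import warnings

        warnings.warn("all values identical across samples; p = 1", stacklevel=2)
        w = n1 * (n1 + 1) / 2 + n1 * n2 / 2  # mid-rank sum
        return WilcoxonResult(w, 1.0, "normal_approx", n1, n2, (float(np.median(a)), float(np.median(b))))
    if not has_ties and n1 + n2 <= 20:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_approx"
    w = float(res.statistic) + n1 * (n1 + 1) / 2  # U -> rank sum
    return WilcoxonResult(
        statistic=w,
        p_two_sided=float(res.pvalue),
        method=method,
        n1=n1,
        n2=n2,
        medians=(float(np.median(a)), float(np.median(b))),
    )
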