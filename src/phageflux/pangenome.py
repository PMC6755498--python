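"""Identity-threshold pan-genome clustering of predicted phage genes.

Genes are clustered into orthologous groups by pairwise protein identity:
an edge joins two genes when their best local-alignment identity,
normalized by the shorter sequence length (the blastp convention), reaches
the threshold, and clusters are the connected components.  Because phage
genes are highly diverse, the threshold is swept (40-90 %) with and
without paralogue splitting, and clusters are classified as core (present
in all genomes), soft-core (at least 90 %), shell, or singleton (exactly
one genome).

Apparent paralogues in these genomes are frequently a single gene
interrupted by an internal stop codon and re-started, annotated as two
fragments; :func:`detect_interrupted` flags such same-genome co-members
whose concatenation matches a full-length cluster member end to end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from phageflux.errors import ConfigError, InputError

logger = logging.getLogger(__name__)

SWEEP_THRESHOLDS = (40, 50, 60, 70, 80, 90)


@dataclass(frozen=True)
class GeneRecord:
    """One predicted gene: amino-acid sequence keyed by (genome, gene) ids."""

    genome_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"empty sequence for gene {self.gene_id!r}")


@dataclass
class PanGenome:
    """Clustering outcome at one (identity threshold, split flag) setting."""

    clusters: list[list[str]]  # gene ids per cluster
    presence: pd.DataFrame  # clusters x genomes, bool
    categories: dict[int, str]  # cluster index -> core/soft_core/shell/singleton
    identity_threshold: float
    split_paralogs: bool

    @property
    def size(self) -> int:
        return len(self.clusters)

    def category_counts(self) -> dict[str, int]:
        counts = {"core": 0, "soft_core": 0, "shell": 0, "singleton": 0}
        for cat in self.categories.values():
            counts[cat] += 1
        return counts

    def write_tsv(self, membership_path, presence_path) -> None:
        with open(membership_path, "w") as fh:
            fh.write("cluster\tcategory\tgene_id\n")
            for i, members in enumerate(self.clusters):
                for gid in members:
                    fh.write(f"{i}\t{self.categories[i]}\t{gid}\n")
        self.presence.astype(int).to_csv(presence_path, sep="\t")


def _aligner() -> Align.PairwiseAligner:
    # blastp-style scoring: BLOSUM62, gap open 11, extend 1, local mode
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def pairwise_identity(a: GeneRecord, b: GeneRecord, mode: str = "local") -> float:
    """Percent identity of the best alignment, over the shorter length.

    ``100 * identical aligned positions / min(len(a), len(b))``; symmetric.
    ``mode="global"`` switches to end-to-end alignment normalized the same
    way (used by the interrupted-gene screen).
    """
    aligner = _aligner()
    if mode == "global":
        aligner.mode = "global"
        aligner.end_open_gap_score = 0.0  # free end gaps: semi-global
        aligner.end_extend_gap_score = 0.0
    aln = aligner.align(a.sequence, b.sequence)
    best = aln[0]
    identities = best.counts().identities
    return 100.0 * identities / min(len(a.sequence), len(b.sequence))


def identity_matrix(genes: Sequence[GeneRecord]) -> np.ndarray:
    """Symmetric matrix of pairwise percent identities (diagonal 100)."""
    n = len(genes)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(genes[i], genes[j])
            mat[i, j] = mat[j, i] = pid
    return mat


def _components(genes, mat, threshold) -> list[list[int]]:
    g = nx.Graph()
    g.add_nodes_from(range(len(genes)))
    idx = np.argwhere(np.triu(mat >= threshold, k=1))
    g.add_edges_from((int(i), int(j)) for i, j in idx)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return comps


def cluster_genes(
    genes: Sequence[GeneRecord],
    threshold: float,
    split_paralogs: bool = False,
    precomputed_identity: np.ndarray | None = None,
    genome_ids: Sequence[str] | None = None,
) -> PanGenome:
    """Cluster genes at an identity threshold into a pan-genome.

    Clusters are connected components of the identity graph.  With
    ``split_paralogs`` on, any cluster holding two or more genes from one
    genome is re-clustered by single linkage at a stricter threshold
    (``threshold + 10``, capped at 95) so same-genome fragments can
    separate; with it off, co-genome members stay together.
    """
    if not 1 <= threshold <= 100:
        raise ConfigError("threshold must lie in [1, 100]")
    genes = list(genes)
    if genome_ids is None:
        genome_ids = sorted({g.genome_id for g in genes})
    if not genes:
        presence = pd.DataFrame(columns=list(genome_ids), dtype=bool)
        return PanGenome([], presence, {}, threshold, split_paralogs)
    keys = [(g.genome_id, g.gene_id) for g in genes]
    if len(set(keys)) != len(keys):
        raise InputError("duplicate (genome_id, gene_id) pairs")
    # clustering must not depend on input order: work in a canonical order
    order = sorted(range(len(genes)), key=lambda i: keys[i])
    genes_sorted = [genes[i] for i in order]
    if precomputed_identity is not None:
        mat = np.asarray(precomputed_identity)[np.ix_(order, order)]
    else:
        mat = identity_matrix(genes_sorted)

    comps = _components(genes_sorted, mat, threshold)
    if split_paralogs:
        strict = min(threshold + 10, 95)
        refined: list[list[int]] = []
        for comp in comps:
            genomes_in = [genes_sorted[i].genome_id for i in comp]
            if len(set(genomes_in)) < len(genomes_in):
                sub = mat[np.ix_(comp, comp)]
                for subcomp in _components(comp, sub, strict):
                    refined.append([comp[i] for i in subcomp])
            else:
                refined.append(comp)
        refined.sort(key=lambda c: c[0])
        comps = refined

    clusters = [[f"{genes_sorted[i].genome_id}|{genes_sorted[i].gene_id}" for i in comp] for comp in comps]
    presence = pd.DataFrame(
        False, index=range(len(comps)), columns=list(genome_ids), dtype=bool
    )
    for ci, comp in enumerate(comps):
        for i in comp:
            presence.loc[ci, genes_sorted[i].genome_id] = True
    n_genomes = len(genome_ids)
    categories = {}
    for ci in range(len(comps)):
        n_present = int(presence.loc[ci].sum())
        if n_present == 1:
            categories[ci] = "singleton"
        elif n_present == n_genomes:
            categories[ci] = "core"
        elif n_present >= 0.9 * n_genomes:
            categories[ci] = "soft_core"
        else:
            categories[ci] = "shell"
    return PanGenome(clusters, presence, categories, threshold, split_paralogs)


def sweep(
    genes: Sequence[GeneRecord],
    thresholds: Iterable[float] = SWEEP_THRESHOLDS,
    genome_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pan-genome summary across identity thresholds x paralogue splitting.

    Returns one row per (threshold, split) combination with the pan-genome
    size and category counts; identities are computed once and reused.
    """
    genes = list(genes)
    mat = identity_matrix(genes) if genes else None
    rows = []
    for t in thresholds:
        for split in (False, True):
            pg = cluster_genes(
                genes, t, split_paralogs=split,
                precomputed_identity=mat, genome_ids=genome_ids,
            )
            counts = pg.category_counts()
            rows.append(
                {
                    "identity": t,
                    "split_paralogs": split,
                    "pan_size": pg.size,
                    **counts,
                }
            )
    return pd.DataFrame(rows)


def detect_interrupted(
    cluster_members: Sequence[GeneRecord],
    cds: Mapping[tuple[str, str], str] | None = None,
    min_identity: float = 80.0,
) -> set[tuple[str, str]]:
    """Flag same-genome cluster co-members that are fragments of one gene.

    Two or more genes from the same genome are flagged as "interrupted"
    (not paralogous) when their concatenation aligns end to end to a
    full-length member from another genome at ``min_identity`` percent,
    normalized by the longer of the two -- genuine duplications double the
    concatenated length and fail that bound.  Requires nucleotide CDSs to
    confirm the fragments' reading frames; without them the screen is
    skipped with a notice.
    """
    if cds is None:
        warnings.warn("no CDS input; interrupted-gene screen skipped", stacklevel=2)
        return set()
    by_genome: dict[str, list[GeneRecord]] = {}
    for g in cluster_members:
        by_genome.setdefault(g.genome_id, []).append(g)
    multi = {gid: gs for gid, gs in by_genome.items() if len(gs) >= 2}
    if not multi:
        return set()
    full_length = [gs[0] for gid, gs in by_genome.items() if len(gs) == 1]
    flagged: set[tuple[str, str]] = set()
    for gid, fragments in multi.items():
        concat = GeneRecord(gid, "+".join(f.gene_id for f in fragments),
                            "".join(f.sequence for f in fragments))
        for ref in full_length:
            aligner = _aligner()
            aligner.mode = "global"
            aln = aligner.align(concat.sequence, ref.sequence)
            identities = aln[0].counts().identities
            pid = 100.0 * identities / max(len(concat.sequence), len(ref.sequence))
            if pid >= min_identity:
                flagged.update((f.genome_id, f.gene_id) for f in fragments)
                break
    return flagged
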