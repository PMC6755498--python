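"""Synthetic data with known ground truth for every pipeline stage.

Three generators, all byte-reproducible from their seeds:

* :func:`simulate_populations` -- K phage populations diverged from a
  common ancestor, each genome a mosaic of founder-derived segments drawn
  under a row-stochastic migration matrix.  This is a direct mosaic-copying
  generative model, not a coalescent: segment lengths are geometric and
  each segment names the founder it copies, which matches the copying
  HMM's own assumptions and makes genetic-flux recovery a clean
  parameter-recovery experiment.
* :func:`simulate_recombining_gene` -- recombinants of two divergent
  parental haplotypes with planted crossovers, for the four-gamete test.
* :func:`simulate_gene_families` -- protein families at controlled
  identity and presence, including the interrupted-gene ("pseudo-
  paralogue") artifact of a stop codon and re-start in mid-gene.

Default sizes mirror the real prophage panel: four populations of 4, 12,
7 and 6 genomes (uneven, as in the study sample) and ~28 kb genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from phageflux.alignio import HaplotypeAlignment
from phageflux.errors import ConfigError
from phageflux.pangenome import GeneRecord
from phageflux import study

NUCS = np.array(list("ACGT"))
AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# codons per amino acid, for emitting a CDS consistent with a protein
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


@dataclass
class SimConfig:
    """Population-simulation settings.

    ``migration[a][b]`` is the expected fraction of a population-a genome
    copied from the population-b founder; rows must sum to 1.
    ``divergence`` is the substitution rate per site separating each
    founder from the common ancestor; ``mutation_rate`` adds private
    per-site noise on top of the mosaic.  ``snp_density``, when set, thins
    founder-variable sites to approximately that per-site density.
    """

    n_pops: int = 4
    pop_sizes: tuple[int, ...] = (4, 12, 7, 6)
    genome_len: int = 28_000
    divergence: float = 0.02
    mutation_rate: float = 0.002
    migration: np.ndarray | None = None  # defaults to identity (no migration)
    mean_segment: float = 1_000.0
    snp_density: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1 or len(self.pop_sizes) != self.n_pops:
            raise ConfigError("pop_sizes must have n_pops entries")
        if self.genome_len < 1:
            raise ConfigError("genome_len must be positive")
        if self.divergence < 0 or self.mutation_rate < 0:
            raise ConfigError("rates must be non-negative")
        if self.divergence == 0 and self.mutation_rate == 0:
            raise ConfigError("no polymorphism possible: divergence and mutation both zero")
        if self.mean_segment <= 0:
            raise ConfigError("mean_segment must be positive")
        if self.migration is None:
            self.migration = np.eye(self.n_pops)
        self.migration = np.asarray(self.migration, dtype=float)
        if self.migration.shape != (self.n_pops, self.n_pops):
            raise ConfigError("migration matrix must be K x K")
        if np.any(self.migration < 0) or not np.allclose(self.migration.sum(axis=1), 1.0):
            raise ConfigError("migration rows must be non-negative and sum to 1")


def _mutate_nt(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.where(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = NUCS[NUCS != out[i]]
        out[i] = rng.choice(choices)
    return out


@dataclass
class SimTruth:
    """Ground truth emitted next to a simulated sample.

    ``migration`` is the planted matrix; ``expected_flux[a, b]`` the
    expected painting-attributed fraction (see
    :func:`expected_attributed_flux`); ``realized[sid]`` the per-individual
    fraction of sites actually copied from each founder.
    """

    migration: np.ndarray
    expected_flux: np.ndarray
    realized: dict[str, np.ndarray]


def simulate_populations(
    cfg: SimConfig,
) -> tuple[HaplotypeAlignment, dict[str, str], SimTruth]:
    """Mosaic genomes from K diverged founders under planted migration.

    Returns ``(alignment, labels, truth)``.  ``truth.expected_flux[a, b]``
    is the expected fraction of a population-a recipient's painting
    attributed to population-b donors under leave-one-out painting of this
    sample -- the migration matrix propagated through the composition of
    the donor panel (donors from any population may themselves carry
    b-derived segments at the same site and share the attribution).
    """
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_pops
    L = cfg.genome_len
    ancestor = rng.choice(NUCS, size=L)
    founders = np.stack([_mutate_nt(ancestor, cfg.divergence, rng) for _ in range(K)])
    if cfg.snp_density is not None:
        variable = np.where(np.any(founders != ancestor[None, :], axis=0))[0]
        target = int(round(cfg.snp_density * L))
        if len(variable) > target:
            revert = rng.choice(variable, size=len(variable) - target, replace=False)
            founders[:, revert] = ancestor[revert]

    records: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    realized: dict[str, np.ndarray] = {}
    for pop in range(K):
        pop_name = f"pop{pop}"
        for ind in range(cfg.pop_sizes[pop]):
            sid = f"{pop_name}_g{ind}"
            genome = np.empty(L, dtype="U1")
            copied = np.zeros(K)
            pos = 0
            while pos < L:
                seg = int(rng.geometric(1.0 / cfg.mean_segment))
                src = rng.choice(K, p=cfg.migration[pop])
                end = min(pos + seg, L)
                genome[pos:end] = founders[src, pos:end]
                copied[src] += end - pos
                pos = end
            genome = _mutate_nt(genome, cfg.mutation_rate, rng)
            records.append((sid, "".join(genome)))
            labels[sid] = pop_name
            realized[sid] = copied / L

    aln = HaplotypeAlignment(records, alphabet="nt", labels=labels)
    truth = SimTruth(
        migration=cfg.migration.copy(),
        expected_flux=expected_attributed_flux(cfg),
        realized=realized,
    )
    return aln, labels, truth


def expected_attributed_flux(cfg: SimConfig) -> np.ndarray:
    """Expected painting-attributed flux fractions implied by the design.

    At a site a population-a recipient copied from founder *f* (probability
    ``M[a, f]``), the copying model divides credit among the donors whose
    material at that site is also f-derived; a population-c donor is
    f-derived there with probability ``M[c, f]``.  Credit to population b
    is therefore ``n_b * M[b, f] / sum_c n_c * M[c, f]`` (the recipient
    itself removed from its own population's count), giving

        flux[a, b] = sum_f M[a, f] * n_b' * M[b, f] / sum_c n_c' * M[c, f]
    """
    M = cfg.migration
    K = cfg.n_pops
    sizes = np.asarray(cfg.pop_sizes, dtype=float)
    flux = np.zeros((K, K))
    for a in range(K):
        n_eff = sizes.copy()
        n_eff[a] -= 1.0  # leave-one-out
        for f in range(K):
            denom = float(n_eff @ M[:, f])
            if denom <= 0:
                continue
            for b in range(K):
                flux[a, b] += M[a, f] * n_eff[b] * M[b, f] / denom
    return flux


def simulate_recombining_gene(
    n_haps: int,
    n_sites: int,
    crossovers: int,
    seed: int = 0,
    parent_divergence: float = 0.5,
    private_mutations: int = 0,
) -> tuple[HaplotypeAlignment, list[int]]:
    """Recombinants of two divergent parents with planted crossovers.

    Two parental haplotypes differ at each site with probability
    ``parent_divergence``; each of the remaining haplotypes starts from a
    random parent and switches parents at the planted crossover positions.
    ``private_mutations`` infinite-sites-style singletons are then added at
    previously monomorphic sites.  Returns the alignment and the sorted
    planted breakpoint positions (0-based: a crossover at p separates
    columns p-1 and p).
    """
    if crossovers >= n_sites:
        raise ConfigError("crossovers must be < n_sites")
    if crossovers < 0 or n_haps < 2:
        raise ConfigError("need crossovers >= 0 and n_haps >= 2")
    rng = np.random.default_rng(seed)
    parent_a = rng.choice(NUCS, size=n_sites)
    parent_b = parent_a.copy()
    diff = rng.random(n_sites) < parent_divergence
    for i in np.where(diff)[0]:
        parent_b[i] = rng.choice(NUCS[NUCS != parent_a[i]])
    parents = np.stack([parent_a, parent_b])

    breakpoints = sorted(
        int(p) for p in rng.choice(np.arange(1, n_sites), size=crossovers, replace=False)
    )
    records = [("hap0", "".join(parent_a)), ("hap1", "".join(parent_b))]
    for h in range(2, n_haps):
        cur = int(rng.integers(2))
        seq = np.empty(n_sites, dtype="U1")
        prev = 0
        for bp in breakpoints + [n_sites]:
            # each recombinant flips parents at a random subset of planted points
            seq[prev:bp] = parents[cur, prev:bp]
            prev = bp
            if rng.random() < 0.5:
                cur = 1 - cur
        records.append((f"hap{h}", "".join(seq)))

    if private_mutations:
        arr = np.array([list(s) for _, s in records], dtype="U1")
        mono = [j for j in range(n_sites) if len(set(arr[:, j].tolist())) == 1]
        rng.shuffle(mono)
        for j in mono[:private_mutations]:
            h = int(rng.integers(len(records)))
            arr[h, j] = rng.choice(NUCS[NUCS != arr[h, j]])
        records = [(sid, "".join(arr[i])) for i, (sid, _) in enumerate(records)]

    return HaplotypeAlignment(records, alphabet="nt"), breakpoints


def _mutate_protein(seq: np.ndarray, n_subs: int, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    if n_subs <= 0:
        return out
    sites = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    for i in sites:
        out[i] = rng.choice(AMINO[AMINO != out[i]])
    return out


def simulate_gene_families(
    n_genomes: int,
    families: list[tuple[float, float, bool]],
    seed: int = 0,
    length: int = 250,
) -> tuple[list[GeneRecord], dict[tuple[str, str], str]]:
    """Protein families at controlled identity and presence.

    Each family is ``(target_identity %, presence_fraction, interrupted)``:
    an ancestral protein is mutated independently per genome so that two
    family members match at about ``target_identity`` percent of sites
    (each copy carries half the implied divergence); the family appears in
    ``round(presence_fraction * n_genomes)`` genomes.  With ``interrupted``
    on, one carrier's copy is emitted as 5' and 3' fragments whose combined
    CDS contains an internal stop codon followed by a new start.  Returns
    the gene records and a CDS map keyed by (genome, gene).
    """
    rng = np.random.default_rng(seed)
    genomes = [f"genome{i}" for i in range(n_genomes)]
    genes: list[GeneRecord] = []
    cds: dict[tuple[str, str], str] = {}
    for fi, (identity, presence, interrupted) in enumerate(families):
        if not (0 < presence <= 1) or not (0 < identity <= 100):
            raise ConfigError("presence in (0,1], identity in (0,100]")
        ancestor = rng.choice(AMINO, size=length)
        n_present = max(1, round(presence * n_genomes))
        carriers = sorted(rng.choice(n_genomes, size=n_present, replace=False).tolist())
        # pairwise identity ~ (1 - d)^2 for per-copy divergence d
        per_copy = 1.0 - np.sqrt(identity / 100.0)
        n_subs = int(round(per_copy * length))
        interrupted_carrier = carriers[0] if interrupted and carriers else None
        for gi in carriers:
            protein = _mutate_protein(ancestor, n_subs, rng)
            gname = f"fam{fi}"
            nt = "ATG" + "".join(_CODON[a] for a in protein) + "TAA"
            if gi == interrupted_carrier:
                cut = length // 2
                five = "".join(protein[:cut])
                three = "".join(protein[cut:])
                genes.append(GeneRecord(genomes[gi], f"{gname}_5p", five))
                genes.append(GeneRecord(genomes[gi], f"{gname}_3p", three))
                # one CDS with an internal stop then a fresh start codon
                cds[(genomes[gi], f"{gname}_5p")] = (
                    "ATG" + "".join(_CODON[a] for a in protein[:cut]) + "TAA"
                )
                cds[(genomes[gi], f"{gname}_3p")] = (
                    "ATG" + "".join(_CODON[a] for a in protein[cut:]) + "TAA"
                )
            else:
                genes.append(GeneRecord(genomes[gi], gname, "".join(protein)))
                cds[(genomes[gi], gname)] = nt
    return genes, cds


def example_panel_alignment(seed: int = 0, length: int = 2_000) -> HaplotypeAlignment:
    """Synthetic stand-in alignment over the published genome panel.

    Sequences are simulated (the real genomes live in public archives) but
    the panel's documented duplicate structure is reproduced exactly: each
    genome in :data:`phageflux.study.IDENTICAL_PAIRS` is emitted
    byte-identical to its partner, so the exclusion filter behaves as it
    does on the real panel.
    """
    rng = np.random.default_rng(seed)
    copies = dict(study.IDENTICAL_PAIRS)
    seqs: dict[str, str] = {}
    for gid, _, _ in study.GENOME_PANEL:
        if gid in copies:
            continue
        seqs[gid] = "".join(rng.choice(NUCS, size=length))
    for copy_id, original in copies.items():
        seqs[copy_id] = seqs[original]
    records = [(gid, seqs[gid]) for gid, _, _ in study.GENOME_PANEL]
    return HaplotypeAlignment(records, alphabet="nt", labels=study.panel_labels())
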