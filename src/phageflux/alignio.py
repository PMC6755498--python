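"""Alignment I/O, genome-exclusion filtering, core-SNP extraction and
per-gene population-genetic statistics.

Coordinates are 0-based half-open throughout; conversion happens only at
I/O boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from phageflux.errors import (
    AlignmentError,
    DegenerateInputError,
    InputError,
    MetadataError,
)

logger = logging.getLogger(__name__)

NT_RESIDUES = frozenset("ACGT")
NT_AMBIGUOUS = frozenset("NRYSWKMBDHV")
AA_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
AA_AMBIGUOUS = frozenset("XBZJUO*")
GAP = "-"


@dataclass
class HaplotypeAlignment:
    """Gap-aware multiple alignment with sample metadata.

    Parameters
    ----------
    records
        Ordered ``(sample_id, sequence)`` pairs.  Sequences are uppercase
        residue strings of identical length.
    alphabet
        ``"nt"`` or ``"aa"``.
    labels
        Optional map from sample id to population label.
    """

    records: list[tuple[str, str]]
    alphabet: str = "nt"
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("alignment has no records")
        if self.alphabet not in ("nt", "aa"):
            raise InputError(f"unknown alphabet {self.alphabet!r}")
        norm = [(sid, seq.upper()) for sid, seq in self.records]
        lengths = {len(seq) for _, seq in norm}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        ids = [sid for sid, _ in norm]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise MetadataError(f"duplicate sample ids: {dupes}")
        if self.alphabet == "nt":
            allowed = NT_RESIDUES | NT_AMBIGUOUS | {GAP}
        else:
            allowed = AA_RESIDUES | AA_AMBIGUOUS | {GAP}
        for sid, seq in norm:
            bad = set(seq) - allowed
            if bad:
                raise AlignmentError(f"illegal residues {sorted(bad)} in record {sid!r}")
        self.records = norm
        if self.labels is not None:
            unknown = set(self.labels) - set(ids)
            if unknown:
                raise MetadataError(f"labels for unknown samples: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    @property
    def n_samples(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def sequence(self, sample_id: str) -> str:
        for sid, seq in self.records:
            if sid == sample_id:
                return seq
        raise MetadataError(f"no such sample: {sample_id!r}")

    def to_array(self) -> np.ndarray:
        """Residues as an (n_samples, length) array of single characters."""
        return np.array([list(seq) for _, seq in self.records], dtype="U1")

    def subset(self, sample_ids: Sequence[str]) -> "HaplotypeAlignment":
        keep = set(sample_ids)
        recs = [(sid, seq) for sid, seq in self.records if sid in keep]
        labels = None
        if self.labels is not None:
            labels = {sid: lab for sid, lab in self.labels.items() if sid in keep}
        return HaplotypeAlignment(recs, alphabet=self.alphabet, labels=labels)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.records:
                fh.write(f">{sid}\n{seq}\n")


@dataclass
class SnpHaplotypes:
    """Biallelic core-SNP matrix with alignment positions.

    ``matrix[i, l]`` is the 0/1 allele of sample *i* at SNP *l*; allele 0 is
    the major allele (ties broken toward the alphabetically first residue).
    ``positions`` are strictly increasing 0-based alignment columns;
    ``distances[l] = positions[l+1] - positions[l]``.
    """

    sample_ids: list[str]
    matrix: np.ndarray
    positions: np.ndarray
    alleles: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise InputError("SNP matrix must be 2-D")
        if self.matrix.shape[0] != len(self.sample_ids):
            raise InputError("SNP matrix rows must match sample ids")
        if self.matrix.shape[1] != len(self.positions):
            raise InputError("SNP matrix columns must match positions")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) >= 1):
            raise InputError("positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    @property
    def distances(self) -> np.ndarray:
        return np.diff(self.positions)

    def write_tsv(self, matrix_path: str | Path, positions_path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.matrix, index=self.sample_ids, columns=[int(p) for p in self.positions]
        ).to_csv(matrix_path, sep="\t")
        with open(positions_path, "w") as fh:
            for p in self.positions:
                fh.write(f"{int(p)}\n")


@dataclass
class GeneStats:
    """Per-gene summary used by the recombination-intensity regression.

    ``n`` aligned sequences, ``L`` gap-filtered length (nt), ``S``
    segregating sites, ``pi`` nucleotide diversity per site, ``rmin``
    minimum recombination events and ``rmin_per_nt = rmin / L``.
    """

    gene_id: str
    n: int
    L: int
    S: int
    pi: float
    rmin: int = 0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise InputError(f"gene {self.gene_id}: non-positive length")
        if not (0.0 <= self.pi <= 1.0):
            raise InputError(f"gene {self.gene_id}: pi out of [0,1]")
        if self.rmin < 0 or self.rmin > max(self.S - 1, 0):
            raise InputError(f"gene {self.gene_id}: rmin out of range")

    @property
    def rmin_per_nt(self) -> float:
        return self.rmin / self.L


def read_alignment(path: str | Path, alphabet: str = "nt") -> HaplotypeAlignment:
    """Read a multi-FASTA alignment.

    All records must have identical length; residues are case-normalized.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return HaplotypeAlignment(records, alphabet=alphabet)


def apply_exclusions(
    genomes: HaplotypeAlignment,
    drop_duplicates: bool = True,
    drop_ids: Iterable[str] = (),
) -> HaplotypeAlignment:
    """Remove named genomes and byte-identical duplicates.

    A genome is a duplicate if its aligned sequence is string-identical to
    an earlier retained genome.  Every removal is logged with its reason.
    Idempotent: re-applying with the same arguments is a no-op.
    """
    drop_ids = list(drop_ids)
    unknown = set(drop_ids) - set(genomes.sample_ids)
    if unknown:
        raise MetadataError(f"drop_ids not in alignment: {sorted(unknown)}")
    dropset = set(drop_ids)
    kept: list[tuple[str, str]] = []
    seen: dict[str, str] = {}
    for sid, seq in genomes.records:
        if sid in dropset:
            logger.info("excluding %s: listed for removal", sid)
            continue
        if drop_duplicates and seq in seen:
            logger.info("excluding %s: identical to %s", sid, seen[seq])
            continue
        if drop_duplicates:
            seen[seq] = sid
        kept.append((sid, seq))
    labels = None
    if genomes.labels is not None:
        keep_ids = {sid for sid, _ in kept}
        labels = {sid: lab for sid, lab in genomes.labels.items() if sid in keep_ids}
    return HaplotypeAlignment(kept, alphabet=genomes.alphabet, labels=labels)


def extract_core_snps(aln: HaplotypeAlignment) -> SnpHaplotypes:
    """Extract biallelic, gap-free, unambiguous polymorphic columns.

    A column qualifies when every sample carries one of exactly two plain
    nucleotides (no gap, no ambiguity code).  Allele 0 is the major allele;
    on a frequency tie the alphabetically first residue is coded 0.
    """
    if aln.alphabet != "nt":
        raise InputError("core-SNP extraction requires a nucleotide alignment")
    if aln.n_samples < 2:
        raise InputError("need at least two samples")
    arr = aln.to_array()
    positions: list[int] = []
    columns: list[np.ndarray] = []
    alleles: list[tuple[str, str]] = []
    for col in range(arr.shape[1]):
        residues = arr[:, col]
        uniq = set(residues.tolist())
        if not uniq <= NT_RESIDUES:
            continue
        if len(uniq) != 2:
            continue
        a, b = sorted(uniq)
        count_a = int(np.sum(residues == a))
        count_b = arr.shape[0] - count_a
        # major allele coded 0; alphabetical tie-break means `a` wins ties
        if count_a >= count_b:
            zero, one = a, b
        else:
            zero, one = b, a
        columns.append((residues == one).astype(np.int8))
        positions.append(col)
        alleles.append((zero, one))
    if not columns:
        logger.warning("no qualifying core-SNP columns found")
        matrix = np.zeros((aln.n_samples, 0), dtype=np.int8)
    else:
        matrix = np.column_stack(columns)
    return SnpHaplotypes(
        sample_ids=aln.sample_ids,
        matrix=matrix,
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
    )


def gap_filter(aln: HaplotypeAlignment) -> np.ndarray:
    """Residue array with every gap-containing column removed (complete deletion)."""
    arr = aln.to_array()
    keep = ~np.any(arr == GAP, axis=0)
    return arr[:, keep]


def nucleotide_diversity(gene_aln: HaplotypeAlignment) -> tuple[float, int, int]:
    """Nucleotide diversity pi with gap-filtered length L and segregating sites S.

    Columns containing any gap are removed first (complete deletion).  pi is
    the mean over unordered sample pairs of (pairwise differences / L).
    """
    if gene_aln.n_samples < 2:
        raise InputError("nucleotide diversity needs at least two sequences")
    arr = gap_filter(gene_aln)
    L = arr.shape[1]
    if L == 0:
        raise DegenerateInputError("no ungapped columns remain")
    n = arr.shape[0]
    S = int(np.sum([len(set(arr[:, j].tolist())) > 1 for j in range(L)]))
    total_diff = 0
    for i in range(n):
        for j in range(i + 1, n):
            total_diff += int(np.sum(arr[i] != arr[j]))
    n_pairs = n * (n - 1) // 2
    pi = total_diff / (n_pairs * L)
    return pi, L, S
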