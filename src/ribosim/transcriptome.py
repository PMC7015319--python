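"""Transcriptome construction and the tRNA/codon-usage matching problem.

A transcriptome is a weighted collection of codon-explicit ORFs: unique
gene sequences plus integer copy numbers.  Sequences are built the way
an efficiency-matched cell would look: codon frequencies are derived
from tRNA abundances under an equal-split rule (a tRNA reading several
codons contributes its copy number in equal shares to each), genes keep
their reading-frame lengths but their codons are i.i.d. draws from those
frequencies (amino-acid identity is deliberately ignored), and per-gene
copy numbers come from a three-category expression mixture: high
(probability 5%, Poisson with lambda = 6.8), intermediate (35%,
geometric p(k) = (1-lambda)^k * lambda with lambda = 0.58) and low (60%,
geometric with lambda = 0.93).

The inverse problem — finding tRNA abundances whose equal-split usage
matches a given codon-frequency vector — is solved by nonnegative least
squares.  Wobble cross-recognition makes the system degenerate (several
tRNA profiles can imply the same usage), which is detected and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.optimize import nnls

from .genetics import (DecodeMap, START_INDEX, STOP_CODONS, codon_index,
                       codon_str)
from .state import MRNAInstance, validate_orf

__all__ = [
    "codon_usage_from_trnas",
    "trnas_from_codon_usage",
    "MatchResult",
    "sample_gene_codons",
    "CopyNumberModel",
    "sample_copy_number",
    "GeneRecord",
    "Transcriptome",
    "build_transcriptome",
    "rebuild_with_usage",
]


# --- codon usage <-> tRNA abundance ------------------------------------


def codon_usage_from_trnas(
    trna_counts, decode_map: DecodeMap, normalize: bool = True
) -> np.ndarray:
    """Codon frequencies implied by tRNA abundances under equal split.

    Each tRNA's count is divided equally among its cognate codons (a
    Lys-tRNA pool of 4360 reading AAA and AAG contributes 2180 to each);
    contributions are summed per codon and, with ``normalize``, scaled to
    sum to one over the sense-codon alphabet.  Returns a vector indexed
    like ``decode_map.alphabet``.  Codons left with zero contribution
    trigger a warning (they would never be decodable in proportion).
    """
    counts = _as_count_vector(trna_counts, decode_map)
    if (counts < 0).any():
        raise ValueError("negative tRNA count")
    contrib = np.zeros(len(decode_map.alphabet))
    pos = {c: i for i, c in enumerate(decode_map.alphabet)}
    for s, codons in enumerate(decode_map.codons_of):
        share = counts[s] / len(codons)
        for c in codons:
            contrib[pos[c]] += share
    if normalize:
        total = contrib.sum()
        if total <= 0:
            raise ValueError("all tRNA counts are zero")
        freqs = contrib / total
        zero = [codon_str(decode_map.alphabet[i])
                for i in np.nonzero(freqs == 0)[0]]
        if zero:
            import warnings

            warnings.warn(
                "codons with zero usage (no decoding tRNA abundance): "
                + ", ".join(zero), stacklevel=2,
            )
        return freqs
    return contrib


@dataclass
class MatchResult:
    """Solution of the tRNA/codon-usage matching problem."""

    counts: np.ndarray          # per-tRNA abundances (continuous)
    residual: np.ndarray        # per-codon usage residual of the solution
    feasible: bool              # max |residual| < tol
    degenerate: bool            # multiple solutions exist (rank-deficient)

    def integer_counts(self, total: int) -> np.ndarray:
        """Largest-remainder rounding to integers summing to ``total``."""
        x = self.counts / self.counts.sum() * total
        base = np.floor(x).astype(int)
        short = int(total - base.sum())
        order = np.argsort(-(x - base))
        base[order[:short]] += 1
        return base


def trnas_from_codon_usage(
    codon_freqs,
    decode_map: DecodeMap,
    total_trna: float = 1.0,
    tol: float = 1e-6,
) -> MatchResult:
    """tRNA abundances whose equal-split usage reproduces ``codon_freqs``.

    Solves min ||A x - f|| with x >= 0, where column s of A spreads tRNA
    s equally over its cognate codons.  Cross-recognition typically makes
    the solution non-unique; the returned split is the minimum-norm NNLS
    solution and ``degenerate`` flags the non-uniqueness.  Infeasibility
    (no nonnegative profile can produce the usage) is reported via
    ``feasible=False`` and the residual, never silently.
    """
    f = np.asarray(codon_freqs, dtype=float)
    if f.shape != (len(decode_map.alphabet),):
        raise ValueError("codon_freqs must be indexed like the decode-map "
                         "alphabet")
    if not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ValueError("codon frequencies must sum to 1")
    S = decode_map.n_species
    C = len(decode_map.alphabet)
    pos = {c: i for i, c in enumerate(decode_map.alphabet)}
    A = np.zeros((C, S))
    for s, codons in enumerate(decode_map.codons_of):
        for c in codons:
            A[pos[c], s] = 1.0 / len(codons)
    x, _ = nnls(A, f)
    residual = A @ x - f
    feasible = bool(np.max(np.abs(residual)) < tol)
    degenerate = bool(np.linalg.matrix_rank(A) < S)
    return MatchResult(x * total_trna, residual, feasible, degenerate)


def _as_count_vector(trna_counts, decode_map: DecodeMap) -> np.ndarray:
    if isinstance(trna_counts, dict):
        return np.array([float(trna_counts[name])
                         for name in decode_map.trna_names])
    arr = np.asarray(trna_counts, dtype=float)
    if arr.shape != (decode_map.n_species,):
        raise ValueError("tRNA count vector has the wrong length")
    return arr


# --- sequence and copy-number sampling ---------------------------------


def sample_gene_codons(
    length_aa: int,
    codon_freqs,
    decode_map: DecodeMap,
    rng: np.random.Generator,
    stop_codon: Optional[str] = None,
) -> np.ndarray:
    """One ORF: start codon + ``length_aa`` i.i.d. sense codons + stop.

    The stop codon is drawn uniformly from UAA/UAG/UGA unless fixed.
    Returned as an integer codon array of length ``length_aa + 2``
    (3*(length_aa+2) nucleotides).
    """
    if length_aa < 1:
        raise ValueError("length_aa must be >= 1")
    f = np.asarray(codon_freqs, dtype=float)
    alphabet = np.asarray(decode_map.alphabet)
    body = rng.choice(alphabet, size=length_aa, p=f / f.sum())
    if stop_codon is None:
        stop = codon_index(sorted(STOP_CODONS)[rng.integers(3)])
    else:
        stop = codon_index(stop_codon)
    return np.concatenate(([START_INDEX], body, [stop])).astype(np.int16)


@dataclass
class CopyNumberModel:
    """Three-category expression mixture for mRNA copy numbers.

    Categories (high, intermediate, low) are drawn with probabilities
    5/35/60%; the high category samples a Poisson with lambda=6.8, the
    others a geometric p(k) = (1-lambda)^k * lambda with lambda = 0.58
    and 0.93.  The raw distributions put mass on k=0; by default a
    selected gene is considered expressed, so k=0 is resampled away
    (switch off with ``zero_truncate=False``, which then redraws the
    whole gene selection upstream).
    """

    p_categories: tuple = (0.05, 0.35, 0.60)
    poisson_lambda: float = 6.8
    geometric_lambdas: tuple = (0.58, 0.93)
    zero_truncate: bool = True

    CATEGORIES = ("high", "intermediate", "low")

    def sample(self, rng: np.random.Generator,
               category: Optional[str] = None) -> tuple[str, int]:
        if category is None:
            category = self.CATEGORIES[
                rng.choice(3, p=np.asarray(self.p_categories))]
        while True:
            if category == "high":
                k = int(rng.poisson(self.poisson_lambda))
            else:
                lam = self.geometric_lambdas[
                    0 if category == "intermediate" else 1]
                # numpy's geometric has support {1,2,...}; shift to the
                # printed parameterisation p(k) = (1-lam)^k lam, k >= 0
                k = int(rng.geometric(lam)) - 1
            if k >= 1 or not self.zero_truncate:
                return category, k


def sample_copy_number(
    rng: np.random.Generator,
    model: Optional[CopyNumberModel] = None,
    category: Optional[str] = None,
) -> tuple[str, int]:
    """Draw (expression category, copy number k) for one gene."""
    return (model or CopyNumberModel()).sample(rng, category)


# --- the transcriptome container ---------------------------------------


@dataclass
class GeneRecord:
    gene_id: str
    codons: np.ndarray
    copies: int

    @property
    def n_nt(self) -> int:
        return 3 * len(self.codons)

    @property
    def length_aa(self) -> int:
        return len(self.codons) - 2


@dataclass
class Transcriptome:
    """Unique gene sequences with copy numbers."""

    genes: list[GeneRecord] = field(default_factory=list)

    @property
    def n_mrnas(self) -> int:
        """N: total mRNA molecules."""
        return sum(g.copies for g in self.genes)

    @property
    def n_nt(self) -> int:
        """N_nt: total nucleotides over all copies."""
        return sum(g.copies * g.n_nt for g in self.genes)

    def validate(self) -> None:
        for g in self.genes:
            validate_orf(g.codons)
            if g.copies < 1:
                raise ValueError(f"gene {g.gene_id} has copies < 1")

    def mrna_instances(self) -> list[MRNAInstance]:
        """Expand to one MRNAInstance per copy (shared codon arrays)."""
        out = []
        for gi, g in enumerate(self.genes):
            for _ in range(g.copies):
                out.append(MRNAInstance(g.gene_id, g.codons, gene_index=gi,
                                        validate=False))
        return out

    def codon_counts(self, alphabet: Sequence[int]) -> np.ndarray:
        """Copy-weighted sense-codon counts over the body of each ORF."""
        pos = {c: i for i, c in enumerate(alphabet)}
        counts = np.zeros(len(alphabet))
        for g in self.genes:
            for c in g.codons[1:-1]:
                counts[pos[int(c)]] += g.copies
        return counts

    # -- I/O -------------------------------------------------------------

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq("".join(codon_str(int(c)) for c in g.codons)),
                      id=g.gene_id, description=f"copies={g.copies}")
            for g in self.genes
        ]
        SeqIO.write(records, path, "fasta")

    def to_copies_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tcopies\n")
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{g.copies}\n")

    @classmethod
    def from_fasta(cls, fasta_path, copies_path=None) -> "Transcriptome":
        copies: dict[str, int] = {}
        if copies_path is not None:
            with open(copies_path) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith("gene_id"):
                        continue
                    gid, k = line.split("\t")
                    copies[gid] = int(k)
        genes = []
        for rec in SeqIO.parse(fasta_path, "fasta"):
            seq = str(rec.seq).upper().replace("T", "U")
            if len(seq) % 3:
                raise ValueError(f"gene {rec.id}: length not a codon multiple")
            codons = np.array(
                [codon_index(seq[i:i + 3]) for i in range(0, len(seq), 3)],
                dtype=np.int16,
            )
            validate_orf(codons)
            k = copies.get(rec.id)
            if k is None:
                # fall back to a copies=N tag in the description
                k = 1
                for tok in rec.description.split():
                    if tok.startswith("copies="):
                        k = int(tok.split("=", 1)[1])
            genes.append(GeneRecord(rec.id, codons, k))
        return cls(genes)


# --- builders ----------------------------------------------------------


def build_transcriptome(
    gene_lengths: Sequence[tuple[str, int]],
    codon_freqs,
    decode_map: DecodeMap,
    rng: np.random.Generator,
    target_nt: Optional[int] = None,
    target_n: Optional[int] = None,
    length_window_nt: Optional[tuple[int, int]] = None,
    copy_model: Optional[CopyNumberModel] = None,
) -> Transcriptome:
    """Accumulate randomly selected genes until a size target is crossed.

    Genes are drawn uniformly from ``gene_lengths`` (pairs of id and
    reading-frame length in amino acids), optionally restricted to a
    total-nucleotide window for length-biased builds; each draw gets a
    sampled copy number and a freshly sampled codon sequence.  Stops as
    soon as total nucleotides reach ``target_nt`` or total mRNAs reach
    ``target_n`` (whichever is given; the final gene may overshoot by at
    most its own length).
    """
    if target_nt is None and target_n is None:
        raise ValueError("one of target_nt / target_n is required")
    pool = list(gene_lengths)
    if length_window_nt is not None:
        lo, hi = length_window_nt
        pool = [(gid, L) for gid, L in pool if lo <= 3 * (L + 2) <= hi]
        if not pool:
            raise ValueError(
                f"no genes with total length in {length_window_nt} nt")
    if not pool:
        raise ValueError("empty gene-length list")
    model = copy_model or CopyNumberModel()
    genes: list[GeneRecord] = []
    n_nt = 0
    n = 0
    counter = 0
    while ((target_nt is None or n_nt < target_nt)
           and (target_n is None or n < target_n)):
        gid, L = pool[rng.integers(len(pool))]
        _, k = model.sample(rng)
        codons = sample_gene_codons(L, codon_freqs, decode_map, rng)
        genes.append(GeneRecord(f"{gid}.{counter}", codons, k))
        counter += 1
        n_nt += k * 3 * (L + 2)
        n += k
    return Transcriptome(genes)


def rebuild_with_usage(
    transcriptome: Transcriptome,
    codon_freqs,
    decode_map: DecodeMap,
    rng: np.random.Generator,
) -> Transcriptome:
    """Mismatch generator: identical genes, copy numbers and reading-frame
    lengths, but codons resampled from a different usage vector.  N,
    N_nt and every per-gene length are preserved exactly."""
    genes = []
    for g in transcriptome.genes:
        stop = codon_str(int(g.codons[-1]))
        codons = sample_gene_codons(g.length_aa, codon_freqs, decode_map,
                                    rng, stop_codon=stop)
        genes.append(GeneRecord(g.gene_id, codons, g.copies))
    return Transcriptome(genes)
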