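"""Deterministic toy-system generators.

Every other module is testable without downloads: a toy spec describes a
micro-cell (a few short genes over a reduced codon alphabet, a couple of
tRNA species, a handful of ribosomes) with round-number rates chosen so
that analytic limits are tight — one rate-limiting step (peptidyl
transfer at 10 /s) an order of magnitude slower than everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Optional

import numpy as np

from .genetics import DecodeMap
from .rates import DEFAULT_RATES, RateTable
from .species import SpeciesPools
from .state import CellState
from .transcriptome import (GeneRecord, Transcriptome, codon_usage_from_trnas,
                            sample_gene_codons)

__all__ = [
    "ToySpec",
    "toy_decode_map",
    "toy_rate_table",
    "make_toy_system",
    "make_toy_state",
    "make_synthetic_gene_lengths",
]

#: round-number toy rates: every first-order step at 100 /s except the
#: rate-limiting peptidyl transfer at 10 /s; associations diffusion-fast
_TOY_FIRST_ORDER = 100.0
_TOY_LIMITING = 10.0
_TOY_SECOND_ORDER = 1.0e8


@dataclass
class ToySpec:
    """Parameters of a deterministic micro-cell."""

    n_genes: int = 3
    length_aa: tuple = (20, 20)          # inclusive range of ORF lengths
    alphabet: tuple = ("GCU", "AAA")     # sense codons in play
    n_trna_species: int = 2
    n_ribosomes: int = 5
    trna_each: int = 20
    copies_each: int = 1
    pool_sizes: dict = field(default_factory=dict)
    volume_um3: float = 1.0e-3
    seed: int = 0
    rate_overrides: dict = field(default_factory=dict)
    tc_off: bool = False


def toy_decode_map(spec: ToySpec) -> DecodeMap:
    """Round-robin assignment of alphabet codons to tRNA species."""
    if spec.n_trna_species < 1:
        raise ValueError("need at least one tRNA species")
    if len(spec.alphabet) < 1:
        raise ValueError("alphabet too small: no sense codons to assign")
    if spec.n_trna_species > len(spec.alphabet):
        raise ValueError(
            "alphabet too small: more tRNA species than codons")
    cognates: dict[str, list[str]] = {
        f"tRNA{j}": [] for j in range(spec.n_trna_species)
    }
    for i, codon in enumerate(spec.alphabet):
        cognates[f"tRNA{i % spec.n_trna_species}"].append(codon)
    return DecodeMap(cognates, alphabet=spec.alphabet)


def toy_rate_table(spec: ToySpec) -> RateTable:
    rates = {}
    for name, (value, order) in DEFAULT_RATES.items():
        if value == 0.0:
            rates[name] = (0.0, order)
        elif order == 2:
            rates[name] = (_TOY_SECOND_ORDER, 2)
        elif name == "k_peptidyl":
            rates[name] = (_TOY_LIMITING, 1)
        else:
            rates[name] = (_TOY_FIRST_ORDER, 1)
    # a small free-TC dissociation rate keeps tiny toy cells ergodic: with
    # only a handful of Ef-Tu, every copy can otherwise end up trapped in
    # ternary complexes of the species the next codon does not need
    rates["k_tc_dissoc"] = (2.0, 1)
    for name, value in spec.rate_overrides.items():
        rates[name] = (float(value), rates[name][1])
    return RateTable(rates, spec.volume_um3)


def make_toy_system(
    spec: Optional[ToySpec] = None,
) -> tuple[Transcriptome, SpeciesPools, RateTable, DecodeMap]:
    """A complete runnable micro-cell, deterministic under the seed."""
    spec = spec or ToySpec()
    dm = toy_decode_map(spec)
    rng = np.random.default_rng(spec.seed)
    usage = codon_usage_from_trnas(np.ones(dm.n_species), dm)
    lo, hi = spec.length_aa
    genes = []
    for i in range(spec.n_genes):
        length = int(rng.integers(lo, hi + 1))
        codons = sample_gene_codons(length, usage, dm, rng, stop_codon="UAA")
        genes.append(GeneRecord(f"toy{i}", codons, spec.copies_each))
    transcriptome = Transcriptome(genes)
    transcriptome.validate()

    p = dict(
        EfTu=8 * spec.n_ribosomes,
        EfTs=spec.n_ribosomes,
        EfG=spec.n_ribosomes,
        RF1=max(2, spec.n_ribosomes // 2),
        RF2=max(2, spec.n_ribosomes // 2),
        RF3=max(2, spec.n_ribosomes // 2),
        RRF=max(2, spec.n_ribosomes // 2),
    )
    p.update(spec.pool_sizes)
    trna = np.full(dm.n_species, spec.trna_each, dtype=np.int64)
    kw = dict(
        n_trna_species=dm.n_species,
        free_30S_PIC=spec.n_ribosomes,
        free_50S=spec.n_ribosomes,
        EfTu_GTP=p["EfTu"],
        Ts_free=p["EfTs"],
        EfG_GTP=p["EfG"],
        RF1=p["RF1"],
        RF2=p["RF2"],
        RF3_GTP=p["RF3"],
        RRF=p["RRF"],
    )
    if spec.tc_off:
        kw["trna_free_tc"] = trna
    else:
        kw["trna_charged"] = trna
    pools = SpeciesPools(**kw)
    return transcriptome, pools, toy_rate_table(spec), dm


def make_toy_state(spec: Optional[ToySpec] = None) -> CellState:
    """Toy system wrapped into a ready-to-run cell state."""
    spec = spec or ToySpec()
    transcriptome, pools, rates, dm = make_toy_system(spec)
    return CellState(transcriptome.mrna_instances(), pools, rates, dm,
                     tc_off=spec.tc_off)


def make_synthetic_gene_lengths(
    n: int,
    mean_aa: float = 150.0,
    sigma: float = 0.45,
    seed: int = 0,
    min_aa: int = 5,
) -> list[tuple[str, int]]:
    """Reproducible synthetic gene-length list (log-normal, in amino
    acids) standing in for a proteome length table."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu = log(mean_aa) - 0.5 * sigma ** 2
    lengths = np.maximum(
        np.rint(rng.lognormal(mu, sigma, size=n)).astype(int), min_aa)
    return [(f"g{i:05d}", int(L)) for i, L in enumerate(lengths)]
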