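"""Cell configuration: pool scaling, presets, experiment arms.

A cell is specified by its ribosome count, volume, per-ribosome ratios
of every translational factor, a tRNA abundance profile, a rate table
and a transcriptome.  All factor and tRNA totals scale linearly with the
ribosome count, so a user only chooses the number of ribosomes and the
mRNA sequences; everything else follows from the ratio table.

Scaled-down cells keep in-vivo concentrations by shrinking the volume
with the ribosome count relative to a reference cell of 15,000 ribosomes
in 1.0 um^3 (the 50S count implied by a 1.2 Mnt transcriptome at ~86%
activity and ~93 nt spacing).  A 100-ribosome miniature cell is then a
faithful, if noisier, replica of the full-size kinetics: every per-pair
bimolecular rate and every per-molecule first-order rate is unchanged.

Named presets reproduce the standard experiment shapes: growth-rate-like
cells, codon-bias mismatch arms, the instant-recycle (TC formation off)
arm, and the factor-doubling arms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .genetics import DecodeMap, default_decode_map, ecoli_trna_counts
from .rates import RateTable
from .species import SpeciesPools
from .state import CellState
from .transcriptome import (Transcriptome, build_transcriptome,
                            codon_usage_from_trnas)

__all__ = [
    "DEFAULT_RATIOS",
    "REFERENCE_RIBOSOMES",
    "REFERENCE_NT_PER_RIBOSOME",
    "CellConfig",
    "scale_pools",
    "distribute_trna",
    "toggle_tc_reactions",
    "scaled_volume",
    "full_scale_preset",
    "FULL_SCALE_PRESETS",
]

#: per-ribosome copy-number ratios for the translational apparatus,
#: Bremer-and-Dennis-style defaults (editable, not hard-coded truth)
DEFAULT_RATIOS: dict[str, float] = {
    "30S": 1.0,
    "50S": 1.0,
    "EfTu": 8.0,
    "EfTs": 1.0,
    "EfG": 1.0,
    "RF1": 0.15,
    "RF2": 0.25,
    "RF3": 0.2,
    "RRF": 0.6,
    "tRNA": 9.5,
}

#: reference cell: ribosomes in 1.0 um^3 at mu ~ 1.0 doublings/h
REFERENCE_RIBOSOMES = 15000
#: transcriptome nucleotides per ribosome in the reference cell
REFERENCE_NT_PER_RIBOSOME = 80


def scaled_volume(n_ribosomes: int) -> float:
    """Volume (um^3) preserving reference concentrations at this size."""
    return n_ribosomes / REFERENCE_RIBOSOMES


def distribute_trna(total: int, profile, decode_map: DecodeMap) -> np.ndarray:
    """Split a total tRNA budget over species proportionally to a
    profile (dict or vector), largest-remainder rounding to integers."""
    if isinstance(profile, dict):
        w = np.array([float(profile[name]) for name in decode_map.trna_names])
    else:
        w = np.asarray(profile, dtype=float)
        if w.shape != (decode_map.n_species,):
            raise ValueError("tRNA profile has the wrong length")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("tRNA profile must be nonnegative and nonzero")
    x = w / w.sum() * total
    base = np.floor(x).astype(np.int64)
    short = int(total - base.sum())
    order = np.argsort(-(x - base))
    base[order[:short]] += 1
    return base


def scale_pools(
    n_ribosomes: int,
    ratio_table: Optional[dict] = None,
    trna_profile=None,
    decode_map: Optional[DecodeMap] = None,
    multipliers: Optional[dict] = None,
    tc_off: bool = False,
) -> SpeciesPools:
    """Molecular pools from a ribosome count and per-ribosome ratios.

    Every count is ``round(ratio * n_ribosomes * multiplier)``;
    ``multipliers`` (e.g. ``{"EfTu": 2.0}`` or ``{"tRNA": 1.5}``) express
    the perturbation arms without touching the ratio table.  tRNAs start
    charged (or parked in free TC in instant-recycle mode); factors start
    in their GTP forms.  A missing ratio raises an error naming the
    species.
    """
    # an explicit ratio table is authoritative: a missing entry is an
    # error naming the species, not a silent default
    ratios = dict(DEFAULT_RATIOS) if ratio_table is None else dict(ratio_table)
    mult = dict(multipliers or {})
    unknown = set(mult) - set(ratios)
    if unknown:
        raise ValueError("multipliers for unknown species: "
                         + ", ".join(sorted(unknown)))
    for key in DEFAULT_RATIOS:
        if key not in ratios:
            raise ValueError(f"missing per-ribosome ratio for {key}")
        if ratios[key] < 0:
            raise ValueError(f"negative ratio for {key}")

    def count(key: str) -> int:
        return int(round(ratios[key] * n_ribosomes * mult.get(key, 1.0)))

    dm = decode_map or default_decode_map()
    if trna_profile is None:
        trna_profile = np.ones(dm.n_species)
    trna_counts = distribute_trna(count("tRNA"), trna_profile, dm)

    kw = dict(
        n_trna_species=dm.n_species,
        free_30S_PIC=count("30S"),
        free_50S=count("50S"),
        EfTu_GTP=count("EfTu"),
        Ts_free=count("EfTs"),
        EfG_GTP=count("EfG"),
        RF1=count("RF1"),
        RF2=count("RF2"),
        RF3_GTP=count("RF3"),
        RRF=count("RRF"),
    )
    if tc_off:
        kw["trna_free_tc"] = trna_counts
    else:
        kw["trna_charged"] = trna_counts
    return SpeciesPools(**kw)


@dataclass
class CellConfig:
    """Complete, serialisable description of one simulation."""

    n_ribosomes: int
    volume_um3: float = 1.0
    mu_label: str = ""                      # bookkeeping only
    ratios: dict = field(default_factory=lambda: dict(DEFAULT_RATIOS))
    trna_profile: Optional[dict] = None     # name -> weight; None = uniform
    multipliers: dict = field(default_factory=dict)
    rates: RateTable = field(default_factory=RateTable)
    tc_off: bool = False
    t_end: float = 100.0
    checkpoint_dt: float = 1.0
    seed: int = 0

    def build_pools(self, decode_map: DecodeMap) -> SpeciesPools:
        return scale_pools(self.n_ribosomes, self.ratios, self.trna_profile,
                           decode_map, self.multipliers, self.tc_off)

    def build_state(self, transcriptome: Transcriptome,
                    decode_map: Optional[DecodeMap] = None) -> CellState:
        dm = decode_map or default_decode_map()
        pools = self.build_pools(dm)
        rates = self.rates.with_volume(self.volume_um3)
        return CellState(transcriptome.mrna_instances(), pools, rates, dm,
                         tc_off=self.tc_off)

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_ribosomes": self.n_ribosomes,
            "volume_um3": self.volume_um3,
            "mu_label": self.mu_label,
            "ratios": dict(self.ratios),
            "trna_profile": self.trna_profile,
            "multipliers": dict(self.multipliers),
            "rates": {k: list(v) for k, v in self.rates.rates.items()},
            "tc_off": self.tc_off,
            "t_end": self.t_end,
            "checkpoint_dt": self.checkpoint_dt,
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CellConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        rates = RateTable({k: (float(v[0]), int(v[1]))
                           for k, v in d.pop("rates").items()})
        return cls(rates=rates, **d)

    def manifest(self) -> dict:
        """Reproducibility manifest: config hash + seed + versions."""
        import ribosim

        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return {
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": self.seed,
            "ribosim_version": ribosim.__version__,
            "numpy_version": np.__version__,
        }


def toggle_tc_reactions(config: CellConfig, off: bool) -> CellConfig:
    """Switch instant-recycle mode: with ``off=True`` the aminoacylation,
    TC-formation and Ef-Ts reactions are bypassed and ejected tRNAs
    return to free TC immediately (tRNAs start parked in free TC)."""
    d = config.to_dict()
    rates = config.rates
    d.pop("rates")
    d["tc_off"] = bool(off)
    return CellConfig(rates=rates, **d)


# --- full-scale experiment shapes --------------------------------------

#: the published experiment shapes: ribosome counts sized so the
#: transcriptome nucleotide content matches the reference density, with
#: per-arm tweaks.  These are config generators; running them at full
#: scale is an overnight computation, not a test.
FULL_SCALE_PRESETS = {
    # name: (n_ribosomes, target_nt, length_window_nt, usage)
    "T07": (7100, 560_000, None, "matched"),
    "T10": (15000, 1_200_000, None, "matched"),
    "T10a": (15000, 1_200_000, None, "mismatched"),
    "T10b": (15000, 1_240_000, (600, 900), "matched"),
    "T10c": (15000, 2_000_000, None, "matched"),
    "T25": (64000, 5_000_000, None, "matched"),
}


def full_scale_preset(name: str, seed: int = 0) -> CellConfig:
    """CellConfig for a named full-scale experiment shape (the matching
    transcriptome is built separately with the stated target)."""
    try:
        n_rib, _, _, _ = FULL_SCALE_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from "
                         + ", ".join(FULL_SCALE_PRESETS)) from None
    mu = {"T07": "0.7", "T25": "2.5"}.get(name, "1.0")
    return CellConfig(
        n_ribosomes=n_rib,
        volume_um3=1.0,
        mu_label=f"mu={mu}",
        trna_profile=ecoli_trna_counts(mu),
        t_end=1000.0,
        seed=seed,
    )


# --- scaled-down presets and arms --------------------------------------


def scaled_cell_config(
    n_ribosomes: int = 80,
    seed: int = 0,
    t_end: float = 150.0,
    tc_off: bool = False,
    multipliers: Optional[dict] = None,
    mu: str = "1.0",
) -> CellConfig:
    """A miniature cell with reference concentrations (volume scales with
    the ribosome count) and the packaged tRNA profile."""
    return CellConfig(
        n_ribosomes=n_ribosomes,
        volume_um3=scaled_volume(n_ribosomes),
        mu_label=f"scaled mu={mu}",
        trna_profile=ecoli_trna_counts(mu),
        multipliers=dict(multipliers or {}),
        tc_off=tc_off,
        t_end=t_end,
        seed=seed,
    )


def mismatched_usage(decode_map: DecodeMap, trna_profile: dict,
                     tilt: float = 0.5) -> np.ndarray:
    """A codon-usage vector moderately diverged from the tRNA-matched
    one, emulating the few-fold discrepancy between a genomic codon bias
    and measured tRNA abundances: species weights are power-tilted
    (weight^tilt) before the equal-split usage is computed, compressing
    the abundance spread and so overloading rare tRNAs a few-fold."""
    w = np.array([float(trna_profile[n]) for n in decode_map.trna_names])
    return codon_usage_from_trnas(w ** tilt, decode_map)


def build_scaled_transcriptome(
    config: CellConfig,
    gene_lengths,
    decode_map: Optional[DecodeMap] = None,
    usage: str | np.ndarray = "matched",
    rng: Optional[np.random.Generator] = None,
    target_nt: Optional[int] = None,
) -> Transcriptome:
    """Transcriptome sized to the cell (reference nt per ribosome),
    codons drawn from the matched usage or a supplied/mismatched one."""
    dm = decode_map or default_decode_map()
    rng = rng or np.random.default_rng(config.seed)
    if isinstance(usage, str) and usage == "matched":
        freqs = codon_usage_from_trnas(config.trna_profile or
                                       {n: 1.0 for n in dm.trna_names}, dm)
    elif isinstance(usage, str) and usage == "mismatched":
        freqs = mismatched_usage(dm, config.trna_profile)
    else:
        freqs = np.asarray(usage, dtype=float)
    if target_nt is None:
        target_nt = REFERENCE_NT_PER_RIBOSOME * config.n_ribosomes
    return build_transcriptome(gene_lengths, freqs, dm, rng,
                               target_nt=target_nt)
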