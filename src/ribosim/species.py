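"""Free molecular species pools.

Integer copy numbers of every free species in the cell: ribosomal
subunits (the small subunit travels as a pre-initiation complex, 30S:PIC,
with the initiation factors and initiator tRNA folded in), the Ef-Tu
nucleotide/Ts cycle, Ef-G, release and recycling factors, and each
elongator tRNA species in its three free states (deacylated, charged,
in free ternary complex).  Amino-acid and NTP concentrations are held
constant and folded into effective rates; they appear here only as
metadata.

Conservation laws (total tRNA per species, total Ef-Tu, Ef-G, RFs, RRF,
30S, 50S) are checked against these pools plus the ribosome-bound
complement by :func:`ribosim.reactions.conservation_totals`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpeciesPools"]


@dataclass
class SpeciesPools:
    """Copy numbers of all free species; per-tRNA states are arrays."""

    n_trna_species: int

    free_30S_PIC: int = 0
    free_50S: int = 0

    EfTu_GTP: int = 0
    EfTu_GDP: int = 0
    EfTu_Ts: int = 0
    Ts_free: int = 0

    EfG_GTP: int = 0
    EfG_GDP: int = 0
    EfG_free: int = 0

    RF1: int = 0
    RF2: int = 0
    RF3_GTP: int = 0
    RF3_GDP: int = 0
    RRF: int = 0

    # Initiation factors, pre-lumped into the 30S:PIC pool by the default
    # catalogue; kept as constant bookkeeping entries.
    IF1: int = 0
    IF2_GTP: int = 0
    IF2_GDP: int = 0
    IF3: int = 0

    trna_deacyl: np.ndarray = field(default=None)  # type: ignore[assignment]
    trna_charged: np.ndarray = field(default=None)  # type: ignore[assignment]
    trna_free_tc: np.ndarray = field(default=None)  # type: ignore[assignment]

    # constant molar concentrations, folded into effective rates
    concentrations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("trna_deacyl", "trna_charged", "trna_free_tc"):
            arr = getattr(self, name)
            if arr is None:
                arr = np.zeros(self.n_trna_species, dtype=np.int64)
            else:
                arr = np.asarray(arr, dtype=np.int64).copy()
                if arr.shape != (self.n_trna_species,):
                    raise ValueError(
                        f"{name} has shape {arr.shape}, expected "
                        f"({self.n_trna_species},)"
                    )
            setattr(self, name, arr)
        self.check_nonnegative()

    # -- derived counts --------------------------------------------------

    def trna_total_free(self) -> np.ndarray:
        return self.trna_deacyl + self.trna_charged + self.trna_free_tc

    @property
    def total_free_tc(self) -> int:
        return int(self.trna_free_tc.sum())

    @property
    def total_charged(self) -> int:
        return int(self.trna_charged.sum())

    @property
    def total_deacyl(self) -> int:
        return int(self.trna_deacyl.sum())

    def check_nonnegative(self) -> None:
        for name in (
            "free_30S_PIC", "free_50S", "EfTu_GTP", "EfTu_GDP", "EfTu_Ts",
            "Ts_free", "EfG_GTP", "EfG_GDP", "EfG_free", "RF1", "RF2",
            "RF3_GTP", "RF3_GDP", "RRF", "IF1", "IF2_GTP", "IF2_GDP", "IF3",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for {name}")
        for name in ("trna_deacyl", "trna_charged", "trna_free_tc"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"negative count in {name}")

    def copy(self) -> "SpeciesPools":
        return SpeciesPools(
            n_trna_species=self.n_trna_species,
            free_30S_PIC=self.free_30S_PIC,
            free_50S=self.free_50S,
            EfTu_GTP=self.EfTu_GTP,
            EfTu_GDP=self.EfTu_GDP,
            EfTu_Ts=self.EfTu_Ts,
            Ts_free=self.Ts_free,
            EfG_GTP=self.EfG_GTP,
            EfG_GDP=self.EfG_GDP,
            EfG_free=self.EfG_free,
            RF1=self.RF1,
            RF2=self.RF2,
            RF3_GTP=self.RF3_GTP,
            RF3_GDP=self.RF3_GDP,
            RRF=self.RRF,
            IF1=self.IF1,
            IF2_GTP=self.IF2_GTP,
            IF2_GDP=self.IF2_GDP,
            IF3=self.IF3,
            trna_deacyl=self.trna_deacyl,
            trna_charged=self.trna_charged,
            trna_free_tc=self.trna_free_tc,
            concentrations=dict(self.concentrations),
        )
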