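"""Kinetic rate table.

Each reaction of the catalogue has a named rate constant that is either
first order (s^-1) or second order (M^-1 s^-1).  Second-order constants
are converted to per-pair propensity factors ``k / (N_A * v)`` with the
cell volume ``v`` so that a bimolecular reaction between pools of size
``n1`` and ``n2`` fires with propensity ``k * n1 * n2 / (N_A * v)``.

Default values are round, literature-scale numbers chosen so that the
per-step timescales of initiation, decoding, translocation, termination
and factor recycling match what is observed for exponentially growing
E. coli (peptide-bond formation and translocation in the tens per second,
diffusion-limited associations near 1e7-1e8 M^-1 s^-1).  They are package
defaults: any entry can be overridden from a TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.constants import N_A

__all__ = ["RateTable", "DEFAULT_RATES", "AVOGADRO"]

AVOGADRO = N_A

# name -> (value, order). Order-2 values in M^-1 s^-1, order-1 in s^-1.
DEFAULT_RATES: dict[str, tuple[float, int]] = {
    # initiation
    "k_pic_bind": (2.0e6, 2),        # 30S:PIC association with a free start region
    "k_50s_join": (1.0e7, 2),        # 50S joining the loaded 30S complex
    "k_init_complete": (20.0, 1),    # maturation into an elongation-competent 70S
    # elongation
    "k_tc_bind": (1.0e8, 2),         # ternary complex delivery to the A site
    "k_gtpase": (150.0, 1),          # GTPase activation + hydrolysis on Ef-Tu
    "k_accom": (120.0, 1),           # aa-tRNA accommodation into the A site
    "k_reject": (0.0, 1),            # optional proofreading rejection branch
    "k_peptidyl": (60.0, 1),         # peptidyl transfer
    "k_efg_bind": (2.0e7, 2),        # Ef-G:GTP association
    "k_transloc": (80.0, 1),         # translocation (sterically gated)
    "k_factor_release": (250.0, 1),  # Ef-Tu:GDP + Ef-G:GDP release
    "k_drop_off": (0.0, 1),          # optional premature termination branch
    # termination / recycling
    "k_rf1_bind": (1.0e7, 2),
    "k_rf2_bind": (1.0e7, 2),
    "k_rf3_bind": (5.0e7, 2),
    "k_term_release": (100.0, 1),    # peptide release, RF1/2 + RF3:GDP leave
    "k_readthrough": (0.0, 1),       # hook only; must stay 0
    "k_rrf_bind": (1.0e7, 2),
    "k_split": (50.0, 1),            # subunit splitting / mRNA release
    # pool-level cycles
    "k_aminoacyl": (25.0, 1),        # lumped aminoacylation per deacylated tRNA
    "k_tc_form": (1.0e8, 2),         # charged tRNA + Ef-Tu:GTP -> free TC
    "k_tc_dissoc": (0.0, 1),         # free TC dissociation (off by default)
    "k_efts_assoc": (3.0e7, 2),      # Ef-Tu:GDP + Ef-Ts association
    "k_efts_exchange": (30.0, 1),    # nucleotide exchange + Ts release (lumped)
    "k_efg_gdp_release": (150.0, 1),
    "k_efg_gtp_bind": (150.0, 1),    # pseudo-first order, [GTP] folded in
    "k_rf3_exchange": (100.0, 1),    # pseudo-first order GDP->GTP on RF3
}

REQUIRED_RATES = frozenset(DEFAULT_RATES)


@dataclass
class RateTable:
    """Named kinetic constants plus the volume used for unit conversion.

    ``volume_um3`` is the cell volume in cubic micrometres; 1.0 um^3 is
    the reference prokaryotic cell.  ``factor(name)`` returns the
    propensity prefactor: the rate itself for first-order reactions and
    ``k/(N_A*v)`` for second-order ones.
    """

    rates: dict[str, tuple[float, int]] = field(
        default_factory=lambda: dict(DEFAULT_RATES)
    )
    volume_um3: float = 1.0

    def __post_init__(self) -> None:
        self.validate()
        self._rebuild_factors()

    def validate(self) -> None:
        missing = REQUIRED_RATES - set(self.rates)
        if missing:
            raise ValueError(
                "missing rate entries: " + ", ".join(sorted(missing))
            )
        for name, (value, order) in self.rates.items():
            if value < 0:
                raise ValueError(f"rate {name} is negative")
            if order not in (1, 2):
                raise ValueError(f"rate {name} has order {order}, expected 1 or 2")
        if self.volume_um3 <= 0:
            raise ValueError("volume must be positive")

    # volume in litres: 1 um^3 = 1e-15 L
    @property
    def na_v(self) -> float:
        return AVOGADRO * self.volume_um3 * 1e-15

    def _rebuild_factors(self) -> None:
        nav = self.na_v
        self._factor = {
            name: (v if order == 1 else v / nav)
            for name, (v, order) in self.rates.items()
        }

    def factor(self, name: str) -> float:
        """Per-pair (order 2) or per-molecule (order 1) propensity factor."""
        try:
            return self._factor[name]
        except KeyError:
            raise ValueError(f"unknown reaction rate {name!r}") from None

    def value(self, name: str) -> float:
        return self.rates[name][0]

    def replace(self, **updates: float) -> "RateTable":
        """Return a copy with the named rate values replaced."""
        rates = dict(self.rates)
        for name, value in updates.items():
            if name not in rates:
                raise ValueError(f"unknown reaction rate {name!r}")
            rates[name] = (float(value), rates[name][1])
        return RateTable(rates, self.volume_um3)

    def with_volume(self, volume_um3: float) -> "RateTable":
        return RateTable(dict(self.rates), volume_um3)

    # -- TSV I/O ---------------------------------------------------------

    @classmethod
    def from_tsv(cls, path, volume_um3: float = 1.0) -> "RateTable":
        """Read columns reaction_name, order, rate[, units]; validated
        against the catalogue (unknown names rejected, missing filled from
        defaults is *not* done — the file must be complete)."""
        rates: dict[str, tuple[float, int]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("reaction_name"):
                    continue
                parts = line.split("\t")
                name, order, value = parts[0], int(parts[1]), float(parts[2])
                if name not in REQUIRED_RATES:
                    raise ValueError(f"unknown reaction rate {name!r} in {path}")
                rates[name] = (value, order)
        return cls(rates, volume_um3)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction_name\torder\trate\tunits\n")
            for name, (value, order) in sorted(self.rates.items()):
                units = "s^-1" if order == 1 else "M^-1.s^-1"
                fh.write(f"{name}\t{order}\t{value!r}\t{units}\n")
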