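"""Genetic-code tables and tRNA decoding maps.

Codons are RNA triplets over the alphabet ``ACGU`` and are handled
internally as integer indices 0..63 (``16*b0 + 4*b1 + b2``).  A
:class:`DecodeMap` records which tRNA species can read which sense codons;
it is the central piece of configuration tying tRNA pools to mRNA
sequences.  A default map for the 42 elongator tRNA species of
*E. coli* K12, assembled from standard wobble-decoding assignments, ships
with the package together with a matching theoretical abundance profile.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "BASES",
    "ALL_CODONS",
    "SENSE_CODONS",
    "STOP_CODONS",
    "START_CODON",
    "codon_index",
    "codon_str",
    "is_stop",
    "DecodeMap",
    "default_decode_map",
    "ecoli_trna_counts",
]

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["T"] = _BASE_INDEX["U"]  # tolerate DNA-alphabet input

ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})
START_CODON = "AUG"
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

STOP_INDICES = frozenset(ALL_CODONS.index(c) for c in STOP_CODONS)
START_INDEX = ALL_CODONS.index(START_CODON)


def codon_index(codon: str) -> int:
    """Map a codon string (RNA or DNA alphabet) to its integer index.

    Raises ``ValueError`` naming the offending codon if it is not a valid
    triplet.
    """
    if len(codon) != 3:
        raise ValueError(f"invalid codon {codon!r}: not a triplet")
    try:
        b0, b1, b2 = (_BASE_INDEX[ch] for ch in codon.upper())
    except KeyError:
        raise ValueError(f"invalid codon {codon!r}: unknown base") from None
    return 16 * b0 + 4 * b1 + b2


def codon_str(index: int) -> str:
    """Inverse of :func:`codon_index`."""
    return ALL_CODONS[index]


def is_stop(index: int) -> bool:
    return index in STOP_INDICES


class DecodeMap:
    """Bidirectional map between tRNA species and their cognate codons.

    Parameters
    ----------
    cognates
        Mapping from tRNA species name to an iterable of cognate codon
        strings.  Several tRNAs may read the same codon (wobble cross
        recognition) and one tRNA may read several codons.
    alphabet
        Optional restriction of the sense-codon alphabet in play (used by
        toy systems).  Defaults to the union of all cognate codons.

    Invariants enforced at construction: stop codons are never cognate to
    any tRNA, and every codon of the alphabet is decoded by at least one
    species.
    """

    def __init__(
        self,
        cognates: Mapping[str, Iterable[str]],
        alphabet: Sequence[str] | None = None,
    ) -> None:
        self.trna_names: list[str] = list(cognates)
        self._index = {name: i for i, name in enumerate(self.trna_names)}
        self.codons_of: list[tuple[int, ...]] = []
        for name in self.trna_names:
            idxs = []
            for codon in cognates[name]:
                ci = codon_index(codon)
                if ci in STOP_INDICES:
                    raise ValueError(
                        f"tRNA {name!r} assigned to stop codon {codon!r}"
                    )
                idxs.append(ci)
            if not idxs:
                raise ValueError(f"tRNA {name!r} decodes no codons")
            self.codons_of.append(tuple(sorted(set(idxs))))

        if alphabet is None:
            alpha = sorted({c for cs in self.codons_of for c in cs})
        else:
            alpha = sorted({codon_index(c) for c in alphabet})
        self.alphabet: tuple[int, ...] = tuple(alpha)

        decoders: dict[int, list[int]] = {c: [] for c in self.alphabet}
        for s, cs in enumerate(self.codons_of):
            for c in cs:
                decoders.setdefault(c, []).append(s)
        for c in self.alphabet:
            if not decoders[c]:
                raise ValueError(
                    f"codon {codon_str(c)} has no decoding tRNA in the map"
                )
        self.decoders_of: dict[int, tuple[int, ...]] = {
            c: tuple(v) for c, v in decoders.items()
        }

    # -- basic queries ---------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.trna_names)

    def index(self, name: str) -> int:
        return self._index[name]

    def decoders(self, codon: int) -> tuple[int, ...]:
        """tRNA species indices able to read ``codon`` (empty for stops)."""
        if codon in STOP_INDICES:
            return ()
        try:
            return self.decoders_of[codon]
        except KeyError:
            raise ValueError(
                f"unknown codon {codon_str(codon)}: not in the decode map "
                "alphabet"
            ) from None

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "DecodeMap":
        """Read a two-column TSV: tRNA name, comma-separated codons."""
        cognates: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, codons = line.split("\t")
                cognates[name] = codons.split(",")
        return cls(cognates)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# tRNA\tcognate_codons\n")
            for name, cs in zip(self.trna_names, self.codons_of):
                fh.write(f"{name}\t{','.join(codon_str(c) for c in cs)}\n")


def _data_text(name: str) -> str:
    return resources.files("ribosim.data").joinpath(name).read_text()


def default_decode_map() -> DecodeMap:
    """The packaged 42-species E. coli elongator-tRNA decode map."""
    cognates: dict[str, list[str]] = {}
    for line in _data_text("ecoli_decode_map.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, codons = line.split("\t")
        cognates[name] = codons.split(",")
    return DecodeMap(cognates)


def ecoli_trna_counts(mu: str = "1.0") -> dict[str, int]:
    """Theoretical E. coli K12 tRNA copy numbers at a given growth rate.

    ``mu`` is one of ``"0.7"``, ``"1.0"`` (tabulated at 1.07) or ``"2.5"``
    doublings per hour.  The numbers are a codon-usage-matched abundance
    profile; they are defaults, not hard-coded truth, and any two-column
    table can be supplied instead.
    """
    col = {"0.7": 1, "1.0": 2, "2.5": 3}[str(mu)]
    counts: dict[str, int] = {}
    for line in _data_text("ecoli_trna_abundance.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        counts[parts[0]] = int(parts[col])
    return counts
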