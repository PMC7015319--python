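"""Ribosome, mRNA and whole-cell state containers.

The ribosome walks an ordered state machine through initiation,
elongation, termination and recycling sub-steps (``Phase``).  Positions
are 1-based codon indices of the P site; codon 1 is the start codon.

Footprint geometry: a bound ribosome occupies 8 codons 5' of its P site
and 6 codons 3' of it.  Two ribosomes with P sites ``p < q`` on the same
mRNA therefore collide when ``q - p < 15``, and a forward move (a
translocation of the upstream ribosome, or loading of a new 30S:PIC at
the start codon, which sits at position 1) is blocked exactly when the
current separation is below 15 codons.  The boundary is half-open: a
follower 15 codons behind its leader may still translocate.
"""

from __future__ import annotations

from enum import IntEnum
from typing import Optional, Sequence

import numpy as np

from .genetics import DecodeMap, STOP_INDICES, START_INDEX, codon_str
from .rates import RateTable
from .species import SpeciesPools

__all__ = [
    "Phase",
    "FOOTPRINT_5P",
    "FOOTPRINT_3P",
    "MIN_SEPARATION",
    "RibosomeComplex",
    "MRNAInstance",
    "CellState",
    "SampledSet",
    "is_blocked",
    "validate_orf",
]

FOOTPRINT_5P = 8
FOOTPRINT_3P = 6
#: minimal P-site separation required for a forward move (8 + 6 + 1)
MIN_SEPARATION = FOOTPRINT_5P + FOOTPRINT_3P + 1


class Phase(IntEnum):
    """Ordered sub-steps of the ribosome state machine."""

    INIT_WAIT50S = 0     # 30S:PIC loaded at the start codon, awaiting 50S
    INIT_JOINED = 1      # 70S assembled, maturing to elongation competence
    AWAIT_TC = 2         # empty A site, awaiting a cognate ternary complex
    TC_BOUND = 3         # TC in the A site, awaiting GTPase/hydrolysis
    GTP_HYDRO = 4        # GTP hydrolysed, awaiting accommodation
    ACCOMMODATED = 5     # aa-tRNA accommodated, awaiting peptidyl transfer
    PRE_TRANSLOC = 6     # peptide bond formed, awaiting Ef-G:GTP
    EFG_BOUND = 7        # Ef-G bound, awaiting (sterically gated) translocation
    POST_TRANSLOC = 8    # translocated, awaiting Ef-Tu:GDP / Ef-G:GDP release
    TERM_WAIT_RF = 9     # stop codon in the A site, awaiting RF1/RF2
    TERM_RF_BOUND = 10   # class-1 RF bound, awaiting RF3:GTP
    TERM_RF3_BOUND = 11  # RF3 bound, awaiting peptide release
    AWAIT_RRF = 12       # peptide released, awaiting RRF
    RRF_BOUND = 13       # RRF bound, awaiting subunit splitting


ELONGATION_PHASES = frozenset(
    {Phase.AWAIT_TC, Phase.TC_BOUND, Phase.GTP_HYDRO, Phase.ACCOMMODATED,
     Phase.PRE_TRANSLOC, Phase.EFG_BOUND, Phase.POST_TRANSLOC}
)
TERMINATION_PHASES = frozenset(
    {Phase.TERM_WAIT_RF, Phase.TERM_RF_BOUND, Phase.TERM_RF3_BOUND,
     Phase.AWAIT_RRF, Phase.RRF_BOUND}
)
#: phases in which the complex holds a 50S subunit
HOLDS_50S_PHASES = frozenset(p for p in Phase if p >= Phase.INIT_JOINED)
#: phases in which the complex holds an Ef-Tu (delivered with the TC)
HOLDS_EFTU_PHASES = frozenset(
    {Phase.TC_BOUND, Phase.GTP_HYDRO, Phase.ACCOMMODATED,
     Phase.PRE_TRANSLOC, Phase.EFG_BOUND, Phase.POST_TRANSLOC}
)
HOLDS_EFG_PHASES = frozenset({Phase.EFG_BOUND, Phase.POST_TRANSLOC})


class RibosomeComplex:
    """One ribosome (or loading 30S:PIC) bound to an mRNA."""

    __slots__ = (
        "id", "mrna", "phase", "p_site", "a_site_trna", "p_site_trna",
        "bound_rf", "await_since", "starved", "t_init", "t_elong_start",
        "t_elong_end", "n_decoded", "stalled_since",
    )

    def __init__(self, rid: int, mrna: "MRNAInstance", t: float) -> None:
        self.id = rid
        self.mrna = mrna
        self.phase = Phase.INIT_WAIT50S
        self.p_site = 1
        self.a_site_trna: Optional[int] = None
        # None during the first cycle: the initiator fMet-tRNA is folded
        # into the 30S:PIC pool and is not an elongator species.
        self.p_site_trna: Optional[int] = None
        self.bound_rf: Optional[int] = None  # 1 or 2 while RF-bound
        self.await_since = 0.0
        self.starved = False
        self.t_init = t
        self.t_elong_start = float("nan")
        self.t_elong_end = float("nan")
        self.n_decoded = 0
        self.stalled_since: Optional[float] = None

    @property
    def a_site_codon(self) -> int:
        # codons are stored 0-based; the A site reads position p_site + 1
        return self.mrna.codons[self.p_site]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Ribosome {self.id} {self.phase.name} p={self.p_site} "
            f"on {self.mrna.gene_id}>"
        )


def validate_orf(codons: Sequence[int]) -> None:
    """Check start codon first, exactly one stop codon last."""
    if len(codons) < 3:
        raise ValueError("ORF must contain at least start, one sense, stop")
    if codons[0] != START_INDEX:
        raise ValueError(
            f"ORF does not begin with a start codon (got {codon_str(codons[0])})"
        )
    if codons[-1] not in STOP_INDICES:
        raise ValueError(
            f"ORF does not end with a stop codon (got {codon_str(codons[-1])})"
        )
    for c in codons[1:-1]:
        if c in STOP_INDICES:
            raise ValueError("internal stop codon in ORF")


class MRNAInstance:
    """One mRNA copy: its codon sequence and bound ribosomes.

    ``ribosomes`` is kept sorted by increasing P-site position, so index 0
    is the 5'-most (most recently initiated) complex.
    """

    __slots__ = ("gene_id", "codons", "ribosomes", "leaf", "gene_index",
                 "_decode_map")

    def __init__(self, gene_id: str, codons: np.ndarray, gene_index: int = 0,
                 validate: bool = True) -> None:
        self.gene_id = gene_id
        self.codons = np.asarray(codons, dtype=np.int16)
        if validate:
            validate_orf(self.codons)
        self.ribosomes: list[RibosomeComplex] = []
        self.leaf = -1          # tree leaf index, set by the engine
        self.gene_index = gene_index
        self._decode_map = None  # attached by CellState

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def length_aa(self) -> int:
        """Number of sense codons after the start (decode events per protein)."""
        return len(self.codons) - 2

    def start_blocked(self) -> bool:
        """True when codons 1..15 overlap an existing footprint, i.e. a
        new 30S:PIC cannot load (5'-most P site below MIN_SEPARATION + 1)."""
        return bool(self.ribosomes) and (
            self.ribosomes[0].p_site - 1 < MIN_SEPARATION
        )

    def local_propensity(self, pools: SpeciesPools, rates: RateTable) -> float:
        """phi_i: the summed propensity of every reaction local to this
        mRNA, recomputed from scratch (oracle for the engine's caches)."""
        from .reactions import enumerate_local_reactions

        return sum(ev.propensity
                   for ev in enumerate_local_reactions(self, pools, rates))

    def check_exclusion(self) -> None:
        """Assert footprint exclusion: separations never below 14 codons
        (the half-open move boundary allows 14 transiently behind a
        leader; a move itself requires >= 15)."""
        ps = [r.p_site for r in self.ribosomes]
        if ps != sorted(ps):
            raise AssertionError("ribosomes out of order on " + self.gene_id)
        for a, b in zip(ps, ps[1:]):
            if b - a < MIN_SEPARATION - 1:
                raise AssertionError(
                    f"footprint overlap on {self.gene_id}: P sites {a},{b}"
                )


def is_blocked(rib: RibosomeComplex, mrna: MRNAInstance | None = None) -> bool:
    """True iff the next forward move of ``rib`` is sterically excluded.

    For a translocating ribosome this compares the P-site separation to
    the ribosome ahead: blocked iff ``q - p < 15``.  The 3'-most ribosome
    is never blocked (the mRNA end does not exclude)."""
    mrna = mrna or rib.mrna
    ribs = mrna.ribosomes
    i = ribs.index(rib)
    if i + 1 >= len(ribs):
        return False
    return ribs[i + 1].p_site - rib.p_site < MIN_SEPARATION


class SampledSet:
    """Set with O(1) add/discard/uniform-sample (swap-remove list)."""

    __slots__ = ("_items", "_pos")

    def __init__(self) -> None:
        self._items: list = []
        self._pos: dict = {}

    def add(self, item) -> None:
        if item in self._pos:
            return
        self._pos[item] = len(self._items)
        self._items.append(item)

    def discard(self, item) -> None:
        pos = self._pos.pop(item, None)
        if pos is None:
            return
        last = self._items.pop()
        if last is not item:
            self._items[pos] = last
            self._pos[last] = pos

    def sample(self, r: float):
        """Pick the element at fraction ``r`` of the list (r in [0,1))."""
        return self._items[int(r * len(self._items))]

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, item) -> bool:
        return item in self._pos

    def __iter__(self):
        return iter(self._items)


class CellState:
    """Complete mutable simulation state shared by both engines.

    Holds the mRNAs, the species pools, the decode map and rate table,
    the waiter registries used for species-aggregated association
    channels, and the event ledgers (decode events and protein
    completions).  The registries are maintained by
    :func:`ribosim.reactions.apply_event` so that the naive reference
    engine (which re-enumerates everything from the raw state each step)
    never reads them — they are the *tested* bookkeeping path.
    """

    def __init__(
        self,
        mrnas: list[MRNAInstance],
        pools: SpeciesPools,
        rates: RateTable,
        decode_map: DecodeMap,
        tc_off: bool = False,
        log_events: bool = False,
    ) -> None:
        if decode_map.n_species != pools.n_trna_species:
            raise ValueError("pool / decode-map species count mismatch")
        if rates.value("k_readthrough") != 0.0:
            raise NotImplementedError(
                "stop-codon read-through is a framework hook; k_readthrough "
                "must be 0"
            )
        self.mrnas = mrnas
        self.pools = pools
        self.rates = rates
        self.decode_map = decode_map
        self.tc_off = tc_off
        self._next_rid = 0
        for m in mrnas:
            m._decode_map = decode_map

        # waiter registries (class membership for association channels)
        S = decode_map.n_species
        self.start_free = SampledSet()        # mRNAs with a loadable start
        self.wait_50s = SampledSet()          # INIT_WAIT50S complexes
        self.wait_tc: list[SampledSet] = [SampledSet() for _ in range(S)]
        self.wait_efg = SampledSet()          # PRE_TRANSLOC
        self.wait_rf: dict[int, SampledSet] = {}   # stop codon -> waiters
        from .genetics import STOP_INDICES as _SI
        for stop in _SI:
            self.wait_rf[stop] = SampledSet()
        self.wait_rf3 = SampledSet()          # TERM_RF_BOUND
        self.wait_rrf = SampledSet()          # AWAIT_RRF

        for m in self.mrnas:
            if not m.start_blocked():
                self.start_free.add(m)

        # ledgers
        self.decode_t: list[float] = []
        self.decode_codon: list[int] = []
        self.decode_trna: list[int] = []
        self.decode_wait: list[float] = []
        self.decode_stalled: list[bool] = []
        self.completions: list[tuple] = []  # (gene_id, length_aa, n_decoded,
        #                                      t_init, t_elong_start,
        #                                      t_elong_end, t_complete)
        self.log_events = log_events
        self.event_log: list[tuple] = []  # (t, reaction, mrna_id, rib_id)

        from .reactions import conservation_totals

        self.initial_totals = conservation_totals(self)

    def write_event_log(self, path) -> None:
        """Write the optional event log as gzip TSV."""
        import gzip

        with gzip.open(path, "wt") as fh:
            fh.write("t\treaction_name\tmrna_id\tribosome_id\n")
            for t, name, mid, rid in self.event_log:
                fh.write(f"{t!r}\t{name}\t{mid}\t{rid}\n")

    def new_ribosome(self, mrna: MRNAInstance, t: float) -> RibosomeComplex:
        rib = RibosomeComplex(self._next_rid, mrna, t)
        self._next_rid += 1
        return rib

    @property
    def n_decode_events(self) -> int:
        return len(self.decode_t)

    def ribosomes(self):
        for m in self.mrnas:
            yield from m.ribosomes
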