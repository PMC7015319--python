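"""Reaction catalogue: enumeration, firing, conservation accounting.

The catalogue realises the full reaction network of prokaryotic
translation: multi-step initiation (30S:PIC loading, 50S joining,
maturation), the elongation cycle (ternary-complex delivery, GTPase
activation and hydrolysis on Ef-Tu, accommodation with an optional
rejection branch, peptidyl transfer, Ef-G:GTP binding, sterically gated
translocation with E-site tRNA release, factor release), class-specific
termination (RF1 reads UAG, RF2 reads UGA, both read UAA; RF3:GTP
stimulated release) and RRF-mediated recycling, together with the
pool-level cycles: lumped aminoacylation, ternary-complex formation from
charged tRNA + Ef-Tu:GTP, the Ef-Tu:GDP/Ef-Ts exchange cycle, and
GDP/GTP exchange on Ef-G and RF3.

:func:`apply_event` is the single place where state changes; both the
binary-tree engine and the naive reference engine fire events through it,
so statistical comparisons between the engines test selection and
bookkeeping, not the kinetics definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genetics import codon_str, is_stop
from .rates import RateTable
from .species import SpeciesPools
from .state import (
    CellState,
    MRNAInstance,
    Phase,
    RibosomeComplex,
    HOLDS_50S_PHASES,
    HOLDS_EFTU_PHASES,
    HOLDS_EFG_PHASES,
    is_blocked,
)

__all__ = [
    "ReactionEvent",
    "enumerate_local_reactions",
    "enumerate_global_reactions",
    "apply_event",
    "conservation_totals",
    "KIND_NAMES",
]

# --- reaction kinds ----------------------------------------------------

(
    PIC_BIND, JOIN_50S, INIT_COMPLETE,
    TC_BIND, GTPASE, ACCOMMODATE, REJECT, PEPTIDYL,
    EFG_BIND, TRANSLOCATE, FACTOR_RELEASE, DROP_OFF,
    RF1_BIND, RF2_BIND, RF3_BIND, TERM_RELEASE, RRF_BIND, SPLIT,
    AMINOACYL, TC_FORM, TC_DISSOC,
    EFTS_ASSOC, EFTS_EXCHANGE, EFG_GDP_RELEASE, EFG_GTP_BIND, RF3_EXCHANGE,
) = range(26)

KIND_NAMES = (
    "pic_bind", "50s_join", "init_complete",
    "tc_bind", "gtpase", "accommodate", "reject", "peptidyl_transfer",
    "efg_bind", "translocate", "factor_release", "drop_off",
    "rf1_bind", "rf2_bind", "rf3_bind", "term_release", "rrf_bind", "split",
    "aminoacylation", "tc_formation", "tc_dissociation",
    "efts_association", "efts_exchange", "efg_gdp_release", "efg_gtp_bind",
    "rf3_exchange",
)

#: kind -> rate-table entry
KIND_RATE = {
    PIC_BIND: "k_pic_bind", JOIN_50S: "k_50s_join",
    INIT_COMPLETE: "k_init_complete", TC_BIND: "k_tc_bind",
    GTPASE: "k_gtpase", ACCOMMODATE: "k_accom", REJECT: "k_reject",
    PEPTIDYL: "k_peptidyl", EFG_BIND: "k_efg_bind",
    TRANSLOCATE: "k_transloc", FACTOR_RELEASE: "k_factor_release",
    DROP_OFF: "k_drop_off", RF1_BIND: "k_rf1_bind", RF2_BIND: "k_rf2_bind",
    RF3_BIND: "k_rf3_bind", TERM_RELEASE: "k_term_release",
    RRF_BIND: "k_rrf_bind", SPLIT: "k_split", AMINOACYL: "k_aminoacyl",
    TC_FORM: "k_tc_form", TC_DISSOC: "k_tc_dissoc",
    EFTS_ASSOC: "k_efts_assoc", EFTS_EXCHANGE: "k_efts_exchange",
    EFG_GDP_RELEASE: "k_efg_gdp_release", EFG_GTP_BIND: "k_efg_gtp_bind",
    RF3_EXCHANGE: "k_rf3_exchange",
}

# stop codon -> class-1 release factors able to read it
from .genetics import codon_index as _ci

RF_READS = {
    _ci("UAA"): (1, 2),
    _ci("UAG"): (1,),
    _ci("UGA"): (2,),
}


@dataclass
class ReactionEvent:
    """One fireable reaction at the current state.

    ``locus`` is the mRNA (plus ribosome) for local reactions and None
    for pool-level ("global") reactions; ``species`` is a tRNA index for
    tRNA-resolved reactions.  Applying the event through
    :func:`apply_event` realises its stoichiometry atomically.
    """

    kind: int
    propensity: float
    mrna: Optional[MRNAInstance] = None
    ribosome: Optional[RibosomeComplex] = None
    species: Optional[int] = None

    @property
    def name(self) -> str:
        return KIND_NAMES[self.kind]


# --- enumeration (used by the naive engine and as the phi oracle) ------


def enumerate_local_reactions(
    mrna: MRNAInstance, pools: SpeciesPools, rates: RateTable
) -> list[ReactionEvent]:
    """Every currently fireable reaction on this mRNA.

    Initiation loading appears only when the start region is unoccluded
    and a free 30S:PIC exists; TC delivery only for species cognate to
    the A-site codon with a nonzero free-TC pool; translocation only when
    the downstream footprint is clear.  Propensities are rate x reactant
    count products, second-order scaled by 1/(N_A v).
    """
    events: list[ReactionEvent] = []
    f = rates.factor

    if not mrna.start_blocked() and pools.free_30S_PIC > 0:
        events.append(ReactionEvent(
            PIC_BIND, f("k_pic_bind") * pools.free_30S_PIC, mrna))

    for rib in mrna.ribosomes:
        ph = rib.phase
        if ph == Phase.INIT_WAIT50S:
            if pools.free_50S > 0:
                events.append(ReactionEvent(
                    JOIN_50S, f("k_50s_join") * pools.free_50S, mrna, rib))
        elif ph == Phase.INIT_JOINED:
            events.append(ReactionEvent(
                INIT_COMPLETE, f("k_init_complete"), mrna, rib))
        elif ph == Phase.AWAIT_TC:
            codon = rib.a_site_codon
            decoders = _decoders_for(mrna, codon)
            for s in decoders:
                n_tc = int(pools.trna_free_tc[s])
                if n_tc > 0:
                    events.append(ReactionEvent(
                        TC_BIND, f("k_tc_bind") * n_tc, mrna, rib, s))
            k_drop = f("k_drop_off")
            if k_drop > 0:
                events.append(ReactionEvent(DROP_OFF, k_drop, mrna, rib))
        elif ph == Phase.TC_BOUND:
            events.append(ReactionEvent(GTPASE, f("k_gtpase"), mrna, rib))
        elif ph == Phase.GTP_HYDRO:
            events.append(ReactionEvent(ACCOMMODATE, f("k_accom"), mrna, rib))
            k_rej = f("k_reject")
            if k_rej > 0:
                events.append(ReactionEvent(REJECT, k_rej, mrna, rib))
        elif ph == Phase.ACCOMMODATED:
            events.append(ReactionEvent(PEPTIDYL, f("k_peptidyl"), mrna, rib))
        elif ph == Phase.PRE_TRANSLOC:
            if pools.EfG_GTP > 0:
                events.append(ReactionEvent(
                    EFG_BIND, f("k_efg_bind") * pools.EfG_GTP, mrna, rib))
        elif ph == Phase.EFG_BOUND:
            if not is_blocked(rib, mrna):
                events.append(ReactionEvent(
                    TRANSLOCATE, f("k_transloc"), mrna, rib))
        elif ph == Phase.POST_TRANSLOC:
            events.append(ReactionEvent(
                FACTOR_RELEASE, f("k_factor_release"), mrna, rib))
        elif ph == Phase.TERM_WAIT_RF:
            stop = rib.a_site_codon
            for rf in RF_READS[stop]:
                n = pools.RF1 if rf == 1 else pools.RF2
                if n > 0:
                    kind = RF1_BIND if rf == 1 else RF2_BIND
                    events.append(ReactionEvent(
                        kind, f(KIND_RATE[kind]) * n, mrna, rib))
        elif ph == Phase.TERM_RF_BOUND:
            if pools.RF3_GTP > 0:
                events.append(ReactionEvent(
                    RF3_BIND, f("k_rf3_bind") * pools.RF3_GTP, mrna, rib))
        elif ph == Phase.TERM_RF3_BOUND:
            events.append(ReactionEvent(
                TERM_RELEASE, f("k_term_release"), mrna, rib))
        elif ph == Phase.AWAIT_RRF:
            if pools.RRF > 0:
                events.append(ReactionEvent(
                    RRF_BIND, f("k_rrf_bind") * pools.RRF, mrna, rib))
        elif ph == Phase.RRF_BOUND:
            events.append(ReactionEvent(SPLIT, f("k_split"), mrna, rib))
    return events


def _decoders_for(mrna: MRNAInstance, codon: int):
    # the decode map is attached to each mRNA at CellState construction
    dm = mrna._decode_map
    if dm is None:
        raise ValueError(
            f"cannot decode codon {codon_str(codon)}: mRNA {mrna.gene_id} "
            "is not attached to a cell state"
        )
    return dm.decoders(codon)


def enumerate_global_reactions(
    pools: SpeciesPools, rates: RateTable, tc_off: bool = False
) -> list[ReactionEvent]:
    """Pool-level reactions: per-tRNA lumped aminoacylation, TC
    formation/dissociation, the Ef-Ts cycle, Ef-G and RF3 nucleotide
    exchange.  In instant-recycle (tc_off) mode the charging and Ef-Tu
    reactions are bypassed entirely."""
    events: list[ReactionEvent] = []
    f = rates.factor
    if not tc_off:
        k_aa = f("k_aminoacyl")
        k_tc = f("k_tc_form")
        k_dis = f("k_tc_dissoc")
        for s in range(pools.n_trna_species):
            n_d = int(pools.trna_deacyl[s])
            if n_d > 0:
                events.append(ReactionEvent(AMINOACYL, k_aa * n_d, species=s))
            n_c = int(pools.trna_charged[s])
            if n_c > 0 and pools.EfTu_GTP > 0:
                events.append(ReactionEvent(
                    TC_FORM, k_tc * n_c * pools.EfTu_GTP, species=s))
            n_tc = int(pools.trna_free_tc[s])
            if k_dis > 0 and n_tc > 0:
                events.append(ReactionEvent(TC_DISSOC, k_dis * n_tc, species=s))
        if pools.EfTu_GDP > 0 and pools.Ts_free > 0:
            events.append(ReactionEvent(
                EFTS_ASSOC, f("k_efts_assoc") * pools.EfTu_GDP * pools.Ts_free))
        if pools.EfTu_Ts > 0:
            events.append(ReactionEvent(
                EFTS_EXCHANGE, f("k_efts_exchange") * pools.EfTu_Ts))
    if pools.EfG_GDP > 0:
        events.append(ReactionEvent(
            EFG_GDP_RELEASE, f("k_efg_gdp_release") * pools.EfG_GDP))
    if pools.EfG_free > 0:
        events.append(ReactionEvent(
            EFG_GTP_BIND, f("k_efg_gtp_bind") * pools.EfG_free))
    if pools.RF3_GDP > 0:
        events.append(ReactionEvent(
            RF3_EXCHANGE, f("k_rf3_exchange") * pools.RF3_GDP))
    return events


# --- firing ------------------------------------------------------------


class ChangeSet:
    """What an event touched; consumed by the tree engine to refresh its
    caches (the naive engine re-enumerates and ignores this)."""

    __slots__ = ("mrna", "tc_touched")

    def __init__(self) -> None:
        self.mrna: Optional[MRNAInstance] = None
        self.tc_touched: set[int] = set()


def _dec(pools: SpeciesPools, field: str, by: int = 1) -> None:
    v = getattr(pools, field) - by
    if v < 0:
        raise RuntimeError(
            f"firing drove {field} negative: stale propensity bookkeeping"
        )
    setattr(pools, field, v)


def _dec_arr(arr, s: int, what: str) -> None:
    arr[s] -= 1
    if arr[s] < 0:
        raise RuntimeError(
            f"firing drove {what}[{s}] negative: stale propensity bookkeeping"
        )


def _release_trna(state: CellState, s: Optional[int], cs: ChangeSet) -> None:
    """Ejected deacylated tRNA: to the deacylated pool, or straight back
    to free TC in instant-recycle mode."""
    if s is None:
        return
    if state.tc_off:
        state.pools.trna_free_tc[s] += 1
        cs.tc_touched.add(s)
    else:
        state.pools.trna_deacyl[s] += 1


def _enter_await_tc(state: CellState, rib: RibosomeComplex, t: float,
                    cs: ChangeSet) -> None:
    rib.phase = Phase.AWAIT_TC
    rib.await_since = t
    decs = state.decode_map.decoders(rib.a_site_codon)
    tc = state.pools.trna_free_tc
    starved = True
    for s in decs:
        state.wait_tc[s].add(rib)
        cs.tc_touched.add(s)
        if tc[s] > 0:
            starved = False
    rib.starved = starved
    rib.stalled_since = t if starved else None


def _leave_await_tc(state: CellState, rib: RibosomeComplex,
                    cs: ChangeSet) -> None:
    for s in state.decode_map.decoders(rib.a_site_codon):
        state.wait_tc[s].discard(rib)
        cs.tc_touched.add(s)


def _enter_termination(state: CellState, rib: RibosomeComplex,
                       t: float) -> None:
    rib.phase = Phase.TERM_WAIT_RF
    rib.t_elong_end = t
    state.wait_rf[rib.a_site_codon].add(rib)


def _advance_reading(state: CellState, rib: RibosomeComplex, t: float,
                     cs: ChangeSet) -> None:
    """Route the ribosome by its A-site codon: sense -> await TC, stop ->
    termination."""
    if is_stop(rib.a_site_codon):
        _enter_termination(state, rib, t)
    else:
        _enter_await_tc(state, rib, t, cs)


def _mark_starvation(state: CellState, s: int) -> None:
    """Free TC of species ``s`` just hit zero: flag waiters whose every
    decoding species is now exhausted."""
    tc = state.pools.trna_free_tc
    dm = state.decode_map
    for rib in state.wait_tc[s]:
        if rib.starved:
            continue
        if all(tc[d] == 0 for d in dm.decoders(rib.a_site_codon)):
            rib.starved = True


def _remove_ribosome(state: CellState, rib: RibosomeComplex,
                     cs: ChangeSet) -> None:
    mrna = rib.mrna
    mrna.ribosomes.remove(rib)
    if not mrna.start_blocked():
        state.start_free.add(mrna)


def _refresh_start(state: CellState, mrna: MRNAInstance) -> None:
    if mrna.start_blocked():
        state.start_free.discard(mrna)
    else:
        state.start_free.add(mrna)


def apply_event(
    state: CellState,
    kind: int,
    t: float,
    mrna: Optional[MRNAInstance] = None,
    rib: Optional[RibosomeComplex] = None,
    species: Optional[int] = None,
) -> ChangeSet:
    """Fire one reaction atomically: apply stoichiometry, advance the
    ribosome phase, maintain the waiter registries, and emit decode /
    completion records.  Raises ``RuntimeError`` if any count would go
    negative (stale propensity bookkeeping)."""
    pools = state.pools
    cs = ChangeSet()
    if rib is not None and mrna is None:
        mrna = rib.mrna
    cs.mrna = mrna
    if state.log_events:
        state.event_log.append((
            t, KIND_NAMES[kind],
            mrna.gene_id if mrna is not None else "",
            rib.id if rib is not None else -1,
        ))

    if kind == PIC_BIND:
        assert mrna is not None
        if mrna.start_blocked():
            raise RuntimeError("PIC loading on an occluded start region")
        _dec(pools, "free_30S_PIC")
        new = state.new_ribosome(mrna, t)
        mrna.ribosomes.insert(0, new)
        state.start_free.discard(mrna)
        state.wait_50s.add(new)

    elif kind == JOIN_50S:
        _dec(pools, "free_50S")
        state.wait_50s.discard(rib)
        rib.phase = Phase.INIT_JOINED

    elif kind == INIT_COMPLETE:
        rib.t_elong_start = t
        _advance_reading(state, rib, t, cs)

    elif kind == TC_BIND:
        _dec_arr(pools.trna_free_tc, species, "trna_free_tc")
        cs.tc_touched.add(species)
        _leave_await_tc(state, rib, cs)
        rib.a_site_trna = species
        rib.phase = Phase.TC_BOUND
        if pools.trna_free_tc[species] == 0:
            _mark_starvation(state, species)

    elif kind == GTPASE:
        rib.phase = Phase.GTP_HYDRO

    elif kind == ACCOMMODATE:
        rib.phase = Phase.ACCOMMODATED

    elif kind == REJECT:
        # proofreading rejection: the aa-tRNA leaves charged, Ef-Tu as GDP
        s = rib.a_site_trna
        rib.a_site_trna = None
        if state.tc_off:
            pools.trna_free_tc[s] += 1
            cs.tc_touched.add(s)
        else:
            pools.trna_charged[s] += 1
            pools.EfTu_GDP += 1
        _enter_await_tc(state, rib, t, cs)

    elif kind == PEPTIDYL:
        rib.phase = Phase.PRE_TRANSLOC
        rib.n_decoded += 1
        state.wait_efg.add(rib)
        state.decode_t.append(t)
        state.decode_codon.append(int(rib.a_site_codon))
        state.decode_trna.append(rib.a_site_trna)
        state.decode_wait.append(t - rib.await_since)
        state.decode_stalled.append(rib.starved)
        rib.starved = False

    elif kind == EFG_BIND:
        _dec(pools, "EfG_GTP")
        state.wait_efg.discard(rib)
        rib.phase = Phase.EFG_BOUND

    elif kind == TRANSLOCATE:
        if is_blocked(rib, mrna):
            raise RuntimeError("translocation fired on a blocked ribosome")
        released = rib.p_site_trna
        rib.p_site += 1
        rib.p_site_trna = rib.a_site_trna
        rib.a_site_trna = None
        rib.phase = Phase.POST_TRANSLOC
        rib.stalled_since = None
        _release_trna(state, released, cs)
        if mrna.ribosomes[0] is rib:
            _refresh_start(state, mrna)

    elif kind == FACTOR_RELEASE:
        if not state.tc_off:
            pools.EfTu_GDP += 1
        pools.EfG_GDP += 1
        _advance_reading(state, rib, t, cs)

    elif kind == DROP_OFF:
        _leave_await_tc(state, rib, cs)
        _release_trna(state, rib.p_site_trna, cs)
        pools.free_50S += 1
        pools.free_30S_PIC += 1
        _remove_ribosome(state, rib, cs)

    elif kind in (RF1_BIND, RF2_BIND):
        _dec(pools, "RF1" if kind == RF1_BIND else "RF2")
        state.wait_rf[rib.a_site_codon].discard(rib)
        rib.bound_rf = 1 if kind == RF1_BIND else 2
        rib.phase = Phase.TERM_RF_BOUND
        state.wait_rf3.add(rib)

    elif kind == RF3_BIND:
        _dec(pools, "RF3_GTP")
        state.wait_rf3.discard(rib)
        rib.phase = Phase.TERM_RF3_BOUND

    elif kind == TERM_RELEASE:
        setattr(pools, "RF1" if rib.bound_rf == 1 else "RF2",
                getattr(pools, "RF1" if rib.bound_rf == 1 else "RF2") + 1)
        rib.bound_rf = None
        pools.RF3_GDP += 1
        rib.phase = Phase.AWAIT_RRF
        state.wait_rrf.add(rib)
        state.completions.append((
            mrna.gene_id, mrna.length_aa, rib.n_decoded, rib.t_init,
            rib.t_elong_start, rib.t_elong_end, t,
        ))

    elif kind == RRF_BIND:
        _dec(pools, "RRF")
        state.wait_rrf.discard(rib)
        rib.phase = Phase.RRF_BOUND

    elif kind == SPLIT:
        pools.RRF += 1
        pools.free_50S += 1
        pools.free_30S_PIC += 1
        _release_trna(state, rib.p_site_trna, cs)
        _remove_ribosome(state, rib, cs)

    elif kind == AMINOACYL:
        _dec_arr(pools.trna_deacyl, species, "trna_deacyl")
        pools.trna_charged[species] += 1

    elif kind == TC_FORM:
        _dec_arr(pools.trna_charged, species, "trna_charged")
        _dec(pools, "EfTu_GTP")
        pools.trna_free_tc[species] += 1
        cs.tc_touched.add(species)

    elif kind == TC_DISSOC:
        _dec_arr(pools.trna_free_tc, species, "trna_free_tc")
        pools.trna_charged[species] += 1
        pools.EfTu_GTP += 1
        cs.tc_touched.add(species)
        if pools.trna_free_tc[species] == 0:
            _mark_starvation(state, species)

    elif kind == EFTS_ASSOC:
        _dec(pools, "EfTu_GDP")
        _dec(pools, "Ts_free")
        pools.EfTu_Ts += 1

    elif kind == EFTS_EXCHANGE:
        _dec(pools, "EfTu_Ts")
        pools.EfTu_GTP += 1
        pools.Ts_free += 1

    elif kind == EFG_GDP_RELEASE:
        _dec(pools, "EfG_GDP")
        pools.EfG_free += 1

    elif kind == EFG_GTP_BIND:
        _dec(pools, "EfG_free")
        pools.EfG_GTP += 1

    elif kind == RF3_EXCHANGE:
        _dec(pools, "RF3_GDP")
        pools.RF3_GTP += 1

    else:  # pragma: no cover
        raise ValueError(f"unknown reaction kind {kind}")

    return cs


# --- conservation ------------------------------------------------------


def conservation_totals(state: CellState) -> dict[str, object]:
    """Exact totals of every conserved quantity, counting ribosome-bound
    complements.  In instant-recycle mode Ef-Tu is not threaded through
    ternary complexes, so the Ef-Tu law reduces to the free pools."""
    import numpy as np

    pools = state.pools
    trna = pools.trna_total_free().copy()
    eftu_on_rib = 0
    efg_on_rib = 0
    rf1_on = rf2_on = rf3_on = rrf_on = 0
    n_rib = 0
    n_50s = 0
    for rib in state.ribosomes():
        n_rib += 1
        if rib.phase in HOLDS_50S_PHASES:
            n_50s += 1
        if rib.a_site_trna is not None:
            trna[rib.a_site_trna] += 1
        if rib.p_site_trna is not None:
            trna[rib.p_site_trna] += 1
        if rib.phase in HOLDS_EFTU_PHASES:
            eftu_on_rib += 1
        if rib.phase in HOLDS_EFG_PHASES:
            efg_on_rib += 1
        if rib.bound_rf == 1:
            rf1_on += 1
        elif rib.bound_rf == 2:
            rf2_on += 1
        if rib.phase == Phase.TERM_RF3_BOUND:
            rf3_on += 1
        if rib.phase == Phase.RRF_BOUND:
            rrf_on += 1

    if state.tc_off:
        eftu_total = pools.EfTu_GTP + pools.EfTu_GDP + pools.EfTu_Ts
    else:
        eftu_total = (pools.EfTu_GTP + pools.EfTu_GDP + pools.EfTu_Ts
                      + pools.total_free_tc + eftu_on_rib)
    return {
        "trna": np.asarray(trna),
        "EfTu": int(eftu_total),
        "EfTs": int(pools.Ts_free + pools.EfTu_Ts),
        "EfG": int(pools.EfG_GTP + pools.EfG_GDP + pools.EfG_free
                   + efg_on_rib),
        "RF1": int(pools.RF1 + rf1_on),
        "RF2": int(pools.RF2 + rf2_on),
        "RF3": int(pools.RF3_GTP + pools.RF3_GDP + rf3_on),
        "RRF": int(pools.RRF + rrf_on),
        "30S": int(pools.free_30S_PIC + n_rib),
        "50S": int(pools.free_50S + n_50s),
        "mRNA": len(state.mrnas),
    }


def check_conservation(state: CellState) -> list[str]:
    """Compare current totals against those at construction; returns the
    list of violated laws (empty when all conserved)."""
    import numpy as np

    now = conservation_totals(state)
    ref = state.initial_totals
    bad = []
    for key in ref:
        if key == "trna":
            if not np.array_equal(now["trna"], ref["trna"]):
                bad.append("trna")
        elif now[key] != ref[key]:
            bad.append(key)
    return bad
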