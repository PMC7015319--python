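"""Reaction catalogue: enumeration, stoichiometry, footprint geometry,
conservation and state-machine soundness."""

import numpy as np
import pytest
from scipy.constants import N_A

import ribosim.reactions as rx
from ribosim.engine import NaiveEngine, TreeEngine
from ribosim.fixtures import ToySpec, make_toy_state
from ribosim.rates import RateTable
from ribosim.species import SpeciesPools
from ribosim.state import CellState, Phase, is_blocked


def single_gene_state(length_aa=30, trna_free_tc=20, **pool_overrides):
    """One gene over a one-codon alphabet, one tRNA species, tRNAs
    pre-parked in free TC, generous factor pools."""
    spec = ToySpec(n_genes=1, length_aa=(length_aa, length_aa),
                   alphabet=("GCU",), n_trna_species=1, n_ribosomes=5)
    state = make_toy_state(spec)
    p = state.pools
    p.trna_charged[:] = 0
    p.trna_free_tc[:] = trna_free_tc
    for name, value in pool_overrides.items():
        setattr(p, name, value)
    # re-baseline the conservation reference after manual edits
    state.initial_totals = rx.conservation_totals(state)
    return state


def place_ribosome(state, mrna, p_site, phase):
    rib = state.new_ribosome(mrna, 0.0)
    rib.p_site = p_site
    rib.phase = phase
    mrna.ribosomes.append(rib)
    mrna.ribosomes.sort(key=lambda r: r.p_site)
    return rib


# --- enumeration -------------------------------------------------------


def test_empty_mrna_offers_only_initiation_loading():
    state = single_gene_state()
    mrna = state.mrnas[0]
    events = rx.enumerate_local_reactions(mrna, state.pools, state.rates)
    assert len(events) == 1
    assert events[0].kind == rx.PIC_BIND
    # and the propensity is k/(NA v) * n_PIC
    expected = (state.rates.factor("k_pic_bind")
                * state.pools.free_30S_PIC)
    assert events[0].propensity == pytest.approx(expected)


def test_no_tc_delivery_without_cognate_free_tc():
    state = single_gene_state(trna_free_tc=0)
    mrna = state.mrnas[0]
    place_ribosome(state, mrna, 5, Phase.AWAIT_TC)
    events = rx.enumerate_local_reactions(mrna, state.pools, state.rates)
    assert not any(ev.kind == rx.TC_BIND for ev in events)


def test_blocked_translocation_excluded_from_enumeration():
    state = single_gene_state(length_aa=60)
    mrna = state.mrnas[0]
    upstream = place_ribosome(state, mrna, 10, Phase.EFG_BOUND)
    place_ribosome(state, mrna, 24, Phase.TC_BOUND)  # 14 codons ahead
    events = rx.enumerate_local_reactions(mrna, state.pools, state.rates)
    kinds = {ev.kind for ev in events}
    assert rx.TRANSLOCATE not in kinds
    # move the leader one codon further: translocation reappears
    mrna.ribosomes[1].p_site = 25
    events = rx.enumerate_local_reactions(mrna, state.pools, state.rates)
    assert any(ev.kind == rx.TRANSLOCATE and ev.ribosome is upstream
               for ev in events)


def test_tc_formation_propensity_is_bimolecular_conversion():
    # charged(x)=10, EfTu:GTP=100, k2=1e8 /M/s, v=1 um^3
    pools = SpeciesPools(n_trna_species=1, EfTu_GTP=100,
                         trna_charged=np.array([10]))
    rates = RateTable(volume_um3=1.0).replace(k_tc_form=1.0e8)
    events = rx.enumerate_global_reactions(pools, rates)
    tc = [ev for ev in events if ev.kind == rx.TC_FORM]
    assert len(tc) == 1
    expected = 10 * 100 * 1.0e8 / (N_A * 1.0e-15)
    assert tc[0].propensity == pytest.approx(expected, rel=1e-12)
    # and against the hand value with Avogadro rounded as printed
    assert tc[0].propensity == pytest.approx(
        10 * 100 * 1e8 / (6.022e23 * 1e-15), rel=1e-3)


def test_no_ts_exchange_when_all_eftu_in_gtp_form():
    pools = SpeciesPools(n_trna_species=1, EfTu_GTP=50, Ts_free=10)
    events = rx.enumerate_global_reactions(pools, RateTable())
    kinds = {ev.kind for ev in events}
    assert rx.EFTS_ASSOC not in kinds
    assert rx.EFTS_EXCHANGE not in kinds


def test_no_aminoacylation_for_exhausted_species():
    pools = SpeciesPools(n_trna_species=2, trna_deacyl=np.array([0, 7]))
    events = rx.enumerate_global_reactions(pools, RateTable())
    aa = [ev.species for ev in events if ev.kind == rx.AMINOACYL]
    assert aa == [1]


# --- footprint geometry ------------------------------------------------


def test_is_blocked_boundary():
    state = single_gene_state(length_aa=60)
    mrna = state.mrnas[0]
    lone = place_ribosome(state, mrna, 10, Phase.EFG_BOUND)
    assert not is_blocked(lone, mrna)          # single ribosome: never
    leader = place_ribosome(state, mrna, 24, Phase.AWAIT_TC)
    assert is_blocked(lone, mrna)              # delta = 14 < 15: blocked
    leader.p_site = 25
    assert not is_blocked(lone, mrna)          # delta = 15: free to move
    assert not is_blocked(leader, mrna)        # leader unobstructed


def test_initiation_occlusion_boundary():
    state = single_gene_state(length_aa=60)
    mrna = state.mrnas[0]
    rib = place_ribosome(state, mrna, 15, Phase.TC_BOUND)
    assert mrna.start_blocked()                # P site 15: 15-1 < 15
    rib.p_site = 16
    assert not mrna.start_blocked()            # P site 16: start region free


# --- firing / stoichiometry --------------------------------------------


def test_tc_formation_stoichiometry():
    state = single_gene_state()
    p = state.pools
    p.trna_charged[0] = 5
    before = (p.EfTu_GTP, p.trna_charged[0], p.trna_free_tc[0])
    rx.apply_event(state, rx.TC_FORM, t=0.0, species=0)
    assert (p.EfTu_GTP, p.trna_charged[0], p.trna_free_tc[0]) == (
        before[0] - 1, before[1] - 1, before[2] + 1)


def test_firing_into_empty_pool_is_a_hard_error():
    state = single_gene_state()
    state.pools.trna_charged[0] = 0
    with pytest.raises(RuntimeError, match="stale propensity"):
        rx.apply_event(state, rx.TC_FORM, t=0.0, species=0)


def drive(state, rib_holder, sequence, t=0.0):
    """Fire a fixed kind sequence on the tracked ribosome."""
    for kind in sequence:
        rx.apply_event(state, kind, t, rib=rib_holder[0])


def test_full_elongation_cycle_net_balance():
    """Over one steady-state cycle: one charged tRNA and one Ef-Tu:GTP
    and Ef-G:GTP consumed; one deacylated tRNA, one Ef-Tu:GDP and one
    Ef-G:GDP produced; free TC unchanged."""
    state = single_gene_state(length_aa=10)
    p = state.pools
    p.trna_charged[0] = 10
    state.initial_totals = rx.conservation_totals(state)
    mrna = state.mrnas[0]
    rx.apply_event(state, rx.PIC_BIND, 0.0, mrna=mrna)
    rib = mrna.ribosomes[0]
    cycle = [rx.TC_BIND, rx.GTPASE, rx.ACCOMMODATE, rx.PEPTIDYL,
             rx.EFG_BIND, rx.TRANSLOCATE, rx.FACTOR_RELEASE]
    rx.apply_event(state, rx.JOIN_50S, 0.0, rib=rib)
    rx.apply_event(state, rx.INIT_COMPLETE, 0.0, rib=rib)
    # first cycle primes the P site with an elongator tRNA
    rx.apply_event(state, rx.TC_FORM, 0.0, species=0)
    for kind in cycle:
        rx.apply_event(state, kind, 0.0, rib=rib,
                       species=0 if kind == rx.TC_BIND else None)
    snapshot = {
        "charged": int(p.trna_charged[0]),
        "deacyl": int(p.trna_deacyl[0]),
        "free_tc": int(p.trna_free_tc[0]),
        "EfTu_GTP": p.EfTu_GTP, "EfTu_GDP": p.EfTu_GDP,
        "EfG_GTP": p.EfG_GTP, "EfG_GDP": p.EfG_GDP,
    }
    rx.apply_event(state, rx.TC_FORM, 0.0, species=0)
    for kind in cycle:
        rx.apply_event(state, kind, 0.0, rib=rib,
                       species=0 if kind == rx.TC_BIND else None)
    assert int(p.trna_charged[0]) == snapshot["charged"] - 1
    assert int(p.trna_deacyl[0]) == snapshot["deacyl"] + 1
    assert int(p.trna_free_tc[0]) == snapshot["free_tc"]
    assert p.EfTu_GTP == snapshot["EfTu_GTP"] - 1
    assert p.EfTu_GDP == snapshot["EfTu_GDP"] + 1
    assert p.EfG_GTP == snapshot["EfG_GTP"] - 1
    assert p.EfG_GDP == snapshot["EfG_GDP"] + 1
    assert rx.check_conservation(state) == []


def test_termination_recycle_empties_single_ribosome_mrna():
    state = single_gene_state(length_aa=1)   # start + GCU + UAA
    p = state.pools
    mrna = state.mrnas[0]
    before_50s, before_pic = p.free_50S, p.free_30S_PIC
    rx.apply_event(state, rx.PIC_BIND, 0.0, mrna=mrna)
    rib = mrna.ribosomes[0]
    for kind, sp in [(rx.JOIN_50S, None), (rx.INIT_COMPLETE, None),
                     (rx.TC_BIND, 0), (rx.GTPASE, None),
                     (rx.ACCOMMODATE, None), (rx.PEPTIDYL, None),
                     (rx.EFG_BIND, None), (rx.TRANSLOCATE, None),
                     (rx.FACTOR_RELEASE, None)]:
        rx.apply_event(state, kind, 0.0, rib=rib, species=sp)
    assert rib.phase == Phase.TERM_WAIT_RF   # stop codon reached
    for kind in [rx.RF1_BIND, rx.RF3_BIND, rx.TERM_RELEASE, rx.RRF_BIND,
                 rx.SPLIT]:
        rx.apply_event(state, kind, 1.0, rib=rib)
    assert mrna.ribosomes == []
    assert p.free_50S == before_50s
    assert p.free_30S_PIC == before_pic
    assert len(state.completions) == 1
    gene_id, length_aa, n_decoded = state.completions[0][:3]
    assert (length_aa, n_decoded) == (1, 1)
    assert rx.check_conservation(state) == []


def test_readthrough_hook_refuses_nonzero_rate():
    from ribosim.fixtures import make_toy_system

    tr, pools, rates, dm = make_toy_system(ToySpec())
    bad = rates.replace(k_readthrough=1.0)
    with pytest.raises(NotImplementedError):
        CellState(tr.mrna_instances(), pools, bad, dm)


# --- trajectory invariants ---------------------------------------------


def test_conservation_exclusion_and_phi_consistency_over_run(toy_state):
    """Every conservation law holds exactly, footprints never overlap,
    and the engine's cached propensities match from-scratch enumeration
    throughout a 2e4-event trajectory."""
    eng = TreeEngine(toy_state, seed=3)
    for chunk in range(20):
        eng.run(t_end=float("inf"), checkpoint_dt=float("inf"),
                max_events=(chunk + 1) * 1000)
        assert rx.check_conservation(toy_state) == []
        for mrna in toy_state.mrnas:
            mrna.check_exclusion()
            cached = eng.tree.leaf(mrna.leaf)
            assert cached == pytest.approx(eng.phi_local(mrna), abs=1e-12)
        oracle = eng.total_propensity_oracle()
        assert eng.tree.root == pytest.approx(oracle, rel=1e-9)


#: reaction kind -> (phase before, phase after); None = created/removed
_TRANSITIONS = {
    rx.JOIN_50S: (Phase.INIT_WAIT50S, Phase.INIT_JOINED),
    rx.INIT_COMPLETE: (Phase.INIT_JOINED,
                       {Phase.AWAIT_TC, Phase.TERM_WAIT_RF}),
    rx.TC_BIND: (Phase.AWAIT_TC, Phase.TC_BOUND),
    rx.GTPASE: (Phase.TC_BOUND, Phase.GTP_HYDRO),
    rx.ACCOMMODATE: (Phase.GTP_HYDRO, Phase.ACCOMMODATED),
    rx.REJECT: (Phase.GTP_HYDRO, Phase.AWAIT_TC),
    rx.PEPTIDYL: (Phase.ACCOMMODATED, Phase.PRE_TRANSLOC),
    rx.EFG_BIND: (Phase.PRE_TRANSLOC, Phase.EFG_BOUND),
    rx.TRANSLOCATE: (Phase.EFG_BOUND, Phase.POST_TRANSLOC),
    rx.FACTOR_RELEASE: (Phase.POST_TRANSLOC,
                        {Phase.AWAIT_TC, Phase.TERM_WAIT_RF}),
    rx.RF1_BIND: (Phase.TERM_WAIT_RF, Phase.TERM_RF_BOUND),
    rx.RF2_BIND: (Phase.TERM_WAIT_RF, Phase.TERM_RF_BOUND),
    rx.RF3_BIND: (Phase.TERM_RF_BOUND, Phase.TERM_RF3_BOUND),
    rx.TERM_RELEASE: (Phase.TERM_RF3_BOUND, Phase.AWAIT_RRF),
    rx.RRF_BIND: (Phase.AWAIT_RRF, Phase.RRF_BOUND),
    rx.SPLIT: (Phase.RRF_BOUND, None),
    rx.DROP_OFF: (Phase.AWAIT_TC, None),
}


def test_state_machine_soundness(toy_state, monkeypatch):
    """Every ribosome walks the configured reaction graph: each fired
    sub-step leaves exactly the expected phase transition."""
    orig = rx.apply_event
    seen = []

    def checked(state, kind, t, mrna=None, rib=None, species=None):
        before = rib.phase if rib is not None else None
        out = orig(state, kind, t, mrna, rib, species)
        if kind in _TRANSITIONS:
            exp_from, exp_to = _TRANSITIONS[kind]
            assert before == exp_from, rx.KIND_NAMES[kind]
            if exp_to is None:
                assert rib not in rib.mrna.ribosomes
            else:
                allowed = exp_to if isinstance(exp_to, set) else {exp_to}
                assert rib.phase in allowed, rx.KIND_NAMES[kind]
            seen.append(kind)
        return out

    monkeypatch.setattr(rx, "apply_event", checked)
    eng = NaiveEngine(toy_state, seed=5)
    eng.run(t_end=float("inf"), checkpoint_dt=float("inf"), max_events=5000)
    # the walk exercised the whole cycle including termination
    assert {rx.JOIN_50S, rx.TC_BIND, rx.TRANSLOCATE, rx.SPLIT} <= set(seen)
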