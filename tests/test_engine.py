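"""SSA engines: waiting-time law, locus selection, analytic limits,
determinism and deadlock reporting."""

import math

import numpy as np
import pytest
from scipy import stats

from ribosim.engine import NaiveEngine, TreeEngine
from ribosim.fixtures import ToySpec, make_toy_state
from ribosim.rates import RateTable
from ribosim.species import SpeciesPools
from ribosim.state import CellState
from ribosim.genetics import DecodeMap


def test_t_end_zero_returns_initial_state(toy_state):
    before = toy_state.pools.copy()
    res = TreeEngine(toy_state, seed=1).run(0.0)
    assert res.event_count == 0 and res.t_final == 0.0
    assert toy_state.pools.free_50S == before.free_50S
    assert not any(m.ribosomes for m in toy_state.mrnas)


def test_same_seed_gives_identical_trajectories():
    r1 = TreeEngine(make_toy_state(), seed=7).run(10.0)
    r2 = TreeEngine(make_toy_state(), seed=7).run(10.0)
    assert r1.event_count == r2.event_count
    assert r1.state.decode_t == r2.state.decode_t
    assert r1.state.completions == r2.state.completions
    r3 = TreeEngine(make_toy_state(), seed=8).run(10.0)
    assert r3.state.decode_t != r1.state.decode_t


def test_waiting_times_follow_exponential_law(toy_state):
    """dt ~ Exponential(Phi): normalised waits dt*Phi are standard
    exponential (mean 1 within 3 SE; KS agreement)."""
    eng = TreeEngine(toy_state, seed=9, collect_dts=True)
    eng.run(t_end=float("inf"), checkpoint_dt=float("inf"), max_events=10_000)
    z = np.array(eng.dts) * np.array(eng.phis)
    assert abs(z.mean() - 1.0) < 3.0 / math.sqrt(len(z))
    assert stats.kstest(z, "expon").pvalue > 0.01


def test_equal_propensity_loci_fire_equally_often():
    """Two identical empty mRNAs compete for the first 30S:PIC: each
    should win half the time over independent replicates."""
    wins = 0
    n = 400
    for i in range(n):
        state = make_toy_state(ToySpec(n_genes=2, length_aa=(10, 10),
                                       seed=0))
        eng = TreeEngine(state, seed=1000 + i)
        while not any(m.ribosomes for m in state.mrnas):
            eng.run(t_end=float("inf"), checkpoint_dt=float("inf"),
                    max_events=eng.event_count + 1)
        loaded = [bool(m.ribosomes) for m in state.mrnas]
        assert sum(loaded) == 1
        wins += loaded[0]
    se = math.sqrt(n * 0.25)
    assert abs(wins - n / 2) < 3 * se


def _pools_only_state(k_aminoacyl: float, n_deacyl: int) -> CellState:
    dm = DecodeMap({"tRNA0": ["GCU"]})
    pools = SpeciesPools(n_trna_species=1,
                         trna_deacyl=np.array([n_deacyl]))
    rates = RateTable(volume_um3=1.0e-3).replace(
        k_aminoacyl=k_aminoacyl, k_tc_form=0.0)
    return CellState([], pools, rates, dm)


@pytest.mark.parametrize("engine_cls", [TreeEngine, NaiveEngine])
def test_pure_death_extinction_time(engine_cls):
    """Irreversible A -> B with n_A = 100 at rate k per molecule: the
    mean extinction time is sum_i 1/(k i) (within 3 SE over replicates)."""
    k, n0, reps = 2.0, 100, 100
    times = []
    for i in range(reps):
        st = _pools_only_state(k, n0)
        res = engine_cls(st, seed=i).run(1e9)
        assert res.deadlock is not None
        assert res.event_count == n0
        times.append(res.t_final)
    expected = sum(1.0 / (k * i) for i in range(1, n0 + 1))
    sd = math.sqrt(sum(1.0 / (k * i) ** 2 for i in range(1, n0 + 1)))
    assert abs(np.mean(times) - expected) < 3 * sd / math.sqrt(reps)


def test_deadlock_report_names_the_missing_factor():
    """With no class-1 release factors every ribosome eventually parks at
    a stop codon and the trajectory ends in a described deadlock."""
    state = make_toy_state(ToySpec(pool_sizes={"RF1": 0, "RF2": 0},
                                   rate_overrides={"k_tc_dissoc": 0.0}))
    res = TreeEngine(state, seed=4).run(1e9)
    assert res.deadlock is not None
    assert res.deadlock.waiting["RF1/RF2"] > 0
    assert "RF1/RF2" in res.deadlock.describe()


def test_serial_pipeline_elongation_rate_limit():
    """One ribosome, one mRNA, saturating pools: C_p approaches the
    harmonic sum of the sub-step rates, dominated by the rate-limiting
    peptidyl transfer."""
    spec = ToySpec(n_genes=1, length_aa=(100, 100), n_ribosomes=1,
                   alphabet=("GCU",), n_trna_species=1, trna_each=20,
                   pool_sizes={"EfTu": 60, "EfG": 30}, seed=2,
                   rate_overrides={"k_tc_dissoc": 0.0})
    state = make_toy_state(spec)
    rates = state.rates
    res = TreeEngine(state, seed=12).run(300.0)
    assert res.deadlock is None
    comps = res.completions_df
    assert len(comps) >= 15
    nav = rates.na_v
    per_codon = (
        1.0 / (rates.value("k_tc_bind") / nav * 20)      # TC delivery
        + 1.0 / rates.value("k_gtpase")
        + 1.0 / rates.value("k_accom")
        + 1.0 / rates.value("k_peptidyl")                 # rate-limiting
        + 1.0 / (rates.value("k_efg_bind") / nav
                 * state.pools.EfG_GTP)
        + 1.0 / rates.value("k_transloc")
        + 1.0 / rates.value("k_factor_release")
    )
    from ribosim.observables import peptide_elongation_rate

    cp = peptide_elongation_rate(comps, burn_in_fraction=0.0,
                                 t_end=res.t_final)
    assert cp == pytest.approx(1.0 / per_codon, rel=0.05)


def test_free_tc_stationary_fraction_matches_birth_death():
    """Charged <-> free-TC two-state toy: stationary free-TC fraction is
    a/(a+b) with per-molecule formation rate a and dissociation rate b."""
    dm = DecodeMap({"tRNA0": ["GCU"]})
    n_eftu, n_trna = 20000, 50
    pools = SpeciesPools(n_trna_species=1, EfTu_GTP=n_eftu,
                         trna_charged=np.array([n_trna]))
    k_form, k_dis = 1.0e8, 30.0
    rates = RateTable(volume_um3=1.0e-3).replace(
        k_tc_form=k_form, k_tc_dissoc=k_dis, k_aminoacyl=0.0)
    state = CellState([], pools, rates, dm)
    res = TreeEngine(state, seed=21).run(60.0, checkpoint_dt=0.05)
    a = k_form / rates.na_v * n_eftu     # Ef-Tu depletion < 0.3%
    expected = a / (a + k_dis)
    from ribosim.observables import free_tc_fraction

    frac = free_tc_fraction(res, window=50.0).iloc[0]
    assert frac == pytest.approx(expected, abs=0.02)


def test_event_log_records_every_fire(tmp_path):
    import gzip

    from ribosim.fixtures import make_toy_system

    tr, pools, rates, dm = make_toy_system(ToySpec(seed=5))
    state = CellState(tr.mrna_instances(), pools, rates, dm,
                      log_events=True)
    res = TreeEngine(state, seed=2).run(2.0)
    assert len(state.event_log) == res.event_count
    path = tmp_path / "events.tsv.gz"
    state.write_event_log(path)
    with gzip.open(path, "rt") as fh:
        lines = fh.read().splitlines()
    assert lines[0].startswith("t\treaction_name")
    assert len(lines) == res.event_count + 1


def test_tree_engine_audit_passes_on_long_run(toy_state):
    eng = TreeEngine(toy_state, seed=2, audit_every=500)
    res = eng.run(t_end=float("inf"), checkpoint_dt=float("inf"),
                  max_events=30_000)
    assert res.truncated
    eng.tree.check_consistency()
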