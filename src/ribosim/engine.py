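"""Exact stochastic simulation engines.

:class:`TreeEngine` is the production engine: per-mRNA leaves of a binary
propensity tree carry the pool-independent first-order reactions local to
each mRNA, while every pool-coupled reaction — the pool-level cycles and
all bimolecular ribosome/pool associations (TC delivery, 50S joining,
Ef-G, RF1/2/3 and RRF binding, 30S:PIC loading) — is aggregated into
species-level channels on one dedicated global leaf.  A channel's
propensity is ``per-pair factor x pool count x number of waiting
complexes``; on firing, the target complex is drawn uniformly among the
waiters, which is exactly equivalent to enumerating each waiter as its
own reaction.  Waiter sets support O(1) add/remove/sample, so the
per-event cost stays O(log2 N) tree work plus O(1) channel refreshes,
with no approximation and no rejection step.

:class:`NaiveEngine` is the independent reference: a textbook
direct-method SSA that re-enumerates every fireable reaction from the
raw state at every step and selects by linear scan.  Both engines fire
through the same :func:`ribosim.reactions.apply_event`, so their
trajectories are statistically equivalent iff the tree/channel
bookkeeping is correct — which is what the equivalence tests check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import reactions as rx
from .genetics import codon_str
from .state import (CellState, ELONGATION_PHASES, MRNAInstance,
                    MIN_SEPARATION, Phase)
from .tree import PropensityTree

__all__ = ["TreeEngine", "NaiveEngine", "TrajectoryResult", "DeadlockReport"]

# indices of the scalar global channels
(
    CH_PIC, CH_50S, CH_EFG, CH_RF1, CH_RF2, CH_RF3, CH_RRF,
    CH_AA, CH_TCF, CH_TCD, CH_TSA, CH_TSX, CH_GREL, CH_GBIND, CH_RF3X,
) = range(15)
N_SCALAR = 15
_TC_OFF_DISABLED = {CH_AA, CH_TCF, CH_TCD, CH_TSA, CH_TSX}

_UAA = rx._ci("UAA")
_UAG = rx._ci("UAG")
_UGA = rx._ci("UGA")


@dataclass
class DeadlockReport:
    """Why the total propensity reached zero."""

    t: float
    waiting: dict[str, int]
    starved_pools: list[str]

    def describe(self) -> str:
        lines = [f"simulation deadlocked at t={self.t:.3f}s"]
        for k, v in self.waiting.items():
            if v:
                lines.append(f"  {v} complexes waiting on {k}")
        if self.starved_pools:
            lines.append("  exhausted pools: " + ", ".join(self.starved_pools))
        return "\n".join(lines)


@dataclass
class TrajectoryResult:
    """Everything a simulation run produced."""

    state: CellState
    t_final: float
    t_end: float
    event_count: int
    seed: int
    checkpoints: list = field(default_factory=list)
    deadlock: Optional[DeadlockReport] = None
    truncated: bool = False

    @property
    def trna_names(self) -> list[str]:
        return self.state.decode_map.trna_names

    @property
    def trna_totals(self) -> np.ndarray:
        return np.asarray(self.state.initial_totals["trna"])

    @property
    def n_50s_total(self) -> int:
        return int(self.state.initial_totals["50S"])

    @property
    def n_nt(self) -> int:
        return int(sum(3 * m.n_codons for m in self.state.mrnas))

    @property
    def completions_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.state.completions,
            columns=["gene_id", "length_aa", "n_decoded", "t_init",
                     "t_elong_start", "t_elong_end", "t_complete"],
        )

    @property
    def decode_df(self) -> pd.DataFrame:
        st = self.state
        names = self.trna_names
        return pd.DataFrame({
            "t": st.decode_t,
            "codon": [codon_str(c) for c in st.decode_codon],
            "trna": [names[s] for s in st.decode_trna],
            "wait": st.decode_wait,
            "stalled": st.decode_stalled,
        })

    @property
    def checkpoints_df(self) -> pd.DataFrame:
        rows = []
        names = self.trna_names
        for cp in self.checkpoints:
            row = {k: v for k, v in cp.items() if k != "free_tc"}
            for name, v in zip(names, cp["free_tc"]):
                row[f"tc_{name}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def state_snapshot(state: CellState, t: float) -> dict:
    """Instantaneous classification of every ribosomal complex plus the
    free pools; the basis of all time-course observables."""
    pools = state.pools
    tc = pools.trna_free_tc
    dm = state.decode_map
    n_wait50s = n_init = n_elong = n_term = 0
    n_starved = n_blocked = 0
    for m in state.mrnas:
        ribs = m.ribosomes
        for i, rib in enumerate(ribs):
            ph = rib.phase
            if ph == Phase.INIT_WAIT50S:
                n_wait50s += 1
            elif ph == Phase.INIT_JOINED:
                n_init += 1
            elif ph in ELONGATION_PHASES:
                n_elong += 1
                if ph == Phase.AWAIT_TC:
                    if all(tc[d] == 0 for d in dm.decoders(rib.a_site_codon)):
                        n_starved += 1
                elif ph == Phase.EFG_BOUND:
                    if (i + 1 < len(ribs)
                            and ribs[i + 1].p_site - rib.p_site
                            < MIN_SEPARATION):
                        n_blocked += 1
            else:
                n_term += 1
    return {
        "t": t,
        "n_wait50s": n_wait50s,
        "n_initiating": n_init,
        "n_elongating": n_elong,
        "n_terminating": n_term,
        "n_starved": n_starved,
        "n_blocked": n_blocked,
        "free_50S": pools.free_50S,
        "free_30S_PIC": pools.free_30S_PIC,
        "EfTu_GTP": pools.EfTu_GTP,
        "EfTu_GDP": pools.EfTu_GDP,
        "EfTu_Ts": pools.EfTu_Ts,
        "free_tc": pools.trna_free_tc.copy(),
        "deacyl_total": int(pools.trna_deacyl.sum()),
        "charged_total": int(pools.trna_charged.sum()),
    }


class _RandStream:
    """Buffered uniform(0,1) draws from a seeded PCG64 generator."""

    __slots__ = ("rng", "_buf", "_i")

    def __init__(self, seed: int) -> None:
        self.rng = np.random.Generator(np.random.PCG64(seed))
        self._buf = self.rng.random(16384)
        self._i = 0

    def next(self) -> float:
        i = self._i
        if i >= len(self._buf):
            self._buf = self.rng.random(16384)
            i = 0
        self._i = i + 1
        return self._buf[i]


class _EngineBase:
    """Shared run loop, clock, ledgers and deadlock reporting."""

    def __init__(self, state: CellState, seed: int,
                 collect_dts: bool = False) -> None:
        self.state = state
        self.seed = int(seed)
        self.rand = _RandStream(self.seed)
        self.t = 0.0
        self.event_count = 0
        self.event_counts: dict[tuple, int] = {}
        self.collect_dts = collect_dts
        self.dts: list[float] = []
        self.phis: list[float] = []  # total propensity before each event
        for i, m in enumerate(state.mrnas):
            m.leaf = i

    def _record(self, kind: int, species, mrna) -> None:
        key = (kind, -1 if species is None else species,
               -1 if mrna is None else mrna.leaf)
        self.event_counts[key] = self.event_counts.get(key, 0) + 1

    def _deadlock_report(self) -> DeadlockReport:
        st = self.state
        waiting = {
            "free 50S subunits": len(st.wait_50s),
            "Ef-G:GTP": len(st.wait_efg),
            "RF1/RF2": sum(len(s) for s in st.wait_rf.values()),
            "RF3:GTP": len(st.wait_rf3),
            "RRF": len(st.wait_rrf),
        }
        names = st.decode_map.trna_names
        starved = [
            f"free TC ({names[s]})"
            for s in range(st.decode_map.n_species)
            if len(st.wait_tc[s]) and st.pools.trna_free_tc[s] == 0
        ]
        return DeadlockReport(self.t, waiting, starved)

    def step(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def total_propensity(self) -> float:  # pragma: no cover - overridden
        raise NotImplementedError

    def run(self, t_end: float, checkpoint_dt: float = 1.0,
            max_events: Optional[int] = None) -> TrajectoryResult:
        """Advance until ``t >= t_end`` or the propensity reaches zero.

        State snapshots are taken on a fixed grid of simulated-time
        checkpoints; the same seed and inputs give bit-identical
        trajectories."""
        checkpoints: list = []
        next_cp = checkpoint_dt
        deadlock = None
        truncated = False
        if t_end <= 0:
            return TrajectoryResult(self.state, self.t, t_end,
                                    self.event_count, self.seed, checkpoints)
        while True:
            total = self.total_propensity()
            if total <= 0.0:
                deadlock = self._deadlock_report()
                break
            dt = -math.log(1.0 - self.rand.next()) / total
            t_new = self.t + dt
            while next_cp <= t_new and next_cp <= t_end + 1e-12:
                checkpoints.append(state_snapshot(self.state, next_cp))
                next_cp += checkpoint_dt
            if t_new >= t_end:
                self.t = t_end
                break
            self.t = t_new
            if self.collect_dts:
                self.dts.append(dt)
                self.phis.append(total)
            self._fire_next(total)
            self.event_count += 1
            if max_events is not None and self.event_count >= max_events:
                truncated = True
                break
        return TrajectoryResult(self.state, self.t, t_end, self.event_count,
                                self.seed, checkpoints, deadlock, truncated)


class NaiveEngine(_EngineBase):
    """Reference direct-method SSA: full re-enumeration and linear scan."""

    def _all_events(self) -> list[rx.ReactionEvent]:
        st = self.state
        events: list[rx.ReactionEvent] = []
        for m in st.mrnas:
            events.extend(rx.enumerate_local_reactions(m, st.pools, st.rates))
        events.extend(
            rx.enumerate_global_reactions(st.pools, st.rates, st.tc_off))
        return events

    def total_propensity(self) -> float:
        return sum(ev.propensity for ev in self._all_events())

    def _fire_next(self, total: float) -> None:
        events = self._all_events()
        target = self.rand.next() * sum(ev.propensity for ev in events)
        acc = 0.0
        chosen = events[-1]
        for ev in events:
            acc += ev.propensity
            if acc > target:
                chosen = ev
                break
        rx.apply_event(self.state, chosen.kind, self.t, chosen.mrna,
                       chosen.ribosome, chosen.species)
        self._record(chosen.kind, chosen.species, chosen.mrna)

    def step(self):
        total = self.total_propensity()
        if total <= 0:
            raise RuntimeError("zero total propensity")
        dt = -math.log(1.0 - self.rand.next()) / total
        self.t += dt
        self._fire_next(total)
        self.event_count += 1
        return dt


class TreeEngine(_EngineBase):
    """Production SSA with binary-tree indexing over mRNAs + global leaf."""

    def __init__(self, state: CellState, seed: int,
                 collect_dts: bool = False, audit_every: int = 1000) -> None:
        super().__init__(state, seed, collect_dts)
        r = state.rates
        self._f = {name: r.factor(name) for name in r.rates}
        f = self._f
        # base first-order rate by phase (translocation gated separately)
        self._phase_rate = [0.0] * len(Phase)
        self._phase_rate[Phase.INIT_JOINED] = f["k_init_complete"]
        self._phase_rate[Phase.AWAIT_TC] = f["k_drop_off"]
        self._phase_rate[Phase.TC_BOUND] = f["k_gtpase"]
        self._phase_rate[Phase.GTP_HYDRO] = f["k_accom"] + f["k_reject"]
        self._phase_rate[Phase.ACCOMMODATED] = f["k_peptidyl"]
        self._phase_rate[Phase.EFG_BOUND] = f["k_transloc"]
        self._phase_rate[Phase.POST_TRANSLOC] = f["k_factor_release"]
        self._phase_rate[Phase.TERM_RF3_BOUND] = f["k_term_release"]
        self._phase_rate[Phase.RRF_BOUND] = f["k_split"]

        S = state.decode_map.n_species
        self.n_species = S
        self.n_mrna = len(state.mrnas)
        self.global_leaf = self.n_mrna
        self.chan = [0.0] * (N_SCALAR + S)
        self._refresh_scalar_channels()
        for s in range(S):
            self._refresh_tc_channel(s)
        leaves = [self.phi_local(m) for m in state.mrnas]
        leaves.append(sum(self.chan))
        self.tree = PropensityTree(leaves)
        self.audit_every = audit_every

    # -- propensity bookkeeping -----------------------------------------

    def phi_local(self, mrna: MRNAInstance) -> float:
        """First-order local propensity of one mRNA (recomputed by scan)."""
        rates = self._phase_rate
        total = 0.0
        ribs = mrna.ribosomes
        n = len(ribs)
        for i in range(n):
            rib = ribs[i]
            ph = rib.phase
            if (ph == Phase.EFG_BOUND and i + 1 < n
                    and ribs[i + 1].p_site - rib.p_site < MIN_SEPARATION):
                continue  # sterically blocked: translocation disabled
            total += rates[ph]
        return total

    def _refresh_scalar_channels(self) -> None:
        st = self.state
        pools = st.pools
        f = self._f
        ch = self.chan
        ch[CH_PIC] = (f["k_pic_bind"] * pools.free_30S_PIC
                      * len(st.start_free))
        ch[CH_50S] = f["k_50s_join"] * pools.free_50S * len(st.wait_50s)
        ch[CH_EFG] = f["k_efg_bind"] * pools.EfG_GTP * len(st.wait_efg)
        n_uaa = len(st.wait_rf[_UAA])
        ch[CH_RF1] = (f["k_rf1_bind"] * pools.RF1
                      * (n_uaa + len(st.wait_rf[_UAG])))
        ch[CH_RF2] = (f["k_rf2_bind"] * pools.RF2
                      * (n_uaa + len(st.wait_rf[_UGA])))
        ch[CH_RF3] = f["k_rf3_bind"] * pools.RF3_GTP * len(st.wait_rf3)
        ch[CH_RRF] = f["k_rrf_bind"] * pools.RRF * len(st.wait_rrf)
        if st.tc_off:
            for i in _TC_OFF_DISABLED:
                ch[i] = 0.0
        else:
            ch[CH_AA] = f["k_aminoacyl"] * int(pools.trna_deacyl.sum())
            ch[CH_TCF] = (f["k_tc_form"] * pools.EfTu_GTP
                          * int(pools.trna_charged.sum()))
            ch[CH_TCD] = f["k_tc_dissoc"] * int(pools.trna_free_tc.sum())
            ch[CH_TSA] = f["k_efts_assoc"] * pools.EfTu_GDP * pools.Ts_free
            ch[CH_TSX] = f["k_efts_exchange"] * pools.EfTu_Ts
        ch[CH_GREL] = f["k_efg_gdp_release"] * pools.EfG_GDP
        ch[CH_GBIND] = f["k_efg_gtp_bind"] * pools.EfG_free
        ch[CH_RF3X] = f["k_rf3_exchange"] * pools.RF3_GDP

    def _refresh_tc_channel(self, s: int) -> None:
        st = self.state
        self.chan[N_SCALAR + s] = (self._f["k_tc_bind"]
                                   * int(st.pools.trna_free_tc[s])
                                   * len(st.wait_tc[s]))

    def total_propensity(self) -> float:
        return self.tree.root

    def recompute_all(self) -> None:
        """Full refresh of channels and leaves (drift control / tests)."""
        self._refresh_scalar_channels()
        for s in range(self.n_species):
            self._refresh_tc_channel(s)
        leaves = [self.phi_local(m) for m in self.state.mrnas]
        leaves.append(sum(self.chan))
        self.tree = PropensityTree(leaves)

    def total_propensity_oracle(self) -> float:
        """From-scratch enumeration total (independent of the caches)."""
        st = self.state
        total = sum(
            ev.propensity
            for m in st.mrnas
            for ev in rx.enumerate_local_reactions(m, st.pools, st.rates)
        )
        total += sum(ev.propensity for ev in
                     rx.enumerate_global_reactions(st.pools, st.rates,
                                                   st.tc_off))
        return total

    # -- firing ----------------------------------------------------------

    def _fire_next(self, total: float) -> None:
        leaf = self.tree.select(self.rand.next())
        if leaf == self.global_leaf:
            cs, kind, species, mrna = self._fire_global()
        else:
            mrna = self.state.mrnas[leaf]
            cs, kind, species = self._fire_local(mrna)
        # refresh caches: the touched mRNA leaf plus the global leaf
        self._refresh_scalar_channels()
        for s in cs.tc_touched:
            self._refresh_tc_channel(s)
        if cs.mrna is not None:
            self.tree.update(cs.mrna.leaf, self.phi_local(cs.mrna))
        self.tree.update(self.global_leaf, sum(self.chan))
        self._record(kind, species, mrna)
        if self.audit_every and self.event_count % self.audit_every == 0:
            root = self.tree.root
            naive = sum(self.tree.leaves())
            if abs(root - naive) > 1e-9 * max(1.0, naive):
                raise AssertionError("propensity tree root drifted")

    def _fire_local(self, mrna: MRNAInstance):
        """Linear scan within one mRNA's reaction list (list order ties)."""
        st = self.state
        rates = self._phase_rate
        leafval = self.tree.leaf(mrna.leaf)
        target = self.rand.next() * leafval
        ribs = mrna.ribosomes
        n = len(ribs)
        acc = 0.0
        chosen = None
        for i in range(n):
            rib = ribs[i]
            ph = rib.phase
            if (ph == Phase.EFG_BOUND and i + 1 < n
                    and ribs[i + 1].p_site - rib.p_site < MIN_SEPARATION):
                continue
            r = rates[ph]
            if r <= 0.0:
                continue
            acc += r
            if acc > target:
                chosen = (rib, ph, target - (acc - r))
                break
        if chosen is None:  # float edge: take the last enabled reaction
            for i in range(n - 1, -1, -1):
                rib = ribs[i]
                ph = rib.phase
                if rates[ph] > 0.0 and not (
                    ph == Phase.EFG_BOUND and i + 1 < n
                    and ribs[i + 1].p_site - rib.p_site < MIN_SEPARATION
                ):
                    chosen = (rib, ph, 0.0)
                    break
        if chosen is None:
            raise RuntimeError("stale local leaf: no enabled reaction")
        rib, ph, rem = chosen
        kind = {
            Phase.INIT_JOINED: rx.INIT_COMPLETE,
            Phase.AWAIT_TC: rx.DROP_OFF,
            Phase.TC_BOUND: rx.GTPASE,
            Phase.ACCOMMODATED: rx.PEPTIDYL,
            Phase.EFG_BOUND: rx.TRANSLOCATE,
            Phase.POST_TRANSLOC: rx.FACTOR_RELEASE,
            Phase.TERM_RF3_BOUND: rx.TERM_RELEASE,
            Phase.RRF_BOUND: rx.SPLIT,
        }.get(ph)
        if ph == Phase.GTP_HYDRO:
            kind = rx.ACCOMMODATE if rem < self._f["k_accom"] else rx.REJECT
        if kind is None:
            raise RuntimeError(f"no local reaction for phase {ph.name}")
        cs = rx.apply_event(st, kind, self.t, mrna, rib)
        return cs, kind, None

    def _fire_global(self):
        st = self.state
        ch = self.chan
        gtotal = self.tree.leaf(self.global_leaf)
        target = self.rand.next() * gtotal
        acc = 0.0
        idx = -1
        rem = 0.0
        for i, v in enumerate(ch):
            if v <= 0.0:
                continue
            acc += v
            if acc > target:
                idx = i
                rem = target - (acc - v)
                break
        if idx < 0:  # float edge
            for i in range(len(ch) - 1, -1, -1):
                if ch[i] > 0.0:
                    idx, rem = i, 0.0
                    break
        if idx < 0:
            raise RuntimeError("stale global leaf: no enabled channel")
        u = rem / ch[idx] if ch[idx] > 0 else 0.0
        pools = st.pools

        if idx >= N_SCALAR:
            s = idx - N_SCALAR
            rib = st.wait_tc[s].sample(u)
            cs = rx.apply_event(st, rx.TC_BIND, self.t, rib.mrna, rib, s)
            return cs, rx.TC_BIND, s, rib.mrna
        if idx == CH_PIC:
            mrna = st.start_free.sample(u)
            cs = rx.apply_event(st, rx.PIC_BIND, self.t, mrna)
            return cs, rx.PIC_BIND, None, mrna
        if idx == CH_50S:
            rib = st.wait_50s.sample(u)
            cs = rx.apply_event(st, rx.JOIN_50S, self.t, rib.mrna, rib)
            return cs, rx.JOIN_50S, None, rib.mrna
        if idx == CH_EFG:
            rib = st.wait_efg.sample(u)
            cs = rx.apply_event(st, rx.EFG_BIND, self.t, rib.mrna, rib)
            return cs, rx.EFG_BIND, None, rib.mrna
        if idx in (CH_RF1, CH_RF2):
            if idx == CH_RF1:
                sets = (st.wait_rf[_UAA], st.wait_rf[_UAG])
                kind = rx.RF1_BIND
            else:
                sets = (st.wait_rf[_UAA], st.wait_rf[_UGA])
                kind = rx.RF2_BIND
            w = len(sets[0]) + len(sets[1])
            j = min(int(u * w), w - 1)
            if j < len(sets[0]):
                rib = sets[0]._items[j]
            else:
                rib = sets[1]._items[j - len(sets[0])]
            cs = rx.apply_event(st, kind, self.t, rib.mrna, rib)
            return cs, kind, None, rib.mrna
        if idx == CH_RF3:
            rib = st.wait_rf3.sample(u)
            cs = rx.apply_event(st, rx.RF3_BIND, self.t, rib.mrna, rib)
            return cs, rx.RF3_BIND, None, rib.mrna
        if idx == CH_RRF:
            rib = st.wait_rrf.sample(u)
            cs = rx.apply_event(st, rx.RRF_BIND, self.t, rib.mrna, rib)
            return cs, rx.RRF_BIND, None, rib.mrna
        if idx == CH_AA:
            s = self._pick_species(pools.trna_deacyl, u)
            cs = rx.apply_event(st, rx.AMINOACYL, self.t, species=s)
            return cs, rx.AMINOACYL, s, None
        if idx == CH_TCF:
            s = self._pick_species(pools.trna_charged, u)
            cs = rx.apply_event(st, rx.TC_FORM, self.t, species=s)
            return cs, rx.TC_FORM, s, None
        if idx == CH_TCD:
            s = self._pick_species(pools.trna_free_tc, u)
            cs = rx.apply_event(st, rx.TC_DISSOC, self.t, species=s)
            return cs, rx.TC_DISSOC, s, None
        kind = {CH_TSA: rx.EFTS_ASSOC, CH_TSX: rx.EFTS_EXCHANGE,
                CH_GREL: rx.EFG_GDP_RELEASE, CH_GBIND: rx.EFG_GTP_BIND,
                CH_RF3X: rx.RF3_EXCHANGE}[idx]
        cs = rx.apply_event(st, kind, self.t)
        return cs, kind, None, None

    @staticmethod
    def _pick_species(counts: np.ndarray, u: float) -> int:
        """Species index proportional to integer counts, u in [0,1)."""
        total = int(counts.sum())
        target = u * total
        acc = 0
        for s in range(len(counts)):
            c = counts[s]
            if c:
                acc += c
                if acc > target:
                    return s
        for s in range(len(counts) - 1, -1, -1):  # pragma: no cover
            if counts[s]:
                return s
        raise RuntimeError("empty species pool in channel")


def compare_engines(state_factory, n_events: int, seed_tree: int,
                    seed_naive: int, min_expected: int = 40) -> dict:
    """Statistical-equivalence comparison of the two engines.

    Runs the tree engine and the naive direct-method engine for
    ``n_events`` each on independently constructed copies of the same
    system, then compares the per-(reaction, species, mRNA) event counts
    with a chi-squared contingency test (rare categories pooled) and the
    waiting-time samples with a two-sample KS test.  Returns the two
    p-values plus bookkeeping; under a correct tree implementation both
    should be comfortably above any small alpha.
    """
    from scipy import stats

    eng_t = TreeEngine(state_factory(), seed=seed_tree, collect_dts=True)
    eng_t.run(t_end=float("inf"), checkpoint_dt=float("inf"),
              max_events=n_events)
    eng_n = NaiveEngine(state_factory(), seed=seed_naive, collect_dts=True)
    eng_n.run(t_end=float("inf"), checkpoint_dt=float("inf"),
              max_events=n_events)

    keys = sorted(set(eng_t.event_counts) | set(eng_n.event_counts))
    a = np.array([eng_t.event_counts.get(k, 0) for k in keys])
    b = np.array([eng_n.event_counts.get(k, 0) for k in keys])
    keep = (a + b) >= min_expected
    a2, b2 = list(a[keep]), list(b[keep])
    tail_a, tail_b = int(a[~keep].sum()), int(b[~keep].sum())
    if tail_a + tail_b >= min_expected:
        a2.append(tail_a)
        b2.append(tail_b)
    _, chi2_p, dof, _ = stats.chi2_contingency(np.vstack([a2, b2]))
    ks = stats.ks_2samp(eng_t.dts, eng_n.dts)
    return {
        "chi2_p": float(chi2_p),
        "ks_p": float(ks.pvalue),
        "dof": int(dof),
        "n_events": n_events,
        "n_categories": len(a2),
    }
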