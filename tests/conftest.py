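"""Shared fixtures: toy cells and the scaled-down experiment arms.

The scaled arms are expensive (minutes of simulated kinetics), so they
are computed once per session and shared by every test that inspects
them.
"""

from __future__ import annotations

import numpy as np
import pytest

from ribosim.config import (build_scaled_transcriptome, mismatched_usage,
                            scaled_cell_config, scaled_volume,
                            toggle_tc_reactions)
from ribosim.engine import TreeEngine
from ribosim.fixtures import ToySpec, make_synthetic_gene_lengths, \
    make_toy_state
from ribosim.genetics import default_decode_map
from ribosim.observables import summarize

ARM_RIBOSOMES = 80          # ~matched-growth miniature cell
ARM_RIBOSOMES_LOW = 48      # leaner cell for the factor-doubling arms
ARM_T_END = 150.0
ARM_SEED = 20260928


@pytest.fixture
def toy_state():
    return make_toy_state(ToySpec())


@pytest.fixture
def toy_state_factory():
    return lambda: make_toy_state(ToySpec())


def _run_arm(cfg, transcriptome, dm, seed):
    state = cfg.build_state(transcriptome, dm)
    result = TreeEngine(state, seed=seed).run(cfg.t_end)
    assert result.deadlock is None, result.deadlock.describe()
    return result


@pytest.fixture(scope="session")
def mismatch_arms():
    """Matched / codon-bias-mismatched / mismatched+instant-recycle runs
    of the same miniature cell (identical genes and copy numbers)."""
    dm = default_decode_map()
    lengths = make_synthetic_gene_lengths(300, mean_aa=50.0, sigma=0.35,
                                          seed=1)
    cfg = scaled_cell_config(n_ribosomes=ARM_RIBOSOMES, seed=ARM_SEED,
                             t_end=ARM_T_END)
    tr_matched = build_scaled_transcriptome(
        cfg, lengths, dm, usage="matched", rng=np.random.default_rng(5))
    mm = mismatched_usage(dm, cfg.trna_profile)
    from ribosim.transcriptome import rebuild_with_usage

    tr_mism = rebuild_with_usage(tr_matched, mm, dm,
                                 np.random.default_rng(6))
    out = {
        "matched": _run_arm(cfg, tr_matched, dm, ARM_SEED),
        "mismatched": _run_arm(cfg, tr_mism, dm, ARM_SEED),
        "mismatched_tc_off": _run_arm(
            toggle_tc_reactions(cfg, True), tr_mism, dm, ARM_SEED),
    }
    return {k: summarize(v) for k, v in out.items()} | {"_results": out}


@pytest.fixture(scope="session")
def doubling_arms():
    """Baseline lean cell vs doubling Ef-Tu/Ts only vs doubling all
    factors, tRNAs and RFs in unison (ribosome count fixed)."""
    dm = default_decode_map()
    lengths = make_synthetic_gene_lengths(300, mean_aa=50.0, sigma=0.35,
                                          seed=1)
    arms = {
        "baseline": {},
        "double_eftu": {"EfTu": 2.0, "EfTs": 2.0},
        "double_all": {"EfTu": 2.0, "EfTs": 2.0, "EfG": 2.0, "RF1": 2.0,
                       "RF2": 2.0, "RF3": 2.0, "RRF": 2.0, "tRNA": 2.0},
    }
    out = {}
    for name, mult in arms.items():
        cfg = scaled_cell_config(n_ribosomes=ARM_RIBOSOMES_LOW,
                                 seed=ARM_SEED, t_end=ARM_T_END, mu="0.7",
                                 multipliers=mult)
        # lean concentrations: volume of the larger reference miniature
        cfg.volume_um3 = scaled_volume(ARM_RIBOSOMES)
        tr = build_scaled_transcriptome(
            cfg, lengths, dm, usage="matched", rng=np.random.default_rng(5),
            target_nt=80 * ARM_RIBOSOMES_LOW)
        out[name] = summarize(_run_arm(cfg, tr, dm, ARM_SEED))
    return out
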