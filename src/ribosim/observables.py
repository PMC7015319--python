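"""Summary observables of a translation trajectory.

Reported quantities mirror what is measured for growing E. coli:

* ``C_p`` — peptide chain elongation rate (aa/s): amino acids
  incorporated per second of *elongation-phase* time, per protein,
  averaged over completions (initiation and termination excluded by
  default; switchable to the full dwell time).
* Ribosome state fractions — every 50S equivalent is classified as
  free, initiating, elongating or terminating; percentages are relative
  to total 50S, so %I + %E + %T + %50S = 100 exactly.  The stalled
  percentage counts elongating ribosomes that are currently either
  substrate-starved (empty A site with no cognate free TC anywhere) or
  sterically blocked (translocation-ready but footprint-excluded); it is
  reported both as a fraction of elongating ribosomes (default) and of
  all ribosomes.
* ``beta_r`` — ribosome activity, 100 minus the free-50S percentage.
* Free-TC ratios — per tRNA species, the time-averaged fraction of its
  total copy number standing in free ternary complex (tail window).
* Per-codon decode statistics — mean A-site waiting time and stalling
  frequency per sense codon from the decode-event ledger.
* ``d_r`` and ``rho`` — mean center-to-center ribosome spacing
  d_r = N_nt / (beta_r * N_50) in nucleotides and its reciprocal
  density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .state import FOOTPRINT_5P, FOOTPRINT_3P

__all__ = [
    "peptide_elongation_rate",
    "running_cp",
    "ribosome_state_fractions",
    "free_tc_fraction",
    "codon_decode_stats",
    "ribosome_spacing",
    "SummaryPanel",
    "summarize",
    "summarize_replicates",
]

#: minimal physical spacing in nucleotides (the extended footprint)
MIN_SPACING_NT = 3 * (FOOTPRINT_5P + FOOTPRINT_3P + 1)


def _per_protein_rates(completions: pd.DataFrame,
                       elongation_only: bool = True) -> pd.Series:
    if elongation_only:
        duration = completions["t_elong_end"] - completions["t_elong_start"]
    else:
        duration = completions["t_complete"] - completions["t_init"]
    if (duration <= 0).any():
        raise ValueError("zero-duration completion record")
    return completions["n_decoded"] / duration


def peptide_elongation_rate(
    completions: pd.DataFrame,
    burn_in_fraction: float = 0.5,
    t_end: Optional[float] = None,
    elongation_only: bool = True,
) -> float:
    """Mean C_p (aa/s) over the quasi-steady tail of a run.

    Completions finishing before ``burn_in_fraction * t_end`` are
    discarded (t_end defaults to the last completion time); proteins
    with zero decode events (single-codon ORFs) are excluded.
    """
    comp = completions[completions["n_decoded"] > 0]
    if comp.empty:
        return float("nan")
    horizon = t_end if t_end is not None else comp["t_complete"].max()
    tail = comp[comp["t_complete"] >= burn_in_fraction * horizon]
    if tail.empty:
        tail = comp
    return float(_per_protein_rates(tail, elongation_only).mean())


def running_cp(completions: pd.DataFrame, window: int = 1000,
               elongation_only: bool = True) -> pd.Series:
    """Running average of per-protein elongation rates over a trailing
    window of protein-synthesis events, indexed by completion time."""
    comp = completions[completions["n_decoded"] > 0].sort_values("t_complete")
    rates = _per_protein_rates(comp, elongation_only)
    out = rates.rolling(window, min_periods=1).mean()
    out.index = comp["t_complete"].values
    return out


def ribosome_state_fractions(checkpoints: pd.DataFrame, n_50s_total: int,
                             burn_in_fraction: float = 0.5) -> dict:
    """Tail-averaged percentages of 50S equivalents in each stage.

    ``pct_S`` is the stalled share of elongating ribosomes;
    ``pct_S_all`` the stalled share of all 50S-holding ribosomes."""
    if checkpoints.empty:
        raise ValueError("no checkpoints recorded")
    t_max = checkpoints["t"].max()
    tail = checkpoints[checkpoints["t"] >= burn_in_fraction * t_max]
    m = tail.mean(numeric_only=True)
    n50 = float(n_50s_total)
    stalled = m["n_starved"] + m["n_blocked"]
    pct_e = 100.0 * m["n_elongating"] / n50
    out = {
        "pct_I": 100.0 * m["n_initiating"] / n50,
        "pct_E": pct_e,
        "pct_T": 100.0 * m["n_terminating"] / n50,
        "pct_50S": 100.0 * m["free_50S"] / n50,
        "pct_30S_PIC": 100.0 * m["free_30S_PIC"] / n50,
        "pct_S": (100.0 * stalled / m["n_elongating"]
                  if m["n_elongating"] else 0.0),
        "pct_S_all": (100.0 * stalled
                      / (m["n_initiating"] + m["n_elongating"]
                         + m["n_terminating"])
                      if m["n_elongating"] else 0.0),
    }
    out["beta_r"] = 100.0 - out["pct_50S"]
    return out


def free_tc_fraction(result, window: float = 100.0) -> pd.Series:
    """Per-tRNA time-averaged ratio of free-TC copies to total copies
    over the last ``window`` seconds of the trajectory (clipped to the
    final half of short runs).  Indexed by tRNA name."""
    cps = result.checkpoints
    if not cps:
        raise ValueError("trajectory has no checkpoints")
    t_max = cps[-1]["t"]
    t_from = max(t_max - window, 0.5 * t_max)
    rows = [cp["free_tc"] for cp in cps if cp["t"] >= t_from]
    mean_tc = np.mean(np.asarray(rows), axis=0)
    totals = result.trna_totals.astype(float)
    frac = np.divide(mean_tc, totals, out=np.zeros_like(mean_tc),
                     where=totals > 0)
    return pd.Series(frac, index=result.trna_names, name="free_tc_fraction")


def codon_decode_stats(decode_df: pd.DataFrame) -> pd.DataFrame:
    """Per-codon mean decode time, event count and stalling frequency."""
    if decode_df.empty:
        raise ValueError("empty decode-event log")
    g = decode_df.groupby("codon")
    out = pd.DataFrame({
        "mean_wait": g["wait"].mean(),
        "n_events": g.size(),
        "stall_frequency": g["stalled"].mean(),
    })
    return out.sort_index()


def ribosome_spacing(n_nt: float, beta_r: float, n_50: float) -> tuple[float, float]:
    """Mean ribosome spacing d_r = N_nt / (beta_r * N_50) and density
    rho = 1/d_r.  ``beta_r`` is the *fraction* (0..1) of active
    subunits.  Warns when d_r drops below the physical footprint."""
    if n_nt <= 0 or beta_r <= 0 or n_50 <= 0:
        raise ValueError("all spacing inputs must be positive")
    d_r = n_nt / (beta_r * n_50)
    if d_r < MIN_SPACING_NT:
        import warnings

        warnings.warn(
            f"d_r = {d_r:.1f} nt is below the {MIN_SPACING_NT} nt footprint: "
            "physically impossible density", stacklevel=2,
        )
    return d_r, 1.0 / d_r


@dataclass
class SummaryPanel:
    """One row of headline observables for a run."""

    C_p: float
    pct_I: float
    pct_E: float
    pct_T: float
    pct_S: float
    pct_S_all: float
    pct_50S: float
    pct_30S_PIC: float
    beta_r: float
    d_r: float
    rho: float
    N: int
    N_nt: int
    free_tc: pd.Series

    def as_series(self) -> pd.Series:
        d = {k: getattr(self, k) for k in
             ("N", "N_nt", "C_p", "pct_I", "pct_E", "pct_T", "pct_S",
              "pct_S_all", "pct_50S", "pct_30S_PIC", "beta_r", "d_r", "rho")}
        return pd.Series(d)


def summarize(result, burn_in_fraction: float = 0.5,
              tc_window: float = 100.0) -> SummaryPanel:
    """Compute the full summary panel from one trajectory."""
    comp = result.completions_df
    cps = result.checkpoints_df
    fr = ribosome_state_fractions(cps, result.n_50s_total, burn_in_fraction)
    cp_rate = peptide_elongation_rate(comp, burn_in_fraction,
                                      t_end=result.t_final)
    d_r, rho = ribosome_spacing(result.n_nt, fr["beta_r"] / 100.0,
                                result.n_50s_total)
    return SummaryPanel(
        C_p=cp_rate,
        pct_I=fr["pct_I"], pct_E=fr["pct_E"], pct_T=fr["pct_T"],
        pct_S=fr["pct_S"], pct_S_all=fr["pct_S_all"],
        pct_50S=fr["pct_50S"], pct_30S_PIC=fr["pct_30S_PIC"],
        beta_r=fr["beta_r"], d_r=d_r, rho=rho,
        N=len(result.state.mrnas), N_nt=result.n_nt,
        free_tc=free_tc_fraction(result, tc_window),
    )


def summarize_replicates(results: Iterable) -> pd.DataFrame:
    """Mean and SD of the summary panel over replicate trajectories."""
    rows = [summarize(r).as_series() for r in results]
    df = pd.DataFrame(rows)
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


def plot_timecourse(result, path=None):  # pragma: no cover - convenience
    """Minimal helper: stage percentages vs time (matplotlib optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.checkpoints_df
    n50 = result.n_50s_total
    fig, ax = plt.subplots()
    for col, label in [("n_initiating", "%I"), ("n_elongating", "%E"),
                       ("n_terminating", "%T"), ("free_50S", "%50S"),
                       ("free_30S_PIC", "%30S:PIC")]:
        ax.plot(df["t"], 100.0 * df[col] / n50, label=label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("% of ribosomal subunits")
    ax.legend()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
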