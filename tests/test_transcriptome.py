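"""Transcriptome construction and the tRNA/codon matching solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribosim.genetics import (DecodeMap, codon_index, codon_str,
                              default_decode_map, ecoli_trna_counts)
from ribosim.transcriptome import (CopyNumberModel, Transcriptome,
                                   build_transcriptome,
                                   codon_usage_from_trnas, rebuild_with_usage,
                                   sample_copy_number, sample_gene_codons,
                                   trnas_from_codon_usage)


# --- equal-split codon usage -------------------------------------------


def test_equal_split_worked_example():
    """A Lys-tRNA pool of 4360 contributes exactly 2180 to each of AAA
    and AAG."""
    dm = DecodeMap({"Lys": ["AAA", "AAG"], "Phe": ["UUU"]})
    raw = codon_usage_from_trnas({"Lys": 4360, "Phe": 100}, dm,
                                 normalize=False)
    idx = {codon_str(c): i for i, c in enumerate(dm.alphabet)}
    assert raw[idx["AAA"]] == 2180
    assert raw[idx["AAG"]] == 2180


def test_single_trna_single_codon_frequency_one():
    dm = DecodeMap({"only": ["GCU"]})
    assert codon_usage_from_trnas({"only": 7}, dm).tolist() == [1.0]


def test_shared_codon_hand_arithmetic():
    # X:100 -> {A=GCU, B=AAA}, Y:300 -> {B}: raw A=50, B=350
    dm = DecodeMap({"X": ["GCU", "AAA"], "Y": ["AAA"]})
    freqs = codon_usage_from_trnas({"X": 100, "Y": 300}, dm)
    idx = {codon_str(c): i for i, c in enumerate(dm.alphabet)}
    assert freqs[idx["GCU"]] == pytest.approx(0.125)
    assert freqs[idx["AAA"]] == pytest.approx(0.875)


def test_zero_usage_codon_warns():
    dm = DecodeMap({"X": ["GCU"], "Y": ["AAA"]})
    with pytest.warns(UserWarning, match="AAA"):
        codon_usage_from_trnas({"X": 10, "Y": 0}, dm)


# --- the matching solver -----------------------------------------------


def test_one_to_one_map_counts_proportional_to_frequencies():
    dm = DecodeMap({"a": ["GCU"], "b": ["AAA"], "c": ["CCC"]})
    # the alphabet is sorted by codon index: AAA, CCC, GCU
    f = np.array([0.5, 0.3, 0.2])
    res = trnas_from_codon_usage(f, dm, total_trna=1000)
    assert res.feasible and not res.degenerate
    # species order a=GCU, b=AAA, c=CCC
    assert res.counts == pytest.approx([200.0, 500.0, 300.0])


def test_matching_round_trip_on_ecoli_map():
    """counts -> usage -> counts -> usage closes to 1e-6 per codon."""
    dm = default_decode_map()
    counts = ecoli_trna_counts("1.0")
    usage = codon_usage_from_trnas(counts, dm)
    res = trnas_from_codon_usage(usage, dm, total_trna=sum(counts.values()))
    assert res.feasible
    usage2 = codon_usage_from_trnas(res.counts, dm)
    assert np.max(np.abs(usage2 - usage)) < 1e-6


def test_shared_codon_solver_flags_degeneracy():
    # two tRNAs reading one codon: multiple solutions exist
    dm = DecodeMap({"t1": ["AAA"], "t2": ["AAA"], "t3": ["GCU"]})
    res = trnas_from_codon_usage(np.array([0.6, 0.4]), dm, total_trna=10)
    assert res.degenerate
    assert res.feasible
    usage = codon_usage_from_trnas(res.counts, dm)
    assert usage == pytest.approx([0.6, 0.4], abs=1e-9)


def test_infeasible_system_reports_residual():
    # a tRNA forced to split equally cannot produce a lopsided usage
    dm = DecodeMap({"xy": ["GCU", "AAA"]})
    res = trnas_from_codon_usage(np.array([0.9, 0.1]), dm)
    assert not res.feasible
    assert np.max(np.abs(res.residual)) > 0.1


def test_integer_counts_sum_exactly():
    dm = default_decode_map()
    usage = codon_usage_from_trnas(ecoli_trna_counts("1.0"), dm)
    res = trnas_from_codon_usage(usage, dm)
    ints = res.integer_counts(760)
    assert ints.sum() == 760
    assert (ints >= 0).all()


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_round_trip_property_random_counts(seed):
    """Random abundances on the packaged map always round-trip through
    usage -> solver -> usage when the solver reports feasibility."""
    dm = default_decode_map()
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, 1000, size=dm.n_species)
    usage = codon_usage_from_trnas(counts, dm)
    res = trnas_from_codon_usage(usage, dm, total_trna=counts.sum())
    if res.feasible:
        usage2 = codon_usage_from_trnas(res.counts, dm)
        assert np.max(np.abs(usage2 - usage)) < 1e-6


# --- gene sampling -----------------------------------------------------


def test_degenerate_frequency_gives_homopolymeric_orf():
    dm = DecodeMap({"a": ["GCU"], "b": ["AAA"]})
    f = np.zeros(2)
    f[list(dm.alphabet).index(codon_index("GCU"))] = 1.0
    codons = sample_gene_codons(12, f, dm, np.random.default_rng(0))
    body = set(int(c) for c in codons[1:-1])
    assert body == {codon_index("GCU")}


def test_orf_length_contract():
    dm = default_decode_map()
    usage = codon_usage_from_trnas(ecoli_trna_counts("1.0"), dm)
    codons = sample_gene_codons(57, usage, dm, np.random.default_rng(1))
    assert len(codons) == 57 + 2        # 3*(length_aa+2) nucleotides
    assert codons[0] == codon_index("AUG")
    assert codon_str(int(codons[-1])) in {"UAA", "UAG", "UGA"}


def test_sampled_codon_frequencies_converge():
    dm = default_decode_map()
    usage = codon_usage_from_trnas(ecoli_trna_counts("1.0"), dm)
    rng = np.random.default_rng(3)
    draws = rng.choice(np.asarray(dm.alphabet), size=1_000_000, p=usage)
    emp = np.array([(draws == c).mean() for c in dm.alphabet])
    assert np.max(np.abs(emp - usage)) < 0.003


# --- copy numbers ------------------------------------------------------


def test_high_category_mean_matches_poisson_lambda():
    rng = np.random.default_rng(0)
    model = CopyNumberModel(zero_truncate=False)
    ks = np.array([model.sample(rng, category="high")[1]
                   for _ in range(30_000)])
    se = ks.std(ddof=1) / np.sqrt(len(ks))
    assert abs(ks.mean() - 6.8) < 3 * se


def test_low_category_truncation_support():
    rng = np.random.default_rng(1)
    ks = [sample_copy_number(rng, category="low")[1] for _ in range(5000)]
    assert min(ks) >= 1


def test_geometric_parameterisation():
    """Low-expression copies follow p(k) = (1-lam)^k lam (before
    truncation): P(1)/P(2) = 1/(1-lam)."""
    lam = 0.93
    rng = np.random.default_rng(2)
    model = CopyNumberModel()
    ks = np.array([model.sample(rng, category="low")[1]
                   for _ in range(60_000)])
    p1 = (ks == 1).mean()
    p2 = (ks == 2).mean()
    assert p1 / p2 == pytest.approx(1.0 / (1.0 - lam), rel=0.1)


def test_category_frequencies():
    rng = np.random.default_rng(3)
    model = CopyNumberModel()
    cats = [model.sample(rng)[0] for _ in range(30_000)]
    for name, p in zip(model.CATEGORIES, model.p_categories):
        n = sum(c == name for c in cats)
        se = np.sqrt(30_000 * p * (1 - p))
        assert abs(n - 30_000 * p) < 3 * se


# --- building ----------------------------------------------------------


def _usage_and_map():
    dm = default_decode_map()
    return codon_usage_from_trnas(ecoli_trna_counts("1.0"), dm), dm


def test_target_n_one_gives_single_gene_record():
    usage, dm = _usage_and_map()
    tr = build_transcriptome([("g", 30)], usage, dm,
                             np.random.default_rng(0), target_n=1)
    assert len(tr.genes) == 1


def test_length_window_restricts_orfs():
    usage, dm = _usage_and_map()
    lengths = [(f"g{i}", L) for i, L in enumerate(range(50, 500, 13))]
    tr = build_transcriptome(lengths, usage, dm, np.random.default_rng(1),
                             target_nt=20_000, length_window_nt=(600, 900))
    for g in tr.genes:
        assert 600 <= g.n_nt <= 900
    with pytest.raises(ValueError, match="no genes"):
        build_transcriptome(lengths, usage, dm, np.random.default_rng(1),
                            target_nt=1000, length_window_nt=(1, 2))


def test_stopping_rule_overshoot_bounded():
    usage, dm = _usage_and_map()
    lengths = [("g", 40)]
    tr = build_transcriptome(lengths, usage, dm, np.random.default_rng(2),
                             target_nt=5000)
    last = tr.genes[-1]
    assert tr.n_nt >= 5000
    assert tr.n_nt - last.copies * last.n_nt < 5000


def test_bookkeeping_matches_recount():
    usage, dm = _usage_and_map()
    lengths = [(f"g{i}", L) for i, L in enumerate((20, 35, 50))]
    tr = build_transcriptome(lengths, usage, dm, np.random.default_rng(3),
                             target_nt=4000)
    assert tr.n_nt == sum(g.copies * 3 * len(g.codons) for g in tr.genes)
    assert tr.n_mrnas == sum(g.copies for g in tr.genes)
    assert len(tr.mrna_instances()) == tr.n_mrnas


def test_mismatch_rebuild_preserves_structure_exactly():
    """A rebuild with different codon usage keeps N, the gene count and
    every per-gene reading-frame length identical."""
    usage, dm = _usage_and_map()
    lengths = [(f"g{i}", L) for i, L in enumerate((20, 35, 50, 80))]
    tr = build_transcriptome(lengths, usage, dm, np.random.default_rng(4),
                             target_nt=6000)
    other = codon_usage_from_trnas(
        {n: 1.0 for n in dm.trna_names}, dm)  # uniform-profile usage
    tr2 = rebuild_with_usage(tr, other, dm, np.random.default_rng(5))
    assert tr2.n_mrnas == tr.n_mrnas
    assert tr2.n_nt == tr.n_nt
    assert [g.gene_id for g in tr2.genes] == [g.gene_id for g in tr.genes]
    assert [g.length_aa for g in tr2.genes] == [g.length_aa
                                                for g in tr.genes]
    assert [g.copies for g in tr2.genes] == [g.copies for g in tr.genes]
    changed = any(
        not np.array_equal(a.codons, b.codons)
        for a, b in zip(tr.genes, tr2.genes)
    )
    assert changed


def test_fasta_roundtrip(tmp_path):
    usage, dm = _usage_and_map()
    tr = build_transcriptome([("gene", 25)], usage, dm,
                             np.random.default_rng(6), target_n=3)
    fasta = tmp_path / "tr.fasta"
    copies = tmp_path / "tr.copies.tsv"
    tr.to_fasta(fasta)
    tr.to_copies_tsv(copies)
    tr2 = Transcriptome.from_fasta(fasta, copies)
    assert tr2.n_mrnas == tr.n_mrnas
    assert all(np.array_equal(a.codons, b.codons)
               for a, b in zip(tr.genes, tr2.genes))
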