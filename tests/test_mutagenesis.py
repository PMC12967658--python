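from collections import Counter
from itertools import combinations
from math import comb

import numpy as np
import pytest

import graphstab as gs
from graphstab.mutagenesis import (
    DEFAULT_DECOY_TABLE,
    MutationPool,
    candidates_to_dataframe,
    load_decoy_table,
    single_point_crossover,
)
from graphstab.mutations import Mutation, diff_sequences, parse_mutation


def _pool_of(*labels):
    return MutationPool(mutations=sorted(parse_mutation(s) for s in labels))


# ---------------------------------------------------------------------------
# harvesting
# ---------------------------------------------------------------------------


def test_extract_positional_diffs():
    actives = [
        gs.SequenceRecord(id="a", sequence="MAT", label=1),
        gs.SequenceRecord(id="b", sequence="MKS", label=1),
    ]
    pool = gs.extract_unique_mutations(actives, "MKT")
    assert [m.label() for m in pool.mutations] == ["K2A", "T3S"]


def test_extract_deduplicates_but_counts_frequency():
    actives = [
        gs.SequenceRecord(id="a", sequence="MAT", label=1),
        gs.SequenceRecord(id="b", sequence="MAS", label=1),
    ]
    pool = gs.extract_unique_mutations(actives, "MKT")
    assert [m.label() for m in pool.mutations] == ["K2A", "T3S"]
    assert pool.active_freq[2] == 2 and pool.active_freq[3] == 1


def test_extract_skips_wt_identical_record_with_warning():
    actives = [gs.SequenceRecord(id="same", sequence="MKT", label=1)]
    with pytest.warns(UserWarning, match="identical to WT"):
        pool = gs.extract_unique_mutations(actives, "MKT")
    assert len(pool) == 0


def test_extract_length_mismatch_rejected():
    with pytest.raises(ValueError, match="length"):
        gs.extract_unique_mutations(
            [gs.SequenceRecord(id="x", sequence="MK", label=1)], "MKT"
        )


# ---------------------------------------------------------------------------
# combinatorial generation
# ---------------------------------------------------------------------------


def test_combinatorial_pair_count_small():
    pool = _pool_of("A1G", "L2V", "F3S")
    out = gs.generate_combinatorial(pool, 2)
    assert len(out) == 3  # C(3, 2)


def test_combinatorial_same_position_pairs_excluded():
    pool = _pool_of("A1G", "A1V", "L2V")
    out = gs.generate_combinatorial(pool, 2)
    assert sorted(c.label() for c in out) == ["A1G:L2V", "A1V:L2V"]


def test_combinatorial_matches_binomial_for_distinct_positions():
    pool = MutationPool(
        mutations=[Mutation(position=i, wt_aa="A", new_aa="G") for i in range(1, 99)]
    )
    out = gs.generate_combinatorial(pool, 2)
    assert len(out) == comb(98, 2) == 4753


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_combinatorial_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 12))
    muts = []
    for _ in range(n):
        pos = int(rng.integers(1, 7))  # few positions -> collisions likely
        new = "GAVLS"[int(rng.integers(5))]
        wt = "K"
        if new != wt:
            muts.append(Mutation(position=pos, wt_aa=wt, new_aa=new))
    muts = sorted(set(muts))
    k = 2
    if len(muts) < k:
        pytest.skip("degenerate draw")
    expected = [
        c for c in combinations(muts, k) if len({m.position for m in c}) == k
    ]
    out = gs.generate_combinatorial(MutationPool(mutations=muts), k)
    assert [c.mutations for c in out] == expected


def test_combinatorial_k_larger_than_pool_rejected():
    with pytest.raises(ValueError, match="exceeds pool size"):
        gs.generate_combinatorial(_pool_of("A1G"), 2)


def test_combinatorial_realizes_sequences():
    pool = _pool_of("M1A", "K2R")
    out = gs.generate_combinatorial(pool, 2, wt_sequence="MKT")
    assert out[0].sequence == "ART"


# ---------------------------------------------------------------------------
# enrichment weights + weighted sampling
# ---------------------------------------------------------------------------


def test_enrichment_weight_formula():
    w = gs.position_enrichment_weights(Counter({7: 4}), Counter({7: 2}), pseudocount=1)
    assert w[7] == pytest.approx(5 / 3)


def test_enrichment_unobserved_position_neutral():
    w = gs.position_enrichment_weights(Counter({1: 0}), Counter({1: 0}), pseudocount=1)
    assert w[1] == 1.0


def test_enrichment_pseudocount_keeps_weights_finite():
    w = gs.position_enrichment_weights(Counter({3: 3}), Counter(), pseudocount=1)
    assert w[3] == 4.0


def _distinct_pool(n):
    return MutationPool(
        mutations=[Mutation(position=i, wt_aa="A", new_aa="G") for i in range(1, n + 1)]
    )


def test_weighted_sampling_favors_heavy_position():
    """A position weighted 100x must appear in > 90% of sampled pairs
    (exact inclusion probability: 1900/2071 ≈ 0.917 for 20 positions)."""
    pool = _distinct_pool(20)
    weights = {p: 1.0 for p in range(1, 21)}
    weights[5] = 100.0
    hits = 0
    for seed in range(1000):
        (cand,) = gs.generate_weighted(pool, weights, k=2, n_candidates=1, seed=seed)
        hits += any(m.position == 5 for m in cand.mutations)
    assert hits / 1000 > 0.9


def test_weighted_sampling_uniform_when_weights_equal():
    pool = _distinct_pool(8)  # C(8,2) = 28 pairs
    weights = {p: 1.0 for p in range(1, 9)}
    counts = Counter()
    n_draws = 1000
    for seed in range(n_draws):
        (cand,) = gs.generate_weighted(pool, weights, k=2, n_candidates=1, seed=seed)
        counts[cand.label()] += 1
    expect = n_draws / 28
    sigma = np.sqrt(n_draws * (1 / 28) * (27 / 28))
    assert len(counts) == 28
    for label, c in counts.items():
        assert abs(c - expect) <= 3 * sigma, label


def test_weighted_sampling_deterministic_and_exhaustive_fallback():
    pool = _distinct_pool(6)
    weights = {p: float(p) for p in range(1, 7)}
    a = gs.generate_weighted(pool, weights, 2, 5, seed=11)
    b = gs.generate_weighted(pool, weights, 2, 5, seed=11)
    assert [c.label() for c in a] == [c.label() for c in b]
    with pytest.warns(UserWarning, match="holds only"):
        full = gs.generate_weighted(pool, weights, 2, 10_000, seed=0)
    assert len(full) == comb(6, 2)


# ---------------------------------------------------------------------------
# evolutionary generation
# ---------------------------------------------------------------------------


def test_single_point_crossover_definition():
    assert single_point_crossover("MKTA", "MRSA", 2) == "MKSA"
    with pytest.raises(ValueError, match="unequal"):
        single_point_crossover("MKTA", "MRS", 2)


def test_evolutionary_population_size_preserved_and_valid():
    wt = "MKTAYNV"
    parents = ["MRTAYNV", "MKSAYNV", "MKTGYNV"]
    seen_sizes = []
    orig = gs.generate_evolutionary

    def scorer(seq):
        return 0.1 + 0.8 * np.mean([a == b for a, b in zip(seq, "MRSGYNV")])

    out = gs.generate_evolutionary(
        parents, scorer, wt, generations=5, population_size=20, seed=0
    )
    assert len(out) == 20
    for cand in out:
        assert len(cand.sequence) == len(wt)
        # mutation sets re-derived against WT round-trip
        assert gs.apply_mutations(wt, cand.mutations) == cand.sequence
        positions = [m.position for m in cand.mutations]
        assert len(positions) == len(set(positions))


def test_evolutionary_improves_fitness_over_parents():
    """Seeded stochastic check: final-population mean fitness beats the
    parents' mean in >= 18 of 20 runs."""
    wt = "MKTAYNVLQ"
    target = "MRSGYNVLQ"
    parents = ["MRTAYNVLQ", "MKSAYNVLQ", "MKTGYNVLQ", "MKTAYNVLR"]

    def scorer(seq):
        return 0.05 + 0.9 * np.mean([a == b for a, b in zip(seq, target)])

    parent_mean = np.mean([scorer(s) for s in parents])
    wins = 0
    for seed in range(20):
        out = gs.generate_evolutionary(
            parents, scorer, wt, generations=8, population_size=30, seed=seed
        )
        if np.mean([c.probability for c in out]) >= parent_mean:
            wins += 1
    assert wins >= 18


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------


def test_decoy_charge_inversion_e_to_k():
    wt = "MATV"
    active = gs.SequenceRecord(id="a", sequence="METV", label=1)  # A2E active mutation
    (decoy,) = gs.generate_decoys([active], wt, seed=0)
    assert decoy.sequence[1] == "K"
    assert decoy.label == 0


def test_decoy_hydrophobic_f_to_small_polar():
    wt = "MATV"
    active = gs.SequenceRecord(id="a", sequence="MFTV", label=1)
    hits = set()
    for seed in range(10):
        (decoy,) = gs.generate_decoys([active], wt, seed=seed)
        hits.add(decoy.sequence[1])
    assert hits <= {"S", "A"} and hits


def test_decoy_differs_exactly_at_active_mutation_positions(synthetic_dataset):
    ds = synthetic_dataset
    actives = [r for r in ds.records if r.label == 1][:30]
    decoys = gs.generate_decoys(actives, ds.wt.sequence, seed=1)
    for act, dec in zip(actives, decoys):
        mut_positions = {m.position for m in diff_sequences(ds.wt.sequence, act.sequence)}
        diff_positions = {
            i + 1 for i, (a, b) in enumerate(zip(act.sequence, dec.sequence)) if a != b
        }
        assert diff_positions == mut_positions


def test_decoy_table_must_cover_all_residues():
    bad = dict(DEFAULT_DECOY_TABLE)
    del bad["W"]
    with pytest.raises(ValueError, match="missing residues"):
        gs.generate_decoys(
            [gs.SequenceRecord(id="a", sequence="MA", label=1)], "MK", decoy_table=bad
        )


def test_decoy_table_csv_override(tmp_path):
    p = tmp_path / "decoys.csv"
    p.write_text("aa,replacements\nF,S|A\nE,K\n")
    table = load_decoy_table(p)
    assert table == {"F": ("S", "A"), "E": ("K",)}


def test_candidates_dataframe_columns():
    pool = _pool_of("M1A", "K2R")
    out = gs.generate_combinatorial(pool, 2, wt_sequence="MKT")
    df = candidates_to_dataframe(out)
    assert list(df.columns) == ["mutations", "sequence", "probability", "method"]
    assert df.loc[0, "mutations"] == "M1A:K2R"
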