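"""Synthetic genome pair, scaffold, DH population and hit-table generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from napusmap.binning import CALL_MISSING
from napusmap.simulate import (
    make_marker_map,
    simulate_dh_population,
    simulate_genome_pair,
    simulate_hit_table,
    simulate_scaffolds,
)


def test_genome_pair_without_loss_or_rearrangement_is_fully_paired():
    pair = simulate_genome_pair(400, 4, loss_rate=0.0, seed=11)
    ids_a = set(pair.genes_A["gene_id"])
    ids_c = set(pair.genes_C["gene_id"])
    assert ids_a == ids_c
    assert {a for a, _ in pair.homoeolog_pairs} == ids_a
    assert pair.deleted_homoeologues == set()
    # with identical layouts, homoeologous positions coincide: the dot
    # plot of pair positions is monotone within every chromosome
    pos_a = pair.positions("A")
    pos_c = pair.positions("C")
    for gid in ids_a:
        assert pos_a[gid][0][1:] == pos_c[gid][0][1:]  # same chromosome number
        assert pos_a[gid][1] == pos_c[gid][1]
    for _, sub in pair.genes_A.groupby("chromosome"):
        assert sub["position"].is_monotonic_increasing


def test_single_track_retention_leaves_no_paralogues():
    pair = simulate_genome_pair(300, 3, retention_probs=(1.0, 0.0, 0.0), seed=2)
    assert all(not v for v in pair.paralog_map["A"].values())
    assert all(not v for v in pair.paralog_map["C"].values())
    assert set(pair.genes_A["track"]) == {1}


def test_homoeologue_loss_fraction_within_binomial_ci():
    loss = 0.1
    pair = simulate_genome_pair(1000, 5, loss_rate=loss, seed=7)
    # every triplication-retained copy is exposed to loss in each lineage
    # independently; it ends up in deleted_homoeologues iff exactly one
    # lineage lost it, so |deleted| ~ Binomial(n_retained, 2*p*(1-p))
    retained = set(pair.paralog_map["A"])
    n = len(retained)
    p = 2 * loss * (1 - loss)
    lo, hi = stats.binom.interval(0.99, n, p)
    assert lo <= len(pair.deleted_homoeologues) <= hi


def test_genome_pair_validation_and_determinism():
    with pytest.raises(ValueError, match="n_genes"):
        simulate_genome_pair(3, 10)
    with pytest.raises(ValueError, match="retention"):
        simulate_genome_pair(100, 2, retention_probs=(0.0, 0.0, 0.0))
    with pytest.raises(ValueError, match="loss_rate"):
        simulate_genome_pair(100, 2, loss_rate=1.0)
    a = simulate_genome_pair(200, 4, loss_rate=0.1, n_inversions=1, seed=5)
    b = simulate_genome_pair(200, 4, loss_rate=0.1, n_inversions=1, seed=5)
    pd.testing.assert_frame_equal(a.genes_A, b.genes_A)
    pd.testing.assert_frame_equal(a.genes_C, b.genes_C)
    assert a.rearrangement_log == b.rearrangement_log


def test_rearrangements_are_logged_and_confined_to_one_lineage():
    pair = simulate_genome_pair(
        1200, 4, n_inversions=1, n_translocations=1, seed=9,
        rearrangement_block=(50, 80),
    )
    kinds = {(e["type"], e["lineage"]) for e in pair.rearrangement_log}
    assert ("inversion", "A") in kinds and ("translocation", "C") in kinds
    assert pair.rearranged_ids("A") and pair.rearranged_ids("C")


def test_scaffolds_conserve_sequence_and_record_chimeras():
    pair = simulate_genome_pair(600, 6, seed=3)
    scaffolds = simulate_scaffolds(pair, "A", mean_length=120_000, n_chimeras=5, seed=4)
    assert sum(scaffolds.lengths.values()) == sum(pair.chromosome_lengths["A"].values())
    assert len(scaffolds.chimera_truth) == 5
    frag_counts = scaffolds.fragments.groupby("scaffold_id").size()
    for sid, truth in scaffolds.chimera_truth.items():
        assert frag_counts[sid] == 2
        chroms = set(scaffolds.fragments.query("scaffold_id == @sid")["chromosome"])
        assert len(chroms) == 2 and set(truth["chromosomes"]) == chroms
    for sid, seq in scaffolds.sequences.items():
        assert len(seq) == scaffolds.lengths[sid]

    none = simulate_scaffolds(pair, "A", mean_length=120_000, n_chimeras=0, seed=4)
    assert none.chimera_truth == {}


def test_scaffold_parameter_validation():
    pair = simulate_genome_pair(100, 1, seed=0)
    with pytest.raises(ValueError, match="two chromosomes"):
        simulate_scaffolds(pair, "A", mean_length=50_000, n_chimeras=1)
    with pytest.raises(ValueError, match="mean_length"):
        simulate_scaffolds(pair, "A", mean_length=0)
    big = simulate_genome_pair(200, 2, seed=0)
    with pytest.raises(ValueError, match="one tenth"):
        simulate_scaffolds(big, "A", mean_length=10_000_000, n_chimeras=3)


def test_scaffold_locate_round_trips_every_gene():
    pair = simulate_genome_pair(500, 5, seed=6)
    scaffolds = simulate_scaffolds(pair, "A", mean_length=100_000, n_chimeras=3, seed=7)
    frag_lookup = scaffolds.fragments.set_index(["scaffold_id"])
    for row in pair.genes_A.itertuples(index=False):
        sid, pos = scaffolds.locate(row.chromosome, row.position)
        assert 0 <= pos < scaffolds.lengths[sid]


def test_dh_population_markov_structure():
    marker_map = pd.DataFrame(
        {"marker_id": ["a", "b"], "linkage_group": ["G", "G"], "cM": [10.0, 10.0]}
    )
    matrix = simulate_dh_population(marker_map, n_lines=50, missing_rate=0.0, seed=1)
    # zero distance: identical columns before masking
    assert np.array_equal(matrix.calls[0], matrix.calls[1])
    assert set(np.unique(matrix.calls)) <= {0, 1}  # never heterozygous

    with pytest.raises(ValueError, match="n_lines"):
        simulate_dh_population(marker_map, n_lines=0)
    bad = marker_map.assign(cM=[10.0, 5.0])
    with pytest.raises(ValueError, match="decrease"):
        simulate_dh_population(bad, n_lines=10)


@pytest.mark.parametrize(
    "delta_cm, expected_r",
    [
        (20.0, 0.5 * (1 - np.exp(-0.4))),  # Haldane closed form: 0.16484
        (10_000.0, 0.5),                   # unlinked limit
    ],
)
def test_dh_recombinant_fraction_matches_haldane(delta_cm, expected_r):
    n = 10_000
    marker_map = pd.DataFrame(
        {"marker_id": ["a", "b"], "linkage_group": ["G"] * 2, "cM": [0.0, delta_cm]}
    )
    matrix = simulate_dh_population(marker_map, n_lines=n, missing_rate=0.0, seed=42)
    recombinants = int((matrix.calls[0] != matrix.calls[1]).sum())
    lo, hi = stats.binom.interval(0.99, n, expected_r)
    assert lo <= recombinants <= hi


def test_dh_missing_and_truth_labels():
    panel = make_marker_map(2, 40, seed=8)
    matrix, truth = simulate_dh_population(
        panel, n_lines=30, missing_rate=0.08, seed=8, with_truth=True
    )
    frac_missing = (matrix.calls == CALL_MISSING).mean()
    assert 0.05 < frac_missing < 0.12
    assert set(truth.true_bins) == set(matrix.marker_ids)  # every marker labelled once
    # truth bins group identical unmasked gamete patterns
    for i, m in enumerate(matrix.marker_ids):
        for j, m2 in enumerate(matrix.marker_ids):
            if truth.true_bins[m] == truth.true_bins[m2]:
                assert np.array_equal(truth.gametes[i], truth.gametes[j])


def test_hit_table_single_clean_feature_gets_one_hit():
    hits = simulate_hit_table(["u1"], {"u1": ("chr1", 5000)}, seed=0)
    assert len(hits) == 1
    assert hits.loc[0, "qseqid"] == "u1" and hits.loc[0, "sseqid"] == "chr1"
    assert hits.loc[0, "evalue_exponent"] <= -40

    assert simulate_hit_table([], {}, seed=0).empty


def test_hit_table_repetitive_features_scatter_near_equal_hits():
    hits = simulate_hit_table(
        ["rep"], {"rep": ("chr1", 5000), "x": ("chr2", 1000), "y": ("chr3", 1000)},
        repetitive_ids={"rep"}, seed=1,
    )
    sub = hits[hits["qseqid"] == "rep"]
    assert len(sub) >= 3
    assert (sub["evalue_exponent"] - sub["evalue_exponent"].min() <= 5).all()


def test_deleted_homoeologue_best_hit_is_the_paralogue():
    # 'u1.t1' was lost from this genome; its retained track-2 paralogue
    # is the best (indeed only) remaining match
    positions = {"u1.t2": ("chr2", 40_000)}
    hits = simulate_hit_table(
        ["u1.t1"], positions, paralog_map={"u1.t1": ["u1.t2"]}, seed=3
    )
    assert list(hits["qseqid"]) == ["u1.t1"]
    best = hits.sort_values("evalue").iloc[0]
    assert best.sseqid == "chr2"
    mid = (best.tstart + best.tend) // 2
    assert abs(mid - 40_000) < 1000


def test_hit_table_deterministic():
    args = (["a", "b"], {"a": ("c1", 100), "b": ("c1", 5000)})
    one = simulate_hit_table(*args, seed=9)
    two = simulate_hit_table(*args, seed=9)
    pd.testing.assert_frame_equal(one, two)
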