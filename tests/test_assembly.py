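"""Chimera detection, scaffold splitting, ordering/orientation and
pseudomolecule (FASTA/AGP/lift) construction."""

import numpy as np
import pytest

from napusmap.assembly import (
    Component,
    MarkerAnchor,
    PseudomoleculeSpec,
    apply_splits,
    build_pseudomolecules,
    detect_chimeras,
    group_anchors,
    order_and_orient,
    read_agp,
    split_scaffold,
    write_agp,
)
from napusmap.linkage import LinkageMap, MapEntry


def anchor(marker, scaffold, pos, group, cm, bin_id=None):
    return MarkerAnchor(marker, scaffold, pos, bin_id or marker, group, cm)


def test_chimera_split_at_midpoint_between_flanking_anchors():
    anchors = {
        "S1": [
            anchor("m1", "S1", 10_000, "A1", 0.0),
            anchor("m2", "S1", 30_000, "A1", 1.0),
            anchor("m3", "S1", 50_000, "A1", 2.0),
            anchor("m4", "S1", 60_000, "A5", 40.0),
            anchor("m5", "S1", 90_000, "A5", 41.0),
        ]
    }
    splits = detect_chimeras(anchors)
    assert len(splits) == 1
    s = splits[0]
    assert (s.scaffold_id, s.position) == ("S1", 55_000)
    assert (s.left_group, s.right_group) == ("A1", "A5")


def test_no_split_for_consistent_or_weakly_supported_scaffolds():
    consistent = {
        "S1": [anchor(f"m{i}", "S1", i * 10_000, "A1", float(i)) for i in range(5)]
    }
    assert detect_chimeras(consistent) == []

    stray = {
        "S1": [
            anchor("m1", "S1", 10_000, "A1", 0.0),
            anchor("m2", "S1", 30_000, "A1", 1.0),
            anchor("odd", "S1", 50_000, "A7", 60.0),  # support 1: ignored
            anchor("m3", "S1", 70_000, "A1", 2.0),
        ]
    }
    assert detect_chimeras(stray) == []


def test_split_on_large_cm_jump_within_one_group():
    anchors = {
        "S1": [
            anchor("m1", "S1", 5_000, "A1", 0.0),
            anchor("m2", "S1", 15_000, "A1", 3.0),
            anchor("m3", "S1", 40_000, "A1", 80.0),
            anchor("m4", "S1", 55_000, "A1", 84.0),
        ]
    }
    splits = detect_chimeras(anchors, max_cm_jump=20.0)
    assert [(s.scaffold_id, s.position) for s in splits] == [("S1", 27_500)]


def test_split_scaffold_fragments_concatenate_exactly():
    seq = "ACGT" * 25
    assert split_scaffold("S1", seq, []) == [("S1", seq)]
    frags = split_scaffold("S1", seq, [40])
    assert [(i, len(s)) for i, s in frags] == [("S1.1", 40), ("S1.2", 60)]
    multi = split_scaffold("S1", seq, [30, 60])
    assert [len(s) for _, s in multi] == [30, 30, 40]
    assert "".join(s for _, s in multi) == seq
    for bad in (0, 100, -5):
        with pytest.raises(ValueError, match="split position"):
            split_scaffold("S1", seq, [bad])


def test_apply_splits_remaps_anchor_coordinates():
    anchors = [
        anchor("m1", "S1", 10, "A1", 0.0),
        anchor("m2", "S1", 60, "A5", 50.0),
        anchor("m3", "S2", 5, "A2", 3.0),
    ]
    from napusmap.assembly import ChimeraSplit

    splits = [ChimeraSplit("S1", 40, "A1", "A5")]
    new_anchors, new_seqs = apply_splits(anchors, splits, {"S1": "A" * 100, "S2": "C" * 10})
    by_id = {a.marker_id: a for a in new_anchors}
    assert (by_id["m1"].scaffold_id, by_id["m1"].position) == ("S1.1", 10)
    assert (by_id["m2"].scaffold_id, by_id["m2"].position) == ("S1.2", 20)
    assert by_id["m3"].scaffold_id == "S2"
    assert set(new_seqs) == {"S1.1", "S1.2", "S2"}


def _map_for(groups):
    return LinkageMap(
        groups={
            g: [MapEntry(f"{g}_{i}", float(i), []) for i in range(10)] for g in groups
        }
    )


def test_orientation_follows_anchor_trend():
    lengths = {"Sf": 10_000, "Sr": 10_000, "S?": 10_000}
    anchors = (
        [anchor(f"f{i}", "Sf", p, "A1", c) for i, (p, c) in
         enumerate(zip((1_000, 5_000, 9_000), (0.0, 3.0, 7.0)))]
        + [anchor(f"r{i}", "Sr", p, "A1", c) for i, (p, c) in
           enumerate(zip((1_000, 5_000, 9_000), (27.0, 23.0, 20.0)))]
        + [anchor("q1", "S?", 2_000, "A1", 40.0)]  # single anchor: undecidable
    )
    spec, unplaced = order_and_orient(anchors, _map_for(["A1"]), lengths)
    comps = {c.scaffold_id: c for c in spec.components["A1"]}
    assert comps["Sf"].orientation == "+" and not comps["Sf"].flagged
    assert comps["Sr"].orientation == "-" and not comps["Sr"].flagged
    assert comps["S?"].orientation == "+" and comps["S?"].flagged
    assert unplaced == []
    # ordered by median cM: Sf (3), Sr (23), S? (40)
    assert [c.scaffold_id for c in spec.components["A1"]] == ["Sf", "Sr", "S?"]


def test_anchorless_scaffolds_are_excluded_and_reported():
    lengths = {"S1": 1_000, "Snone": 2_000}
    anchors = [anchor("m1", "S1", 10, "A1", 0.0), anchor("m2", "S1", 900, "A1", 2.0)]
    spec, unplaced = order_and_orient(anchors, _map_for(["A1"]), lengths)
    assert unplaced == ["Snone"]
    assert [c.scaffold_id for c in spec.components["A1"]] == ["S1"]


def test_chromosome_is_modal_linkage_group():
    lengths = {"S1": 10_000}
    anchors = [
        anchor("m1", "S1", 1_000, "A2", 0.0),
        anchor("m2", "S1", 2_000, "A2", 1.0),
        anchor("m3", "S1", 3_000, "A9", 55.0),
    ]
    spec, _ = order_and_orient(anchors, _map_for(["A2", "A9"]), lengths)
    assert list(spec.components) == ["A2"]


def _two_component_spec(gap=100):
    return PseudomoleculeSpec(
        components={
            "A1": [
                Component("S1", 0, 1_000, "+"),
                Component("S2", 0, 2_000, "+"),
            ]
        },
        gap_size=gap,
    )


def test_pseudomolecule_lengths_and_lift():
    rng = np.random.default_rng(0)
    seqs = {
        "S1": "".join(rng.choice(list("ACGT"), 1_000)),
        "S2": "".join(rng.choice(list("ACGT"), 2_000)),
    }
    fasta, agp, lift = build_pseudomolecules(_two_component_spec(), seqs)
    assert len(fasta["A1"]) == 3_100
    assert fasta["A1"][1_000:1_100] == "N" * 100
    # first base of the second component lands just past the gap:
    # 1,000 component bases + 100 gap bases, then position 1,101
    assert lift.to_chromosome("S2", 1, "+") == ("A1", 1_101, "+")
    assert lift.to_scaffold("A1", 1_101, "+") == ("S2", 1, "+")


def test_minus_component_is_reverse_complemented():
    spec = PseudomoleculeSpec(
        components={"C1": [Component("S1", 0, 8, "-")]}, gap_size=100
    )
    fasta, _, lift = build_pseudomolecules(spec, {"S1": "AACCGGTT"})
    assert fasta["C1"] == "AACCGGTT"[::-1].translate(str.maketrans("ACGT", "TGCA"))
    chrom, pos, strand = lift.to_chromosome("S1", 1, "+")
    assert (chrom, pos, strand) == ("C1", 8, "-")


def test_lift_round_trip_identity(rng):
    seqs = {f"S{i}": "".join(rng.choice(list("ACGT"), int(rng.integers(500, 2_000))))
            for i in range(6)}
    spec = PseudomoleculeSpec(
        components={
            "A1": [Component(f"S{i}", 0, len(seqs[f"S{i}"]), "+" if i % 2 else "-")
                   for i in range(3)],
            "A2": [Component(f"S{i}", 0, len(seqs[f"S{i}"]), "+") for i in range(3, 6)],
        },
        gap_size=77,
    )
    _, _, lift = build_pseudomolecules(spec, seqs)
    for _ in range(1_000):
        sid = f"S{int(rng.integers(0, 6))}"
        pos = int(rng.integers(1, len(seqs[sid]) + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, cpos, cstrand = lift.to_chromosome(sid, pos, strand)
        assert lift.to_scaffold(chrom, cpos, cstrand) == (sid, pos, strand)


def test_agp_round_trip_rebuilds_identical_fasta(tmp_path, rng):
    seqs = {f"S{i}": "".join(rng.choice(list("ACGT"), 300)) for i in range(4)}
    spec = PseudomoleculeSpec(
        components={
            "A1": [Component("S0", 0, 300, "+"), Component("S1", 0, 300, "-")],
            "A2": [Component("S2", 0, 300, "+"), Component("S3", 0, 300, "+")],
        },
        gap_size=50,
    )
    fasta, agp, _ = build_pseudomolecules(spec, seqs)
    path = tmp_path / "out.agp"
    write_agp(agp, path)
    rebuilt_spec = read_agp(path)
    fasta2, _, _ = build_pseudomolecules(rebuilt_spec, seqs)
    assert fasta2 == fasta
    assert rebuilt_spec.gap_size == 50


def test_pseudomolecule_build_errors_name_the_component():
    spec = _two_component_spec()
    with pytest.raises(ValueError, match="S2"):
        build_pseudomolecules(spec, {"S1": "A" * 1_000})
    bad = PseudomoleculeSpec(
        components={"A1": [Component("S1", 0, 2_000, "+")]}, gap_size=100
    )
    with pytest.raises(ValueError, match="exceeds"):
        build_pseudomolecules(bad, {"S1": "A" * 1_000})


def test_group_anchors_sorts_by_position():
    anchors = [
        anchor("m2", "S1", 500, "A1", 1.0),
        anchor("m1", "S1", 100, "A1", 0.0),
    ]
    grouped = group_anchors(anchors)
    assert [a.marker_id for a in grouped["S1"]] == ["m1", "m2"]
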