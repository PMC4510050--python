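"""Dot chaining, shadow-block detection, diagnosis and the dot plot."""

import itertools

import numpy as np
import pandas as pd
import pytest

from napusmap.collinearity import (
    CATEGORY_MISSING,
    CATEGORY_REPETITIVE,
    chain_dots,
    chains_to_frame,
    detect_shadows,
    diagnose_noncollinear,
    make_dot_points,
    render_dotplot,
)
from napusmap.hits import hit_frame

MAX_GAP = 2_000_000


def points_frame(rows):
    return pd.DataFrame(rows, columns=["unigene_id", "a_chrom", "a_pos", "c_chrom", "c_pos"])


def oracle_best_chain(points, max_gap=MAX_GAP):
    """Exhaustive search for the largest valid chain on <= 20 points."""
    rows = sorted(points.itertuples(index=False), key=lambda r: r.a_pos)
    best = 1

    def extend(chain, sign):
        nonlocal best
        best = max(best, len(chain))
        last = chain[-1]
        for r in rows:
            a_gap = r.a_pos - last.a_pos
            if not 0 < a_gap <= max_gap:
                continue
            c_gap = r.c_pos - last.c_pos
            if sign == "+" and not 0 < c_gap <= max_gap:
                continue
            if sign == "-" and not 0 < -c_gap <= max_gap:
                continue
            extend(chain + [r], sign)

    for r in rows:
        for sign in "+-":
            extend([r], sign)
    return best


def test_collinear_run_forms_single_plus_chain():
    pts = points_frame(
        [(f"u{i}", "A01", i * 100_000, "C01", i * 100_000 + 5_000) for i in range(10)]
    )
    chains = chain_dots(pts)
    assert len(chains) == 1
    assert (chains[0].sign, chains[0].size) == ("+", 10)
    assert chains[0].members == [f"u{i}" for i in range(10)]


def test_reversed_c_positions_form_minus_chain():
    pts = points_frame(
        [(f"u{i}", "A01", i * 100_000, "C01", (9 - i) * 100_000) for i in range(10)]
    )
    chains = chain_dots(pts)
    assert len(chains) == 1 and chains[0].sign == "-"


def test_interleaved_chains_both_recovered_and_match_oracle():
    rows = []
    for i in range(10):  # two diagonals, far apart in C, interleaved in A
        rows.append((f"a{i}", "A01", i * 200_000 + 1, "C01", i * 200_000 + 10))
        rows.append((f"b{i}", "A01", i * 200_000 + 100_000, "C01",
                     30_000_000 + i * 200_000))
    pts = points_frame(rows)
    chains = chain_dots(pts)
    assert sorted(ch.size for ch in chains) == [10, 10]
    memberships = {frozenset(ch.members) for ch in chains}
    assert frozenset(f"a{i}" for i in range(10)) in memberships
    assert frozenset(f"b{i}" for i in range(10)) in memberships
    assert max(ch.size for ch in chains) == oracle_best_chain(pts)


@pytest.mark.parametrize("seed", range(4))
def test_chaining_matches_exhaustive_oracle_on_small_instances(seed):
    rng = np.random.default_rng(seed)
    rows = []
    start_c = int(rng.integers(0, 5_000_000))
    sign = 1 if rng.random() < 0.5 else -1
    n_diag = int(rng.integers(6, 13))
    a_pos = 100_000
    for i in range(n_diag):  # one collinear run with jittered spacing
        a_pos += int(rng.integers(50_000, 300_000))
        rows.append((
            f"d{i}", "A01", a_pos,
            "C01", start_c + sign * i * 150_000 + int(rng.integers(-20_000, 20_000)),
        ))
    for j in range(4):  # isolated noise, farther than max_gap from anything
        rows.append((f"n{j}", "A01", 20_000_000 + j * 5_000_000,
                     "C01", 40_000_000 + j * 7_000_000))
    pts = points_frame(rows)
    chains = chain_dots(pts, min_points=2)
    assert max(ch.size for ch in chains) == oracle_best_chain(pts)


def test_chains_below_min_points_are_discarded():
    pts = points_frame(
        [(f"u{i}", "A01", i * 100_000, "C01", i * 100_000) for i in range(4)]
    )
    assert chain_dots(pts, min_points=5) == []
    assert chain_dots(pts.iloc[0:0]) == []


def _mk_chain_points(prefix, a0, c0, n, step, weak=False, a_chrom="A01", c_chrom="C01"):
    exp = -60.0 if weak else -120.0
    return [
        (f"{prefix}{i}", a_chrom, a0 + i * step, c_chrom, c0 + i * step, exp, exp)
        for i in range(n)
    ]


def exp_points_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["unigene_id", "a_chrom", "a_pos", "c_chrom", "c_pos", "a_exp", "c_exp"],
    )


def test_single_chain_is_main_and_disjoint_chains_are_both_main():
    single = chain_dots(points_frame(
        [(f"u{i}", "A01", i * 100_000, "C01", i * 100_000) for i in range(6)]
    ))
    assert [ch.role for ch in detect_shadows(single)] == ["main"]

    disjoint = points_frame(
        [(f"u{i}", "A01", i * 100_000, "C01", i * 100_000) for i in range(6)]
        + [(f"v{i}", "A01", 50_000_000 + i * 100_000, "C02", i * 100_000)
           for i in range(6)]
    )
    roles = {ch.role for ch in detect_shadows(chain_dots(disjoint))}
    assert roles == {"main"}


def test_sparse_weak_overlapping_chain_is_a_shadow():
    rows = _mk_chain_points("m", 0, 0, 40, 100_000)                     # main diagonal
    rows += _mk_chain_points("s", 150_000, 0, 6, 600_000, weak=True,
                             c_chrom="C05")                              # sparse + weak
    chains = detect_shadows(chain_dots(exp_points_frame(rows)))
    roles = {ch.members[0][0]: ch.role for ch in chains}
    assert roles["m"] == "main" and roles["s"] == "shadow"


def test_dense_strong_displaced_block_stays_main():
    rows = _mk_chain_points("m", 0, 0, 15, 100_000)
    rows += _mk_chain_points("m2", 4_000_000, 1_500_000, 15, 100_000)
    # displaced block inside the A span, full anchor strength, C-disjoint
    rows += _mk_chain_points("d", 1_550_000, 0, 20, 100_000, c_chrom="C07")
    chains = detect_shadows(chain_dots(exp_points_frame(rows)))
    for ch in chains:
        assert ch.role == "main", ch.members[0]


def _diag_hits(q, rows):
    return hit_frame(
        [
            {
                "qseqid": q, "sseqid": chrom, "pident": 97.0, "length": 1000,
                "mismatch": 3, "gapopen": 0, "qstart": 1, "qend": 1000,
                "sstart": pos + 1, "send": pos + 1000,
                "evalue": 10.0 ** exp, "bitscore": 500.0,
            }
            for chrom, pos, exp in rows
        ]
    )


def _context_chains():
    rows = _mk_chain_points("m", 0, 0, 40, 100_000)
    rows += _mk_chain_points("s", 150_000, 7_000_000, 6, 600_000, weak=True,
                             c_chrom="C05")
    return detect_shadows(chain_dots(exp_points_frame(rows)))


def test_diagnosis_repetitive_multihit_rule():
    chains = _context_chains()
    hits_c = _diag_hits("x", [("C01", p, -118 - i) for i, p in
                              enumerate(range(100_000, 600_000, 100_000))])
    hits_a = _diag_hits("x", [("A01", 200_000, -120)])
    d = diagnose_noncollinear("x", hits_a, hits_c, chains)
    assert d.category == CATEGORY_REPETITIVE
    assert d.evidence["n_near_best_C"] >= 3


def test_diagnosis_missing_homoeologue_rule():
    chains = _context_chains()
    # strong own-genome hit inside the main chain span; only a markedly
    # weaker hit in the other genome, falling in the shadow interval
    hits_a = _diag_hits("u", [("A01", 2_050_000, -120)])
    hits_c = _diag_hits("u", [("C05", 8_200_000, -58)])
    d = diagnose_noncollinear("u", hits_a, hits_c, chains)
    assert d.category == CATEGORY_MISSING
    assert d.evidence.get("shadow_chain")


def test_diagnosis_preconditions():
    chains = _context_chains()
    with pytest.raises(ValueError, match="main chain"):
        diagnose_noncollinear("m0", _diag_hits("m0", [("A01", 0, -120)]),
                              _diag_hits("m0", [("C01", 0, -120)]), chains)
    with pytest.raises(ValueError, match="no hits"):
        diagnose_noncollinear("ghost", _diag_hits("g", []), _diag_hits("g", []), chains)


def test_diagnosis_is_deterministic():
    chains = _context_chains()
    hits_a = _diag_hits("u", [("A01", 2_050_000, -120)])
    hits_c = _diag_hits("u", [("C05", 8_200_000, -58)])
    first = diagnose_noncollinear("u", hits_a, hits_c, chains)
    second = diagnose_noncollinear("u", hits_a, hits_c, chains)
    assert first.category == second.category and first.evidence == second.evidence


def test_render_dotplot_writes_tsv_and_colors(tmp_path):
    pts = make_dot_points(
        pd.DataFrame(
            {
                "feature_id": ["u1", "u2", "u3"],
                "a_chrom": ["A01", "A01", "A02"],
                "a_pos": [100, 200, 300],
                "c_chrom": ["C01", "C02", "C01"],
                "c_pos": [150, 250, 350],
            }
        ),
        at_tags={"u1": "At3", "u2": "organelle"},
    )
    out = tmp_path / "plot.png"
    tsv = render_dotplot(pts, out)
    assert out.exists()
    table = pd.read_csv(tsv, sep="\t")
    assert len(table) == 3  # every plotted point present
    colors = dict(zip(table["unigene_id"], table["color"]))
    assert colors == {"u1": "darkblue", "u2": "black", "u3": "grey"}


def test_render_dotplot_rejects_unknown_tags(tmp_path):
    pts = make_dot_points(
        pd.DataFrame(
            {"feature_id": ["u1"], "a_chrom": ["A01"], "a_pos": [1],
             "c_chrom": ["C01"], "c_pos": [1]}
        ),
        at_tags={"u1": "At9"},
    )
    out = tmp_path / "plot.png"
    with pytest.raises(ValueError, match="At9"):
        render_dotplot(pts, out)
    assert not out.with_suffix(".tsv").exists()  # error precedes any output


def test_chains_to_frame_columns():
    pts = points_frame(
        [(f"u{i}", "A01", i * 100_000, "C01", i * 100_000) for i in range(6)]
    )
    frame = chains_to_frame(chain_dots(pts))
    assert list(frame.columns) == [
        "chain_id", "role", "sign", "a_chrom", "a_start", "a_end",
        "c_chrom", "c_start", "c_end", "n_points",
    ]
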