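"""A-vs-C dot set, collinear chaining, shadow detection and diagnosis.

Dual-anchored unigenes form a dot set (A position, C position).  Within
each (A chromosome, C chromosome) pair, dots are chained into collinear
runs by a greedy sparse chaining rule: points are scanned in ascending A
position and each point joins the best eligible open chain, where a
chain of sign s is eligible when both the A gap and the signed C gap lie
in (0, max_gap].  Chains shorter than ``min_points`` are discarded.

The dominant chain over an A interval is the *main* (homoeologous)
block; smaller chains that shadow its A interval while mapping to a
disjoint C location are *shadow* blocks.  In an allopolyploid descended
from a hexaploid ancestor, loss of a homoeologue leaves a paralogue as
the best cross-genome match, and the two retained paralogous tracks
produce up to two such shadow segments per collinear block -- hence at
most two shadows are linked to each main chain.

Unigenes outside the main chains are diagnosed by ordered rules:
multiple near-best hits mean a repetitive sequence; absence of any
qualifying hit near the predicted homoeologous position combined with a
best hit inside a shadow block means a lost homoeologue anchored to a
paralogue; coherent membership of a non-main chain otherwise indicates
a true rearrangement; anything else is ambiguous.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_MAX_GAP = 2_000_000
DEFAULT_MIN_POINTS = 5

AT_TAG_COLORS = {
    "none": "grey",
    "organelle": "black",
    "At1": "lightblue",
    "At2": "orange",
    "At3": "darkblue",
    "At4": "green",
    "At5": "red",
}

CATEGORY_REPETITIVE = "REPETITIVE_MULTIHIT"
CATEGORY_MISSING = "MISSING_HOMOEOLOGUE_PARALOGUE"
CATEGORY_REARRANGEMENT = "TRUE_REARRANGEMENT"
CATEGORY_AMBIGUOUS = "AMBIGUOUS"


@dataclasses.dataclass
class Chain:
    """A collinear run of dots between one A and one C chromosome."""

    chain_id: str
    a_chrom: str
    c_chrom: str
    sign: str  # '+' or '-'
    members: list[str]
    a_positions: list[int]
    c_positions: list[int]
    role: str = "main"
    #: per member, the e-value exponent of its weaker anchor (max of the
    #: A and C exponents); None when the dot table carries no exponents
    weak_exponents: list[float] | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def a_interval(self) -> tuple[int, int]:
        return self.a_positions[0], self.a_positions[-1]

    @property
    def c_interval(self) -> tuple[int, int]:
        return min(self.c_positions), max(self.c_positions)


def make_dot_points(dual_table: pd.DataFrame,
                    at_tags: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Attach A.-thaliana-style colour tags to a dual anchor table."""
    points = dual_table.rename(columns={"feature_id": "unigene_id"}).copy()
    tags = at_tags or {}
    points["at_tag"] = [tags.get(u, "none") for u in points["unigene_id"]]
    return points


def chain_dots(
    points: pd.DataFrame,
    max_gap: int = DEFAULT_MAX_GAP,
    min_points: int = DEFAULT_MIN_POINTS,
) -> list[Chain]:
    """Greedy sparse chaining of dual-anchor dots into collinear chains.

    Each point (scanned by ascending A position per chromosome pair)
    joins the eligible open chain with the highest score (member count;
    ties by longest A span, then earliest-started chain), or opens a new
    chain.  A chain's sign is fixed by its second member.  Chains with
    fewer than ``min_points`` members are discarded; the survivors are
    ranked by member count.
    """
    return _rank(_collect_chains(points, max_gap, min_points))


def _collect_chains(points: pd.DataFrame, max_gap: int, min_points: int) -> list[Chain]:
    chains: list[Chain] = []
    counter = 0
    has_exp = {"a_exp", "c_exp"}.issubset(points.columns)
    for (a_chrom, c_chrom), sub in points.groupby(["a_chrom", "c_chrom"], sort=True):
        sub = sub.sort_values(["a_pos", "unigene_id"], kind="mergesort")
        open_chains: list[tuple[int, Chain]] = []  # (creation index, chain)
        all_chains: list[Chain] = []
        for row in sub.itertuples(index=False):
            a, c = int(row.a_pos), int(row.c_pos)
            weak = max(row.a_exp, row.c_exp) if has_exp else None
            open_chains = [
                (k, ch) for k, ch in open_chains if a - ch.a_positions[-1] <= max_gap
            ]
            best = None
            best_key = None
            for k, ch in open_chains:
                a_gap = a - ch.a_positions[-1]
                if not 0 < a_gap <= max_gap:
                    continue
                c_gap = c - ch.c_positions[-1]
                if ch.sign == "+":
                    ok = 0 < c_gap <= max_gap
                elif ch.sign == "-":
                    ok = 0 < -c_gap <= max_gap
                else:
                    ok = 0 < abs(c_gap) <= max_gap
                if not ok:
                    continue
                span = ch.a_positions[-1] - ch.a_positions[0]
                key = (ch.size, span, -k)
                if best is None or key > best_key:
                    best, best_key = ch, key
            if best is None:
                counter += 1
                ch = Chain(
                    chain_id=f"ch{counter:05d}",
                    a_chrom=a_chrom, c_chrom=c_chrom, sign="?",
                    members=[row.unigene_id], a_positions=[a], c_positions=[c],
                    weak_exponents=[weak] if has_exp else None,
                )
                open_chains.append((counter, ch))
                all_chains.append(ch)
            else:
                if best.sign == "?":
                    best.sign = "+" if c > best.c_positions[-1] else "-"
                best.members.append(row.unigene_id)
                best.a_positions.append(a)
                best.c_positions.append(c)
                if has_exp:
                    best.weak_exponents.append(weak)
        chains.extend(ch for ch in all_chains if ch.size >= min_points)
    for ch in chains:
        if ch.sign == "?":
            ch.sign = "+"
    return chains


def _rank(chains: list[Chain]) -> list[Chain]:
    return sorted(chains, key=lambda ch: (-ch.size, ch.chain_id))


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _density(ch: Chain) -> float:
    span = ch.a_interval[1] - ch.a_interval[0]
    return ch.size / max(span, 1)


def detect_shadows(chains: Sequence[Chain], overlap_frac: float = 0.5,
                   max_shadows: int = 2, density_max: float = 0.5,
                   strength_margin: float = 25.0) -> list[Chain]:
    """Label each chain as a main block or a paralogous shadow of one.

    Chains are visited by decreasing size.  A chain whose A interval
    overlaps an already-accepted main chain's A interval (on the same A
    chromosome) by at least ``overlap_frac`` of the smaller interval,
    while its C interval is disjoint from that main's (different C
    chromosome or non-overlapping range), becomes a shadow of it; each
    main chain takes at most ``max_shadows`` shadows, by size rank.

    A shadow must additionally look like a paralogue block rather than a
    displaced (segmentally rearranged) collinear block, which is equally
    C-disjoint.  Two discriminators are used: *sparsity* -- a paralogue
    shadow contains only the genes whose homoeologue was lost, so its
    point density over its A interval is at most ``density_max`` times
    the host main's -- and, when the dot table carries anchor e-value
    exponents, *anchor weakness* -- a shadow's members are anchored
    through paralogue matches, so its median weaker-anchor exponent must
    exceed the host's by at least ``strength_margin`` (paralogues
    diverged at the ancestral hexaploidy, long before the A/C split).
    A displaced block fails both: it is dense and anchored at full
    strength.

    The two-shadow cap reflects the two retained paralogous tracks of
    the ancestral hexaploidy and therefore applies per A-genome locus:
    a candidate is refused only when two accepted shadows of the same
    host already overlap its own A interval.  Because a fragmented host
    can rank below its shadow, label assignment is iterated to a
    fixpoint, demoting mains that qualify as shadows of another main.
    """
    ranked = _rank(list(chains))

    def median_weak(ch: Chain) -> float | None:
        if ch.weak_exponents is None:
            return None
        return float(np.median(ch.weak_exponents))

    def a_overlaps(x: Chain, y: Chain) -> bool:
        smaller = min(
            x.a_interval[1] - x.a_interval[0], y.a_interval[1] - y.a_interval[0]
        )
        ov = _overlap(x.a_interval, y.a_interval)
        if smaller <= 0:
            return ov > 0 or x.a_interval[0] <= y.a_interval[1] and y.a_interval[0] <= x.a_interval[1]
        return ov / smaller >= overlap_frac

    def qualifies(ch: Chain, main: Chain, accepted: dict[str, list[Chain]]) -> bool:
        if main is ch or main.a_chrom != ch.a_chrom:
            return False
        if not a_overlaps(ch, main):
            return False
        c_disjoint = main.c_chrom != ch.c_chrom or _overlap(
            ch.c_interval, main.c_interval
        ) == 0
        if not c_disjoint:
            return False
        mw_ch, mw_main = median_weak(ch), median_weak(main)
        if mw_ch is not None and mw_main is not None:
            # anchor weakness is decisive when exponents are available:
            # paralogue-grade matches are evidence enough on their own
            # (rearrangements can relocate paralogous segments, so a
            # locus may legitimately show more than two shadow locations)
            return mw_ch >= mw_main + strength_margin
        if _density(ch) > density_max * _density(main):
            return False
        # without anchor strength, cap the shadows per locus at the two
        # retained paralogous tracks; the cap counts distinct paralogous
        # locations, not chain fragments -- a shadow segment broken into
        # several chains on the same C chromosome is one segment
        local = {
            s.c_chrom for s in accepted.get(main.chain_id, []) if a_overlaps(ch, s)
        }
        return ch.c_chrom in local or len(local) < max_shadows

    for ch in ranked:
        ch.role = "main"
    for _ in range(len(ranked)):
        accepted: dict[str, list[Chain]] = {}
        changed = False
        for ch in ranked:
            mains = [m for m in ranked if m.role == "main"]
            host = next((m for m in mains if qualifies(ch, m, accepted)), None)
            role = "main" if host is None else "shadow"
            if role != ch.role:
                ch.role = role
                changed = True
            if host is not None:
                accepted.setdefault(host.chain_id, []).append(ch)
        if not changed:
            break
    return ranked


def chains_to_frame(chains: Sequence[Chain]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "chain_id": ch.chain_id,
                "role": ch.role,
                "sign": ch.sign,
                "a_chrom": ch.a_chrom,
                "a_start": ch.a_interval[0],
                "a_end": ch.a_interval[1],
                "c_chrom": ch.c_chrom,
                "c_start": ch.c_interval[0],
                "c_end": ch.c_interval[1],
                "n_points": ch.size,
            }
            for ch in chains
        ],
        columns=["chain_id", "role", "sign", "a_chrom", "a_start", "a_end",
                 "c_chrom", "c_start", "c_end", "n_points"],
    )


# ---------------------------------------------------------------------------
# Diagnosis of non-collinear unigenes
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Diagnosis:
    unigene_id: str
    category: str
    evidence: dict


def _member_lookup(chains: Sequence[Chain]) -> dict[str, list[Chain]]:
    out: dict[str, list[Chain]] = {}
    for ch in chains:
        for m in ch.members:
            out.setdefault(m, []).append(ch)
    return out


def _best_row(hits: pd.DataFrame):
    if hits.empty:
        return None
    ordered = hits.sort_values(
        by=["evalue", "bitscore", "sseqid", "tstart"],
        ascending=[True, False, True, True], kind="mergesort",
    )
    return ordered.iloc[0]


def _near_best_count(hits: pd.DataFrame, window: float) -> int:
    if hits.empty:
        return 0
    best = hits["evalue_exponent"].min()
    return int((hits["evalue_exponent"] <= best + window).sum())


def _predict_partner(chains: Sequence[Chain], genome: str, chrom: str, pos: int):
    """Interpolate the homoeologous position from the local main chain.

    ``genome`` is 'A' when ``pos`` is an A-genome position and the C
    partner is predicted, and vice versa.  Returns (chrom, pos) or None
    when no main chain flanks the position.
    """
    best_chain = None
    for ch in chains:
        if ch.role != "main":
            continue
        own_chrom = ch.a_chrom if genome == "A" else ch.c_chrom
        if own_chrom != chrom:
            continue
        own = ch.a_positions if genome == "A" else ch.c_positions
        if min(own) <= pos <= max(own):
            if best_chain is None or ch.size > best_chain.size:
                best_chain = ch
    if best_chain is None:
        return None
    own = np.array(best_chain.a_positions if genome == "A" else best_chain.c_positions)
    other = np.array(best_chain.c_positions if genome == "A" else best_chain.a_positions)
    order = np.argsort(own)
    pred = float(np.interp(pos, own[order], other[order].astype(float)))
    other_chrom = best_chain.c_chrom if genome == "A" else best_chain.a_chrom
    return other_chrom, int(pred)


def diagnose_noncollinear(
    unigene_id: str,
    hits_a: pd.DataFrame,
    hits_c: pd.DataFrame,
    chains: Sequence[Chain],
    near_best_window: float = 5.0,
    k_multi: int = 3,
    threshold_exponent: float = -30.0,
    max_gap: int = DEFAULT_MAX_GAP,
    paralogue_margin: float = 25.0,
) -> Diagnosis:
    """Classify why a unigene maps to a non-homoeologous position.

    Rules applied in order: (1) at least ``k_multi`` hits within
    ``near_best_window`` exponents of the best in either genome is a
    repetitive artefact; (2) the best cross-genome hit is at least
    ``paralogue_margin`` e-value exponents weaker than the within-genome
    best and no qualifying hit lies within ``max_gap`` of the predicted
    homoeologous position, meaning the homoeologue was lost and a
    paralogue matched (a paralogue diverged at the ancestral hexaploidy,
    long before the A/C split, so its match is markedly weaker than a
    homoeologue's -- whereas a segmentally rearranged gene keeps a
    full-strength partner hit); whether the best hit falls inside a
    detected shadow block is recorded as supporting evidence;
    (3) coherent membership of a non-main chain is a true rearrangement;
    otherwise ambiguous.  The unigene must not belong to a main chain.
    """
    if hits_a.empty and hits_c.empty:
        raise ValueError(f"unigene {unigene_id!r} has no hits in either genome")
    members = _member_lookup(chains).get(unigene_id, [])
    if any(ch.role == "main" for ch in members):
        raise ValueError(f"unigene {unigene_id!r} belongs to a main chain")

    n_near_a = _near_best_count(hits_a, near_best_window)
    n_near_c = _near_best_count(hits_c, near_best_window)
    evidence: dict = {"n_near_best_A": n_near_a, "n_near_best_C": n_near_c,
                      "in_shadow": any(ch.role == "shadow" for ch in members)}

    if max(n_near_a, n_near_c) >= k_multi:
        return Diagnosis(unigene_id, CATEGORY_REPETITIVE, evidence)

    best_a = _best_row(hits_a)
    best_c = _best_row(hits_c)
    threshold = 10.0 ** threshold_exponent
    shadow_chains = [ch for ch in chains if ch.role == "shadow"]

    def rule2(genome: str, own_best, other_hits: pd.DataFrame, other_best) -> bool:
        if own_best is None or other_best is None:
            return False
        if other_best.evalue_exponent < own_best.evalue_exponent + paralogue_margin:
            return False  # partner match at full strength: not a paralogue
        own_pos = int((own_best.tstart + own_best.tend) // 2)
        pred = _predict_partner(chains, genome, own_best.sseqid, own_pos)
        if pred is not None:
            pred_chrom, pred_pos = pred
            evidence[f"predicted_{'C' if genome == 'A' else 'A'}"] = (pred_chrom, pred_pos)
            qualifying = other_hits[
                (other_hits["sseqid"] == pred_chrom)
                & (other_hits["evalue"] <= threshold)
                & (((other_hits["tstart"] + other_hits["tend"]) // 2 - pred_pos).abs()
                   <= max_gap)
            ]
            if not qualifying.empty:
                evidence["homoeologue_hit_near_prediction"] = True
                return False
        best_pos = int((other_best.tstart + other_best.tend) // 2)
        for ch in shadow_chains:
            chrom = ch.c_chrom if genome == "A" else ch.a_chrom
            lo, hi = ch.c_interval if genome == "A" else ch.a_interval
            if other_best.sseqid == chrom and lo <= best_pos <= hi:
                evidence["shadow_chain"] = ch.chain_id
                break
        return True

    if rule2("A", best_a, hits_c, best_c) or rule2("C", best_c, hits_a, best_a):
        return Diagnosis(unigene_id, CATEGORY_MISSING, evidence)

    if members:  # coherent member of a (non-main) chain in both genomes
        evidence["chain"] = members[0].chain_id
        return Diagnosis(unigene_id, CATEGORY_REARRANGEMENT, evidence)
    return Diagnosis(unigene_id, CATEGORY_AMBIGUOUS, evidence)


def diagnose_sample(
    points: pd.DataFrame,
    chains: Sequence[Chain],
    hits_a: pd.DataFrame,
    hits_c: pd.DataFrame,
    sample: int | None = None,
    seed: int = 0,
    **kwargs,
) -> list[Diagnosis]:
    """Diagnose (a sample of) the dual-anchored unigenes outside main chains."""
    member = _member_lookup(chains)
    candidates = [
        u for u in points["unigene_id"]
        if not any(ch.role == "main" for ch in member.get(u, []))
    ]
    if sample is not None and len(candidates) > sample:
        rng = np.random.default_rng(seed)
        candidates = sorted(rng.choice(candidates, size=sample, replace=False))
    by_query_a = dict(tuple(hits_a.groupby("qseqid")))
    by_query_c = dict(tuple(hits_c.groupby("qseqid")))
    empty = hits_a.iloc[0:0]
    out = []
    for u in candidates:
        out.append(
            diagnose_noncollinear(
                u, by_query_a.get(u, empty), by_query_c.get(u, empty), chains, **kwargs
            )
        )
    return out


def diagnoses_to_frame(diagnoses: Sequence[Diagnosis]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {"unigene_id": d.unigene_id, "category": d.category,
             "evidence": ";".join(f"{k}={v}" for k, v in sorted(d.evidence.items()))}
            for d in diagnoses
        ],
        columns=["unigene_id", "category", "evidence"],
    )


# ---------------------------------------------------------------------------
# Dot plot rendering
# ---------------------------------------------------------------------------


def render_dotplot(
    points: pd.DataFrame,
    out_path: str | Path,
    chains: Sequence[Chain] | None = None,
    a_lengths: Mapping[str, int] | None = None,
    c_lengths: Mapping[str, int] | None = None,
    color_scheme: Mapping[str, str] = AT_TAG_COLORS,
) -> Path:
    """Whole-genome dot plot with chromosomes laid end to end.

    Point colours encode similarity to A. thaliana chromosome
    assignments (grey = no match, black = organellar, and one colour per
    At chromosome).  A TSV companion with every plotted point and its
    colour is written next to the image before rendering, so a rendering
    failure never corrupts it.
    """
    out_path = Path(out_path)
    tags = points.get("at_tag", pd.Series(["none"] * len(points)))
    unknown = set(tags) - set(color_scheme)
    if unknown:
        raise ValueError(f"unknown at_tag values: {sorted(unknown)}")

    def offsets(chroms, lengths, pos_col, chrom_col):
        if lengths is None:
            lengths = {
                c: int(points.loc[points[chrom_col] == c, pos_col].max()) + 1
                for c in chroms
            }
        off, total = {}, 0
        for c in sorted(chroms):
            off[c] = total
            total += lengths[c]
        return off, total, lengths

    a_off, a_total, _ = offsets(set(points["a_chrom"]), a_lengths, "a_pos", "a_chrom")
    c_off, c_total, _ = offsets(set(points["c_chrom"]), c_lengths, "c_pos", "c_chrom")

    table = points.copy()
    table["color"] = [color_scheme[t] for t in tags]
    table["x"] = [a_off[c] + p for c, p in zip(points["a_chrom"], points["a_pos"])]
    table["y"] = [c_off[c] + p for c, p in zip(points["c_chrom"], points["c_pos"])]
    tsv_path = out_path.with_suffix(".tsv")
    table.to_csv(tsv_path, sep="\t", index=False)

    from matplotlib.figure import Figure

    fig = Figure(figsize=(8, 8))
    ax = fig.add_subplot(111)
    ax.scatter(table["x"], table["y"], s=2, c=table["color"], linewidths=0)
    for off in list(a_off.values())[1:]:
        ax.axvline(off, color="0.8", lw=0.5)
    for off in list(c_off.values())[1:]:
        ax.axhline(off, color="0.8", lw=0.5)
    ax.set_xlim(0, a_total)
    ax.set_ylim(0, c_total)
    ax.set_xlabel("A genome (bp, chromosomes end to end)")
    ax.set_ylabel("C genome (bp, chromosomes end to end)")
    fig.savefig(out_path, dpi=150)
    return tsv_path
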