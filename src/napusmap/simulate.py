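"""Synthetic inputs with known truth for every stage of the pipeline.

The generator emulates the situation in allopolyploid *Brassica napus*
and its progenitor A and C genomes:

* an ancestral gene order is triplicated into three subgenome tracks
  (the shared hexaploid ancestry of the diploid Brassicas), with
  per-track retention probabilities modelling biased fractionation;
* the triplicated genome is duplicated into an A and a C lineage which
  then diverge by independent gene losses (copy number variation) and
  segmental rearrangements (inversions and translocations);
* genome sequence scaffolds are fragments of chromosomes, optionally
  with injected chimeric joins between chromosomes;
* a doubled-haploid population is a set of single doubled gametes drawn
  from a Markov chain along each linkage group with Haldane (no
  interference) switch probabilities, then degraded by missing calls and
  optional scoring errors;
* similarity searches are emulated directly as BLAST-tabular hit tables:
  each surviving gene copy yields a strong best hit at its true
  position, paralogous copies (other tracks) yield hits weakened by a
  fixed e-value-exponent penalty, repetitive sequences yield several
  near-equal hits scattered across chromosomes, and a gene whose
  homoeologue was lost has no hit at the homoeologous position -- so its
  best cross-genome match is a paralogue, which is what produces the
  displaced "shadow" copies of collinear blocks.

Sequence content is random nucleotide text: similarity lives entirely in
the hit tables, so FASTA is generated only where downstream code needs
actual sequence (scaffold splitting, pseudomolecule construction).

Every function is deterministic given its seed.  All positions are
0-based bp internally.
"""

from __future__ import annotations

import bisect
import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import CALL_A, CALL_B, CALL_MISSING, ScoringMatrix
from .hits import hit_frame

GENE_SPACING = 10_000  # bp between adjacent gene midpoints


# ---------------------------------------------------------------------------
# Genome pair
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SimulatedGenomePair:
    """A pair of homoeologous genomes with full truth bookkeeping.

    Gene copies are named ``g<ancestral>.t<track>``; the same id names the
    copy in both lineages, the lineage being implied by which gene table
    it appears in.
    """

    genes_A: pd.DataFrame  # columns: gene_id, chromosome, position, track
    genes_C: pd.DataFrame
    homoeolog_pairs: set[tuple[str, str]]
    paralog_map: dict[str, dict[str, list[str]]]  # side -> gene_id -> paralogue ids
    deleted_homoeologues: set[str]  # surviving copies whose partner was lost
    rearrangement_log: list[dict]
    chromosome_lengths: dict[str, dict[str, int]]  # side -> chromosome -> bp
    proto_chromosome: dict[str, int]  # ancestral gene id -> proto chromosome
    spacing: int = GENE_SPACING

    def genes(self, side: str) -> pd.DataFrame:
        return self.genes_A if side == "A" else self.genes_C

    def positions(self, side: str) -> dict[str, tuple[str, int]]:
        df = self.genes(side)
        return dict(zip(df["gene_id"], zip(df["chromosome"], df["position"])))

    def rearranged_ids(self, side: str | None = None) -> set[str]:
        out: set[str] = set()
        for event in self.rearrangement_log:
            if side is None or event["lineage"] == side:
                out.update(event["gene_ids"])
        return out


def _chrom_name(side: str, index: int) -> str:
    return f"{side}{index + 1:02d}"


def simulate_genome_pair(
    n_genes: int,
    n_chromosomes: int,
    retention_probs: Sequence[float] = (0.7, 0.3, 0.2),
    n_inversions: int = 0,
    n_translocations: int = 0,
    loss_rate: float = 0.0,
    seed: int = 0,
    spacing: int = GENE_SPACING,
    rearrangement_block: tuple[int, int] = (250, 400),
) -> SimulatedGenomePair:
    """Simulate an A/C genome pair descended from a hexaploid ancestor.

    The ancestral order of ``n_genes`` genes (split into contiguous proto
    chromosomes) is triplicated into 3 subgenome tracks with per-track
    retention, duplicated into A and C lineages, and each lineage then
    suffers independent gene losses (probability ``loss_rate`` per copy)
    and ``n_inversions`` inversions plus ``n_translocations``
    translocations of contiguous blocks of ``rearrangement_block`` genes.
    Chromosome *c* carries track-1 copies of proto chromosome *c*
    followed by track-2 copies of proto *c+1* and track-3 copies of
    proto *c+2* (cyclically), so paralogous segments of each block sit on
    two other chromosomes.
    """
    if n_genes < n_chromosomes:
        raise ValueError("n_genes must be at least n_chromosomes")
    if (
        len(retention_probs) != 3
        or not all(0 <= p <= 1 for p in retention_probs)
        or max(retention_probs) <= 0
    ):
        raise ValueError("retention_probs must be 3 probabilities with at least one > 0")
    if not 0 <= loss_rate < 1:
        raise ValueError("loss_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    proto = {f"g{i:05d}": (i * n_chromosomes) // n_genes for i in range(n_genes)}
    ancestral = list(proto)

    # track retention, shared by both lineages (decided before duplication)
    retained: list[tuple[str, int]] = []
    for t, p in enumerate(retention_probs, start=1):
        keep = rng.random(n_genes) < p
        retained.extend((g, t) for g, k in zip(ancestral, keep) if k)
    retained_ids = {f"{g}.t{t}" for g, t in retained}

    def layout() -> list[list[str]]:
        chroms: list[list[str]] = [[] for _ in range(n_chromosomes)]
        for c in range(n_chromosomes):
            for t, offset in ((1, 0), (2, 1), (3, 2)):
                p = (c + offset) % n_chromosomes
                chroms[c].extend(
                    f"{g}.t{t}" for g in ancestral
                    if proto[g] == p and (g, t) in set_retained
                )
        return chroms

    set_retained = set(retained)
    log: list[dict] = []
    survivors: dict[str, set[str]] = {}
    tables: dict[str, pd.DataFrame] = {}
    lengths: dict[str, dict[str, int]] = {}

    for side in ("A", "C"):
        chroms = layout()
        # independent losses per lineage
        alive = {
            cid for chrom in chroms for cid in chrom if rng.random() >= loss_rate
        }
        chroms = [[cid for cid in chrom if cid in alive] for chrom in chroms]

        def pick_block(min_len: int = rearrangement_block[0]) -> tuple[int, int, int] | None:
            candidates = [c for c in range(n_chromosomes) if len(chroms[c]) >= min_len]
            if not candidates:
                return None
            c = int(rng.choice(candidates))
            size = int(rng.integers(rearrangement_block[0], rearrangement_block[1] + 1))
            size = min(size, len(chroms[c]))
            start = int(rng.integers(0, len(chroms[c]) - size + 1))
            return c, start, size

        for _ in range(n_inversions):
            picked = pick_block()
            if picked is None:
                break
            c, start, size = picked
            block = chroms[c][start : start + size]
            chroms[c][start : start + size] = block[::-1]
            log.append({"type": "inversion", "lineage": side,
                        "chromosome": _chrom_name(side, c), "gene_ids": list(block)})
        for _ in range(n_translocations):
            if n_chromosomes < 2:
                raise ValueError("translocations require at least 2 chromosomes")
            picked = pick_block()
            if picked is None:
                break
            c, start, size = picked
            block = chroms[c][start : start + size]
            del chroms[c][start : start + size]
            dest = int(rng.choice([d for d in range(n_chromosomes) if d != c]))
            at = int(rng.integers(0, len(chroms[dest]) + 1))
            chroms[dest][at:at] = block
            log.append({"type": "translocation", "lineage": side,
                        "chromosome": _chrom_name(side, c),
                        "destination": _chrom_name(side, dest), "gene_ids": list(block)})

        records = []
        side_lengths = {}
        for c, chrom in enumerate(chroms):
            name = _chrom_name(side, c)
            side_lengths[name] = max(len(chrom), 1) * spacing
            for idx, cid in enumerate(chrom):
                records.append({
                    "gene_id": cid,
                    "chromosome": name,
                    "position": idx * spacing + spacing // 2,
                    "track": int(cid.rsplit(".t", 1)[1]),
                })
        tables[side] = pd.DataFrame.from_records(
            records, columns=["gene_id", "chromosome", "position", "track"]
        )
        lengths[side] = side_lengths
        survivors[side] = set(tables[side]["gene_id"])

    both = survivors["A"] & survivors["C"]
    pairs = {(cid, cid) for cid in both}
    deleted = (survivors["A"] | survivors["C"]) - both

    # keyed by every triplication-retained copy (not only side survivors):
    # a copy lost from one lineage still *queries* that lineage, where its
    # best remaining relatives are the surviving other-track paralogues
    paralog_map: dict[str, dict[str, list[str]]] = {}
    for side in ("A", "C"):
        by_gene: dict[str, list[str]] = {}
        for cid in survivors[side]:
            g = cid.rsplit(".t", 1)[0]
            by_gene.setdefault(g, []).append(cid)
        side_map = {}
        for cid in retained_ids:
            g = cid.rsplit(".t", 1)[0]
            side_map[cid] = sorted(x for x in by_gene.get(g, []) if x != cid)
        paralog_map[side] = side_map

    return SimulatedGenomePair(
        genes_A=tables["A"],
        genes_C=tables["C"],
        homoeolog_pairs=pairs,
        paralog_map=paralog_map,
        deleted_homoeologues=deleted,
        rearrangement_log=log,
        chromosome_lengths=lengths,
        proto_chromosome=proto,
        spacing=spacing,
    )


# ---------------------------------------------------------------------------
# Scaffolds
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SimulatedScaffoldSet:
    """Chromosome fragments reassembled as (possibly chimeric) scaffolds."""

    fragments: pd.DataFrame
    # columns: scaffold_id, frag_index, chromosome, start, end (0-based
    # half-open source interval), flipped (bool), scaff_start, scaff_end
    chimera_truth: dict[str, dict]  # scaffold_id -> junction truth
    sequences: dict[str, str]
    lengths: dict[str, int]
    true_order: dict[str, list[tuple[str, str]]]  # chromosome -> [(scaffold_id, orientation)]

    def locate(self, chromosome: str, position: int) -> tuple[str, int]:
        """Map a chromosome position to (scaffold_id, scaffold position)."""
        starts, rows = self._index[chromosome]
        i = bisect.bisect_right(starts, position) - 1
        if i < 0:
            raise KeyError(f"position {position} before first fragment of {chromosome}")
        row = rows[i]
        if not row["start"] <= position < row["end"]:
            raise KeyError(f"position {position} not covered on {chromosome}")
        offset = position - row["start"]
        if row["flipped"]:
            return row["scaffold_id"], row["scaff_end"] - 1 - offset
        return row["scaffold_id"], row["scaff_start"] + offset

    def __post_init__(self) -> None:
        self._index = {}
        for chrom, sub in self.fragments.groupby("chromosome"):
            sub = sub.sort_values("start")
            self._index[chrom] = (
                list(sub["start"]),
                sub.to_dict("records"),
            )


_DNA = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _DNA[rng.integers(0, 4, size=length)].tobytes().decode()


def simulate_scaffolds(
    genome: SimulatedGenomePair,
    side: str,
    mean_length: int,
    n_chimeras: int = 0,
    seed: int = 0,
    with_sequence: bool = True,
) -> SimulatedScaffoldSet:
    """Fragment one genome into scaffolds, injecting chimeric joins.

    Chromosomes are cut at exponentially spaced breakpoints (mean
    ``mean_length``); ``n_chimeras`` scaffolds are then formed by joining
    two fragments from different chromosomes (each fragment is flipped
    with probability 0.5, as real assembly orientation is arbitrary).
    Only fragments spanning at least two gene positions are joined into
    chimeras, so every injected junction has markers on both sides --
    a junction without flanking markers would be invisible to any
    map-based detector.
    """
    if mean_length <= 0:
        raise ValueError("mean_length must be positive")
    lengths = genome.chromosome_lengths[side]
    if n_chimeras > 0 and len(lengths) < 2:
        raise ValueError("chimeras require at least two chromosomes")
    rng = np.random.default_rng(seed)

    fragments: list[dict] = []
    for chrom in sorted(lengths):
        total = lengths[chrom]
        pos = 0
        while pos < total:
            step = max(int(rng.exponential(mean_length)), genome.spacing)
            end = min(pos + step, total)
            fragments.append({"chromosome": chrom, "start": pos, "end": end})
            pos = end
    if n_chimeras > len(fragments) // 10:
        raise ValueError("n_chimeras must be at most one tenth of the scaffold count")

    def n_gene_slots(frag) -> int:
        # gene midpoints sit at idx*spacing + spacing//2
        half = genome.spacing // 2
        first = -(-(frag["start"] - half) // genome.spacing)  # ceil
        last = (frag["end"] - half - 1) // genome.spacing
        return max(last - first + 1, 0)

    order = list(rng.permutation(len(fragments)))
    markered = [i for i in order if n_gene_slots(fragments[i]) >= 2]
    chimera_members: list[tuple[int, int]] = []
    used: set[int] = set()
    for _ in range(n_chimeras):
        first = next(i for i in markered if i not in used)
        used.add(first)
        second = next(
            i for i in markered
            if i not in used and fragments[i]["chromosome"] != fragments[first]["chromosome"]
        )
        used.add(second)
        chimera_members.append((first, second))
    singles = [i for i in order if i not in used]

    scaffold_parts: list[list[int]] = chimera_members + [[i] for i in singles]  # type: ignore[list-item]
    scaffold_parts = [list(p) for p in scaffold_parts]
    # deterministic shuffle of scaffold naming order
    naming = list(rng.permutation(len(scaffold_parts)))

    rows: list[dict] = []
    chimera_truth: dict[str, dict] = {}
    scaff_lengths: dict[str, int] = {}
    for rank, part_idx in enumerate(naming):
        parts = scaffold_parts[part_idx]
        sid = f"S{rank + 1:05d}"
        offset = 0
        for k, frag_i in enumerate(parts):
            frag = fragments[frag_i]
            flen = frag["end"] - frag["start"]
            rows.append({
                "scaffold_id": sid,
                "frag_index": k,
                "chromosome": frag["chromosome"],
                "start": frag["start"],
                "end": frag["end"],
                "flipped": bool(rng.random() < 0.5),
                "scaff_start": offset,
                "scaff_end": offset + flen,
            })
            offset += flen
        scaff_lengths[sid] = offset
        if len(parts) == 2:
            chimera_truth[sid] = {
                "junction": rows[-1]["scaff_start"],
                "chromosomes": (
                    fragments[parts[0]]["chromosome"],
                    fragments[parts[1]]["chromosome"],
                ),
            }

    frag_df = pd.DataFrame.from_records(rows)
    sequences = (
        {sid: _random_sequence(rng, L) for sid, L in sorted(scaff_lengths.items())}
        if with_sequence
        else {}
    )

    true_order: dict[str, list[tuple[str, str]]] = {}
    non_chimeric = frag_df[~frag_df["scaffold_id"].isin(chimera_truth)]
    for chrom, sub in non_chimeric.groupby("chromosome"):
        sub = sub.sort_values("start")
        true_order[chrom] = [
            (r["scaffold_id"], "-" if r["flipped"] else "+") for r in sub.to_dict("records")
        ]

    return SimulatedScaffoldSet(
        fragments=frag_df,
        chimera_truth=chimera_truth,
        sequences=sequences,
        lengths=scaff_lengths,
        true_order=true_order,
    )


# ---------------------------------------------------------------------------
# DH population
# ---------------------------------------------------------------------------


def make_marker_map(
    n_groups: int,
    markers_per_group: int,
    length_cm: float = 100.0,
    seed: int = 0,
    group_prefix: str = "A",
) -> pd.DataFrame:
    """A random marker map: uniform marker positions on each linkage group."""
    rng = np.random.default_rng(seed)
    records = []
    for g in range(n_groups):
        group = f"{group_prefix}{g + 1:02d}"
        cms = np.sort(rng.uniform(0.0, length_cm, size=markers_per_group))
        for i, cm in enumerate(cms):
            records.append({
                "marker_id": f"m{group}_{i + 1:04d}",
                "linkage_group": group,
                "cM": float(cm),
            })
    return pd.DataFrame.from_records(records)


@dataclasses.dataclass
class DHTruth:
    true_bins: dict[str, str]     # marker_id -> true bin label
    gametes: np.ndarray           # (n_markers, n_lines) 0/1, before masking/errors


def simulate_dh_population(
    marker_map: pd.DataFrame,
    n_lines: int,
    missing_rate: float = 0.05,
    error_rate: float = 0.0,
    seed: int = 0,
    with_truth: bool = False,
):
    """Simulate DH scoring strings along a marker map.

    Each line is a single gamete doubled: a Markov chain runs along each
    linkage group with switch probability between adjacent markers given
    by the inverse Haldane function r = 0.5*(1 - exp(-2*dcM/100)).  Calls
    are then masked to missing at ``missing_rate`` and flipped at
    ``error_rate``; no heterozygous call is ever emitted.
    """
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    for group, sub in marker_map.groupby("linkage_group", sort=False):
        if (np.diff(sub["cM"].to_numpy()) < 0).any():
            raise ValueError(f"cM positions decrease within linkage group {group}")
    rng = np.random.default_rng(seed)

    marker_ids: list[str] = []
    groups: list[str] = []
    gamete_blocks: list[np.ndarray] = []
    true_bins: dict[str, str] = {}
    for group, sub in marker_map.groupby("linkage_group", sort=False):
        cms = sub["cM"].to_numpy()
        m = len(cms)
        r = 0.5 * (1.0 - np.exp(-2.0 * np.diff(cms) / 100.0))
        states = np.empty((m, n_lines), dtype=np.int8)
        states[0] = rng.random(n_lines) < 0.5
        if m > 1:
            switches = rng.random((m - 1, n_lines)) < r[:, None]
            states[1:] = switches
            states = np.cumsum(states, axis=0) % 2
        _, labels = np.unique(states, axis=0, return_inverse=True)
        for mk, lab in zip(sub["marker_id"], labels):
            true_bins[mk] = f"{group}:{int(lab)}"
        marker_ids.extend(sub["marker_id"])
        groups.extend([group] * m)
        gamete_blocks.append(states.astype(np.int8))

    gametes = np.vstack(gamete_blocks)
    calls = gametes.copy()
    if error_rate > 0:
        flip = rng.random(calls.shape) < error_rate
        calls[flip] = 1 - calls[flip]
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = CALL_MISSING

    matrix = ScoringMatrix(
        marker_ids=marker_ids,
        line_ids=[f"L{i + 1:03d}" for i in range(n_lines)],
        calls=calls,
        linkage_groups=groups,
    )
    if with_truth:
        return matrix, DHTruth(true_bins=true_bins, gametes=gametes)
    return matrix


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------


def simulate_hit_table(
    features: Sequence[str],
    positions: Mapping[str, tuple[str, int]],
    repetitive_ids: Iterable[str] = (),
    paralog_map: Mapping[str, Sequence[str]] | None = None,
    evalue_model: tuple[float, float] = (-120.0, 60.0),
    seed: int = 0,
    target_lengths: Mapping[str, int] | None = None,
    feature_length: int = 1000,
) -> pd.DataFrame:
    """Emulate a similarity search of features against one genome.

    Each feature present in ``positions`` gets one best hit at its true
    position with e-value exponent drawn around
    ``evalue_model[0]``; paralogous copies (via ``paralog_map``) yield
    hits weakened by ``evalue_model[1]`` exponents; features in
    ``repetitive_ids`` yield >= 3 near-equal hits scattered across
    chromosomes.  A feature absent from ``positions`` (a deleted
    homoeologue) gets no hit at its true position but keeps its paralogue
    hits.
    """
    best_mean, paralog_penalty = evalue_model
    rng = np.random.default_rng(seed)
    paralog_map = paralog_map or {}
    repetitive = set(repetitive_ids)
    targets = sorted({t for t, _ in positions.values()})
    records: list[dict] = []

    def add_hit(feature: str, target: str, centre: int, exponent: float) -> None:
        half = feature_length // 2
        lo = max(centre - half, 0)
        hi = lo + feature_length
        if target_lengths and target in target_lengths:
            hi = min(hi, target_lengths[target])
            lo = max(hi - feature_length, 0)
        exponent = min(exponent, -1.0)
        strand_minus = rng.random() < 0.5
        sstart, send = (hi, lo + 1) if strand_minus else (lo + 1, hi)
        records.append({
            "qseqid": feature,
            "sseqid": target,
            "pident": round(100.0 + exponent / 20.0, 2),
            "length": feature_length,
            "mismatch": max(int(-exponent / 10), 0),
            "gapopen": 0,
            "qstart": 1,
            "qend": feature_length,
            "sstart": sstart,
            "send": send,
            "evalue": 10.0 ** max(exponent, -300.0),
            "bitscore": round(50.0 - 2.0 * exponent, 1),
        })

    for feature in features:
        base = rng.normal(best_mean, 8.0)
        base = min(base, -40.0)  # best hits always clear reporting thresholds
        if feature in repetitive:
            k = int(rng.integers(3, 6))
            if feature in positions:
                target, pos = positions[feature]
                add_hit(feature, target, pos, base + rng.uniform(0.0, 4.0))
                k -= 1
            for _ in range(k):
                target = targets[int(rng.integers(0, len(targets)))]
                limit = target_lengths[target] if target_lengths else 10_000_000
                add_hit(feature, target, int(rng.integers(0, max(limit, 1))),
                        base + rng.uniform(0.0, 4.0))
            continue
        if feature in positions:
            target, pos = positions[feature]
            add_hit(feature, target, pos, base)
        for par in paralog_map.get(feature, []):
            if par in positions:
                target, pos = positions[par]
                add_hit(feature, target, pos, base + paralog_penalty + rng.normal(0.0, 3.0))
    return hit_frame(records)


# ---------------------------------------------------------------------------
# Study-scale bundles used by the command line, tests and acceptance runs
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MappingPanelStudy:
    marker_map: pd.DataFrame
    matrix: ScoringMatrix
    truth: DHTruth


def simulate_mapping_panel(
    seed: int,
    n_groups: int = 10,
    markers_per_group: int = 200,
    n_lines: int = 75,
    missing_rate: float = 0.05,
    error_rate: float = 0.0,
    length_cm: float = 100.0,
) -> MappingPanelStudy:
    """Default DH mapping panel: 10 groups x 200 markers, 75 lines."""
    marker_map = make_marker_map(n_groups, markers_per_group, length_cm, seed=seed)
    matrix, truth = simulate_dh_population(
        marker_map, n_lines, missing_rate, error_rate, seed=seed + 1, with_truth=True
    )
    return MappingPanelStudy(marker_map=marker_map, matrix=matrix, truth=truth)


@dataclasses.dataclass
class AssemblyStudy:
    pair: SimulatedGenomePair
    scaffolds: SimulatedScaffoldSet
    hit_table: pd.DataFrame
    marker_info: pd.DataFrame  # marker_id, linkage_group, bin_id, cM
    cm_per_bp: float


def simulate_assembly_inputs(
    seed: int,
    n_genes: int = 2000,
    n_chromosomes: int = 10,
    n_scaffolds: int = 200,
    n_chimeras: int = 5,
    cm_per_bp: float = 1e-5,
    with_sequence: bool = True,
) -> AssemblyStudy:
    """Inputs for the scaffold stage: one genome, fragmented, with chimeras.

    Markers are the genes themselves, carrying their true map position
    (cM proportional to bp); the hit table places each marker on its
    scaffold, including across injected chimeric joins.
    """
    pair = simulate_genome_pair(
        n_genes, n_chromosomes, retention_probs=(1.0, 1.0, 1.0),
        loss_rate=0.0, seed=seed,
    )
    total = sum(pair.chromosome_lengths["A"].values())
    scaffolds = simulate_scaffolds(
        pair, "A", mean_length=max(total // n_scaffolds, pair.spacing),
        n_chimeras=n_chimeras, seed=seed + 1, with_sequence=with_sequence,
    )
    genes = pair.genes_A
    scaffold_pos = {
        g: scaffolds.locate(chrom, pos)
        for g, chrom, pos in zip(genes["gene_id"], genes["chromosome"], genes["position"])
    }
    hit_table = simulate_hit_table(
        list(genes["gene_id"]),
        positions=scaffold_pos,
        target_lengths=scaffolds.lengths,
        seed=seed + 2,
        feature_length=200,
    )
    marker_info = pd.DataFrame({
        "marker_id": genes["gene_id"],
        "linkage_group": genes["chromosome"],
        "bin_id": genes["gene_id"],
        "cM": genes["position"] * cm_per_bp,
    })
    return AssemblyStudy(
        pair=pair, scaffolds=scaffolds, hit_table=hit_table,
        marker_info=marker_info, cm_per_bp=cm_per_bp,
    )


@dataclasses.dataclass
class CollinearityStudy:
    pair: SimulatedGenomePair
    features: list[str]
    hits_A: pd.DataFrame
    hits_C: pd.DataFrame
    repetitive_ids: set[str]
    causes: dict[str, str]  # feature -> repetitive | missing-homoeologue | rearranged
    at_tags: dict[str, str]


def simulate_collinearity_inputs(
    seed: int,
    n_genes: int = 6000,
    n_chromosomes: int = 10,
    retention_probs: Sequence[float] = (0.7, 0.3, 0.2),
    loss_rate: float = 0.15,
    n_inversions: int = 3,
    n_translocations: int = 3,
    repetitive_frac: float = 0.02,
) -> CollinearityStudy:
    """Inputs for the collinearity stage: dual hit tables with truth labels.

    A unigene exists for every gene copy surviving in at least one
    lineage.  Truth causes of non-collinear anchoring, with precedence:
    repetitive > missing-homoeologue > rearranged.
    """
    pair = simulate_genome_pair(
        n_genes, n_chromosomes, retention_probs=retention_probs,
        n_inversions=n_inversions, n_translocations=n_translocations,
        loss_rate=loss_rate, seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    pos_A = pair.positions("A")
    pos_C = pair.positions("C")
    features = sorted(set(pos_A) | set(pos_C))
    n_rep = int(len(features) * repetitive_frac)
    repetitive = set(rng.choice(features, size=n_rep, replace=False))

    hits_A = simulate_hit_table(
        features, pos_A, repetitive_ids=repetitive, paralog_map=pair.paralog_map["A"],
        target_lengths=pair.chromosome_lengths["A"], seed=seed + 2,
    )
    hits_C = simulate_hit_table(
        features, pos_C, repetitive_ids=repetitive, paralog_map=pair.paralog_map["C"],
        target_lengths=pair.chromosome_lengths["C"], seed=seed + 3,
    )

    rearranged = pair.rearranged_ids()
    causes: dict[str, str] = {}
    for f in features:
        if f in repetitive:
            causes[f] = "repetitive"
        elif f in pair.deleted_homoeologues:
            causes[f] = "missing-homoeologue"
        elif f in rearranged:
            causes[f] = "rearranged"

    at_tags = {
        f: ("none" if f in repetitive
            else f"At{pair.proto_chromosome[f.rsplit('.t', 1)[0]] % 5 + 1}")
        for f in features
    }
    return CollinearityStudy(
        pair=pair, features=features, hits_A=hits_A, hits_C=hits_C,
        repetitive_ids=repetitive, causes=causes, at_tags=at_tags,
    )
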