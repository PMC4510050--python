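"""Map-guided scaffold assembly: anchoring, chimera splitting, ordering,
orientation and pseudomolecule (FASTA + AGP) construction.

Markers anchored to scaffolds through their best similarity hits carry a
linkage-map position (bin, linkage group, cM).  A scaffold whose anchors
fall into two internally consistent but mutually inconsistent runs is
chimeric and is split at the midpoint between the flanking anchors.
Scaffolds are then assigned to a chromosome (the modal linkage group of
their anchors), ordered along it by median anchor cM, and oriented by
the sign of the Spearman correlation between anchor scaffold positions
and cM.  Pseudomolecules are emitted as FASTA plus an AGP 2.0 component
file, with a bijective coordinate lift between scaffold and chromosome
coordinates over all placed ranges.

Coordinates are 0-based half-open internally; AGP and the public lift
API use the formats' 1-based inclusive convention.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .hits import best_hits, load_hits  # noqa: F401  (re-exported surface)
from .linkage import LinkageMap


@dataclasses.dataclass(frozen=True)
class MarkerAnchor:
    """A marker placed on a scaffold with its linkage-map position."""

    marker_id: str
    scaffold_id: str
    position: int  # midpoint of the hit's target span, 0-based
    bin_id: str
    linkage_group: str
    cm: float


def anchors_from_hits(
    hits: pd.DataFrame, marker_positions: Mapping[str, tuple[str, str, float]]
) -> list[MarkerAnchor]:
    """Build marker anchors from best hits plus map positions.

    ``marker_positions`` maps marker_id -> (bin_id, linkage_group, cM),
    e.g. from :meth:`napusmap.linkage.LinkageMap.marker_positions`.
    Markers without a hit or without a map position are skipped.
    """
    best = best_hits(hits)
    anchors = []
    for row in best.itertuples(index=False):
        if row.qseqid not in marker_positions:
            continue
        bin_id, group, cm = marker_positions[row.qseqid]
        anchors.append(
            MarkerAnchor(
                marker_id=row.qseqid,
                scaffold_id=row.sseqid,
                position=int((row.tstart + row.tend) // 2),
                bin_id=bin_id,
                linkage_group=group,
                cm=float(cm),
            )
        )
    return anchors


def group_anchors(anchors: Sequence[MarkerAnchor]) -> dict[str, list[MarkerAnchor]]:
    """Anchors per scaffold, sorted by scaffold position."""
    out: dict[str, list[MarkerAnchor]] = {}
    for a in anchors:
        out.setdefault(a.scaffold_id, []).append(a)
    for sid in out:
        out[sid].sort(key=lambda a: (a.position, a.marker_id))
    return out


# ---------------------------------------------------------------------------
# Chimera detection and splitting
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ChimeraSplit:
    scaffold_id: str
    position: int  # split offset in scaffold coordinates
    left_group: str
    right_group: str


def _consistent(run: Sequence[MarkerAnchor], max_cm_jump: float) -> bool:
    groups = {a.linkage_group for a in run}
    if len(groups) != 1:
        return False
    cms = [a.cm for a in run]
    return max(cms) - min(cms) <= max_cm_jump


def _sides_differ(left: Sequence[MarkerAnchor], right: Sequence[MarkerAnchor],
                  max_cm_jump: float) -> bool:
    if left[0].linkage_group != right[0].linkage_group:
        return True
    lcm = [a.cm for a in left]
    rcm = [a.cm for a in right]
    gap = max(min(rcm) - max(lcm), min(lcm) - max(rcm), 0.0)
    return gap > max_cm_jump


def detect_chimeras(
    anchors_by_scaffold: Mapping[str, Sequence[MarkerAnchor]],
    min_support: int = 2,
    max_cm_jump: float = 20.0,
) -> list[ChimeraSplit]:
    """Find scaffolds whose anchors disagree about their map location.

    A split is declared between consecutive anchors when at least
    ``min_support`` anchors on each side form internally consistent runs
    (one linkage group, cM range <= ``max_cm_jump``) while the two sides
    differ in linkage group or lie more than ``max_cm_jump`` apart.  The
    split position is the floor midpoint between the flanking anchors.
    A single stray anchor therefore never triggers a split, and multiple
    junctions per scaffold are reported independently.
    """
    splits: list[ChimeraSplit] = []
    for sid in sorted(anchors_by_scaffold):
        anchors = list(anchors_by_scaffold[sid])
        if any(a.position > b.position for a, b in zip(anchors, anchors[1:])):
            anchors = sorted(anchors, key=lambda a: (a.position, a.marker_id))
        n = len(anchors)
        for i in range(n - 1):
            # maximal consistent run ending at i
            lo = i
            while lo > 0 and _consistent(anchors[lo - 1 : i + 1], max_cm_jump):
                lo -= 1
            left = anchors[lo : i + 1]
            # maximal consistent run starting at i + 1
            hi = i + 1
            while hi < n - 1 and _consistent(anchors[i + 1 : hi + 2], max_cm_jump):
                hi += 1
            right = anchors[i + 1 : hi + 1]
            if len(left) < min_support or len(right) < min_support:
                continue
            if not (_consistent(left, max_cm_jump) and _consistent(right, max_cm_jump)):
                continue
            if _sides_differ(left, right, max_cm_jump):
                splits.append(
                    ChimeraSplit(
                        scaffold_id=sid,
                        position=(anchors[i].position + anchors[i + 1].position) // 2,
                        left_group=left[0].linkage_group,
                        right_group=right[0].linkage_group,
                    )
                )
    return splits


def split_scaffold(scaffold_id: str, sequence: str, positions: Sequence[int]) -> list[tuple[str, str]]:
    """Cut a scaffold at the given offsets; fragment ids get .1/.2/... suffixes.

    The fragments concatenate back to the original sequence exactly.
    """
    cuts = sorted(set(int(p) for p in positions))
    for p in cuts:
        if not 0 < p < len(sequence):
            raise ValueError(
                f"split position {p} outside (0, {len(sequence)}) for {scaffold_id}"
            )
    bounds = [0] + cuts + [len(sequence)]
    if not cuts:
        return [(scaffold_id, sequence)]
    return [
        (f"{scaffold_id}.{k + 1}", sequence[bounds[k] : bounds[k + 1]])
        for k in range(len(bounds) - 1)
    ]


def apply_splits(
    anchors: Sequence[MarkerAnchor],
    splits: Sequence[ChimeraSplit],
    sequences: Mapping[str, str],
) -> tuple[list[MarkerAnchor], dict[str, str]]:
    """Split sequences and remap anchors onto the split fragments."""
    by_scaffold: dict[str, list[int]] = {}
    for s in splits:
        by_scaffold.setdefault(s.scaffold_id, []).append(s.position)

    new_sequences: dict[str, str] = {}
    for sid, seq in sequences.items():
        for fid, fseq in split_scaffold(sid, seq, by_scaffold.get(sid, [])):
            new_sequences[fid] = fseq

    new_anchors: list[MarkerAnchor] = []
    for a in anchors:
        cuts = sorted(by_scaffold.get(a.scaffold_id, []))
        if not cuts:
            new_anchors.append(a)
            continue
        bounds = [0] + cuts + [len(sequences[a.scaffold_id])]
        for k in range(len(bounds) - 1):
            if bounds[k] <= a.position < bounds[k + 1]:
                new_anchors.append(
                    dataclasses.replace(
                        a,
                        scaffold_id=f"{a.scaffold_id}.{k + 1}",
                        position=a.position - bounds[k],
                    )
                )
                break
    return new_anchors, new_sequences


# ---------------------------------------------------------------------------
# Ordering and orientation
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Component:
    scaffold_id: str
    start: int  # source range, 0-based half-open
    end: int
    orientation: str  # '+', '-' ('?' scaffolds are placed '+' and flagged)
    flagged: bool = False


@dataclasses.dataclass
class PseudomoleculeSpec:
    """Per-chromosome ordered, oriented scaffold components plus gap policy."""

    components: dict[str, list[Component]]
    gap_size: int = 100

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "chromosome": chrom,
                "rank": k + 1,
                "scaffold_id": c.scaffold_id,
                "source_start": c.start,
                "source_end": c.end,
                "orientation": "?" if c.flagged else c.orientation,
            }
            for chrom, comps in self.components.items()
            for k, c in enumerate(comps)
        ]
        return pd.DataFrame.from_records(
            records,
            columns=["chromosome", "rank", "scaffold_id", "source_start",
                     "source_end", "orientation"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def order_and_orient(
    anchors: Sequence[MarkerAnchor],
    linkage_map: LinkageMap,
    scaffold_lengths: Mapping[str, int],
    gap_size: int = 100,
) -> tuple[PseudomoleculeSpec, list[str]]:
    """Order and orient scaffolds along the map into a pseudomolecule spec.

    Chromosome = modal linkage group of the scaffold's anchors; position
    key = median anchor cM; order by key, ties broken by descending
    scaffold length then id.  Orientation is the sign of the Spearman
    correlation between anchor scaffold positions and cM; scaffolds with
    fewer than two distinct positions or cM values are placed '+' and
    flagged.  Scaffolds without anchors are excluded and returned
    separately (second element).
    """
    grouped = group_anchors(anchors)
    unplaced = sorted(set(scaffold_lengths) - set(grouped))
    placements: dict[str, list[tuple]] = {}
    for sid, scaffold_anchors in grouped.items():
        if sid not in scaffold_lengths:
            raise ValueError(f"anchored scaffold {sid!r} has no known length")
        groups = pd.Series([a.linkage_group for a in scaffold_anchors])
        counts = groups.value_counts()
        modal = sorted(counts[counts == counts.max()].index)[0]
        cms = np.array([a.cm for a in scaffold_anchors if a.linkage_group == modal])
        positions = np.array(
            [a.position for a in scaffold_anchors if a.linkage_group == modal]
        )
        key = float(np.median(cms))
        if len(np.unique(cms)) < 2 or len(np.unique(positions)) < 2:
            orientation, flagged = "+", True
        else:
            rho = stats.spearmanr(positions, cms).statistic
            if np.isnan(rho) or rho == 0:
                orientation, flagged = "+", True
            elif rho > 0:
                orientation, flagged = "+", False
            else:
                orientation, flagged = "-", False
        placements.setdefault(modal, []).append(
            (key, -scaffold_lengths[sid], sid, orientation, flagged)
        )

    components: dict[str, list[Component]] = {}
    for chrom in sorted(placements):
        comps = []
        for key, neglen, sid, orientation, flagged in sorted(placements[chrom]):
            comps.append(
                Component(
                    scaffold_id=sid,
                    start=0,
                    end=scaffold_lengths[sid],
                    orientation=orientation,
                    flagged=flagged,
                )
            )
        components[chrom] = comps
    return PseudomoleculeSpec(components=components, gap_size=gap_size), unplaced


# ---------------------------------------------------------------------------
# Pseudomolecule construction, AGP, coordinate lifting
# ---------------------------------------------------------------------------


class CoordinateLift:
    """Bijective coordinate lifting between scaffolds and pseudomolecules.

    Public positions are 1-based (matching AGP/BLAST conventions); strand
    flips across '-' components.
    """

    def __init__(self) -> None:
        self._by_scaffold: dict[str, list[tuple[int, int, str, int, str]]] = {}
        self._by_chrom: dict[str, list[tuple[int, int, str, int, int, str]]] = {}

    def _add(self, chrom: str, chrom_start: int, comp: Component) -> None:
        self._by_scaffold.setdefault(comp.scaffold_id, []).append(
            (comp.start, comp.end, chrom, chrom_start, comp.orientation)
        )
        self._by_chrom.setdefault(chrom, []).append(
            (chrom_start, chrom_start + comp.end - comp.start,
             comp.scaffold_id, comp.start, comp.end, comp.orientation)
        )

    def to_chromosome(self, scaffold_id: str, position: int, strand: str = "+"):
        """(scaffold, 1-based pos, strand) -> (chromosome, 1-based pos, strand)."""
        pos0 = position - 1
        for start, end, chrom, chrom_start, orientation in self._by_scaffold.get(
            scaffold_id, []
        ):
            if start <= pos0 < end:
                if orientation == "+":
                    return chrom, chrom_start + (pos0 - start) + 1, strand
                flipped = "-" if strand == "+" else "+"
                return chrom, chrom_start + (end - 1 - pos0) + 1, flipped
        raise KeyError(f"{scaffold_id}:{position} is not a placed position")

    def to_scaffold(self, chromosome: str, position: int, strand: str = "+"):
        """(chromosome, 1-based pos, strand) -> (scaffold, 1-based pos, strand)."""
        pos0 = position - 1
        for cstart, cend, sid, sstart, send, orientation in self._by_chrom.get(
            chromosome, []
        ):
            if cstart <= pos0 < cend:
                if orientation == "+":
                    return sid, sstart + (pos0 - cstart) + 1, strand
                flipped = "-" if strand == "+" else "+"
                return sid, (send - 1 - (pos0 - cstart)) + 1, flipped
        raise KeyError(f"{chromosome}:{position} is not a placed (non-gap) position")


def build_pseudomolecules(
    spec: PseudomoleculeSpec,
    sequences: Mapping[str, str],
    gap_size: int | None = None,
) -> tuple[dict[str, str], pd.DataFrame, CoordinateLift]:
    """Concatenate oriented components into pseudomolecule FASTA + AGP 2.0.

    Consecutive components are separated by ``gap_size`` N's ('-'
    components are reverse-complemented).  Returns the chromosome
    sequences, the AGP table and a :class:`CoordinateLift`.
    """
    gap = spec.gap_size if gap_size is None else gap_size
    fasta: dict[str, str] = {}
    agp_rows: list[dict] = []
    lift = CoordinateLift()
    for chrom in spec.components:
        parts: list[str] = []
        offset = 0
        part_number = 0
        for k, comp in enumerate(spec.components[chrom]):
            if comp.scaffold_id not in sequences:
                raise ValueError(f"scaffold {comp.scaffold_id!r} missing from FASTA")
            seq = sequences[comp.scaffold_id]
            if not 0 <= comp.start < comp.end <= len(seq):
                raise ValueError(
                    f"component range {comp.start}-{comp.end} exceeds "
                    f"{comp.scaffold_id} (length {len(seq)})"
                )
            if k > 0 and gap > 0:
                part_number += 1
                agp_rows.append({
                    "object": chrom,
                    "object_beg": offset + 1,
                    "object_end": offset + gap,
                    "part_number": part_number,
                    "component_type": "N",
                    "component_id_or_gap_length": str(gap),
                    "component_beg_or_gap_type": "scaffold",
                    "component_end_or_linkage": "yes",
                    "orientation_or_evidence": "map",
                })
                parts.append("N" * gap)
                offset += gap
            segment = seq[comp.start : comp.end]
            if comp.orientation == "-":
                segment = str(Seq(segment).reverse_complement())
            part_number += 1
            agp_rows.append({
                "object": chrom,
                "object_beg": offset + 1,
                "object_end": offset + len(segment),
                "part_number": part_number,
                "component_type": "W",
                "component_id_or_gap_length": comp.scaffold_id,
                "component_beg_or_gap_type": str(comp.start + 1),
                "component_end_or_linkage": str(comp.end),
                "orientation_or_evidence": comp.orientation,
            })
            lift._add(chrom, offset, comp)
            parts.append(segment)
            offset += len(segment)
        fasta[chrom] = "".join(parts)
    agp = pd.DataFrame.from_records(agp_rows, columns=AGP_COLUMNS)
    return fasta, agp, lift


AGP_COLUMNS = [
    "object", "object_beg", "object_end", "part_number", "component_type",
    "component_id_or_gap_length", "component_beg_or_gap_type",
    "component_end_or_linkage", "orientation_or_evidence",
]


def write_agp(agp: pd.DataFrame, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("##agp-version 2.0\n")
        agp.to_csv(fh, sep="\t", header=False, index=False)


def read_agp(path: str | Path) -> PseudomoleculeSpec:
    """Parse an AGP 2.0 file back into a pseudomolecule spec."""
    components: dict[str, list[Component]] = {}
    gap_size = 0
    with Path(path).open() as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            chrom, ctype = f[0], f[4]
            if ctype == "N":
                gap_size = int(f[5])
                continue
            components.setdefault(chrom, []).append(
                Component(
                    scaffold_id=f[5],
                    start=int(f[6]) - 1,
                    end=int(f[7]),
                    orientation="+" if f[8] == "?" else f[8],
                    flagged=f[8] == "?",
                )
            )
    return PseudomoleculeSpec(components=components, gap_size=gap_size)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with Path(path).open("w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def assemble_pseudomolecules(
    anchors: Sequence[MarkerAnchor],
    sequences: Mapping[str, str],
    linkage_map: LinkageMap,
    min_support: int = 2,
    max_cm_jump: float = 20.0,
    gap_size: int = 100,
):
    """Full scaffold stage: detect chimeras, split, order/orient, build.

    Returns (fasta, agp, lift, spec, splits, unplaced scaffold ids).
    """
    splits = detect_chimeras(group_anchors(anchors), min_support, max_cm_jump)
    new_anchors, new_sequences = apply_splits(anchors, splits, sequences)
    lengths = {sid: len(seq) for sid, seq in new_sequences.items()}
    spec, unplaced = order_and_orient(new_anchors, linkage_map, lengths, gap_size)
    fasta, agp, lift = build_pseudomolecules(spec, new_sequences)
    return fasta, agp, lift, spec, splits, unplaced
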