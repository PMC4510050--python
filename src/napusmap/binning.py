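"""Scoring-string matrices and recombination-bin calling for DH populations.

A doubled-haploid (DH) line carries a single doubled gamete, so every SNP
marker is scored across lines as parental allele ``A`` or ``B`` (never
heterozygous) or as missing.  The per-marker string of calls in fixed line
order is the *scoring string*.  Markers showing no recombination among the
genotyped lines collapse into a *recombination bin* -- the unit of map
resolution -- represented by a consensus scoring string (positionwise
majority of the non-missing member calls, ties treated as missing).

Bin calling with missing data is not transitive, so this module uses a
deterministic seeded-growth rule: markers are processed in input order, a
bin is seeded with the first unassigned marker, and candidates are added
greedily (in input order) whenever they conflict with the bin's running
consensus at no more than ``error_tolerance`` jointly non-missing
positions; the consensus is recomputed after every addition.  At
``error_tolerance=0`` a non-missing consensus call can never flip, which
makes the rule order-stable for conflict-free inputs and guarantees that
every member agrees with the final consensus wherever both are non-missing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: internal call codes; the missing symbol used in files is configurable
CALL_A = np.int8(0)
CALL_B = np.int8(1)
CALL_MISSING = np.int8(2)

DEFAULT_MISSING_CHAR = "-"


class ScoringFormatError(ValueError):
    """A scoring-string file violates the expected layout or alphabet."""


def encode_calls(string: str, missing_char: str = DEFAULT_MISSING_CHAR) -> np.ndarray:
    """Encode a scoring string over {A, B, missing} into int8 codes."""
    out = np.empty(len(string), dtype=np.int8)
    for i, ch in enumerate(string):
        if ch == "A":
            out[i] = CALL_A
        elif ch == "B":
            out[i] = CALL_B
        elif ch == missing_char:
            out[i] = CALL_MISSING
        else:
            raise ScoringFormatError(
                f"invalid call {ch!r}; expected 'A', 'B' or {missing_char!r}"
            )
    return out


def decode_calls(codes: np.ndarray, missing_char: str = DEFAULT_MISSING_CHAR) -> str:
    lut = np.array(["A", "B", missing_char])
    return "".join(lut[np.asarray(codes, dtype=np.int8)])


@dataclasses.dataclass
class ScoringMatrix:
    """DH genotype calls, markers x lines, over the alphabet {A, B, missing}."""

    marker_ids: list[str]
    line_ids: list[str]
    calls: np.ndarray  # (n_markers, n_lines) int8
    linkage_groups: list[str] | None = None  # optional per-marker tag

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.marker_ids), len(self.line_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.line_ids)} lines"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids are not unique")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line ids are not unique")
        if self.calls.size and not np.isin(self.calls, [CALL_A, CALL_B, CALL_MISSING]).all():
            raise ValueError("calls contain codes outside {A, B, missing}")
        if self.linkage_groups is not None and len(self.linkage_groups) != len(self.marker_ids):
            raise ValueError("linkage_groups length does not match marker count")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def row(self, marker_id: str) -> np.ndarray:
        return self.calls[self.marker_ids.index(marker_id)]

    def strings(self, missing_char: str = DEFAULT_MISSING_CHAR) -> dict[str, str]:
        return {
            m: decode_calls(self.calls[i], missing_char)
            for i, m in enumerate(self.marker_ids)
        }

    def subset_lines(self, indices: Sequence[int]) -> "ScoringMatrix":
        idx = list(indices)
        return ScoringMatrix(
            marker_ids=list(self.marker_ids),
            line_ids=[self.line_ids[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            linkage_groups=list(self.linkage_groups) if self.linkage_groups else None,
        )


@dataclasses.dataclass
class RecombinationBin:
    """A co-segregating marker group with its consensus scoring string."""

    bin_id: str
    member_marker_ids: list[str]
    consensus: np.ndarray  # int8 over {A, B, missing}, length n_lines
    linkage_group: str | None = None

    def consensus_string(self, missing_char: str = DEFAULT_MISSING_CHAR) -> str:
        return decode_calls(self.consensus, missing_char)

    @property
    def n_members(self) -> int:
        return len(self.member_marker_ids)


# ---------------------------------------------------------------------------
# TSV input/output
#
# Layout (tab separated), emulating the role of the published scoring tables:
#   marker_id  linkage_group  <line ids joined by ','>
#   m0001      A01            AAB-B...
# The third column header carries the line ids so a round trip preserves
# them; an empty linkage group is written as '.'.
# ---------------------------------------------------------------------------


def read_scoring_tsv(path: str | Path, missing_char: str = DEFAULT_MISSING_CHAR) -> ScoringMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        fields = header.split("\t")
        if len(fields) != 3:
            raise ScoringFormatError(
                f"{path}: expected 3 tab-separated columns in header, got {len(fields)}"
            )
        line_ids = fields[2].split(",")
        n_lines = len(line_ids)
        marker_ids: list[str] = []
        groups: list[str | None] = []
        rows: list[np.ndarray] = []
        seen: set[str] = set()
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            parts = raw.split("\t")
            if len(parts) != 3:
                raise ScoringFormatError(f"{path}:{lineno}: expected 3 columns")
            marker, group, string = parts
            if marker in seen:
                raise ScoringFormatError(f"{path}:{lineno}: duplicate marker id {marker!r}")
            seen.add(marker)
            if len(string) != n_lines:
                raise ScoringFormatError(
                    f"{path}:{lineno}: scoring string for {marker!r} has length "
                    f"{len(string)}, expected {n_lines}"
                )
            try:
                rows.append(encode_calls(string, missing_char))
            except ScoringFormatError as exc:
                raise ScoringFormatError(f"{path}:{lineno}: marker {marker!r}: {exc}") from exc
            marker_ids.append(marker)
            groups.append(None if group in (".", "") else group)
    any_group = any(g is not None for g in groups)
    calls = np.vstack(rows) if rows else np.empty((0, n_lines), dtype=np.int8)
    return ScoringMatrix(
        marker_ids=marker_ids,
        line_ids=line_ids,
        calls=calls,
        linkage_groups=[g or "" for g in groups] if any_group else None,
    )


def write_scoring_tsv(
    matrix: ScoringMatrix, path: str | Path, missing_char: str = DEFAULT_MISSING_CHAR
) -> None:
    path = Path(path)
    groups = matrix.linkage_groups or [None] * matrix.n_markers
    with path.open("w") as fh:
        fh.write("marker_id\tlinkage_group\t" + ",".join(matrix.line_ids) + "\n")
        for i, marker in enumerate(matrix.marker_ids):
            group = groups[i] if groups[i] else "."
            fh.write(f"{marker}\t{group}\t{decode_calls(matrix.calls[i], missing_char)}\n")


# ---------------------------------------------------------------------------
# Panel extension
# ---------------------------------------------------------------------------


def extend_panel(
    base: ScoringMatrix, extra: ScoringMatrix, markers: str = "intersection"
) -> ScoringMatrix:
    """Append newly genotyped lines to an existing scoring panel.

    The merged panel carries the base lines followed by the extra lines.
    By default only markers present in both panels are kept (in base
    order); with ``markers='union'`` markers private to one panel are
    retained and filled with missing calls for the other panel's lines.
    """
    shared_lines = set(base.line_ids) & set(extra.line_ids)
    if shared_lines:
        raise ValueError(f"line ids present in both panels: {sorted(shared_lines)[:5]}")
    base_index = {m: i for i, m in enumerate(base.marker_ids)}
    extra_index = {m: i for i, m in enumerate(extra.marker_ids)}
    common = [m for m in base.marker_ids if m in extra_index]
    if not common:
        raise ValueError("panels share no markers")
    if markers == "intersection":
        keep = common
    elif markers == "union":
        keep = list(base.marker_ids) + [m for m in extra.marker_ids if m not in base_index]
    else:
        raise ValueError("markers must be 'intersection' or 'union'")

    n_out_lines = base.n_lines + extra.n_lines
    calls = np.full((len(keep), n_out_lines), CALL_MISSING, dtype=np.int8)
    groups: list[str] | None = None
    base_groups = dict(zip(base.marker_ids, base.linkage_groups or []))
    extra_groups = dict(zip(extra.marker_ids, extra.linkage_groups or []))
    if base_groups or extra_groups:
        groups = []
    for k, m in enumerate(keep):
        if m in base_index:
            calls[k, : base.n_lines] = base.calls[base_index[m]]
        if m in extra_index:
            calls[k, base.n_lines :] = extra.calls[extra_index[m]]
        if groups is not None:
            groups.append(base_groups.get(m) or extra_groups.get(m) or "")
    return ScoringMatrix(
        marker_ids=keep,
        line_ids=list(base.line_ids) + list(extra.line_ids),
        calls=calls,
        linkage_groups=groups,
    )


# ---------------------------------------------------------------------------
# Bin calling
# ---------------------------------------------------------------------------


def _conflicts(row: np.ndarray, consensus: np.ndarray) -> int:
    return int(
        np.count_nonzero((row != consensus) & (row != CALL_MISSING) & (consensus != CALL_MISSING))
    )


def _consensus_from_counts(count_a: np.ndarray, count_b: np.ndarray) -> np.ndarray:
    consensus = np.full(count_a.shape, CALL_MISSING, dtype=np.int8)
    consensus[count_a > count_b] = CALL_A
    consensus[count_b > count_a] = CALL_B
    return consensus


def bin_markers(matrix: ScoringMatrix, error_tolerance: int = 0) -> list[RecombinationBin]:
    """Collapse markers into recombination bins with consensus strings.

    Two markers share a bin iff their calls conflict at no more than
    ``error_tolerance`` jointly non-missing positions, resolved
    transitively by seeded greedy growth against the running consensus
    (see module docstring).  When per-marker linkage-group tags are
    present, bins are called within each group.

    A marker masked at the one line that separates two adjacent bins is
    genuinely ambiguous: it is compatible with both consensuses, and the
    growth pass alone would always leave it in the earlier-seeded bin.
    A deterministic reassignment pass therefore moves every marker
    compatible with more than one bin consensus to the *largest*
    compatible bin (ties broken by bin creation order) -- the
    maximum-prior choice, since a marker is proportionally more likely
    to belong to a bin with more members.  Consensuses are recomputed
    from the final membership and emptied bins dropped.
    """
    if matrix.n_markers == 0:
        raise ValueError("cannot bin an empty scoring matrix")

    if matrix.linkage_groups is not None:
        group_order: list[str] = []
        by_group: dict[str, list[int]] = {}
        for i, g in enumerate(matrix.linkage_groups):
            if g not in by_group:
                by_group[g] = []
                group_order.append(g)
            by_group[g].append(i)
        blocks = [(g, by_group[g]) for g in group_order]
    else:
        blocks = [(None, list(range(matrix.n_markers)))]

    bins: list[RecombinationBin] = []
    counter = 0
    for group, indices in blocks:
        assigned = np.zeros(len(indices), dtype=bool)
        rows = matrix.calls[indices]
        for si, seed_local in enumerate(range(len(indices))):
            if assigned[seed_local]:
                continue
            assigned[seed_local] = True
            members = [seed_local]
            count_a = (rows[seed_local] == CALL_A).astype(np.int32)
            count_b = (rows[seed_local] == CALL_B).astype(np.int32)
            consensus = _consensus_from_counts(count_a, count_b)

            if error_tolerance == 0:
                # Safe prefilter: at tolerance 0 the consensus constraints
                # only tighten, so candidates incompatible with the seed
                # string can never become compatible later.
                cand = np.flatnonzero(
                    ~assigned
                    & (
                        (
                            (rows != consensus)
                            & (rows != CALL_MISSING)
                            & (consensus != CALL_MISSING)
                        ).sum(axis=1)
                        == 0
                    )
                )
            else:
                cand = np.flatnonzero(~assigned)

            for j in cand:
                if assigned[j]:
                    continue
                if _conflicts(rows[j], consensus) <= error_tolerance:
                    assigned[j] = True
                    members.append(int(j))
                    count_a += rows[j] == CALL_A
                    count_b += rows[j] == CALL_B
                    consensus = _consensus_from_counts(count_a, count_b)

            counter += 1
            bins.append(
                RecombinationBin(
                    bin_id=f"bin{counter:05d}",
                    member_marker_ids=[matrix.marker_ids[indices[m]] for m in members],
                    consensus=consensus,
                    linkage_group=group,
                )
            )
    return _reassign_ambiguous(matrix, bins, error_tolerance)


def _reassign_ambiguous(
    matrix: ScoringMatrix, bins: list[RecombinationBin], error_tolerance: int
) -> list[RecombinationBin]:
    """Move markers compatible with several bins to the largest one."""
    row_of = {m: i for i, m in enumerate(matrix.marker_ids)}
    sizes = {b.bin_id: b.n_members for b in bins}
    creation = {b.bin_id: k for k, b in enumerate(bins)}
    by_group: dict[str | None, list[RecombinationBin]] = {}
    for b in bins:
        by_group.setdefault(b.linkage_group, []).append(b)
    current = {m: b for b in bins for m in b.member_marker_ids}

    changed = False
    for m in matrix.marker_ids:
        row = matrix.calls[row_of[m]]
        cur = current[m]
        compatible = [
            b for b in by_group[cur.linkage_group]
            if _conflicts(row, b.consensus) <= error_tolerance
        ]
        if len(compatible) > 1:
            target = max(compatible, key=lambda b: (sizes[b.bin_id], -creation[b.bin_id]))
            if target is not cur:
                cur.member_marker_ids.remove(m)
                target.member_marker_ids.append(m)
                current[m] = target
                changed = True
    if not changed:
        return bins
    out = []
    for b in bins:
        if not b.member_marker_ids:
            continue
        rows = matrix.calls[[row_of[m] for m in b.member_marker_ids]]
        count_a = (rows == CALL_A).sum(axis=0)
        count_b = (rows == CALL_B).sum(axis=0)
        b.consensus = _consensus_from_counts(count_a, count_b)
        out.append(b)
    return out


def bin_resolution_curve(
    matrix: ScoringMatrix,
    line_counts: Iterable[int],
    seed: int | None = None,
    error_tolerance: int = 0,
) -> pd.DataFrame:
    """Number of recombination bins as a function of population size.

    For each requested line count *k* the bins are recomputed on the
    first *k* lines (or, with a seed, on the first *k* of one fixed random
    permutation, so that requested subsets are nested and the bin count is
    non-decreasing in *k*).
    """
    counts = list(line_counts)
    for k in counts:
        if k <= 0:
            raise ValueError(f"line count must be positive, got {k}")
        if k > matrix.n_lines:
            raise ValueError(f"requested {k} lines but matrix has {matrix.n_lines}")
    if seed is None:
        order = np.arange(matrix.n_lines)
    else:
        order = np.random.default_rng(seed).permutation(matrix.n_lines)
    records = []
    for k in counts:
        sub = matrix.subset_lines(order[:k])
        records.append({"n_lines": k, "n_bins": len(bin_markers(sub, error_tolerance))})
    return pd.DataFrame.from_records(records)
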