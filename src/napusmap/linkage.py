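"""Two-point DH linkage statistics, grouping, bin ordering and cM assignment.

For a doubled-haploid population each line is a single doubled gamete, so
the two-point recombination fraction between two markers (or bin
consensus strings) is simply R/N over the jointly non-missing lines,
where R counts lines with differing calls.  The LOD score against free
recombination (r = 0.5) is

    LOD = R*log10(r) + (N-R)*log10(1-r) + N*log10(2)

evaluated at the maximum-likelihood estimate r = R/N (capped at 0.5); in
the limit R = 0 this is exactly N*log10(2).

Bins are grouped by single-linkage clustering on confident linkage edges,
ordered within a group by minimising the total number of adjacent-pair
recombination events (exhaustively for small groups, by greedy
nearest-neighbour seeding plus 2-opt/relocation refinement otherwise),
and placed on a cM scale by accumulating a map function (Kosambi by
default, Haldane available) over adjacent recombination fractions.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .binning import CALL_MISSING, RecombinationBin, encode_calls

LOG10_2 = math.log10(2.0)


class InsufficientOverlapError(ValueError):
    """Two strings share no jointly non-missing position."""


@dataclasses.dataclass(frozen=True)
class TwoPointEstimate:
    N: int       # informative (jointly non-missing) line count
    R: int       # recombinant line count
    r_hat: float
    lod: float


def _coerce(calls) -> np.ndarray:
    if isinstance(calls, RecombinationBin):
        return calls.consensus
    if isinstance(calls, str):
        return encode_calls(calls)
    return np.asarray(calls, dtype=np.int8)


def two_point(x, y) -> TwoPointEstimate:
    """Two-point recombination estimate between two DH scoring strings."""
    a, b = _coerce(x), _coerce(y)
    if a.shape != b.shape:
        raise ValueError("scoring strings have different lengths")
    both = (a != CALL_MISSING) & (b != CALL_MISSING)
    n = int(both.sum())
    if n == 0:
        raise InsufficientOverlapError("no jointly non-missing position")
    r = int(((a != b) & both).sum())
    r_hat = r / n
    if r == 0:
        lod = n * LOG10_2
    else:
        rt = min(r_hat, 0.5)
        lod = r * math.log10(rt) + (n - r) * math.log10(1.0 - rt) + n * LOG10_2
    return TwoPointEstimate(N=n, R=r, r_hat=r_hat, lod=lod)


def map_distance(r: float, function: str = "haldane") -> float:
    """Transform a recombination fraction into cM (Haldane or Kosambi)."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    if function == "haldane":
        return -50.0 * math.log(1.0 - 2.0 * r)
    if function == "kosambi":
        return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    raise ValueError(f"unknown map function {function!r}")


# ---------------------------------------------------------------------------
# Pairwise statistics over a set of bins
# ---------------------------------------------------------------------------


def _pair_tables(bins: Sequence[RecombinationBin]):
    """(R, N, r_hat, lod) matrices over all bin pairs.

    Pairs with no informative line get r_hat = 0.5, R = N = 0, lod = 0 --
    i.e. they behave as unlinked.
    """
    n = len(bins)
    R = np.zeros((n, n), dtype=np.int64)
    N = np.zeros((n, n), dtype=np.int64)
    r_hat = np.full((n, n), 0.5)
    lod = np.zeros((n, n))
    for i in range(n):
        r_hat[i, i] = 0.0
        for j in range(i + 1, n):
            try:
                est = two_point(bins[i], bins[j])
            except InsufficientOverlapError:
                continue
            R[i, j] = R[j, i] = est.R
            N[i, j] = N[j, i] = est.N
            r_hat[i, j] = r_hat[j, i] = est.r_hat
            lod[i, j] = lod[j, i] = est.lod
    return R, N, r_hat, lod


@dataclasses.dataclass
class GroupingResult:
    groups: dict[str, list[RecombinationBin]]
    conflicts: list[tuple[str, str]]  # linked bin pairs whose prior tags disagree


def group_bins(
    bins: Sequence[RecombinationBin], lod_min: float = 6.0, r_max: float = 0.35
) -> GroupingResult:
    """Partition bins into linkage groups.

    Single-linkage clustering on edges with lod >= ``lod_min`` and
    r_hat <= ``r_max``.  When bins carry prior linkage-group tags the tag
    partition takes precedence and the clustering only validates it:
    qualifying edges between differently tagged bins are reported as
    conflicts.
    """
    if not bins:
        raise ValueError("no bins to group")
    _, _, r_hat, lod = _pair_tables(bins)
    n = len(bins)
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if lod[i, j] >= lod_min and r_hat[i, j] <= r_max
    ]

    tagged = all(b.linkage_group for b in bins)
    if tagged:
        groups: dict[str, list[RecombinationBin]] = {}
        for b in bins:
            groups.setdefault(b.linkage_group, []).append(b)
        conflicts = [
            (bins[i].bin_id, bins[j].bin_id)
            for i, j in edges
            if bins[i].linkage_group != bins[j].linkage_group
        ]
        return GroupingResult(groups=groups, conflicts=conflicts)

    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from(edges)
    components = sorted(nx.connected_components(graph), key=min)
    groups = {
        f"LG{k + 1:02d}": [bins[i] for i in sorted(comp)]
        for k, comp in enumerate(components)
    }
    return GroupingResult(groups=groups, conflicts=[])


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------


def _path_cost(order: Sequence[int], R: np.ndarray) -> int:
    return int(sum(R[order[k], order[k + 1]] for k in range(len(order) - 1)))


def _order_exhaustive(R: np.ndarray) -> list[int]:
    n = R.shape[0]
    best: tuple[int, tuple[int, ...]] | None = None
    for perm in itertools.permutations(range(n)):
        if perm[0] > perm[-1]:
            continue  # each path equals its reverse
        cost = _path_cost(perm, R)
        if best is None or cost < best[0] or (cost == best[0] and perm < best[1]):
            best = (cost, perm)
    return list(best[1])


def _order_heuristic(R: np.ndarray, r_hat: np.ndarray, start: int | None = None) -> list[int]:
    n = R.shape[0]
    if n == 1:
        return [0]
    if start is None:
        start = int(np.argmax(r_hat.mean(axis=1)))  # most extreme bin: a terminus
    order = [start]
    remaining = set(range(n)) - {start}
    while remaining:
        last = order[-1]
        nxt = min(remaining, key=lambda j: (R[last, j], j))
        order.append(nxt)
        remaining.remove(nxt)

    improved = True
    while improved:
        improved = False
        # 2-opt: reverse a segment
        for i in range(n - 1):
            for j in range(i + 1, n):
                before = 0
                after = 0
                if i > 0:
                    before += R[order[i - 1], order[i]]
                    after += R[order[i - 1], order[j]]
                if j < n - 1:
                    before += R[order[j], order[j + 1]]
                    after += R[order[i], order[j + 1]]
                if after < before:
                    order[i : j + 1] = reversed(order[i : j + 1])
                    improved = True
        # or-opt: relocate segments of 1..4 bins, optionally reversed;
        # single-bin moves alone cannot fix a short block attached to
        # the wrong chromosome end
        for seg_len in (1, 2, 3, 4):
            for i in range(n - seg_len + 1):
                current = _path_cost(order, R)
                segment = order[i : i + seg_len]
                rest = order[:i] + order[i + seg_len :]
                best_trial, best_cost = None, current
                for pos in range(len(rest) + 1):
                    for block in (segment, segment[::-1]):
                        trial = rest[:pos] + block + rest[pos:]
                        c = _path_cost(trial, R)
                        if c < best_cost:
                            best_trial, best_cost = trial, c
                if best_trial is not None:
                    order = best_trial
                    improved = True
    return order


def order_bins(
    group: Sequence[RecombinationBin],
    prior_order: Sequence[str] | None = None,
    method: str = "auto",
) -> list[RecombinationBin]:
    """Order bins within a linkage group by minimal adjacent recombination.

    The objective is the total number of recombination events between
    adjacent bins.  ``method='auto'`` solves groups of <= 8 bins
    exhaustively and larger ones heuristically; the heuristic seeds with
    the prior order when given, else greedy nearest-neighbour from the
    most extreme bin, then refines with 2-opt and single-bin relocation.
    The result is canonicalised so the first bin id sorts before the last.
    """
    bins = list(group)
    if not bins:
        raise ValueError("empty group")
    if len(bins) == 1:
        return bins
    R, _, r_hat, _ = _pair_tables(bins)

    if method == "auto":
        method = "exhaustive" if len(bins) <= 8 else "heuristic"
    if method == "exhaustive":
        idx = _order_exhaustive(R)
    elif method == "heuristic":
        start = None
        if prior_order:
            id_to_idx = {b.bin_id: i for i, b in enumerate(bins)}
            seeded = [id_to_idx[b] for b in prior_order if b in id_to_idx]
            if len(seeded) == len(bins):
                # refine the prior order directly
                order = seeded
                idx = _order_heuristic_from(order, R)
                return _canonical([bins[i] for i in idx])
            start = seeded[0] if seeded else None
        idx = _order_heuristic(R, r_hat, start=start)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _canonical([bins[i] for i in idx])


def _order_heuristic_from(order: list[int], R: np.ndarray) -> list[int]:
    # 2-opt refinement only, starting from the supplied (prior) order
    n = len(order)
    if n <= 2:
        return order
    improved = True
    order = list(order)
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                before = after = 0
                if i > 0:
                    before += R[order[i - 1], order[i]]
                    after += R[order[i - 1], order[j]]
                if j < n - 1:
                    before += R[order[j], order[j + 1]]
                    after += R[order[i], order[j + 1]]
                if after < before:
                    order[i : j + 1] = reversed(order[i : j + 1])
                    improved = True
    return order


def _canonical(bins: list[RecombinationBin]) -> list[RecombinationBin]:
    if bins[0].bin_id > bins[-1].bin_id:
        return bins[::-1]
    return bins


def ordering_cost(order: Sequence[RecombinationBin]) -> int:
    """Total adjacent-pair recombination events of an ordering."""
    total = 0
    for a, b in zip(order, order[1:]):
        try:
            total += two_point(a, b).R
        except InsufficientOverlapError:
            total += len(a.consensus)
    return total


# ---------------------------------------------------------------------------
# cM assignment and the linkage map container
# ---------------------------------------------------------------------------

#: adjacent recombination fractions are clamped below this before the map
#: function, which is undefined at r >= 0.5
_R_CLAMP = 0.4999


@dataclasses.dataclass
class MapEntry:
    bin_id: str
    cm: float
    member_marker_ids: list[str]


@dataclasses.dataclass
class LinkageMap:
    """Linkage groups, each an ordered list of bins with cM positions."""

    groups: dict[str, list[MapEntry]]

    def marker_positions(self) -> dict[str, tuple[str, str, float]]:
        """marker_id -> (bin_id, linkage_group, cM)."""
        out: dict[str, tuple[str, str, float]] = {}
        for group, entries in self.groups.items():
            for e in entries:
                for m in e.member_marker_ids:
                    out[m] = (e.bin_id, group, e.cm)
        return out

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "linkage_group": g,
                "bin_id": e.bin_id,
                "cM": e.cm,
                "member_markers": ",".join(e.member_marker_ids),
            }
            for g, entries in self.groups.items()
            for e in entries
        ]
        return pd.DataFrame.from_records(
            records, columns=["linkage_group", "bin_id", "cM", "member_markers"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def assign_cM(
    ordered_bins: Sequence[RecombinationBin], function: str = "kosambi"
) -> list[tuple[RecombinationBin, float]]:
    """Cumulative cM positions along an ordered list of bins, starting at 0."""
    bins = list(ordered_bins)
    if not bins:
        raise ValueError("empty group")
    positions = [0.0]
    for a, b in zip(bins, bins[1:]):
        try:
            est = two_point(a, b)
        except InsufficientOverlapError as exc:
            raise InsufficientOverlapError(
                f"adjacent bins {a.bin_id} and {b.bin_id} share no informative line"
            ) from exc
        positions.append(positions[-1] + map_distance(min(est.r_hat, _R_CLAMP), function))
    return list(zip(bins, positions))


def build_linkage_map(
    bins: Sequence[RecombinationBin],
    lod_min: float = 6.0,
    r_max: float = 0.35,
    function: str = "kosambi",
    order_method: str = "auto",
) -> LinkageMap:
    """Group, order and scale bins into a linkage map."""
    grouping = group_bins(bins, lod_min=lod_min, r_max=r_max)
    groups: dict[str, list[MapEntry]] = {}
    for name in sorted(grouping.groups):
        ordered = order_bins(grouping.groups[name], method=order_method)
        groups[name] = [
            MapEntry(bin_id=b.bin_id, cm=cm, member_marker_ids=list(b.member_marker_ids))
            for b, cm in assign_cM(ordered, function=function)
        ]
    return LinkageMap(groups=groups)
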