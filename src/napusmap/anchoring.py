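"""Anchoring unigenes and SNP-array probe sequences onto pseudomolecules.

Each feature is placed at the midpoint of its best similarity hit,
provided the hit's e-value passes the reporting threshold (1e-30,
inclusive, by default).  Features anchored independently to the A and C
pseudomolecule sets are joined by id to give the dual-position table
that feeds the collinearity analysis.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .hits import best_hits


@dataclasses.dataclass(frozen=True)
class AnchoredFeature:
    feature_id: str
    feature_type: str  # 'unigene' or 'probe'
    chromosome: str
    position: int  # midpoint of best-hit span, 0-based
    strand: str
    evalue_exponent: float


def anchor_features(
    hits: pd.DataFrame,
    chromosome_lengths: Mapping[str, int],
    threshold_exponent: float = -30.0,
    feature_types: Mapping[str, str] | None = None,
) -> tuple[list[AnchoredFeature], list[str]]:
    """Place each feature at its best hit if the e-value passes threshold.

    The best hit uses the deterministic tie-break of
    :func:`napusmap.hits.best_hits`; a feature is kept iff
    evalue <= 10**threshold_exponent (boundary inclusive).  Returns the
    anchored features sorted by (chromosome, position, feature_id) and
    the ids of unanchored features; together they partition the input.
    """
    unknown = set(hits["sseqid"]) - set(chromosome_lengths)
    if unknown:
        raise ValueError(f"hits to unknown chromosomes: {sorted(unknown)[:5]}")
    threshold = 10.0 ** threshold_exponent
    best = best_hits(hits)
    anchored: list[AnchoredFeature] = []
    unanchored: list[str] = []
    for row in best.itertuples(index=False):
        if row.evalue <= threshold:
            anchored.append(
                AnchoredFeature(
                    feature_id=row.qseqid,
                    feature_type=(feature_types or {}).get(row.qseqid, "unigene"),
                    chromosome=row.sseqid,
                    position=int((row.tstart + row.tend) // 2),
                    strand=row.strand,
                    evalue_exponent=float(row.evalue_exponent),
                )
            )
        else:
            unanchored.append(row.qseqid)
    anchored.sort(key=lambda a: (a.chromosome, a.position, a.feature_id))
    unanchored.sort()
    return anchored, unanchored


def anchors_to_frame(anchored: Sequence[AnchoredFeature]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [dataclasses.asdict(a) for a in anchored],
        columns=["chromosome", "position", "feature_id", "feature_type",
                 "evalue_exponent", "strand"],
    )


def write_anchor_tsv(anchored: Sequence[AnchoredFeature], path: str | Path) -> None:
    anchors_to_frame(anchored).to_csv(path, sep="\t", index=False)


def write_anchor_bed(anchored: Sequence[AnchoredFeature], path: str | Path) -> None:
    """BED6 export: 0-based half-open single-base intervals at the anchor point."""
    with Path(path).open("w") as fh:
        for a in anchored:
            score = min(int(-a.evalue_exponent), 1000)
            fh.write(
                f"{a.chromosome}\t{a.position}\t{a.position + 1}\t"
                f"{a.feature_id}\t{score}\t{a.strand}\n"
            )


def dual_anchor_join(
    anchored_a: Sequence[AnchoredFeature], anchored_c: Sequence[AnchoredFeature]
) -> pd.DataFrame:
    """Inner join of unigene anchors across the two genomes.

    Returns one row per unigene anchored in both, with its A and C
    chromosome and position; the join size is bounded by the smaller
    anchored set.
    """
    def frame(anchored, suffix):
        rows = [
            {
                "feature_id": a.feature_id,
                f"{suffix}_chrom": a.chromosome,
                f"{suffix}_pos": a.position,
                f"{suffix}_exp": a.evalue_exponent,
            }
            for a in anchored
            if a.feature_type == "unigene"
        ]
        return pd.DataFrame.from_records(
            rows,
            columns=["feature_id", f"{suffix}_chrom", f"{suffix}_pos", f"{suffix}_exp"],
        )

    joined = frame(anchored_a, "a").merge(frame(anchored_c, "c"), on="feature_id")
    return joined.sort_values("feature_id", kind="mergesort").reset_index(drop=True)
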