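"""Large-deletion detection from capture-target coverage gaps.

A homozygous deletion spanning one or more whole capture targets leaves
those targets with zero aligned reads.  Given a per-base depth track
(bedGraph) and the target intervals, this module computes per-target
mean depth and covered fraction, then merges runs of consecutive
uncovered targets into candidate deletion spans.  The reported span is a
minimum bound: the true breakpoints lie at or outside it, somewhere in
the unobserved sequence flanking the first and last uncovered targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TargetSet


class DepthTrack:
    """Sorted, non-overlapping depth intervals per chromosome (0-based half-open)."""

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, depths), each sorted by start
        self.intervals = intervals

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "DepthTrack":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "depth"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": np.int64},
        )
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            out[str(chrom)] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["depth"].to_numpy(),
            )
        return cls(out)

    @classmethod
    def from_records(cls, records: list[tuple[str, int, int, int]]) -> "DepthTrack":
        out: dict[str, list[list[int]]] = {}
        for chrom, start, end, depth in records:
            out.setdefault(chrom, []).append([start, end, depth])
        final = {}
        for chrom, rows in out.items():
            rows.sort()
            arr = np.array(rows, dtype=np.int64)
            final[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(final)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, (starts, ends, depths) in self.intervals.items():
                for s, e, d in zip(starts, ends, depths):
                    fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")

    def overlapping(self, chrom: str, start: int, end: int):
        """Yield (start, end, depth) clipped to [start, end)."""
        if chrom not in self.intervals:
            return
        starts, ends, depths = self.intervals[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        for i in range(lo, len(starts)):
            if starts[i] >= end:
                break
            yield max(int(starts[i]), start), min(int(ends[i]), end), int(depths[i])


@dataclass
class CandidateDeletion:
    """One run of consecutive uncovered targets.

    ``span_start``/``span_end`` are minimum bounds: the first uncovered
    target's start to the last uncovered target's end.
    """

    chrom: str
    span_start: int
    span_end: int
    n_targets: int
    target_ids: list[str] = field(default_factory=list)

    @property
    def span_bp(self) -> int:
        return self.span_end - self.span_start


def target_coverage(depth: DepthTrack, targets: TargetSet) -> pd.DataFrame:
    """Per-target mean depth and fraction of bases with depth > 0.

    Chromosomes present in the targets but absent from the depth track
    are treated as depth 0 with a warning.
    """
    missing = [c for c in targets.chroms() if c not in depth.intervals]
    if missing:
        warnings.warn(f"no depth data for chromosome(s) {missing}; treated as depth 0")
    rows = []
    for idx, region in enumerate(targets):
        length = region.length
        base_sum = 0
        covered = 0
        for s, e, d in depth.overlapping(region.chrom, region.start, region.end):
            base_sum += (e - s) * d
            if d > 0:
                covered += e - s
        rows.append(
            {
                "region_id": region.region_id,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "order": idx,
                "mean_depth": base_sum / length,
                "covered_fraction": covered / length,
            }
        )
    return pd.DataFrame(rows)


def detect_uncovered(
    cov: pd.DataFrame,
    max_depth: float = 0,
    min_consecutive: int = 1,
    min_flank_covered: bool = True,
    max_gap_bp: int | None = None,
) -> list[CandidateDeletion]:
    """Group consecutive uncovered targets into candidate deletions.

    A target is uncovered when its covered fraction is 0 (``max_depth``
    = 0, the default) or its mean depth is <= ``max_depth``.
    Consecutiveness is in target order along a chromosome; genomic gap
    length between targets is ignored unless ``max_gap_bp`` is set.
    With ``min_flank_covered`` the targets immediately flanking a run
    must themselves be covered, suppressing chromosome-end artifacts.
    """
    candidates: list[CandidateDeletion] = []
    cov = cov.sort_values(["chrom", "order"])
    if max_depth == 0:
        uncovered_mask = cov["covered_fraction"].to_numpy() == 0.0
    else:
        uncovered_mask = cov["mean_depth"].to_numpy() <= max_depth
    for chrom, sub in cov.assign(_unc=uncovered_mask).groupby("chrom", sort=False):
        rows = sub.to_dict("records")
        run: list[dict] = []
        for i, row in enumerate(rows):
            if row["_unc"]:
                if run and max_gap_bp is not None and row["start"] - run[-1]["end"] > max_gap_bp:
                    _close_run(run, rows, chrom, candidates, min_consecutive, min_flank_covered)
                    run = []
                run.append(row)
            elif run:
                _close_run(run, rows, chrom, candidates, min_consecutive, min_flank_covered)
                run = []
        if run:
            _close_run(run, rows, chrom, candidates, min_consecutive, min_flank_covered)
    return candidates


def _close_run(
    run: list[dict],
    rows: list[dict],
    chrom: str,
    out: list[CandidateDeletion],
    min_consecutive: int,
    min_flank_covered: bool,
) -> None:
    if len(run) < min_consecutive:
        return
    if min_flank_covered:
        orders = [r["order"] for r in rows]
        first_i = orders.index(run[0]["order"])
        last_i = orders.index(run[-1]["order"])
        left_ok = first_i > 0 and not rows[first_i - 1]["_unc"]
        right_ok = last_i < len(rows) - 1 and not rows[last_i + 1]["_unc"]
        if not (left_ok and right_ok):
            return
    out.append(
        CandidateDeletion(
            chrom=chrom,
            span_start=int(run[0]["start"]),
            span_end=int(run[-1]["end"]),
            n_targets=len(run),
            target_ids=[r["region_id"] for r in run],
        )
    )


def candidates_to_frame(candidates: list[CandidateDeletion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "span_start": c.span_start,
                "span_end": c.span_end,
                "span_bp": c.span_bp,
                "n_targets": c.n_targets,
                "target_ids": ",".join(c.target_ids),
            }
            for c in candidates
        ],
        columns=["chrom", "span_start", "span_end", "span_bp", "n_targets", "target_ids"],
    )
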