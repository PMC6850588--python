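"""Cross-assembly translation of capture-target coordinates.

Targets defined on an old assembly are located on a new one from a
precomputed tabular alignment-hit table (12-column BLAST-like format):
the highest-identity hit under an e-value threshold is assigned to each
query, and a synteny pass then re-examines assignments that break the
collinear order of their source-assembly neighbors, re-assigning them to
a concordant alternative hit when one exists or flagging them as
putative translocations otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass
class Assignment:
    query_id: str
    chrom: str | None
    start: int | None  # 0-based half-open on the new assembly
    end: int | None
    identity: float | None
    status: str  # unique | synteny_adjusted | translocation_flagged | unplaced

    @property
    def placed(self) -> bool:
        return self.chrom is not None


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular alignment hit table."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=HIT_COLUMNS)
    # subject coordinates may be reversed for minus-orientation hits
    lo = df[["sstart", "send"]].min(axis=1) - 1
    hi = df[["sstart", "send"]].max(axis=1)
    df["slo"], df["shi"] = lo, hi
    return df


def best_hit_assign(
    hits: pd.DataFrame,
    evalue_max: float = 1e-10,
    queries: list[str] | None = None,
) -> dict[str, Assignment]:
    """Assign every query its maximum-identity significant hit.

    Hits above the e-value threshold are discarded; identity ties break
    on higher bitscore, then leftmost subject coordinate.  Queries with
    no surviving hit are unplaced.
    """
    if "slo" not in hits.columns:
        hits = hits.copy()
        hits["slo"] = hits[["sstart", "send"]].min(axis=1) - 1
        hits["shi"] = hits[["sstart", "send"]].max(axis=1)
    sig = hits[hits["evalue"] <= evalue_max]
    assignments: dict[str, Assignment] = {}
    for qid, sub in sig.groupby("qseqid", sort=False):
        sub = sub.sort_values(
            ["pident", "bitscore", "slo"], ascending=[False, False, True], kind="mergesort"
        )
        top = sub.iloc[0]
        assignments[str(qid)] = Assignment(
            query_id=str(qid),
            chrom=str(top["sseqid"]),
            start=int(top["slo"]),
            end=int(top["shi"]),
            identity=float(top["pident"]),
            status="unique",
        )
    for qid in queries if queries is not None else hits["qseqid"].astype(str).unique():
        if str(qid) not in assignments:
            assignments[str(qid)] = Assignment(str(qid), None, None, None, None, "unplaced")
    return assignments


def synteny_refine(
    assignments: dict[str, Assignment],
    hits: pd.DataFrame,
    source_order: dict[str, list[str]],
    window: int = 5,
    evalue_max: float = 1e-10,
    min_neighbors: int = 2,
) -> dict[str, Assignment]:
    """Re-examine assignments that break source-assembly collinearity.

    ``source_order`` maps each source chromosome to its query ids in
    source coordinate order.  For each placed query still in status
    ``unique``, the majority chromosome of up to ``window`` placed
    neighbors each side is computed; a query assigned elsewhere — or far
    outside the interval interpolated between its nearest concordant
    neighbors — is re-searched among its remaining significant hits for
    the highest-identity hit inside that interval (status
    ``synteny_adjusted``) and otherwise keeps its original locus with
    status ``translocation_flagged``.  Already-adjusted or flagged
    entries pass through untouched, so the operation is idempotent.
    """
    if "slo" not in hits.columns:
        hits = read_hits_frame(hits)
    sig = hits[hits["evalue"] <= evalue_max]
    refined = {qid: replace(a) for qid, a in assignments.items()}

    for _, order in source_order.items():
        placed = [qid for qid in order if qid in refined and refined[qid].placed]
        for i, qid in enumerate(placed):
            a = refined[qid]
            if a.status != "unique":
                continue
            before = [refined[placed[j]] for j in range(max(0, i - window), i)]
            after = [refined[placed[j]] for j in range(i + 1, min(len(placed), i + window + 1))]
            neighbors = before + after
            if len(neighbors) < min_neighbors:
                continue
            majority_chrom, majority_n = Counter(n.chrom for n in neighbors).most_common(1)[0]
            if majority_n <= len(neighbors) / 2:
                continue  # no clear majority: leave as-is
            concordant = _neighbor_interval(before, after, majority_chrom, a)
            if a.chrom == majority_chrom and (
                concordant is None or concordant[0] <= a.start <= concordant[1]
            ):
                continue
            # discordant: look for an alternative significant hit in the interval
            alt = sig[(sig["qseqid"].astype(str) == qid) & (sig["sseqid"].astype(str) == majority_chrom)]
            if concordant is not None:
                alt = alt[(alt["slo"] >= concordant[0]) & (alt["shi"] <= concordant[1])]
            if len(alt):
                alt = alt.sort_values(["pident", "bitscore", "slo"], ascending=[False, False, True])
                top = alt.iloc[0]
                refined[qid] = Assignment(
                    qid,
                    str(top["sseqid"]),
                    int(top["slo"]),
                    int(top["shi"]),
                    float(top["pident"]),
                    "synteny_adjusted",
                )
            else:
                refined[qid] = replace(a, status="translocation_flagged")
    return refined


def _neighbor_interval(
    before: list[Assignment], after: list[Assignment], majority_chrom: str, a: Assignment
) -> tuple[int, int] | None:
    """Positional interval interpolated between flanking concordant neighbors.

    The interval spans the loci of the majority-chromosome neighbors,
    padded by one query length each side.  It is only defined when the
    query has at least one such neighbor on each side in source order;
    edge queries are checked on chromosome agreement alone.
    """
    b = [n for n in before if n.chrom == majority_chrom]
    f = [n for n in after if n.chrom == majority_chrom]
    if not b or not f:
        return None
    on_chrom = b + f
    lo = min(n.start for n in on_chrom)
    hi = max(n.end for n in on_chrom)
    qlen = (a.end - a.start) if a.placed else max(n.end - n.start for n in on_chrom)
    return lo - qlen, hi + qlen


def read_hits_frame(hits: pd.DataFrame) -> pd.DataFrame:
    hits = hits.copy()
    hits["slo"] = hits[["sstart", "send"]].min(axis=1) - 1
    hits["shi"] = hits[["sstart", "send"]].max(axis=1)
    return hits


def write_translated_targets(
    assignments: dict[str, Assignment], bed_path: str | Path, tsv_path: str | Path
) -> pd.DataFrame:
    """Emit a BED of placed loci and a TSV ledger of per-status counts."""
    placed = sorted(
        (a for a in assignments.values() if a.placed), key=lambda a: (a.chrom, a.start)
    )
    with open(bed_path, "w") as fh:
        for a in placed:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.query_id}\t{a.status}\n")
    ledger = Counter(a.status for a in assignments.values())
    df = pd.DataFrame(
        [{"status": k, "n_queries": v} for k, v in sorted(ledger.items())]
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    return df
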