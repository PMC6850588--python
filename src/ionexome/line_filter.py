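"""Extraction of line-specific induced mutations from a cohort's raw call sets.

A mutagenized cohort shares a large background of intracultivar variants
(differences between the lab stock and the reference genome) that appear
in every line, while true induced mutations are private to a single
line.  The filter removes any variant observed in two or more lines,
applies per-record read-support filters, and unions the survivors across
callers with deduplication, producing a per-line/per-caller ledger of
raw, common and filtered counts.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CallSet,
    Caller,
    ReferenceGenome,
    TargetSet,
    VariantRecord,
    normalize_variant,
    variant_key,
)


@dataclass
class FilterConfig:
    """Thresholds for the intracultivar / read-support filters.

    ``min_support_reads`` counts variant-supporting reads (not total
    depth) unless ``support_mode="total_depth"``.  ``pooled_het_mode``
    replaces the reference-read-fraction test — which every pooled
    heterozygous sample would fail — with a minimum alt-allele-fraction
    test.
    """

    share_min_lines: int = 2
    min_support_reads: int = 10
    max_ref_fraction: float = 0.05
    require_biallelic: bool = True
    min_cohort_size: int = 4
    pooled_het_mode: bool = False
    min_alt_fraction: float = 0.20  # used only in pooled_het_mode
    support_mode: str = "alt_reads"  # or "total_depth"
    outcross_fold: float = 10.0  # unique count > fold x cohort median flags a line

    def __post_init__(self) -> None:
        if self.share_min_lines < 2:
            raise ValueError("share_min_lines must be >= 2")
        if not 0 <= self.max_ref_fraction <= 1:
            raise ValueError("max_ref_fraction must be in [0, 1]")
        if self.support_mode not in ("alt_reads", "total_depth"):
            raise ValueError(f"unknown support_mode {self.support_mode!r}")


@dataclass
class FilterReport:
    """Table-style ledger of counts at each filtering stage.

    One row per (line, caller) with raw/common/filtered counts plus the
    per-line unique mutation count after cross-caller union and
    deduplication.
    """

    rows: list[dict] = field(default_factory=list)
    unique_counts: dict[str, int] = field(default_factory=dict)
    unknown_depth_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    outcross_flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["line_id", "caller", "raw_count", "common_count", "filtered_count"])
        df["unique_mutation_count"] = df["line_id"].map(self.unique_counts)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def find_shared_variants(cohort: list[CallSet], cfg: FilterConfig) -> set[tuple]:
    """Keys of variants present in >= ``share_min_lines`` distinct lines.

    Sharing is judged on normalized variant keys over the raw calls,
    before any record-level filter, mirroring a ledger whose "common"
    column is counted on raw output.
    """
    if not cohort:
        raise ValueError("empty cohort: sharing cannot be determined")
    n_lines = len({cs.line_id for cs in cohort})
    if n_lines < cfg.min_cohort_size:
        warnings.warn(
            f"cohort has {n_lines} lines (< {cfg.min_cohort_size}); "
            "intracultivar variant removal may be unreliable"
        )
    lines_per_key: dict[tuple, set[str]] = defaultdict(set)
    for cs in cohort:
        for v in cs:
            lines_per_key[variant_key(v)].add(cs.line_id)
    return {k for k, lines in lines_per_key.items() if len(lines) >= cfg.share_min_lines}


def _passes_record_filters(v: VariantRecord, cfg: FilterConfig) -> bool:
    if cfg.require_biallelic and v.n_alt_alleles > 1:
        return False
    if not v.depth_known:
        return False
    support = v.alt_reads if cfg.support_mode == "alt_reads" else v.alt_reads + v.ref_reads
    if support < cfg.min_support_reads:
        return False
    total = v.alt_reads + v.ref_reads
    if total > 0:
        if cfg.pooled_het_mode:
            if v.alt_reads / total < cfg.min_alt_fraction:
                return False
        elif v.ref_reads / total > cfg.max_ref_fraction:
            return False
    return True


def apply_record_filters(cs: CallSet, cfg: FilterConfig) -> tuple[CallSet, int]:
    """Read-support / allele-count filters on one call set.

    Returns the filtered call set and the number of records dropped
    solely because their depths were unknown.
    """
    kept: list[VariantRecord] = []
    n_unknown = 0
    for v in cs:
        if not v.depth_known:
            n_unknown += 1
            continue
        if _passes_record_filters(v, cfg):
            kept.append(v)
    return CallSet(cs.line_id, kept), n_unknown


def intersect_targets(cs: CallSet, targets: TargetSet) -> CallSet:
    """Keep records whose affected interval overlaps >= 1 bp of a target."""
    kept = []
    for v in cs:
        start, end = v.interval()
        if targets.tree(v.chrom).overlap(start, end):
            kept.append(v)
    return CallSet(cs.line_id, kept)


def extract_line_specific(
    cohort: list[CallSet],
    cfg: FilterConfig | None = None,
    reference: ReferenceGenome | None = None,
    targets: TargetSet | None = None,
) -> tuple[dict[str, CallSet], FilterReport]:
    """Run the full filtering pipeline on a cohort.

    The cohort is a list of call sets, possibly several per line (one
    per caller).  Steps, per line and caller: normalize; remove variants
    shared between ``share_min_lines`` or more lines; apply record
    filters; then union the callers with key deduplication.  When
    ``targets`` is given the deduplicated records are finally
    intersected with the capture targets.

    Returns ``(per-line CallSet, FilterReport)``.  Lines whose unique
    count exceeds ``cfg.outcross_fold`` times the cohort median are
    flagged as possible outcross/contamination in the report.
    """
    cfg = cfg or FilterConfig()
    normalized = [
        CallSet(cs.line_id, [normalize_variant(v, reference) for v in cs]) for cs in cohort
    ]
    shared = find_shared_variants(normalized, cfg)

    report = FilterReport()
    per_line_filtered: dict[str, dict[Caller, CallSet]] = defaultdict(dict)
    for cs in normalized:
        caller = cs.records[0].caller if cs.records else Caller.SNV_CALLER
        raw = len(cs)
        common = sum(1 for v in cs if variant_key(v) in shared)
        line_specific = CallSet(cs.line_id, [v for v in cs if variant_key(v) not in shared])
        filtered, n_unknown = apply_record_filters(line_specific, cfg)
        report.rows.append(
            {
                "line_id": cs.line_id,
                "caller": caller.value,
                "raw_count": raw,
                "common_count": common,
                "filtered_count": len(filtered),
            }
        )
        report.unknown_depth_counts[(cs.line_id, caller.value)] = n_unknown
        if caller in per_line_filtered[cs.line_id]:
            prev = per_line_filtered[cs.line_id][caller]
            per_line_filtered[cs.line_id][caller] = CallSet(cs.line_id, prev.records + filtered.records)
        else:
            per_line_filtered[cs.line_id][caller] = filtered

    result: dict[str, CallSet] = {}
    for line_id, by_caller in per_line_filtered.items():
        seen: dict[tuple, VariantRecord] = {}
        for caller in (Caller.SNV_CALLER, Caller.SV_CALLER):
            for v in by_caller.get(caller, CallSet(line_id)):
                seen.setdefault(variant_key(v), v)
        merged = CallSet(line_id, list(seen.values()))
        if targets is not None:
            merged = intersect_targets(merged, targets)
        result[line_id] = merged
        report.unique_counts[line_id] = len(merged)

    counts = np.array(sorted(report.unique_counts.values()))
    if len(counts) >= 2:
        median = float(np.median(counts))
        threshold = cfg.outcross_fold * max(median, 1.0)
        report.outcross_flags = sorted(
            line for line, n in report.unique_counts.items() if n > threshold
        )
    return result, report
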