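"""Domain types and call-set ingestion shared by every pipeline stage.

Variants from an SNV/indel caller (VCF 4.x) and from a structural-variant
caller (tab-delimited event records) are normalized into a single
:class:`VariantRecord` representation so that cross-line sharing and
cross-caller deduplication are well defined.

Coordinate convention: all internal coordinates are 0-based half-open.
VCF positions are converted on read/write; BED intervals are consumed
natively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from intervaltree import IntervalTree


class Caller(str, Enum):
    """Provenance of a variant call."""

    SNV_CALLER = "snv_caller"
    SV_CALLER = "sv_caller"


class VarClass(str, Enum):
    SNV = "SNV"
    DEL = "DEL"
    INS = "INS"
    RPL = "RPL"  # replacement: deletion + insertion at one locus
    INV = "INV"
    TD = "TD"  # tandem duplication


class VcfParseError(ValueError):
    """Raised when a VCF body line cannot be parsed."""


class NormalizationError(ValueError):
    """Raised when a record contradicts the supplied reference sequence."""


@dataclass
class VariantRecord:
    """One variant call for one line.

    ``pos`` is the 0-based position of the first affected base (for an
    insertion: the base before which sequence is inserted, once
    normalized).  ``ref_allele``/``alt_allele`` are stored verbatim as
    read; :func:`normalize_variant` trims them to a minimal
    representation in which one of the two may be empty.
    """

    line_id: str
    caller: Caller
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    var_class: VarClass
    size_bp: int
    alt_reads: int | None = None
    ref_reads: int | None = None
    n_alt_alleles: int = 1

    @property
    def pos_1based(self) -> int:
        return self.pos + 1

    @property
    def depth_known(self) -> bool:
        return self.alt_reads is not None and self.ref_reads is not None

    def interval(self) -> tuple[int, int]:
        """Affected genomic interval, 0-based half-open.

        SNV: the single base; DEL/RPL/INV/TD: the affected span;
        INS: the 2-bp window around the insertion point.
        """
        if self.var_class is VarClass.SNV:
            return self.pos, self.pos + 1
        if self.var_class is VarClass.INS:
            return max(self.pos - 1, 0), self.pos + 1
        span = max(self.size_bp, len(self.ref_allele), 1)
        return self.pos, self.pos + span


def classify_alleles(ref: str, alt: str) -> tuple[VarClass, int]:
    """Infer variant class and size from a REF/ALT allele pair.

    Works on both anchored (VCF-style) and trimmed alleles by virtually
    trimming the common prefix/suffix first.
    """
    r, a = ref.upper(), alt.upper()
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    while r and a and r[0] == a[0]:
        r, a = r[1:], a[1:]
    if len(r) == 1 and len(a) == 1:
        return VarClass.SNV, 0
    if not a:
        return VarClass.DEL, len(r)
    if not r:
        return VarClass.INS, len(a)
    return VarClass.RPL, len(r)


@dataclass
class CallSet:
    """All records for one line from one or more callers, sorted."""

    line_id: str
    records: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sort()

    def sort(self) -> None:
        self.records.sort(key=lambda v: (v.chrom, v.pos, v.ref_allele, v.alt_allele))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)


@dataclass(frozen=True)
class TargetRegion:
    """One capture interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    region_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region {self.region_id}: {self.start} >= {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class TargetSet:
    """Merged, sorted capture intervals: the universe for counting."""

    def __init__(self, regions: Iterable[TargetRegion], merge: bool = True):
        regs = sorted(regions, key=lambda r: (r.chrom, r.start))
        self.regions: list[TargetRegion] = _merge_regions(regs) if merge else regs
        self._trees: dict[str, IntervalTree] = {}

    @classmethod
    def from_bed(cls, path: str | Path, merge: bool = True) -> "TargetSet":
        regions = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}: BED line {i + 1} has fewer than 3 columns")
                name = fields[3] if len(fields) > 3 else f"{fields[0]}:{fields[1]}-{fields[2]}"
                regions.append(TargetRegion(fields[0], int(fields[1]), int(fields[2]), name))
        return cls(regions, merge=merge)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")

    @property
    def total_bases(self) -> int:
        return sum(r.length for r in self.regions)

    def tree(self, chrom: str) -> IntervalTree:
        if chrom not in self._trees:
            tree = IntervalTree()
            for r in self.regions:
                if r.chrom == chrom:
                    tree.addi(r.start, r.end, r)
            self._trees[chrom] = tree
        return self._trees[chrom]

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.chrom, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[TargetRegion]:
        return iter(self.regions)


def _merge_regions(sorted_regions: list[TargetRegion]) -> list[TargetRegion]:
    merged: list[TargetRegion] = []
    for r in sorted_regions:
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            prev = merged[-1]
            if r.end > prev.end:
                rid = prev.region_id if prev.region_id == r.region_id else f"{prev.region_id}|{r.region_id}"
                merged[-1] = TargetRegion(prev.chrom, prev.start, r.end, rid)
        else:
            merged.append(r)
    return merged


class ReferenceGenome:
    """Uniform sequence access over a FASTA file or an in-memory dict."""

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = {k: v.upper() for k, v in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def seq(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start:end]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs


# ---------------------------------------------------------------------------
# Normalization and equivalence keys
# ---------------------------------------------------------------------------

def normalize_variant(v: VariantRecord, reference: ReferenceGenome | None = None) -> VariantRecord:
    """Return a minimal, left-aligned copy of ``v``.

    The common allele prefix/suffix is trimmed (so a deletion becomes
    ``ref=deleted bases, alt=""`` and an insertion ``ref="", alt=inserted
    bases``) and, when a reference is supplied, indels are shifted to
    their leftmost equivalent position.  Idempotent.  Inversion/tandem
    duplication records, which carry no allele sequence, pass through
    with their span untouched.

    Raises :class:`NormalizationError` when the stored reference allele
    disagrees with the supplied reference sequence.
    """
    if v.var_class in (VarClass.INV, VarClass.TD):
        return replace(v)

    ref, alt, pos = v.ref_allele.upper(), v.alt_allele.upper(), v.pos

    if reference is not None and ref:
        actual = reference.seq(v.chrom, pos, pos + len(ref))
        if actual != ref:
            raise NormalizationError(
                f"{v.line_id} {v.chrom}:{v.pos_1based} REF={v.ref_allele}: reference has {actual!r}"
            )

    # An SV-caller deletion/replacement may carry only a span; fill the
    # deleted allele so the equivalence key can match the same event
    # from the SNV caller.  Without a reference the record cannot be
    # normalized further and passes through unchanged.
    if not ref and v.var_class in (VarClass.DEL, VarClass.RPL):
        if reference is None:
            return replace(v)
        ref = reference.seq(v.chrom, pos, pos + v.size_bp)

    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1

    if reference is not None:
        if not alt and ref:  # deletion: shift left while preceding base equals last deleted base
            while pos > 0 and reference.seq(v.chrom, pos - 1, pos) == ref[-1]:
                ref = reference.seq(v.chrom, pos - 1, pos) + ref[:-1]
                pos -= 1
        elif not ref and alt:  # insertion
            while pos > 0 and reference.seq(v.chrom, pos - 1, pos) == alt[-1]:
                alt = reference.seq(v.chrom, pos - 1, pos) + alt[:-1]
                pos -= 1

    if len(ref) == 1 and len(alt) == 1:
        var_class, size = VarClass.SNV, 0
    elif not alt and ref:
        var_class, size = VarClass.DEL, len(ref)
    elif not ref and alt:
        var_class, size = VarClass.INS, len(alt)
    elif ref and alt:
        var_class, size = VarClass.RPL, len(ref)
    else:  # both empty: allele-free record of known class/size
        var_class, size = v.var_class, v.size_bp

    return replace(v, pos=pos, ref_allele=ref, alt_allele=alt, var_class=var_class, size_bp=size)


def variant_key(v: VariantRecord) -> tuple:
    """Equivalence key for sharing and deduplication.

    Equal keys ⇔ same normalized (chrom, pos, ref, alt, class);
    line and caller are deliberately excluded.  ``size_bp`` is part of
    the tuple so allele-free events (INV/TD) compare on their span.
    """
    return (v.chrom, v.pos, v.ref_allele.upper(), v.alt_allele.upper(), v.var_class.value, v.size_bp)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_MISSING_INT = -2147483648  # htslib missing-value sentinel


def read_vcf(path: str | Path, line_id: str) -> CallSet:
    """Read a single-sample VCF into a CallSet.

    Multi-allelic records are expanded to one :class:`VariantRecord` per
    alternate allele; each expanded record remembers ``n_alt_alleles``
    so the multi-allele filter can act later.  Allele depths are taken
    from the per-sample AD field; records without AD are retained with
    depths flagged unknown.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    idx = 0
    try:
        for variant in vcf:
            idx += 1
            ad = None
            try:
                ad = variant.format("AD")
            except KeyError:
                ad = None
            alts = variant.ALT or []
            for i, alt in enumerate(alts):
                ref_reads = alt_reads = None
                if ad is not None and ad.shape[1] > i + 1:
                    r, a = int(ad[0][0]), int(ad[0][i + 1])
                    if r != _MISSING_INT and a != _MISSING_INT and (r >= 0 and a >= 0):
                        ref_reads, alt_reads = r, a
                var_class, size = classify_alleles(variant.REF, alt)
                records.append(
                    VariantRecord(
                        line_id=line_id,
                        caller=Caller.SNV_CALLER,
                        chrom=variant.CHROM,
                        pos=variant.POS - 1,
                        ref_allele=variant.REF,
                        alt_allele=alt,
                        var_class=var_class,
                        size_bp=size,
                        alt_reads=alt_reads,
                        ref_reads=ref_reads,
                        n_alt_alleles=len(alts),
                    )
                )
    except Exception as exc:  # noqa: BLE001 - re-raise with locus context
        if isinstance(exc, VcfParseError):
            raise
        raise VcfParseError(f"{path}: malformed VCF near data record {idx + 1}: {exc}") from exc
    finally:
        vcf.close()
    return CallSet(line_id, records)


def write_vcf(
    cs: CallSet,
    path: str | Path,
    reference: ReferenceGenome | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a CallSet as single-sample VCF 4.2 with GT and AD.

    Records expanded from one multi-allelic locus (same chrom/pos/ref,
    matching ``n_alt_alleles``) are re-joined onto one line so that a
    read/write round trip preserves every field.  Normalized records
    with an empty allele are re-anchored on the preceding reference
    base, which requires ``reference``.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cs.line_id}")

    i, recs = 0, cs.records
    while i < len(recs):
        group = [recs[i]]
        v = recs[i]
        j = i + 1
        while (
            j < len(recs)
            and len(group) < v.n_alt_alleles
            and recs[j].chrom == v.chrom
            and recs[j].pos == v.pos
            and recs[j].ref_allele == v.ref_allele
            and recs[j].n_alt_alleles == v.n_alt_alleles
        ):
            group.append(recs[j])
            j += 1
        lines.append(_vcf_line(group, reference))
        i = j

    Path(path).write_text("\n".join(lines) + "\n")


def _vcf_line(group: list[VariantRecord], reference: ReferenceGenome | None) -> str:
    v = group[0]
    pos, ref = v.pos, v.ref_allele
    alts = [g.alt_allele for g in group]
    if not ref or any(not a for a in alts):
        if reference is None:
            raise ValueError(
                f"cannot write allele-free record at {v.chrom}:{v.pos_1based} without a reference"
            )
        anchor_pos = pos - 1 if pos > 0 else pos
        anchor = reference.seq(v.chrom, anchor_pos, anchor_pos + 1)
        if pos > 0:
            pos, ref = pos - 1, anchor + ref
            alts = [anchor + a for a in alts]
        else:  # anchor on the following base instead
            ref = ref + anchor
            alts = [a + anchor for a in alts]
    depths = [str(v.ref_reads) if v.ref_reads is not None else "."]
    depths += [str(g.alt_reads) if g.alt_reads is not None else "." for g in group]
    ad = ",".join(depths)
    gt = "0/1" if len(group) == 1 else "1/2"
    return f"{v.chrom}\t{pos + 1}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT:AD\t{gt}:{ad}"


_PINDEL_CLASS = {
    "D": VarClass.DEL,
    "I": VarClass.INS,
    "INV": VarClass.INV,
    "TD": VarClass.TD,
    "RPL": VarClass.RPL,
}


@dataclass
class ParseReport:
    """Tally of records skipped while reading an SV-caller file."""

    n_parsed: int = 0
    n_skipped: int = 0
    skipped_codes: dict[str, int] = field(default_factory=dict)


def read_pindel(path: str | Path, line_id: str, report: ParseReport | None = None) -> CallSet:
    """Read tab-delimited structural-variant event records.

    Expected columns: event code (D/I/INV/TD/RPL), chrom, 1-based start,
    1-based inclusive end, size in bp, inserted sequence (``.`` if
    none), supporting-read count.  For insertions, start == end == the
    base after which the sequence is inserted.  Unknown event codes are
    skipped with a warning counted in the parse report.
    """
    records: list[VariantRecord] = []
    report = report if report is not None else ParseReport()
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            code = fields[0]
            if code not in _PINDEL_CLASS:
                report.n_skipped += 1
                report.skipped_codes[code] = report.skipped_codes.get(code, 0) + 1
                warnings.warn(f"{path}: line {i + 1}: unknown event code {code!r}, skipped")
                continue
            var_class = _PINDEL_CLASS[code]
            chrom, start, end = fields[1], int(fields[2]), int(fields[3])
            size = int(fields[4])
            inserted = "" if fields[5] in (".", "") else fields[5].upper()
            supports = int(fields[6])
            if var_class is VarClass.INS:
                pos = start  # 0-based insertion point after 1-based base `start`
                ref_allele, alt_allele = "", inserted
            elif var_class is VarClass.RPL:
                pos = start - 1
                ref_allele, alt_allele = "", inserted  # deleted seq filled at normalization
            else:
                pos = start - 1
                ref_allele, alt_allele = "", ""
            records.append(
                VariantRecord(
                    line_id=line_id,
                    caller=Caller.SV_CALLER,
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref_allele,
                    alt_allele=alt_allele,
                    var_class=var_class,
                    size_bp=size,
                    alt_reads=supports,
                    ref_reads=0,
                    n_alt_alleles=1,
                )
            )
            report.n_parsed += 1
    return CallSet(line_id, records)


def write_pindel(cs: CallSet, path: str | Path) -> None:
    """Write SV-caller records in the tab-delimited dialect read_pindel expects."""
    inverse = {v: k for k, v in _PINDEL_CLASS.items()}
    with open(path, "w") as fh:
        fh.write("#type\tchrom\tstart\tend\tsize\tinserted\tsupports\n")
        for v in cs.records:
            code = inverse[v.var_class]
            if v.var_class is VarClass.INS:
                start = end = v.pos  # base after which insertion occurs, 1-based
            else:
                start, end = v.pos + 1, v.pos + max(v.size_bp, 1)
            inserted = v.alt_allele if v.alt_allele else "."
            supports = v.alt_reads if v.alt_reads is not None else 0
            fh.write(f"{code}\t{v.chrom}\t{start}\t{end}\t{v.size_bp}\t{inserted}\t{supports}\n")
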