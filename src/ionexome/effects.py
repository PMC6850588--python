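"""Predicted-consequence classification of mutations against gene models.

Each variant is assigned a fine-grained consequence (missense, nonsense,
frameshift, ...) against the representative transcript of every gene it
overlaps (within a configurable flank), and the worst consequence is
reported.  Fine consequences roll up into four reporting buckets:
coding-sequence changes, upstream/5'UTR, downstream/3'UTR, and
synonymous-or-intronic.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .core import ReferenceGenome, VarClass, VariantRecord


class Detail(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOP_LOSS = "stop_loss"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_DISRUPTING = "splice_disrupting"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    UTR5 = "utr5"
    UTR3 = "utr3"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    INTERGENIC = "intergenic"


class Bucket(str, Enum):
    CODING_CHANGE = "coding_change"
    UPSTREAM_5UTR = "upstream_5utr"
    DOWNSTREAM_3UTR = "downstream_3utr"
    SILENT_OR_INTRONIC = "silent_or_intronic"


# worst first; ties never occur because the order is total
SEVERITY_ORDER: list[Detail] = [
    Detail.NONSENSE,
    Detail.FRAMESHIFT,
    Detail.STOP_LOSS,
    Detail.SPLICE_DISRUPTING,
    Detail.MISSENSE,
    Detail.INFRAME_INDEL,
    Detail.UTR5,
    Detail.UTR3,
    Detail.UPSTREAM,
    Detail.DOWNSTREAM,
    Detail.SYNONYMOUS,
    Detail.INTRONIC,
    Detail.INTERGENIC,
]
_SEVERITY_RANK = {d: i for i, d in enumerate(SEVERITY_ORDER)}

DETAIL_TO_BUCKET: dict[Detail, Bucket] = {
    Detail.MISSENSE: Bucket.CODING_CHANGE,
    Detail.NONSENSE: Bucket.CODING_CHANGE,
    Detail.STOP_LOSS: Bucket.CODING_CHANGE,
    Detail.FRAMESHIFT: Bucket.CODING_CHANGE,
    Detail.INFRAME_INDEL: Bucket.CODING_CHANGE,
    Detail.SPLICE_DISRUPTING: Bucket.CODING_CHANGE,
    Detail.UTR5: Bucket.UPSTREAM_5UTR,
    Detail.UPSTREAM: Bucket.UPSTREAM_5UTR,
    Detail.UTR3: Bucket.DOWNSTREAM_3UTR,
    Detail.DOWNSTREAM: Bucket.DOWNSTREAM_3UTR,
    Detail.SYNONYMOUS: Bucket.SILENT_OR_INTRONIC,
    Detail.INTRONIC: Bucket.SILENT_OR_INTRONIC,
    Detail.INTERGENIC: Bucket.SILENT_OR_INTRONIC,
}


@dataclass(frozen=True)
class EffectCall:
    bucket: Bucket
    detail: Detail
    gene_id: str | None = None


@dataclass
class GeneModel:
    """Representative transcript of one gene.

    Intervals are 0-based half-open in genomic coordinates, sorted by
    start regardless of strand.  ``phases[i]`` is the GFF3 phase of
    ``cds[i]``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    phases: list[int] = field(default_factory=list)
    cds_incomplete: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        order = sorted(range(len(self.cds)), key=lambda i: self.cds[i][0])
        self.cds = [self.cds[i] for i in order]
        if self.phases:
            self.phases = [self.phases[i] for i in order]
        else:
            self.phases = [0] * len(self.cds)
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"{self.gene_id}: CDS [{cs},{ce}) not contained in any exon")
        if sum(e - s for s, e in self.cds) % 3 != 0:
            self.cds_incomplete = True

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    def utr_intervals(self) -> list[tuple[int, int, str]]:
        """Exonic non-CDS intervals tagged 'utr5'/'utr3' in transcript orientation."""
        if not self.cds:
            return []
        cds_min, cds_max = self.cds[0][0], self.cds[-1][1]
        out = []
        for es, ee in self.exons:
            pieces = [(es, ee)]
            for cs, ce in self.cds:
                nxt = []
                for ps, pe in pieces:
                    if ce <= ps or cs >= pe:
                        nxt.append((ps, pe))
                        continue
                    if ps < cs:
                        nxt.append((ps, cs))
                    if ce < pe:
                        nxt.append((ce, pe))
                pieces = nxt
            for ps, pe in pieces:
                if pe <= cds_min:
                    side = "utr5" if self.strand == "+" else "utr3"
                elif ps >= cds_max:
                    side = "utr3" if self.strand == "+" else "utr5"
                else:  # exonic non-CDS strictly between CDS segments: treat as intronic-like
                    continue
                out.append((ps, pe, side))
        return out

    def coding_offset(self, genomic_pos: int) -> int | None:
        """Offset of a genomic base in the concatenated CDS (transcript orientation)."""
        segs = self.cds if self.strand == "+" else list(reversed(self.cds))
        off = 0
        for s, e in segs:
            if s <= genomic_pos < e:
                return off + (genomic_pos - s if self.strand == "+" else e - 1 - genomic_pos)
            off += e - s
        return None

    def coding_sequence(self, reference: ReferenceGenome) -> str:
        seq = "".join(reference.seq(self.chrom, s, e) for s, e in self.cds)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def first_phase(self) -> int:
        if not self.phases:
            return 0
        return self.phases[0] if self.strand == "+" else self.phases[-1]


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into one GeneModel per gene.

    The first mRNA (by ID) of each gene is taken as the representative
    transcript.  Orphan CDS features — CDS without a resolvable parent —
    raise an error naming the feature.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    attached_cds: set[str] = set()
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = sorted(db.children(gene, featuretype="mRNA"), key=lambda f: f.id)
        parent = mrnas[0] if mrnas else gene
        exons = [(f.start - 1, f.end) for f in db.children(parent, featuretype="exon")]
        cds_feats = list(db.children(parent, featuretype="CDS"))
        for f in cds_feats:
            attached_cds.add(f.id)
        cds = [(f.start - 1, f.end) for f in cds_feats]
        phases = [int(f.frame) if f.frame not in (".", None) else 0 for f in cds_feats]
        if not exons:
            exons = list(cds)
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
                phases=phases,
            )
        )
    for f in db.features_of_type("CDS"):
        if f.id not in attached_cds and not f.attributes.get("Parent"):
            raise ValueError(f"orphan CDS feature {f.id} at {f.seqid}:{f.start}-{f.end}")
    return models


class GeneIndex:
    """Interval lookup over gene spans (padded by the flank window)."""

    def __init__(self, models: list[GeneModel], flank_bp: int = 5000):
        self.models = models
        self.flank_bp = flank_bp
        self._trees: dict[str, IntervalTree] = {}
        for g in models:
            t = self._trees.setdefault(g.chrom, IntervalTree())
            s, e = g.span
            t.addi(max(0, s - flank_bp), e + flank_bp, g)

    def nearby(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _snv_coding_detail(v: VariantRecord, g: GeneModel, reference: ReferenceGenome) -> Detail:
    off = g.coding_offset(v.pos)
    if off is None:
        return Detail.MISSENSE  # SNV at CDS edge after span overlap: conservative
    coding = g.coding_sequence(reference)
    phase0 = g.first_phase()
    idx = off - phase0
    if idx < 0:
        return Detail.MISSENSE
    trimmed = coding[phase0:]
    codon_i, within = divmod(idx, 3)
    codon = trimmed[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return Detail.MISSENSE
    alt = v.alt_allele.upper()
    if g.strand == "-":
        alt = str(Seq(alt).complement())
    mutated = codon[:within] + alt + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutated).translate())
    if ref_aa == alt_aa:
        return Detail.SYNONYMOUS
    if alt_aa == "*":
        return Detail.NONSENSE
    if ref_aa == "*":
        return Detail.STOP_LOSS
    return Detail.MISSENSE


def _gene_detail(
    v: VariantRecord, g: GeneModel, reference: ReferenceGenome | None, flank_bp: int
) -> Detail | None:
    iv = v.interval()
    candidates: list[Detail] = []

    if any(_overlaps(iv, c) for c in g.cds):
        if v.var_class is VarClass.SNV:
            if reference is None:
                raise ValueError("reference sequence required to evaluate coding SNVs")
            candidates.append(_snv_coding_detail(v, g, reference))
        else:
            if v.var_class is VarClass.DEL or v.var_class is VarClass.INS:
                net = v.size_bp
            elif v.var_class is VarClass.RPL:
                net = abs(len(v.ref_allele) - len(v.alt_allele)) if v.ref_allele else v.size_bp
            elif v.var_class is VarClass.TD:
                net = v.size_bp
            else:  # inversion: length preserved
                net = 0
            candidates.append(Detail.FRAMESHIFT if net % 3 != 0 else Detail.INFRAME_INDEL)

    for intron_s, intron_e in g.introns():
        if _overlaps(iv, (intron_s, min(intron_s + 2, intron_e))) or _overlaps(
            iv, (max(intron_e - 2, intron_s), intron_e)
        ):
            candidates.append(Detail.SPLICE_DISRUPTING)
            break

    for us, ue, side in g.utr_intervals():
        if _overlaps(iv, (us, ue)):
            candidates.append(Detail.UTR5 if side == "utr5" else Detail.UTR3)

    if not candidates:
        span = g.span
        if _overlaps(iv, span):
            candidates.append(Detail.INTRONIC)
        elif _overlaps(iv, (max(0, span[0] - flank_bp), span[0])):
            candidates.append(Detail.UPSTREAM if g.strand == "+" else Detail.DOWNSTREAM)
        elif _overlaps(iv, (span[1], span[1] + flank_bp)):
            candidates.append(Detail.DOWNSTREAM if g.strand == "+" else Detail.UPSTREAM)

    if not candidates:
        return None
    return min(candidates, key=lambda d: _SEVERITY_RANK[d])


def classify_effect(
    v: VariantRecord,
    models: GeneIndex | list[GeneModel],
    reference: ReferenceGenome | None = None,
    flank_bp: int = 5000,
) -> EffectCall:
    """Worst predicted consequence of ``v`` across overlapping genes.

    Variants on chromosomes absent from the gene models classify as
    intergenic with a warning.
    """
    index = models if isinstance(models, GeneIndex) else GeneIndex(models, flank_bp)
    iv = v.interval()
    if v.chrom not in index._trees:
        warnings.warn(f"chromosome {v.chrom} absent from gene models; classified intergenic")
        return EffectCall(Bucket.SILENT_OR_INTRONIC, Detail.INTERGENIC)
    best: tuple[int, Detail, str | None] | None = None
    for g in index.nearby(v.chrom, iv[0], iv[1]):
        detail = _gene_detail(v, g, reference, index.flank_bp)
        if detail is None:
            continue
        rank = _SEVERITY_RANK[detail]
        if best is None or rank < best[0]:
            best = (rank, detail, g.gene_id)
    if best is None:
        return EffectCall(Bucket.SILENT_OR_INTRONIC, Detail.INTERGENIC)
    return EffectCall(DETAIL_TO_BUCKET[best[1]], best[1], best[2])


def summarize_effects(calls: list[EffectCall], separate_intergenic: bool = False) -> dict:
    """Bucket counts and fractions over a collection of effect calls.

    With ``separate_intergenic`` the intergenic detail is reported as
    its own category rather than folded into silent_or_intronic.
    """
    bucket_counts: Counter = Counter()
    detail_counts: Counter = Counter()
    for c in calls:
        detail_counts[c.detail.value] += 1
        if separate_intergenic and c.detail is Detail.INTERGENIC:
            bucket_counts["intergenic"] += 1
        else:
            bucket_counts[c.bucket.value] += 1
    total = sum(bucket_counts.values())
    fractions = (
        {k: v / total for k, v in bucket_counts.items()} if total else None
    )
    return {
        "n": total,
        "bucket_counts": dict(bucket_counts),
        "bucket_fractions": fractions,
        "detail_counts": dict(detail_counts),
    }
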