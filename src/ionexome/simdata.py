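"""Fully synthetic mutagenized-cohort generation.

Emits everything the rest of the pipeline consumes — a random genome
(FASTA), gene models (GFF3), capture targets (BED), per-line call files
(VCF for the SNV/indel caller, tab-delimited events for the SV caller),
read-depth tracks (bedGraph) and a ground-truth table — so every stage
is testable at desk scale without downloads.

The generator emulates an M2 cohort in which every line shares a large
background of intracultivar variants while each line additionally
carries a small number of private induced mutations drawn from the
heavy-ion mutation spectrum: class proportions dominated by SNVs and
deletions, mostly 1–10 bp indels, a transition/transversion split close
to 47:53, and a moderate GC preference at mutated sites.  Variants are
emitted directly as call files rather than as simulated reads; read
simulation and alignment are out of scope, which keeps tests
seconds-fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CallSet,
    Caller,
    ReferenceGenome,
    TargetRegion,
    TargetSet,
    VarClass,
    VariantRecord,
    normalize_variant,
    variant_key,
    write_pindel,
    write_vcf,
)
from .coverage import DepthTrack
from .effects import GeneIndex, GeneModel, classify_effect

# Default per-line mean in-target mutation counts by irradiation condition:
# (seed state, dose in Gy) -> (mean count, LET in keV/um).
DOSE_MEAN_DEFAULTS: dict[tuple[str, float], tuple[float, float]] = {
    ("dry", 75.0): (2.80, 30.0),
    ("dry", 100.0): (4.44, 30.0),
    ("dry", 150.0): (9.06, 30.0),
    ("dry", 175.0): (10.33, 30.0),
    ("dry", 200.0): (11.75, 30.0),
    ("imbibed", 15.0): (2.75, 50.0),
}

CLASS_PROB_DEFAULTS: dict[VarClass, float] = {
    VarClass.SNV: 0.575,
    VarClass.DEL: 0.373,
    VarClass.INS: 0.036,
    VarClass.RPL: 0.013,
    VarClass.INV: 0.003,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the optimum dry-seed condition: 150 Gy carbon
    ions at 30 keV/um, per-line counts scattered around 9.06 with the
    spread of the observed per-line distribution (sigma 4.37), a shared
    intracultivar background of ~1300 variants per caller pair, and a
    mean on-target read depth of 80.
    """

    rng_seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 300_000
    n_genes: int = 60
    target_flank_bp: int = 50
    n_lines: int = 12
    dose_gy: float = 150.0
    seed_state: str = "dry"
    let_kev_um: float = 30.0
    mean_count: float = 9.06
    count_sigma: float = 4.37
    count_model: str = "normal"  # or "poisson"
    class_probs: dict[VarClass, float] = field(default_factory=lambda: dict(CLASS_PROB_DEFAULTS))
    gc_enrichment: float = 1.60
    ti_fraction: float = 271 / 573
    n_shared_background: int = 1300
    shared_snv_fraction: float = 0.8  # remainder of the background are small deletions
    mean_depth: int = 80
    het_mode: bool = False  # pooled M2 samples: ~50% alt-allele fraction
    genome_gc: float = 0.44

    def __post_init__(self) -> None:
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities sum to {total}, not 1")
        if self.count_model not in ("normal", "poisson"):
            raise ValueError(f"unknown count model {self.count_model!r}")


@dataclass
class TruthTable:
    """Ground truth for every injected variant."""

    frame: pd.DataFrame

    def shared_keys(self) -> set[tuple]:
        sub = self.frame[self.frame["line_id"] == "shared"]
        return set(sub["key"])

    def line_specific_keys(self) -> dict[str, set[tuple]]:
        sub = self.frame[self.frame["line_id"] != "shared"]
        return {str(line): set(g["key"]) for line, g in sub.groupby("line_id")}

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["key"] = out["key"].map(lambda k: "|".join(str(x) for x in k))
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome / gene model / target construction
# ---------------------------------------------------------------------------

def make_genome_and_targets(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ReferenceGenome, list[GeneModel], TargetSet]:
    """Random genome with non-overlapping multi-exon genes and merged targets.

    Genes are laid out in evenly spaced slots along each chromosome;
    each has 1-4 exons, a CDS whose total length is divisible by 3
    (phases propagated per exon) and short terminal UTRs.  Capture
    targets are the exons padded by ``target_flank_bp`` and merged.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    p_gc = cfg.genome_gc / 2
    p_at = (1 - cfg.genome_gc) / 2
    seqs: dict[str, str] = {}
    for c in range(cfg.n_chroms):
        name = f"chr{c + 1:02d}"
        arr = rng.choice(list("ACGT"), size=cfg.chrom_length_bp, p=[p_at, p_gc, p_gc, p_at])
        seqs[name] = "".join(arr)
    genome = ReferenceGenome(seqs)

    genes_per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    slot = cfg.chrom_length_bp // (genes_per_chrom + 1)
    models: list[GeneModel] = []
    regions: list[TargetRegion] = []
    gi = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1:02d}"
        for s in range(genes_per_chrom):
            if gi >= cfg.n_genes:
                break
            gi += 1
            gene_id = f"gene{gi:04d}"
            start = (s + 1) * slot
            n_exons = int(rng.integers(1, 5))
            cds_lens = rng.integers(90, 301, size=n_exons)
            # make total CDS length divisible by 3
            rem = int(cds_lens.sum()) % 3
            cds_lens[0] += (3 - rem) % 3
            intron_lens = rng.integers(80, 301, size=max(n_exons - 1, 0))
            utr5, utr3 = int(rng.integers(20, 61)), int(rng.integers(20, 61))
            strand = "+" if rng.random() < 0.5 else "-"

            exons: list[tuple[int, int]] = []
            cds: list[tuple[int, int]] = []
            pos = start
            for i in range(n_exons):
                ex_start = pos
                c_start = ex_start + (utr5 if i == 0 else 0)
                c_end = c_start + int(cds_lens[i])
                ex_end = c_end + (utr3 if i == n_exons - 1 else 0)
                exons.append((ex_start, ex_end))
                cds.append((c_start, c_end))
                pos = ex_end + (int(intron_lens[i]) if i < n_exons - 1 else 0)
            # the gene (plus target flanks) must stay inside its slot
            if pos + 2 * cfg.target_flank_bp >= start + slot or pos >= cfg.chrom_length_bp:
                raise ValueError(
                    f"overlapping gene placement: {cfg.n_genes} genes do not fit on "
                    f"{cfg.n_chroms} chromosome(s) of {cfg.chrom_length_bp} bp"
                )
            # GFF3 phases in genomic order
            phases = _phases_for(cds, strand)
            models.append(
                GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons, cds=cds, phases=phases)
            )
            for j, (es, ee) in enumerate(exons):
                regions.append(
                    TargetRegion(
                        chrom,
                        max(0, es - cfg.target_flank_bp),
                        ee + cfg.target_flank_bp,
                        f"{gene_id}_ex{j + 1}",
                    )
                )
    if gi < cfg.n_genes:
        raise ValueError(
            f"could not place {cfg.n_genes} genes on {cfg.n_chroms} chromosome(s) "
            f"of {cfg.chrom_length_bp} bp"
        )
    return genome, models, TargetSet(regions)


def _phases_for(cds: list[tuple[int, int]], strand: str) -> list[int]:
    order = cds if strand == "+" else list(reversed(cds))
    phases_t = []
    cum = 0
    for s, e in order:
        phases_t.append((3 - cum % 3) % 3)
        cum += e - s
    return phases_t if strand == "+" else list(reversed(phases_t))


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chroms():
            fh.write(f">{chrom}\n")
            seq = genome.seq(chrom, 0, genome.length(chrom))
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            s, e = g.span
            fh.write(
                f"{g.chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i + 1};Parent={mrna_id}\n"
                )
            for i, (cs, ce) in enumerate(g.cds):
                fh.write(
                    f"{g.chrom}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t{g.phases[i]}\t"
                    f"ID={mrna_id}.cds{i + 1};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# Variant injection
# ---------------------------------------------------------------------------

class _Placer:
    """Tracks occupied loci so injected variants never collide."""

    def __init__(self, margin: int = 12):
        self.margin = margin
        self.occupied: dict[str, list[tuple[int, int]]] = {}
        self.keys: set[tuple] = set()

    def free(self, chrom: str, start: int, end: int) -> bool:
        for s, e in self.occupied.get(chrom, []):
            if start - self.margin < e and s < end + self.margin:
                return False
        return True

    def take(self, chrom: str, start: int, end: int, key: tuple) -> None:
        self.occupied.setdefault(chrom, []).append((start, end))
        self.keys.add(key)


def _sample_target_pos(
    targets: TargetSet, rng: np.random.Generator, interior_pad: int = 0
) -> tuple[str, int]:
    lengths = np.array([max(r.length - 2 * interior_pad, 1) for r in targets.regions])
    idx = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
    r = targets.regions[idx]
    lo = r.start + interior_pad
    hi = max(r.end - interior_pad, lo + 1)
    return r.chrom, int(rng.integers(lo, hi))


def _sample_genome_pos(genome: ReferenceGenome, rng: np.random.Generator) -> tuple[str, int]:
    chroms = genome.chroms()
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
    return chroms[ci], int(rng.integers(100, lengths[ci] - 100))


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _sample_snv(
    genome: ReferenceGenome,
    rng: np.random.Generator,
    pos_sampler,
    gc_weight: float,
    ti_fraction: float,
) -> tuple[str, int, str, str]:
    """GC-biased site choice, transition/transversion split per config."""
    while True:
        chrom, pos = pos_sampler()
        ref = genome.seq(chrom, pos, pos + 1)
        if ref not in "ACGT":
            continue
        w = gc_weight if ref in "GC" else 1.0
        if rng.random() > w / max(gc_weight, 1.0):
            continue
        if rng.random() < ti_fraction:
            alt = _TRANSITION[ref]
        else:
            alt = _TRANSVERSIONS[ref][int(rng.integers(2))]
        return chrom, pos, ref, alt


def _sample_del_size(rng: np.random.Generator) -> int:
    u = rng.random()
    if u < 0.333:
        return 1
    if u < 0.333 + 0.534:
        return int(rng.integers(2, 11))
    return 11 + int(rng.geometric(0.15))


def _sample_ins_size(rng: np.random.Generator) -> int:
    u = rng.random()
    if u < 0.639:
        return 1
    if u < 0.639 + 0.333:
        return int(rng.integers(2, 12))
    return 12 + int(rng.geometric(0.2))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _depths(cfg: SimConfig, rng: np.random.Generator) -> tuple[int, int]:
    total = max(int(rng.poisson(cfg.mean_depth)), 12)
    if cfg.het_mode:
        alt = int(rng.binomial(total, 0.5))
        alt = min(max(alt, 1), total)
    else:
        # homozygous call: reference reads are rare mismapping noise,
        # kept safely below the reference-fraction filter
        ref = min(int(rng.binomial(total, 0.005)), int(0.04 * total))
        alt = total - ref
    return alt, total - alt


def _make_variant(
    cfg: SimConfig,
    genome: ReferenceGenome,
    rng: np.random.Generator,
    placer: _Placer,
    line_id: str,
    var_class: VarClass,
    pos_sampler,
    max_tries: int = 200,
) -> VariantRecord | None:
    """One injected variant of the requested class, normalized, non-colliding."""
    for _ in range(max_tries):
        if var_class is VarClass.SNV:
            chrom, pos, ref, alt = _sample_snv(
                genome, rng, pos_sampler, cfg.gc_enrichment, cfg.ti_fraction
            )
            size = 0
        elif var_class is VarClass.DEL:
            chrom, pos = pos_sampler()
            size = _sample_del_size(rng)
            ref, alt = genome.seq(chrom, pos, pos + size), ""
        elif var_class is VarClass.INS:
            chrom, pos = pos_sampler()
            size = _sample_ins_size(rng)
            ref, alt = "", _random_seq(rng, size)
        elif var_class is VarClass.RPL:
            chrom, pos = pos_sampler()
            size = int(rng.integers(2, 12))
            ins_len = int(rng.integers(1, 8))
            ref, alt = genome.seq(chrom, pos, pos + size), _random_seq(rng, ins_len)
            # reject pairs that trimming would reclassify (shared end bases)
            if alt == ref or alt[0] == ref[0] or alt[-1] == ref[-1]:
                continue
        else:  # INV
            chrom, pos = pos_sampler()
            size = int(rng.integers(50, 400))
            ref, alt = "", ""
        if pos + max(size, 1) + 1 >= genome.length(chrom):
            continue
        alt_reads, ref_reads = _depths(cfg, rng)
        rec = VariantRecord(
            line_id=line_id,
            caller=Caller.SNV_CALLER,
            chrom=chrom,
            pos=pos,
            ref_allele=ref,
            alt_allele=alt,
            var_class=var_class,
            size_bp=size,
            alt_reads=alt_reads,
            ref_reads=ref_reads,
        )
        rec = normalize_variant(rec, genome)
        key = variant_key(rec)
        s, e = rec.interval()
        if key in placer.keys or not placer.free(chrom, s, e):
            continue
        placer.take(chrom, s, e, key)
        return rec
    return None


def _route_callers(rec: VariantRecord) -> list[Caller]:
    """Which caller's file(s) report this event.

    SNVs come from the SNV caller; small indels are seen by both callers
    (exercising cross-caller deduplication); larger events and
    replacements/inversions only by the SV caller.
    """
    if rec.var_class is VarClass.SNV:
        return [Caller.SNV_CALLER]
    if rec.var_class in (VarClass.DEL, VarClass.INS) and rec.size_bp <= 10:
        return [Caller.SNV_CALLER, Caller.SV_CALLER]
    return [Caller.SV_CALLER]


def _draw_count(cfg: SimConfig, rng: np.random.Generator) -> int:
    if cfg.count_model == "poisson":
        return int(rng.poisson(cfg.mean_count))
    return max(int(round(rng.normal(cfg.mean_count, cfg.count_sigma))), 0)


def inject_variants(
    cfg: SimConfig,
    genome: ReferenceGenome,
    targets: TargetSet,
    out_dir: str | Path,
    models: list[GeneModel] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TruthTable, dict[str, dict[str, Path]]]:
    """Write per-line call files and the ground-truth table.

    Shared background variants appear in every line's files; each line
    additionally receives a private count drawn around the configured
    dose mean, with classes, sizes and base changes drawn from the
    configured spectrum.  Returns the truth table and a map
    ``line_id -> {"vcf": path, "pindel": path}``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    placer = _Placer()
    index = GeneIndex(models) if models else None

    genome_bases = sum(genome.length(c) for c in genome.chroms())
    if targets.total_bases < cfg.n_lines * cfg.mean_count * 30:
        raise ValueError("target space too small for the requested private variant count")
    if genome_bases < cfg.n_shared_background * 60:
        raise ValueError("genome too small for the requested shared background")

    classes = list(cfg.class_probs)
    probs = np.array([cfg.class_probs[c] for c in classes])

    # shared intracultivar background: SNVs plus small deletions, genome-wide
    shared: list[VariantRecord] = []
    genome_sampler = lambda: _sample_genome_pos(genome, rng)  # noqa: E731
    for _ in range(cfg.n_shared_background):
        cls = VarClass.SNV if rng.random() < cfg.shared_snv_fraction else VarClass.DEL
        rec = _make_variant(cfg, genome, rng, placer, "shared", cls, genome_sampler)
        if rec is not None:
            shared.append(rec)

    target_sampler = lambda: _sample_target_pos(targets, rng, interior_pad=2)  # noqa: E731
    truth_rows: list[dict] = []
    for rec in shared:
        truth_rows.append(_truth_row(rec, "shared", targets, index, genome))

    line_ids = [f"line{int(i) + 1:03d}" for i in range(cfg.n_lines)]
    paths: dict[str, dict[str, Path]] = {}
    for line_id in line_ids:
        n_private = _draw_count(cfg, rng)
        private: list[VariantRecord] = []
        drawn = rng.choice(len(classes), size=n_private, p=probs)
        for ci in drawn:
            rec = _make_variant(
                cfg, genome, rng, placer, line_id, classes[int(ci)], target_sampler
            )
            if rec is not None:
                private.append(rec)
        for rec in private:
            truth_rows.append(_truth_row(rec, line_id, targets, index, genome))

        vcf_records: list[VariantRecord] = []
        pindel_records: list[VariantRecord] = []
        for rec in shared + private:
            rec_line = VariantRecord(
                line_id=line_id,
                caller=rec.caller,
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref_allele,
                alt_allele=rec.alt_allele,
                var_class=rec.var_class,
                size_bp=rec.size_bp,
                alt_reads=rec.alt_reads,
                ref_reads=rec.ref_reads,
            )
            for caller in _route_callers(rec_line):
                if caller is Caller.SNV_CALLER:
                    vcf_records.append(rec_line)
                else:
                    pindel_records.append(
                        VariantRecord(
                            line_id=line_id,
                            caller=Caller.SV_CALLER,
                            chrom=rec_line.chrom,
                            pos=rec_line.pos,
                            ref_allele="" if rec_line.var_class is not VarClass.INS else "",
                            alt_allele=rec_line.alt_allele,
                            var_class=rec_line.var_class,
                            size_bp=rec_line.size_bp,
                            alt_reads=rec_line.alt_reads,
                            ref_reads=0,
                        )
                    )
        vcf_path = out_dir / f"{line_id}.vcf"
        pindel_path = out_dir / f"{line_id}.pindel.txt"
        contigs = {c: genome.length(c) for c in genome.chroms()}
        write_vcf(CallSet(line_id, vcf_records), vcf_path, reference=genome, contig_lengths=contigs)
        write_pindel(CallSet(line_id, pindel_records), pindel_path)
        paths[line_id] = {"vcf": vcf_path, "pindel": pindel_path}

    frame = pd.DataFrame(truth_rows)
    truth = TruthTable(frame)
    truth.to_tsv(out_dir / "truth.tsv")
    return truth, paths


def _truth_row(
    rec: VariantRecord,
    line_id: str,
    targets: TargetSet,
    index: GeneIndex | None,
    genome: ReferenceGenome,
) -> dict:
    s, e = rec.interval()
    in_target = bool(targets.tree(rec.chrom).overlap(s, e))
    bucket = ""
    if index is not None and rec.var_class is not VarClass.INV:
        bucket = classify_effect(rec, index, genome).bucket.value
    return {
        "line_id": line_id,
        "chrom": rec.chrom,
        "pos": rec.pos,
        "var_class": rec.var_class.value,
        "size_bp": rec.size_bp,
        "ref": rec.ref_allele,
        "alt": rec.alt_allele,
        "in_target": in_target,
        "zygosity": "het" if line_id != "shared" else "background",
        "intended_bucket": bucket,
        "key": variant_key(rec),
    }


# ---------------------------------------------------------------------------
# Depth tracks and large deletions
# ---------------------------------------------------------------------------

def make_depth_track(
    cfg: SimConfig,
    targets: TargetSet,
    rng: np.random.Generator | None = None,
    pad: int = 20,
) -> DepthTrack:
    """Baseline capture depth: each target (padded) covered near the mean depth."""
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    records = []
    prev: dict[str, int] = {}
    for r in targets:
        depth = max(int(rng.normal(cfg.mean_depth, cfg.mean_depth * 0.1)), 1)
        start = max(0, r.start - pad, prev.get(r.chrom, 0))
        end = r.end + pad
        if end > start:
            records.append((r.chrom, start, end, depth))
            prev[r.chrom] = end
    return DepthTrack.from_records(records)


def inject_large_deletion(
    depth: DepthTrack,
    targets: TargetSet,
    n_targets: int,
    rng: np.random.Generator | None = None,
    start_index: int | None = None,
    heterozygous: bool = False,
) -> tuple[DepthTrack, dict]:
    """Zero (or halve) depth across a run of consecutive targets.

    Picks ``n_targets`` consecutive targets on one chromosome, not
    touching the chromosome ends, and zeroes every depth interval inside
    a deletion span whose true breakpoints fall in the flanking
    intergenic gaps.  In heterozygous mode the depth is halved instead,
    emulating a pooled sample in which the deletion segregates.
    Returns the modified track and a truth row with the true breakpoints.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    pad = 20  # must match the depth-track padding around targets
    by_chrom: dict[str, list] = {}
    for r in targets:
        by_chrom.setdefault(r.chrom, []).append(r)

    def _valid(regs: list, idx: int) -> bool:
        if idx < 1 or idx + n_targets >= len(regs):
            return False
        run_ = regs[idx : idx + n_targets]
        left_gap = run_[0].start - regs[idx - 1].end
        right_gap = regs[idx + n_targets].start - run_[-1].end
        return left_gap > 2 * pad + 2 and right_gap > 2 * pad + 2

    if start_index is not None:
        candidates = [
            (c, start_index) for c, regs in sorted(by_chrom.items()) if _valid(regs, start_index)
        ]
    else:
        candidates = [
            (c, i)
            for c, regs in sorted(by_chrom.items())
            for i in range(1, len(regs) - n_targets)
            if _valid(regs, i)
        ]
    if not candidates:
        raise ValueError(f"no chromosome has {n_targets} consecutive targets with covered flanks")
    chrom, start_index = candidates[int(rng.integers(len(candidates)))]
    regs = by_chrom[chrom]
    run = regs[start_index : start_index + n_targets]
    prev_end = regs[start_index - 1].end
    next_start = regs[start_index + n_targets].start
    # true breakpoints fall in the flanking gaps, outside the flanks' padded
    # depth intervals but upstream/downstream of the run's padded intervals
    true_start = int(rng.integers(prev_end + pad + 1, run[0].start - pad + 1))
    true_end = int(rng.integers(run[-1].end + pad, next_start - pad))

    new_intervals = {}
    for c, (starts, ends, depths) in depth.intervals.items():
        starts, ends, depths = starts.copy(), ends.copy(), depths.copy()
        if c == chrom:
            inside = (starts >= true_start) & (ends <= true_end)
            depths[inside] = depths[inside] // 2 if heterozygous else 0
        new_intervals[c] = (starts, ends, depths)
    truth = {
        "chrom": chrom,
        "true_start": true_start,
        "true_end": true_end,
        "n_targets": n_targets,
        "target_ids": [r.region_id for r in run],
        "zygosity": "het" if heterozygous else "hom",
    }
    return DepthTrack(new_intervals), truth
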