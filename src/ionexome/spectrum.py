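"""Cohort-level mutation statistics.

Composition of the induced-mutation spectrum (class fractions, indel
size distributions, substitution matrix, transition/transversion split,
GC preference), the per-line count distribution with a Gaussian fit,
dose-response summaries (per-Gy mutation rates), linear extrapolation
from capture targets to the whole genome, per-chromosome frequencies,
and visual-phenotype (chlorophyll-deficient mutant) rates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import ReferenceGenome, TargetSet, VarClass, VariantRecord

# Rice (Oryza sativa, Nipponbare IRGSP-1.0) study constants: total capture
# target length and assembled genome length, in bases.
RICE_TARGET_BASES = 34_040_553
RICE_GENOME_BASES = 373_245_519

_BASES = ("A", "C", "G", "T")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass
class SpectrumSummary:
    """Cohort mutation composition."""

    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    deletion_sizes: Counter
    insertion_sizes: Counter
    substitution_matrix: pd.DataFrame  # rows: ref base, cols: alt base
    n_transitions: int
    n_transversions: int
    base_counts: dict[str, int]  # mutated-site counts per reference base

    @property
    def n_total(self) -> int:
        return sum(self.class_counts.values())

    @property
    def n_snv(self) -> int:
        return self.class_counts.get("SNV", 0)


@dataclass
class GaussianFit:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class DoseGroup:
    """One irradiation condition with its per-line in-target mutation counts."""

    dose_gy: float
    let_kev_um: float
    seed_state: str  # "dry" or "imbibed"
    per_line_counts: list[int] = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        return len(self.per_line_counts)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_line_counts))

    @property
    def se(self) -> float:
        x = np.asarray(self.per_line_counts, dtype=float)
        return float(x.std(ddof=1) / np.sqrt(len(x)))


@dataclass
class CohortPhenotype:
    """Visual phenotype summary for one irradiation condition.

    Chlorophyll-deficient mutant (CDM) class counts are counts of
    harvested lines that showed at least one plant of that class.
    """

    seed_state: str
    dose_gy: float
    let_kev_um: float
    n_lines_harvested: int
    cdm_counts: dict[str, int]  # albino / pale_green / yellow / virescent / stripe
    survival_pct: float | None = None
    fertility_pct: float | None = None

    def __post_init__(self) -> None:
        for cls, n in self.cdm_counts.items():
            if n > self.n_lines_harvested:
                raise ValueError(f"{cls} count {n} exceeds lines harvested {self.n_lines_harvested}")


def is_transition(ref_base: str, alt_base: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine substitutions."""
    r, a = ref_base.upper(), alt_base.upper()
    if r == a or r not in _BASES or a not in _BASES:
        raise ValueError(f"invalid substitution {ref_base}->{alt_base}")
    return (r in _PURINES) == (a in _PURINES)


def summarize_spectrum(calls: list[VariantRecord]) -> SpectrumSummary:
    """Tally class composition, indel sizes and SNV substitution pattern.

    Records are expected to be normalized (and typically
    target-intersected).  Multi-base replacements are excluded from the
    substitution matrix.
    """
    class_counts: Counter = Counter()
    del_sizes: Counter = Counter()
    ins_sizes: Counter = Counter()
    matrix = pd.DataFrame(0, index=list(_BASES), columns=list(_BASES), dtype=int)
    n_ti = n_tv = 0
    base_counts = dict.fromkeys(_BASES, 0)

    for v in calls:
        class_counts[v.var_class.value] += 1
        if v.var_class is VarClass.DEL:
            del_sizes[v.size_bp] += 1
        elif v.var_class is VarClass.INS:
            ins_sizes[v.size_bp] += 1
        elif v.var_class is VarClass.SNV:
            r, a = v.ref_allele.upper(), v.alt_allele.upper()
            if r in _BASES and a in _BASES and r != a:
                matrix.loc[r, a] += 1
                base_counts[r] += 1
                if is_transition(r, a):
                    n_ti += 1
                else:
                    n_tv += 1

    total = sum(class_counts.values())
    fractions = {k: v / total for k, v in class_counts.items()} if total else {}
    return SpectrumSummary(
        class_counts=dict(class_counts),
        class_fractions=fractions,
        deletion_sizes=del_sizes,
        insertion_sizes=ins_sizes,
        substitution_matrix=matrix,
        n_transitions=n_ti,
        n_transversions=n_tv,
        base_counts=base_counts,
    )


def base_preference(summary: SpectrumSummary, target_at_gc_ratio: float) -> dict:
    """Mutated-site GC:AT ratio and GC enrichment over target composition.

    ``target_at_gc_ratio`` is the GC/AT base ratio of the target space
    (1.07 means an AT:GC ratio of 1:1.07).  Enrichment is the ratio of
    the mutated-site GC/AT ratio to the target ratio.
    """
    n = summary.base_counts
    at = n["A"] + n["T"]
    gc = n["C"] + n["G"]
    if at == 0:
        return {"ratio_mut": None, "enrichment": None, "n_at": at, "n_gc": gc}
    ratio_mut = gc / at
    return {
        "ratio_mut": ratio_mut,
        "enrichment": ratio_mut / target_at_gc_ratio,
        "n_at": at,
        "n_gc": gc,
    }


def target_gc_at_ratio(reference: ReferenceGenome, targets: TargetSet) -> float:
    """GC/AT base-count ratio over the target intervals."""
    at = gc = 0
    for r in targets:
        seq = reference.seq(r.chrom, r.start, r.end)
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if at == 0:
        raise ValueError("no A/T bases in targets")
    return gc / at


def size_histogram(
    calls: list[VariantRecord], var_class: VarClass, bins: list[tuple[int, int]] | None = None
) -> pd.DataFrame:
    """Size distribution of one variant class.

    ``bins`` is a list of inclusive (lo, hi) ranges; by default each
    observed size is its own bin.  Fractions are over all events of the
    class.
    """
    sizes = [v.size_bp for v in calls if v.var_class is var_class]
    total = len(sizes)
    if not sizes:
        return pd.DataFrame(columns=["bin", "count", "fraction"])
    if bins is None:
        counter = Counter(sizes)
        rows = [
            {"bin": f"{s}", "count": c, "fraction": c / total} for s, c in sorted(counter.items())
        ]
    else:
        rows = []
        for lo, hi in bins:
            c = sum(1 for s in sizes if lo <= s <= hi)
            rows.append({"bin": f"{lo}-{hi}" if hi != lo else f"{lo}", "count": c, "fraction": c / total})
    return pd.DataFrame(rows)


def gaussian_fit(per_line_counts: list[int] | np.ndarray, method: str = "mle") -> GaussianFit:
    """Fit a Gaussian to the per-line mutation count distribution.

    ``method="mle"``: mu is the sample mean and sigma the square root of
    the central second moment (population formula).  ``method=
    "histogram_ls"``: least-squares fit of a Gaussian curve to the
    unit-binned count histogram, which can differ from the MLE when the
    distribution is skewed.
    """
    x = np.asarray(per_line_counts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 counts to fit")
    if method == "mle":
        mu = float(x.mean())
        sigma = float(np.sqrt(((x - mu) ** 2).mean()))
        if sigma == 0:
            raise ValueError("degenerate (constant) counts: sigma = 0")
        return GaussianFit(mu, sigma)
    if method == "histogram_ls":
        lo, hi = int(x.min()), int(x.max())
        centers = np.arange(lo, hi + 1, dtype=float)
        heights = np.array([(x == c).sum() for c in centers], dtype=float)

        def _gauss(t, amp, mu, sigma):
            return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)

        p0 = (heights.max(), x.mean(), max(x.std(), 1.0))
        popt, _ = curve_fit(_gauss, centers, heights, p0=p0, maxfev=20000)
        return GaussianFit(float(popt[1]), float(abs(popt[2])))
    raise ValueError(f"unknown method {method!r}")


def per_gy_rate(mean_count: float, dose_gy: float, se: float | None = None) -> dict:
    """Mutations per line per gray; the SE scales identically."""
    if dose_gy <= 0:
        raise ValueError("dose must be positive")
    out = {"rate_per_gy": mean_count / dose_gy}
    if se is not None:
        out["se_per_gy"] = se / dose_gy
    return out


def extrapolate_genome(
    per_line_count: float,
    target_bases: int = RICE_TARGET_BASES,
    genome_bases: int = RICE_GENOME_BASES,
) -> float:
    """Linear extrapolation from in-target counts to the whole genome.

    Assumes the per-base mutation frequency outside the capture targets
    equals that inside them.
    """
    if target_bases <= 0:
        raise ValueError("target_bases must be positive")
    return per_line_count * (genome_bases / target_bases)


def chrom_frequency(
    calls: list[VariantRecord], targets: TargetSet, n_lines: int
) -> tuple[pd.DataFrame, float | None]:
    """Per-chromosome mutation frequency per target megabase per line.

    Returns the per-chromosome table and the max/min frequency ratio
    across chromosomes with nonzero target length.
    """
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    target_bases: Counter = Counter()
    for r in targets:
        target_bases[r.chrom] += r.length
    counts: Counter = Counter(v.chrom for v in calls)
    rows = []
    for chrom in sorted(set(target_bases) | set(counts)):
        mb = target_bases.get(chrom, 0) / 1e6
        freq = counts.get(chrom, 0) / (mb * n_lines) if mb > 0 else None
        rows.append(
            {"chrom": chrom, "count": counts.get(chrom, 0), "target_mb": mb, "frequency": freq}
        )
    df = pd.DataFrame(rows)
    freqs = df["frequency"].dropna()
    ratio = float(freqs.max() / freqs.min()) if len(freqs) > 0 and freqs.min() > 0 else None
    return df, ratio


def cdm_mutation_rate(phen: CohortPhenotype) -> float:
    """Percentage of harvested lines showing a chlorophyll-deficient mutant."""
    if phen.n_lines_harvested == 0:
        raise ValueError("no lines harvested")
    return 100.0 * sum(phen.cdm_counts.values()) / phen.n_lines_harvested


def dose_response_table(groups: list[DoseGroup]) -> pd.DataFrame:
    """Per-condition dose-response summary.

    One row per condition with mean +/- SE in-target count, per-Gy rate,
    and genome-extrapolated count; the condition maximizing the per-Gy
    rate is marked.
    """
    rows = []
    for g in groups:
        mean, se = g.mean, g.se if g.n_lines > 1 else float("nan")
        rate = per_gy_rate(mean, g.dose_gy, se if np.isfinite(se) else None)
        rows.append(
            {
                "seed_state": g.seed_state,
                "dose_gy": g.dose_gy,
                "let_kev_um": g.let_kev_um,
                "n_lines": g.n_lines,
                "mean_count": mean,
                "se_count": se,
                "rate_per_gy": rate["rate_per_gy"],
                "se_per_gy": rate.get("se_per_gy", float("nan")),
                "genome_extrapolated": extrapolate_genome(mean),
            }
        )
    df = pd.DataFrame(rows)
    df["max_per_gy"] = df["rate_per_gy"] == df["rate_per_gy"].max()
    return df
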