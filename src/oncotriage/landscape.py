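"""Mutational-landscape statistics.

Tumor mutational burden (all Level-1 variants, synonymous included, per Mb
of capture design), mutation-type distributions, the pyrimidine-collapsed
six-class SNV spectrum, pathogenicity fractions against a table-driven
oracle, and per-sample mutated-gene counts.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from statistics import mean, median
from typing import Iterable

from .cascade import LevelSet
from .errors import ValidationError
from .types import (
    Cohort,
    FunctionalClass,
    PathogenicityCall,
    PathogenicityOracle,
    SampleType,
    VariantCall,
)

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def round1(x: float) -> float:
    """Half-up rounding to one decimal place (reporting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class TmbResult:
    """Per-sample and cohort mutational burden in mutations/Mb.

    Summary statistics (mean/median/min/max) cover cell lines only; FFPE
    samples are reported separately in ``ffpe``.
    """

    per_sample: dict[str, float]
    mean: float | None
    median: float | None
    tmb_min: float | None
    tmb_max: float | None
    target_size_mb: float
    ffpe: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict:
        r = lambda v: None if v is None else round1(v)
        return {
            "per_sample": {s: round1(v) for s, v in self.per_sample.items()},
            "mean": r(self.mean), "median": r(self.median),
            "min": r(self.tmb_min), "max": r(self.tmb_max),
            "ffpe": {s: round1(v) for s, v in self.ffpe.items()},
            "target_size_mb": self.target_size_mb,
        }


def compute_tmb(l1: LevelSet, cohort: Cohort) -> TmbResult:
    """TMB per sample = Level-1 variant count / target size in Mb.

    Counts all Level-1 variants including synonymous ones. Samples with no
    variants get TMB 0.
    """
    if l1.level != "L1":
        raise ValidationError(f"compute_tmb expects an L1 set, got {l1.level}")
    if cohort.target_size_mb <= 0:
        raise ValidationError("target_size_mb must be positive")
    counts = Counter(v.sample_id for v in l1.variants)
    per_sample, ffpe = {}, {}
    cell_values = []
    for s in cohort.samples:
        tmb = counts.get(s.sample_id, 0) / cohort.target_size_mb
        per_sample[s.sample_id] = tmb
        if s.sample_type == SampleType.CELL_LINE:
            cell_values.append(tmb)
        else:
            ffpe[s.sample_id] = tmb
    if cell_values:
        stats = (mean(cell_values), median(cell_values),
                 min(cell_values), max(cell_values))
    else:
        stats = (None, None, None, None)
    return TmbResult(per_sample=per_sample, mean=stats[0], median=stats[1],
                     tmb_min=stats[2], tmb_max=stats[3],
                     target_size_mb=cohort.target_size_mb, ffpe=ffpe)


@dataclass
class MutationTypeDistribution:
    """Counts and proportions per functional class, pooled and per sample.

    ``mean_proportions`` is the unweighted mean of per-sample proportions
    (so each sample contributes equally regardless of burden).
    """

    pooled_counts: dict[FunctionalClass, int]
    pooled_proportions: dict[FunctionalClass, float] | None
    per_sample_counts: dict[str, dict[FunctionalClass, int]] = field(default_factory=dict)
    per_sample_proportions: dict[str, dict[FunctionalClass, float]] = field(default_factory=dict)
    mean_proportions: dict[FunctionalClass, float] | None = None
    n: int = 0
    undefined: bool = False


def mutation_type_distribution(
    variants: Iterable[VariantCall], scope: str = "pooled"
) -> MutationTypeDistribution:
    """Distribution of functional classes; ``scope`` is ``pooled`` or
    ``per_sample`` (the latter additionally averages per-sample
    proportions). Empty input yields zero counts flagged undefined."""
    variants = list(variants)
    pooled = {c: 0 for c in FunctionalClass}
    for v in variants:
        pooled[v.functional_class] += 1
    n = len(variants)
    if n == 0:
        return MutationTypeDistribution(
            pooled_counts=pooled, pooled_proportions=None, n=0, undefined=True
        )
    pooled_props = {c: k / n for c, k in pooled.items()}
    result = MutationTypeDistribution(
        pooled_counts=pooled, pooled_proportions=pooled_props, n=n
    )
    if scope == "per_sample":
        by_sample: dict[str, list[VariantCall]] = {}
        for v in variants:
            by_sample.setdefault(v.sample_id, []).append(v)
        for sid, vs in by_sample.items():
            counts = {c: 0 for c in FunctionalClass}
            for v in vs:
                counts[v.functional_class] += 1
            result.per_sample_counts[sid] = counts
            result.per_sample_proportions[sid] = {
                c: k / len(vs) for c, k in counts.items()
            }
        result.mean_proportions = {
            c: mean(p[c] for p in result.per_sample_proportions.values())
            for c in FunctionalClass
        }
    return result


def spectrum_class(ref: str, alt: str) -> str | None:
    """Pyrimidine-collapsed class of a single-base substitution, or None
    for indels/non-ACGT alleles (purine changes fold onto complements:
    G>A is counted as C>T)."""
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return None
    if ref not in "ACGT" or alt not in "ACGT":
        return None
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass
class SnvSpectrum:
    counts: dict[str, int]
    dominant_class: str | None
    n_snv: int
    n_other: int  # indels / non-classifiable variants, for conservation checks


def snv_spectrum(variants: Iterable[VariantCall]) -> SnvSpectrum:
    """Six-class SNV spectrum; indels ignored but counted in ``n_other``.

    Dominant class is the argmax with lexicographic tie-break (first class
    in C>A..T>G order wins)."""
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    n_other = 0
    for v in variants:
        cls = spectrum_class(v.ref, v.alt)
        if cls is None:
            n_other += 1
        else:
            counts[cls] += 1
    n_snv = sum(counts.values())
    dominant = None
    if n_snv > 0:
        # lexicographic tie-break: first class in canonical order wins
        best = max(counts.values())
        dominant = next(c for c in SPECTRUM_CLASSES if counts[c] == best)
    return SnvSpectrum(counts=counts, dominant_class=dominant,
                       n_snv=n_snv, n_other=n_other)


@dataclass
class PathogenicFraction:
    numerator: int
    denominator: int
    percent: float | None  # 1 d.p., half-up; None when denominator is 0
    undefined: bool = False


def pathogenic_fraction(
    variants: Iterable[VariantCall],
    oracle: PathogenicityOracle,
    restrict_to: FunctionalClass | None = FunctionalClass.MISSENSE,
    unknown_policy: str = "exclude",
) -> PathogenicFraction:
    """Fraction of SNVs called deleterious by the oracle.

    Only single-nucleotide variants matching ``restrict_to`` (None = any
    class) enter the denominator. Oracle calls of "unknown" are excluded
    from both numerator and denominator by default; with
    ``unknown_policy="neutral"`` they stay in the denominator as
    non-pathogenic.
    """
    if unknown_policy not in ("exclude", "neutral"):
        raise ValidationError(f"unknown_policy must be exclude|neutral, got {unknown_policy}")
    num = den = 0
    for v in variants:
        if not v.is_snv:
            continue
        if restrict_to is not None and v.functional_class != restrict_to:
            continue
        call = oracle.call_variant(v)
        if call == PathogenicityCall.UNKNOWN:
            if unknown_policy == "exclude":
                continue
            den += 1
        else:
            den += 1
            if call == PathogenicityCall.DELETERIOUS:
                num += 1
    if den == 0:
        return PathogenicFraction(numerator=num, denominator=0,
                                  percent=None, undefined=True)
    return PathogenicFraction(numerator=num, denominator=den,
                              percent=round1(100.0 * num / den))


def genes_per_sample(l2: LevelSet) -> dict[str, int]:
    """Distinct gene symbols with at least one Level-2 variant, per sample."""
    if l2.level != "L2":
        raise ValidationError(f"genes_per_sample expects an L2 set, got {l2.level}")
    genes: dict[str, set[str]] = {s.sample_id: set() for s in l2.samples}
    for v in l2.variants:
        if v.gene_symbol:
            genes.setdefault(v.sample_id, set()).add(v.gene_symbol)
    return {sid: len(g) for sid, g in genes.items()}
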