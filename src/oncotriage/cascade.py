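"""Three-level somatic-variant triage cascade and hotspot cross-referencing.

Level 1 keeps quality-filtered exonic variants (synonymous included — they
count toward mutational burden and are only dropped at Level 2); 5'UTR and
splice-site variants that pass the same quality thresholds are held in a
side channel for the Level-3 census rescue. Level 2 is the protein-modifying
subset, annotated with sample-wise recurrence and disease-list membership.
Level 3 restricts to Cancer Gene Census genes and re-admits the census
UTR/splice side-channel variants. Hotspot matching maps query-species
protein positions onto human hotspot positions via a per-gene codon offset
(e.g. canine TP53 E273K ↔ human E285K, offset +12).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .errors import ConfigError, ValidationError
from .hgvs import parse_protein_change
from .types import (
    CensusRole,
    Cohort,
    FunctionalClass,
    GeneCatalog,
    HotspotEntry,
    RegionClass,
    SampleDescriptor,
    SampleType,
    VariantCall,
    VariantKey,
)


@dataclass(frozen=True)
class Level1Params:
    """Quality thresholds for Level-1 filtering.

    ``min_alt_count`` and ``min_alt_fraction`` are inclusive lower bounds;
    ``min_depth`` is applied as a strict greater-than (a variant at exactly
    the threshold depth is excluded).
    """

    min_alt_count: int = 2
    min_alt_fraction: float = 0.05
    min_depth: int = 10
    exclude_known_snp: bool = True
    exclude_pon: bool = True

    def __post_init__(self) -> None:
        if self.min_alt_count < 0 or self.min_depth < 0 or self.min_alt_fraction < 0:
            raise ConfigError("Level 1 thresholds must be non-negative")
        if self.min_alt_fraction > 1:
            raise ConfigError("min_alt_fraction must be <= 1")

    def quality_failures(self, v: VariantCall) -> list[str]:
        """Names of the quality criteria the variant fails (region aside)."""
        reasons = []
        if v.alt_read_count < self.min_alt_count:
            reasons.append("alt_count")
        if v.alt_allele_fraction < self.min_alt_fraction:
            reasons.append("alt_fraction")
        if v.read_depth <= self.min_depth:
            reasons.append("depth")
        if self.exclude_known_snp and v.is_known_snp:
            reasons.append("known_snp")
        if self.exclude_pon and v.in_pon:
            reasons.append("pon")
        return reasons

    def passes_quality(self, v: VariantCall) -> bool:
        return not self.quality_failures(v)


ProvenanceKey = tuple[str, VariantKey]  # (sample_id, variant key)


@dataclass
class LevelSet:
    """The surviving variant set at one cascade level, with provenance.

    ``provenance`` maps (sample_id, variant key) to the list of filter tags
    applied to that observation. Level-specific annotations (side channel,
    recurrence counts, census roles, non-coding-only genes) are populated by
    the operation that produces the set.
    """

    level: str
    variants: list[VariantCall]
    samples: list[SampleDescriptor] = field(default_factory=list)
    params: Level1Params | None = None
    provenance: dict[ProvenanceKey, list[str]] = field(default_factory=dict)
    # L1 only: quality-passing utr5/splice variants for the Level-3 rescue
    side_channel: list[VariantCall] = field(default_factory=list)
    # L2 only
    recurrence: dict[VariantKey, int] = field(default_factory=dict)
    disease_flags: dict[str, bool] = field(default_factory=dict)
    min_recurrence: int = 3
    # L3 only
    roles: dict[str, CensusRole] = field(default_factory=dict)
    noncoding_only_genes: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.variants)

    @property
    def genes(self) -> set[str]:
        return {v.gene_symbol for v in self.variants if v.gene_symbol}

    @property
    def keys(self) -> set[VariantKey]:
        return {v.key for v in self.variants}

    @property
    def cell_line_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.sample_type == SampleType.CELL_LINE]

    def to_cohort(self, target_size_mb: float = 150.0) -> Cohort:
        return Cohort(samples=list(self.samples), variants=list(self.variants),
                      target_size_mb=target_size_mb)


def apply_level1(cohort: Cohort, params: Level1Params | None = None) -> LevelSet:
    """Level 1: exonic variants passing all quality thresholds.

    Synonymous variants are retained (they count toward TMB) and tagged for
    downstream exclusion. Quality-passing utr5/splice variants go to the
    side channel; they never enter the Level-1 set itself.
    """
    params = params or Level1Params()
    retained: list[VariantCall] = []
    side: list[VariantCall] = []
    provenance: dict[ProvenanceKey, list[str]] = {}
    for v in cohort.variants:
        tags: list[str] = []
        failures = params.quality_failures(v)
        if v.region_class == RegionClass.EXONIC:
            if failures:
                tags = [f"fail:{r}" for r in failures]
            else:
                tags = ["pass:level1"]
                if v.functional_class == FunctionalClass.SYNONYMOUS:
                    tags.append("tag:synonymous")
                retained.append(v)
        elif v.region_class in (RegionClass.UTR5, RegionClass.SPLICE):
            if failures:
                tags = [f"fail:{r}" for r in failures]
            else:
                tags = ["side_channel:utr_splice"]
                side.append(v)
        else:
            tags = ["fail:region"]
        provenance[(v.sample_id, v.key)] = tags
    return LevelSet(
        level="L1", variants=retained, samples=list(cohort.samples),
        params=params, provenance=provenance, side_channel=side,
    )


def sample_recurrence(
    variants: Iterable[VariantCall], count_samples: Iterable[str]
) -> dict[VariantKey, int]:
    """Distinct-sample count per variant key, restricted to ``count_samples``.

    A key counts once per sample regardless of call multiplicity.
    """
    allowed = set(count_samples)
    seen: dict[VariantKey, set[str]] = {}
    for v in variants:
        if v.sample_id in allowed:
            seen.setdefault(v.key, set()).add(v.sample_id)
    return {k: len(s) for k, s in seen.items()}


def apply_level2(
    l1: LevelSet,
    catalog: GeneCatalog,
    min_recurrence: int = 3,
    *,
    count_ffpe: bool = False,
    keep_unknown: bool = False,
) -> LevelSet:
    """Level 2: protein-modifying subset of Level 1 with recurrence and
    disease-list annotations.

    Recurrence counts samples (cell lines only unless ``count_ffpe``), not
    reads. Recurrence and disease-list membership are annotations consumed
    by the driver catalog, never exclusion filters here.
    """
    if l1.level != "L1":
        raise ValidationError(f"apply_level2 expects an L1 set, got {l1.level}")
    if min_recurrence < 1:
        raise ConfigError("min_recurrence must be >= 1")
    excluded = {FunctionalClass.SYNONYMOUS}
    if not keep_unknown:
        excluded.add(FunctionalClass.UNKNOWN)
    retained = [v for v in l1.variants if v.functional_class not in excluded]
    provenance = dict(l1.provenance)
    for v in l1.variants:
        tag = ("pass:level2" if v.functional_class not in excluded
               else f"drop:level2:{v.functional_class.value}")
        provenance.setdefault((v.sample_id, v.key), []).append(tag)
    count_ids = (
        [s.sample_id for s in l1.samples] if count_ffpe else
        [s.sample_id for s in l1.samples if s.sample_type == SampleType.CELL_LINE]
    )
    recurrence = sample_recurrence(retained, count_ids)
    disease_flags = {
        g: (g in catalog.disease_genes)
        for g in {v.gene_symbol for v in retained if v.gene_symbol}
    }
    return LevelSet(
        level="L2", variants=retained, samples=list(l1.samples), params=l1.params,
        provenance=provenance, side_channel=list(l1.side_channel),
        recurrence=recurrence, disease_flags=disease_flags,
        min_recurrence=min_recurrence,
    )


def apply_level3(
    l2: LevelSet,
    l1_side_channel: Sequence[VariantCall] | None = None,
    catalog: GeneCatalog | None = None,
) -> LevelSet:
    """Level 3: Cancer Gene Census subset plus the UTR5/splice rescue.

    The returned set is the union of L2 variants in census genes and
    side-channel utr5/splice variants in census genes (re-checked against
    the Level-1 quality thresholds). Genes represented only by UTR5/splice
    variants are flagged in ``noncoding_only_genes``.
    """
    if catalog is None:
        raise ConfigError("apply_level3 requires a GeneCatalog")
    if l2.level != "L2":
        raise ValidationError(f"apply_level3 expects an L2 set, got {l2.level}")
    side = list(l1_side_channel) if l1_side_channel is not None else list(l2.side_channel)
    params = l2.params or Level1Params()

    coding = [v for v in l2.variants if catalog.in_census(v.gene_symbol)]
    rescue = [
        v for v in side
        if v.region_class in (RegionClass.UTR5, RegionClass.SPLICE)
        and catalog.in_census(v.gene_symbol)
        and params.passes_quality(v)
    ]
    provenance = dict(l2.provenance)
    for v in coding:
        provenance.setdefault((v.sample_id, v.key), []).append("pass:level3:census_coding")
    for v in rescue:
        provenance.setdefault((v.sample_id, v.key), []).append("pass:level3:utr_splice_rescue")

    variants = coding + rescue
    roles = {g: catalog.role_of(g) for g in {v.gene_symbol for v in variants if v.gene_symbol}}
    coding_genes = {v.gene_symbol for v in coding if v.gene_symbol}
    rescue_genes = {v.gene_symbol for v in rescue if v.gene_symbol}
    return LevelSet(
        level="L3", variants=variants, samples=list(l2.samples), params=params,
        provenance=provenance, recurrence=dict(l2.recurrence),
        disease_flags=dict(l2.disease_flags), min_recurrence=l2.min_recurrence,
        roles=roles, noncoding_only_genes=rescue_genes - coding_genes,
    )


@dataclass(frozen=True)
class HotspotMatch:
    """A variant whose protein change maps onto a known human hotspot."""

    variant: VariantCall
    hotspot: HotspotEntry
    query_position: int
    mapped_position: int


@dataclass
class HotspotScan:
    """Result of hotspot cross-referencing: matches plus the number of
    non-empty protein-change strings that could not be parsed."""

    matches: list[HotspotMatch] = field(default_factory=list)
    n_unparseable: int = 0

    def __iter__(self) -> Iterator[HotspotMatch]:
        return iter(self.matches)

    def __len__(self) -> int:
        return len(self.matches)

    def samples_for(self, gene: str) -> set[str]:
        g = gene.strip().upper()
        return {m.variant.sample_id for m in self.matches
                if m.hotspot.gene_symbol == g}


def match_hotspots(
    variants: Iterable[VariantCall] | LevelSet, catalog: GeneCatalog
) -> HotspotScan:
    """Cross-reference variant protein changes against the hotspot catalog.

    A match requires: same gene symbol, query position + codon offset equal
    to the human hotspot position, and identical ref/alt amino acids after
    one-letter normalization. Variants with unparseable (non-substitution)
    protein changes are skipped and counted.
    """
    scan = HotspotScan()
    for v in variants:
        if not v.protein_change:
            continue
        parsed = parse_protein_change(v.protein_change)
        if parsed is None:
            scan.n_unparseable += 1
            continue
        ref, qpos, alt = parsed
        for h in catalog.hotspots_for(v.gene_symbol):
            mapped = qpos + h.species_codon_offset
            if (mapped == h.human_position
                    and ref == h.human_ref_aa and alt == h.human_alt_aa):
                scan.matches.append(
                    HotspotMatch(variant=v, hotspot=h,
                                 query_position=qpos, mapped_position=mapped)
                )
    return scan
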