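"""Core domain types: variant observations, cohorts, gene catalogs.

A :class:`VariantCall` is one annotated somatic variant observed in one
sample. Variant *identity* for recurrence counting is the genomic key
``(chrom, pos, ref, alt)``; HGVS strings are annotations, never identity.
Coordinates are 1-based inclusive with VCF-style anchored indel alleles.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ValidationError
from .hgvs import normalize_protein_change

VariantKey = tuple[str, int, str, str]


class RegionClass(str, enum.Enum):
    EXONIC = "exonic"
    UTR5 = "utr5"
    SPLICE = "splice"
    OTHER = "other"


class FunctionalClass(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    NONFRAMESHIFT_INSERTION = "nonframeshift_insertion"
    NONFRAMESHIFT_DELETION = "nonframeshift_deletion"
    UNKNOWN = "unknown"

    @property
    def is_nonsynonymous(self) -> bool:
        """Protein-modifying: everything except synonymous and unknown."""
        return self not in (FunctionalClass.SYNONYMOUS, FunctionalClass.UNKNOWN)


class CensusRole(str, enum.Enum):
    ONCOGENE = "oncogene"
    TUMOR_SUPPRESSOR = "tumor_suppressor"
    FUSION = "fusion"
    ONCOGENE_AND_TSG = "oncogene_and_tsg"
    UNANNOTATED = "unannotated"


class SampleType(str, enum.Enum):
    CELL_LINE = "cell_line"
    FFPE_TUMOR = "ffpe_tumor"
    FFPE_NORMAL = "ffpe_normal"


class PathogenicityCall(str, enum.Enum):
    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"
    UNKNOWN = "unknown"


_NUCS = set("ACGTN")


@dataclass
class VariantCall:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    read_depth: int
    alt_read_count: int
    alt_allele_fraction: float | None = None
    region_class: RegionClass = RegionClass.OTHER
    functional_class: FunctionalClass = FunctionalClass.UNKNOWN
    gene_symbol: str = ""
    cdna_change: str = ""
    protein_change: str = ""
    is_known_snp: bool = False
    in_pon: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.read_depth < 0 or self.alt_read_count < 0:
            raise ValidationError("read counts must be non-negative")
        if self.alt_read_count > self.read_depth:
            raise ValidationError(
                f"alt_read_count {self.alt_read_count} exceeds read_depth "
                f"{self.read_depth} at {self.chrom}:{self.pos}"
            )
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not set(self.ref) <= _NUCS or not set(self.alt) <= _NUCS:
            raise ValidationError(f"non-nucleotide allele at {self.chrom}:{self.pos}")
        if self.alt_allele_fraction is None:
            if self.read_depth > 0:
                self.alt_allele_fraction = self.alt_read_count / self.read_depth
            else:
                self.alt_allele_fraction = 0.0
        if not 0.0 <= self.alt_allele_fraction <= 1.0:
            raise ValidationError(
                f"alt_allele_fraction {self.alt_allele_fraction} outside [0,1]"
            )
        if (
            self.functional_class == FunctionalClass.SYNONYMOUS
            and self.region_class != RegionClass.EXONIC
        ):
            raise ValidationError("synonymous variants must be exonic")
        self.gene_symbol = self.gene_symbol.strip().upper()

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class SampleDescriptor:
    sample_id: str
    sample_type: SampleType = SampleType.CELL_LINE


@dataclass
class Cohort:
    """Samples, their variant calls, and the capture-design size in Mb."""

    samples: list[SampleDescriptor]
    variants: list[VariantCall]
    target_size_mb: float = 150.0

    def __post_init__(self) -> None:
        if self.target_size_mb <= 0:
            raise ValidationError("target_size_mb must be positive")
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate sample_id in cohort")
        known = set(ids)
        for v in self.variants:
            if v.sample_id not in known:
                raise ValidationError(
                    f"variant sample_id {v.sample_id!r} not among cohort samples"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def cell_line_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.sample_type == SampleType.CELL_LINE]

    def sample_type_of(self, sample_id: str) -> SampleType:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.sample_type
        raise KeyError(sample_id)

    def by_sample(self) -> dict[str, list[VariantCall]]:
        out: dict[str, list[VariantCall]] = {sid: [] for sid in self.sample_ids}
        for v in self.variants:
            out[v.sample_id].append(v)
        return out


@dataclass(frozen=True)
class HotspotEntry:
    """A known human hotspot with the codon offset to the query species.

    ``species_codon_offset`` = human position − query-species position, so a
    query variant at protein position ``q`` maps onto human position
    ``q + species_codon_offset``.
    """

    gene_symbol: str
    human_ref_aa: str
    human_position: int
    human_alt_aa: str
    species_codon_offset: int = 0

    def __post_init__(self) -> None:
        if self.human_position < 1:
            raise ValidationError("hotspot position must be >= 1")
        if self.human_ref_aa == self.human_alt_aa:
            raise ValidationError("hotspot ref and alt amino acids must differ")
        object.__setattr__(self, "gene_symbol", self.gene_symbol.strip().upper())


def _norm_symbols(symbols: Iterable[str]) -> set[str]:
    return {s.strip().upper() for s in symbols if s.strip()}


@dataclass
class GeneCatalog:
    """Disease-gene list, role-annotated cancer-gene census, top human
    drivers, and the cross-species hotspot catalog."""

    disease_genes: set[str] = field(default_factory=set)
    census: dict[str, CensusRole] = field(default_factory=dict)
    top_driver_genes: set[str] = field(default_factory=set)
    hotspots: list[HotspotEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.disease_genes = _norm_symbols(self.disease_genes)
        self.census = {g.strip().upper(): r for g, r in self.census.items()}
        self.top_driver_genes = _norm_symbols(self.top_driver_genes)

    def role_of(self, gene: str) -> CensusRole:
        return self.census.get(gene.strip().upper(), CensusRole.UNANNOTATED)

    def in_census(self, gene: str) -> bool:
        return gene.strip().upper() in self.census

    def hotspots_for(self, gene: str) -> list[HotspotEntry]:
        g = gene.strip().upper()
        return [h for h in self.hotspots if h.gene_symbol == g]


@dataclass
class PathogenicityOracle:
    """Table-driven pathogenicity calls keyed by (gene, protein change).

    Deterministic by construction: lookups never mutate state and missing
    entries always yield :attr:`PathogenicityCall.UNKNOWN`.
    """

    calls: dict[tuple[str, str], PathogenicityCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = {
            (g.strip().upper(), normalize_protein_change(p)): c
            for (g, p), c in self.calls.items()
        }

    def call(self, gene: str, protein_change: str) -> PathogenicityCall:
        key = (gene.strip().upper(), normalize_protein_change(protein_change))
        return self.calls.get(key, PathogenicityCall.UNKNOWN)

    def call_variant(self, variant: VariantCall) -> PathogenicityCall:
        return self.call(variant.gene_symbol, variant.protein_change)


def distinct_keys(variants: Iterable[VariantCall]) -> set[VariantKey]:
    return {v.key for v in variants}


def distinct_genes(variants: Iterable[VariantCall]) -> set[str]:
    return {v.gene_symbol for v in variants if v.gene_symbol}
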