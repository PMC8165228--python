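"""Recurrence analysis, driver-list intersections, census role
classification, and oncoplot-style gene × sample summarization."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .cascade import LevelSet
from .errors import ConfigError, ValidationError
from .types import CensusRole, FunctionalClass, GeneCatalog, SampleType, VariantKey


@dataclass(frozen=True)
class VariantRecurrence:
    key: VariantKey
    gene: str
    samples: tuple[str, ...]
    n_samples: int


@dataclass(frozen=True)
class GeneRecurrence:
    gene: str
    samples: tuple[str, ...]
    n_samples: int


@dataclass
class RecurrenceTable:
    """Variant- and gene-level recurrence records, sorted by descending
    sample count then key. Gene-level counts are unions over the gene's
    variants, so a gene can be recurrent even when none of its individual
    variants is."""

    variant_records: list[VariantRecurrence]
    gene_records: list[GeneRecurrence]
    min_samples: int = 3

    @property
    def recurrent_variants(self) -> list[VariantRecurrence]:
        return [r for r in self.variant_records if r.n_samples >= self.min_samples]

    @property
    def recurrent_genes(self) -> list[GeneRecurrence]:
        return [r for r in self.gene_records if r.n_samples >= self.min_samples]

    @property
    def recurrent_variant_genes(self) -> set[str]:
        """Genes of recurrent *variants* ("recurrent variants collapsed to
        genes") — generally smaller than ``recurrent_genes``."""
        return {r.gene for r in self.recurrent_variants if r.gene}


def recurrence_table(
    l2: LevelSet, min_samples: int = 3, *, count_ffpe: bool = False
) -> RecurrenceTable:
    """Sample-wise recurrence at variant and gene level.

    Counts distinct samples per variant key / per gene; FFPE samples are
    excluded from the counts by default (recurrence is defined across the
    cell-line panel).
    """
    if l2.level != "L2":
        raise ValidationError(f"recurrence_table expects an L2 set, got {l2.level}")
    if min_samples < 1:
        raise ConfigError("min_samples must be >= 1")
    allowed = {
        s.sample_id for s in l2.samples
        if count_ffpe or s.sample_type == SampleType.CELL_LINE
    }
    var_samples: dict[VariantKey, set[str]] = {}
    var_gene: dict[VariantKey, str] = {}
    gene_samples: dict[str, set[str]] = {}
    for v in l2.variants:
        if v.sample_id not in allowed:
            continue
        var_samples.setdefault(v.key, set()).add(v.sample_id)
        var_gene.setdefault(v.key, v.gene_symbol)
        if v.gene_symbol:
            gene_samples.setdefault(v.gene_symbol, set()).add(v.sample_id)
    variant_records = sorted(
        (
            VariantRecurrence(key=k, gene=var_gene[k],
                              samples=tuple(sorted(s)), n_samples=len(s))
            for k, s in var_samples.items()
        ),
        key=lambda r: (-r.n_samples, r.key),
    )
    gene_records = sorted(
        (
            GeneRecurrence(gene=g, samples=tuple(sorted(s)), n_samples=len(s))
            for g, s in gene_samples.items()
        ),
        key=lambda r: (-r.n_samples, r.gene),
    )
    return RecurrenceTable(variant_records=variant_records,
                           gene_records=gene_records, min_samples=min_samples)


@dataclass
class OverlapReport:
    intersection: set[str]
    size: int
    provenance: dict[str, tuple[bool, bool]]  # gene -> (in query, in catalog list)


def intersect_driver_lists(genes: Iterable[str], catalog_list: Iterable[str]) -> OverlapReport:
    """Symbol-normalized intersection of a gene set with a catalog list,
    with per-gene membership provenance."""
    a = {g.strip().upper() for g in genes if g.strip()}
    b = {g.strip().upper() for g in catalog_list if g.strip()}
    inter = a & b
    return OverlapReport(
        intersection=inter,
        size=len(inter),
        provenance={g: (g in a, g in b) for g in sorted(a | b)},
    )


@dataclass
class RolePartition:
    """Exhaustive one-role-per-gene partition; counts sum to the number of
    input genes."""

    counts: dict[CensusRole, int]
    assignments: dict[str, CensusRole]

    @property
    def n_annotated(self) -> int:
        return sum(k for r, k in self.counts.items() if r != CensusRole.UNANNOTATED)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def classify_roles(genes: Iterable[str], catalog: GeneCatalog) -> RolePartition:
    """Assign each gene exactly one census role (or unannotated)."""
    assignments = {
        g.strip().upper(): catalog.role_of(g) for g in genes if g.strip()
    }
    counts = {r: 0 for r in CensusRole}
    for role in assignments.values():
        counts[role] += 1
    return RolePartition(counts=counts, assignments=assignments)


@dataclass
class OncoplotMatrix:
    """Gene × sample mutation-presence matrix; each cell is the set of
    functional classes observed (empty = wild-type). Rows are ordered by
    mutational incidence (samples hit, descending) then symbol."""

    genes: list[str]
    samples: list[str]
    cells: dict[tuple[str, str], frozenset[FunctionalClass]]

    def cell(self, gene: str, sample: str) -> frozenset[FunctionalClass]:
        return self.cells.get((gene.strip().upper(), sample), frozenset())

    def incidence(self, gene: str) -> int:
        g = gene.strip().upper()
        return sum(1 for s in self.samples if self.cells.get((g, s)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                [",".join(sorted(c.value for c in self.cell(g, s))) for s in self.samples]
                for g in self.genes
            ],
            index=self.genes,
            columns=self.samples,
        )


def oncoplot_matrix(
    levelset: LevelSet, gene_subset: Iterable[str], *, include_ffpe: bool = False
) -> OncoplotMatrix:
    """Build the oncoplot matrix for ``gene_subset`` over the level set's
    samples (cell lines only by default). Genes without variants get
    all-empty (wild-type) rows."""
    genes = sorted({g.strip().upper() for g in gene_subset if g.strip()})
    samples = [
        s.sample_id for s in levelset.samples
        if include_ffpe or s.sample_type == SampleType.CELL_LINE
    ]
    accum: dict[tuple[str, str], set[FunctionalClass]] = {}
    wanted = set(genes)
    for v in levelset.variants:
        if v.gene_symbol in wanted and v.sample_id in set(samples):
            accum.setdefault((v.gene_symbol, v.sample_id), set()).add(v.functional_class)
    cells = {k: frozenset(s) for k, s in accum.items()}
    matrix = OncoplotMatrix(genes=genes, samples=samples, cells=cells)
    matrix.genes = sorted(genes, key=lambda g: (-matrix.incidence(g), g))
    return matrix
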