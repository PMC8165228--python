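"""Synthetic data generators emulating the study conditions.

The cohort generator produces an annotated somatic-variant cohort with the
statistical structure the analysis assumes: eight cell lines (plus an
optional FFPE tumor/normal pair), a missense-dominated mutation-type
mixture, a C>T-dominant SNV spectrum, germline/artifact contamination
(known-SNP and panel-of-normals flags), variants constructed to fail each
Level-1 quality criterion, planted recurrent variant keys, and planted
driver mutations including the canine TP53 E273K hotspot. Pass/fail status
is constructed (depths and alt counts assigned directly), not sampled, so
filter tests are exact; every planting is recorded in a ground-truth
record.

The expression generator draws negative-binomial counts with planted
fold-changes (defaults mirror the profiled aberrations: 9x MDM2 and
5.5x MDM4 in D17/D22, 19x MET in D17/D22, MDM2 depleted in the TP53-mutant
line, and elevated MAPK/ERK pathway genes).

``table1_fixture`` transcribes the published driver-variant table (eight
genes, 21 variants across eight cell lines and the FFPE tumor) with
functional classes inferred from the cDNA HGVS syntax.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .expression import ExpressionMatrix
from .types import (
    CensusRole,
    Cohort,
    FunctionalClass,
    GeneCatalog,
    HotspotEntry,
    PathogenicityCall,
    PathogenicityOracle,
    RegionClass,
    SampleDescriptor,
    SampleType,
    VariantCall,
    VariantKey,
)

CELL_LINE_NAMES = ("Penny", "Wall", "Sky", "Desmond", "Pedro", "D17", "D22", "Lord")
FFPE_TUMOR_NAME = "Wall-FFPE"
FFPE_NORMAL_NAME = "Wall-FFPE-Normal"

DEFAULT_TYPE_WEIGHTS: dict[FunctionalClass, float] = {
    FunctionalClass.MISSENSE: 0.387,
    FunctionalClass.FRAMESHIFT_INSERTION: 0.158,
    FunctionalClass.FRAMESHIFT_DELETION: 0.125,
    FunctionalClass.SYNONYMOUS: 0.196,
    FunctionalClass.STOPGAIN: 0.050,
    FunctionalClass.STOPLOSS: 0.010,
    FunctionalClass.NONFRAMESHIFT_INSERTION: 0.030,
    FunctionalClass.NONFRAMESHIFT_DELETION: 0.030,
    FunctionalClass.UNKNOWN: 0.014,
}

DEFAULT_SPECTRUM_WEIGHTS: dict[str, float] = {
    "C>A": 0.10, "C>G": 0.08, "C>T": 0.45, "T>A": 0.08, "T>C": 0.20, "T>G": 0.09,
}

MECHANISM_PANEL = ("TP53", "MDM2", "MDM4", "MET", "MAPK1", "MAP2K1",
                   "MAP2K2", "MYC")

_AA = "ACDEFGHIKLMNPQRSTVWY"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_NUC = "ACGT"


@dataclass(frozen=True)
class PlantedDriver:
    gene: str
    protein_change: str
    samples: tuple[str, ...]
    region_class: RegionClass = RegionClass.EXONIC


@dataclass
class CohortSimConfig:
    n_cell_lines: int = 8
    include_ffpe_pair: bool = True
    variants_per_sample: int = 1444
    type_weights: dict[FunctionalClass, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS))
    spectrum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM_WEIGHTS))
    known_snp_rate: float = 0.10
    pon_rate: float = 0.05
    sub_threshold_rate: float = 0.10
    utr_splice_rate: float = 0.03
    n_recurrent_variants: int = 234
    recurrence_sample_range: tuple[int, int] = (3, 8)
    planted_drivers: list[PlantedDriver] = field(default_factory=lambda: [
        PlantedDriver("TP53", "p.E273K", ("Wall", FFPE_TUMOR_NAME)),
    ])
    deleterious_missense_rate: float = 0.505
    n_background_genes: int = 4500
    target_size_mb: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cell_lines < 1 or self.n_cell_lines > len(CELL_LINE_NAMES):
            raise ConfigError(
                f"n_cell_lines must be in [1, {len(CELL_LINE_NAMES)}]")
        for name, w in (("type_weights", self.type_weights),
                        ("spectrum_weights", self.spectrum_weights)):
            total = sum(w.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {total})")
        for name, r in (("known_snp_rate", self.known_snp_rate),
                        ("pon_rate", self.pon_rate),
                        ("sub_threshold_rate", self.sub_threshold_rate),
                        ("utr_splice_rate", self.utr_splice_rate),
                        ("deleterious_missense_rate", self.deleterious_missense_rate)):
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{name} must be in [0,1]")
        lo, hi = self.recurrence_sample_range
        if not (1 <= lo <= hi <= self.n_cell_lines):
            raise ConfigError(
                f"recurrence_sample_range {self.recurrence_sample_range} exceeds "
                f"the {self.n_cell_lines} cell lines")
        names = set(self.cell_lines)
        if self.include_ffpe_pair:
            names |= {FFPE_TUMOR_NAME, FFPE_NORMAL_NAME}
        for d in self.planted_drivers:
            for s in d.samples:
                if s not in names:
                    raise ConfigError(f"planted driver sample {s!r} not in cohort")
        if self.variants_per_sample < 1:
            raise ConfigError("variants_per_sample must be >= 1")

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return CELL_LINE_NAMES[: self.n_cell_lines]


@dataclass
class PlantedRecurrent:
    key: VariantKey
    gene: str
    protein_change: str
    samples: tuple[str, ...]


@dataclass
class Level1Failure:
    sample_id: str
    key: VariantKey
    criterion: str  # depth | alt_count | alt_fraction | known_snp | pon


@dataclass
class GroundTruth:
    """Bookkeeping of everything the generator planted."""

    recurrent: list[PlantedRecurrent] = field(default_factory=list)
    drivers: list[tuple[PlantedDriver, VariantKey]] = field(default_factory=list)
    level1_failures: list[Level1Failure] = field(default_factory=list)
    utr_census: list[tuple[str, VariantKey, str]] = field(default_factory=list)
    utr_noncensus: list[tuple[str, VariantKey, str]] = field(default_factory=list)
    passing_per_sample: dict[str, int] = field(default_factory=dict)
    type_counts: dict[FunctionalClass, int] = field(default_factory=dict)
    spectrum_counts: dict[str, int] = field(default_factory=dict)


def default_gene_catalog() -> GeneCatalog:
    """Deterministic catalog fixture: a role census partitioned into
    28 fusion / 74 tumor-suppressor / 63 oncogene / 25 dual-role genes
    (190 total, real symbols where the study names them and synthetic
    fillers elsewhere), a partial 27-gene osteosarcoma disease list, a
    top-20 human pan-cancer driver list, and the TP53 cross-species
    hotspot (canine 273 ↔ human 285, codon offset +12)."""
    tsg_real = ["TP53", "PTCH1", "LRP1B", "ARID1A", "TET2", "WRN", "NF1", "APC"]
    onc_real = ["PIK3CA", "MED12", "NFATC2", "KRAS", "ALK", "MET", "MYC",
                "MDM2", "MDM4", "PDGFRB"]
    census: dict[str, CensusRole] = {}
    for g in tsg_real:
        census[g] = CensusRole.TUMOR_SUPPRESSOR
    for i in range(74 - len(tsg_real)):
        census[f"CGT{i:03d}"] = CensusRole.TUMOR_SUPPRESSOR
    for g in onc_real:
        census[g] = CensusRole.ONCOGENE
    for i in range(63 - len(onc_real)):
        census[f"CGO{i:03d}"] = CensusRole.ONCOGENE
    for i in range(28):
        census[f"CGF{i:03d}"] = CensusRole.FUSION
    for i in range(25):
        census[f"CGB{i:03d}"] = CensusRole.ONCOGENE_AND_TSG

    # partial disease list: the named osteosarcoma-associated genes plus
    # synthetic fillers up to the catalog size of 27
    disease_named = ["PDGFRB", "PTCH1", "WRN", "TP53", "ALK", "MYC", "MET",
                     "PIK3CA", "KRAS", "APC", "NF1"]
    disease = set(disease_named) | {f"OSD{i:02d}" for i in range(27 - len(disease_named))}

    top20 = {
        "PIK3CA", "KRAS", "APC", "NF1", "PTEN", "IDH1", "BRAF", "EGFR",
        "CDKN2A", "RB1", "SMAD4", "FBXW7", "ATM", "CTNNB1", "NRAS", "ATRX",
        "CIC", "VHL", "KMT2D", "ARID1B",
    }
    hotspots = [HotspotEntry("TP53", "E", 285, "K", species_codon_offset=12)]
    return GeneCatalog(disease_genes=disease, census=census,
                       top_driver_genes=top20, hotspots=hotspots)


class _Loci:
    """Collision-free position allocator over a simple gene model."""

    def __init__(self, genes: Sequence[str], rng: np.random.Generator,
                 window: int = 250_000):
        self.window = window
        self.rng = rng
        self.base: dict[str, tuple[str, int]] = {}
        for i, g in enumerate(genes):
            self.base[g] = (f"chr{(i % 38) + 1}", 100_000 + (i // 38) * 300_000)
        self.used: dict[str, set[int]] = {}

    def locus(self, gene: str) -> tuple[str, int]:
        if gene not in self.base:
            # genes outside the pre-registered model (e.g. planted drivers)
            i = len(self.base)
            self.base[gene] = (f"chr{(i % 38) + 1}", 100_000 + (i // 38) * 300_000)
        chrom, base = self.base[gene]
        used = self.used.setdefault(gene, set())
        while True:
            off = int(self.rng.integers(0, self.window))
            if off not in used:
                used.add(off)
                return chrom, base + off


def _snv_alleles(rng: np.random.Generator, spectrum: dict[str, float]) -> tuple[str, str]:
    classes = sorted(spectrum)
    probs = np.array([spectrum[c] for c in classes])
    cls = classes[int(rng.choice(len(classes), p=probs / probs.sum()))]
    ref, alt = cls[0], cls[2]
    if rng.random() < 0.5:  # present on the purine strand half the time
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt


def _indel_alleles(rng: np.random.Generator, kind: FunctionalClass) -> tuple[str, str]:
    frameshift = kind in (FunctionalClass.FRAMESHIFT_INSERTION,
                          FunctionalClass.FRAMESHIFT_DELETION)
    length = int(rng.choice([1, 2, 4, 5, 7, 8] if frameshift else [3, 6, 9]))
    anchor = _NUC[int(rng.integers(0, 4))]
    seq = "".join(_NUC[int(rng.integers(0, 4))] for _ in range(length))
    if kind in (FunctionalClass.FRAMESHIFT_INSERTION, FunctionalClass.NONFRAMESHIFT_INSERTION):
        return anchor, anchor + seq
    return anchor + seq, anchor


def _passing_depth(rng: np.random.Generator) -> tuple[int, int]:
    depth = int(rng.integers(30, 201))
    frac = rng.uniform(0.15, 0.9)
    alt = min(depth, max(2, int(round(frac * depth))))
    return depth, alt


def _protein_sub(rng: np.random.Generator, kind: FunctionalClass) -> str:
    pos = int(rng.integers(1, 901))
    ref = _AA[int(rng.integers(0, 20))]
    if kind == FunctionalClass.STOPGAIN:
        return f"p.{ref}{pos}*"
    if kind == FunctionalClass.STOPLOSS:
        return f"p.*{pos}{ref}"
    alt = ref
    while alt == ref:
        alt = _AA[int(rng.integers(0, 20))]
    return f"p.{ref}{pos}{alt}"


_SNV_CLASSES = {FunctionalClass.MISSENSE, FunctionalClass.SYNONYMOUS,
                FunctionalClass.STOPGAIN, FunctionalClass.STOPLOSS,
                FunctionalClass.UNKNOWN}


def generate_variant_cohort(
    cfg: CohortSimConfig, catalog: GeneCatalog | None = None
) -> tuple[Cohort, PathogenicityOracle, GroundTruth]:
    """Generate a cohort, a consistent pathogenicity oracle, and the
    ground-truth record of every planting. Reproducible given the seed."""
    cfg.validate()
    if catalog is None:
        catalog = default_gene_catalog()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth(
        type_counts={c: 0 for c in FunctionalClass},
        spectrum_counts={c: 0 for c in DEFAULT_SPECTRUM_WEIGHTS},
    )

    background = [f"SG{i:05d}" for i in range(cfg.n_background_genes)]
    # the mutation-expression panel genes only ever mutate when explicitly
    # planted, so generated cohorts have controlled wild-type status
    census_genes = sorted(set(catalog.census) - set(MECHANISM_PANEL))
    gene_pool = background + census_genes
    loci = _Loci(gene_pool, rng)

    samples = [SampleDescriptor(s, SampleType.CELL_LINE) for s in cfg.cell_lines]
    if cfg.include_ffpe_pair:
        samples.append(SampleDescriptor(FFPE_TUMOR_NAME, SampleType.FFPE_TUMOR))
        samples.append(SampleDescriptor(FFPE_NORMAL_NAME, SampleType.FFPE_NORMAL))

    # --- planted recurrent keys (missense, shared genomic key across samples)
    planted_by_sample: dict[str, list[dict]] = {s.sample_id: [] for s in samples}
    lo, hi = cfg.recurrence_sample_range
    for _ in range(cfg.n_recurrent_variants):
        gene = background[int(rng.integers(0, len(background)))]
        chrom, pos = loci.locus(gene)
        ref, alt = _snv_alleles(rng, cfg.spectrum_weights)
        pchg = _protein_sub(rng, FunctionalClass.MISSENSE)
        k = int(rng.integers(lo, hi + 1))
        chosen = tuple(sorted(rng.choice(list(cfg.cell_lines), size=k, replace=False)))
        key: VariantKey = (chrom, pos, ref, alt)
        truth.recurrent.append(PlantedRecurrent(key, gene, pchg, chosen))
        for s in chosen:
            planted_by_sample[s].append(dict(
                gene=gene, key=key, fclass=FunctionalClass.MISSENSE,
                pchg=pchg, region=RegionClass.EXONIC, forced=False))

    # --- planted drivers (identical key across their samples)
    for d in cfg.planted_drivers:
        gene = d.gene.strip().upper()
        chrom, pos = loci.locus(gene)
        ref, alt = _snv_alleles(rng, cfg.spectrum_weights)
        key = (chrom, pos, ref, alt)
        fclass = (FunctionalClass.MISSENSE if d.region_class == RegionClass.EXONIC
                  else FunctionalClass.UNKNOWN)
        truth.drivers.append((d, key))
        for s in d.samples:
            planted_by_sample[s].append(dict(
                gene=gene, key=key, fclass=fclass,
                pchg=d.protein_change, region=d.region_class, forced=True))

    missense_pairs: dict[tuple[str, str], bool] = {}  # (gene, pchg) -> forced deleterious

    def register_missense(gene: str, pchg: str, forced: bool = False) -> None:
        prev = missense_pairs.get((gene, pchg))
        missense_pairs[(gene, pchg)] = bool(prev) or forced

    variants: list[VariantCall] = []

    def emit(sample: str, gene: str, key: VariantKey, fclass: FunctionalClass,
             region: RegionClass, pchg: str, depth: int, alt_count: int,
             known_snp: bool = False, pon: bool = False) -> VariantCall:
        chrom, pos, ref, alt = key
        v = VariantCall(
            sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
            read_depth=depth, alt_read_count=alt_count,
            region_class=region, functional_class=fclass, gene_symbol=gene,
            protein_change=pchg, is_known_snp=known_snp, in_pon=pon,
        )
        variants.append(v)
        return v

    def tally(fclass: FunctionalClass, ref: str, alt: str) -> None:
        truth.type_counts[fclass] += 1
        if len(ref) == 1 and len(alt) == 1:
            r, a = (ref, alt) if ref in "CT" else (_COMPLEMENT[ref], _COMPLEMENT[alt])
            truth.spectrum_counts[f"{r}>{a}"] += 1

    classes = list(cfg.type_weights)
    weights = np.array([cfg.type_weights[c] for c in classes])
    weights = weights / weights.sum()
    mis_idx = classes.index(FunctionalClass.MISSENSE)

    tumor_samples = [s.sample_id for s in samples if s.sample_type != SampleType.FFPE_NORMAL]
    for sid in tumor_samples:
        planted = planted_by_sample[sid]
        if len(planted) > cfg.variants_per_sample:
            raise ConfigError(
                f"sample {sid}: {len(planted)} planted variants exceed "
                f"variants_per_sample={cfg.variants_per_sample}")
        for p in planted:
            depth, alt_count = _passing_depth(rng)
            emit(sid, p["gene"], p["key"], p["fclass"], p["region"], p["pchg"],
                 depth, alt_count)
            tally(p["fclass"], p["key"][2], p["key"][3])
            if p["fclass"] == FunctionalClass.MISSENSE:
                # only driver plantings pin the oracle; recurrent variants
                # draw their pathogenicity at the configured rate
                register_missense(p["gene"], p["pchg"], forced=p["forced"])

        # fill to the per-sample budget, debiting planted missense from the
        # multinomial draw so the realised mixture matches the weights
        n_fill = cfg.variants_per_sample - len(planted)
        counts = rng.multinomial(cfg.variants_per_sample, weights)
        counts[mis_idx] -= len(planted)
        while counts.min() < 0:
            j = int(np.argmin(counts))
            deficit = -counts[j]
            counts[j] = 0
            counts[int(np.argmax(counts))] -= deficit
        assert counts.sum() == n_fill
        for fclass, n_cls in zip(classes, counts):
            for _ in range(int(n_cls)):
                gene = gene_pool[int(rng.integers(0, len(gene_pool)))]
                chrom, pos = loci.locus(gene)
                if fclass in _SNV_CLASSES:
                    ref, alt = _snv_alleles(rng, cfg.spectrum_weights)
                else:
                    ref, alt = _indel_alleles(rng, fclass)
                pchg = ""
                if fclass in (FunctionalClass.MISSENSE, FunctionalClass.STOPGAIN,
                              FunctionalClass.STOPLOSS):
                    pchg = _protein_sub(rng, fclass)
                depth, alt_count = _passing_depth(rng)
                emit(sid, gene, (chrom, pos, ref, alt), fclass,
                     RegionClass.EXONIC, pchg, depth, alt_count)
                tally(fclass, ref, alt)
                if fclass == FunctionalClass.MISSENSE:
                    register_missense(gene, pchg)
        truth.passing_per_sample[sid] = cfg.variants_per_sample

        # guaranteed Level-1 failures
        def _fail_variant(criterion: str) -> None:
            gene = background[int(rng.integers(0, len(background)))]
            chrom, pos = loci.locus(gene)
            ref, alt = _snv_alleles(rng, cfg.spectrum_weights)
            known = pon = False
            if criterion == "depth":
                depth = int(rng.integers(5, 11))           # <= 10: fails depth only
                alt_count = int(rng.integers(2, depth + 1))
            elif criterion == "alt_count":
                depth = int(rng.integers(11, 20))          # 1/depth >= 0.052
                alt_count = 1
            elif criterion == "alt_fraction":
                depth = int(rng.integers(80, 201))         # 2/depth <= 0.025
                alt_count = 2
            else:
                depth, alt_count = _passing_depth(rng)
                known = criterion == "known_snp"
                pon = criterion == "pon"
            key = (chrom, pos, ref, alt)
            emit(sid, gene, key, FunctionalClass.MISSENSE, RegionClass.EXONIC,
                 "", depth, alt_count, known_snp=known, pon=pon)
            truth.level1_failures.append(Level1Failure(sid, key, criterion))

        for _ in range(int(round(cfg.known_snp_rate * cfg.variants_per_sample))):
            _fail_variant("known_snp")
        for _ in range(int(round(cfg.pon_rate * cfg.variants_per_sample))):
            _fail_variant("pon")
        n_sub = int(round(cfg.sub_threshold_rate * cfg.variants_per_sample))
        for i in range(n_sub):
            _fail_variant(("depth", "alt_count", "alt_fraction")[i % 3])

        # quality-passing utr5/splice variants (Level-3 rescue side channel)
        n_utr = int(round(cfg.utr_splice_rate * cfg.variants_per_sample))
        for i in range(n_utr):
            in_census = i % 2 == 0
            pool = census_genes if in_census else background
            gene = pool[int(rng.integers(0, len(pool)))]
            chrom, pos = loci.locus(gene)
            ref, alt = _snv_alleles(rng, cfg.spectrum_weights)
            region = RegionClass.UTR5 if i % 4 < 2 else RegionClass.SPLICE
            depth, alt_count = _passing_depth(rng)
            key = (chrom, pos, ref, alt)
            emit(sid, gene, key, FunctionalClass.UNKNOWN, region, "",
                 depth, alt_count)
            (truth.utr_census if in_census else truth.utr_noncensus).append(
                (sid, key, gene))

    if cfg.include_ffpe_pair:
        # the normal tissue contributes only a few blacklist artifacts
        for _ in range(max(1, cfg.variants_per_sample // 100)):
            gene = background[int(rng.integers(0, len(background)))]
            chrom, pos = loci.locus(gene)
            ref, alt = _snv_alleles(rng, cfg.spectrum_weights)
            depth, alt_count = _passing_depth(rng)
            key = (chrom, pos, ref, alt)
            emit(FFPE_NORMAL_NAME, gene, key, FunctionalClass.MISSENSE,
                 RegionClass.EXONIC, "", depth, alt_count, pon=True)
            truth.level1_failures.append(Level1Failure(FFPE_NORMAL_NAME, key, "pon"))

    oracle_calls = {}
    for (gene, pchg), forced in missense_pairs.items():
        if forced or rng.random() < cfg.deleterious_missense_rate:
            oracle_calls[(gene, pchg)] = PathogenicityCall.DELETERIOUS
        else:
            oracle_calls[(gene, pchg)] = PathogenicityCall.NEUTRAL
    oracle = PathogenicityOracle(calls=oracle_calls)

    cohort = Cohort(samples=samples, variants=variants,
                    target_size_mb=cfg.target_size_mb)
    return cohort, oracle, truth


# --------------------------------------------------------------------------
# expression counts

DEFAULT_EXPR_SAMPLES = ("Penny", "Wall", "Desmond", "Sky", "D17", "D22")

DEFAULT_PLANTED_FOLDS: tuple[tuple[str, str, float], ...] = (
    ("MDM2", "D17", 9.0), ("MDM2", "D22", 9.0),
    ("MDM4", "D17", 5.5), ("MDM4", "D22", 5.5),
    ("MET", "D17", 19.0), ("MET", "D22", 19.0),
    ("MDM2", "Wall", 0.2),
    ("TP53", "Wall", 2.0), ("TP53", "D17", 2.0), ("TP53", "D22", 2.0),
    ("MAPK1", "D17", 2.5), ("MAPK1", "D22", 2.5),
    ("MAP2K1", "D17", 2.5), ("MAP2K1", "D22", 2.5),
    ("MYC", "D17", 2.0), ("MYC", "D22", 2.0),
)

FOCUS_GENES = ("TP53", "MDM2", "MDM4", "MET", "MAPK1", "MAP2K1", "MYC",
               "PTCH1", "MED12", "PDGFRB", "PIK3CA")


@dataclass
class ExprSimConfig:
    n_genes: int = 2000
    samples: tuple[str, ...] = DEFAULT_EXPR_SAMPLES
    base_mean: float = 200.0
    focus_mean: float = 2000.0
    dispersion: float = 0.005
    depth_factors: tuple[float, ...] | None = None
    planted_fold_changes: tuple[tuple[str, str, float], ...] = DEFAULT_PLANTED_FOLDS
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.base_mean <= 0 or self.focus_mean <= 0:
            raise ConfigError("n_genes and means must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.depth_factors is not None and len(self.depth_factors) != len(self.samples):
            raise ConfigError("depth_factors must match the number of samples")
        known = set(self.samples)
        for gene, sample, fold in self.planted_fold_changes:
            if fold <= 0:
                raise ConfigError(f"planted fold for {gene} must be positive")
            if sample not in known:
                raise ConfigError(f"planted fold sample {sample!r} not in samples")


@dataclass
class ExprGroundTruth:
    true_folds: dict[tuple[str, str], float]
    gene_means: dict[str, float]
    depth_factors: dict[str, float]


def generate_expression_counts(
    cfg: ExprSimConfig,
) -> tuple[ExpressionMatrix, ExprGroundTruth]:
    """Negative-binomial counts with planted multiplicative fold-changes.

    Focus genes (the mutation-expression integration panel) get a high
    fixed baseline mean so planted folds are recoverable within sampling
    noise; background genes draw log-normal baseline means.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = list(FOCUS_GENES) + [f"BG{i:05d}" for i in range(cfg.n_genes)]
    means = np.concatenate([
        np.full(len(FOCUS_GENES), cfg.focus_mean),
        np.exp(rng.normal(np.log(cfg.base_mean), 1.2, size=cfg.n_genes)),
    ])
    depth = (np.array(cfg.depth_factors) if cfg.depth_factors is not None
             else np.ones(len(cfg.samples)))
    fold = np.ones((len(genes), len(cfg.samples)))
    gene_index = {g: i for i, g in enumerate(genes)}
    true_folds = {}
    for gene, sample, f in cfg.planted_fold_changes:
        g = gene.strip().upper()
        if g not in gene_index:
            raise ConfigError(f"planted fold gene {g!r} not in the gene model")
        fold[gene_index[g], cfg.samples.index(sample)] = f
        true_folds[(g, sample)] = f
    mu = means[:, None] * fold * depth[None, :]
    r = 1.0 / cfg.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts.astype(int), index=genes, columns=list(cfg.samples)))
    truth = ExprGroundTruth(
        true_folds=true_folds,
        gene_means={g: float(m) for g, m in zip(genes, means)},
        depth_factors={s: float(d) for s, d in zip(cfg.samples, depth)},
    )
    return matrix, truth


# --------------------------------------------------------------------------
# published driver-table fixture

# (gene, cDNA change [verbatim, typos preserved], samples carrying it);
# sample order: Penny, Wall, Sky, Desmond, Pedro, D17, D22, Lord, Wall-FFPE
_TABLE1_ROWS: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("PTCH1", "c.17A>G", ("Lord",)),
    ("PTCH1", "c.3850C>T", ("Penny",)),
    ("PTCH1", "c.4014insT", ("Wall", FFPE_TUMOR_NAME)),
    ("PTCH1", "c.4023delA", ("Wall", FFPE_TUMOR_NAME)),
    ("PTCH1", "c.4200_4201insAGTCCCCG", ("Wall", "Desmond", FFPE_TUMOR_NAME)),
    ("PTCH1", "c.4203_4210del", ("Wall", "Desmond", FFPE_TUMOR_NAME)),
    ("LRP1B", "c.12056A>T", ("Desmond",)),
    ("LRP1B", "c.3112A>C", ("D22",)),
    ("LRP1B", "c.3105_3106insATTGGGCCTGTGATGGTGA", ("D22",)),
    ("ARID1A", "c.6276A>T", ("Wall", FFPE_TUMOR_NAME)),
    ("ARID1A", "c.4863_4862insCCCCCCA", ("Sky",)),
    ("ARID1A", "c.4858_4852del", ("Sky",)),
    ("ARID1A", "c.1877G>A", ("Pedro",)),
    ("NFATC2", "c.510G>A", ("Pedro",)),
    ("TET2", "c.1349G>C", ("D17",)),
    ("TET2", "c.2817_2818insCTGTGACTTCCTCCCTGGTCAGACA", ("D17",)),
    ("TET2", "c.2894_2897del", ("Pedro",)),
    ("PIK3CA", "c.2217G>T", ("D17", "D22")),
    ("TP53", "c.818C>T", ("Wall", FFPE_TUMOR_NAME)),
    ("MED12", "c.2089_2090insATGGACTGCCCTTCCCCTCAC", ("Desmond",)),
    ("MED12", "c.2581G>A", ("D17", "D22")),
)

# protein changes are not printed in the table; the text states it for the
# TP53 hotspot only, so the fixture carries no invented annotations
_TABLE1_PROTEIN = {("TP53", "c.818C>T"): "p.E273K"}

_TABLE1_LOCI = {
    "PTCH1": ("chr11", 1_000_000),
    "LRP1B": ("chr37", 2_000_000),
    "ARID1A": ("chr2", 3_000_000),
    "NFATC2": ("chr24", 4_000_000),
    "TET2": ("chr19", 5_000_000),
    "PIK3CA": ("chr34", 6_000_000),
    "TP53": ("chr5", 7_000_000),
    "MED12": ("chrX", 8_000_000),
}

_SNV_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_INS_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?ins([ACGT]+)$")
_DEL_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGT]*)$")


def classify_cdna(cdna: str) -> tuple[int, str, str, FunctionalClass]:
    """Infer (cDNA position, ref, alt, functional class) from a cDNA HGVS
    string: substitutions default to missense; ins/del are frameshift or
    non-frameshift by length mod 3. Reversed deletion coordinates (a known
    table typo) are interpreted by absolute span."""
    m = _SNV_RE.match(cdna)
    if m:
        return int(m.group(1)), m.group(2), m.group(3), FunctionalClass.MISSENSE
    m = _INS_RE.match(cdna)
    if m:
        seq = m.group(3)
        fclass = (FunctionalClass.NONFRAMESHIFT_INSERTION if len(seq) % 3 == 0
                  else FunctionalClass.FRAMESHIFT_INSERTION)
        return int(m.group(1)), "A", "A" + seq, fclass
    m = _DEL_RE.match(cdna)
    if m:
        a = int(m.group(1))
        b = int(m.group(2)) if m.group(2) else a
        span = abs(b - a) + 1
        fclass = (FunctionalClass.NONFRAMESHIFT_DELETION if span % 3 == 0
                  else FunctionalClass.FRAMESHIFT_DELETION)
        return min(a, b), "A" + "G" * span, "A", fclass
    raise ValueError(f"unrecognised cDNA change {cdna!r}")


def table1_fixture(target_size_mb: float = 150.0) -> Cohort:
    """The published driver table as a Cohort: 21 variants in eight genes
    across eight cell lines and the FFPE tumor. cDNA strings are preserved
    verbatim as identifiers (including apparent typos); depths are nominal
    quality-passing values."""
    samples = [SampleDescriptor(s, SampleType.CELL_LINE) for s in CELL_LINE_NAMES]
    samples.append(SampleDescriptor(FFPE_TUMOR_NAME, SampleType.FFPE_TUMOR))
    variants: list[VariantCall] = []
    for gene, cdna, carriers in _TABLE1_ROWS:
        cpos, ref, alt, fclass = classify_cdna(cdna)
        chrom, base = _TABLE1_LOCI[gene]
        for sid in carriers:
            variants.append(
                VariantCall(
                    sample_id=sid, chrom=chrom, pos=base + cpos, ref=ref, alt=alt,
                    read_depth=120, alt_read_count=60,
                    region_class=RegionClass.EXONIC, functional_class=fclass,
                    gene_symbol=gene, cdna_change=cdna,
                    protein_change=_TABLE1_PROTEIN.get((gene, cdna), ""),
                )
            )
    return Cohort(samples=samples, variants=variants, target_size_mb=target_size_mb)
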