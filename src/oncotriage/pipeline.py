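"""End-to-end orchestration: config, full analysis, and the run report.

The report mirrors the cascade bookkeeping (variant/gene counts per level),
the landscape statistics, recurrence and role summaries, hotspot matches,
and — when a count matrix is supplied — the expression fold-change profiles
and mechanism flags. All thresholds are recorded for provenance, and a
config hash makes reruns comparable.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .cascade import (
    Level1Params,
    apply_level1,
    apply_level2,
    apply_level3,
    match_hotspots,
)
from .drivers import classify_roles, intersect_driver_lists, oncoplot_matrix, recurrence_table
from .errors import ConfigError
from .expression import (
    ExpressionMatrix,
    MechanismThresholds,
    filter_low_expression,
    flag_mechanisms,
    fold_change_profile,
    normalize,
)
from .io import (
    read_counts,
    read_gene_catalog,
    read_oracle,
    read_variant_table,
    write_variant_table,
)
from .landscape import (
    compute_tmb,
    genes_per_sample,
    mutation_type_distribution,
    pathogenic_fraction,
    snv_spectrum,
)
from .types import Cohort, GeneCatalog, PathogenicityOracle

# genes profiled for the mutation-expression integration panel
EXPRESSION_PANEL = ("TP53", "MDM2", "MDM4", "MET", "MAPK1", "MAP2K1", "MAP2K2",
                    "MYC", "PTCH1", "MED12", "PDGFRB", "PIK3CA")


@dataclass
class PipelineConfig:
    """File-based configuration; in-memory use goes through :func:`analyze`."""

    variant_table: str | None = None
    disease_genes: str | None = None
    census: str | None = None
    hotspots: str | None = None
    top_drivers: str | None = None
    oracle: str | None = None
    counts: str | None = None
    output_dir: str = "triage_out"
    target_size_mb: float = 150.0
    min_alt_count: int = 2
    min_alt_fraction: float = 0.05
    min_depth: int = 10
    exclude_known_snp: bool = True
    exclude_pon: bool = True
    min_recurrence: int = 3
    min_cpm: float = 1.0
    min_cpm_samples: int = 2
    overexpression_fold: float = 2.0
    underexpression_fold: float = 0.5
    downstream_fold: float = 1.5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @property
    def level1_params(self) -> Level1Params:
        return Level1Params(
            min_alt_count=self.min_alt_count,
            min_alt_fraction=self.min_alt_fraction,
            min_depth=self.min_depth,
            exclude_known_snp=self.exclude_known_snp,
            exclude_pon=self.exclude_pon,
        )

    @property
    def mechanism_thresholds(self) -> MechanismThresholds:
        return MechanismThresholds(
            overexpression_fold=self.overexpression_fold,
            underexpression_fold=self.underexpression_fold,
            downstream_fold=self.downstream_fold,
        )

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunReport:
    counts: dict[str, int]
    tmb: dict
    mutation_types: dict
    spectrum: dict
    recurrence: dict
    role_partition: dict
    hotspot_matches: list[dict]
    pathogenic_fractions: dict
    genes_per_sample: dict[str, int]
    driver_overlap: dict
    mechanism_flags: list[dict] = field(default_factory=list)
    fold_changes: dict = field(default_factory=dict)
    version: str = __version__
    config_hash: str = ""
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "tmb": self.tmb,
            "mutation_types": self.mutation_types,
            "spectrum": self.spectrum,
            "recurrence": self.recurrence,
            "role_partition": self.role_partition,
            "hotspot_matches": self.hotspot_matches,
            "pathogenic_fractions": self.pathogenic_fractions,
            "genes_per_sample": self.genes_per_sample,
            "driver_overlap": self.driver_overlap,
            "mechanism_flags": self.mechanism_flags,
            "fold_changes": self.fold_changes,
            "version": self.version,
            "config_hash": self.config_hash,
            "thresholds": self.thresholds,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _fraction_dict(fr) -> dict:
    return {"numerator": fr.numerator, "denominator": fr.denominator,
            "percent": fr.percent, "undefined": fr.undefined}


def analyze(
    cohort: Cohort,
    catalog: GeneCatalog,
    oracle: PathogenicityOracle | None = None,
    *,
    params: Level1Params | None = None,
    min_recurrence: int = 3,
    expression: ExpressionMatrix | None = None,
    min_cpm: float = 1.0,
    min_cpm_samples: int = 2,
    mechanism_thresholds: MechanismThresholds | None = None,
    output_dir: str | Path | None = None,
    config_hash: str = "",
) -> RunReport:
    """Run the full triage analysis on in-memory objects.

    The expression stage is optional (RNA is often available for only part
    of a panel); when a matrix is supplied, it is filtered, TMM-normalized,
    profiled for the integration panel genes, and fed to the mechanism
    rules together with the hotspot matches.
    """
    params = params or Level1Params()
    oracle = oracle or PathogenicityOracle()

    l1 = apply_level1(cohort, params)
    l2 = apply_level2(l1, catalog, min_recurrence)
    l3 = apply_level3(l2, l1.side_channel, catalog)
    scan = match_hotspots(l3, catalog)

    tmb = compute_tmb(l1, cohort)
    types = mutation_type_distribution(l1.variants, scope="per_sample")
    spectrum = snv_spectrum(l1.variants)
    rec = recurrence_table(l2, min_samples=min_recurrence)
    roles = classify_roles(l3.genes, catalog)
    gps = genes_per_sample(l2)
    overlap = intersect_driver_lists(
        l2.genes & catalog.disease_genes, catalog.top_driver_genes)

    fractions = {
        "missense_l1": _fraction_dict(pathogenic_fraction(l1.variants, oracle)),
        "recurrent_snv": _fraction_dict(pathogenic_fraction(
            [v for v in l2.variants
             if l2.recurrence.get(v.key, 0) >= min_recurrence], oracle)),
        "level3_snv": _fraction_dict(pathogenic_fraction(l3.variants, oracle)),
    }

    report = RunReport(
        counts={
            "level1_variants": len(l1),
            "level1_side_channel": len(l1.side_channel),
            "level2_variants": len(l2),
            "level2_genes": len(l2.genes),
            "level3_variants": len(l3),
            "level3_genes": len(l3.genes),
            "noncoding_only_genes": len(l3.noncoding_only_genes),
            "recurrent_variants": len(rec.recurrent_variants),
            "recurrent_genes": len(rec.recurrent_genes),
            "recurrent_variant_genes": len(rec.recurrent_variant_genes),
            "hotspot_matches": len(scan),
        },
        tmb=tmb.summary(),
        mutation_types={
            "pooled_counts": {c.value: k for c, k in types.pooled_counts.items()},
            "mean_proportions": (
                {c.value: round(p, 4) for c, p in types.mean_proportions.items()}
                if types.mean_proportions else None),
        },
        spectrum={"counts": spectrum.counts, "dominant": spectrum.dominant_class,
                  "n_snv": spectrum.n_snv},
        recurrence={
            "min_samples": min_recurrence,
            "variant_level": len(rec.recurrent_variants),
            "gene_level": len(rec.recurrent_genes),
            "collapsed_genes": len(rec.recurrent_variant_genes),
        },
        role_partition={r.value: k for r, k in roles.counts.items()},
        hotspot_matches=[
            {
                "sample_id": m.variant.sample_id,
                "gene": m.hotspot.gene_symbol,
                "protein_change": m.variant.protein_change,
                "query_position": m.query_position,
                "mapped_position": m.mapped_position,
            }
            for m in scan
        ],
        pathogenic_fractions=fractions,
        genes_per_sample=gps,
        driver_overlap={"genes": sorted(overlap.intersection), "size": overlap.size},
        config_hash=config_hash,
        thresholds={
            "min_alt_count": params.min_alt_count,
            "min_alt_fraction": params.min_alt_fraction,
            "min_depth": params.min_depth,
            "min_recurrence": min_recurrence,
        },
    )

    profiles = {}
    if expression is not None:
        filtered = filter_low_expression(expression, min_cpm, min_cpm_samples)
        norm = normalize(filtered)
        for gene in EXPRESSION_PANEL:
            if gene in norm.cpm.index:
                profiles[gene] = fold_change_profile(norm, gene)
        flags = flag_mechanisms(cohort, scan, profiles,
                                mechanism_thresholds, samples=filtered.samples)
        report.mechanism_flags = [
            {"sample_id": f.sample_id, "mechanism": f.mechanism,
             "evidence": [list(e) for e in f.evidence], "complete": f.complete}
            for f in flags
        ]
        report.fold_changes = {
            g: {s: round(fc, 3) for s, fc in p.fold_changes.items()}
            for g, p in profiles.items()
        }

    if output_dir is not None:
        _write_outputs(Path(output_dir), cohort, catalog, l1, l2, l3, tmb,
                       types, spectrum, rec, roles, report, profiles)
    return report


def _write_outputs(outdir, cohort, catalog, l1, l2, l3, tmb, types, spectrum,
                   rec, roles, report, profiles) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, ls in (("level1", l1), ("level2", l2), ("level3", l3)):
        write_variant_table(
            Cohort(samples=list(ls.samples), variants=list(ls.variants),
                   target_size_mb=cohort.target_size_mb),
            outdir / f"{name}.tsv", provenance=ls.provenance)
    pd.DataFrame(
        [{"sample_id": s, "tmb": round(v, 3)} for s, v in tmb.per_sample.items()]
    ).to_csv(outdir / "tmb.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"functional_class": c.value, "count": k}
         for c, k in types.pooled_counts.items()]
    ).to_csv(outdir / "mutation_types.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"class": c, "count": k} for c, k in spectrum.counts.items()]
    ).to_csv(outdir / "spectrum.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"chrom": r.key[0], "pos": r.key[1], "ref": r.key[2], "alt": r.key[3],
          "gene": r.gene, "n_samples": r.n_samples,
          "samples": ",".join(r.samples)} for r in rec.variant_records]
    ).to_csv(outdir / "recurrence_variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene": r.gene, "n_samples": r.n_samples,
          "samples": ",".join(r.samples)} for r in rec.gene_records]
    ).to_csv(outdir / "recurrence_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"role": r.value, "count": k} for r, k in roles.counts.items()]
    ).to_csv(outdir / "role_partition.tsv", sep="\t", index=False)
    # oncoplot over the disease-associated genes hit at Level 2
    onco = oncoplot_matrix(l2, l2.genes & catalog.disease_genes)
    onco.to_frame().to_csv(outdir / "oncoplot.tsv", sep="\t")
    pd.DataFrame(report.hotspot_matches).to_csv(
        outdir / "hotspot_matches.tsv", sep="\t", index=False)
    if profiles:
        pd.DataFrame(
            {g: p.fold_changes for g, p in profiles.items()}
        ).T.to_csv(outdir / "fold_changes.tsv", sep="\t")
    if report.mechanism_flags:
        pd.DataFrame(
            [{"sample_id": f["sample_id"], "mechanism": f["mechanism"],
              "complete": f["complete"]} for f in report.mechanism_flags]
        ).to_csv(outdir / "mechanism_flags.tsv", sep="\t", index=False)
    report.to_json(outdir / "report.json")


def run_full_analysis(cfg: PipelineConfig) -> RunReport:
    """Load every configured input file and run :func:`analyze`."""
    if cfg.variant_table is None:
        raise ConfigError("config must name a variant_table")
    for name in ("variant_table", "disease_genes", "census", "hotspots"):
        path = getattr(cfg, name)
        if path is None:
            raise ConfigError(f"config must name {name}")
        if not Path(path).exists():
            raise ConfigError(f"{name} path does not exist: {path}")
    cohort = read_variant_table(cfg.variant_table, target_size_mb=cfg.target_size_mb)
    catalog = read_gene_catalog(cfg.disease_genes, cfg.census, cfg.hotspots,
                                cfg.top_drivers)
    oracle = read_oracle(cfg.oracle) if cfg.oracle else None
    expression = read_counts(cfg.counts) if cfg.counts else None
    return analyze(
        cohort, catalog, oracle,
        params=cfg.level1_params,
        min_recurrence=cfg.min_recurrence,
        expression=expression,
        min_cpm=cfg.min_cpm,
        min_cpm_samples=cfg.min_cpm_samples,
        mechanism_thresholds=cfg.mechanism_thresholds,
        output_dir=cfg.output_dir,
        config_hash=cfg.hash(),
    )
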