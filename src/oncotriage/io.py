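"""Readers and writers for the formats the pipeline touches.

Covered formats: minimal single-sample VCF v4.2 (DP/AD depth fields),
the tab-delimited annotated variant table, gene-catalog TSVs, the
pathogenicity-oracle TSV, count matrices, and a MAF-like export.

The annotated-variant table accepts the common ANNOVAR spelling of
functional consequences ("nonsynonymous SNV", "frameshift insertion", ...)
via a documented dialect table; unrecognised labels fall back to
unknown/other with a warning rather than an error.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

from .errors import FormatError, ValidationError
from .types import (
    Cohort,
    CensusRole,
    FunctionalClass,
    GeneCatalog,
    HotspotEntry,
    PathogenicityCall,
    PathogenicityOracle,
    RegionClass,
    SampleDescriptor,
    SampleType,
    VariantCall,
)

# --------------------------------------------------------------------------
# dialect tables (ANNOVAR spellings -> canonical enums)

FUNCTIONAL_DIALECT: dict[str, FunctionalClass] = {
    "missense": FunctionalClass.MISSENSE,
    "nonsynonymous snv": FunctionalClass.MISSENSE,
    "synonymous": FunctionalClass.SYNONYMOUS,
    "synonymous snv": FunctionalClass.SYNONYMOUS,
    "stopgain": FunctionalClass.STOPGAIN,
    "stopgain snv": FunctionalClass.STOPGAIN,
    "stoploss": FunctionalClass.STOPLOSS,
    "stoploss snv": FunctionalClass.STOPLOSS,
    "frameshift insertion": FunctionalClass.FRAMESHIFT_INSERTION,
    "frameshift_insertion": FunctionalClass.FRAMESHIFT_INSERTION,
    "frameshift deletion": FunctionalClass.FRAMESHIFT_DELETION,
    "frameshift_deletion": FunctionalClass.FRAMESHIFT_DELETION,
    "nonframeshift insertion": FunctionalClass.NONFRAMESHIFT_INSERTION,
    "nonframeshift_insertion": FunctionalClass.NONFRAMESHIFT_INSERTION,
    "nonframeshift deletion": FunctionalClass.NONFRAMESHIFT_DELETION,
    "nonframeshift_deletion": FunctionalClass.NONFRAMESHIFT_DELETION,
    "unknown": FunctionalClass.UNKNOWN,
}

REGION_DIALECT: dict[str, RegionClass] = {
    "exonic": RegionClass.EXONIC,
    "utr5": RegionClass.UTR5,
    "5utr": RegionClass.UTR5,
    "utr-5": RegionClass.UTR5,
    "splice": RegionClass.SPLICE,
    "splicing": RegionClass.SPLICE,
    "splice_site": RegionClass.SPLICE,
    "other": RegionClass.OTHER,
}

ROLE_DIALECT: dict[str, CensusRole] = {
    "oncogene": CensusRole.ONCOGENE,
    "tsg": CensusRole.TUMOR_SUPPRESSOR,
    "tumor suppressor": CensusRole.TUMOR_SUPPRESSOR,
    "tumor_suppressor": CensusRole.TUMOR_SUPPRESSOR,
    "fusion": CensusRole.FUSION,
    "oncogene, tsg": CensusRole.ONCOGENE_AND_TSG,
    "oncogene,tsg": CensusRole.ONCOGENE_AND_TSG,
    "oncogene_and_tsg": CensusRole.ONCOGENE_AND_TSG,
    "both": CensusRole.ONCOGENE_AND_TSG,
}

VARIANT_TABLE_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_count",
    "region_class", "functional_class", "gene", "c_change", "p_change",
    "known_snp", "pon",
]

_TRUTHY = {"1", "true", "yes", "x", "t"}
_FALSY = {"0", "false", "no", "", "-", "f"}


# --------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path, sample_id: str) -> list[VariantCall]:
    """Read a minimal VCF into per-ALT :class:`VariantCall` records.

    Depth comes from FORMAT/DP (falling back to INFO/DP); the alternate
    count from FORMAT/AD, falling back to FORMAT-or-INFO AF times depth.
    Annotation fields are left unknown/empty; annotation is joined from the
    variant table separately.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    def fmt(rec, tag):
        if not vcf.samples:
            return None
        try:
            return rec.format(tag)
        except KeyError:
            return None

    calls: list[VariantCall] = []
    for i, rec in enumerate(vcf, start=1):
        dp = None
        fmt_dp = fmt(rec, "DP")
        if fmt_dp is not None:
            dp = int(fmt_dp[0][0])
        elif rec.INFO.get("DP") is not None:
            dp = int(rec.INFO.get("DP"))
        ad = fmt(rec, "AD")
        af = fmt(rec, "AF")
        if af is None and rec.INFO.get("AF") is not None:
            info_af = rec.INFO.get("AF")
            af = [info_af if isinstance(info_af, tuple) else (info_af,)]
        if dp is None:
            raise FormatError(f"{path} record {i} ({rec.CHROM}:{rec.POS}): no DP field")
        for j, alt in enumerate(rec.ALT):
            if ad is not None:
                alt_count = int(ad[0][j + 1])
                frac = alt_count / dp if dp > 0 else None
            elif af is not None:
                frac = float(af[0][j])
                alt_count = int(round(frac * dp))
            else:
                raise FormatError(
                    f"{path} record {i} ({rec.CHROM}:{rec.POS}): no AD or AF field"
                )
            calls.append(
                VariantCall(
                    sample_id=sample_id,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    read_depth=dp,
                    alt_read_count=alt_count,
                    alt_allele_fraction=frac,
                )
            )
    return calls


def write_vcf(variants: Sequence[VariantCall], path: str | Path, sample_id: str | None = None) -> None:
    """Write a minimal single-sample VCF v4.2 with DP and AD."""
    if sample_id is None:
        sample_id = variants[0].sample_id if variants else "SAMPLE"
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}",
    ]
    for v in variants:
        ref_count = v.read_depth - v.alt_read_count
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
            f"GT:DP:AD\t0/1:{v.read_depth}:{ref_count},{v.alt_read_count}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# annotated variant table

def _parse_bool(text: str, column: str, row: int) -> bool:
    t = text.strip().lower()
    if t in _TRUTHY:
        return True
    if t in _FALSY:
        return False
    raise FormatError(f"row {row}: cannot parse boolean {column}={text!r}")


def read_variant_table(
    path: str | Path, target_size_mb: float = 150.0
) -> Cohort:
    """Read the tab-delimited annotated variant table into a Cohort.

    Unparseable functional/region labels map to unknown/other with a
    warning. An optional ``sample_type`` column (cell_line / ffpe_tumor /
    ffpe_normal) is honoured; absent, every sample is a cell line. Samples
    are ordered by first appearance; a sample with zero variants has no
    rows to appear in and is not reconstructed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    has_type = "sample_type" in df.columns
    sample_types: dict[str, SampleType] = {}
    order: list[str] = []
    variants: list[VariantCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rec = dict(zip(df.columns, row))
        sid = rec["sample_id"].strip()
        if sid not in sample_types:
            order.append(sid)
            stype = SampleType.CELL_LINE
            if has_type and rec["sample_type"].strip():
                try:
                    stype = SampleType(rec["sample_type"].strip().lower())
                except ValueError as exc:
                    raise FormatError(f"row {i}: unknown sample_type {rec['sample_type']!r}") from exc
            sample_types[sid] = stype
        fc_label = rec["functional_class"].strip().lower()
        fc = FUNCTIONAL_DIALECT.get(fc_label)
        if fc is None:
            warnings.warn(f"row {i}: unknown functional class {rec['functional_class']!r}; using 'unknown'")
            fc = FunctionalClass.UNKNOWN
        rc_label = rec["region_class"].strip().lower()
        rc = REGION_DIALECT.get(rc_label)
        if rc is None:
            warnings.warn(f"row {i}: unknown region class {rec['region_class']!r}; using 'other'")
            rc = RegionClass.OTHER
        depth = int(rec["depth"])
        alt_count = int(rec["alt_count"])
        if alt_count > depth:
            raise ValidationError(f"row {i}: alt_count {alt_count} exceeds depth {depth}")
        variants.append(
            VariantCall(
                sample_id=sid,
                chrom=rec["chrom"].strip(),
                pos=int(rec["pos"]),
                ref=rec["ref"].strip(),
                alt=rec["alt"].strip(),
                read_depth=depth,
                alt_read_count=alt_count,
                region_class=rc,
                functional_class=fc,
                gene_symbol=rec["gene"],
                cdna_change=rec["c_change"].strip(),
                protein_change=rec["p_change"].strip(),
                is_known_snp=_parse_bool(rec["known_snp"], "known_snp", i),
                in_pon=_parse_bool(rec["pon"], "pon", i),
            )
        )
    samples = [SampleDescriptor(sid, sample_types[sid]) for sid in order]
    return Cohort(samples=samples, variants=variants, target_size_mb=target_size_mb)


def write_variant_table(cohort: Cohort, path: str | Path,
                        provenance: dict | None = None) -> None:
    """Write the cohort as the canonical tab-delimited variant table."""
    rows = []
    types = {s.sample_id: s.sample_type for s in cohort.samples}
    for v in cohort.variants:
        row = {
            "sample_id": v.sample_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "depth": v.read_depth,
            "alt_count": v.alt_read_count,
            "region_class": v.region_class.value,
            "functional_class": v.functional_class.value,
            "gene": v.gene_symbol,
            "c_change": v.cdna_change,
            "p_change": v.protein_change,
            "known_snp": int(v.is_known_snp),
            "pon": int(v.in_pon),
            "sample_type": types[v.sample_id].value,
        }
        if provenance is not None:
            row["provenance"] = ";".join(provenance.get((v.sample_id, v.key), []))
        rows.append(row)
    cols = VARIANT_TABLE_COLUMNS + ["sample_type"] + (["provenance"] if provenance is not None else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# gene catalogs

def _read_symbol_list(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0].strip().upper())
    return out


def read_gene_catalog(
    disease_path: str | Path,
    census_path: str | Path,
    hotspot_path: str | Path,
    top_driver_path: str | Path | None = None,
) -> GeneCatalog:
    """Load the disease-gene list, role census, hotspot catalog, and
    (optionally) the top human driver list; duplicate symbols keep the
    first occurrence with a warning. Empty files give empty catalogs."""
    disease = set(_read_symbol_list(disease_path))

    census: dict[str, CensusRole] = {}
    cdf = pd.read_csv(census_path, sep="\t", dtype=str, keep_default_na=False)
    for need in ("symbol", "role"):
        if need not in cdf.columns:
            raise FormatError(f"{census_path}: missing required column {need}")
    for i, rec in enumerate(cdf.itertuples(index=False), start=2):
        sym = rec.symbol.strip().upper()
        role = ROLE_DIALECT.get(rec.role.strip().lower())
        if role is None:
            raise FormatError(f"{census_path} row {i}: unknown role label {rec.role!r}")
        if sym in census:
            warnings.warn(f"{census_path} row {i}: duplicate symbol {sym}; keeping first")
            continue
        census[sym] = role

    hotspots: list[HotspotEntry] = []
    hdf = pd.read_csv(hotspot_path, sep="\t", dtype=str, keep_default_na=False)
    for need in ("gene", "ref_aa", "human_pos", "alt_aa", "offset"):
        if need not in hdf.columns:
            raise FormatError(f"{hotspot_path}: missing required column {need}")
    for i, rec in enumerate(hdf.itertuples(index=False), start=2):
        try:
            hotspots.append(
                HotspotEntry(
                    gene_symbol=rec.gene,
                    human_ref_aa=rec.ref_aa.strip(),
                    human_position=int(rec.human_pos),
                    human_alt_aa=rec.alt_aa.strip(),
                    species_codon_offset=int(rec.offset),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{hotspot_path} row {i}: {exc}") from exc

    top = set(_read_symbol_list(top_driver_path)) if top_driver_path else set()
    return GeneCatalog(disease_genes=disease, census=census,
                       top_driver_genes=top, hotspots=hotspots)


def write_gene_catalog(catalog: GeneCatalog, directory: str | Path) -> dict[str, Path]:
    """Write the four catalog files into ``directory``; returns their paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "disease": d / "disease_genes.txt",
        "census": d / "census.tsv",
        "hotspots": d / "hotspots.tsv",
        "top_drivers": d / "top_driver_genes.txt",
    }
    paths["disease"].write_text("\n".join(sorted(catalog.disease_genes)) + "\n")
    pd.DataFrame(
        [{"symbol": g, "role": r.value} for g, r in sorted(catalog.census.items())]
    ).to_csv(paths["census"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene": h.gene_symbol,
                "ref_aa": h.human_ref_aa,
                "human_pos": h.human_position,
                "alt_aa": h.human_alt_aa,
                "offset": h.species_codon_offset,
            }
            for h in catalog.hotspots
        ],
        columns=["gene", "ref_aa", "human_pos", "alt_aa", "offset"],
    ).to_csv(paths["hotspots"], sep="\t", index=False)
    paths["top_drivers"].write_text("\n".join(sorted(catalog.top_driver_genes)) + "\n")
    return paths


# --------------------------------------------------------------------------
# pathogenicity oracle

def read_oracle(path: str | Path) -> PathogenicityOracle:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for need in ("gene", "protein_change", "call"):
        if need not in df.columns:
            raise FormatError(f"{path}: missing required column {need}")
    calls = {}
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            call = PathogenicityCall(rec.call.strip().lower())
        except ValueError as exc:
            raise FormatError(f"{path} row {i}: unknown call {rec.call!r}") from exc
        calls[(rec.gene, rec.protein_change)] = call
    return PathogenicityOracle(calls=calls)


def write_oracle(oracle: PathogenicityOracle, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene": g, "protein_change": p, "call": c.value}
            for (g, p), c in sorted(oracle.calls.items())
        ],
        columns=["gene", "protein_change", "call"],
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# count matrix

def read_counts(path: str | Path):
    """Read a TSV count matrix (first column gene symbols) into an
    :class:`~oncotriage.expression.ExpressionMatrix`. Duplicate gene rows
    are summed; duplicate sample columns are a format error."""
    from .expression import ExpressionMatrix  # local import: avoid cycle

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_cols = header[1:]
    if len(sample_cols) != len(set(sample_cols)):
        raise FormatError(f"{path}: duplicate sample column name")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing values in count matrix")
    arr = df.to_numpy()
    if (arr < 0).any():
        raise ValidationError(f"{path}: negative counts")
    if not ((arr % 1) == 0).all():
        raise ValidationError(f"{path}: non-integer counts")
    df = df.astype(int)
    df.index = [str(g).strip().upper() for g in df.index]
    df = df.groupby(level=0, sort=False).sum()
    return ExpressionMatrix(df)


def write_counts(matrix, path: str | Path) -> None:
    df = matrix.counts.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# --------------------------------------------------------------------------
# MAF-like export

_MAF_CLASS = {
    FunctionalClass.MISSENSE: "Missense_Mutation",
    FunctionalClass.SYNONYMOUS: "Silent",
    FunctionalClass.STOPGAIN: "Nonsense_Mutation",
    FunctionalClass.STOPLOSS: "Nonstop_Mutation",
    FunctionalClass.FRAMESHIFT_INSERTION: "Frame_Shift_Ins",
    FunctionalClass.FRAMESHIFT_DELETION: "Frame_Shift_Del",
    FunctionalClass.NONFRAMESHIFT_INSERTION: "In_Frame_Ins",
    FunctionalClass.NONFRAMESHIFT_DELETION: "In_Frame_Del",
    FunctionalClass.UNKNOWN: "Unknown",
}


def export_maf(variants: Iterable[VariantCall], path: str | Path) -> None:
    """MAF-like export for downstream oncoplot tooling."""
    pd.DataFrame(
        [
            {
                "Hugo_Symbol": v.gene_symbol,
                "Chromosome": v.chrom,
                "Start_Position": v.pos,
                "Reference_Allele": v.ref,
                "Tumor_Seq_Allele2": v.alt,
                "Variant_Classification": _MAF_CLASS[v.functional_class],
                "Tumor_Sample_Barcode": v.sample_id,
            }
            for v in variants
        ],
        columns=[
            "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
            "Tumor_Seq_Allele2", "Variant_Classification", "Tumor_Sample_Barcode",
        ],
    ).to_csv(path, sep="\t", index=False)
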