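import numpy as np
import pytest

from oncotriage import (
    Cohort,
    FunctionalClass,
    RegionClass,
    SampleDescriptor,
    SampleType,
    VariantCall,
    default_gene_catalog,
    generate_variant_cohort,
    table1_fixture,
)
from oncotriage.simulate import CohortSimConfig


@pytest.fixture(scope="session")
def catalog():
    return default_gene_catalog()


@pytest.fixture(scope="session")
def small_sim(catalog):
    """A scaled-down generated cohort with full ground truth."""
    cfg = CohortSimConfig(
        variants_per_sample=150,
        n_recurrent_variants=40,
        n_background_genes=400,
        seed=11,
    )
    cohort, oracle, truth = generate_variant_cohort(cfg, catalog)
    return cfg, cohort, oracle, truth


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


def make_random_cohort(rng: np.random.Generator, n_variants: int = 400,
                       n_samples: int = 5) -> Cohort:
    """Arbitrary cohort straddling every filter boundary, for brute-force
    equivalence tests."""
    samples = [SampleDescriptor(f"S{i}", SampleType.CELL_LINE) for i in range(n_samples)]
    regions = list(RegionClass)
    classes = [c for c in FunctionalClass]
    genes = [f"G{i:03d}" for i in range(40)]
    nucs = "ACGT"
    variants = []
    for _ in range(n_variants):
        depth = int(rng.integers(1, 31))        # straddles the >10 threshold
        alt = int(rng.integers(0, depth + 1))   # straddles min count/fraction
        ref = nucs[rng.integers(0, 4)]
        alt_base = ref
        while alt_base == ref:
            alt_base = nucs[rng.integers(0, 4)]
        region = regions[rng.integers(0, len(regions))]
        fclass = classes[rng.integers(0, len(classes))]
        if fclass == FunctionalClass.SYNONYMOUS and region != RegionClass.EXONIC:
            region = RegionClass.EXONIC
        variants.append(VariantCall(
            sample_id=f"S{rng.integers(0, n_samples)}",
            chrom=f"chr{rng.integers(1, 5)}",
            pos=int(rng.integers(1, 2000)),     # duplicate keys are likely
            ref=ref, alt=alt_base,
            read_depth=depth, alt_read_count=alt,
            region_class=region, functional_class=fclass,
            gene_symbol=genes[rng.integers(0, len(genes))],
            is_known_snp=bool(rng.random() < 0.15),
            in_pon=bool(rng.random() < 0.1),
        ))
    return Cohort(samples=samples, variants=variants)
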