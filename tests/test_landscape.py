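import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncotriage import (
    Cohort,
    FunctionalClass,
    PathogenicityCall,
    PathogenicityOracle,
    RegionClass,
    SampleDescriptor,
    SampleType,
    VariantCall,
    apply_level1,
    apply_level2,
    compute_tmb,
    genes_per_sample,
    mutation_type_distribution,
    pathogenic_fraction,
    snv_spectrum,
)
from oncotriage.landscape import round1, spectrum_class
from conftest import make_random_cohort


def _mk(sample="S", pos=1, ref="C", alt="T", gene="G1",
        fclass=FunctionalClass.MISSENSE, pchg=""):
    return VariantCall(sample, "chr1", pos, ref, alt, 100, 40,
                       region_class=RegionClass.EXONIC, functional_class=fclass,
                       gene_symbol=gene, protein_change=pchg)


class TestTmb:
    def test_simple_division(self):
        """585 Level-1 variants over a 150 Mb design give 3.9 mutations/Mb."""
        cohort = Cohort([SampleDescriptor("S")],
                        [_mk(pos=i + 1) for i in range(585)], target_size_mb=150)
        tmb = compute_tmb(apply_level1(cohort), cohort)
        assert tmb.per_sample["S"] == pytest.approx(3.9)
        assert tmb.mean == tmb.median == tmb.tmb_min == tmb.tmb_max

    def test_includes_synonymous(self):
        cohort = Cohort([SampleDescriptor("S")], [
            _mk(pos=1), _mk(pos=2, fclass=FunctionalClass.SYNONYMOUS)],
            target_size_mb=2.0)
        tmb = compute_tmb(apply_level1(cohort), cohort)
        assert tmb.per_sample["S"] == pytest.approx(1.0)

    def test_zero_variant_sample_is_zero(self):
        cohort = Cohort([SampleDescriptor("A"), SampleDescriptor("B")],
                        [_mk(sample="A")])
        tmb = compute_tmb(apply_level1(cohort), cohort)
        assert tmb.per_sample["B"] == 0.0

    def test_ffpe_excluded_from_summary(self):
        samples = [SampleDescriptor("CL"),
                   SampleDescriptor("T", SampleType.FFPE_TUMOR)]
        variants = [_mk(sample="CL", pos=1)] + [
            _mk(sample="T", pos=i + 1) for i in range(100)]
        cohort = Cohort(samples, variants, target_size_mb=1.0)
        tmb = compute_tmb(apply_level1(cohort), cohort)
        assert tmb.mean == pytest.approx(1.0)
        assert tmb.ffpe["T"] == pytest.approx(100.0)

    def test_linearity_in_target_size(self):
        variants = [_mk(pos=i + 1) for i in range(30)]
        a = compute_tmb(apply_level1(Cohort([SampleDescriptor("S")], variants, 10.0)),
                        Cohort([SampleDescriptor("S")], variants, 10.0))
        b = compute_tmb(apply_level1(Cohort([SampleDescriptor("S")], variants, 20.0)),
                        Cohort([SampleDescriptor("S")], variants, 20.0))
        assert a.per_sample["S"] == pytest.approx(2 * b.per_sample["S"])


class TestMutationTypes:
    def test_proportions(self):
        vs = ([_mk(pos=i) for i in range(1, 5)]
              + [_mk(pos=i, ref="CA", alt="C",
                     fclass=FunctionalClass.FRAMESHIFT_DELETION) for i in range(5, 8)]
              + [_mk(pos=i, fclass=FunctionalClass.SYNONYMOUS) for i in range(8, 11)])
        dist = mutation_type_distribution(vs)
        assert dist.pooled_proportions[FunctionalClass.MISSENSE] == pytest.approx(0.4)
        assert dist.pooled_proportions[FunctionalClass.FRAMESHIFT_DELETION] == pytest.approx(0.3)
        assert dist.pooled_proportions[FunctionalClass.SYNONYMOUS] == pytest.approx(0.3)
        assert sum(dist.pooled_proportions.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(dist.pooled_counts.values()) == len(vs)

    def test_single_class_is_one(self):
        dist = mutation_type_distribution([_mk()])
        assert dist.pooled_proportions[FunctionalClass.MISSENSE] == 1.0

    def test_empty_flagged_undefined(self):
        dist = mutation_type_distribution([])
        assert dist.undefined and dist.pooled_proportions is None
        assert sum(dist.pooled_counts.values()) == 0

    def test_per_sample_mean_unweighted(self):
        vs = [_mk(sample="A")] + [
            _mk(sample="B", pos=i, fclass=FunctionalClass.SYNONYMOUS)
            for i in range(1, 10)]
        dist = mutation_type_distribution(vs, scope="per_sample")
        # A: 100% missense; B: 0% -> unweighted mean 50%
        assert dist.mean_proportions[FunctionalClass.MISSENSE] == pytest.approx(0.5)


class TestSpectrum:
    def test_purine_changes_fold_onto_pyrimidines(self):
        assert spectrum_class("G", "A") == "C>T"
        assert spectrum_class("A", "C") == "T>G"
        assert spectrum_class("C", "T") == "C>T"

    def test_indels_ignored_but_conserved(self):
        vs = [_mk(pos=1), _mk(pos=2, ref="CA", alt="C",
                              fclass=FunctionalClass.FRAMESHIFT_DELETION)]
        spec = snv_spectrum(vs)
        assert spec.n_snv + spec.n_other == len(vs)
        assert spec.n_other == 1

    def test_dominant_class(self):
        vs = ([_mk(pos=i + 1, ref="C", alt="T") for i in range(5)]
              + [_mk(pos=10 + i, ref="T", alt="C") for i in range(3)]
              + [_mk(pos=20 + i, ref="C", alt="A") for i in range(2)])
        assert snv_spectrum(vs).dominant_class == "C>T"

    def test_tie_breaks_lexicographically(self):
        vs = [_mk(pos=1, ref="C", alt="T"), _mk(pos=2, ref="T", alt="C")]
        assert snv_spectrum(vs).dominant_class == "C>T"

    def test_matches_naive_counter(self):
        rng = np.random.default_rng(3)
        cohort = make_random_cohort(rng, n_variants=700)
        spec = snv_spectrum(cohort.variants)
        naive = Counter()
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for v in cohort.variants:
            if len(v.ref) == 1 and len(v.alt) == 1:
                r, a = (v.ref, v.alt) if v.ref in "CT" else (comp[v.ref], comp[v.alt])
                naive[f"{r}>{a}"] += 1
        assert spec.counts == {c: naive.get(c, 0) for c in spec.counts}


@given(st.sampled_from("ACGT"), st.sampled_from("ACGT"))
@settings(max_examples=20, derandomize=True)
def test_spectrum_class_strand_symmetric(ref, alt):
    """Folding is strand-symmetric: a change and its reverse complement land
    in the same class, and every class starts from a pyrimidine."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if ref == alt:
        assert spectrum_class(ref, alt) is None
    else:
        cls = spectrum_class(ref, alt)
        assert cls == spectrum_class(comp[ref], comp[alt])
        assert cls[0] in "CT"


class TestPathogenicFraction:
    def test_printed_style_fraction(self):
        oracle = PathogenicityOracle({
            ("G1", "p.A1C"): PathogenicityCall.DELETERIOUS,
            ("G1", "p.A2C"): PathogenicityCall.NEUTRAL,
            ("G1", "p.A3C"): PathogenicityCall.NEUTRAL,
        })
        vs = [_mk(pos=i, pchg=f"p.A{i}C") for i in (1, 2, 3)]
        fr = pathogenic_fraction(vs, oracle)
        assert (fr.numerator, fr.denominator, fr.percent) == (1, 3, 33.3)

    def test_all_neutral_is_zero(self):
        oracle = PathogenicityOracle({("G1", "p.A1C"): PathogenicityCall.NEUTRAL})
        fr = pathogenic_fraction([_mk(pos=1, pchg="p.A1C")], oracle)
        assert fr.percent == 0.0

    def test_unknown_policy(self):
        oracle = PathogenicityOracle({("G1", "p.A1C"): PathogenicityCall.DELETERIOUS})
        vs = [_mk(pos=1, pchg="p.A1C"), _mk(pos=2, pchg="p.A2C")]  # 2nd unknown
        assert pathogenic_fraction(vs, oracle).denominator == 1
        fr = pathogenic_fraction(vs, oracle, unknown_policy="neutral")
        assert (fr.numerator, fr.denominator, fr.percent) == (1, 2, 50.0)

    def test_indels_and_other_classes_excluded(self):
        oracle = PathogenicityOracle({("G1", "p.A1C"): PathogenicityCall.DELETERIOUS})
        vs = [
            _mk(pos=1, pchg="p.A1C"),
            _mk(pos=2, ref="CA", alt="C", fclass=FunctionalClass.FRAMESHIFT_DELETION),
            _mk(pos=3, fclass=FunctionalClass.STOPGAIN, pchg="p.A1C"),
        ]
        fr = pathogenic_fraction(vs, oracle)
        assert fr.denominator == 1

    def test_zero_denominator_flagged(self):
        fr = pathogenic_fraction([], PathogenicityOracle())
        assert fr.undefined and fr.percent is None


def test_round1_half_up():
    assert round1(50.45) == 50.5
    assert round1(51.4285) == 51.4
    assert round1(9.6283) == 9.6


class TestGenesPerSample:
    def test_distinct_gene_count(self):
        vs = [_mk(pos=1, gene="A"), _mk(pos=2, gene="A"), _mk(pos=3, gene="B")]
        l2 = apply_level2(apply_level1(Cohort([SampleDescriptor("S")], vs)),
                          __import__("oncotriage").GeneCatalog())
        assert genes_per_sample(l2) == {"S": 2}

    def test_driver_table_wall_genes(self, table1, catalog):
        """In the driver-table fixture the Wall cell line carries variants
        in exactly three genes (PTCH1, ARID1A, TP53)."""
        l2 = apply_level2(apply_level1(table1), catalog)
        gps = genes_per_sample(l2)
        assert gps["Wall"] == 3
        wall_genes = {v.gene_symbol for v in l2.variants if v.sample_id == "Wall"}
        assert wall_genes == {"PTCH1", "ARID1A", "TP53"}

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        cohort = make_random_cohort(rng, n_variants=500)
        l2 = apply_level2(apply_level1(cohort), __import__("oncotriage").GeneCatalog())
        brute = {}
        for s in cohort.sample_ids:
            brute[s] = len({v.gene_symbol for v in l2.variants if v.sample_id == s})
        assert genes_per_sample(l2) == brute


def test_composition_recovery_from_generator(small_sim):
    """Generated class and spectrum proportions match the configured weights
    within 3 binomial standard errors."""
    cfg, cohort, _, truth = small_sim
    n_types = sum(truth.type_counts.values())
    for fclass, weight in cfg.type_weights.items():
        p_hat = truth.type_counts[fclass] / n_types
        se = math.sqrt(weight * (1 - weight) / n_types)
        assert abs(p_hat - weight) <= 3 * se + 1e-12, fclass
    n_spec = sum(truth.spectrum_counts.values())
    for cls, weight in cfg.spectrum_weights.items():
        p_hat = truth.spectrum_counts[cls] / n_spec
        se = math.sqrt(weight * (1 - weight) / n_spec)
        assert abs(p_hat - weight) <= 3 * se + 1e-12, cls
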