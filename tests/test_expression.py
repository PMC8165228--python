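import numpy as np
import pandas as pd
import pytest

from oncotriage import (
    ExpressionMatrix,
    FoldChangeProfile,
    MechanismThresholds,
    filter_low_expression,
    flag_mechanisms,
    fold_change_profile,
    normalize,
    tmm_factors,
)
from oncotriage.cascade import HotspotScan, HotspotMatch
from oncotriage.errors import ValidationError
from oncotriage.types import HotspotEntry, VariantCall, RegionClass, FunctionalClass


def _matrix(data, samples=None):
    samples = samples or [f"S{i}" for i in range(len(next(iter(data.values()))))]
    return ExpressionMatrix(pd.DataFrame(data, index=samples).T.astype(int))


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        m = _matrix({"G1": [0, 0], "G2": [100, 100]})
        assert filter_low_expression(m).genes == ["G2"]

    def test_boundary_retained(self):
        # CPM of gene == min_cpm in exactly min_samples samples
        m = ExpressionMatrix(pd.DataFrame(
            {"A": [1, 999_999], "B": [1, 999_999], "C": [0, 1_000_000]},
            index=["G1", "G2"]))
        out = filter_low_expression(m, min_cpm=1.0, min_samples=2)
        assert "G1" in out.genes

    def test_matches_brute_force(self):
        rng = np.random.default_rng(31)
        counts = rng.integers(0, 50, size=(80, 4))
        m = ExpressionMatrix(pd.DataFrame(
            counts, index=[f"G{i}" for i in range(80)], columns=list("ABCD")))
        out = filter_low_expression(m, min_cpm=5000.0, min_samples=2)
        lib = counts.sum(axis=0)
        keep = [
            i for i in range(80)
            if sum(counts[i, j] / lib[j] * 1e6 >= 5000.0 for j in range(4)) >= 2
        ]
        assert out.genes == [f"G{i}" for i in keep]

    def test_min_samples_validated(self):
        m = _matrix({"G1": [1, 2]})
        with pytest.raises(ValidationError):
            filter_low_expression(m, min_samples=3)


def _sim_matrix(seed=20240915, ngen=400, bias_genes=40, bias_fold=4.0,
                depth=(1.0, 2.2, 0.6, 1.4, 1.0), base_mean=150.0,
                dispersion=0.05):
    rng = np.random.default_rng(seed)
    means = np.exp(rng.normal(np.log(base_mean), 1.0, size=ngen))
    depth = np.asarray(depth)
    fold = np.ones((ngen, len(depth)))
    fold[:bias_genes, 1] = bias_fold
    mu = means[:, None] * fold * depth[None, :]
    r = 1 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    m = ExpressionMatrix(pd.DataFrame(
        counts, index=[f"G{i:04d}" for i in range(ngen)],
        columns=[f"S{j}" for j in range(len(depth))]))
    return m, mu


class TestTmm:
    def test_identical_samples_give_unity(self):
        m = _matrix({"G1": [10, 10], "G2": [500, 500], "G3": [3, 3]})
        assert tmm_factors(m).tolist() == pytest.approx([1.0, 1.0])

    def test_pure_depth_difference_absorbed(self):
        """Doubling every count is a library-size effect: factors stay 1."""
        base = {"G1": 10, "G2": 500, "G3": 35, "G4": 120}
        m = ExpressionMatrix(pd.DataFrame(
            {"A": list(base.values()), "B": [2 * v for v in base.values()]},
            index=list(base)))
        assert tmm_factors(m).tolist() == pytest.approx([1.0, 1.0])

    def test_matches_reference_implementation(self):
        """Frozen factors computed with edgeR::calcNormFactors (TMM) on the
        same simulated matrix (library-size spread plus a 4x composition
        bias on 10% of genes in the second sample)."""
        m, _ = _sim_matrix()
        expected = [1.05513965, 0.83475798, 1.02242896, 1.03886423, 1.06890115]
        assert tmm_factors(m).tolist() == pytest.approx(expected, rel=1e-6)

    def test_composition_bias_recovered(self):
        """The factor ratio for the biased sample recovers the generating
        value (unbiased-library share) within 5%; counts are deep enough
        that the log-ratio estimator's small-count bias is negligible."""
        m, mu = _sim_matrix(seed=1, base_mean=500.0, dispersion=0.01)
        f = tmm_factors(m)
        t_unbiased = mu[:, 0].sum() / 1.0          # per unit depth
        t_biased = mu[:, 1].sum() / 2.2
        expected_ratio = t_unbiased / t_biased      # < 1: bias inflates library
        got_ratio = f.iloc[1] / f.iloc[0]
        assert got_ratio == pytest.approx(expected_ratio, rel=0.05)

    def test_invariant_under_gene_permutation_and_relabeling(self):
        m, _ = _sim_matrix(seed=5, ngen=200)
        f = tmm_factors(m)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(m.genes))
        shuffled = ExpressionMatrix(m.counts.iloc[perm])
        assert tmm_factors(shuffled).tolist() == pytest.approx(f.tolist())
        renamed = ExpressionMatrix(
            m.counts.rename(columns={s: f"X_{s}" for s in m.samples}))
        assert tmm_factors(renamed).tolist() == pytest.approx(f.tolist())

    def test_geometric_mean_is_one(self):
        m, _ = _sim_matrix(seed=9, ngen=150)
        f = tmm_factors(m)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)
        assert (f > 0).all()

    def test_zero_library_named_in_error(self):
        m = _matrix({"G1": [10, 0], "G2": [5, 0]}, samples=["ok", "empty"])
        with pytest.raises(ValidationError, match="empty"):
            tmm_factors(m)


def test_cpm_recomputation_identity():
    m, _ = _sim_matrix(seed=2, ngen=120)
    n = normalize(m)
    lib = m.counts.sum(axis=0).astype(float)
    for s in m.samples:
        expected = m.counts[s] / (lib[s] * n.tmm_factors[s]) * 1e6
        assert np.allclose(n.cpm[s], expected)


class TestFoldChange:
    def test_ninefold_against_explicit_baseline(self):
        cpm = pd.DataFrame([[90.0, 10.0, 10.0, 12.0]], index=["MDM2"],
                           columns=list("ABCD"))
        import oncotriage
        n = oncotriage.NormalizedExpression(
            cpm=cpm, tmm_factors=pd.Series(1.0, index=list("ABCD")),
            library_sizes=pd.Series(1e6, index=list("ABCD")))
        prof = fold_change_profile(n, "MDM2", baseline_samples=["B", "C"])
        assert prof.fc("A") == pytest.approx(9.0, rel=0.05)

    def test_leave_one_out_symmetric_is_unity(self):
        import oncotriage
        cpm = pd.DataFrame([[20.0, 20.0, 20.0]], index=["G"], columns=list("ABC"))
        n = oncotriage.NormalizedExpression(
            cpm=cpm, tmm_factors=pd.Series(1.0, index=list("ABC")),
            library_sizes=pd.Series(1e6, index=list("ABC")))
        prof = fold_change_profile(n, "G")
        assert all(v == pytest.approx(1.0) for v in prof.fold_changes.values())

    def test_zero_baseline_flagged(self):
        import oncotriage
        cpm = pd.DataFrame([[5.0, 0.0, 0.0]], index=["G"], columns=list("ABC"))
        n = oncotriage.NormalizedExpression(
            cpm=cpm, tmm_factors=pd.Series(1.0, index=list("ABC")),
            library_sizes=pd.Series(1e6, index=list("ABC")))
        prof = fold_change_profile(n, "G")
        assert prof.baseline_zero["A"] is True
        assert prof.fc("A") > 1  # pseudo-count keeps it finite

    def test_absent_gene_raises(self):
        import oncotriage
        cpm = pd.DataFrame([[5.0, 5.0]], index=["G"], columns=list("AB"))
        n = oncotriage.NormalizedExpression(
            cpm=cpm, tmm_factors=pd.Series(1.0, index=list("AB")),
            library_sizes=pd.Series(1e6, index=list("AB")))
        with pytest.raises(KeyError):
            fold_change_profile(n, "NOPE")


def _profile(gene, fcs):
    return FoldChangeProfile(gene=gene, fold_changes=dict(fcs),
                             baseline="test")


def _tp53_scan(sample_ids):
    entry = HotspotEntry("TP53", "E", 285, "K", 12)
    matches = []
    for s in sample_ids:
        v = VariantCall(s, "chr5", 100, "C", "T", 50, 25,
                        region_class=RegionClass.EXONIC,
                        functional_class=FunctionalClass.MISSENSE,
                        gene_symbol="TP53", protein_change="p.E273K")
        matches.append(HotspotMatch(v, entry, 273, 285))
    return HotspotScan(matches=matches)


class TestMechanismFlags:
    SAMPLES = ["Wall", "D17", "Penny"]

    def _profiles(self, **overrides):
        base = {g: {s: 1.0 for s in self.SAMPLES}
                for g in ("TP53", "MDM2", "MDM4", "MET", "MAPK1", "MAP2K1", "MYC")}
        for gene, per_sample in overrides.items():
            base[gene].update(per_sample)
        return {g: _profile(g, fcs) for g, fcs in base.items()}

    def test_hotspot_lof(self):
        profiles = self._profiles(MDM2={"Wall": 0.3})
        flags = flag_mechanisms(None, _tp53_scan(["Wall"]), profiles,
                                samples=self.SAMPLES)
        assert [(f.sample_id, f.mechanism) for f in flags
                if f.mechanism != "none"] == [("Wall", "tp53_hotspot_lof")]
        ev = {e[0]: e for e in flags[0].evidence}
        assert ev["mdm2_fc_le"] == ("mdm2_fc_le", 0.3, 0.5, True)

    def test_mdm_overexpression_needs_wild_type(self):
        profiles = self._profiles(MDM2={"D17": 9.0}, MDM4={"D17": 5.5})
        flags = flag_mechanisms(None, _tp53_scan(["Wall"]), profiles,
                                samples=self.SAMPLES)
        fired = [(f.sample_id, f.mechanism) for f in flags if f.mechanism != "none"]
        assert fired == [("D17", "tp53_mdm_overexpression")]

    def test_met_mapk_needs_two_downstream(self):
        profiles = self._profiles(MET={"D17": 19.0}, MAPK1={"D17": 2.0},
                                  MYC={"D17": 1.6})
        flags = flag_mechanisms(None, HotspotScan(), profiles, samples=["D17"])
        assert [f.mechanism for f in flags] == ["met_mapk_activation"]
        only_one = self._profiles(MET={"D17": 19.0}, MAPK1={"D17": 2.0})
        flags = flag_mechanisms(None, HotspotScan(), only_one, samples=["D17"])
        assert [f.mechanism for f in flags] == ["none"]

    def test_all_flat_is_none(self):
        flags = flag_mechanisms(None, HotspotScan(), self._profiles(),
                                samples=self.SAMPLES)
        assert all(f.mechanism == "none" for f in flags)

    def test_thresholds_recorded_and_deterministic(self):
        th = MechanismThresholds(overexpression_fold=3.0)
        profiles = self._profiles(MDM2={"D17": 2.5})
        flags = flag_mechanisms(None, HotspotScan(), profiles, thresholds=th,
                                samples=["D17"])
        assert flags[0].mechanism == "none"  # 2.5 < 3.0 cutoff
        again = flag_mechanisms(None, HotspotScan(), profiles, thresholds=th,
                                samples=["D17"])
        assert [(f.sample_id, f.mechanism, f.evidence) for f in flags] == [
            (f.sample_id, f.mechanism, f.evidence) for f in again]

    def test_missing_profile_warns_but_flags(self):
        profiles = {"MDM2": _profile("MDM2", {"D17": 9.0})}
        with pytest.warns(UserWarning, match="without profiles"):
            flags = flag_mechanisms(None, HotspotScan(), profiles, samples=["D17"])
        assert flags[0].mechanism == "tp53_mdm_overexpression"
        assert flags[0].complete is False
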