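"""Genome scan: kinship arithmetic, OLS oracle equivalence, permutation
thresholds, credible intervals and SNP association."""

import warnings

import numpy as np
import pandas as pd
import pytest

from dotox import quantgen, scan, synthetic
from dotox.containers import FOUNDER_IDS, HaplotypeDosage, VarianceComponents


def make_dosage(arr, positions=None, chrom=1):
    """HaplotypeDosage from a raw (n, m, 8) array."""
    arr = np.asarray(arr, float)
    n, m, _ = arr.shape
    if positions is None:
        positions = np.arange(1.0, m + 1.0)
    mmap = pd.DataFrame(
        {"marker": [f"mk{j}" for j in range(m)], "chr": chrom, "pos_Mb": positions}
    )
    return HaplotypeDosage([f"m{i}" for i in range(n)], mmap, arr)


class TestKinship:
    def test_identical_homozygous_mice_give_one(self):
        d = np.zeros((2, 5, 8))
        d[:, :, 0] = 2.0  # both mice homozygous founder A everywhere
        K = scan.kinship_from_dosages(make_dosage(d))
        assert np.allclose(K, 1.0)

    def test_disjoint_founder_content_gives_zero(self):
        d = np.zeros((2, 5, 8))
        d[0, :, 0] = 2.0
        d[1, :, 1] = 2.0
        K = scan.kinship_from_dosages(make_dosage(d))
        assert K[0, 1] == 0.0

    def test_three_mouse_toy_matches_hand_arithmetic(self):
        # one marker; mouse0 = AA, mouse1 = AB, mouse2 = BB
        d = np.zeros((3, 1, 8))
        d[0, 0, 0] = 2.0
        d[1, 0, 0] = 1.0
        d[1, 0, 1] = 1.0
        d[2, 0, 1] = 2.0
        K = scan.kinship_from_dosages(make_dosage(d))
        # K[i,j] = (p_i . p_j), p = d/2:
        expected = np.array(
            [
                [1.0, 0.5, 0.0],
                [0.5, 0.5, 0.5],
                [0.0, 0.5, 1.0],
            ]
        )
        assert np.allclose(K, expected)

    def test_psd_and_symmetric(self, kinship_small):
        assert np.allclose(kinship_small, kinship_small.T)
        w = np.linalg.eigvalsh(kinship_small)
        assert w.min() > -1e-10
        assert np.all(np.diag(kinship_small) <= 1.0 + 1e-8)

    def test_single_mouse_rejected(self):
        with pytest.raises(ValueError):
            scan.kinship_from_dosages(make_dosage(np.full((1, 3, 8), 0.25)))


class TestFitNull:
    def test_identity_kinship_flags_unidentifiable_h2(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=100)
        with pytest.warns(UserWarning, match="unidentifiable"):
            vc, wh = scan.fit_null(y, np.eye(100))
        assert np.isnan(vc.h2)
        # total variance still recovered
        assert vc.sigma_e2 == pytest.approx(np.var(y, ddof=1), rel=0.05)

    def test_null_trait_gives_small_h2(self, founders_default):
        mos = synthetic.simulate_do_population(founders_default, 150, seed=40)
        K = scan.kinship_from_dosages(synthetic.true_dosages(mos, founders_default))
        rng = np.random.default_rng(41)
        h2s = [scan.fit_null(rng.normal(size=150), K)[0].h2 for _ in range(10)]
        assert np.mean(h2s) < 0.15
        assert sum(h < 0.1 for h in h2s) >= 7


class TestLinkageScan:
    def test_constant_phenotype_gives_zero_lod(self, truth_small):
        with pytest.warns(UserWarning, match="constant"):
            res = scan.linkage_scan(np.ones(40), truth_small)
        assert np.all(res.table["lod"] == 0.0)

    def test_matches_brute_force_ols_oracle(self, truth_small):
        rng = np.random.default_rng(7)
        y = rng.normal(size=40)
        res = scan.linkage_scan(y, truth_small, K=None)
        n, m, _ = truth_small.dosages.shape
        X0 = np.ones((n, 1))
        rss0 = float(np.sum((y - y.mean()) ** 2))
        for j in range(m):
            X1 = np.column_stack([X0, truth_small.dosages[:, j, :]])
            beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
            rss1 = float(np.sum((y - X1 @ beta) ** 2))
            lod = 0.5 * n * np.log10(rss0 / rss1)
            assert res.table["lod"].iloc[j] == pytest.approx(lod, abs=1e-8)

    def test_lod_invariant_to_affine_rescaling(self, truth_small, kinship_small):
        rng = np.random.default_rng(8)
        y = rng.normal(size=40)
        r1 = scan.linkage_scan(y, truth_small, K=kinship_small)
        r2 = scan.linkage_scan(3.7 * y - 11.0, truth_small, K=kinship_small)
        assert np.allclose(r1.table["lod"], r2.table["lod"], atol=1e-6)

    def test_uninformative_marker_has_zero_lod(self, truth_small):
        rng = np.random.default_rng(9)
        y = rng.normal(size=40)
        d = truth_small.dosages.copy()
        d[:, 5, :] = 0.25  # uniform dosages carry no information
        res = scan.linkage_scan(y, make_dosage(d), K=None)
        assert res.table["lod"].iloc[5] == pytest.approx(0.0, abs=1e-8)

    def test_founder_coefficients_centered(self, truth_small):
        rng = np.random.default_rng(10)
        y = rng.normal(size=40)
        res = scan.linkage_scan(y, truth_small)
        coefs = res.table[[f"coef_{f}" for f in FOUNDER_IDS]].to_numpy()
        assert np.allclose(coefs.sum(axis=1), 0.0, atol=1e-8)

    def test_detection_improves_with_effect_size(self, founders_default):
        mos = synthetic.simulate_do_population(founders_default, 120, seed=50)
        truth = synthetic.true_dosages(mos, founders_default)
        d_focal = truth.founder_dosage_at(10, 31.87, "F")
        g = (d_focal >= 1).astype(float)
        rng = np.random.default_rng(51)
        lods = []
        for beta in (0.0, 0.4, 1.2):
            mean_lod = np.mean(
                [
                    scan.linkage_scan(
                        beta * g + rng.normal(scale=0.35, size=120), truth
                    ).max_lod
                    for _ in range(5)
                ]
            )
            lods.append(mean_lod)
        assert lods[0] < lods[1] < lods[2]


class TestPermutations:
    def test_alpha_monotonicity_and_stability(self, truth_small):
        rng = np.random.default_rng(12)
        y = rng.normal(size=40)
        t05a = scan.permutation_threshold(y, truth_small, n_perm=1000, alpha=0.05, seed=1)
        t05b = scan.permutation_threshold(y, truth_small, n_perm=1000, alpha=0.05, seed=2)
        t01 = scan.permutation_threshold(y, truth_small, n_perm=1000, alpha=0.01, seed=1)
        assert t01 >= t05a
        assert abs(t05a - t05b) < 0.5

    def test_planted_qtl_exceeds_threshold(self, founders_default):
        mos = synthetic.simulate_do_population(founders_default, 120, seed=52)
        truth = synthetic.true_dosages(mos, founders_default)
        g = (truth.founder_dosage_at(10, 31.87, "F") >= 1).astype(float)
        rng = np.random.default_rng(53)
        y = 1.2 * g + rng.normal(scale=0.35, size=120)
        res = scan.linkage_scan(y, truth)
        thr = scan.permutation_threshold(y, truth, n_perm=300, seed=54)
        assert res.max_lod > thr

    def test_too_few_permutations_rejected(self, truth_small):
        with pytest.raises(ValueError):
            scan.permutation_threshold(np.ones(40), truth_small, n_perm=50)


class TestCredibleInterval:
    def _scan_from_lods(self, lods, positions):
        table = pd.DataFrame(
            {
                "marker": [f"mk{j}" for j in range(len(lods))],
                "chr": 1,
                "pos_Mb": positions,
                "lod": lods,
            }
        )
        return table

    def test_single_spike_collapses_to_marker(self):
        t = self._scan_from_lods([0, 0, 20, 0, 0], [10, 20, 30, 40, 50])
        lo, hi = scan.credible_interval(t, 1)
        assert (lo, hi) == (30.0, 30.0)

    def test_symmetric_profile_gives_symmetric_interval(self):
        t = self._scan_from_lods([1, 2, 3, 2, 1], [10, 20, 30, 40, 50])
        lo, hi = scan.credible_interval(t, 1, prob=0.95)
        assert 30.0 - lo == hi - 30.0

    def test_five_marker_hand_computation(self):
        lods = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        t = self._scan_from_lods(lods, [5, 10, 15, 20, 25])
        w = 10.0**lods
        w /= w.sum()
        # peak 15 (w=0.82); adding both flanking markers (0.082 each) is
        # needed to pass 0.95
        assert w[2] < 0.95 < w[1] + w[2] + w[3]
        lo, hi = scan.credible_interval(t, 1, prob=0.95)
        assert (lo, hi) == (10.0, 20.0)

    def test_flat_profile_spans_chromosome_with_warning(self):
        t = self._scan_from_lods([1.0] * 5, [5, 10, 15, 20, 25])
        with pytest.warns(UserWarning, match="flat"):
            lo, hi = scan.credible_interval(t, 1)
        assert (lo, hi) == (5.0, 25.0)

    def test_unknown_chromosome_rejected(self):
        t = self._scan_from_lods([1, 2, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            scan.credible_interval(t, 99)


class TestSnpAssociation:
    def test_private_allele_dosage_arithmetic(self):
        # mouse homozygous for founder F at a SNP private to F -> dosage 2
        d = np.zeros((2, 3, 8))
        d[0, :, 5] = 2.0  # founder F
        d[1, :, 0] = 1.0
        d[1, :, 1] = 1.0
        alleles = np.zeros((3, 8))
        alleles[:, 5] = 1.0
        snp, kept = scan.impute_snp_dosages(make_dosage(d), alleles)
        assert np.allclose(snp[0], 2.0)
        assert np.allclose(snp[1], 0.0)

    def test_monomorphic_snps_skipped(self):
        d = np.full((3, 4, 8), 0.25)
        alleles = np.ones((4, 8))
        alleles[1, :] = 0.0
        alleles[2, 3] = 0.0  # only polymorphic SNP
        snp, kept = scan.impute_snp_dosages(make_dosage(d), alleles)
        assert list(kept) == [2]

    def test_mixed_toy_equals_weighted_sum(self):
        rng = np.random.default_rng(3)
        d = rng.dirichlet(np.ones(8), size=(2, 5)) * 2.0
        alleles = rng.integers(0, 2, size=(5, 8)).astype(float)
        alleles[0] = [1, 0, 1, 0, 1, 0, 1, 0]
        snp, kept = scan.impute_snp_dosages(make_dosage(d), alleles)
        for col, j in enumerate(kept):
            assert np.allclose(snp[:, col], d[:, j, :] @ alleles[j])

    def test_causal_snp_has_top_lod(self, founders_default):
        mos = synthetic.simulate_do_population(founders_default, 150, seed=60)
        truth = synthetic.true_dosages(mos, founders_default)
        chrom, lo, hi = founders_default.private_interval
        idx = founders_default.markers_in(chrom, lo, hi)
        snp, kept = scan.impute_snp_dosages(
            truth, founders_default.alleles[idx].astype(float), idx
        )
        causal = 0  # every interval SNP is private to F: all tag the causal allele
        rng = np.random.default_rng(61)
        y = 0.9 * (snp[:, causal] >= 1.0) + rng.normal(scale=0.35, size=150)
        res = scan.snp_association_scan(y, snp)
        # private-founder SNPs spanning the interval all tag the causal
        # haplotype: near-equal LOD across the interval
        assert res["lod"].min() > 0.8 * res["lod"].max()
        assert res["lod"].max() > 5

    def test_all_monomorphic_warns_and_returns_empty(self):
        y = np.arange(5.0)
        with pytest.warns(UserWarning, match="monomorphic"):
            res = scan.snp_association_scan(y, np.full((5, 3), 2.0))
        assert res.empty


class TestScanWithKinshipOracle:
    def test_fixed_varcomp_identity_kinship_equals_ols(self, truth_small):
        rng = np.random.default_rng(70)
        y = rng.normal(size=40)
        vc = VarianceComponents(sigma_g2=0.0, sigma_e2=1.0, h2=0.0, loglik=0.0)
        res_k = scan.linkage_scan(y, truth_small, K=np.eye(40), varcomp=vc)
        res_o = scan.linkage_scan(y, truth_small, K=None)
        assert np.allclose(res_k.table["lod"], res_o.table["lod"], atol=1e-8)
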