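"""Imputation, info score, coverage and concordance checks."""

import itertools

import numpy as np
import pytest

from arraykit import (
    MISSING,
    ArrayManifest,
    GenotypeMatrix,
    HaplotypePanel,
    ManifestEntry,
    PosteriorMatrix,
    SimConfig,
    ThresholdConfig,
    concordance,
    count_nonsyn,
    genomic_coverage,
    info_score,
    info_scores,
    ls_impute,
    shared_content,
    simulate_annotations,
    simulate_panel,
)
from arraykit.evaluate import _haploid_posteriors

from conftest import make_variants


def exhaustive_path_posterior(ref_H, positions, typed_cols, obs, rho, eps):
    """Allele posteriors by brute-force summation over all K^L copying paths.

    P(path) is uniform over the K starting states times per-gap transition
    factors ((1-r) + r/K to stay, r/K to jump, r = 1 - exp(-rho d));
    emission at a typed site matches the observed allele with 1-eps.  The
    posterior allele probability at each site is the path-weighted mean of
    the copied reference allele.
    """
    K, L = ref_H.shape
    r = 1.0 - np.exp(-rho * np.diff(positions).astype(float))
    typed_map = {int(c): t for t, c in enumerate(typed_cols)}
    num = np.zeros(L)
    den = 0.0
    for path in itertools.product(range(K), repeat=L):
        w = 1.0 / K
        for i in range(1, L):
            stay = (1.0 - r[i - 1]) + r[i - 1] / K
            w *= stay if path[i] == path[i - 1] else r[i - 1] / K
        for site, t in typed_map.items():
            w *= (1.0 - eps) if ref_H[path[site], site] == obs[t] else eps
        den += w
        for site in range(L):
            num[site] += w * ref_H[path[site], site]
    return num / den


class TestLsImpute:
    def _tiny(self, seed=0, K=4, L=6):
        rng = np.random.default_rng(seed)
        variants = make_variants(L, step=50_000)
        H = rng.integers(0, 2, size=(K, L)).astype(np.int8)
        # keep every column polymorphic so posteriors are informative
        H[0] = 1 - H[1]
        ref = HaplotypePanel(variants=variants, sample_ids=[f"r{i}" for i in range(K // 2)],
                             haplotypes=H)
        return ref

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_path_oracle(self, seed):
        ref = self._tiny(seed)
        rng = np.random.default_rng(100 + seed)
        typed_cols = np.array([0, 2, 5])
        rho, eps = 2e-6, 0.05
        obs = rng.integers(0, 2, size=(2, 3)).astype(np.int8)
        got = _haploid_posteriors(ref.haplotypes, ref.positions, typed_cols, obs, rho, eps)
        for b in range(2):
            expected = exhaustive_path_posterior(ref.haplotypes, ref.positions,
                                                 typed_cols, obs[b], rho, eps)
            assert np.abs(got[b] - expected).max() < 1e-10

    def test_genotype_posteriors_are_haploid_products(self):
        """Diploid triples equal the convolution of the two exhaustive
        haploid posteriors (independent copying processes given phase)."""
        ref = self._tiny(3)
        typed_idx = [0, 2, 5]
        typed = HaplotypePanel(variants=[ref.variants[i] for i in typed_idx],
                               sample_ids=["t0"],
                               haplotypes=ref.haplotypes[:2, typed_idx].copy())
        rho, eps = 2e-6, 0.05
        post = ls_impute(ref, typed, rho_per_bp=rho, eps=eps)
        a1 = exhaustive_path_posterior(ref.haplotypes, ref.positions, np.array(typed_idx),
                                       typed.haplotypes[0], rho, eps)
        a2 = exhaustive_path_posterior(ref.haplotypes, ref.positions, np.array(typed_idx),
                                       typed.haplotypes[1], rho, eps)
        expected = np.stack([(1 - a1) * (1 - a2), a1 * (1 - a2) + (1 - a1) * a2, a1 * a2], axis=1)
        assert np.abs(post.probs[0] - expected).max() < 1e-10

    def test_degenerate_identical_panel_concentrates(self):
        variants = make_variants(5, step=1000)
        H = np.tile(np.array([1, 0, 1, 0, 1], dtype=np.int8), (4, 1))
        ref = HaplotypePanel(variants=variants, sample_ids=["a", "b"], haplotypes=H)
        typed = HaplotypePanel(variants=[variants[0]], sample_ids=["t"],
                               haplotypes=H[:2, :1].copy())
        post = ls_impute(ref, typed, eps=0.01)
        # every haplotype is identical: posterior = that haplotype's genotype
        assert np.allclose(post.probs[0, :, 2], [1, 0, 1, 0, 1])

    def test_typed_site_mode_matches_observation_as_eps_vanishes(self):
        panel = simulate_panel(SimConfig(n_variants=60, n_haplotypes=60,
                                         region_bp=500_000, seed=7))
        ref = HaplotypePanel(variants=list(panel.variants), sample_ids=panel.sample_ids[:25],
                             haplotypes=panel.haplotypes[:50])
        typed_idx = list(range(0, 60, 3))
        targets = HaplotypePanel(variants=[panel.variants[i] for i in typed_idx],
                                 sample_ids=panel.sample_ids[25:],
                                 haplotypes=panel.haplotypes[50:, typed_idx].copy())
        post = ls_impute(ref, targets, eps=1e-6)
        truth = targets.haplotypes[0::2] + targets.haplotypes[1::2]
        modes = post.probs[:, typed_idx, :].argmax(axis=2)
        agreement = (modes == truth).mean()
        assert agreement > 0.99

    def test_parameter_validation(self):
        ref = self._tiny()
        typed = HaplotypePanel(variants=[ref.variants[0]], sample_ids=["t"],
                               haplotypes=ref.haplotypes[:2, :1].copy())
        with pytest.raises(ValueError):
            ls_impute(ref, typed, rho_per_bp=0)
        with pytest.raises(ValueError):
            ls_impute(ref, typed, eps=0.5)
        with pytest.raises(TypeError, match="phased"):
            ls_impute(ref, typed.genotypes())


class TestInfoScore:
    def _post(self, probs):
        probs = np.asarray(probs, dtype=float)[None, :, :].transpose(1, 0, 2)
        n, v = probs.shape[0], probs.shape[1]
        return PosteriorMatrix(variants=make_variants(v), sample_ids=[f"s{i}" for i in range(n)],
                               probs=probs)

    def test_hard_calls_give_one(self):
        probs = np.array([[[1, 0, 0]], [[0, 1, 0]], [[0, 0, 1]], [[0, 1, 0]]], dtype=float)
        post = PosteriorMatrix(variants=make_variants(1), sample_ids=list("abcd"),
                               probs=probs)
        assert info_score(post, 0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("theta", [0.1, 0.3, 0.5])
    def test_hwe_marginal_posteriors_give_zero(self, theta):
        """If every sample's posterior is the HWE genotype distribution at
        frequency theta, the dosage variance identity f - e^2 = 2 theta (1-theta)
        makes info exactly 0."""
        trip = [(1 - theta) ** 2, 2 * theta * (1 - theta), theta ** 2]
        probs = np.tile(np.array(trip), (20, 1, 1))
        post = PosteriorMatrix(variants=make_variants(1),
                               sample_ids=[f"s{i}" for i in range(20)], probs=probs)
        assert info_score(post, 0) == pytest.approx(0.0, abs=1e-10)

    def test_monomorphic_convention_is_one(self):
        probs = np.tile(np.array([1.0, 0.0, 0.0]), (5, 1, 1))
        post = PosteriorMatrix(variants=make_variants(1),
                               sample_ids=[f"s{i}" for i in range(5)], probs=probs)
        assert info_score(post, 0) == 1.0

    def test_malformed_posterior_rejected(self):
        with pytest.raises(ValueError):
            PosteriorMatrix(variants=make_variants(1), sample_ids=["a"],
                            probs=np.array([[[0.5, 0.2, 0.2]]]))


class TestGenomicCoverage:
    def _manifest(self, variants):
        return ArrayManifest([ManifestEntry(variant=v, categories={"tag"}) for v in variants])

    def test_fully_typed_panel_is_fully_covered(self):
        vs = make_variants(6)
        rep = genomic_coverage(np.zeros(6), vs, np.full(6, 0.2), self._manifest(vs))
        assert rep.overall == 1.0
        assert rep.by_stratum["common"][0] == 1.0

    def test_info_threshold_count(self):
        vs = make_variants(2)
        rep = genomic_coverage(np.array([0.9, 0.7]), vs, np.array([0.2, 0.2]),
                               ArrayManifest())
        assert rep.overall == pytest.approx(0.5)

    def test_mixed_strata_hand_count(self):
        # 4 common (MAF>=5%), 2 low-frequency; infos chosen so common covers
        # 3/4 and low 1/2; one rare variant excluded from the denominator
        vs = make_variants(7)
        mafs = np.array([0.3, 0.2, 0.1, 0.05, 0.02, 0.01, 0.001])
        infos = np.array([0.95, 0.85, 0.5, 0.8, 0.9, 0.2, 0.99])
        rep = genomic_coverage(infos, vs, mafs, ArrayManifest())
        assert rep.by_stratum["common"] == (pytest.approx(3 / 4), 4)
        assert rep.by_stratum["low_frequency"] == (pytest.approx(1 / 2), 2)
        assert rep.overall == pytest.approx(4 / 6)
        assert rep.n_reference == 6

    def test_windows_are_half_open_5mb_bins(self, cfg):
        vs = [make_variants(1, start=pos)[0] for pos in ()]
        from arraykit import VariantRecord
        vs = [VariantRecord(id="a", chrom="1", pos=5_000_000, alleleA="A", alleleB="G"),
              VariantRecord(id="b", chrom="1", pos=5_000_001, alleleA="A", alleleB="G"),
              VariantRecord(id="c", chrom="2", pos=1, alleleA="A", alleleB="G")]
        rep = genomic_coverage(np.array([0.9, 0.1, 0.9]), vs, np.full(3, 0.2), ArrayManifest())
        w = rep.by_window.set_index(["chrom", "window_start"])["coverage"]
        # pos 5,000,000 is in the first bin [1, 5,000,001); 5,000,001 starts the second
        assert w[("1", 1)] == 1.0
        assert w[("1", 5_000_001)] == 0.0
        assert w[("2", 1)] == 1.0

    def test_empty_denominator_is_error(self):
        vs = make_variants(2)
        with pytest.raises(ValueError, match="denominator"):
            genomic_coverage(np.ones(2), vs, np.array([0.001, 0.005]), ArrayManifest())

    def test_monotone_in_manifest_content(self, small_panel, cfg):
        infos = np.random.default_rng(0).uniform(0, 1, small_panel.n_variants)
        mafs = small_panel.maf()
        small = self._manifest(small_panel.variants[:50])
        large = self._manifest(small_panel.variants[:200])
        rep_s = genomic_coverage(infos, small_panel.variants, mafs, small, cfg)
        rep_l = genomic_coverage(infos, small_panel.variants, mafs, large, cfg)
        assert rep_l.overall >= rep_s.overall


class TestConcordance:
    def _geno(self, calls, ids=None):
        calls = np.asarray(calls, dtype=np.int8)
        return GenotypeMatrix(variants=make_variants(calls.shape[1]),
                              sample_ids=ids or [f"s{i}" for i in range(calls.shape[0])],
                              calls=calls)

    def test_identical_matrices_rate_one(self):
        g = self._geno([[0, 1, 2], [1, 1, 0]])
        assert concordance(g, g).rate == 1.0

    def test_one_mismatch_in_ten(self):
        a = self._geno([[0, 1, 2, 1, 0], [2, 1, 0, 1, 2]])
        calls = a.calls.copy()
        calls[0, 0] = 1
        b = self._geno(calls)
        rep = concordance(a, b)
        assert rep.n_compared == 10 and rep.rate == pytest.approx(0.9)

    def test_missing_pairs_excluded_from_both_counts(self):
        a = self._geno([[0, 1, MISSING]])
        b = self._geno([[0, MISSING, 2]])
        rep = concordance(a, b)
        assert rep.n_compared == 1 and rep.n_concordant == 1

    def test_het_only_restriction(self):
        # mismatches only at homozygous truth sites
        truth = self._geno([[0, 1, 2, 1], [2, 1, 0, 1]])
        calls = truth.calls.copy()
        calls[0, 0] = 1  # truth hom 0
        calls[1, 2] = 2  # truth hom 0
        test = self._geno(calls)
        overall = concordance(test, truth)
        het = concordance(test, truth, het_only=True)
        assert het.rate == 1.0 and overall.rate < 1.0

    def test_blind_duplicate_sample_map(self):
        a = self._geno([[0, 1, 2]], ids=["dup"])
        b = self._geno([[0, 1, 1], [0, 1, 2]], ids=["x", "orig"])
        rep = concordance(a, b, sample_map={"dup": "orig"})
        assert rep.rate == 1.0

    def test_zero_comparable_pairs_is_error(self):
        a = self._geno([[MISSING, MISSING]])
        b = self._geno([[0, 1]])
        with pytest.raises(ValueError, match="zero comparable"):
            concordance(a, b)


class TestSharedContent:
    def test_allele_order_insensitive_match(self):
        from arraykit import VariantRecord
        a = ArrayManifest([ManifestEntry(
            variant=VariantRecord(id="a", chrom="1", pos=100, alleleA="A", alleleB="G"),
            categories={"tag"})])
        b = ArrayManifest([ManifestEntry(
            variant=VariantRecord(id="b", chrom="1", pos=100, alleleA="G", alleleB="A"),
            categories={"tag"})])
        n, pairs = shared_content(a, b)
        assert n == 1

    def test_different_alleles_no_match(self):
        from arraykit import VariantRecord
        a = ArrayManifest([ManifestEntry(
            variant=VariantRecord(id="a", chrom="1", pos=100, alleleA="A", alleleB="G"),
            categories={"tag"})])
        b = ArrayManifest([ManifestEntry(
            variant=VariantRecord(id="b", chrom="1", pos=100, alleleA="A", alleleB="C"),
            categories={"tag"})])
        assert shared_content(a, b)[0] == 0

    def test_planted_overlap_count(self, small_panel):
        rng = np.random.default_rng(9)
        idx = rng.permutation(small_panel.n_variants)
        a_idx, b_idx = idx[:50], idx[33:83]  # 17 planted overlaps
        mk = lambda ii: ArrayManifest([ManifestEntry(variant=small_panel.variants[i],
                                                     categories={"tag"}) for i in ii])
        n, _ = shared_content(mk(a_idx), mk(b_idx))
        assert n == 17


class TestCountNonsyn:
    def test_hand_counted_fixture(self, small_panel):
        annot = simulate_annotations(small_panel, seed=21)
        manifest = ArrayManifest([ManifestEntry(variant=v, categories={"functional"})
                                  for v in small_panel.variants[:100]])
        counts_any = count_nonsyn(manifest, annot, "EAS", rule="any_predictor")
        counts_two = count_nonsyn(manifest, annot, "EAS", rule="more_than_one")
        # independent hand count
        exp_nonsyn = exp_any = exp_two = 0
        for v in small_panel.variants[:100]:
            rec = annot.get(v.key)
            if rec.consequence != "nonsynonymous":
                continue
            exp_nonsyn += 1
            if rec.pop_maf["EAS"] > 0:
                if rec.n_damaging >= 1:
                    exp_any += 1
                if rec.n_damaging >= 2:
                    exp_two += 1
        assert counts_any == {"nonsyn": exp_nonsyn, "nonsyn_pop_observed_damaging": exp_any}
        assert counts_two == {"nonsyn": exp_nonsyn, "nonsyn_pop_observed_damaging": exp_two}
        assert counts_two["nonsyn_pop_observed_damaging"] <= counts_any["nonsyn_pop_observed_damaging"]

    def test_zero_eas_frequency_not_counted_as_damaging(self, small_panel):
        annot = simulate_annotations(small_panel, seed=22, p_absent=1.0)
        manifest = ArrayManifest([ManifestEntry(variant=v, categories={"functional"})
                                  for v in small_panel.variants])
        counts = count_nonsyn(manifest, annot, "EAS")
        assert counts["nonsyn"] > 0
        assert counts["nonsyn_pop_observed_damaging"] == 0

    def test_unknown_population_is_error(self, small_panel):
        annot = simulate_annotations(small_panel, seed=23)
        with pytest.raises(ValueError, match="unknown population"):
            count_nonsyn(ArrayManifest(), annot, "AFR")
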