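"""Likelihood machinery: closed forms, EM behaviour, optimizer agreement."""

import numpy as np
import pytest

from pooxe import (
    DegenerateDataError,
    FitOptions,
    HaplotypeSpace,
    SimParams,
    build_space,
    complete_data_loglik,
    fit_stratum,
    observed_data_loglik,
    simulate_dataset,
)
from pooxe.likelihood import _StateModel, _em, _group_patterns

SNP_SPACE = HaplotypeSpace(loci=("s1",), haplotypes=((0,), (1,)), reference_index=0)


class TestCompleteDataLoglik:
    def test_uniform_null_counts(self):
        # all RR=1, uniform freqs: every state has probability H^-4
        counts = np.ones(16)
        ll = complete_data_loglik([0.5, 0.5], [0, 0], [0, 0], counts, SNP_SPACE)
        assert ll == pytest.approx(16 * np.log(1 / 16), abs=1e-10)

    def test_single_snp_normalizer(self):
        # one family in state (t_m=1, u_m=0, t_f=0, u_f=0): index 8 in the
        # (tm, um, tf, uf) enumeration
        counts = np.zeros(16)
        counts[8] = 1
        ll = complete_data_loglik([0.8, 0.2], [0, np.log(2)], [0, 0], counts, SNP_SPACE)
        assert ll == pytest.approx(np.log(0.2 * 0.8**3 * 2 / 1.2), abs=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5, size=16).astype(float)
        f = np.array([0.7, 0.3])
        lrm = np.array([0.0, 0.4])
        lrp = np.array([0.0, -0.2])
        ll = complete_data_loglik(f, lrm, lrp, counts, SNP_SPACE)
        # permuting haplotype labels together with all parameters and the
        # state counts leaves the likelihood unchanged
        swapped = HaplotypeSpace(loci=("s1",), haplotypes=((1,), (0,)), reference_index=0)
        model = _StateModel(SNP_SPACE)
        perm = np.ravel_multi_index(
            (1 - model.tm, 1 - model.um, 1 - model.tf, 1 - model.uf), (2, 2, 2, 2)
        )
        counts_sw = np.empty(16)
        counts_sw[perm] = counts
        ll_sw = complete_data_loglik(f[::-1], lrm[::-1], lrp[::-1], counts_sw, swapped)
        assert ll_sw == pytest.approx(ll, abs=1e-9)

    def test_zero_probability_state_with_count(self):
        counts = np.zeros(16)
        counts[8] = 2
        ll = complete_data_loglik([1.0 - 1e-300, 1e-300], [0, -690], [0, 0], counts, SNP_SPACE)
        assert ll < -1000  # effectively impossible state


class TestObservedDataLoglik:
    def test_unambiguous_triad_equals_complete_data(self):
        # (M=2, F=0, C=1): unique state (t_m=1, u_m=1, t_f=0, u_f=0) -> index 12
        f = np.array([0.6, 0.4])
        lrm = np.array([0.0, 0.5])
        lrp = np.array([0.0, -0.3])
        counts = np.zeros(16)
        counts[12] = 1
        obs = observed_data_loglik(f, lrm, lrp, [[2]], [[0]], [[1]], SNP_SPACE)
        assert obs == pytest.approx(complete_data_loglik(f, lrm, lrp, counts, SNP_SPACE), abs=1e-12)

    def test_dyad_equals_father_marginalization(self):
        f = np.array([0.75, 0.25])
        lrm = np.array([0.0, np.log(1.8)])
        lrp = np.array([0.0, np.log(0.7)])
        for m_geno in (0, 1, 2):
            for c_geno in (0, 1, 2):
                lik = 0.0
                ok = False
                for f_geno in (0, 1, 2):
                    try:
                        lik += np.exp(
                            observed_data_loglik(f, lrm, lrp, [[m_geno]], [[f_geno]], [[c_geno]], SNP_SPACE)
                        )
                        ok = True
                    except DegenerateDataError:
                        continue
                if not ok:
                    continue
                dyad = observed_data_loglik(f, lrm, lrp, [[m_geno]], [[-1]], [[c_geno]], SNP_SPACE)
                assert np.exp(dyad) == pytest.approx(lik, abs=1e-15)

    def test_triple_heterozygote_origins_contribute_equally(self):
        # (1,1,1) triad with rr_mat == rr_pat: both phase assignments equal
        f = np.array([0.5, 0.5])
        lr = np.array([0.0, 0.9])
        model = _StateModel(SNP_SPACE)
        masks, counts, _ = _group_patterns(model, [[1]], [[1]], [[1]])
        pi = model.state_probs(f, np.exp(lr), np.exp(lr))
        contributions = pi[masks[0].astype(bool)]
        assert len(contributions) == 2
        assert contributions[0] == pytest.approx(contributions[1], rel=1e-12)


def grid_search_oracle(mother, father, child, space, n_coarse=61, n_fine=41):
    """Two-stage dense grid over (p, rr_mat, rr_pat); returns best loglik."""
    def best_on(ps, rms, rps):
        top = -np.inf
        arg = None
        for p in ps:
            for rm in rms:
                for rp in rps:
                    ll = observed_data_loglik(
                        [1 - p, p], [0, np.log(rm)], [0, np.log(rp)], mother, father, child, space
                    )
                    if ll > top:
                        top, arg = ll, (p, rm, rp)
        return top, arg

    ps = np.linspace(0.02, 0.98, n_coarse)
    rrs = np.exp(np.linspace(-2.0, 2.0, n_coarse))
    top, (p, rm, rp) = best_on(ps, rrs, rrs)
    ps2 = np.linspace(max(p - 0.03, 1e-3), min(p + 0.03, 1 - 1e-3), n_fine)
    rms2 = np.exp(np.linspace(np.log(rm) - 0.1, np.log(rm) + 0.1, n_fine))
    rps2 = np.exp(np.linspace(np.log(rp) - 0.1, np.log(rp) + 0.1, n_fine))
    top2, _ = best_on(ps2, rms2, rps2)
    return max(top, top2)


class TestFitStratum:
    def test_em_matches_grid_search_on_tiny_data(self):
        # six families, mixed configurations, interior optimum
        mother = [[1], [1], [2], [0], [1], [1]]
        father = [[0], [1], [1], [1], [-1], [0]]
        child = [[1], [2], [2], [0], [1], [0]]
        fit = fit_stratum(mother, father, child, SNP_SPACE)
        oracle = grid_search_oracle(mother, father, child, SNP_SPACE)
        assert fit.loglik == pytest.approx(oracle, abs=1e-3)
        assert fit.loglik >= oracle - 1e-9

    def test_em_and_bfgs_agree(self):
        ds = simulate_dataset(SimParams(n_unexposed_families=400, n_exposed_families=0,
                                        rr_mat=1.6, dyad_fraction=0.25, seed=21))
        space, f0 = build_space(ds.mother, ds.father, ds.child, ds.snps["snp_id"])
        em = fit_stratum(ds.mother, ds.father, ds.child, space, init_freq=f0)
        bf = fit_stratum(ds.mother, ds.father, ds.child, space, init_freq=f0,
                         options=FitOptions(method="bfgs"))
        assert em.loglik == pytest.approx(bf.loglik, abs=1e-6)
        assert np.allclose(em.log_rr_mat, bf.log_rr_mat, atol=1e-4)
        assert np.allclose(em.freq, bf.freq, atol=1e-5)

    def test_em_loglik_never_decreases(self):
        # run EM manually and track the objective at every iteration
        ds = simulate_dataset(SimParams(n_unexposed_families=300, n_exposed_families=0,
                                        rr_mat=2.0, dyad_fraction=0.3, seed=33))
        space, f0 = build_space(ds.mother, ds.father, ds.child, ds.snps["snp_id"])
        model = _StateModel(space)
        masks, counts, _ = _group_patterns(model, ds.mother, ds.father, ds.child)
        # the internal EM raises if the objective ever decreases
        _em(model, masks, counts, f0, space.reference_index, False, 1e-10, 4000)

    def test_null_recovery_within_4_se(self):
        ds = simulate_dataset(SimParams(n_unexposed_families=5000, n_exposed_families=0, seed=55))
        space, f0 = build_space(ds.mother, ds.father, ds.child, ds.snps["snp_id"])
        fit = fit_stratum(ds.mother, ds.father, ds.child, space, init_freq=f0)
        h = [i for i, hp in enumerate(space.haplotypes) if hp == (1,)][0]
        for block in ("rr_mat", "rr_pat"):
            est = fit.log_rr_mat[h] if block == "rr_mat" else fit.log_rr_pat[h]
            se = np.sqrt(fit.var_log_rr(block, h))
            assert abs(est) < 4 * se

    def test_swapping_parents_swaps_risk_estimates(self):
        ds = simulate_dataset(SimParams(n_unexposed_families=600, n_exposed_families=0,
                                        rr_mat=2.0, rr_pat=0.8, seed=77))
        space, f0 = build_space(ds.mother, ds.father, ds.child, ds.snps["snp_id"])
        fit = fit_stratum(ds.mother, ds.father, ds.child, space, init_freq=f0)
        swapped = fit_stratum(ds.father, ds.mother, ds.child, space, init_freq=f0)
        assert np.allclose(fit.log_rr_mat, swapped.log_rr_pat, atol=1e-7)
        assert np.allclose(fit.log_rr_pat, swapped.log_rr_mat, atol=1e-7)

    def test_constrained_fit_matches_unconstrained_without_poo(self):
        ds = simulate_dataset(SimParams(n_unexposed_families=10_000, n_exposed_families=0,
                                        rr_mat=1.5, rr_pat=1.5, seed=88))
        space, f0 = build_space(ds.mother, ds.father, ds.child, ds.snps["snp_id"])
        free = fit_stratum(ds.mother, ds.father, ds.child, space, init_freq=f0)
        tied = fit_stratum(ds.mother, ds.father, ds.child, space, init_freq=f0,
                           constrain_equal_rr=True)
        h = [i for i, hp in enumerate(space.haplotypes) if hp == (1,)][0]
        assert tied.log_rr_mat[h] == pytest.approx(
            (free.log_rr_mat[h] + free.log_rr_pat[h]) / 2, abs=0.05
        )
        assert np.exp(tied.log_rr_mat[h]) == pytest.approx(1.5, abs=0.12)

    def test_monomorphic_data_raises(self):
        mother = np.zeros((50, 1), dtype=int)
        with pytest.raises(DegenerateDataError):
            build_space(mother, mother, mother, ["s1"])

    def test_both_parents_missing_families_excluded(self):
        ds = simulate_dataset(SimParams(n_unexposed_families=400, n_exposed_families=0, seed=91))
        mother = ds.mother.copy()
        mother[:10] = -1
        father = ds.father.copy()
        father[:10] = -1
        space, f0 = build_space(ds.mother, ds.father, ds.child, ds.snps["snp_id"])
        fit = fit_stratum(mother, father, ds.child, space, init_freq=f0)
        assert fit.n_families == 390


class TestHaplotypeSpaces:
    def test_two_snp_space_resolution(self):
        # two independent SNPs: all four haplotypes common, reference most frequent
        ds = simulate_dataset(SimParams(n_unexposed_families=1500, n_exposed_families=0,
                                        variant_allele_freq=0.3, n_effect_snps=2, seed=101))
        space, f0 = build_space(ds.mother, ds.father, ds.child, ds.snps["snp_id"])
        assert space.n_haplotypes == 4
        assert space.haplotypes[space.reference_index] == (0, 0)
        assert f0[space.reference_index] == pytest.approx(0.49, abs=0.05)

    def test_haplotype_fit_recovers_marginal_freq(self):
        ds = simulate_dataset(SimParams(n_unexposed_families=1500, n_exposed_families=0,
                                        variant_allele_freq=0.3, n_effect_snps=2, seed=103))
        space, f0 = build_space(ds.mother, ds.father, ds.child, ds.snps["snp_id"])
        fit = fit_stratum(ds.mother, ds.father, ds.child, space, init_freq=f0)
        # marginal variant frequency at locus 0 from haplotype frequencies
        marg = sum(fit.freq[i] for i, h in enumerate(space.haplotypes) if h[0] == 1)
        assert marg == pytest.approx(0.3, abs=0.03)

    def test_rare_haplotypes_dropped_by_floor(self):
        # perfectly correlated SNPs -> only 2 of 4 haplotypes observed
        ds = simulate_dataset(SimParams(n_unexposed_families=800, n_exposed_families=0,
                                        variant_allele_freq=0.3, seed=104))
        mother = np.hstack([ds.mother, ds.mother])
        father = np.hstack([ds.father, ds.father])
        child = np.hstack([ds.child, ds.child])
        space, _ = build_space(mother, father, child, ["a", "b"])
        assert space.n_haplotypes == 2
        assert set(space.haplotypes) == {(0, 0), (1, 1)}
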