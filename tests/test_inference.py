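"""Effect estimates, Wald algebra, and the marker scan."""

import numpy as np
import pytest
from scipy.stats import kstest, norm

from pooxe import (
    DegenerateDataError,
    SimParams,
    build_space,
    child_and_gxe_tests,
    fit_stratum,
    poo_effect,
    pooxe_test,
    scan,
    simulate_dataset,
    stratified_analysis,
    top_hits,
)
from conftest import fit_single_snp_pooxe


def _fits(dataset, constrained=False):
    space, f0 = build_space(dataset.mother, dataset.father, dataset.child,
                            dataset.snps["snp_id"])
    mask_u, mask_e = dataset.stratum_masks("exposure")
    kw = dict(init_freq=f0, constrain_equal_rr=constrained)
    fit_u = fit_stratum(dataset.mother[mask_u], dataset.father[mask_u],
                        dataset.child[mask_u], space, "unexposed", **kw)
    fit_e = fit_stratum(dataset.mother[mask_e], dataset.father[mask_e],
                        dataset.child[mask_e], space, "exposed", **kw)
    both = mask_u | mask_e
    pooled = fit_stratum(dataset.mother[both], dataset.father[both],
                         dataset.child[both], space, "pooled", **kw)
    h = [i for i, hp in enumerate(space.haplotypes) if hp == (1,)][0]
    return space, fit_u, fit_e, pooled, h


class TestWaldAlgebra:
    def test_poo_ratio_of_point_estimates(self, effect_dataset):
        _, fit_u, fit_e, _, h = _fits(effect_dataset)
        est = poo_effect(fit_e, h)
        assert est.estimate == pytest.approx(
            np.exp(fit_e.log_rr_mat[h] - fit_e.log_rr_pat[h]), rel=1e-12
        )
        assert est.ci_low < est.estimate < est.ci_high
        # CI reproduces from the reported log-scale se
        assert est.ci_high == pytest.approx(
            est.estimate * np.exp(norm.ppf(0.975) * est.se_log), rel=1e-6
        )

    def test_pooxe_closed_form_z(self):
        # log RRR_E = log 2 (se 0.2), log RRR_U = 0 (se 0.2)
        se = np.sqrt(0.2**2 + 0.2**2)
        z = np.log(2.0) / se
        assert z == pytest.approx(2.4507, abs=1e-4)
        assert 2 * norm.sf(z) == pytest.approx(0.0143, abs=2e-4)

    def test_pooxe_ratio_and_symmetry(self, effect_dataset):
        _, fit_u, fit_e, _, h = _fits(effect_dataset)
        res = pooxe_test(fit_e, fit_u, h)
        flipped = pooxe_test(fit_u, fit_e, h)
        assert flipped.estimate.estimate == pytest.approx(1 / res.estimate.estimate, rel=1e-10)
        assert flipped.estimate.p == pytest.approx(res.estimate.p, rel=1e-10)
        # identical strata -> ratio 1, z = 0
        same = pooxe_test(fit_e, fit_e, h)
        assert same.estimate.estimate == pytest.approx(1.0, rel=1e-12)
        assert same.estimate.z == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_spaces_rejected(self, effect_dataset, null_dataset):
        _, _, fit_e, _, h = _fits(effect_dataset)
        ds2 = simulate_dataset(SimParams(n_unexposed_families=300, n_exposed_families=300,
                                         n_effect_snps=2, seed=6))
        space2, f02 = build_space(ds2.mother, ds2.father, ds2.child, ds2.snps["snp_id"])
        other = fit_stratum(ds2.mother, ds2.father, ds2.child, space2, init_freq=f02)
        with pytest.raises(ValueError):
            pooxe_test(fit_e, other, h)


class TestChildAndGxe:
    def test_child_effect_recovered_without_poo(self):
        ds = simulate_dataset(
            SimParams(n_unexposed_families=2500, n_exposed_families=2500,
                      rr_mat=1.5, rr_pat=1.5, seed=31)
        )
        _, fit_u, fit_e, pooled, h = _fits(ds, constrained=True)
        child, gxe = child_and_gxe_tests(fit_e, fit_u, pooled, h)
        assert child.effect_type == "Child"
        assert child.estimate.ci_low <= 1.5 <= child.estimate.ci_high
        # no interaction planted
        assert gxe.estimate.ci_low <= 1.0 <= gxe.estimate.ci_high

    def test_gxe_on_identical_fits_is_unity(self, effect_dataset):
        _, fit_u, fit_e, pooled, h = _fits(effect_dataset, constrained=True)
        _, gxe = child_and_gxe_tests(fit_u, fit_u, pooled, h)
        assert gxe.estimate.estimate == pytest.approx(1.0, rel=1e-12)

    def test_requires_constrained_fits(self, effect_dataset):
        _, fit_u, fit_e, pooled, h = _fits(effect_dataset, constrained=False)
        with pytest.raises(ValueError):
            child_and_gxe_tests(fit_e, fit_u, pooled, h)


class TestNullCalibration:
    def test_null_pvalues_uniform(self):
        # moderate replicate count; KS at the 1% level
        ps = []
        for s in range(250):
            ds = simulate_dataset(
                SimParams(n_unexposed_families=500, n_exposed_families=500, seed=200_000 + s)
            )
            ps.append(fit_single_snp_pooxe(ds).estimate.p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestScan:
    def test_scan_table_schema_and_determinism(self, effect_dataset):
        t1 = scan(effect_dataset, "exposure")
        t2 = scan(effect_dataset, "exposure")
        assert list(t1.columns[:6]) == ["marker", "chrom", "pos", "target", "reference",
                                        "effect_type"]
        assert (t1["effect_type"] == "PoOxE").all()
        assert t1.equals(t2)

    def test_effect_snp_detected_among_nulls(self):
        ds = simulate_dataset(
            SimParams(variant_allele_freq=0.2, rr_mat=(1.0, 4.0), n_null_snps=30,
                      n_effect_snps=1, seed=71)
        )
        table = scan(ds, "exposure")
        best = top_hits(table, k=3)
        assert "effect_000" in set(best["marker"])

    def test_missing_exposure_families_excluded(self):
        ds = simulate_dataset(
            SimParams(n_unexposed_families=600, n_exposed_families=300,
                      exposure_missing_fraction=0.2, seed=73)
        )
        table = scan(ds, "exposure")
        n_used = table["n_unexposed"].iloc[0] + table["n_exposed"].iloc[0]
        n_missing = ds.exposure["exposure"].isna().sum()
        assert n_used == ds.n_families - n_missing
        assert n_missing > 0

    def test_all_missing_exposure_is_hard_error(self, effect_dataset):
        ds = effect_dataset.subset_families(np.ones(effect_dataset.n_families, bool))
        ds.exposure["exposure"] = np.nan
        with pytest.raises(ValueError):
            scan(ds, "exposure")

    def test_unknown_exposure_column(self, effect_dataset):
        with pytest.raises(KeyError):
            scan(effect_dataset, "no_such_exposure")

    def test_haplotype_mode_two_snp_windows(self):
        ds = simulate_dataset(
            SimParams(n_unexposed_families=700, n_exposed_families=350,
                      variant_allele_freq=0.3, n_effect_snps=3, seed=75)
        )
        table = scan(ds, "exposure", mode="haplotype", window=2)
        # 2 windows; each contributes up to 3 non-reference haplotypes
        assert set(table["marker"]) == {"effect_000-effect_001", "effect_001-effect_002"}
        assert ((table["p"] > 0) & (table["p"] <= 1)).all()


class TestWaldVersusLikelihoodRatio:
    def test_wald_and_lr_pvalues_agree_asymptotically(self):
        """Wald p-values track a likelihood-ratio oracle (Spearman rho > 0.99)
        across replicates spanning null and non-null interactions."""
        from scipy.optimize import minimize
        from scipy.stats import chi2, spearmanr

        from pooxe.likelihood import _StateModel, _group_patterns, _batch_loglik, _pack

        def lr_pvalue(ds, space, f0):
            """Oracle: LR test of H0 RRR_PoOxE=1 via joint two-stratum fits."""
            model = _StateModel(space)
            mask_u, mask_e = ds.stratum_masks("exposure")
            grouped = {}
            for name, mask in (("u", mask_u), ("e", mask_e)):
                grouped[name] = _group_patterns(
                    model, ds.mother[mask], ds.father[mask], ds.child[mask]
                )[:2]
            ref = space.reference_index

            def negll_free(t):
                # t = [eta_u, lm_u, lp_u, eta_e, lm_e, lp_e]
                return -float(
                    _batch_loglik(t[:3], model, *grouped["u"], ref, False)[0]
                    + _batch_loglik(t[3:], model, *grouped["e"], ref, False)[0]
                )

            def negll_null(t):
                # shared PoO difference: lm_e - lp_e = lm_u - lp_u = t[6]... use
                # t = [eta_u, lp_u, eta_e, lp_e, delta_poo, mean shift lm_e-lp_e const]
                eta_u, lp_u, eta_e, lp_e, delta = t
                tu = np.array([eta_u, lp_u + delta, lp_u])
                te = np.array([eta_e, lp_e + delta, lp_e])
                return -float(
                    _batch_loglik(tu, model, *grouped["u"], ref, False)[0]
                    + _batch_loglik(te, model, *grouped["e"], ref, False)[0]
                )

            x0 = _pack(f0, np.zeros(2), np.zeros(2), ref, False)
            free = minimize(negll_free, np.concatenate([x0, x0]), method="BFGS",
                            options={"gtol": 1e-6})
            null = minimize(negll_null, np.array([x0[0], 0.0, x0[0], 0.0, 0.0]),
                            method="BFGS", options={"gtol": 1e-6})
            stat = max(2.0 * (null.fun - free.fun), 0.0)
            return chi2.sf(stat, df=1)

        wald_ps, lr_ps = [], []
        for i, s in enumerate(range(40)):
            rrr = [1.0, 1.5, 2.0, 0.6][i % 4]
            ds = simulate_dataset(
                SimParams(n_unexposed_families=1100, n_exposed_families=500,
                          rr_mat=(1.0, rrr), seed=300_000 + s)
            )
            space, f0 = build_space(ds.mother, ds.father, ds.child, ds.snps["snp_id"])
            res = fit_single_snp_pooxe(ds)
            wald_ps.append(res.estimate.p)
            lr_ps.append(lr_pvalue(ds, space, f0))
        rho = spearmanr(wald_ps, lr_ps).statistic
        assert rho > 0.99
        # and the two tests agree closely on the log scale for moderate p
        logw, logl = np.log10(wald_ps), np.log10(lr_ps)
        assert np.median(np.abs(logw - logl)) < 0.1


class TestStratifiedAnalysis:
    def test_four_effect_rows_per_target(self):
        ds = simulate_dataset(
            SimParams(n_unexposed_families=800, n_exposed_families=400,
                      rr_mat=(1.0, 2.0), n_effect_snps=2, seed=77)
        )
        table = stratified_analysis(ds, "exposure", snp_ids=["effect_000"],
                                    haplotype_windows=[["effect_000", "effect_001"]])
        assert set(table["effect_type"]) == {"Child", "GxE", "PoO", "PoOxE"}
        one = table[table["marker"] == "effect_000"]
        assert len(one) == 4
        # published-table fields present for every row
        assert table[["rrr", "ci_low", "ci_high", "p", "frequency"]].notna().all().all()
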