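import numpy as np
import pytest

from pooxe import SimParams, build_space, fit_stratum, pooxe_test, simulate_dataset


@pytest.fixture(scope="session")
def null_dataset():
    """Moderate null dataset: no effects, MAF 0.2, both strata."""
    return simulate_dataset(SimParams(n_unexposed_families=800, n_exposed_families=400, seed=701))


@pytest.fixture(scope="session")
def effect_dataset():
    """Dataset with a maternal effect in the exposed stratum only (RRR_PoOxE=2)."""
    return simulate_dataset(
        SimParams(variant_allele_freq=0.2, rr_mat=(1.0, 2.0), seed=42)
    )


def fit_single_snp_pooxe(dataset, snp_index=0, exposure="exposure"):
    """Helper: resolve the space on pooled families, fit both strata,
    return the PoOxE Wald result for the variant allele."""
    cols = [snp_index]
    m, f, c = dataset.mother[:, cols], dataset.father[:, cols], dataset.child[:, cols]
    loci = dataset.snps["snp_id"].to_numpy()[cols]
    mask_u, mask_e = dataset.stratum_masks(exposure)
    both = mask_u | mask_e
    space, f0 = build_space(m[both], f[both], c[both], loci)
    fit_u = fit_stratum(m[mask_u], f[mask_u], c[mask_u], space, "unexposed", init_freq=f0)
    fit_e = fit_stratum(m[mask_e], f[mask_e], c[mask_e], space, "exposed", init_freq=f0)
    target = [i for i, h in enumerate(space.haplotypes) if h == (1,)][0]
    return pooxe_test(fit_e, fit_u, target)


@pytest.fixture(scope="session")
def pooxe_runner():
    return fit_single_snp_pooxe
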