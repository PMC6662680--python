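"""Replicated simulation experiments for calibrating the scan statistics.

These are the standard checks run against the estimator: type-I error
of the Wald PoOxE test under a global null, confidence-interval
coverage at known true ratios, realized false-discovery proportions at
a q-value threshold, Monte-Carlo verification of asymptotic power, and
ranking behaviour of a causal SNP inside a null scan. Each function
consumes an integer seed and spawns independent child seeds per
replicate, so results are reproducible and replicates are uncorrelated.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .fdr import qvalue
from .inference import PoOxEResult, pooxe_test, scan as scan_markers
from .likelihood import build_space, fit_stratum
from .power import PowerDesign, asymptotic_power
from .simulate import SimParams, simulate_dataset

__all__ = [
    "single_snp_pooxe",
    "null_rejection_rate",
    "ci_coverage",
    "fdr_calibration",
    "monte_carlo_power",
    "scan_ranking",
]

_MAX_SEED = 2**31 - 1


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _MAX_SEED, size=n)


def single_snp_pooxe(params: SimParams) -> PoOxEResult:
    """Simulate one dataset and run the full single-SNP PoOxE analysis."""
    ds = simulate_dataset(params)
    mask_u, mask_e = ds.stratum_masks("exposure")
    both = mask_u | mask_e
    m, f, c = ds.mother[:, :1], ds.father[:, :1], ds.child[:, :1]
    loci = ds.snps["snp_id"].to_numpy()[:1]
    space, f0 = build_space(m[both], f[both], c[both], loci)
    fit_u = fit_stratum(m[mask_u], f[mask_u], c[mask_u], space, "unexposed", init_freq=f0)
    fit_e = fit_stratum(m[mask_e], f[mask_e], c[mask_e], space, "exposed", init_freq=f0)
    target = [i for i, h in enumerate(space.haplotypes) if h == (1,)][0]
    return pooxe_test(fit_e, fit_u, target, marker=str(loci[0]))


def null_rejection_rate(
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
    n_unexposed: int = 1100,
    n_exposed: int = 500,
    maf: float = 0.2,
) -> float:
    """Empirical type-I error of the Wald PoOxE test under the global null."""
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        res = single_snp_pooxe(
            SimParams(n_unexposed_families=n_unexposed, n_exposed_families=n_exposed,
                      variant_allele_freq=maf, seed=int(s))
        )
        rejections += res.estimate.p < alpha
    return rejections / n_reps


def ci_coverage(
    true_rrr_pooxe: float,
    n_reps: int,
    seed: int,
    n_unexposed: int = 1100,
    n_exposed: int = 500,
    maf: float = 0.2,
) -> float:
    """Empirical coverage of the 95% CI for RRR_PoOxE.

    The interaction is planted through the maternal risk in the exposed
    stratum (RRR_PoOxE = RR_mat(exposed)), all other risks 1.
    """
    covered = 0
    for s in _child_seeds(seed, n_reps):
        res = single_snp_pooxe(
            SimParams(n_unexposed_families=n_unexposed, n_exposed_families=n_exposed,
                      variant_allele_freq=maf, rr_mat=(1.0, true_rrr_pooxe), seed=int(s))
        )
        covered += res.estimate.ci_low <= true_rrr_pooxe <= res.estimate.ci_high
    return covered / n_reps


def fdr_calibration(
    n_reps: int,
    seed: int,
    m: int = 10_000,
    n_alt: int = 1_000,
    q_threshold: float = 0.2,
    effect_z: float = 2.0,
) -> float:
    """Mean realized false-discovery proportion at a q-value threshold.

    Each replicate draws ``m - n_alt`` null p-values from Uniform(0,1)
    and ``n_alt`` alternatives as upper-tail p-values of a unit-variance
    z-test with mean shift ``effect_z``, then runs the full pi0 + q-value
    path and records the fraction of null markers among q < threshold
    calls (0 when nothing is called).
    """
    rng = np.random.default_rng(seed)
    n_null = m - n_alt
    fdps = np.empty(n_reps)
    for r in range(n_reps):
        p = np.concatenate([
            rng.random(n_null),
            norm.sf(rng.standard_normal(n_alt) + effect_z),
        ])
        res = qvalue(p)
        called = res.q_values < q_threshold
        n_called = called.sum()
        fdps[r] = called[:n_null].sum() / n_called if n_called else 0.0
    return float(fdps.mean())


def monte_carlo_power(
    design: PowerDesign,
    n_reps: int,
    seed: int,
) -> float:
    """Empirical rejection rate of the Wald test at the design's settings."""
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        res = single_snp_pooxe(
            SimParams(
                n_unexposed_families=design.n_unexposed,
                n_exposed_families=design.n_exposed,
                variant_allele_freq=design.maf,
                rr_mat=(design.rr_mat_unexposed, design.rr_mat_exposed),
                rr_pat=(design.rr_pat_unexposed, design.rr_pat_exposed),
                dyad_fraction=design.dyad_fraction,
                seed=int(s),
            )
        )
        rejections += res.estimate.p < design.alpha
    return rejections / n_reps


def scan_ranking(
    true_rrr_pooxe: float,
    n_null_snps: int,
    n_reps: int,
    seed: int,
    n_unexposed: int = 1100,
    n_exposed: int = 500,
    maf: float = 0.2,
    top_k: int = 5,
) -> dict:
    """Causal-SNP recovery inside a null scan.

    Returns the fraction of replicates in which the causal SNP ranks in
    the top ``top_k`` by p-value and the fraction whose CI covers the
    true RRR_PoOxE.
    """
    in_top = 0
    covered = 0
    for s in _child_seeds(seed, n_reps):
        ds = simulate_dataset(
            SimParams(n_unexposed_families=n_unexposed, n_exposed_families=n_exposed,
                      variant_allele_freq=maf, rr_mat=(1.0, true_rrr_pooxe),
                      n_null_snps=n_null_snps, n_effect_snps=1, seed=int(s))
        )
        table = scan_markers(ds, "exposure")
        ranked = table.sort_values("p", kind="mergesort").reset_index(drop=True)
        rank = ranked.index[ranked["marker"] == "effect_000"][0]
        in_top += rank < top_k
        row = table[table["marker"] == "effect_000"].iloc[0]
        covered += row["ci_low"] <= true_rrr_pooxe <= row["ci_high"]
    return {"top_k_rate": in_top / n_reps, "ci_coverage": covered / n_reps}
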