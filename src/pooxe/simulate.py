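"""Synthetic case-parent triad data with known parent-of-origin effects.

The generator is the exact probabilistic twin of the model the estimator
fits: parents are drawn under Hardy-Weinberg equilibrium and random
mating, each parent transmits one allele to the child, and ascertainment
of an affected child tilts the transmitted-allele distribution by a
multiplicative relative risk per inherited variant allele — ``rr_mat``
for the maternally inherited copy and ``rr_pat`` for the paternally
inherited one. Exposure strata (maternal exposure 0/1) have their own
allele frequency and risk parameters, so a parent-of-origin x
environment interaction

    RRR_PoOxE = (rr_mat_E / rr_pat_E) / (rr_mat_U / rr_pat_U)

can be planted with known truth. Latent states are the four ordered
allele indicators ``(t_m, u_m, t_f, u_f)`` (transmitted / untransmitted,
maternal / paternal), collapsed to the observable genotype dosages
``M = t_m + u_m``, ``F = t_f + u_f``, ``C = t_m + t_f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MISSING, TriadDataset

__all__ = ["SimParams", "triad_state_distribution", "simulate_dataset", "inject_errors"]

# ordered latent states (t_m, u_m, t_f, u_f) over {0,1}^4
_STATES = np.array([[(s >> 3) & 1, (s >> 2) & 1, (s >> 1) & 1, s & 1] for s in range(16)], dtype=np.int8)


def _as_pair(x) -> tuple[float, float]:
    if np.isscalar(x):
        return float(x), float(x)
    a, b = x
    return float(a), float(b)


@dataclass(frozen=True)
class SimParams:
    """Design of a simulated triad/dyad study.

    Per-stratum parameters are ``(unexposed, exposed)`` pairs; a scalar
    is broadcast to both strata. Defaults reproduce the reference power
    design: 1100 unexposed and 500 exposed complete triads at variant
    allele frequency 0.2 with no effects.

    ``n_effect_snps`` SNPs carry the stated relative risks;
    ``n_null_snps`` additional SNPs have all relative risks equal to 1.
    """

    n_unexposed_families: int = 1100
    n_exposed_families: int = 500
    variant_allele_freq: tuple[float, float] | float = 0.2
    rr_mat: tuple[float, float] | float = (1.0, 1.0)
    rr_pat: tuple[float, float] | float = (1.0, 1.0)
    dyad_fraction: float = 0.0
    exposure_missing_fraction: float = 0.0
    n_null_snps: int = 0
    n_effect_snps: int = 1
    genotype_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_unexposed_families", "n_exposed_families", "n_null_snps", "n_effect_snps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dyad_fraction", "exposure_missing_fraction", "genotype_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for p in _as_pair(self.variant_allele_freq):
            if not 0.0 < p < 1.0:
                raise ValueError("variant_allele_freq must lie in (0, 1)")
        for rr in _as_pair(self.rr_mat) + _as_pair(self.rr_pat):
            if rr <= 0.0:
                raise ValueError("relative risks must be positive")

    @property
    def freq_by_stratum(self) -> tuple[float, float]:
        return _as_pair(self.variant_allele_freq)

    @property
    def rr_mat_by_stratum(self) -> tuple[float, float]:
        return _as_pair(self.rr_mat)

    @property
    def rr_pat_by_stratum(self) -> tuple[float, float]:
        return _as_pair(self.rr_pat)

    @property
    def rrr_poo_by_stratum(self) -> tuple[float, float]:
        rm, rp = self.rr_mat_by_stratum, self.rr_pat_by_stratum
        return rm[0] / rp[0], rm[1] / rp[1]

    @property
    def rrr_pooxe(self) -> float:
        """True ratio of parent-of-origin ratios, exposed over unexposed."""
        u, e = self.rrr_poo_by_stratum
        return e / u


def triad_state_distribution(p: float, rr_mat: float, rr_pat: float) -> np.ndarray:
    """Distribution of the 16 ordered latent states of a case triad.

    Returns a length-16 vector indexed by ``8*t_m + 4*u_m + 2*t_f + u_f``
    with

        P(state) = p^S (1-p)^(4-S) rr_mat^t_m rr_pat^t_f / Z,

    where ``S`` is the number of variant alleles among the four and the
    normalizer factorizes as ``Z = (1-p+p*rr_mat) * (1-p+p*rr_pat)``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must lie in (0, 1)")
    if rr_mat <= 0 or rr_pat <= 0:
        raise ValueError("relative risks must be positive")
    tm, um, tf, uf = _STATES.T
    total = _STATES.sum(axis=1)
    w = p**total * (1.0 - p) ** (4 - total) * rr_mat**tm * rr_pat**tf
    z = (1.0 - p + p * rr_mat) * (1.0 - p + p * rr_pat)
    return w / z


def _draw_stratum(rng: np.random.Generator, n: int, p: float, rr_mat: float, rr_pat: float):
    """Draw (M, F, C) dosage arrays for n families of one stratum."""
    probs = triad_state_distribution(p, rr_mat, rr_pat)
    states = rng.choice(16, size=n, p=probs)
    st = _STATES[states]
    m = (st[:, 0] + st[:, 1]).astype(np.int8)
    f = (st[:, 2] + st[:, 3]).astype(np.int8)
    c = (st[:, 0] + st[:, 2]).astype(np.int8)
    return m, f, c


def simulate_dataset(params: SimParams) -> TriadDataset:
    """Simulate a triad dataset under the parent-of-origin risk model.

    Families are i.i.d. within exposure stratum. Effect SNPs (named
    ``effect_###``) use the stratum relative risks; null SNPs
    (``null_###``) use all risks 1 at the same allele frequencies. A
    ``dyad_fraction`` of families, chosen at random, have the father
    entirely untyped; ``exposure_missing_fraction`` of families have
    exposure set to missing. Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n_u, n_e = params.n_unexposed_families, params.n_exposed_families
    n = n_u + n_e
    if n == 0:
        raise ValueError("at least one family is required")
    p_u, p_e = params.freq_by_stratum
    rm_u, rm_e = params.rr_mat_by_stratum
    rp_u, rp_e = params.rr_pat_by_stratum

    snp_ids = [f"effect_{i:03d}" for i in range(params.n_effect_snps)]
    snp_ids += [f"null_{i:03d}" for i in range(params.n_null_snps)]
    s = len(snp_ids)
    if s == 0:
        raise ValueError("at least one SNP is required")

    mother = np.empty((n, s), dtype=np.int8)
    father = np.empty((n, s), dtype=np.int8)
    child = np.empty((n, s), dtype=np.int8)
    for j, snp in enumerate(snp_ids):
        null = snp.startswith("null_")
        rm = (1.0, 1.0) if null else (rm_u, rm_e)
        rp = (1.0, 1.0) if null else (rp_u, rp_e)
        mother[:n_u, j], father[:n_u, j], child[:n_u, j] = _draw_stratum(rng, n_u, p_u, rm[0], rp[0])
        mother[n_u:, j], father[n_u:, j], child[n_u:, j] = _draw_stratum(rng, n_e, p_e, rm[1], rp[1])

    exposure = np.concatenate([np.zeros(n_u), np.ones(n_e)])
    if params.exposure_missing_fraction > 0:
        miss = rng.random(n) < params.exposure_missing_fraction
        exposure[miss] = np.nan
    if params.dyad_fraction > 0:
        dyad = rng.random(n) < params.dyad_fraction
        father[dyad, :] = MISSING

    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": np.ones(s, dtype=int),
            "pos": np.arange(1, s + 1) * 1000,
            "allele_ref": ["1"] * s,
            "allele_var": ["2"] * s,
        }
    )
    dataset = TriadDataset(
        snps=snps,
        mother=mother,
        father=father,
        child=child,
        family_ids=np.array([f"fam{i:05d}" for i in range(n)]),
        exposure=pd.DataFrame({"exposure": exposure}),
    )
    if params.genotype_error_rate > 0:
        dataset = inject_errors(dataset, params.genotype_error_rate, seed=int(rng.integers(2**31 - 1)))
    return dataset


def inject_errors(dataset: TriadDataset, rate: float, seed: int = 0) -> TriadDataset:
    """Return a copy with random single-allele flips in genotype calls.

    Each non-missing genotype call (individual x SNP) is perturbed
    independently with probability ``rate``: one of its two allele slots
    is flipped (dosage 0 -> 1, 2 -> 1, 1 -> 0 or 2 at random), creating
    Mendelian inconsistencies and Hardy-Weinberg departures for QC to
    catch. The input dataset is not modified.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = dataset.subset_families(np.ones(dataset.n_families, dtype=bool))
    if rate == 0.0:
        return out
    for geno in (out.mother, out.father, out.child):
        hit = (rng.random(geno.shape) < rate) & (geno != MISSING)
        # flip one of the two allele slots: hets move up or down at random
        direction = np.where(geno == 0, 1, np.where(geno == 2, -1, rng.choice([-1, 1], size=geno.shape)))
        geno[hit] = (geno + direction)[hit]
    return out
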