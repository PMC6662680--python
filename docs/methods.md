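# Methods

## The triad risk model

A case-parent triad contributes the unphased genotypes of mother,
father and affected child at 1-3 diallelic SNPs. The model conditions
on the child being a case. Its latent state is the ordered quadruple of
parental haplotypes `(t_m, u_m, t_f, u_f)` — transmitted and
untransmitted, maternal and paternal. Under Hardy-Weinberg equilibrium,
random mating, and a rare-disease multiplicative risk acting once per
inherited non-reference haplotype,

    pi(s) = f(t_m) f(u_m) f(t_f) f(u_f) RR_mat(t_m) RR_pat(t_f) / Z,
    Z = (Σ_h f(h) RR_mat(h)) (Σ_h f(h) RR_pat(h)),

with `f` the haplotype frequency vector and `RR_mat`, `RR_pat` the
relative risks per maternally / paternally inherited copy (reference
haplotype fixed at 1). There is no separate homozygote ("double-dose")
parameter: the reported quantities are per-allele RRs and their ratios,
so the leaner model with one multiplicative factor per inherited copy
is used throughout, and the simulator is its exact generative twin.

Derived quantities:

- `RRR_PoO = RR_mat / RR_pat` — the parent-of-origin effect within one
  exposure stratum;
- `RRR_PoOxE = RRR_PoO(exposed) / RRR_PoO(unexposed)` — the
  interaction; the genome-wide scan tests `H0: RRR_PoOxE = 1`.

Strata are fitted fully separately (frequencies and risks), which makes
the two stratum estimates independent and justifies adding their
squared standard errors for the ratio test. Families with missing
exposure are dropped per exposure scan, not globally.

## Estimation

The observed-data likelihood sums `pi` over all latent states
compatible with each family's genotypes: a missing father (dyad) is
marginalized completely, and ambiguous multi-locus phase contributes
all consistent haplotype assignments. Families are collapsed to unique
genotype patterns, so the E-step is a small matrix product regardless
of sample size.

Reparameterizing with the tilted transmission distributions
`f_m(h) ∝ f(h) RR_mat(h)` and `f_p(h) ∝ f(h) RR_pat(h)` factorizes the
complete-data likelihood into three independent multinomials (the two
untransmitted slots share `f`; the transmitted slots follow `f_m` and
`f_p`). The M-step is therefore closed form — frequencies from expected
untransmitted counts, risks from the ratio of tilted to untilted
frequencies — and EM is monotone in the observed log-likelihood (the
implementation asserts this every iteration). The same objective is
exposed to a BFGS optimizer over (multinomial-logit frequencies, log
risks); tests require the two routes to agree. Convergence is declared
when the log-likelihood improves by less than 1e-8 (configurable, max
5000 iterations); non-convergence flags the fit rather than raising,
and flagged fits refuse to emit Wald numbers.

Standard errors come from the inverse of the observed information,
computed by central finite differences (step 1e-4) of the observed
log-likelihood at the optimum, on the unconstrained scale. The PoO
contrast variance is `var(λ_m) + var(λ_p) - 2 cov(λ_m, λ_p)`.

For the Child and GxE rows the maternal and paternal risks are
constrained equal; the same reparameterization (one shared tilted
distribution) keeps the M-step closed form. Child effects come from a
pooled-strata constrained fit, GxE from the exposed/unexposed ratio of
stratum constrained fits.

## Haplotype spaces

For 1-3 SNPs the space starts from all 2^L haplotypes. A
frequency-only EM pass (risks fixed at 1) on the pooled strata fixes
the reference — the most frequent haplotype — and applies the frequency
floor (default 1%): haplotypes below the floor are excluded from the
space and their (rare) carrier families skipped with a logged count.
This mirrors follow-up practice where only the observed haplotype
combinations are analyzed; an alternative would be to tie rare
haplotypes' risks to the reference while keeping their frequencies,
but that breaks the closed-form M-step for a negligible gain at the
floor's scale. Both strata always share one resolved space, so
cross-stratum ratios compare like with like.

## Quality control

Filters and defaults: missing call rate > 5%; parental MAF < 5%; exact
conditional HWE test p < 0.001; Mendelian error rate > 1%; perfect LD
(r² = 1 within an absolute tolerance of 1e-12) with a retained SNP
among the 5 preceding map positions. MAF, HWE and LD use parents only,
since case children are ascertained and non-independent; the Mendel
rate uses complete triads. The Mendel threshold and the
parents-vs-everyone convention are deliberate configuration defaults
(`QCThresholds`), as source conventions vary. The first four filters
are evaluated independently on every SNP (their combined removal is
order-insensitive); LD pruning runs last on the survivors. A family
with a Mendelian-impossible triple at a retained SNP has that SNP set
missing for all three members — the likelihood would otherwise assign
it zero probability. The exclusion report counts each criterion
independently while removing each SNP once.

The HWE test enumerates the conditional distribution of the
heterozygote count given the diploid total and minor-allele count
(probability ∝ 2^h n!/(n_AA! h! n_aa!), log-gamma arithmetic) and sums
all outcomes no more probable than the observed one; monomorphic input
returns 1 by convention. An exact big-integer enumeration oracle in the
test suite agrees to ~6e-14 over every configuration with n ≤ 200.

## Multiple testing

q-values follow the standard spline path: `pi0(λ) = #{p>λ}/(m(1-λ))` on
λ = 0, 0.05, …, 0.90, a natural cubic spline through these points
evaluated at λ = 0.90, clipped to (0, 1]; below 100 tests pi0 falls
back to 1 (logged). The step-down transform then gives
`q_(i) = min_j≥i (pi0 · m · p_(j)/j)`; with pi0 = 1 this is exactly
Benjamini-Hochberg. QQ data use uniform order-statistic medians as
expected quantiles and pointwise Beta(i, m-i+1) bands — a band
construction choice recorded in the output metadata; the bands are
pointwise, not simultaneous, so even weak contamination moves bulk
ranks outside them.

## Asymptotic power

Per stratum, the per-family expected Fisher information of the
observable genotype multinomial — triads collapse the 16 latent states
to (M, F, C) dosage cells, dyads to (M, C) — is computed at the true
parameters over (logit allele frequency, log RR_mat, log RR_pat), with
cell-probability gradients by central differences. With `v` the
(1, -1) risk-contrast variance from the inverse information,

    se² = v_E/n_E + v_U/n_U,
    power = Φ(δ - z_{1-α/2}) + Φ(-δ - z_{1-α/2}),  δ = |log RRR_PoOxE|/se.

At `RRR_PoOxE = 1` this reduces to α exactly. Using observable- rather
than complete-data information means a dyad fraction correctly lowers
power. Power curves vary the maternal RR in the exposed stratum so the
abscissa equals `RRR_PoOxE` directly; curve reproduction defaults to
complete triads (dyad fraction 0).

## What the simulator does and does not emulate

The generator draws families i.i.d. within stratum from the exact
fitted model: HWE, random mating, multiplicative per-copy risks, fixed
stratum sizes (exposure assigned by design so power experiments have
exact n), completely-at-random father missingness and exposure
missingness, one child per family, autosomal diallelic SNPs, and
independent SNPs given the stratum. It does not emulate population
stratification or admixture, linkage disequilibrium between markers
(except when planted by construction), X-linked inheritance,
informative missingness, maternal-genotype main effects, or sibling
sets. Calibration results on these simulations therefore validate the
estimator and test machinery under the model's own assumptions; they do
not certify robustness to violations of those assumptions in real data.
How families with several offspring should enter the likelihood is not
specified by the design this package follows; the reader keeps the
first child per family and logs the rest.

## Numerical choices and degenerate inputs

- Probabilities are floored at 1e-300 inside logs; a family compatible
  with no latent state (a Mendelian error that survived QC) is skipped
  and counted, never silently absorbed.
- Monomorphic data (fewer than two haplotypes above the floor) raise a
  `DegenerateDataError`; a scan records per-marker failures and
  excludes them from the multiplicity count only when no p-value was
  produced.
- Zero p-values are floored at 1e-300 for the -log10 QQ scale.
- Grid/experiment seeds are spawned from a single integer seed via a
  generator, keeping every derived seed below 2^31; identical seeds
  give byte-identical written outputs.

## Problem sizes in the test and calibration runs

Calibration experiments use the reference design — 1100 unexposed and
500 exposed complete triads, MAF 0.2, α = 0.05 — with 2000 replicates
for type-I error, 1000 per setting for CI coverage, 1000 replicates of
m = 10,000 markers for FDR calibration, 500 replicates per cell of the
3×3 power grid, and 60 replicates of a 201-SNP recovery scan; these
sizes put Monte-Carlo error well below the effect sizes being checked
while keeping the default suite quick to run.
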