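"""Maximum-likelihood fitting of the case-parent triad risk model.

The model: each parent carries two haplotypes drawn independently from a
population frequency vector ``f`` (Hardy-Weinberg equilibrium, random
mating), each transmits one to the affected child, and ascertainment of
the case multiplies the probability of a latent state
``(t_m, u_m, t_f, u_f)`` (transmitted/untransmitted haplotype of the
mother/father) by ``RR_mat(t_m) * RR_pat(t_f)`` — a multiplicative
relative risk per inherited non-reference haplotype, separate for the
maternal and paternal copy. The state probability is

    pi(s) = f(t_m) f(u_m) f(t_f) f(u_f) RR_mat(t_m) RR_pat(t_f) / Z,
    Z = (sum_h f(h) RR_mat(h)) * (sum_h f(h) RR_pat(h)).

Observed data are unphased genotype dosages for mother, father and
child, with the father possibly untyped (a dyad) and phase ambiguous
for multi-locus haplotypes; the observed-data likelihood sums ``pi``
over all latent states compatible with each family's genotypes.

Fitting is by EM. Reparameterizing with the tilted transmission
frequencies ``fm(h) = f(h) RR_mat(h) / sum f RR_mat`` (and ``fp``
likewise) factorizes the complete-data likelihood into independent
multinomials — untransmitted slots ~ ``f``, maternal transmitted ~
``fm``, paternal transmitted ~ ``fp`` — so the M-step is closed form
and EM is monotone in the observed log-likelihood. A direct
quasi-Newton optimizer over the same unconstrained parameterization
(multinomial-logit frequencies, log risks) is provided as a cross-check.
Standard errors come from the numerically differentiated observed
information at the optimum.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .datasets import MISSING

__all__ = [
    "HaplotypeSpace",
    "FitOptions",
    "StratumFit",
    "DegenerateDataError",
    "build_space",
    "complete_data_loglik",
    "observed_data_loglik",
    "fit_stratum",
]

_TINY = 1e-300


class DegenerateDataError(ValueError):
    """Raised when the data cannot identify the model (e.g. monomorphic SNP)."""


@dataclass(frozen=True)
class HaplotypeSpace:
    """Haplotypes over an ordered set of 1-3 SNPs.

    ``haplotypes`` are tuples of variant-allele indicators (0/1) per
    locus. ``reference_index`` points at the baseline haplotype whose
    relative risks are fixed to 1; by convention it is the most frequent
    haplotype after an initial frequency-only EM pass. Haplotypes whose
    initial frequency falls below ``frequency_floor`` are excluded from
    the space (see :func:`build_space`).
    """

    loci: tuple[str, ...]
    haplotypes: tuple[tuple[int, ...], ...]
    reference_index: int = 0
    frequency_floor: float = 0.01

    def __post_init__(self) -> None:
        if not 1 <= len(self.loci) <= 3:
            raise ValueError("1 to 3 loci are supported")
        if len(self.haplotypes) < 2:
            raise DegenerateDataError("at least two haplotypes are required")
        if not 0 <= self.reference_index < len(self.haplotypes):
            raise ValueError("reference_index out of range")

    @classmethod
    def full(cls, loci, frequency_floor: float = 0.01) -> "HaplotypeSpace":
        loci = tuple(loci)
        haps = tuple(itertools.product((0, 1), repeat=len(loci)))
        return cls(loci=loci, haplotypes=haps, frequency_floor=frequency_floor)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def hap_string(self, h: int) -> str:
        return "-".join(str(a) for a in self.haplotypes[h])


@dataclass(frozen=True)
class FitOptions:
    tol: float = 1e-8
    max_iter: int = 5000
    method: str = "em"  # "em" or "bfgs"
    hessian_step: float = 1e-4


class _StateModel:
    """Enumeration of the H^4 ordered latent states for one space."""

    def __init__(self, space: HaplotypeSpace):
        self.space = space
        h = space.n_haplotypes
        hap = np.array(space.haplotypes, dtype=np.int8)  # (H, L)
        grid = np.indices((h, h, h, h)).reshape(4, -1)
        self.tm, self.um, self.tf, self.uf = grid
        self.n_states = h**4
        # observable genotype dosages per state: (S, L)
        self.gm = hap[self.tm] + hap[self.um]
        self.gf = hap[self.tf] + hap[self.uf]
        self.gc = hap[self.tm] + hap[self.tf]

    def state_probs(self, f: np.ndarray, rrm: np.ndarray, rrp: np.ndarray) -> np.ndarray:
        """pi over states; parameters may carry leading batch dimensions."""
        f, rrm, rrp = np.atleast_2d(f), np.atleast_2d(rrm), np.atleast_2d(rrp)
        w = (
            f[:, self.tm] * f[:, self.um] * f[:, self.tf] * f[:, self.uf]
            * rrm[:, self.tm] * rrp[:, self.tf]
        )
        z = np.einsum("bh,bh->b", f, rrm) * np.einsum("bh,bh->b", f, rrp)
        return np.squeeze(w / z[:, None])

    def pattern_mask(self, gm: np.ndarray, gf: np.ndarray, gc: np.ndarray) -> np.ndarray:
        """States compatible with one family's genotype pattern (-1 = missing)."""
        ok = np.ones(self.n_states, dtype=bool)
        for l in range(len(self.space.loci)):
            if gm[l] != MISSING:
                ok &= self.gm[:, l] == gm[l]
            if gf[l] != MISSING:
                ok &= self.gf[:, l] == gf[l]
            if gc[l] != MISSING:
                ok &= self.gc[:, l] == gc[l]
        return ok


def _group_patterns(model: _StateModel, mother, father, child):
    """Collapse families into unique genotype patterns with state masks.

    Returns (masks (K, S) float, counts (K,), n_skipped) where skipped
    families are those compatible with no latent state (surviving
    Mendelian errors).
    """
    mother = np.atleast_2d(np.asarray(mother, dtype=np.int8))
    father = np.atleast_2d(np.asarray(father, dtype=np.int8))
    child = np.atleast_2d(np.asarray(child, dtype=np.int8))
    rows = np.hstack([mother, father, child])
    uniq, counts = np.unique(rows, axis=0, return_counts=True)
    l = mother.shape[1]
    masks, kept = [], []
    n_skipped = 0
    for i, row in enumerate(uniq):
        mask = model.pattern_mask(row[:l], row[l : 2 * l], row[2 * l :])
        if mask.any():
            masks.append(mask)
            kept.append(i)
        else:
            n_skipped += int(counts[i])
    if not masks:
        raise DegenerateDataError("no family is compatible with any latent state")
    return np.array(masks, dtype=np.float64), counts[kept].astype(np.float64), n_skipped


def _freq_em(model: "_StateModel", masks, counts, tol: float, max_iter: int) -> np.ndarray:
    """Frequency-only EM (all relative risks fixed at 1)."""
    h = model.space.n_haplotypes
    f = np.full(h, 1.0 / h)
    ones = np.ones(h)
    n4 = 4.0 * counts.sum()
    prev = -np.inf
    for _ in range(max_iter):
        pi = model.state_probs(f, ones, ones)
        classw = masks @ pi
        ll = float(counts @ np.log(np.maximum(classw, _TINY)))
        ns = pi * (masks.T @ (counts / np.maximum(classw, _TINY)))
        tot = (
            np.bincount(model.tm, weights=ns, minlength=h)
            + np.bincount(model.um, weights=ns, minlength=h)
            + np.bincount(model.tf, weights=ns, minlength=h)
            + np.bincount(model.uf, weights=ns, minlength=h)
        )
        f = np.maximum(tot / n4, _TINY)
        f /= f.sum()
        if abs(ll - prev) < tol:
            break
        prev = ll
    return f


def build_space(
    mother, father, child, loci, frequency_floor: float = 0.01, tol: float = 1e-6, max_iter: int = 500
) -> tuple[HaplotypeSpace, np.ndarray]:
    """Resolve the haplotype space on data: reference and supported set.

    Runs a frequency-only EM (all relative risks fixed at 1) on the full
    2^L haplotype set, drops haplotypes with estimated frequency below
    ``frequency_floor``, and sets the reference to the most frequent
    haplotype. Returns the resolved space and the initial frequency
    vector over its haplotypes (renormalized).
    """
    full = HaplotypeSpace.full(loci, frequency_floor)
    model = _StateModel(full)
    masks, counts, _ = _group_patterns(model, mother, father, child)
    f = _freq_em(model, masks, counts, tol, max_iter)
    keep = np.flatnonzero(f >= frequency_floor)
    if keep.size < 2:
        raise DegenerateDataError(
            "fewer than two haplotypes exceed the frequency floor (monomorphic data?)"
        )
    f_kept = f[keep] / f[keep].sum()
    haps = tuple(full.haplotypes[i] for i in keep)
    ref = int(np.argmax(f_kept))
    space = HaplotypeSpace(
        loci=full.loci, haplotypes=haps, reference_index=ref, frequency_floor=frequency_floor
    )
    return space, f_kept


@dataclass
class StratumFit:
    """ML estimates for one exposure stratum.

    ``log_rr_mat``/``log_rr_pat`` are full per-haplotype vectors with the
    reference entry fixed at 0. The covariance is over the free
    parameter vector laid out as multinomial-logit frequencies
    (non-reference haplotypes, in order) followed by log maternal risks
    and log paternal risks (or a single shared log risk block when the
    fit was constrained to ``RR_mat = RR_pat``).
    """

    stratum: str
    space: HaplotypeSpace
    freq: np.ndarray
    log_rr_mat: np.ndarray
    log_rr_pat: np.ndarray
    covariance: np.ndarray
    loglik: float
    n_families: int
    n_skipped: int
    converged: bool
    iterations: int
    constrained: bool = False
    param_names: list[str] = field(default_factory=list)

    def _free(self) -> list[int]:
        ref = self.space.reference_index
        return [h for h in range(self.space.n_haplotypes) if h != ref]

    def _col(self, block: str, h: int) -> int:
        free = self._free()
        k = len(free)
        i = free.index(h)
        if block == "freq":
            return i
        if self.constrained:
            if block != "rr":
                raise ValueError("constrained fit has a single risk block 'rr'")
            return k + i
        return k + i if block == "rr_mat" else 2 * k + i

    def var_log_rr(self, block: str, h: int) -> float:
        c = self._col(block, h)
        return float(self.covariance[c, c])

    def var_log_poo(self, h: int) -> float:
        """Variance of log(RR_mat/RR_pat) for haplotype h."""
        if self.constrained:
            raise ValueError("parent-of-origin contrast undefined for a constrained fit")
        a, b = self._col("rr_mat", h), self._col("rr_pat", h)
        return float(self.covariance[a, a] + self.covariance[b, b] - 2.0 * self.covariance[a, b])

    def to_json(self) -> str:
        return json.dumps(
            {
                "stratum": self.stratum,
                "loci": list(self.space.loci),
                "haplotypes": [self.space.hap_string(h) for h in range(self.space.n_haplotypes)],
                "reference_index": self.space.reference_index,
                "freq": self.freq.tolist(),
                "log_rr_mat": self.log_rr_mat.tolist(),
                "log_rr_pat": self.log_rr_pat.tolist(),
                "covariance": self.covariance.tolist(),
                "loglik": self.loglik,
                "n_families": self.n_families,
                "n_skipped": self.n_skipped,
                "converged": self.converged,
                "iterations": self.iterations,
                "constrained": self.constrained,
            },
            indent=1,
        )


def complete_data_loglik(
    freq: np.ndarray,
    log_rr_mat: np.ndarray,
    log_rr_pat: np.ndarray,
    state_counts: np.ndarray,
    space: HaplotypeSpace,
) -> float:
    """Log-likelihood of fully observed latent state counts.

    ``state_counts`` indexes the H^4 ordered states in the same order as
    ``np.indices((H,H,H,H))``. A zero-probability state with positive
    count yields ``-inf``.
    """
    model = _StateModel(space)
    counts = np.asarray(state_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("state counts must be nonnegative")
    pi = model.state_probs(np.asarray(freq, float), np.exp(log_rr_mat), np.exp(log_rr_pat))
    pos = counts > 0
    if np.any(pi[pos] <= 0.0):
        return -np.inf
    return float(counts[pos] @ np.log(pi[pos]))


def observed_data_loglik(
    freq, log_rr_mat, log_rr_pat, mother, father, child, space: HaplotypeSpace
) -> float:
    """Observed-data log-likelihood: sums pi over states compatible with
    each family's (possibly incomplete, unphased) genotypes."""
    model = _StateModel(space)
    masks, counts, _ = _group_patterns(model, mother, father, child)
    pi = model.state_probs(np.asarray(freq, float), np.exp(log_rr_mat), np.exp(log_rr_pat))
    return float(counts @ np.log(np.maximum(masks @ pi, _TINY)))


# ---------------------------------------------------------------------------
# parameter packing: theta = [eta (H-1 logit freqs), lam_m, lam_p] or
# [eta, lam] for the RR_mat = RR_pat constrained model


def _unpack(theta: np.ndarray, h: int, ref: int, constrained: bool):
    theta = np.atleast_2d(theta)
    k = h - 1
    free = [i for i in range(h) if i != ref]
    logits = np.zeros((theta.shape[0], h))
    logits[:, free] = theta[:, :k]
    f = np.exp(logits - logits.max(axis=1, keepdims=True))
    f /= f.sum(axis=1, keepdims=True)
    lm = np.zeros((theta.shape[0], h))
    lp = np.zeros((theta.shape[0], h))
    if constrained:
        lm[:, free] = theta[:, k : 2 * k]
        lp = lm
    else:
        lm[:, free] = theta[:, k : 2 * k]
        lp[:, free] = theta[:, 2 * k : 3 * k]
    return f, np.exp(lm), np.exp(lp)


def _pack(freq, log_rr_mat, log_rr_pat, ref: int, constrained: bool) -> np.ndarray:
    h = len(freq)
    free = [i for i in range(h) if i != ref]
    eta = np.log(freq[free] / freq[ref])
    if constrained:
        return np.concatenate([eta, np.asarray(log_rr_mat)[free]])
    return np.concatenate([eta, np.asarray(log_rr_mat)[free], np.asarray(log_rr_pat)[free]])


def _batch_loglik(theta, model, masks, counts, ref, constrained):
    f, rrm, rrp = _unpack(theta, model.space.n_haplotypes, ref, constrained)
    pi = np.atleast_2d(model.state_probs(f, rrm, rrp))
    classw = pi @ masks.T
    return np.log(np.maximum(classw, _TINY)) @ counts


def _em(model, masks, counts, f0, ref, constrained, tol, max_iter):
    h = model.space.n_haplotypes
    n = counts.sum()
    f = f0.copy()
    rrm = np.ones(h)
    rrp = np.ones(h)
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = model.state_probs(f, rrm, rrp)
        classw = masks @ pi
        ll = float(counts @ np.log(np.maximum(classw, _TINY)))
        if ll < prev - 1e-9:  # EM monotonicity guard
            raise RuntimeError(f"EM log-likelihood decreased: {prev} -> {ll}")
        ns = pi * (masks.T @ (counts / np.maximum(classw, _TINY)))
        n_tm = np.bincount(model.tm, weights=ns, minlength=h)
        n_um = np.bincount(model.um, weights=ns, minlength=h)
        n_tf = np.bincount(model.tf, weights=ns, minlength=h)
        n_uf = np.bincount(model.uf, weights=ns, minlength=h)
        f = np.maximum((n_um + n_uf) / (2.0 * n), _TINY)
        f /= f.sum()
        if constrained:
            ft = np.maximum((n_tm + n_tf) / (2.0 * n), _TINY)
            rr = (ft / f) * (f[ref] / ft[ref])
            rrm = rrp = rr
        else:
            fm = np.maximum(n_tm / n, _TINY)
            fp = np.maximum(n_tf / n, _TINY)
            rrm = (fm / f) * (f[ref] / fm[ref])
            rrp = (fp / f) * (f[ref] / fp[ref])
        if abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
    pi = model.state_probs(f, rrm, rrp)
    ll = float(counts @ np.log(np.maximum(masks @ pi, _TINY)))
    return f, np.log(rrm), np.log(rrp), ll, converged, it


def _fd_hessian(fun, theta0: np.ndarray, step: float) -> np.ndarray:
    """Central-difference Hessian using one batched objective call."""
    d = len(theta0)
    pts = [theta0]
    for i in range(d):
        e = np.zeros(d)
        e[i] = step
        pts += [theta0 + e, theta0 - e]
    pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]
    for i, j in pairs:
        ei, ej = np.zeros(d), np.zeros(d)
        ei[i], ej[j] = step, step
        pts += [theta0 + ei + ej, theta0 + ei - ej, theta0 - ei + ej, theta0 - ei - ej]
    vals = fun(np.array(pts))
    hess = np.empty((d, d))
    f0 = vals[0]
    for i in range(d):
        hess[i, i] = (vals[1 + 2 * i] - 2.0 * f0 + vals[2 + 2 * i]) / step**2
    base = 1 + 2 * d
    for k, (i, j) in enumerate(pairs):
        a, b, c, e = vals[base + 4 * k : base + 4 * k + 4]
        hess[i, j] = hess[j, i] = (a - b - c + e) / (4.0 * step**2)
    return hess


def fit_stratum(
    mother,
    father,
    child,
    space: HaplotypeSpace,
    stratum: str = "",
    constrain_equal_rr: bool = False,
    init_freq: np.ndarray | None = None,
    options: FitOptions | None = None,
) -> StratumFit:
    """Fit the triad model to one exposure stratum by maximum likelihood.

    ``mother``/``father``/``child`` are ``(n_families, n_loci)`` dosage
    arrays at the space's loci (-1 missing; an all-missing father row is
    a dyad). Families whose genotypes are incompatible with every latent
    state of the space are skipped and counted in ``n_skipped``;
    families with both parents entirely missing are excluded up front.
    With ``constrain_equal_rr`` the maternal and paternal risks are tied
    (the child-effect model used for Child and GxE rows).

    Non-convergence after ``max_iter`` flags the fit rather than
    raising. Covariance is the inverse observed information from a
    central-difference Hessian at the optimum.
    """
    opts = options or FitOptions()
    mother = np.atleast_2d(np.asarray(mother, dtype=np.int8))
    father = np.atleast_2d(np.asarray(father, dtype=np.int8))
    child = np.atleast_2d(np.asarray(child, dtype=np.int8))
    both_missing = np.all(mother == MISSING, axis=1) & np.all(father == MISSING, axis=1)
    if both_missing.any():
        keep = ~both_missing
        mother, father, child = mother[keep], father[keep], child[keep]
    if mother.shape[0] == 0:
        raise DegenerateDataError(f"no informative families in stratum {stratum!r}")

    model = _StateModel(space)
    masks, counts, n_skipped = _group_patterns(model, mother, father, child)
    h = space.n_haplotypes
    ref = space.reference_index
    if init_freq is None:
        f0 = _freq_em(model, masks, counts, tol=1e-4, max_iter=200)
    else:
        f0 = np.asarray(init_freq, dtype=float)
    f0 = np.maximum(f0, 1e-6)
    f0 = f0 / f0.sum()

    if opts.method == "em":
        f, lrm, lrp, ll, converged, it = _em(
            model, masks, counts, f0, ref, constrain_equal_rr, opts.tol, opts.max_iter
        )
    elif opts.method == "bfgs":
        theta0 = _pack(f0, np.zeros(h), np.zeros(h), ref, constrain_equal_rr)
        res = minimize(
            lambda t: -float(_batch_loglik(t, model, masks, counts, ref, constrain_equal_rr)[0]),
            theta0,
            method="BFGS",
            options={"gtol": 1e-7, "maxiter": opts.max_iter},
        )
        fb, rrmb, rrpb = _unpack(res.x, h, ref, constrain_equal_rr)
        f, lrm, lrp = fb[0], np.log(rrmb[0]), np.log(rrpb[0])
        ll, converged, it = -float(res.fun), bool(res.success), int(res.nit)
    else:
        raise ValueError(f"unknown fit method: {opts.method}")

    theta_hat = _pack(f, lrm, lrp, ref, constrain_equal_rr)
    hess = _fd_hessian(
        lambda t: _batch_loglik(t, model, masks, counts, ref, constrain_equal_rr),
        theta_hat,
        opts.hessian_step,
    )
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-hess)
    cov = 0.5 * (cov + cov.T)

    free = [i for i in range(h) if i != ref]
    names = [f"logit_freq[{space.hap_string(i)}]" for i in free]
    if constrain_equal_rr:
        names += [f"log_rr[{space.hap_string(i)}]" for i in free]
    else:
        names += [f"log_rr_mat[{space.hap_string(i)}]" for i in free]
        names += [f"log_rr_pat[{space.hap_string(i)}]" for i in free]

    return StratumFit(
        stratum=stratum,
        space=space,
        freq=f,
        log_rr_mat=lrm,
        log_rr_pat=lrp,
        covariance=cov,
        loglik=ll,
        n_families=int(counts.sum()),
        n_skipped=n_skipped,
        converged=converged,
        iterations=it,
        constrained=constrain_equal_rr,
        param_names=names,
    )
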