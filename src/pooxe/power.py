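"""Asymptotic power of the Wald test for parent-of-origin x environment
interaction in case-parent triad designs.

For each exposure stratum the per-family expected Fisher information of
the observable genotype multinomial — complete triads collapse the 16
latent states to (M, F, C) dosage cells, dyads marginalize the father —
is computed at the true parameters. The asymptotic variance of the log
ratio-of-ratios is

    var(log RRR_PoOxE) = v_E / n_E + v_U / n_U,

with ``v`` the (log RR_mat - log RR_pat) contrast variance from the
inverse information, and the two-sided power at level alpha is

    Phi(delta - z_{1-alpha/2}) + Phi(-delta - z_{1-alpha/2}),
    delta = |log RRR_PoOxE| / se.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .simulate import _STATES, triad_state_distribution

__all__ = ["PowerDesign", "asymptotic_power", "power_curve"]


@dataclass(frozen=True)
class PowerDesign:
    """A PoOxE study design for power evaluation.

    Defaults follow the reference scenario: minor allele frequency 0.2,
    1100 unexposed and 500 exposed complete triads, significance level
    0.05, effects acting only through the maternal risk in the exposed
    stratum.
    """

    n_unexposed: int = 1100
    n_exposed: int = 500
    maf: float = 0.2
    rr_mat_exposed: float = 1.0
    rr_pat_exposed: float = 1.0
    rr_mat_unexposed: float = 1.0
    rr_pat_unexposed: float = 1.0
    alpha: float = 0.05
    dyad_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf < 1.0:
            raise ValueError("maf must lie strictly in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 <= self.dyad_fraction <= 1.0:
            raise ValueError("dyad_fraction must lie in [0, 1]")
        if min(self.n_unexposed, self.n_exposed) <= 0:
            raise ValueError("both strata need at least one family")
        for rr in (self.rr_mat_exposed, self.rr_pat_exposed, self.rr_mat_unexposed, self.rr_pat_unexposed):
            if rr <= 0:
                raise ValueError("relative risks must be positive")

    @property
    def rrr_pooxe(self) -> float:
        return (self.rr_mat_exposed / self.rr_pat_exposed) / (
            self.rr_mat_unexposed / self.rr_pat_unexposed
        )


# observable collapse matrices: rows are distinct observable cells
def _cell_matrix(dyad: bool) -> tuple[np.ndarray, np.ndarray]:
    tm, um, tf, uf = _STATES.T
    if dyad:
        obs = np.stack([tm + um, tm + tf], axis=1)  # (M, C)
    else:
        obs = np.stack([tm + um, tf + uf, tm + tf], axis=1)  # (M, F, C)
    cells, inverse = np.unique(obs, axis=0, return_inverse=True)
    collapse = np.zeros((len(cells), 16))
    collapse[inverse, np.arange(16)] = 1.0
    return cells, collapse


_TRIAD_CELLS, _TRIAD_COLLAPSE = _cell_matrix(dyad=False)
_DYAD_CELLS, _DYAD_COLLAPSE = _cell_matrix(dyad=True)


def _cell_probs(theta: np.ndarray, collapse: np.ndarray) -> np.ndarray:
    """Observable-cell probabilities at theta = (logit p, log rrm, log rrp)."""
    p = 1.0 / (1.0 + np.exp(-theta[0]))
    pi = triad_state_distribution(p, np.exp(theta[1]), np.exp(theta[2]))
    return collapse @ pi


def _fisher_info(theta: np.ndarray, collapse: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Per-family expected information of the observable multinomial."""
    grads = []
    for i in range(3):
        e = np.zeros(3)
        e[i] = step
        grads.append((_cell_probs(theta + e, collapse) - _cell_probs(theta - e, collapse)) / (2 * step))
    grad = np.stack(grads, axis=1)  # (cells, 3)
    probs = _cell_probs(theta, collapse)
    return (grad.T / probs) @ grad


def _stratum_variance(maf: float, rr_mat: float, rr_pat: float, dyad_fraction: float) -> float:
    """Asymptotic per-family variance of log(RR_mat/RR_pat) in one stratum."""
    theta = np.array([np.log(maf / (1.0 - maf)), np.log(rr_mat), np.log(rr_pat)])
    info = (1.0 - dyad_fraction) * _fisher_info(theta, _TRIAD_COLLAPSE)
    if dyad_fraction > 0.0:
        info = info + dyad_fraction * _fisher_info(theta, _DYAD_COLLAPSE)
    cov = np.linalg.inv(info)
    contrast = np.array([0.0, 1.0, -1.0])
    return float(contrast @ cov @ contrast)


def asymptotic_power(design: PowerDesign) -> float:
    """Two-sided asymptotic power of the Wald PoOxE test.

    At a true RRR_PoOxE of 1 the noncentrality is zero and the power
    equals alpha exactly.
    """
    v_e = _stratum_variance(design.maf, design.rr_mat_exposed, design.rr_pat_exposed, design.dyad_fraction)
    v_u = _stratum_variance(design.maf, design.rr_mat_unexposed, design.rr_pat_unexposed, design.dyad_fraction)
    se = np.sqrt(v_e / design.n_exposed + v_u / design.n_unexposed)
    delta = abs(np.log(design.rrr_pooxe)) / se
    z = norm.ppf(1.0 - design.alpha / 2.0)
    return float(norm.cdf(delta - z) + norm.cdf(-delta - z))


def power_curve(
    design: PowerDesign,
    rrr_grid=None,
    maf_grid=None,
    n_grid=None,
) -> pd.DataFrame:
    """Power along a grid of one design axis.

    ``rrr_grid`` varies the maternal relative risk in the exposed
    stratum so that RRR_PoOxE equals the grid value (the reference
    scenario's convention); ``maf_grid`` varies the allele frequency;
    ``n_grid`` takes ``(n_unexposed, n_exposed)`` pairs. Exactly one
    grid must be given.
    """
    given = [g is not None for g in (rrr_grid, maf_grid, n_grid)]
    if sum(given) != 1:
        raise ValueError("provide exactly one of rrr_grid, maf_grid, n_grid")
    rows = []
    if rrr_grid is not None:
        base = (design.rr_mat_unexposed / design.rr_pat_unexposed) * design.rr_pat_exposed
        for rrr in np.asarray(rrr_grid, dtype=float):
            d = replace(design, rr_mat_exposed=float(rrr * base))
            rows.append({"rrr_pooxe": float(rrr), "power": asymptotic_power(d)})
    elif maf_grid is not None:
        for maf in np.asarray(maf_grid, dtype=float):
            d = replace(design, maf=float(maf))
            rows.append({"maf": float(maf), "power": asymptotic_power(d)})
    else:
        for n_u, n_e in n_grid:
            d = replace(design, n_unexposed=int(n_u), n_exposed=int(n_e))
            rows.append({"n_unexposed": int(n_u), "n_exposed": int(n_e), "power": asymptotic_power(d)})
    return pd.DataFrame(rows)
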