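"""Effect estimates and Wald tests built on stratum fits.

Four effect types are reported, mirroring the stratified analyses of a
parent-of-origin x environment (PoOxE) study:

* ``Child`` — a single relative risk per inherited target haplotype,
  maternal and paternal origin constrained equal, fitted on both strata
  pooled.
* ``GxE`` — ratio of the constrained (child-effect) relative risks,
  exposed over unexposed.
* ``PoO`` — the parent-of-origin ratio RRR_PoO = RR_mat / RR_pat within
  one stratum.
* ``PoOxE`` — the ratio of ratios RRR_PoOxE =
  RRR_PoO(exposed) / RRR_PoO(unexposed), the genome-wide scan statistic.

All tests are two-sided Wald tests on the log scale; strata are
independent samples (each family belongs to exactly one stratum), so
standard errors of cross-stratum ratios add in quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datasets import TriadDataset
from .likelihood import (
    DegenerateDataError,
    FitOptions,
    HaplotypeSpace,
    StratumFit,
    build_space,
    fit_stratum,
)

__all__ = [
    "EffectEstimate",
    "PoOxEResult",
    "poo_effect",
    "pooxe_test",
    "child_and_gxe_tests",
    "scan",
    "stratified_analysis",
    "top_hits",
]

_Z975 = norm.ppf(0.975)


@dataclass(frozen=True)
class EffectEstimate:
    """A ratio estimate with its Wald machinery on the log scale."""

    estimate: float
    ci_low: float
    ci_high: float
    se_log: float
    z: float
    p: float

    @classmethod
    def from_log(cls, log_est: float, se: float) -> "EffectEstimate":
        z = log_est / se if se > 0 else np.nan
        p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else np.nan
        return cls(
            estimate=float(np.exp(log_est)),
            ci_low=float(np.exp(log_est - _Z975 * se)),
            ci_high=float(np.exp(log_est + _Z975 * se)),
            se_log=float(se),
            z=float(z),
            p=p,
        )


@dataclass
class PoOxEResult:
    """One row of a stratified analysis: a marker x effect-type estimate."""

    marker: str
    target: str
    reference: str
    effect_type: str  # Child | GxE | PoO | PoOxE
    estimate: EffectEstimate
    rrr_poo_exposed: EffectEstimate | None = None
    rrr_poo_unexposed: EffectEstimate | None = None
    q_value: float | None = None

    @property
    def rrr_pooxe(self) -> EffectEstimate | None:
        return self.estimate if self.effect_type == "PoOxE" else None

    @property
    def wald_z(self) -> float:
        return self.estimate.z

    @property
    def p_value(self) -> float:
        return self.estimate.p


def _require_converged(fit: StratumFit) -> None:
    if not fit.converged:
        raise RuntimeError(f"stratum fit {fit.stratum!r} did not converge; refusing to report")


def _check_same_space(a: StratumFit, b: StratumFit) -> None:
    if a.space.loci != b.space.loci or a.space.haplotypes != b.space.haplotypes or (
        a.space.reference_index != b.space.reference_index
    ):
        raise ValueError("stratum fits use different haplotype spaces")


def poo_effect(fit: StratumFit, target: int) -> EffectEstimate:
    """Parent-of-origin effect RRR_PoO = RR_mat/RR_pat for one haplotype.

    Standard error uses var(log RR_mat) + var(log RR_pat) minus twice
    their covariance, from the fit's observed-information covariance.
    """
    _require_converged(fit)
    log_rrr = float(fit.log_rr_mat[target] - fit.log_rr_pat[target])
    se = float(np.sqrt(max(fit.var_log_poo(target), 0.0)))
    return EffectEstimate.from_log(log_rrr, se)


def pooxe_test(fit_exposed: StratumFit, fit_unexposed: StratumFit, target: int, marker: str = "",
               target_label: str = "", reference_label: str = "") -> PoOxEResult:
    """Wald test of H0: RRR_PoOxE = 1 for one target haplotype."""
    _check_same_space(fit_exposed, fit_unexposed)
    poo_e = poo_effect(fit_exposed, target)
    poo_u = poo_effect(fit_unexposed, target)
    log_rrr = np.log(poo_e.estimate) - np.log(poo_u.estimate)
    se = float(np.sqrt(poo_e.se_log**2 + poo_u.se_log**2))
    return PoOxEResult(
        marker=marker,
        target=target_label,
        reference=reference_label,
        effect_type="PoOxE",
        estimate=EffectEstimate.from_log(float(log_rrr), se),
        rrr_poo_exposed=poo_e,
        rrr_poo_unexposed=poo_u,
    )


def child_and_gxe_tests(
    fit_exposed: StratumFit,
    fit_unexposed: StratumFit,
    fit_pooled: StratumFit,
    target: int,
    marker: str = "",
    target_label: str = "",
    reference_label: str = "",
) -> tuple[PoOxEResult, PoOxEResult]:
    """Child and GxE rows from constrained (RR_mat = RR_pat) fits.

    Child is the single relative risk from the pooled constrained fit;
    GxE is the exposed/unexposed ratio of the stratum constrained risks.
    """
    for f in (fit_exposed, fit_unexposed, fit_pooled):
        if not f.constrained:
            raise ValueError("Child/GxE rows require constrained (equal-RR) fits")
        _require_converged(f)
    _check_same_space(fit_exposed, fit_unexposed)
    log_rr = float(fit_pooled.log_rr_mat[target])
    se_rr = float(np.sqrt(max(fit_pooled.var_log_rr("rr", target), 0.0)))
    child = PoOxEResult(
        marker=marker, target=target_label, reference=reference_label,
        effect_type="Child", estimate=EffectEstimate.from_log(log_rr, se_rr),
    )
    log_ratio = float(fit_exposed.log_rr_mat[target] - fit_unexposed.log_rr_mat[target])
    se = float(
        np.sqrt(
            max(fit_exposed.var_log_rr("rr", target), 0.0)
            + max(fit_unexposed.var_log_rr("rr", target), 0.0)
        )
    )
    gxe = PoOxEResult(
        marker=marker, target=target_label, reference=reference_label,
        effect_type="GxE", estimate=EffectEstimate.from_log(log_ratio, se),
    )
    return child, gxe


def _hap_labels(space: HaplotypeSpace, snps: pd.DataFrame, h: int) -> str:
    """Table-style haplotype label: lowercase target allele, uppercase reference."""
    parts = []
    for l, locus in enumerate(space.loci):
        row = snps.loc[snps["snp_id"] == locus].iloc[0]
        allele = space.haplotypes[h][l]
        parts.append(str(row["allele_var"]).lower() if allele == 1 else str(row["allele_ref"]).upper())
    return "-".join(parts)


def _fit_marker(
    dataset: TriadDataset,
    cols: list[int],
    mask_u: np.ndarray,
    mask_e: np.ndarray,
    frequency_floor: float,
    options: FitOptions | None,
    constrained: bool = False,
):
    """Resolve one marker's space on pooled families and fit both strata."""
    both = mask_u | mask_e
    m, f, c = dataset.mother[:, cols], dataset.father[:, cols], dataset.child[:, cols]
    loci = dataset.snps["snp_id"].to_numpy()[cols]
    space, f_init = build_space(m[both], f[both], c[both], loci, frequency_floor)
    fit_u = fit_stratum(m[mask_u], f[mask_u], c[mask_u], space, stratum="unexposed",
                        constrain_equal_rr=constrained, init_freq=f_init, options=options)
    fit_e = fit_stratum(m[mask_e], f[mask_e], c[mask_e], space, stratum="exposed",
                        constrain_equal_rr=constrained, init_freq=f_init, options=options)
    pooled = None
    if constrained:
        pooled = fit_stratum(m[both], f[both], c[both], space, stratum="pooled",
                             constrain_equal_rr=True, init_freq=f_init, options=options)
    return space, fit_u, fit_e, pooled


def _result_row(res: PoOxEResult, chrom, pos, n_u: int, n_e: int) -> dict:
    est = res.estimate
    row = {
        "marker": res.marker,
        "chrom": chrom,
        "pos": pos,
        "target": res.target,
        "reference": res.reference,
        "effect_type": res.effect_type,
        "rrr": est.estimate,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "z": est.z,
        "p": est.p,
        "q": np.nan,
        "n_unexposed": n_u,
        "n_exposed": n_e,
    }
    row["rrr_poo_exposed"] = res.rrr_poo_exposed.estimate if res.rrr_poo_exposed else np.nan
    row["rrr_poo_unexposed"] = res.rrr_poo_unexposed.estimate if res.rrr_poo_unexposed else np.nan
    return row


_COLUMNS = [
    "marker", "chrom", "pos", "target", "reference", "effect_type",
    "rrr", "ci_low", "ci_high", "z", "p", "q",
    "rrr_poo_exposed", "rrr_poo_unexposed", "n_unexposed", "n_exposed",
]


def scan(
    dataset: TriadDataset,
    exposure_name: str,
    mode: str = "snp",
    window: int = 2,
    snp_ids: list[str] | None = None,
    frequency_floor: float = 0.01,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Genome-wide PoOxE scan: one Wald test per marker.

    ``mode="snp"`` tests every SNP singly; ``mode="haplotype"`` slides a
    window of ``window`` adjacent SNPs and tests every non-reference
    haplotype in each window. Families with missing exposure are
    excluded from this scan only. Markers whose fit fails or does not
    converge are reported with a NaN p-value and a note.
    """
    mask_u, mask_e = dataset.stratum_masks(exposure_name)
    if mask_u.sum() == 0 or mask_e.sum() == 0:
        raise DegenerateDataError("a stratified scan needs families in both exposure strata")
    if snp_ids is not None:
        col_idx = [dataset.snp_index(s) for s in snp_ids]
    else:
        col_idx = list(range(dataset.n_snps))
    if mode == "snp":
        marker_cols = [[j] for j in col_idx]
    elif mode == "haplotype":
        if not 2 <= window <= 3:
            raise ValueError("haplotype windows of 2 or 3 SNPs are supported")
        marker_cols = [col_idx[i : i + window] for i in range(len(col_idx) - window + 1)]
    else:
        raise ValueError(f"unknown scan mode: {mode}")

    rows, failures = [], []
    n_u, n_e = int(mask_u.sum()), int(mask_e.sum())
    for cols in marker_cols:
        snp_rows = dataset.snps.iloc[cols]
        marker = "-".join(snp_rows["snp_id"])
        chrom = snp_rows["chrom"].iloc[0]
        pos = snp_rows["pos"].iloc[0]
        try:
            space, fit_u, fit_e, _ = _fit_marker(
                dataset, cols, mask_u, mask_e, frequency_floor, options
            )
            ref = space.reference_index
            ref_label = _hap_labels(space, dataset.snps, ref)
            for h in range(space.n_haplotypes):
                if h == ref:
                    continue
                res = pooxe_test(
                    fit_e, fit_u, h, marker=marker,
                    target_label=_hap_labels(space, dataset.snps, h),
                    reference_label=ref_label,
                )
                rows.append(_result_row(res, chrom, pos, n_u, n_e))
        except (DegenerateDataError, RuntimeError) as exc:
            failures.append((marker, str(exc)))
    if failures:
        warnings.warn(f"{len(failures)} marker(s) failed to fit and were excluded", stacklevel=2)
    table = pd.DataFrame(rows, columns=_COLUMNS)
    table.attrs["failures"] = failures
    table.attrs["exposure"] = exposure_name
    return table


def stratified_analysis(
    dataset: TriadDataset,
    exposure_name: str,
    snp_ids: list[str],
    haplotype_windows: list[list[str]] | None = None,
    frequency_floor: float = 0.01,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Four-effect stratified table (Child, GxE, PoO, PoOxE) for selected
    SNPs and multi-SNP haplotypes, one row per effect per target."""
    mask_u, mask_e = dataset.stratum_masks(exposure_name)
    markers = [[s] for s in snp_ids] + [list(w) for w in (haplotype_windows or [])]
    rows = []
    n_u, n_e = int(mask_u.sum()), int(mask_e.sum())
    for ids in markers:
        cols = [dataset.snp_index(s) for s in ids]
        snp_rows = dataset.snps.iloc[cols]
        marker = "-".join(snp_rows["snp_id"])
        chrom, pos = snp_rows["chrom"].iloc[0], snp_rows["pos"].iloc[0]
        space, fit_u, fit_e, _ = _fit_marker(dataset, cols, mask_u, mask_e, frequency_floor, options)
        _, fit_u_c, fit_e_c, pooled_c = _fit_marker(
            dataset, cols, mask_u, mask_e, frequency_floor, options, constrained=True
        )
        ref = space.reference_index
        ref_label = _hap_labels(space, dataset.snps, ref)
        for h in range(space.n_haplotypes):
            if h == ref:
                continue
            label = _hap_labels(space, dataset.snps, h)
            child, gxe = child_and_gxe_tests(
                fit_e_c, fit_u_c, pooled_c, h, marker=marker,
                target_label=label, reference_label=ref_label,
            )
            poo = PoOxEResult(
                marker=marker, target=label, reference=ref_label,
                effect_type="PoO", estimate=poo_effect(fit_u, h) if n_e == 0 else _pooled_poo(
                    dataset, cols, mask_u | mask_e, space, frequency_floor, options, h
                ),
            )
            pooxe = pooxe_test(fit_e, fit_u, h, marker=marker,
                               target_label=label, reference_label=ref_label)
            for res in (child, gxe, poo, pooxe):
                row = _result_row(res, chrom, pos, n_u, n_e)
                row["frequency"] = float(
                    np.average([fit_u.freq[h], fit_e.freq[h]], weights=[n_u, n_e])
                )
                rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS + ["frequency"])


def _pooled_poo(dataset, cols, mask, space, frequency_floor, options, h) -> EffectEstimate:
    """Main-effect PoO row: RRR_PoO fitted on both strata pooled."""
    fit = fit_stratum(
        dataset.mother[mask][:, cols], dataset.father[mask][:, cols],
        dataset.child[mask][:, cols], space, stratum="pooled", options=options,
    )
    return poo_effect(fit, h)


def top_hits(table: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k markers sorted by p-value (the published-table view)."""
    return table.sort_values("p", kind="mergesort").head(k).reset_index(drop=True)
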