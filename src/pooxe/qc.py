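"""SNP-level quality control for triad genotype data.

Filters, with their default thresholds: call-rate (more than 5% missing
calls), minor allele frequency (below 5%), the exact conditional test
for Hardy-Weinberg equilibrium (p below 0.001), Mendelian-error rate
across families (above 1%), and perfect linkage disequilibrium with a
flanking SNP (r^2 = 1; the later SNP in map order is dropped). Allele
frequencies, the HWE test and LD are computed on parents only —
children are ascertained cases and not a population sample. The report
counts each criterion independently, so a SNP failing several criteria
appears in several rows but is removed once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .datasets import MISSING, TriadDataset

__all__ = [
    "QCThresholds",
    "SnpQCMetrics",
    "QCReport",
    "hwe_exact_test",
    "mendel_error_rate",
    "ld_prune_perfect",
    "run_qc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    missing_max: float = 0.05
    maf_min: float = 0.05
    hwe_p_min: float = 0.001
    mendel_max: float = 0.01
    ld_window: int = 5


@dataclass
class SnpQCMetrics:
    snp_id: str
    call_rate_missing_fraction: float
    maf: float
    hwe_p: float
    mendel_error_rate: float
    r2_with_flanking: float
    excluded_by: set[str] = field(default_factory=set)


@dataclass
class QCReport:
    total_snps: int
    exclusion_counts: dict[str, int]
    remaining_snps: int
    metrics: list[SnpQCMetrics]

    def to_frame(self) -> pd.DataFrame:
        """Two-column exclusion summary in the published-table layout."""
        rows = [("Total number of SNPs", self.total_snps)]
        labels = {
            "hwe": "Failed HWE test",
            "missing": "More than allowed missing calls",
            "maf": "MAF below threshold",
            "ld": "r2=1 with flanking SNPs",
            "mendel": "Mendelian errors detected",
        }
        for key, label in labels.items():
            rows.append((label, self.exclusion_counts.get(key, 0)))
        rows.append(("Number of SNPs remaining after quality control", self.remaining_snps))
        return pd.DataFrame(rows, columns=["criterion", "count"])

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [m.snp_id for m in self.metrics],
                "missing_fraction": [m.call_rate_missing_fraction for m in self.metrics],
                "maf": [m.maf for m in self.metrics],
                "hwe_p": [m.hwe_p for m in self.metrics],
                "mendel_error_rate": [m.mendel_error_rate for m in self.metrics],
                "r2_with_flanking": [m.r2_with_flanking for m in self.metrics],
                "excluded_by": [",".join(sorted(m.excluded_by)) for m in self.metrics],
            }
        )


def _hwe_het_probs(n: int, x: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Given ``n`` diploids carrying ``x`` minor alleles in total, the
    heterozygote count ``h`` (same parity as x, ``h <= min(x, 2n-x)``)
    has probability proportional to ``2^h n! / (n_AA! h! n_aa!)``.
    Returns (het counts, probabilities), computed in log space.
    """
    hs = np.arange(x % 2, min(x, 2 * n - x) + 1, 2)
    n_minor_hom = (x - hs) // 2
    n_major_hom = n - hs - n_minor_hom
    logw = (
        hs * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_minor_hom + 1)
        - gammaln(hs + 1)
        - gammaln(n_major_hom + 1)
    )
    return hs, np.exp(logw - logsumexp(logw))


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional test for Hardy-Weinberg equilibrium.

    Two-sided p-value: the summed probability of all heterozygote
    counts (fixing the diploid total and the minor-allele total) no
    more probable than the observed one. Monomorphic input returns 1 by
    convention.
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotyped individual is required")
    x = min(2 * n_hom_major + n_het, 2 * n_hom_minor + n_het)
    if x == 0:
        return 1.0
    hs, probs = _hwe_het_probs(n, x)
    p_obs = probs[np.searchsorted(hs, n_het)]
    return float(min(probs[probs <= p_obs * (1.0 + 1e-12)].sum(), 1.0))


# (M, F, C) triples possible under biparental transmission
_VALID_TRANSMISSION = np.zeros((3, 3, 3), dtype=bool)
for _m in range(3):
    for _f in range(3):
        _mt = {0: (0,), 1: (0, 1), 2: (1,)}[_m]
        _ft = {0: (0,), 1: (0, 1), 2: (1,)}[_f]
        for _a in _mt:
            for _b in _ft:
                _VALID_TRANSMISSION[_m, _f, _a + _b] = True


def mendel_error_rate(mother, father, child) -> float:
    """Fraction of complete-genotype families with an impossible triple.

    Families with any missing member at this SNP are skipped; an empty
    denominator raises.
    """
    m = np.asarray(mother, dtype=int)
    f = np.asarray(father, dtype=int)
    c = np.asarray(child, dtype=int)
    complete = (m != MISSING) & (f != MISSING) & (c != MISSING)
    if complete.sum() == 0:
        raise ValueError("Mendelian error rate undefined: no complete families")
    ok = _VALID_TRANSMISSION[m[complete], f[complete], c[complete]]
    return float((~ok).mean())


def _mendel_flags(dataset: TriadDataset) -> np.ndarray:
    """(n_families, n_snps) boolean matrix of Mendelian-impossible triples."""
    m, f, c = dataset.mother, dataset.father, dataset.child
    complete = (m != MISSING) & (f != MISSING) & (c != MISSING)
    flags = np.zeros(m.shape, dtype=bool)
    flags[complete] = ~_VALID_TRANSMISSION[m[complete], f[complete], c[complete]]
    return flags


def ld_prune_perfect(genotypes: np.ndarray, window: int = 5, atol: float = 1e-12):
    """Indices of SNPs retained after perfect-LD pruning.

    ``genotypes`` is an (individuals x SNPs) dosage matrix (-1 missing)
    in map order. Each SNP is compared with the previously retained
    SNPs among its ``window`` map-order predecessors on
    pairwise-complete samples; squared Pearson correlation of exactly 1
    (within ``atol``) drops the later SNP. Zero-variance pairs are
    skipped with a log message.
    """
    g = np.asarray(genotypes, dtype=float)
    g[np.asarray(genotypes) == MISSING] = np.nan
    n_snps = g.shape[1]
    retained: list[int] = []
    dropped_r2 = np.zeros(n_snps)
    for j in range(n_snps):
        drop = False
        for k in reversed(retained):
            if j - k > window:
                break
            both = ~np.isnan(g[:, j]) & ~np.isnan(g[:, k])
            if both.sum() < 2:
                continue
            a, b = g[both, j], g[both, k]
            va, vb = a.var(), b.var()
            if va == 0.0 or vb == 0.0:
                logger.info("zero-variance SNP pair (%d, %d) skipped in LD pruning", k, j)
                continue
            r2 = np.corrcoef(a, b)[0, 1] ** 2
            dropped_r2[j] = max(dropped_r2[j], r2)
            if abs(r2 - 1.0) <= atol:
                drop = True
                break
        if not drop:
            retained.append(j)
    return np.array(retained, dtype=int), dropped_r2


def run_qc(dataset: TriadDataset, thresholds: QCThresholds | None = None) -> tuple[QCReport, TriadDataset]:
    """Apply all SNP filters and return the report plus filtered dataset.

    Call-rate, MAF, HWE and Mendel flags are evaluated on every SNP
    independently (their intersection with the retained set is
    order-insensitive); perfect-LD pruning runs last, on the survivors.
    In the filtered dataset, a family with a Mendelian-inconsistent
    triple at a retained SNP has that SNP set missing for all three
    members.
    """
    th = thresholds or QCThresholds()
    if dataset.n_snps == 0 or dataset.n_families == 0:
        raise ValueError("cannot run QC on an empty dataset")
    has_father = dataset.has_father
    parents = np.vstack([dataset.mother, dataset.father[has_father]])
    members = np.vstack([dataset.mother, dataset.child, dataset.father[has_father]])

    missing_frac = (members == MISSING).mean(axis=0)
    par_ok = parents != MISSING
    with np.errstate(invalid="ignore"):
        var_freq = np.where(
            par_ok.sum(axis=0) > 0,
            np.where(parents == MISSING, 0, parents).sum(axis=0) / (2.0 * np.maximum(par_ok.sum(axis=0), 1)),
            np.nan,
        )
    maf = np.minimum(var_freq, 1.0 - var_freq)

    hwe_p = np.empty(dataset.n_snps)
    for j in range(dataset.n_snps):
        col = parents[:, j]
        col = col[col != MISSING]
        hwe_p[j] = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))

    mendel_flags = _mendel_flags(dataset)
    complete = (
        (dataset.mother != MISSING) & (dataset.father != MISSING) & (dataset.child != MISSING)
    )
    n_complete = complete.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mendel_rate = np.where(n_complete > 0, mendel_flags.sum(axis=0) / np.maximum(n_complete, 1), 0.0)

    fail = {
        "missing": missing_frac > th.missing_max,
        "maf": maf < th.maf_min,
        "hwe": hwe_p < th.hwe_p_min,
        "mendel": mendel_rate > th.mendel_max,
    }
    survivors = np.flatnonzero(~(fail["missing"] | fail["maf"] | fail["hwe"] | fail["mendel"]))
    retained_rel, r2_flank = ld_prune_perfect(parents[:, survivors], window=th.ld_window)
    retained = survivors[retained_rel]
    ld_fail = np.zeros(dataset.n_snps, dtype=bool)
    ld_fail[np.setdiff1d(survivors, retained)] = True
    fail["ld"] = ld_fail
    r2_full = np.zeros(dataset.n_snps)
    r2_full[survivors] = r2_flank

    snp_ids = dataset.snps["snp_id"].to_numpy()
    metrics = []
    for j in range(dataset.n_snps):
        excluded = {k for k, v in fail.items() if v[j]}
        metrics.append(
            SnpQCMetrics(
                snp_id=str(snp_ids[j]),
                call_rate_missing_fraction=float(missing_frac[j]),
                maf=float(maf[j]) if np.isfinite(maf[j]) else 0.0,
                hwe_p=float(hwe_p[j]),
                mendel_error_rate=float(mendel_rate[j]),
                r2_with_flanking=float(r2_full[j]),
                excluded_by=excluded,
            )
        )
    report = QCReport(
        total_snps=dataset.n_snps,
        exclusion_counts={k: int(v.sum()) for k, v in fail.items()},
        remaining_snps=len(retained),
        metrics=metrics,
    )

    filtered = dataset.subset_snps(retained)
    kept_flags = mendel_flags[:, retained]
    if kept_flags.any():
        filtered.mother[kept_flags] = MISSING
        filtered.father[kept_flags] = MISSING
        filtered.child[kept_flags] = MISSING
    return report, filtered
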