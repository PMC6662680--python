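"""In-memory containers for case-parent triad genotype data.

A dataset holds one nuclear family per row: the mother's, father's and
affected child's genotypes at each diallelic SNP, coded as the dosage
(0/1/2) of the variant (target) allele, with ``-1`` for a missing call.
A family whose father is entirely untyped is a mother-child dyad; both
designs are fitted by the likelihood machinery, which marginalizes over
the missing parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class TriadRecord:
    """One nuclear family: genotypes per SNP plus exposure status.

    Genotypes are variant-allele dosages; ``-1`` marks a missing call.
    ``father`` may be all-missing (a parent-offspring dyad).
    """

    family_id: str
    mother: np.ndarray
    father: np.ndarray
    child: np.ndarray
    exposure: dict[str, float] = field(default_factory=dict)

    @property
    def is_dyad(self) -> bool:
        return bool(np.all(self.father == MISSING))


@dataclass
class TriadDataset:
    """Genotypes and exposures for a set of case-parent families.

    Attributes
    ----------
    snps : pd.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, allele_ref,
        allele_var`` (``allele_var`` is the dosage-counted target allele).
    mother, father, child : np.ndarray
        ``int8`` arrays of shape ``(n_families, n_snps)`` holding
        variant-allele dosages, ``-1`` for missing.
    family_ids : np.ndarray
        Family identifiers, aligned with the genotype rows.
    exposure : pd.DataFrame
        One row per family (same order); one float column per exposure,
        coded 0/1 with ``NaN`` for missing.
    """

    snps: pd.DataFrame
    mother: np.ndarray
    father: np.ndarray
    child: np.ndarray
    family_ids: np.ndarray
    exposure: pd.DataFrame

    def __post_init__(self) -> None:
        n, s = self.mother.shape
        if self.father.shape != (n, s) or self.child.shape != (n, s):
            raise ValueError("genotype matrices must share one shape")
        if len(self.family_ids) != n or len(self.exposure) != n:
            raise ValueError("family metadata misaligned with genotypes")
        if len(self.snps) != s:
            raise ValueError("SNP table misaligned with genotype columns")

    @property
    def n_families(self) -> int:
        return self.mother.shape[0]

    @property
    def n_snps(self) -> int:
        return self.mother.shape[1]

    @property
    def has_father(self) -> np.ndarray:
        """Boolean mask of families with an (at least partially) typed father."""
        return ~np.all(self.father == MISSING, axis=1)

    def record(self, i: int) -> TriadRecord:
        exp = {k: float(v) for k, v in self.exposure.iloc[i].items()}
        return TriadRecord(
            family_id=str(self.family_ids[i]),
            mother=self.mother[i].copy(),
            father=self.father[i].copy(),
            child=self.child[i].copy(),
            exposure=exp,
        )

    def subset_families(self, mask: np.ndarray) -> "TriadDataset":
        return TriadDataset(
            snps=self.snps.copy(),
            mother=self.mother[mask].copy(),
            father=self.father[mask].copy(),
            child=self.child[mask].copy(),
            family_ids=self.family_ids[mask].copy(),
            exposure=self.exposure.loc[mask].reset_index(drop=True),
        )

    def subset_snps(self, cols: np.ndarray) -> "TriadDataset":
        return TriadDataset(
            snps=self.snps.iloc[cols].reset_index(drop=True),
            mother=self.mother[:, cols].copy(),
            father=self.father[:, cols].copy(),
            child=self.child[:, cols].copy(),
            family_ids=self.family_ids.copy(),
            exposure=self.exposure.copy(),
        )

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snps["snp_id"].to_numpy() == snp_id)
        if idx.size == 0:
            raise KeyError(f"unknown SNP id: {snp_id}")
        return int(idx[0])

    def stratum_masks(self, exposure_name: str) -> tuple[np.ndarray, np.ndarray]:
        """(unexposed, exposed) family masks; families with missing exposure in neither."""
        if exposure_name not in self.exposure.columns:
            raise KeyError(f"exposure column not found: {exposure_name}")
        col = self.exposure[exposure_name].to_numpy(dtype=float)
        if np.all(np.isnan(col)):
            raise ValueError(f"exposure column {exposure_name!r} is entirely missing")
        return (col == 0), (col == 1)
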