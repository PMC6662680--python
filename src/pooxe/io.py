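"""Reading and writing the PED/MAP + exposure text dialect.

PED: one whitespace-delimited row per individual — family id,
individual id, father id, mother id, sex (1 male / 2 female / 0
unknown), phenotype (2 affected child, 0 parents), then two allele
columns per SNP with ``0`` for a missing allele. MAP: chromosome, SNP
id, genetic distance, 1-based physical position. Exposure: a TSV keyed
on family id with one 0/1/NA column per exposure.

On reading, genotypes are recoded to the dosage of the minor allele,
with the minor allele determined from the parents of the dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import MISSING, TriadDataset
from .qc import QCThresholds

__all__ = [
    "RunConfig",
    "write_triad_dataset",
    "read_triad_dataset",
    "dataset_summary",
    "write_provenance",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a pipeline run; round-trips through YAML."""

    ped: str = ""
    map: str = ""
    exposure: str = ""
    exposure_name: str = "exposure"
    subset_column: str | None = None
    subset_value: str | None = None
    out_dir: str = "results"
    seed: int = 0
    mode: str = "snp"
    window: int = 2
    alpha: float = 0.05
    frequency_floor: float = 0.01
    fit_tol: float = 1e-8
    fit_max_iter: int = 5000
    qc: dict = field(default_factory=lambda: asdict(QCThresholds()))
    log_level: str = "INFO"

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(**self.qc)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def write_triad_dataset(dataset: TriadDataset, prefix) -> dict[str, Path]:
    """Write PED, MAP and exposure files with deterministic formatting.

    Returns the paths keyed as ``ped``/``map``/``exposure``. A dyad
    family gets no father row and father id 0 in the child row.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": prefix.with_suffix(".ped"),
        "map": prefix.with_suffix(".map"),
        "exposure": prefix.with_suffix(".exposure.tsv"),
    }
    snps = dataset.snps
    with open(paths["map"], "w", newline="\n") as fh:
        for _, row in snps.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{row['pos']}\n")

    ref = snps["allele_ref"].to_numpy()
    var = snps["allele_var"].to_numpy()

    def allele_pairs(dosages: np.ndarray) -> list[str]:
        out = []
        for j, d in enumerate(dosages):
            if d == MISSING:
                out.append("0 0")
            elif d == 0:
                out.append(f"{ref[j]} {ref[j]}")
            elif d == 1:
                out.append(f"{ref[j]} {var[j]}")
            else:
                out.append(f"{var[j]} {var[j]}")
        return out

    has_father = dataset.has_father
    with open(paths["ped"], "w", newline="\n") as fh:
        for i, fam in enumerate(dataset.family_ids):
            mid, fid, cid = f"{fam}_m", f"{fam}_f", f"{fam}_c"
            father_id = fid if has_father[i] else "0"
            fh.write(" ".join([fam, mid, "0", "0", "2", "0"] + allele_pairs(dataset.mother[i])) + "\n")
            if has_father[i]:
                fh.write(" ".join([fam, fid, "0", "0", "1", "0"] + allele_pairs(dataset.father[i])) + "\n")
            fh.write(" ".join([fam, cid, father_id, mid, "0", "2"] + allele_pairs(dataset.child[i])) + "\n")

    exp = dataset.exposure.copy()
    exp.insert(0, "family_id", dataset.family_ids)
    exp.to_csv(paths["exposure"], sep="\t", index=False, na_rep="NA", lineterminator="\n")
    return paths


def read_triad_dataset(ped_path, map_path, exposure_path) -> TriadDataset:
    """Assemble a triad dataset from PED/MAP/exposure files.

    Families are linked through the child's father/mother ids; one
    absent parent makes a dyad, inconsistent ids raise. A family with
    several offspring keeps the first child row (the rest are logged).
    Genotypes are recoded to minor-allele dosage, the minor allele
    being determined from parental genotypes; autosomes only (rows with
    non-autosomal chromosome codes are dropped with a logged count).
    """
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str}
    )
    autosomal = map_df["chrom"].str.fullmatch(r"\d+")
    n_dropped = int((~autosomal).sum())
    if n_dropped:
        logger.warning("dropping %d non-autosomal MAP rows", n_dropped)
    keep_snps = np.flatnonzero(autosomal.to_numpy())
    map_df = map_df.iloc[keep_snps].reset_index(drop=True)
    n_snps_total = len(autosomal)

    ped = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    if ped.shape[1] != 6 + 2 * n_snps_total:
        raise ValueError(
            f"PED has {ped.shape[1]} columns; expected {6 + 2 * n_snps_total} for {n_snps_total} SNPs"
        )
    ids = ped.iloc[:, 1].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate individual ids in PED")
    a1 = ped.iloc[:, 6::2].to_numpy()[:, keep_snps]
    a2 = ped.iloc[:, 7::2].to_numpy()[:, keep_snps]
    by_id = {iid: i for i, iid in enumerate(ids)}

    children = ped.index[(ped.iloc[:, 2] != "0") | (ped.iloc[:, 3] != "0")].to_numpy()
    fam_first: dict[str, int] = {}
    extra_offspring = 0
    for row in children:
        fam = ped.iat[row, 0]
        if fam in fam_first:
            extra_offspring += 1
        else:
            fam_first[fam] = row
    if extra_offspring:
        logger.warning("keeping first offspring only: %d extra offspring rows ignored", extra_offspring)
    if not fam_first:
        raise ValueError("no child rows (nonzero parent ids) found in PED")

    # determine per-SNP allele codes and the minor allele from parents
    parent_rows = []
    fam_trios = []  # (family_id, mother_row | None, father_row | None, child_row)
    for fam, crow in fam_first.items():
        fid, mid = ped.iat[crow, 2], ped.iat[crow, 3]
        frow = by_id.get(fid) if fid != "0" else None
        mrow = by_id.get(mid) if mid != "0" else None
        if fid != "0" and frow is None:
            frow = None  # father referenced but absent: treat as dyad
        if mid != "0" and mrow is None:
            mrow = None
        if mrow is None and frow is None:
            raise ValueError(f"family {fam}: child references no resolvable parent")
        fam_trios.append((fam, mrow, frow, crow))
        parent_rows += [r for r in (mrow, frow) if r is not None]

    n_fam, n_snps = len(fam_trios), len(keep_snps)
    pa1, pa2 = a1[parent_rows], a2[parent_rows]
    allele_ref, allele_var = [], []
    for j in range(n_snps):
        col = np.concatenate([pa1[:, j], pa2[:, j]])
        col = col[col != "0"]
        values, counts = np.unique(col, return_counts=True)
        if len(values) == 0:
            allele_ref.append("1")
            allele_var.append("2")
            continue
        order = np.argsort(counts, kind="mergesort")
        minor = values[order[0]] if len(values) > 1 else None
        major = values[order[-1]]
        allele_ref.append(str(major))
        allele_var.append(str(minor) if minor is not None else ("2" if major == "1" else "1"))

    def dosage_row(row: int | None) -> np.ndarray:
        if row is None:
            return np.full(n_snps, MISSING, dtype=np.int8)
        x1, x2 = a1[row], a2[row]
        miss = (x1 == "0") | (x2 == "0")
        d = (x1 == np.array(allele_var)).astype(np.int8) + (x2 == np.array(allele_var)).astype(np.int8)
        d[miss] = MISSING
        return d

    mother = np.vstack([dosage_row(m) for _, m, _, _ in fam_trios])
    father = np.vstack([dosage_row(f) for _, _, f, _ in fam_trios])
    child = np.vstack([dosage_row(c) for _, _, _, c in fam_trios])
    family_ids = np.array([fam for fam, _, _, _ in fam_trios])

    exp = pd.read_csv(exposure_path, sep="\t", dtype={"family_id": str}, na_values=["NA"])
    exp = exp.set_index("family_id").reindex(family_ids).reset_index(drop=True)

    snps = pd.DataFrame(
        {
            "snp_id": map_df["snp_id"],
            "chrom": map_df["chrom"].astype(int),
            "pos": map_df["pos"].astype(int),
            "allele_ref": allele_ref,
            "allele_var": allele_var,
        }
    )
    return TriadDataset(
        snps=snps, mother=mother, father=father, child=child,
        family_ids=family_ids, exposure=exp,
    )


def dataset_summary(
    dataset: TriadDataset,
    exposures: list[str] | None = None,
    subset_column: str | None = None,
) -> pd.DataFrame:
    """Family and individual tallies, per subset value and pooled.

    Counts complete triads, dyads, families and genotyped individuals
    (3 per triad, 2 per dyad — one child per family), plus exposed and
    missing-exposure family counts per exposure.
    """
    exposures = exposures if exposures is not None else list(dataset.exposure.columns)
    if subset_column is not None:
        if subset_column not in dataset.exposure.columns:
            raise KeyError(f"subset column not found: {subset_column}")
        values = dataset.exposure[subset_column]
        groups = [(str(v), (values == v).to_numpy()) for v in pd.unique(values.dropna())]
    else:
        groups = []
    groups.append(("pooled", np.ones(dataset.n_families, dtype=bool)))

    rows = []
    for label, mask in groups:
        has_father = dataset.has_father[mask]
        n_triads = int(has_father.sum())
        n_dyads = int((~has_father).sum())
        row = {
            "subset": label,
            "families": n_triads + n_dyads,
            "complete_triads": n_triads,
            "dyads": n_dyads,
            "individuals": 3 * n_triads + 2 * n_dyads,
        }
        for name in exposures:
            if name == subset_column:
                continue
            col = dataset.exposure.loc[mask, name]
            row[f"{name}_exposed"] = int((col == 1).sum())
            row[f"{name}_missing"] = int(col.isna().sum())
        rows.append(row)
    return pd.DataFrame(rows)


def write_provenance(path, *, config: RunConfig | None = None, seed: int | None = None,
                     stage_counts: dict | None = None, extra: dict | None = None) -> None:
    """Machine-readable record of a run, sufficient to reproduce it."""
    from . import __version__

    payload = {
        "version": __version__,
        "seed": seed,
        "config": asdict(config) if config is not None else None,
        "stage_counts": stage_counts or {},
    }
    payload.update(extra or {})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
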