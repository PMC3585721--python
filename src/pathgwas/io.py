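"""Core data containers and plain-text file formats.

Genotypes travel as a samples x SNPs minor-allele dosage matrix (int8; 0/1/2,
-1 = missing) together with a SNP map and a sample/covariate table. On disk we
use PLINK-style ``.ped``/``.map`` text, a covariate TSV, a BED-like gene
annotation (1-based inclusive coordinates, documented in its header line) and
GMT gene sets. All writers round-trip losslessly through the readers here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel in dosage matrices

AUTOSOMES = {str(c) for c in range(1, 23)}

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos", "allele1", "allele2"]
SAMPLE_COLUMNS = ["sample_id", "status", "age", "gender", "pack_years", "site"]


class DataFormatError(ValueError):
    """Raised when an on-disk file does not parse as the documented layout."""


@dataclass
class GenotypeDataset:
    """Case-control genotype data: dosages plus SNP map plus sample table.

    dosages: (n_samples, n_snps) int8, minor-allele counts, -1 for missing.
    snp_map: DataFrame with columns snp_id, chrom (string label), pos (1-based
        bp), allele1 (minor), allele2 (major); one row per dosage column.
    samples: DataFrame with columns sample_id, status (1=case, 0=control),
        age (years), gender (0/1), pack_years, site (study label); one row per
        dosage row.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.snp_map = self.snp_map.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if len(self.snp_map) != self.n_snps:
            raise ValueError("snp_map rows must match dosage columns")
        if len(self.samples) != self.n_samples:
            raise ValueError("samples rows must match dosage rows")
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,missing}")
        if (self.snp_map["pos"] <= 0).any():
            raise ValueError("SNP positions must be strictly positive (1-based)")
        status = self.samples["status"]
        if status.isna().any() or not status.isin([0, 1]).all():
            raise ValueError("status must be binary (0/1) and present for every sample")
        if self.snp_map["snp_id"].duplicated().any():
            raise ValueError("snp ids must be unique")

    def subset(
        self,
        sample_idx: np.ndarray | Sequence[int] | None = None,
        snp_idx: np.ndarray | Sequence[int] | None = None,
    ) -> "GenotypeDataset":
        """Return a new dataset restricted to the given positional indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            dosages=self.dosages[np.ix_(si, vi)],
            snp_map=self.snp_map.iloc[vi].reset_index(drop=True),
            samples=self.samples.iloc[si].reset_index(drop=True),
        )

    def subset_snp_ids(self, snp_ids: Iterable[str]) -> "GenotypeDataset":
        wanted = set(snp_ids)
        idx = np.flatnonzero(self.snp_map["snp_id"].isin(wanted).to_numpy())
        return self.subset(snp_idx=idx)


def concat_datasets(a: GenotypeDataset, b: GenotypeDataset) -> GenotypeDataset:
    """Pool two studies sample-wise on their common SNPs (inner join by id).

    SNP coordinates and alleles must agree on the shared ids; sample tables are
    concatenated, so distinct ``site`` labels keep the studies identifiable.
    """
    common = a.snp_map.merge(b.snp_map, on="snp_id", suffixes=("_a", "_b"))
    if len(common) == 0:
        raise ValueError("datasets share no SNP ids")
    mism = (common["chrom_a"] != common["chrom_b"]) | (common["pos_a"] != common["pos_b"])
    if mism.any():
        raise ValueError("shared SNP ids disagree on chromosome/position")
    ids = common["snp_id"].tolist()
    pos_a = {s: i for i, s in enumerate(a.snp_map["snp_id"])}
    pos_b = {s: i for i, s in enumerate(b.snp_map["snp_id"])}
    ia = np.array([pos_a[s] for s in ids])
    ib = np.array([pos_b[s] for s in ids])
    return GenotypeDataset(
        dosages=np.vstack([a.dosages[:, ia], b.dosages[:, ib]]),
        snp_map=a.snp_map.iloc[ia].reset_index(drop=True),
        samples=pd.concat([a.samples, b.samples], ignore_index=True),
    )


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval: 1-based inclusive [start, end] on an autosome."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class Pathway:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"pathway {self.name}: duplicate member genes")


@dataclass
class PathwayCatalog:
    pathways: list[Pathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.pathways]
        if len(set(names)) != len(names):
            raise ValueError("pathway names must be unique")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def remove_genes(self, genes: Iterable[str]) -> "PathwayCatalog":
        """Return a catalog with the named genes dropped from every pathway."""
        drop = set(genes)
        return PathwayCatalog(
            [
                Pathway(p.name, p.description, tuple(g for g in p.genes if g not in drop))
                for p in self.pathways
            ]
        )


# ---------------------------------------------------------------------------
# PLINK-style .ped / .map text
# ---------------------------------------------------------------------------

def write_dataset(
    dataset: GenotypeDataset,
    annotation: Sequence[GeneAnnotation],
    catalog: PathwayCatalog,
    directory: str | Path,
    prefix: str = "study",
) -> dict[str, Path]:
    """Write a dataset plus annotation plus catalog as plain text files.

    Emits ``<prefix>.ped``/``<prefix>.map`` (PLINK-style text; the .map carries
    two extra allele columns so dosages round-trip without re-inferring the
    minor allele), ``<prefix>.cov.tsv`` (sample covariates), ``genes.bed``
    (BED-like, 1-based inclusive, documented in its header line) and
    ``pathways.gmt``. Returns a dict of artifact name to path.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "ped": directory / f"{prefix}.ped",
            "map": directory / f"{prefix}.map",
            "cov": directory / f"{prefix}.cov.tsv",
            "bed": directory / "genes.bed",
            "gmt": directory / "pathways.gmt",
        }
        _write_map(dataset.snp_map, paths["map"])
        _write_ped(dataset, paths["ped"])
        dataset.samples.to_csv(paths["cov"], sep="\t", index=False)
        write_gene_bed(annotation, paths["bed"])
        write_gmt(catalog, paths["gmt"])
    except OSError as exc:  # pragma: no cover - depends on filesystem state
        raise OSError(f"failed writing dataset under {directory}: {exc}") from exc
    return paths


def _write_map(snp_map: pd.DataFrame, path: Path) -> None:
    # chrom, snp_id, genetic distance (0), bp position, minor allele, major allele
    out = pd.DataFrame(
        {
            "chrom": snp_map["chrom"],
            "snp_id": snp_map["snp_id"],
            "cm": 0,
            "pos": snp_map["pos"],
            "allele1": snp_map["allele1"],
            "allele2": snp_map["allele2"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def _write_ped(dataset: GenotypeDataset, path: Path) -> None:
    a1 = dataset.snp_map["allele1"].to_numpy()
    a2 = dataset.snp_map["allele2"].to_numpy()
    # row 0/1/2 of the lookup = dosage; row 3 = missing ("0 0")
    lookup = np.empty((4, len(a1)), dtype=object)
    lookup[0] = [f"{x} {x}" for x in a2]
    lookup[1] = [f"{x} {y}" for x, y in zip(a1, a2)]
    lookup[2] = [f"{x} {x}" for x in a1]
    lookup[3] = "0 0"
    cols = np.arange(len(a1))
    with open(path, "w") as fh:
        for i in range(dataset.n_samples):
            row = dataset.samples.iloc[i]
            sex = 1 if row["gender"] == 1 else 2
            pheno = 2 if row["status"] == 1 else 1
            d = dataset.dosages[i]
            cells = lookup[np.where(d == MISSING, 3, d), cols]
            fh.write(
                f"{row['site']}\t{row['sample_id']}\t0\t0\t{sex}\t{pheno}\t"
                + "\t".join(cells)
                + "\n"
            )


def read_dataset(directory: str | Path, prefix: str = "study") -> GenotypeDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    snp_map = _read_map(directory / f"{prefix}.map")
    samples = pd.read_csv(
        directory / f"{prefix}.cov.tsv",
        sep="\t",
        dtype={"site": str, "sample_id": str},
    )
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise DataFormatError(f"covariate table lacks columns {missing_cols}")
    dosages = _read_ped(directory / f"{prefix}.ped", snp_map)
    return GenotypeDataset(
        dosages=dosages, snp_map=snp_map, samples=samples[SAMPLE_COLUMNS]
    )


def _read_map(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "allele1": str, "allele2": str},
    )
    return df[SNP_MAP_COLUMNS]


def _read_ped(path: Path, snp_map: pd.DataFrame) -> np.ndarray:
    n_snps = len(snp_map)
    a1 = snp_map["allele1"].to_numpy()
    # genotype cell -> dosage = number of copies of the minor allele
    code = [
        {f"{x} {x}": 2, f"{x} {y}": 1, f"{y} {x}": 1, f"{y} {y}": 0, "0 0": MISSING}
        for x, y in zip(a1, snp_map["allele2"].to_numpy())
    ]
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6 + n_snps:
                raise DataFormatError(
                    f"{path}:{lineno}: expected {6 + n_snps} fields, got {len(fields)}"
                )
            try:
                rows.append(
                    np.array(
                        [code[j][cell] for j, cell in enumerate(fields[6:])],
                        dtype=np.int8,
                    )
                )
            except KeyError as exc:
                raise DataFormatError(
                    f"{path}:{lineno}: genotype {exc} does not match .map alleles"
                ) from exc
    return (
        np.vstack(rows) if rows else np.empty((0, n_snps), dtype=np.int8)
    )


# ---------------------------------------------------------------------------
# BED-like gene annotation (1-based inclusive, unlike true BED)
# ---------------------------------------------------------------------------

_BED_HEADER = "#gene_id\tchrom\tstart\tend\t(1-based, inclusive both ends)"


def write_gene_bed(annotation: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for g in annotation:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\n")


def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise DataFormatError(f"{path}: bad annotation line: {line!r}")
            gid, chrom, start, end = parts
            if gid in seen:
                raise DataFormatError(f"{path}: duplicate gene id {gid}")
            seen.add(gid)
            genes.append(GeneAnnotation(gid, chrom, int(start), int(end)))
    return genes


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def write_gmt(catalog: PathwayCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in catalog:
            fh.write("\t".join([p.name, p.description, *p.genes]) + "\n")


def read_gmt(path: str | Path) -> PathwayCatalog:
    pathways: list[Pathway] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataFormatError(f"{path}: GMT line needs name and description")
            pathways.append(Pathway(parts[0], parts[1], tuple(parts[2:])))
    return PathwayCatalog(pathways)
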