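"""SNP-to-gene window mapping, representative-SNP gene scores, pathway sets.

A SNP is assigned to every gene whose interval, extended by ``window_bp`` on
each side, contains its position (1-based, inclusive at exactly the window
edge). Each gene is then summarized by its representative SNP -- the assigned
SNP with the smallest association p-value, ties broken by genomic position
then id -- and ranked by the squared Wald statistic of that SNP (a 1-df
chi-square scale, which keeps the weighted enrichment score well defined).
Pathways are restricted to genes that carry at least one scored SNP and
filtered to the configured size range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import SnpAssociation
from .io import GeneAnnotation, PathwayCatalog

__all__ = [
    "GeneScore",
    "PathwayGeneSet",
    "assign_snps_to_genes",
    "score_genes",
    "build_pathway_sets",
    "pathway_overlap",
]


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    representative_snp: str
    p_min: float
    r: float  # ranking statistic: squared Wald z of the representative SNP
    n_snps: int


@dataclass(frozen=True)
class PathwayGeneSet:
    name: str
    genes: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.genes)


def assign_snps_to_genes(
    snp_map: pd.DataFrame,
    annotation: Sequence[GeneAnnotation],
    window_bp: int = 50_000,
) -> dict[str, list[str]]:
    """Map snp_id -> gene_ids for SNPs within window_bp of a gene boundary.

    SNP s at position x on chromosome c belongs to gene g on c iff
    start(g) - window_bp <= x <= end(g) + window_bp. A SNP may map to several
    genes; SNPs mapping to none are absent from the result.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    mapping: dict[str, list[str]] = {}
    if not len(annotation):
        return mapping
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom, genes in by_chrom.items():
        rows = snp_map[snp_map["chrom"] == chrom]
        if rows.empty:
            continue
        pos = rows["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        ids_sorted = rows["snp_id"].to_numpy()[order]
        for g in genes:
            lo = np.searchsorted(pos_sorted, g.start - window_bp, side="left")
            hi = np.searchsorted(pos_sorted, g.end + window_bp, side="right")
            for sid in ids_sorted[lo:hi]:
                mapping.setdefault(sid, []).append(g.gene_id)
    return mapping


def score_genes(
    mapping: Mapping[str, Sequence[str]],
    associations: Sequence[SnpAssociation],
    snp_map: pd.DataFrame,
) -> list[GeneScore]:
    """Per-gene representative-SNP score from the association results.

    Non-converged (flagged) SNPs never represent a gene; a gene whose SNPs are
    all flagged is dropped. Ties on p break by position, then snp id.
    """
    assoc_by_id = {a.snp_id: a for a in associations}
    pos_by_id = dict(zip(snp_map["snp_id"], snp_map["pos"]))

    per_gene: dict[str, list[SnpAssociation]] = {}
    counts: dict[str, int] = {}
    for sid, genes in mapping.items():
        a = assoc_by_id.get(sid)
        if a is None:
            raise KeyError(f"mapped SNP {sid} has no association result")
        for gid in genes:
            counts[gid] = counts.get(gid, 0) + 1
            if a.converged:
                per_gene.setdefault(gid, []).append(a)

    scores = []
    for gid, snps in per_gene.items():
        best = min(snps, key=lambda a: (a.p, pos_by_id[a.snp_id], a.snp_id))
        scores.append(
            GeneScore(
                gene_id=gid,
                representative_snp=best.snp_id,
                p_min=best.p,
                r=best.wald_z**2,
                n_snps=counts[gid],
            )
        )
    scores.sort(key=lambda s: s.gene_id)
    return scores


def build_pathway_sets(
    catalog: PathwayCatalog,
    scored_genes: Sequence[GeneScore],
    size_min: int = 10,
    size_max: int = 200,
) -> list[PathwayGeneSet]:
    """Restrict pathways to scored genes and keep sizes in [size_min, size_max]."""
    if not scored_genes:
        raise ValueError("scored_genes is empty; nothing to build pathway sets from")
    scored = {s.gene_id for s in scored_genes}
    sets = []
    for p in catalog:
        genes = tuple(g for g in p.genes if g in scored)
        if size_min <= len(genes) <= size_max:
            sets.append(PathwayGeneSet(p.name, genes))
    return sets


def pathway_overlap(
    set_a: PathwayGeneSet, set_b: PathwayGeneSet, denominator: str = "total"
) -> float:
    """Percentage of shared genes between two pathways.

    ``total`` (default) divides by the sum of the two set sizes, so two
    16-gene pathways sharing 2 genes overlap by 100*2/32 = 6.25% and identical
    sets max out at 50%. ``union`` divides by the union size instead.
    """
    if set_a.size == 0 or set_b.size == 0:
        raise ValueError("pathway_overlap requires nonempty sets")
    shared = len(set(set_a.genes) & set(set_b.genes))
    if denominator == "total":
        denom = set_a.size + set_b.size
    elif denominator == "union":
        denom = len(set(set_a.genes) | set(set_b.genes))
    else:
        raise ValueError("denominator must be 'total' or 'union'")
    return 100.0 * shared / denom
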