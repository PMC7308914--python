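"""Gene Activity Scores: per-gene accessibility proxies.

A gene's activity is the sum of accessibility counts over its gene body
extended a fixed distance upstream of the TSS (2 kb by default).  Two
summarization routes exist and are both exposed: matrix-level (every
region overlapping a gene window contributes its full count to that gene,
multi-gene regions to each of them) and molecule-level (run the BUS
counting step with the region->gene mapping, where ambiguous molecules are
discarded instead).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.sparse as sp

from .bus_ops import CountMatrix
from .reference import GenomicInterval, RegionMapping, RegionSet

__all__ = [
    "GeneModel",
    "read_gene_models",
    "build_gene_windows",
    "map_regions_to_genes",
    "gene_activity",
]


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A gene body with strand; coordinates 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (chrom, start, end, gene_id, score, strand)
    or a minimal GTF subset (``gene`` features with a gene_id attribute)."""
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_gtf_genes(path)
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 fields")
            try:
                genes.append(
                    GeneModel(
                        gene_id=fields[3],
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        strand=fields[5],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _read_gtf_genes(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in fields[8].rstrip(";").split(";")
                if kv.strip()
            )
            genes.append(
                GeneModel(
                    gene_id=attrs["gene_id"],
                    chrom=fields[0],
                    start=int(fields[3]) - 1,  # GTF is 1-based inclusive
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    return genes


def build_gene_windows(
    genes: Iterable[GeneModel], upstream: int = 2000
) -> RegionSet:
    """Extend each gene body ``upstream`` bp beyond its TSS.

    The TSS is the start for + strand genes and the end for - strand
    genes, so + strand windows extend left (clamped at 0) and - strand
    windows extend right.  Window ids are gene ids.
    """
    intervals, ids = [], []
    for g in genes:
        if g.strand == "+":
            iv = GenomicInterval(g.chrom, max(0, g.start - upstream), g.end)
        else:
            iv = GenomicInterval(g.chrom, g.start, g.end + upstream)
        intervals.append(iv)
        ids.append(g.gene_id)
    return RegionSet(intervals, ids)


def map_regions_to_genes(
    regions: RegionSet, windows: RegionSet
) -> RegionMapping:
    """Many-to-many map: region -> every gene window it overlaps by >= 1 bp.

    Regions overlapping no window are absent from the mapping.  Half-open
    coordinates: a region ending where a window starts does not overlap.
    """
    # sweep per chromosome over sorted windows
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, iv in windows:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, gid))
    for lst in by_chrom.values():
        lst.sort()
    mapping: RegionMapping = {}
    for rid, iv in regions:
        hits = [
            gid
            for (ws, we, gid) in by_chrom.get(iv.chrom, ())
            if ws < iv.end and iv.start < we
        ]
        if hits:
            mapping[rid] = sorted(hits)
    return mapping


def gene_activity(matrix: CountMatrix, mapping: RegionMapping) -> CountMatrix:
    """Matrix-level summarization of region counts into gene activity.

    Each gene's column is the sum of the columns of its mapped regions; a
    region mapped to several genes contributes its full count to each.
    Regions absent from the mapping are dropped.
    """
    genes = sorted({g for tgts in mapping.values() for g in tgts})
    gcol = {g: j for j, g in enumerate(genes)}
    # region x gene indicator
    rows, cols = [], []
    for j, feat in enumerate(matrix.features):
        for g in mapping.get(feat, ()):
            rows.append(j)
            cols.append(gcol[g])
    indicator = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(matrix.features), len(genes)),
    )
    out = matrix.matrix @ indicator
    return CountMatrix(matrix=out.tocsr(), barcodes=list(matrix.barcodes), features=genes)
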