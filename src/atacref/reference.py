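"""Interval catalogs: reading, distance-merging, and sequence extraction.

The quantification reference is a catalog of candidate accessible regions
(e.g. a DNase I hypersensitive site list).  Regions are 0-based half-open
(BED convention) and unstranded; merging follows ``bedtools merge -d``
semantics, i.e. intervals whose gap is <= the threshold are united
transitively.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

from pyfaidx import Fasta

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "RegionMapping",
    "read_intervals",
    "merge_intervals",
    "extract_sequences",
    "write_mapping",
    "read_mapping",
]


@dataclasses.dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def default_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


class RegionSet:
    """An ordered, sorted collection of intervals with unique stable ids.

    Default ids are ``chrom:start-end``.  Construction sorts by
    (chrom, start, end) and carries ids along.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        ids: Iterable[str] | None = None,
    ) -> None:
        intervals = list(intervals)
        if ids is None:
            # identical intervals share the default id: they are one region
            intervals = sorted(set(intervals))
            ids = [iv.default_id for iv in intervals]
        else:
            ids = list(ids)
        if len(ids) != len(intervals):
            raise ValueError("ids and intervals differ in length")
        order = sorted(range(len(intervals)), key=lambda i: intervals[i])
        self.intervals: list[GenomicInterval] = [intervals[i] for i in order]
        self.ids: list[str] = [ids[i] for i in order]
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate region id: {dup}")
        self._by_id = dict(zip(self.ids, self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[str, GenomicInterval]]:
        return iter(zip(self.ids, self.intervals))

    def __getitem__(self, region_id: str) -> GenomicInterval:
        return self._by_id[region_id]

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals and self.ids == other.ids

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals)"


# Many-to-one (merge projection) or many-to-many (gene projection) map from
# source region ids to target feature ids.
RegionMapping = dict[str, list[str]]


def read_intervals(path: str | Path, format: str = "bed") -> RegionSet:
    """Read a BED3+ file or whitespace-delimited interval list.

    Extra columns beyond chrom/start/end are ignored.  Records are sorted;
    input order is irrelevant.  Malformed lines raise ``ValueError`` naming
    the line number.
    """
    if format not in ("bed", "interval-list"):
        raise ValueError(f"unknown interval format: {format!r}")
    sep = "\t" if format == "bed" else None
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split(sep)
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 fields")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(intervals)


def merge_intervals(
    regions: RegionSet, gap: int
) -> tuple[RegionSet, RegionMapping]:
    """Merge intervals whose gap is <= ``gap`` bp (transitively).

    Overlapping intervals always merge.  A gap of exactly ``gap`` merges,
    matching ``bedtools merge -d``.  Returns the merged set and the
    many-to-one source-id -> merged-id mapping.
    """
    if gap < 0:
        raise ValueError(f"gap must be non-negative, got {gap}")
    merged: list[GenomicInterval] = []
    groups: list[list[str]] = []
    for rid, iv in regions:
        if merged and iv.chrom == merged[-1].chrom and iv.start - merged[-1].end <= gap:
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, iv.end)
            )
            groups[-1].append(rid)
        else:
            merged.append(iv)
            groups.append([rid])
    target = RegionSet(merged)
    mapping: RegionMapping = {}
    for iv, members in zip(merged, groups):
        for rid in members:
            mapping[rid] = [iv.default_id]
    return target, mapping


def extract_sequences(
    genome: str | Path, regions: RegionSet, out_fasta: str | Path
) -> Path:
    """Write one upper-cased forward-strand FASTA record per region.

    Headers are the region ids.  Missing chromosomes or out-of-bounds
    intervals raise ``ValueError`` naming the offending region.
    """
    fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    out_fasta = Path(out_fasta)
    with open(out_fasta, "w") as out:
        for rid, iv in regions:
            if iv.chrom not in fa:
                raise ValueError(f"region {rid}: chromosome {iv.chrom!r} not in genome")
            if iv.end > len(fa[iv.chrom]):
                raise ValueError(
                    f"region {rid}: end {iv.end} beyond chromosome length "
                    f"{len(fa[iv.chrom])}"
                )
            seq = fa[iv.chrom][iv.start : iv.end]
            out.write(f">{rid}\n{seq}\n")
    return out_fasta


def write_mapping(mapping: RegionMapping, path: str | Path) -> Path:
    """Write a mapping as two-column TSV (source_id, target_id), one row
    per (source, target) pair — the "t2g"-style file consumed by counting."""
    path = Path(path)
    with open(path, "w") as out:
        for src in mapping:
            for tgt in mapping[src]:
                out.write(f"{src}\t{tgt}\n")
    return path


def read_mapping(path: str | Path) -> RegionMapping:
    mapping: RegionMapping = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            mapping.setdefault(fields[0], []).append(fields[1])
    return mapping
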