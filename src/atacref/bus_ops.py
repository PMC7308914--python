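"""BUS-style record handling: sorting, pseudoUMI deduplication, counting,
feature projection, and sparse-matrix I/O.

A BUS record is a (cell barcode, pseudoUMI, equivalence class) tuple with a
multiplicity.  Counting groups records per (barcode, pseudoUMI): a group is
one candidate molecule.  Each record's equivalence class is mapped to a set
of target features (native regions under the identity mapping, merged
intervals or genes otherwise); the group's target set is the intersection
across its records.  A singleton target gains one molecule; empty or
multi-target groups are discarded.  Many-to-one projection can therefore
rescue molecules that are ambiguous at native resolution — the mechanism
behind quantifying a full catalog and summarizing onto merged intervals.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .kmer_index import KmerIndex, pseudoalign
from .read_structure import BusInput
from .reference import RegionMapping

__all__ = [
    "BusRecord",
    "CountMatrix",
    "quantify_stream",
    "sort_records",
    "count",
    "write_matrix",
    "read_matrix",
    "write_bus_tsv",
    "read_bus_tsv",
]


@dataclasses.dataclass(frozen=True)
class BusRecord:
    """One (barcode, pseudoUMI, equivalence class) observation."""

    cb: str
    umi: str
    ec: tuple[str, ...]  # sorted region ids of the equivalence class
    count: int = 1


@dataclasses.dataclass
class CountMatrix:
    """Sparse cells x features molecule counts with name vectors."""

    matrix: sp.csr_matrix
    barcodes: list[str]
    features: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.barcodes), len(self.features)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.features)} features"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.barcodes, columns=self.features
        )


def quantify_stream(
    stream: Iterable[BusInput], index: KmerIndex
) -> Iterator[BusRecord]:
    """Pseudoalign a BusInput stream; unmapped reads are dropped."""
    for rec in stream:
        ec = pseudoalign(rec.seq, index)
        if ec is not None:
            yield BusRecord(cb=rec.cb, umi=rec.umi, ec=ec)


def sort_records(records: Iterable[BusRecord]) -> list[BusRecord]:
    """Sort by (cb, umi, ec) and collapse identical keys, summing counts."""
    out: list[BusRecord] = []
    for rec in sorted(records, key=lambda r: (r.cb, r.umi, r.ec)):
        if out and (out[-1].cb, out[-1].umi, out[-1].ec) == (rec.cb, rec.umi, rec.ec):
            out[-1] = dataclasses.replace(out[-1], count=out[-1].count + rec.count)
        else:
            out.append(rec)
    return out


def _check_sorted(records: list[BusRecord]) -> None:
    keys = [(r.cb, r.umi, r.ec) for r in records]
    if keys != sorted(keys):
        raise ValueError("records are not sorted; call sort_records first")


def count(
    records: list[BusRecord],
    mapping: RegionMapping | None = None,
    whitelist: Iterable[str] | None = None,
) -> CountMatrix:
    """Deduplicate and count molecules per (cell, target feature).

    ``mapping`` projects region ids onto target feature ids; ``None`` means
    the identity (count at native region resolution).  Each (cb, umi)
    group contributes one molecule to its target iff the intersection of
    the records' mapped target sets is a singleton.  When a whitelist is
    supplied, records from other barcodes are dropped before grouping and
    the matrix rows are exactly the whitelist (in given order).
    """
    _check_sorted(records)
    wl = list(whitelist) if whitelist is not None else None
    wl_set = set(wl) if wl is not None else None

    def targets(ec: tuple[str, ...]) -> frozenset[str]:
        if mapping is None:
            return frozenset(ec)
        out: set[str] = set()
        for rid in ec:
            try:
                out.update(mapping[rid])
            except KeyError:
                raise ValueError(f"region id {rid!r} missing from mapping") from None
        return frozenset(out)

    counts: dict[tuple[str, str], int] = {}
    feature_ids: dict[str, int] = {}
    if mapping is not None:
        for tgts in mapping.values():
            for t in tgts:
                feature_ids.setdefault(t, len(feature_ids))

    # records are sorted, so (cb, umi) groups are contiguous
    i, n = 0, len(records)
    while i < n:
        j = i
        cb, umi = records[i].cb, records[i].umi
        group_targets: frozenset[str] | None = None
        while j < n and records[j].cb == cb and records[j].umi == umi:
            t = targets(records[j].ec)
            group_targets = t if group_targets is None else group_targets & t
            j += 1
        if (
            (wl_set is None or cb in wl_set)
            and group_targets is not None
            and len(group_targets) == 1
        ):
            (target,) = group_targets
            if mapping is None:
                feature_ids.setdefault(target, len(feature_ids))
            key = (cb, target)
            counts[key] = counts.get(key, 0) + 1
        i = j

    if wl is not None:
        barcodes = wl
    else:
        barcodes = sorted({cb for cb, _ in counts})
    features = sorted(feature_ids)
    brow = {cb: i for i, cb in enumerate(barcodes)}
    fcol = {f: j for j, f in enumerate(features)}
    rows, cols, data = [], [], []
    for (cb, target), c in counts.items():
        if cb not in brow:
            continue
        rows.append(brow[cb])
        cols.append(fcol[target])
        data.append(c)
    matrix = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(barcodes), len(features)), dtype=np.int64
    )
    return CountMatrix(matrix=matrix, barcodes=list(barcodes), features=features)


def write_matrix(matrix: CountMatrix, out_dir: str | Path) -> Path:
    """Write MatrixMarket + barcodes.tsv + features.tsv (10x-style layout).

    The MTX file is features x cells (columns are cells), matching the 10x
    convention."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(out_dir / "matrix.mtx"), sp.coo_matrix(matrix.matrix.T), field="integer"
    )
    (out_dir / "barcodes.tsv").write_text("".join(b + "\n" for b in matrix.barcodes))
    (out_dir / "features.tsv").write_text("".join(f + "\n" for f in matrix.features))
    return out_dir


def read_matrix(in_dir: str | Path) -> CountMatrix:
    in_dir = Path(in_dir)
    m = scipy.io.mmread(str(in_dir / "matrix.mtx")).T.tocsr()
    barcodes = (in_dir / "barcodes.tsv").read_text().splitlines()
    features = (in_dir / "features.tsv").read_text().splitlines()
    return CountMatrix(matrix=m, barcodes=barcodes, features=features)


def write_bus_tsv(records: Iterable[BusRecord], path: str | Path) -> Path:
    """On-disk BUS-like TSV: cb, umi, comma-joined EC members, count."""
    path = Path(path)
    with open(path, "w") as out:
        for r in records:
            out.write(f"{r.cb}\t{r.umi}\t{','.join(r.ec)}\t{r.count}\n")
    return path


def read_bus_tsv(path: str | Path) -> list[BusRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            cb, umi, ec, c = line.rstrip("\n").split("\t")
            records.append(BusRecord(cb, umi, tuple(ec.split(",")), int(c)))
    return records
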