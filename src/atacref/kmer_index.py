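"""Canonical k-mer index and pseudoalignment to equivalence classes.

A read is assigned not to a position but to the *set* of reference regions
compatible with its k-mer content (its equivalence class, EC).  The index
maps each canonical k-mer occurring in the reference to the EC of exactly
the regions containing it; a query read's EC is the intersection of the ECs
of its indexed k-mers.  This is deliberately simpler than a de Bruijn-graph
pseudoaligner: no contig skipping, no union fallback — reads whose k-mer
hits intersect to the empty set are unmapped.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "KmerIndex",
    "UNMAPPED",
    "canonical",
    "revcomp",
    "build_index",
    "pseudoalign",
    "read_fasta",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Sentinel returned for reads with no consistent equivalence class.
UNMAPPED = None

_ACGT = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    if not _ACGT.issuperset(kmer):
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs from a FASTA file.

    The record id is the header token before the first whitespace.
    """
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        yield name, "".join(chunks)


class KmerIndex:
    """Canonical k-mer -> equivalence-class index over region sequences.

    Attributes
    ----------
    k : int
        k-mer length (odd, so no k-mer equals its own reverse complement).
    kmer_map : dict[str, int]
        canonical k-mer -> equivalence-class id.
    ec_table : list[tuple[str, ...]]
        equivalence-class id -> sorted tuple of region ids.
    region_ids : list[str]
        the ordered region catalog.
    """

    FORMAT_VERSION = 1

    def __init__(
        self,
        k: int,
        kmer_map: dict[str, int],
        ec_table: list[tuple[str, ...]],
        region_ids: list[str],
    ) -> None:
        self.k = k
        self.kmer_map = kmer_map
        self.ec_table = ec_table
        self.region_ids = region_ids

    def __len__(self) -> int:
        return len(self.kmer_map)

    def ec_regions(self, ec_id: int) -> tuple[str, ...]:
        return self.ec_table[ec_id]

    # -- serialization (versioned, self-describing JSON header + body) ----

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as out:
            header = {
                "format": "atacref-kmer-index",
                "version": self.FORMAT_VERSION,
                "k": self.k,
                "n_regions": len(self.region_ids),
                "n_kmers": len(self.kmer_map),
                "n_ecs": len(self.ec_table),
            }
            out.write(json.dumps(header) + "\n")
            out.write("\t".join(self.region_ids) + "\n")
            for members in self.ec_table:
                out.write("\t".join(members) + "\n")
            for kmer, ec in self.kmer_map.items():
                out.write(f"{kmer}\t{ec}\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "KmerIndex":
        with open(path) as fh:
            header = json.loads(fh.readline())
            if header.get("format") != "atacref-kmer-index":
                raise ValueError(f"{path}: not an atacref k-mer index")
            if header["version"] != cls.FORMAT_VERSION:
                raise ValueError(f"{path}: unsupported index version")
            region_ids = fh.readline().rstrip("\n").split("\t")
            ec_table = [
                tuple(fh.readline().rstrip("\n").split("\t"))
                for _ in range(header["n_ecs"])
            ]
            kmer_map: dict[str, int] = {}
            for _ in range(header["n_kmers"]):
                kmer, ec = fh.readline().split()
                kmer_map[kmer] = int(ec)
        return cls(header["k"], kmer_map, ec_table, region_ids)


def build_index(
    region_fasta: str | Path | Iterable[tuple[str, str]], k: int = 31
) -> KmerIndex:
    """Build a canonical k-mer index from region sequences.

    Every length-k window containing only ACGT contributes its canonical
    form; a k-mer present in several regions maps to the EC of exactly the
    set of regions containing it.  Regions shorter than k contribute
    nothing (logged).

    ``region_fasta`` may be a FASTA path or an iterable of (id, sequence).
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd (canonical ambiguity), got {k}")
    if not (1 < k <= 31):
        raise ValueError(f"k must be in (1, 31], got {k}")
    if isinstance(region_fasta, (str, Path)):
        records = read_fasta(region_fasta)
    else:
        records = iter(region_fasta)

    # canonical k-mer -> set of region ids containing it
    occurrences: dict[str, set[str]] = {}
    region_ids: list[str] = []
    n_records = 0
    for rid, seq in records:
        n_records += 1
        region_ids.append(rid)
        seq = seq.upper()
        if len(seq) < k:
            logger.warning("region %s shorter than k=%d; skipped", rid, k)
            continue
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if not _ACGT.issuperset(kmer):
                continue
            rc = kmer.translate(_COMPLEMENT)[::-1]
            if rc < kmer:
                kmer = rc
            hit = occurrences.get(kmer)
            if hit is None:
                occurrences[kmer] = {rid}
            else:
                hit.add(rid)
    if n_records == 0:
        raise ValueError("empty reference FASTA: no records to index")

    # Distinct region sets become equivalence classes.
    ec_ids: dict[tuple[str, ...], int] = {}
    ec_table: list[tuple[str, ...]] = []
    kmer_map: dict[str, int] = {}
    for kmer, members in occurrences.items():
        key = tuple(sorted(members))
        ec = ec_ids.get(key)
        if ec is None:
            ec = len(ec_table)
            ec_ids[key] = ec
            ec_table.append(key)
        kmer_map[kmer] = ec
    return KmerIndex(k, kmer_map, ec_table, region_ids)


def pseudoalign(seq: str, index: KmerIndex) -> tuple[str, ...] | None:
    """Assign a read to its equivalence class, or ``UNMAPPED``.

    Collects the canonical k-mers of ``seq`` that are present in the index
    and intersects their region sets.  Windows containing non-ACGT
    characters are skipped.  Reads shorter than k, reads with no indexed
    k-mer, and reads whose hits intersect to the empty set are unmapped.
    """
    k = index.k
    seq = seq.upper()
    if len(seq) < k:
        return UNMAPPED
    kmer_map = index.kmer_map
    ec_table = index.ec_table
    result: set[str] | None = None
    seen_ecs: set[int] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if not _ACGT.issuperset(kmer):
            continue
        rc = kmer.translate(_COMPLEMENT)[::-1]
        if rc < kmer:
            kmer = rc
        ec = kmer_map.get(kmer)
        if ec is None or ec in seen_ecs:
            continue
        seen_ecs.add(ec)
        members = ec_table[ec]
        if result is None:
            result = set(members)
        else:
            result.intersection_update(members)
            if not result:
                return UNMAPPED
    if not result:
        return UNMAPPED
    return tuple(sorted(result))
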