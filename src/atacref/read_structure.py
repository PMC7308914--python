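"""10x scATAC read restructuring: technology descriptors, pseudoUMI
streams, and cell-barcode selection.

10x scATAC triples carry the forward genomic read in R1, the 16 nt cell
barcode in R2 and the reverse genomic read in R3.  UMI-based pipelines need
a (barcode, UMI, sequence) layout, so a surrogate "pseudoUMI" is fabricated
in one of three ways: random nucleotides, the first n nt of the reverse
mate (n_fwd: align R1), or the first n nt of the forward mate (n_rev: align
R3).  The n_fwd/n_rev strategies rest on the observation that PCR
duplicates of a fragment share its end sequences, so the mate's 5' prefix
acts as a molecular identifier.
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
import random
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "TechDescriptor",
    "BusInput",
    "parse_tech",
    "read_fastq",
    "make_stream",
    "select_barcodes",
    "STRATEGIES",
]

logger = logging.getLogger(__name__)

STRATEGIES = ("random", "n_fwd", "n_rev")

BARCODE_LENGTH = 16


@dataclasses.dataclass(frozen=True)
class TechDescriptor:
    """Slot layout (file index, start, end) for barcode, UMI and sequence.

    A sequence slot of (f, 0, 0) means "the entire read of file f".
    """

    barcode: tuple[int, int, int]
    umi: tuple[int, int, int]
    sequence: tuple[int, int, int]


@dataclasses.dataclass(frozen=True)
class BusInput:
    """One restructured record: cell barcode, pseudoUMI, genomic read."""

    cb: str
    umi: str
    seq: str


def parse_tech(descriptor: str) -> TechDescriptor:
    """Parse a ``bc_file,bc_start,bc_end:umi...:seq...`` technology string.

    Example: ``"0,0,16:0,16,26:1,0,0"`` — barcode is file0[0:16], UMI is
    file0[16:26], the genomic sequence is all of file 1.
    """
    parts = descriptor.split(":")
    if len(parts) != 3:
        raise ValueError(
            f"technology descriptor needs 3 colon-separated slots, "
            f"got {len(parts)}: {descriptor!r}"
        )
    slots = []
    for part in parts:
        fields = part.split(",")
        if len(fields) != 3:
            raise ValueError(f"slot {part!r} needs 3 comma-separated integers")
        try:
            f, s, e = (int(x) for x in fields)
        except ValueError as exc:
            raise ValueError(f"non-integer in slot {part!r}") from exc
        if f < 0 or s < 0 or e < 0:
            raise ValueError(f"negative value in slot {part!r}")
        slots.append((f, s, e))
    for name, (f, s, e) in zip(("barcode", "umi"), slots):
        if s >= e:
            raise ValueError(f"{name} slot needs start < end, got {s},{e}")
    return TechDescriptor(barcode=slots[0], umi=slots[1], sequence=slots[2])


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, qualities) from a FASTQ file (gzip ok)."""
    with _open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record at {header!r}")
            yield header[1:].rstrip("\n").split()[0], seq, qual


def make_stream(
    r1: str | Path,
    r2: str | Path,
    r3: str | Path,
    strategy: str,
    n: int = 10,
    seed: int = 0,
) -> Iterator[BusInput]:
    """Restructure a FASTQ triple into a (barcode, pseudoUMI, seq) stream.

    For every record i the barcode is R2_i[0:16].  Strategy ``random``
    draws n random nucleotides per record from a generator seeded with
    ``seed`` and keeps R1 as the genomic read; ``n_fwd`` takes the UMI from
    R3_i[0:n] and aligns R1; ``n_rev`` takes the UMI from R1_i[0:n] and
    aligns R3.  Records whose UMI-slot read is shorter than n, or whose
    barcode read is shorter than 16 nt, are skipped with a warning.  A
    record-count mismatch between the three files is an error.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if n < 1:
        raise ValueError(f"pseudoUMI length must be positive, got {n}")
    rng = random.Random(seed)
    it1, it2, it3 = read_fastq(r1), read_fastq(r2), read_fastq(r3)
    _SENTINEL = object()
    i = 0
    while True:
        rec1 = next(it1, _SENTINEL)
        rec2 = next(it2, _SENTINEL)
        rec3 = next(it3, _SENTINEL)
        exhausted = sum(r is _SENTINEL for r in (rec1, rec2, rec3))
        if exhausted == 3:
            return
        if exhausted:
            raise ValueError("FASTQ files have differing record counts")
        i += 1
        _, seq1, _ = rec1
        _, seq2, _ = rec2
        _, seq3, _ = rec3
        if len(seq2) < BARCODE_LENGTH:
            logger.warning("record %d: barcode read shorter than 16 nt; skipped", i)
            continue
        cb = seq2[:BARCODE_LENGTH]
        if strategy == "random":
            umi = "".join(rng.choices("ACGT", k=n))
            seq = seq1
        elif strategy == "n_fwd":
            if len(seq3) < n:
                logger.warning("record %d: R3 shorter than n=%d; skipped", i, n)
                continue
            umi, seq = seq3[:n], seq1
        else:  # n_rev
            if len(seq1) < n:
                logger.warning("record %d: R1 shorter than n=%d; skipped", i, n)
                continue
            umi, seq = seq1[:n], seq3
        yield BusInput(cb=cb, umi=umi, seq=seq)


def count_barcodes(stream: Iterable[BusInput]) -> dict[str, int]:
    """Tally reads per cell barcode."""
    counts: dict[str, int] = {}
    for rec in stream:
        counts[rec.cb] = counts.get(rec.cb, 0) + 1
    return counts


def select_barcodes(
    cb_counts: dict[str, int], expected_cells: int
) -> list[str]:
    """Knee-style whitelist: keep barcodes with count >= m/10, where m is
    the read count of the barcode at rank ``expected_cells``.

    Barcodes are ranked by descending count (ties broken lexicographically,
    so the rule is deterministic).  If there are fewer distinct barcodes
    than ``expected_cells``, m falls back to the minimum observed count and
    every barcode is kept, with a warning.
    """
    if not cb_counts:
        raise ValueError("empty barcode count table")
    if expected_cells < 1:
        raise ValueError(f"expected_cells must be >= 1, got {expected_cells}")
    ranked = sorted(cb_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if expected_cells > len(ranked):
        logger.warning(
            "expected_cells=%d exceeds %d distinct barcodes; keeping all",
            expected_cells,
            len(ranked),
        )
        m = ranked[-1][1]
    else:
        m = ranked[expected_cells - 1][1]
    threshold = m / 10
    return [cb for cb, c in ranked if c >= threshold]
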