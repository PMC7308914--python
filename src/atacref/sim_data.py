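"""Synthetic 10x-style scATAC data with known ground truth.

The simulator emulates the parts of a droplet scATAC experiment the
quantification method actually sees: a genome with a catalog of accessible
regions, cell populations whose clusters up-weight disjoint blocks of
cluster-specific regions, paired-end fragments drawn from those regions,
PCR duplicates (verbatim re-emissions of a fragment), per-base substitution
errors, and the 10x read layout — forward genomic read in R1, 16 nt cell
barcode in R2, reverse genomic read in R3.

It deliberately does not model Tn5 insertion bias, GC bias, or the
nucleosome-ladder fragment-size mixture; fragment starts are uniform within
a region and insert sizes are truncated-normal.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .kmer_index import revcomp
from .reference import GenomicInterval, RegionSet

__all__ = [
    "SimSpec",
    "GroundTruth",
    "simulate_reference",
    "simulate_cells",
    "simulate_reads",
    "simulate_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass
class SimSpec:
    """Parameters of a synthetic experiment.

    Defaults describe the standard study condition used throughout the
    test battery: 200 cells in 3 clusters over 500 regions with 2,000
    fragments per cell, 30% cluster-specific regions, 10% PCR duplicates
    and a 0.2% per-base error rate.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 400_000
    n_regions: int = 500
    region_length: int = 400
    n_cells: int = 200
    n_clusters: int = 3
    specific_fraction: float = 0.3
    specific_weight: float = 8.0
    reads_per_cell: int = 2000
    duplicate_rate: float = 0.1
    error_rate: float = 0.002
    read_length: int = 50
    insert_mean: int = 200
    insert_sd: int = 30
    min_region_gap: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "n_chroms",
            "chrom_length",
            "n_regions",
            "region_length",
            "n_cells",
            "n_clusters",
            "reads_per_cell",
            "read_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("duplicate_rate", "error_rate", "specific_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (31 <= self.read_length <= self.region_length):
            raise ValueError("require region_length >= read_length >= 31")
        if self.n_cells > 4**16:
            raise ValueError("barcode space exhausted: n_cells > 4^16")


@dataclasses.dataclass
class GroundTruth:
    """Per-cell labels and per-fragment provenance.

    ``labels``: Series cluster label per barcode.  ``fragments``: one row
    per distinct molecule (frag_id, cb, region_id, start, end; coordinates
    genome-absolute, half-open).  Duplicate reads share a frag_id.
    """

    labels: pd.Series
    fragments: pd.DataFrame

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.fragments.assign(
            cluster=self.labels.loc[self.fragments["cb"]].values
        ).to_csv(path, sep="\t", index=False)
        return path


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_reference(spec: SimSpec) -> tuple[dict[str, str], RegionSet]:
    """Random genome plus non-overlapping regions separated by >= 1 kb.

    Returns the genome as {chrom: sequence} and the region catalog.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    per_chrom = [
        spec.n_regions // spec.n_chroms + (1 if c < spec.n_regions % spec.n_chroms else 0)
        for c in range(spec.n_chroms)
    ]
    genome: dict[str, str] = {}
    intervals: list[GenomicInterval] = []
    for c, n_r in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        genome[chrom] = _random_seq(rng, spec.chrom_length)
        needed = n_r * (spec.region_length + spec.min_region_gap)
        if needed > spec.chrom_length:
            raise ValueError(
                f"{n_r} regions of {spec.region_length} bp with "
                f"{spec.min_region_gap} bp gaps do not fit in {spec.chrom_length} bp"
            )
        slack = spec.chrom_length - needed
        # distribute the slack randomly over the n_r+1 gaps
        extra = rng.multinomial(slack, np.ones(n_r + 1) / (n_r + 1))
        pos = 0
        for i in range(n_r):
            pos += spec.min_region_gap + int(extra[i])
            intervals.append(GenomicInterval(chrom, pos, pos + spec.region_length))
            pos += spec.region_length
    return genome, RegionSet(intervals)


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        for chrom, seq in genome.items():
            out.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
    return path


def simulate_cells(
    spec: SimSpec, regions: RegionSet
) -> tuple[list[str], pd.Series, np.ndarray]:
    """Barcodes, cluster labels and per-cluster region weight vectors.

    Clusters are near-equal sized.  The first ``specific_fraction`` of the
    region catalog is split into contiguous per-cluster blocks; a cluster's
    own block is up-weighted by ``specific_weight``, everything else is
    uniform; weights are normalized per cluster.
    """
    rng = np.random.default_rng(spec.seed + 1)
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < spec.n_cells:
        cb = _random_seq(rng, 16)
        if cb not in seen:
            seen.add(cb)
            barcodes.append(cb)
    labels = pd.Series(
        [f"c{i % spec.n_clusters}" for i in range(spec.n_cells)], index=barcodes
    )
    n_regions = len(regions)
    n_specific = int(round(spec.specific_fraction * n_regions))
    block = n_specific // spec.n_clusters if spec.n_clusters else 0
    weights = np.ones((spec.n_clusters, n_regions))
    for k in range(spec.n_clusters):
        weights[k, k * block : (k + 1) * block] = spec.specific_weight
    weights /= weights.sum(axis=1, keepdims=True)
    return barcodes, labels, weights


def _inject_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        alternatives = [b for b in "ACGT" if b != cur]
        arr[i] = alternatives[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _open_out(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "wt", compresslevel=1)
    return open(path, "w")


def simulate_reads(
    genome: dict[str, str],
    regions: RegionSet,
    barcodes: list[str],
    labels: pd.Series,
    weights: np.ndarray,
    spec: SimSpec,
    out_dir: str | Path,
    errors_per_copy: bool = False,
) -> tuple[Path, Path, Path, GroundTruth]:
    """Emit the R1/R2/R3 FASTQ triple plus ground truth.

    Per cell, ``reads_per_cell`` fragments are drawn from regions according
    to the cell's cluster weight vector; the fragment start is uniform
    within the region and the insert length truncated-normal.  R1 is the
    forward ``read_length`` bp from the fragment 5' end, R3 the reverse
    complement of the 3' end, R2 the cell barcode.  A ``duplicate_rate``
    fraction of fragments is emitted twice.  Substitution errors are
    injected once per molecule, so duplicate copies stay verbatim-identical
    (the regime in which prefix-based pseudoUMI deduplication is exact);
    with ``errors_per_copy=True`` errors are drawn independently per copy
    instead, to probe how sequencing errors break duplicate detection.

    Read names encode ground truth: ``cell:<cb>|frag:<id>|region:<id>|dup:<k>``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 2)
    cluster_index = {c: k for k, c in enumerate(sorted(labels.unique()))}
    region_ids = list(regions.ids)
    region_ivs = list(regions.intervals)
    n_regions = len(region_ids)
    L = spec.read_length

    paths = (out_dir / "R1.fastq.gz", out_dir / "R2.fastq.gz", out_dir / "R3.fastq.gz")
    frag_rows: list[tuple] = []
    frag_id = 0
    with _open_out(paths[0]) as f1, _open_out(paths[1]) as f2, _open_out(paths[2]) as f3:
        for cb in barcodes:
            w = weights[cluster_index[labels.loc[cb]]]
            region_draws = rng.choice(n_regions, size=spec.reads_per_cell, p=w)
            for ridx in region_draws:
                iv = region_ivs[ridx]
                rid = region_ids[ridx]
                chrom_seq = genome[iv.chrom]
                # truncate the insert into [read_length, region length]
                insert = int(round(rng.normal(spec.insert_mean, spec.insert_sd)))
                insert = max(L, min(insert, len(iv)))
                start = iv.start + int(rng.integers(0, len(iv) - insert + 1))
                end = start + insert
                fragment = chrom_seq[start:end]
                r1 = fragment[:L]
                r3 = revcomp(fragment[-L:])
                if not errors_per_copy:
                    r1 = _inject_errors(r1, rng, spec.error_rate)
                    r3 = _inject_errors(r3, rng, spec.error_rate)
                n_copies = 2 if rng.random() < spec.duplicate_rate else 1
                frag_rows.append((frag_id, cb, rid, start, end, n_copies))
                for k in range(n_copies):
                    o1, o3 = r1, r3
                    if errors_per_copy:
                        o1 = _inject_errors(o1, rng, spec.error_rate)
                        o3 = _inject_errors(o3, rng, spec.error_rate)
                    name = f"cell:{cb}|frag:{frag_id}|region:{rid}|dup:{k}"
                    f1.write(f"@{name}\n{o1}\n+\n{'I' * len(o1)}\n")
                    f2.write(f"@{name}\n{cb}\n+\n{'I' * len(cb)}\n")
                    f3.write(f"@{name}\n{o3}\n+\n{'I' * len(o3)}\n")
                frag_id += 1
    truth = GroundTruth(
        labels=labels.copy(),
        fragments=pd.DataFrame(
            frag_rows, columns=["frag_id", "cb", "region_id", "start", "end", "n_copies"]
        ),
    )
    return (*paths, truth)


def simulate_dataset(
    spec: SimSpec, out_dir: str | Path, errors_per_copy: bool = False
) -> dict:
    """Full synthetic dataset: genome FASTA, regions BED, FASTQ triple,
    truth TSV.  Returns a dict of paths plus the in-memory objects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, regions = simulate_reference(spec)
    genome_path = write_genome_fasta(genome, out_dir / "genome.fa")
    bed_path = out_dir / "regions.bed"
    with open(bed_path, "w") as bed:
        for _rid, iv in regions:
            bed.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    barcodes, labels, weights = simulate_cells(spec, regions)
    r1, r2, r3, truth = simulate_reads(
        genome, regions, barcodes, labels, weights, spec, out_dir,
        errors_per_copy=errors_per_copy,
    )
    truth_path = truth.write(out_dir / "truth.tsv")
    return {
        "genome": genome_path,
        "regions_bed": bed_path,
        "r1": r1,
        "r2": r2,
        "r3": r3,
        "truth_tsv": truth_path,
        "region_set": regions,
        "genome_dict": genome,
        "truth": truth,
        "spec": spec,
    }
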