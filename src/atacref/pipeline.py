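"""End-to-end pipeline composition with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

from . import __version__, bus_ops, eval_metrics, kmer_index, read_structure, reference

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Every knob of the reference-quantify-cluster pipeline.

    Defaults are the method's standard operating point: k=31 pseudoalignment,
    500 bp interval merging, 10 nt pseudoUMI from the forward mate (n_rev:
    align R3), 10,000 expected cells, 2 kb upstream gene windows, Leiden
    resolution 0.2.
    """

    genome: str
    intervals: str
    r1: str
    r2: str
    r3: str
    out_dir: str
    genes: str | None = None
    k: int = 31
    merge_gap: int = 500
    strategy: str = "n_rev"
    umi_len: int = 10
    expected_cells: int = 10000
    upstream: int = 2000
    min_regions_per_cell: int = 200
    min_cells_per_region: int = 10
    resolution: float = 0.2
    top_n: int = 1000
    alpha: float = 0.05
    near: int = 20000
    seed: int = 0
    summarize: bool = True  # also project full-catalog counts onto merged intervals

    def validate(self) -> None:
        for attr in ("genome", "intervals", "r1", "r2", "r3"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if self.strategy not in read_structure.STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.umi_len < 1 or self.merge_gap < 0 or self.k < 3:
            raise ValueError("parameter out of range")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """build-ref -> index -> quant -> count (-> project) -> cluster.

    Writes MTX count matrices, cluster labels, and a manifest recording
    versions, parameters, seeds and input checksums.  Any stage failure
    aborts with the stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "atacref",
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in ("genome", "intervals", "r1", "r2", "r3")
        },
        "stages": [],
    }
    stage = "build-ref"
    try:
        regions = reference.read_intervals(config.intervals)
        merged, mapping = reference.merge_intervals(regions, config.merge_gap)
        reference.write_mapping(mapping, out / "t2g.tsv")
        region_fa = reference.extract_sequences(
            config.genome, regions, out / "regions.fa"
        )
        manifest["stages"].append(stage)

        stage = "index"
        index = kmer_index.build_index(region_fa, k=config.k)
        index.save(out / "index.txt")
        manifest["stages"].append(stage)

        stage = "quant"
        stream = read_structure.make_stream(
            config.r1, config.r2, config.r3,
            strategy=config.strategy, n=config.umi_len, seed=config.seed,
        )
        records = bus_ops.sort_records(bus_ops.quantify_stream(stream, index))
        bus_ops.write_bus_tsv(records, out / "records.bus.tsv")
        manifest["stages"].append(stage)

        stage = "count"
        cb_counts: dict[str, int] = {}
        for r in records:
            cb_counts[r.cb] = cb_counts.get(r.cb, 0) + r.count
        whitelist = read_structure.select_barcodes(cb_counts, config.expected_cells)
        native = bus_ops.count(records, mapping=None, whitelist=whitelist)
        bus_ops.write_matrix(native, out / "counts_native")
        manifest["stages"].append(stage)

        if config.summarize:
            stage = "project"
            projected = bus_ops.count(records, mapping=mapping, whitelist=whitelist)
            bus_ops.write_matrix(projected, out / "counts_merged")
            manifest["stages"].append(stage)

        if config.genes:
            stage = "gene-activity"
            from . import gene_activity as ga

            genes = ga.read_gene_models(config.genes)
            windows = ga.build_gene_windows(genes, upstream=config.upstream)
            gmap = ga.map_regions_to_genes(regions, windows)
            gmatrix = ga.gene_activity(native, gmap)
            bus_ops.write_matrix(gmatrix, out / "counts_genes")
            manifest["stages"].append(stage)

        stage = "cluster"
        labels = eval_metrics.cluster_cells(
            native,
            min_regions_per_cell=config.min_regions_per_cell,
            min_cells_per_region=config.min_cells_per_region,
            resolution=config.resolution,
            seed=config.seed,
        )
        eval_metrics.write_labeling(labels, out / "clusters.tsv")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
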