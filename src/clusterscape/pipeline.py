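"""End-to-end pipeline: filter -> embed -> cluster -> convert -> render.

A :class:`RunConfig` collects every tunable of the pipeline with defaults
matching the reference analysis (learning rate 2000, DBSCAN eps 2 /
min_pts 10, significance cut-offs 1 and 0.05, sphere segments 32, batch
size 5000, grouping threshold 50000).  Configs load from flat JSON with
dotted keys (``{"tsne.learning_rate": 2000}``); unknown keys are rejected.

:func:`run_pipeline` executes the chosen pathway(s) and writes a manifest
listing every artifact with its SHA-256 content hash, which doubles as the
determinism check: identical config + seed give identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import blenderview, htmlview
from .cluster import DbscanParams, cluster_dbscan
from .filtering import filter_significant
from .geometry import lift_to_3d, scale_coordinates
from .io import convert_coordinates, read_gene_table, read_metadata_table, read_point_cloud, write_point_cloud
from .tsne import EmbeddingSnapshot, EmbeddingTrajectory, TsneParams, embed_tsne3d

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

logger = logging.getLogger("clusterscape")

_PATHWAYS = ("html", "blender", "both")


@dataclass
class RunConfig:
    """Fully defaulted pipeline configuration (dotted keys map to underscores)."""

    # inputs: either a gene table (embedded here) or pre-computed coordinates
    gene_table: str | None = None
    lfc_columns: list | None = None
    pval_columns: list | None = None
    coords: str | None = None
    coords_dims: int = 3
    metadata: str | None = None

    pathway: str = "both"
    seed: int = 0
    outdir: str = "clusterscape_out"
    log_level: str = "INFO"

    filter_lfc_cut: float = 1.0
    filter_p_cut: float = 0.05

    tsne_learning_rate: float = 2000.0
    tsne_perplexity: float = 30.0
    tsne_n_iter: int = 1000
    tsne_snapshot_every: int = 50
    # t-SNE units are arbitrary; embeddings the pipeline itself computes are
    # rescaled so the final snapshot spans about [-target_span, target_span],
    # the range the clustering/display defaults assume.  0 disables.
    tsne_target_span: float = 20.0

    dbscan_eps: float = 2.0
    dbscan_min_pts: int = 10

    scene_radius: float = 0.5
    scene_segments: int = 32
    scene_scale_factor: float = 1.0
    scene_title: str = "3D embedding viewer"

    blender_frames_per_iteration: int = 10
    blender_batch_size: int = 5000
    blender_group_threshold: int = 50000

    def validate(self) -> "RunConfig":
        if self.pathway not in _PATHWAYS:
            raise ValueError(f"pathway must be one of {_PATHWAYS}, got {self.pathway!r}")
        if self.gene_table is None and self.coords is None:
            raise ValueError("config needs either 'gene_table' or 'coords'")
        for label, path in (("gene_table", self.gene_table), ("coords", self.coords),
                            ("metadata", self.metadata)):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label} file not found: {path}")
        if self.gene_table is not None and not (self.lfc_columns and self.pval_columns):
            raise ValueError("gene_table input requires lfc_columns and pval_columns")
        if self.coords_dims not in (2, 3):
            raise ValueError("coords_dims must be 2 or 3")
        # constructing the parameter objects runs their own range checks
        DbscanParams(eps=self.dbscan_eps, min_pts=self.dbscan_min_pts)
        TsneParams(
            learning_rate=self.tsne_learning_rate,
            perplexity=self.tsne_perplexity,
            n_iter=self.tsne_n_iter,
            seed=self.seed,
            snapshot_every=self.tsne_snapshot_every,
        )
        if self.scene_scale_factor <= 0:
            raise ValueError("scene_scale_factor must be positive")
        if self.tsne_target_span < 0:
            raise ValueError("tsne_target_span must be non-negative (0 disables)")
        if not (self.filter_lfc_cut > 0 and self.filter_p_cut > 0):
            raise ValueError("filter cut-offs must be positive")
        return self

    def to_dotted(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            key = f.name
            for prefix in ("filter_", "tsne_", "dbscan_", "scene_", "blender_"):
                if key.startswith(prefix):
                    key = prefix[:-1] + "." + key[len(prefix):]
                    break
            out[key] = value
        return out


def validate_config(source) -> RunConfig:
    """Build a validated RunConfig from a JSON file path or a plain dict.

    Keys use the flat dotted form (``dbscan.eps``); unknown keys raise.
    """
    if isinstance(source, (str, Path)):
        data = json.loads(Path(source).read_text(encoding="utf-8"))
    else:
        data = dict(source)
    fields = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    for key, value in data.items():
        attr = key.replace(".", "_")
        if attr not in fields:
            raise KeyError(f"unknown config key: {key!r}")
        kwargs[attr] = value
    return RunConfig(**kwargs).validate()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pathway(s); returns the run manifest.

    Stages: read (and filter + embed when starting from a gene table, or
    load + lift when starting from coordinates), cluster, convert, render.
    The manifest lists every artifact path with its SHA-256 hash and is
    also written to ``outdir/run_manifest.json``.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(asctime)s %(levelname)s %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: dict = {"config": config.to_dotted(), "artifacts": artifacts, "complete": False}

    def register(path: Path) -> None:
        artifacts[str(path.relative_to(outdir))] = _sha256(path)

    try:
        if config.gene_table is not None:
            logger.info("stage: filter — reading %s", config.gene_table)
            table = read_gene_table(config.gene_table, list(config.lfc_columns),
                                    list(config.pval_columns))
            matrix = filter_significant(table, config.filter_lfc_cut, config.filter_p_cut)
            logger.info("stage: filter — %d of %d genes retained", matrix.n_genes, table.n_genes)
            logger.info("stage: embed — t-SNE, %d iterations", config.tsne_n_iter)
            trajectory = embed_tsne3d(
                matrix,
                TsneParams(
                    learning_rate=config.tsne_learning_rate,
                    perplexity=config.tsne_perplexity,
                    n_iter=config.tsne_n_iter,
                    seed=config.seed,
                    snapshot_every=config.tsne_snapshot_every,
                ),
            )
            span = float(np.abs(trajectory.final.coords).max())
            if config.tsne_target_span > 0 and span > 0:
                # one factor for every snapshot keeps the animation's motion honest
                factor = config.tsne_target_span / span
                logger.info("stage: embed — normalizing span %.1f -> %.1f",
                            span, config.tsne_target_span)
                trajectory = EmbeddingTrajectory(
                    snapshots=[
                        EmbeddingSnapshot(s.iteration, scale_coordinates(s.cloud, factor))
                        for s in trajectory.snapshots
                    ],
                    params=trajectory.params,
                )
        else:
            logger.info("stage: load coordinates — %s", config.coords)
            cloud = read_point_cloud(config.coords, dims=config.coords_dims)
            if cloud.dims == 2:
                cloud = lift_to_3d(cloud)
            trajectory = EmbeddingTrajectory(
                snapshots=[EmbeddingSnapshot(iteration=0, cloud=cloud)]
            )

        final = trajectory.final
        logger.info("stage: cluster — DBSCAN eps=%g min_pts=%d on %d points",
                    config.dbscan_eps, config.dbscan_min_pts, final.n_points)
        labels = cluster_dbscan(final, DbscanParams(config.dbscan_eps, config.dbscan_min_pts))
        logger.info("stage: cluster — %d clusters, %d noise points",
                    labels.n_clusters, labels.n_noise)

        if config.scene_scale_factor != 1.0:
            scaled_snaps = [
                EmbeddingSnapshot(s.iteration, scale_coordinates(s.cloud, config.scene_scale_factor))
                for s in trajectory.snapshots
            ]
            trajectory = EmbeddingTrajectory(snapshots=scaled_snaps, params=trajectory.params)
            final = trajectory.final

        coords_path = outdir / "embedding.csv"
        write_point_cloud(final, coords_path, labels=labels)
        register(coords_path)
        labels_path = outdir / "clusters.csv"
        labels.to_csv(labels_path)
        register(labels_path)

        metadata = read_metadata_table(config.metadata) if config.metadata else None

        if config.pathway in ("html", "both"):
            logger.info("stage: render html")
            scene_cfg = htmlview.SceneConfig(
                point_radius=config.scene_radius,
                sphere_segments=(config.scene_segments, config.scene_segments),
                title=config.scene_title,
            )
            html_cloud = convert_coordinates(final, "htmlview")
            scene = htmlview.build_scene(html_cloud, labels, metadata, scene_cfg)
            doc = htmlview.render_html(scene)
            report = htmlview.validate_html(doc)
            if not report.ok:
                raise RuntimeError(f"rendered document failed self-validation: {report.messages}")
            html_path = doc.save(outdir / "viewer.html")
            register(html_path)

        if config.pathway in ("blender", "both"):
            logger.info("stage: render blender bundle")
            blender_snaps = [
                EmbeddingSnapshot(s.iteration, convert_coordinates(s.cloud, "blenderview"))
                for s in trajectory.snapshots
            ]
            blender_traj = EmbeddingTrajectory(snapshots=blender_snaps, params=trajectory.params)
            bundle = blenderview.emit_bundle(
                blender_traj,
                labels,
                frames_per_iteration=config.blender_frames_per_iteration,
                batch_size=config.blender_batch_size,
                radius=config.scene_radius,
            )
            bundle_dir = outdir / "blender_bundle"
            bundle.save(bundle_dir)
            for member in sorted(bundle_dir.iterdir()):
                register(member)

        manifest["complete"] = True
    finally:
        manifest_path = outdir / "run_manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    logger.info("run complete — %d artifacts in %s", len(artifacts), outdir)
    return manifest
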