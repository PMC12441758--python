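"""Synthetic inputs for the full pipeline.

Everything the pipeline consumes can be generated here, seeded and in
memory: gene tables with a planted number of significant genes, 3-D
Gaussian blob clouds with known cluster labels, simulated convergence
trajectories, and a small gridded placeholder image standing in for a real
HDRI background.  Default blob geometry puts coordinates roughly in
[-20, 20], the scale of a typical t-SNE embedding, so the clustering
defaults (eps = 2, min_pts = 10) are meaningful out of the box.

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterLabels, _renumber
from .io import GeneTable, MetadataTable, PointCloud
from .tsne import EmbeddingSnapshot, EmbeddingTrajectory, TsneParams

__all__ = [
    "BlobSpec",
    "make_blobs3d",
    "make_gene_table",
    "make_trajectory",
    "make_metadata",
    "make_hdri_placeholder",
]


@dataclass
class BlobSpec:
    """Geometry of a planted 3-D blob cloud."""

    k: int = 3
    points_per_cluster: int = 200
    center_spread: float = 15.0
    cluster_sd: float = 0.5
    noise_points: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.center_spread <= self.cluster_sd:
            raise ValueError("center_spread must exceed cluster_sd for separable blobs")


def make_blobs3d(spec: BlobSpec) -> tuple[PointCloud, ClusterLabels]:
    """Draw k Gaussian blobs at uniform centers plus uniform noise points.

    Returns the cloud and the planted truth labels (noise = -1), with
    cluster numbers following the same size/min-id convention the
    clustering module uses, so partitions compare directly.
    """
    rng = np.random.default_rng(spec.seed)
    centers = rng.uniform(-spec.center_spread, spec.center_spread, size=(spec.k, 3))
    coords, labels = [], []
    for c in range(spec.k):
        coords.append(rng.normal(centers[c], spec.cluster_sd, size=(spec.points_per_cluster, 3)))
        labels.extend([c] * spec.points_per_cluster)
    if spec.noise_points:
        span = spec.center_spread * 2
        coords.append(rng.uniform(-span, span, size=(spec.noise_points, 3)))
        labels.extend([-1] * spec.noise_points)
    coords = np.vstack(coords)
    ids = np.array([f"pt{i:05d}" for i in range(len(labels))], dtype=object)
    labels = _renumber(np.asarray(labels, dtype=int), ids)
    return (
        PointCloud(ids=ids, coords=coords),
        ClusterLabels(ids=ids.copy(), labels=labels),
    )


def make_gene_table(
    n_genes: int = 1000,
    n_conditions: int = 4,
    n_significant: int = 250,
    lfc_effect: float = 3.0,
    n_modules: int = 0,
    seed: int = 0,
) -> GeneTable:
    """Gene table with exactly ``n_significant`` planted significant genes.

    Each planted gene gets |log2FC| around ``lfc_effect`` (always > 1)
    with p ~ U(0, 0.05) in at least one condition; all remaining entries
    are constructed to fail at least one of the default cut-offs
    (|log2FC| > 1, p < 0.05).

    With ``n_modules`` > 0 the significant genes are drawn from that many
    co-regulation modules: genes in one module share a sign pattern across
    conditions up to small jitter, emulating co-regulated transcriptional
    responses, so a downstream embedding condenses each module into its
    own clump.
    """
    if n_significant > n_genes:
        raise ValueError("n_significant cannot exceed n_genes")
    if lfc_effect <= 1:
        raise ValueError("lfc_effect must exceed 1, else planted genes would be filtered out")
    rng = np.random.default_rng(seed)
    gene_ids = [f"AT{g:07d}" for g in range(n_genes)]
    conditions = [f"cond_{c}" for c in range(n_conditions)]

    # background: small fold-changes or non-significant p-values everywhere
    lfc = rng.uniform(-0.9, 0.9, size=(n_genes, n_conditions))
    pval = rng.uniform(0.05, 1.0, size=(n_genes, n_conditions))
    # occasional large-but-insignificant entries keep the background honest
    loud = rng.random(size=lfc.shape) < 0.05
    lfc[loud] = rng.uniform(1.5, 4.0, size=int(loud.sum())) * rng.choice([-1, 1], size=int(loud.sum()))

    def significant_p():
        p = rng.uniform(0.0, 0.05)
        while p >= 0.05:  # guard against the closed upper edge
            p = rng.uniform(0.0, 0.05)
        return p

    significant = rng.choice(n_genes, size=n_significant, replace=False)
    if n_modules > 0:
        # sign pattern per module; every module is active in >= 1 condition
        patterns = []
        for _ in range(n_modules):
            active = rng.random(n_conditions) < 0.6
            if not active.any():
                active[rng.integers(n_conditions)] = True
            signs = rng.choice([-1.0, 1.0], size=n_conditions)
            patterns.append((active, signs))
        for rank, g in enumerate(significant):
            active, signs = patterns[rank % n_modules]
            for c in range(n_conditions):
                if active[c]:
                    lfc[g, c] = signs[c] * (lfc_effect + rng.normal(scale=0.15))
                    if abs(lfc[g, c]) <= 1.0:
                        lfc[g, c] = signs[c] * lfc_effect
                    pval[g, c] = significant_p()
    else:
        for g in significant:
            n_hits = int(rng.integers(1, n_conditions + 1))
            hit_conditions = rng.choice(n_conditions, size=n_hits, replace=False)
            for c in hit_conditions:
                lfc[g, c] = lfc_effect * rng.choice([-1, 1])
                pval[g, c] = significant_p()
    index = pd.Index(gene_ids, name="gene_id")
    return GeneTable(
        lfc=pd.DataFrame(lfc, index=index, columns=conditions),
        pval=pd.DataFrame(pval, index=index, columns=conditions),
    )


def make_trajectory(
    final: PointCloud,
    n_snapshots: int = 5,
    start_scale: float = 1e-2,
    seed: int = 0,
    snapshot_every: int = 50,
) -> EmbeddingTrajectory:
    """Simulate a convergence trajectory ending exactly at ``final``.

    Snapshot 0 is a seeded random cloud at ``start_scale``; intermediate
    snapshots interpolate linearly toward the final coordinates with
    Gaussian jitter that decays to zero, emulating how optimization
    iterations settle.  The last snapshot equals ``final`` bit-for-bit.
    """
    if n_snapshots < 2:
        raise ValueError("a trajectory needs at least 2 snapshots")
    if final.dims != 3:
        raise ValueError("final cloud must be 3D")
    rng = np.random.default_rng(seed)
    start = rng.normal(scale=start_scale, size=final.coords.shape)
    spread = float(np.abs(final.coords).max() or 1.0)
    snapshots = []
    for s in range(n_snapshots):
        t = s / (n_snapshots - 1)
        if s == n_snapshots - 1:
            coords = final.coords.copy()
        else:
            jitter_sd = 0.02 * spread * (1 - t)
            coords = (1 - t) * start + t * final.coords
            if s > 0:
                coords = coords + rng.normal(scale=jitter_sd, size=coords.shape)
        snapshots.append(
            EmbeddingSnapshot(
                iteration=s * snapshot_every,
                cloud=PointCloud(ids=final.ids.copy(), coords=coords),
            )
        )
    params = TsneParams(seed=seed, snapshot_every=snapshot_every,
                        n_iter=(n_snapshots - 1) * snapshot_every)
    return EmbeddingTrajectory(snapshots=snapshots, params=params)


def make_metadata(ids, seed: int = 0) -> MetadataTable:
    """Toy metadata: display name, two hover fields and a hyperlink per id."""
    rng = np.random.default_rng(seed)
    kinds = ["root", "shoot", "leaf", "flower"]
    table = pd.DataFrame(
        {
            "display_name": [f"Gene {i}" for i in ids],
            "tissue": rng.choice(kinds, size=len(list(ids))),
            "score": np.round(rng.uniform(0, 1, size=len(list(ids))), 3),
            "hyperlink": [f"https://example.org/gene/{i}" for i in ids],
        },
        index=pd.Index(ids, name="id"),
    )
    return MetadataTable(table=table)


def make_hdri_placeholder(path, grid_spacing: int = 32, size: tuple[int, int] = (512, 256)) -> Path:
    """Write a small synthetic equirectangular gridded image (HDRI stand-in).

    A 2:1 grid-on-grey PNG serving scene-setup tests and demos; it is a
    placeholder, not a real high-dynamic-range radiance file.
    """
    from PIL import Image

    if grid_spacing < 2:
        raise ValueError("grid_spacing must be at least 2 pixels")
    width, height = size
    if width != 2 * height:
        raise ValueError("equirectangular images need a 2:1 aspect ratio")
    pixels = np.full((height, width, 3), 90, dtype=np.uint8)
    pixels[::grid_spacing, :, :] = 200
    pixels[:, ::grid_spacing, :] = 200
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(pixels).save(path)
    return path
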