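"""Blender script bundle generation for animated 3-D embeddings.

Nothing here runs Blender.  The module emits plain-text Python scripts for
Blender's scripting window (4.1-era ``bpy`` interfaces) that

* generate one UV-sphere object per point at its embedding coordinates,
  batched to keep single script runs tractable, with one material per
  cluster;
* set the first (frame 0) location keyframes, then one further script per
  captured optimization snapshot so the embedding's convergence can be
  animated;
* optionally delete keyframes in a frame range for selected points; and
* set up the scene: a gridded HDRI world background, a camera (optionally
  orbiting), render resolution and the frame range covering the last
  keyframe.

Every keyframe-bearing script carries its data as one literal list, so the
bundle's portable :class:`KeyframeTable` can be reproduced exactly by
statically replaying the scripts — used for validation without ever
executing Blender.
"""

from __future__ import annotations

import ast
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import NOISE, ClusterLabels
from .io import PointCloud
from .tsne import EmbeddingTrajectory

__all__ = [
    "BatchPlan",
    "KeyframeTable",
    "BlenderSceneConfig",
    "BlenderScriptBundle",
    "plan_batches",
    "object_name_for",
    "emit_generation_script",
    "emit_keyframe_scripts",
    "emit_deletion_script",
    "emit_scene_setup",
    "emit_bundle",
    "validate_script",
    "replay_keyframe_scripts",
    "simulate_deletion",
]

BATCH_SIZE_DEFAULT = 5000
GROUP_THRESHOLD_DEFAULT = 50000


@dataclass
class BatchPlan:
    """Contiguous batches covering points 0..n-1."""

    batches: list[tuple[int, int]]  # (start index, count)
    batch_size: int = BATCH_SIZE_DEFAULT
    group_as_single_object: bool = False

    @property
    def n_points(self) -> int:
        return sum(count for _, count in self.batches)

    @property
    def sizes(self) -> list[int]:
        return [count for _, count in self.batches]


def plan_batches(
    n_points: int,
    batch_size: int = BATCH_SIZE_DEFAULT,
    group_threshold: int = GROUP_THRESHOLD_DEFAULT,
) -> BatchPlan:
    """Split ``n_points`` into ceil(n/batch_size) contiguous batches.

    Above ``group_threshold`` points the plan requests joining each batch
    into a single object to reduce scene-management strain, at the cost of
    per-point animation.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be at least 1")
    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    batches = [
        (start, min(batch_size, n_points - start))
        for start in range(0, n_points, batch_size)
    ]
    return BatchPlan(
        batches=batches,
        batch_size=batch_size,
        group_as_single_object=n_points > group_threshold,
    )


@dataclass
class KeyframeTable:
    """Portable (id, frame, x, y, z) rows; one row per point per snapshot."""

    rows: pd.DataFrame
    frames_per_iteration: int = 10

    def __post_init__(self) -> None:
        expected = ["id", "frame", "x", "y", "z"]
        if list(self.rows.columns) != expected:
            raise ValueError(f"keyframe table columns must be {expected}")
        if len(self.rows) and (self.rows["frame"] < 0).any():
            raise ValueError("frame numbers must be non-negative")
        if len(self.rows):
            grouped = self.rows.groupby("id", sort=False)["frame"]
            if not (grouped.apply(lambda s: s.is_monotonic_increasing and s.is_unique)).all():
                raise ValueError("frames must be strictly increasing per id")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def max_frame(self) -> int:
        return int(self.rows["frame"].max()) if len(self.rows) else 0

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")

    @classmethod
    def from_csv(cls, path, frames_per_iteration: int = 10) -> "KeyframeTable":
        rows = pd.read_csv(
            path, dtype={"id": str, "frame": int, "x": float, "y": float, "z": float},
            encoding="utf-8",
        )
        return cls(rows=rows, frames_per_iteration=frames_per_iteration)

    def equals(self, other: "KeyframeTable") -> bool:
        if len(self.rows) != len(other.rows):
            return False
        a = self.rows.reset_index(drop=True)
        b = other.rows.reset_index(drop=True)
        return bool(
            (a["id"] == b["id"]).all()
            and (a["frame"] == b["frame"]).all()
            and np.array_equal(a[["x", "y", "z"]].to_numpy(), b[["x", "y", "z"]].to_numpy())
        )


_NAME_SANITIZER = re.compile(r"[^A-Za-z0-9_.\-]")


def object_name_for(point_id: str) -> str:
    """Deterministic Blender object name for a point id (``pt_`` + sanitized id)."""
    return "pt_" + _NAME_SANITIZER.sub("_", str(point_id))


def _object_names(ids) -> dict:
    names = {}
    seen = {}
    for point_id in ids:
        name = object_name_for(point_id)
        if name in seen:
            raise ValueError(
                f"object-name collision after sanitization: ids {seen[name]!r} and "
                f"{point_id!r} both map to {name!r}"
            )
        seen[name] = point_id
        names[point_id] = name
    return names


def _hex_to_rgba(color: str) -> tuple[float, float, float, float]:
    color = color.lstrip("#")
    r, g, b = (int(color[i : i + 2], 16) / 255.0 for i in (0, 2, 4))
    return (round(r, 6), round(g, 6), round(b, 6), 1.0)


def _fmt_loc(xyz) -> str:
    return f"({float(xyz[0])!r}, {float(xyz[1])!r}, {float(xyz[2])!r})"


def emit_generation_script(
    cloud: PointCloud,
    labels: ClusterLabels,
    plan: BatchPlan | None = None,
    radius: float = 0.5,
    segments: tuple[int, int] = (32, 32),
    palette: tuple[str, ...] | None = None,
) -> str:
    """Emit the object-generation script: one sphere per point, one material per cluster.

    The cloud must already be in the Blender axis convention.  Under a
    grouping plan each batch is joined into a single object (per-point
    animation is then unavailable; the script says so).
    """
    from .htmlview import DEFAULT_PALETTE, SceneConfig, assign_palette

    if cloud.dims != 3:
        raise ValueError("emit_generation_script expects 3D coordinates")
    plan = plan or plan_batches(cloud.n_points)
    if plan.n_points != cloud.n_points:
        raise ValueError("batch plan does not cover the cloud")
    names = _object_names(cloud.ids)
    config = SceneConfig(palette=tuple(palette) if palette else DEFAULT_PALETTE)
    label_map = labels.to_dict()
    colors = assign_palette(labels, config)

    def material_name(label: int) -> str:
        return "noise" if label == NOISE else f"cluster_{label}"

    lines = [
        "# Object generation script — run in Blender's scripting window.",
        "# Generated by clusterscape; one UV sphere per data point.",
        "import bpy",
        "",
    ]
    distinct = sorted({int(label_map[i]) for i in cloud.ids})
    for label in distinct:
        mat = material_name(label)
        sample = next(i for i in cloud.ids if label_map[i] == label)
        rgba = _hex_to_rgba(colors[sample])
        lines.append(f'_mat_{mat} = bpy.data.materials.new(name="{mat}")')
        lines.append(f"_mat_{mat}.diffuse_color = {rgba}")
    lines.append("")
    if plan.group_as_single_object:
        lines.append("# NOTE: grouping mode joins each batch into a single object to reduce")
        lines.append("# computational strain on very large clouds; per-point animation is")
        lines.append("# not possible on joined batches.")
        lines.append("")
    seg_w, seg_h = segments
    for b, (start, count) in enumerate(plan.batches):
        lines.append(f"# --- batch {b + 1} of {len(plan.batches)}: points {start}-{start + count - 1} ---")
        batch_names = []
        for i in range(start, start + count):
            point_id = cloud.ids[i]
            name = names[point_id]
            batch_names.append(name)
            mat = material_name(int(label_map[point_id]))
            lines.append(
                f"bpy.ops.mesh.primitive_uv_sphere_add(radius={float(radius)!r}, "
                f"segments={seg_w}, ring_count={seg_h}, location={_fmt_loc(cloud.coords[i])})"
            )
            lines.append("_obj = bpy.context.active_object")
            lines.append(f'_obj.name = "{name}"')
            lines.append(f"_obj.data.materials.append(_mat_{mat})")
        if plan.group_as_single_object:
            lines.append("bpy.ops.object.select_all(action='DESELECT')")
            lines.append(f"for _n in {batch_names!r}:")
            lines.append("    bpy.data.objects[_n].select_set(True)")
            lines.append(f'bpy.context.view_layer.objects.active = bpy.data.objects["{batch_names[0]}"]')
            lines.append("bpy.ops.object.join()")
            lines.append(f'bpy.context.active_object.name = "points_batch_{b}"')
        lines.append("")
    return "\n".join(lines)


def _keyframe_script(ids, names, coords, frame: int, header: str) -> str:
    entries = ",\n".join(
        f'    ("{names[point_id]}", {frame}, {_fmt_loc(coords[i])})'
        for i, point_id in enumerate(ids)
    )
    return (
        f"# {header}\n"
        "import bpy\n"
        "\n"
        "_keyframes = [\n"
        f"{entries},\n"
        "]\n"
        "for _name, _frame, _loc in _keyframes:\n"
        "    _obj = bpy.data.objects[_name]\n"
        "    _obj.location = _loc\n"
        '    _obj.keyframe_insert(data_path="location", frame=_frame)\n'
    )


def emit_keyframe_scripts(
    trajectory: EmbeddingTrajectory,
    frames_per_iteration: int = 10,
    expected_ids=None,
) -> tuple[list[str], KeyframeTable]:
    """Emit one keyframe script per snapshot plus the portable keyframe table.

    Snapshot ``s`` (0-based) lands on frame ``s * frames_per_iteration``;
    the first script anchors the generation coordinates at frame 0.
    """
    if frames_per_iteration < 1:
        raise ValueError("frames_per_iteration must be a positive integer")
    if trajectory.n_snapshots < 1:
        raise ValueError("trajectory must contain at least one snapshot")
    ids = list(trajectory.ids)
    if expected_ids is not None:
        offenders = sorted(set(map(str, ids)) ^ set(map(str, expected_ids)))
        if offenders:
            raise ValueError(f"trajectory ids do not match generated objects: {offenders}")
    names = _object_names(ids)
    scripts = []
    rows = []
    for s, snap in enumerate(trajectory.snapshots):
        frame = s * frames_per_iteration
        header = (
            "First keyframes: anchor generation coordinates at frame 0."
            if s == 0
            else f"Keyframes for snapshot {s} (iteration {snap.iteration}) at frame {frame}."
        )
        scripts.append(_keyframe_script(ids, names, snap.cloud.coords, frame, header))
        for i, point_id in enumerate(ids):
            x, y, z = snap.cloud.coords[i]
            rows.append((str(point_id), frame, float(x), float(y), float(z)))
    table = KeyframeTable(
        rows=pd.DataFrame(rows, columns=["id", "frame", "x", "y", "z"]),
        frames_per_iteration=frames_per_iteration,
    )
    return scripts, table


def emit_deletion_script(ids, frame_range: tuple[int, int]) -> str:
    """Emit a script deleting location keyframes for ``ids`` within a closed frame range.

    An empty id list is refused: keyframe deletion is expensive and a
    silent scene-wide wipe would be easy to trigger by accident.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("refusing to emit a deletion script for an empty id list")
    first, last = frame_range
    if first > last:
        raise ValueError("frame_range must satisfy first <= last")
    names = [object_name_for(i) for i in ids]
    entries = ",\n".join(f'    "{n}"' for n in names)
    return (
        "# Keyframe deletion script — run in Blender's scripting window.\n"
        "# WARNING: deleting keyframes is slower than creating them and can\n"
        "# stall or crash Blender when many points are affected; prefer\n"
        "# deleting in small batches.\n"
        "import bpy\n"
        "\n"
        f"_first, _last = {int(first)}, {int(last)}\n"
        "_targets = [\n"
        f"{entries},\n"
        "]\n"
        "for _name in _targets:\n"
        "    _obj = bpy.data.objects.get(_name)\n"
        "    if _obj is None or _obj.animation_data is None or _obj.animation_data.action is None:\n"
        "        continue\n"
        "    for _fc in _obj.animation_data.action.fcurves:\n"
        '        if _fc.data_path != "location":\n'
        "            continue\n"
        "        for _kp in list(_fc.keyframe_points):\n"
        "            if _first <= _kp.co.x <= _last:\n"
        "                _fc.keyframe_points.remove(_kp)\n"
    )


@dataclass
class BlenderSceneConfig:
    """Scene-setup options: world HDRI, camera, resolution and frame range."""

    hdri_path: str = "gridded_background.png"
    camera_distance: float = 60.0
    camera_orbit: bool = False
    resolution: tuple[int, int] = (1920, 1080)
    frame_start: int = 0
    frame_end: int = 0

    def __post_init__(self) -> None:
        if self.camera_distance <= 0:
            raise ValueError("camera_distance must be positive")
        if self.frame_end < self.frame_start:
            raise ValueError("frame_end must be >= frame_start")


def emit_scene_setup(config: BlenderSceneConfig | None = None) -> str:
    """Emit the scene-setup script: HDRI world, camera, resolution, frame range."""
    config = config or BlenderSceneConfig()
    d = config.camera_distance
    lines = [
        "# Scene setup script — run once before rendering.",
        "import bpy",
        "import math",
        "",
        "scene = bpy.context.scene",
        f"scene.render.resolution_x = {config.resolution[0]}",
        f"scene.render.resolution_y = {config.resolution[1]}",
        f"scene.frame_start = {config.frame_start}",
        f"scene.frame_end = {config.frame_end}",
        "",
        "# Gridded HDRI world background (single environment texture).",
        'world = bpy.data.worlds.get("World") or bpy.data.worlds.new("World")',
        "scene.world = world",
        "world.use_nodes = True",
        '_bg = world.node_tree.nodes["Background"]',
        '_env = world.node_tree.nodes.new("ShaderNodeTexEnvironment")',
        f'_env.image = bpy.data.images.load(r"{config.hdri_path}")',
        'world.node_tree.links.new(_env.outputs["Color"], _bg.inputs["Color"])',
        "",
        '_cam_data = bpy.data.cameras.new("ViewCamera")',
        '_cam = bpy.data.objects.new("ViewCamera", _cam_data)',
        "bpy.context.collection.objects.link(_cam)",
        "scene.camera = _cam",
        f"_cam.location = ({d!r}, {(-d)!r}, {d / 2!r})",
        '_track = _cam.constraints.new(type="TRACK_TO")',
        '_empty = bpy.data.objects.new("CameraTarget", None)',
        "bpy.context.collection.objects.link(_empty)",
        "_empty.location = (0.0, 0.0, 0.0)",
        "_track.target = _empty",
    ]
    if config.camera_orbit:
        lines += [
            "",
            "# Camera orbit: quarter turn around the z axis over the frame range.",
            f'_cam.keyframe_insert(data_path="location", frame={config.frame_start})',
            f"_cam.location = ({-d!r}, {(-d)!r}, {d / 2!r})",
            f'_cam.keyframe_insert(data_path="location", frame={config.frame_end})',
        ]
    lines.append("")
    return "\n".join(lines)


@dataclass
class BlenderScriptBundle:
    """Emitted script texts plus the portable keyframe table."""

    generation_script: str
    first_keyframe_script: str
    iteration_keyframe_scripts: list[str]
    scene_setup_script: str
    keyframe_table: KeyframeTable
    deletion_script: str | None = None

    @property
    def all_scripts(self) -> list[str]:
        scripts = [
            self.generation_script,
            self.first_keyframe_script,
            *self.iteration_keyframe_scripts,
            self.scene_setup_script,
        ]
        if self.deletion_script is not None:
            scripts.append(self.deletion_script)
        return scripts

    def save(self, outdir) -> Path:
        """Write every bundle member plus a manifest JSON; returns the manifest path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        members = {
            "01_generate_points.py": self.generation_script,
            "02_first_keyframes.py": self.first_keyframe_script,
        }
        for i, script in enumerate(self.iteration_keyframe_scripts, start=1):
            members[f"03_keyframes_snapshot_{i:03d}.py"] = script
        members["04_scene_setup.py"] = self.scene_setup_script
        if self.deletion_script is not None:
            members["05_delete_keyframes.py"] = self.deletion_script
        for name, text in members.items():
            (outdir / name).write_text(text, encoding="utf-8")
        self.keyframe_table.to_csv(outdir / "keyframes.csv")
        manifest = {
            "scripts": sorted(members),
            "keyframe_table": "keyframes.csv",
            "frames_per_iteration": self.keyframe_table.frames_per_iteration,
            "n_keyframe_rows": self.keyframe_table.n_rows,
            "max_frame": self.keyframe_table.max_frame,
        }
        path = outdir / "bundle_manifest.json"
        path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
        return path


def emit_bundle(
    trajectory: EmbeddingTrajectory,
    labels: ClusterLabels,
    frames_per_iteration: int = 10,
    batch_size: int = BATCH_SIZE_DEFAULT,
    radius: float = 0.5,
    scene_config: BlenderSceneConfig | None = None,
    palette: tuple[str, ...] | None = None,
) -> BlenderScriptBundle:
    """Build the full script bundle for a trajectory (Blender axis convention)."""
    cloud = trajectory.snapshots[0].cloud
    plan = plan_batches(cloud.n_points, batch_size=batch_size)
    generation = emit_generation_script(cloud, labels, plan, radius=radius, palette=palette)
    scripts, table = emit_keyframe_scripts(trajectory, frames_per_iteration)
    if scene_config is None:
        scene_config = BlenderSceneConfig(frame_end=table.max_frame)
    setup = emit_scene_setup(scene_config)
    return BlenderScriptBundle(
        generation_script=generation,
        first_keyframe_script=scripts[0],
        iteration_keyframe_scripts=scripts[1:],
        scene_setup_script=setup,
        keyframe_table=table,
    )


def validate_script(text: str) -> None:
    """Static syntax check (the scripting-window dialect is Python); raises on failure."""
    ast.parse(text)


def _literal_assignment(tree: ast.Module, name: str):
    for node in tree.body:
        if (
            isinstance(node, ast.Assign)
            and len(node.targets) == 1
            and isinstance(node.targets[0], ast.Name)
            and node.targets[0].id == name
        ):
            return ast.literal_eval(node.value)
    raise ValueError(f"script carries no literal {name!r} assignment")


def replay_keyframe_scripts(scripts, ids) -> KeyframeTable:
    """Statically replay keyframe scripts against an empty table.

    Extracts each script's literal keyframe list (no execution), maps
    object names back to the supplied ids, and rebuilds the KeyframeTable
    the emitter would have produced.
    """
    name_to_id = {object_name_for(i): str(i) for i in ids}
    rows = []
    for script in scripts:
        validate_script(script)
        for name, frame, loc in _literal_assignment(ast.parse(script), "_keyframes"):
            if name not in name_to_id:
                raise ValueError(f"script references unknown object {name!r}")
            rows.append((name_to_id[name], int(frame), *map(float, loc)))
    return KeyframeTable(rows=pd.DataFrame(rows, columns=["id", "frame", "x", "y", "z"]))


def simulate_deletion(script: str, table: KeyframeTable, ids) -> KeyframeTable:
    """Apply a deletion script's effect to a KeyframeTable without running Blender."""
    validate_script(script)
    tree = ast.parse(script)
    targets = set(_literal_assignment(tree, "_targets"))
    bounds = None
    for node in tree.body:
        if isinstance(node, ast.Assign) and isinstance(node.targets[0], ast.Tuple):
            names = [t.id for t in node.targets[0].elts if isinstance(t, ast.Name)]
            if names == ["_first", "_last"]:
                bounds = ast.literal_eval(node.value)
    if bounds is None:
        raise ValueError("deletion script carries no _first/_last bounds")
    first, last = bounds
    id_to_name = {str(i): object_name_for(i) for i in ids}
    names = table.rows["id"].map(id_to_name)
    drop = names.isin(targets) & table.rows["frame"].between(first, last)
    return KeyframeTable(
        rows=table.rows[~drop].reset_index(drop=True),
        frames_per_iteration=table.frames_per_iteration,
    )
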