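"""Standalone interactive HTML 3-D scatter viewer.

One self-contained HTML5 document per dataset: the point records are
embedded as a single JSON block, rendering and mouse-orbit interaction
come from exactly two pinned jsDelivr-hosted scripts (three.js and the
standalone OrbitControls build), and everything else is inline.  Hovering
a sphere shows its metadata; clicking follows its hyperlink if one was
provided.

Level-of-detail is controlled by the sphere segment counts (the last two
arguments of the ``sphereGeometry`` constructor); halving them from the
(32, 32) default to (16, 16) is visually near-lossless while markedly
reducing vertex load on large clouds.
"""

from __future__ import annotations

import json
import re
import shutil
from dataclasses import dataclass, field
from html.parser import HTMLParser
from importlib import resources
from pathlib import Path

import jinja2

from .cluster import NOISE, ClusterLabels
from .io import MetadataTable, PointCloud

__all__ = [
    "CDN_MANIFEST",
    "DEFAULT_PALETTE",
    "SceneConfig",
    "SceneSpec",
    "HtmlDocument",
    "assign_palette",
    "build_scene",
    "render_html",
    "validate_html",
    "ValidationReport",
]

# Pinned CDN dependencies: the WebGL renderer and the matching standalone
# orbit-controls build.  Pinned versions keep archived documents rendering
# identically years later.
CDN_MANIFEST: tuple[tuple[str, str], ...] = (
    ("three.min.js", "https://cdn.jsdelivr.net/npm/three@0.110.0/build/three.min.js"),
    (
        "OrbitControls.js",
        "https://cdn.jsdelivr.net/npm/three-orbitcontrols@2.110.3/OrbitControls.js",
    ),
)

# 17 visually distinct colors: enough for the largest cluster count the
# package's reference analyses produced; longer label sets recycle.
DEFAULT_PALETTE: tuple[str, ...] = (
    "#e6194b", "#3cb44b", "#ffe119", "#4363d8", "#f58231", "#911eb4",
    "#46f0f0", "#f032e6", "#bcf60c", "#fabebe", "#008080", "#e6beff",
    "#9a6324", "#fffac8", "#800000", "#aaffc3", "#808000",
)

_HEX = re.compile(r"^#[0-9a-fA-F]{6}$")


@dataclass
class SceneConfig:
    """Rendering options shared by every point in a scene."""

    point_radius: float = 0.5
    sphere_segments: tuple[int, int] = (32, 32)
    palette: tuple[str, ...] = DEFAULT_PALETTE
    noise_color: str = "#888888"
    background: str = "#0b0b14"
    camera_distance: float = 60.0
    cull_offscreen: bool = False
    opacity: float = 1.0
    title: str = "3D embedding viewer"

    def __post_init__(self) -> None:
        w, h = self.sphere_segments
        if w < 3 or h < 2:
            raise ValueError("sphere_segments must be at least (3, 2)")
        if not self.palette:
            raise ValueError("palette must be non-empty")
        for color in (*self.palette, self.noise_color, self.background):
            if not _HEX.match(color):
                raise ValueError(f"invalid 6-digit hex color: {color!r}")
        if not (0.0 < self.opacity <= 1.0):
            raise ValueError("opacity must lie in (0, 1]")
        if self.point_radius <= 0:
            raise ValueError("point_radius must be positive")


@dataclass
class SceneSpec:
    """Renderer-agnostic scene: one record per point plus shared config."""

    records: list[dict]
    config: SceneConfig
    manifest: tuple[tuple[str, str], ...] = CDN_MANIFEST

    @property
    def n_points(self) -> int:
        return len(self.records)


@dataclass
class HtmlDocument:
    text: str
    manifest: tuple[tuple[str, str], ...]
    point_count: int

    def save(self, path, asset_dir=None) -> Path:
        """Write the document; with ``asset_dir``, copy local script files beside it."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.text, encoding="utf-8")
        if asset_dir is not None:
            for name, url in self.manifest:
                if not url.startswith(("http://", "https://")):
                    src = Path(asset_dir) / name
                    if src.exists():
                        shutil.copy(src, path.parent / name)
        return path


def assign_palette(labels: ClusterLabels, config: SceneConfig) -> dict:
    """Map each id to its cluster color: palette[label mod len(palette)], noise_color for -1."""
    colors = {}
    for point_id, label in zip(labels.ids, labels.labels):
        if label == NOISE:
            colors[point_id] = config.noise_color
        else:
            colors[point_id] = config.palette[label % len(config.palette)]
    return colors


def build_scene(
    cloud: PointCloud,
    labels: ClusterLabels,
    metadata: MetadataTable | None = None,
    config: SceneConfig | None = None,
) -> SceneSpec:
    """Join coordinates, cluster colors and optional metadata into a SceneSpec.

    The cloud must already be in the viewer's axis convention
    (``convert_coordinates(..., "htmlview")``).  Points without metadata
    fall back to their id as the hover name.
    """
    config = config or SceneConfig()
    if cloud.dims != 3:
        raise ValueError("build_scene expects 3D coordinates")
    label_map = labels.to_dict()
    missing = [i for i in cloud.ids if i not in label_map]
    if missing:
        raise ValueError(f"labels missing ids: {missing}")
    colors = assign_palette(labels, config)
    records = []
    for point_id, xyz in zip(cloud.ids, cloud.coords):
        meta = metadata.get(point_id) if metadata is not None else None
        records.append(
            {
                "id": str(point_id),
                "position": [float(xyz[0]), float(xyz[1]), float(xyz[2])],
                "cluster": int(label_map[point_id]),
                "color": colors[point_id],
                "radius": config.point_radius,
                "display_name": meta["display_name"] if meta else str(point_id),
                "hover_fields": [list(f) for f in meta["hover_fields"]] if meta else [],
                "hyperlink": meta["hyperlink"] if meta else None,
            }
        )
    return SceneSpec(records=records, config=config)


_TEMPLATES = {"viewer": "viewer.html.j2"}


def _environment() -> jinja2.Environment:
    return jinja2.Environment(
        loader=jinja2.FunctionLoader(
            lambda name: resources.files("clusterscape.templates").joinpath(name).read_text("utf-8")
        ),
        undefined=jinja2.StrictUndefined,
        keep_trailing_newline=True,
        autoescape=False,
    )


def render_html(scene: SceneSpec, template: str = "viewer", offline: bool = False) -> HtmlDocument:
    """Render a SceneSpec to a complete HTML5 document (a pure function).

    ``offline`` rewrites the two script references to local filenames next
    to the document instead of the pinned CDN URLs, for archival use with
    pre-downloaded copies.
    """
    if template not in _TEMPLATES:
        raise ValueError(
            f"unknown template {template!r}; available: {sorted(_TEMPLATES)}"
        )
    manifest = tuple(
        (name, f"./{name}" if offline else url) for name, url in CDN_MANIFEST
    )
    cfg = scene.config
    text = _environment().get_template(_TEMPLATES[template]).render(
        title=cfg.title,
        background=cfg.background,
        camera_distance=repr(float(cfg.camera_distance)),
        seg_w=cfg.sphere_segments[0],
        seg_h=cfg.sphere_segments[1],
        opacity=repr(float(cfg.opacity)),
        cull=cfg.cull_offscreen,
        scripts=[url for _, url in manifest],
        data_json=json.dumps(scene.records, separators=(",", ":"), ensure_ascii=False),
        point_count=scene.n_points,
    )
    return HtmlDocument(text=text, manifest=manifest, point_count=scene.n_points)


class _TagChecker(HTMLParser):
    VOID = {
        "area", "base", "br", "col", "embed", "hr", "img", "input",
        "link", "meta", "param", "source", "track", "wbr",
    }

    def __init__(self):
        super().__init__(convert_charrefs=True)
        self.stack: list[str] = []
        self.errors: list[str] = []
        self.saw_doctype = False
        self.script_srcs: list[str] = []
        self.json_blocks: list[str] = []
        self._in_json = False

    def handle_decl(self, decl):
        if decl.lower().startswith("doctype html"):
            self.saw_doctype = True

    def handle_starttag(self, tag, attrs):
        attrs = dict(attrs)
        if tag == "script":
            if "src" in attrs:
                self.script_srcs.append(attrs["src"])
            self._in_json = attrs.get("type") == "application/json"
            if self._in_json:
                self.json_blocks.append("")
        if tag not in self.VOID:
            self.stack.append(tag)

    def handle_data(self, data):
        if self._in_json and self.json_blocks:
            self.json_blocks[-1] += data

    def handle_endtag(self, tag):
        if tag == "script":
            self._in_json = False
        if tag in self.VOID:
            return
        if not self.stack:
            self.errors.append(f"unexpected closing tag </{tag}>")
        elif self.stack[-1] != tag:
            self.errors.append(f"mismatched tag: expected </{self.stack[-1]}>, got </{tag}>")
            self.stack.pop()
        else:
            self.stack.pop()


@dataclass
class ValidationReport:
    checks: dict = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(self.checks.values())


def validate_html(doc: HtmlDocument) -> ValidationReport:
    """Structural self-check of a rendered document.

    Verifies well-formed markup, that the embedded JSON record count
    matches ``point_count``, that each manifest script reference appears
    exactly once, and that no template placeholder survived rendering.
    """
    report = ValidationReport()
    parser = _TagChecker()
    parser.feed(doc.text)
    parser.close()
    if parser.stack:
        parser.errors.append(f"unclosed tags: {parser.stack}")
    report.checks["well_formed"] = parser.saw_doctype and not parser.errors
    report.messages.extend(parser.errors)

    n_records = None
    for block in parser.json_blocks:
        try:
            payload = json.loads(block)
        except json.JSONDecodeError:
            continue
        if isinstance(payload, list):
            n_records = len(payload)
            break
    report.checks["record_count"] = n_records == doc.point_count
    if n_records != doc.point_count:
        report.messages.append(
            f"embedded record count {n_records} != declared point_count {doc.point_count}"
        )

    for name, url in doc.manifest:
        count = parser.script_srcs.count(url)
        report.checks[f"dependency:{name}"] = count == 1
        if count != 1:
            report.messages.append(f"dependency {name} referenced {count} times (expected 1)")

    unresolved = "{{" in doc.text or "{%" in doc.text
    report.checks["no_unresolved_placeholders"] = not unresolved
    if unresolved:
        report.messages.append("unresolved template placeholders present")
    return report
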