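"""HTML viewer: palette, scene assembly, rendering, self-validation."""

import json

import numpy as np
import pytest
from lxml import html as lxml_html

from clusterscape import PointCloud, convert_coordinates
from clusterscape.cluster import ClusterLabels
from clusterscape.htmlview import (
    CDN_MANIFEST,
    SceneConfig,
    assign_palette,
    build_scene,
    render_html,
    validate_html,
)
from clusterscape.synthetic import BlobSpec, make_blobs3d, make_metadata


def _labels(ids, values):
    return ClusterLabels(ids=np.asarray(ids, dtype=object), labels=np.asarray(values))


def _scene(n=50, seed=0, config=None, with_metadata=False):
    cloud, truth = make_blobs3d(BlobSpec(k=3, points_per_cluster=n // 3 + 1, seed=seed))
    cloud = PointCloud(ids=cloud.ids[:n], coords=cloud.coords[:n])
    labels = _labels(cloud.ids, truth.labels[:n] % 3)
    meta = make_metadata(list(cloud.ids), seed=seed) if with_metadata else None
    return build_scene(convert_coordinates(cloud, "htmlview"), labels, meta,
                       config or SceneConfig())


def extract_records(doc_text):
    """Independent extraction oracle: lxml parse, not the package's parser."""
    tree = lxml_html.fromstring(doc_text)
    blocks = tree.xpath('//script[@type="application/json"]')
    assert len(blocks) == 1
    return json.loads(blocks[0].text), tree


class TestSceneConfig:
    def test_defaults(self):
        config = SceneConfig()
        assert config.sphere_segments == (32, 32)
        assert len(config.palette) == 17

    @pytest.mark.parametrize("kwargs", [
        {"sphere_segments": (2, 2)},
        {"palette": ()},
        {"noise_color": "red"},
        {"opacity": 0.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SceneConfig(**kwargs)


class TestAssignPalette:
    def test_all_noise_gets_noise_color(self):
        config = SceneConfig()
        labels = _labels(["a", "b"], [-1, -1])
        colors = assign_palette(labels, config)
        assert set(colors.values()) == {config.noise_color}

    def test_17_clusters_17_colors_bijective(self):
        config = SceneConfig()
        ids = [f"p{i}" for i in range(17)]
        colors = assign_palette(_labels(ids, list(range(17))), config)
        assert len(set(colors.values())) == 17
        assert set(colors.values()) == set(config.palette)

    def test_colors_recycle_with_palette_period(self):
        config = SceneConfig(palette=("#ff0000", "#00ff00", "#0000ff"))
        ids = [f"p{i}" for i in range(9)]
        colors = assign_palette(_labels(ids, list(range(9))), config)
        for i in range(9):
            assert colors[f"p{i}"] == config.palette[i % 3]


class TestBuildScene:
    def test_single_point_without_metadata_hover_is_id(self):
        cloud = PointCloud(ids=np.array(["g1"], dtype=object), coords=[[0.0, 0.0, 0.0]])
        scene = build_scene(cloud, _labels(["g1"], [0]))
        rec = scene.records[0]
        assert rec["display_name"] == "g1"
        assert rec["hover_fields"] == []
        assert rec["hyperlink"] is None

    def test_hyperlink_carried_verbatim(self):
        scene = _scene(n=10, with_metadata=True)
        assert scene.records[0]["hyperlink"].startswith("https://example.org/gene/")

    def test_missing_labels_error_lists_ids(self):
        cloud = PointCloud(ids=np.array(["g1", "g2"], dtype=object),
                           coords=np.zeros((2, 3)) + [[0, 0, 0], [5, 5, 5]])
        with pytest.raises(ValueError, match="g2"):
            build_scene(cloud, _labels(["g1"], [0]))

    def test_coordinates_passed_through_unmodified(self):
        scene = _scene(n=20)
        cloud, truth = make_blobs3d(BlobSpec(k=3, points_per_cluster=20 // 3 + 1, seed=0))
        converted = convert_coordinates(
            PointCloud(ids=cloud.ids[:20], coords=cloud.coords[:20]), "htmlview")
        got = np.array([r["position"] for r in scene.records])
        assert np.array_equal(got, converted.coords)

    def test_large_fixture_one_record_per_point(self):
        # stand-in for a 12,198-cell single-cell embedding
        rng = np.random.default_rng(3)
        n = 12_198
        cloud = PointCloud(ids=np.array([f"cell{i}" for i in range(n)], dtype=object),
                           coords=rng.normal(scale=20, size=(n, 3)))
        scene = build_scene(cloud, _labels(cloud.ids, rng.integers(0, 17, size=n)))
        assert scene.n_points == n
        assert len({r["id"] for r in scene.records}) == n


class TestRenderHtml:
    def test_empty_scene_is_valid_with_both_scripts(self):
        from clusterscape.htmlview import SceneSpec

        doc = render_html(SceneSpec(records=[], config=SceneConfig()))
        report = validate_html(doc)
        assert report.ok, report.messages
        records, tree = extract_records(doc.text)
        assert records == []
        srcs = tree.xpath("//script/@src")
        assert srcs == [url for _, url in CDN_MANIFEST]

    def test_render_is_pure(self):
        assert render_html(_scene(n=30)).text == render_html(_scene(n=30)).text

    def test_unknown_template_lists_available(self):
        with pytest.raises(ValueError, match="viewer"):
            render_html(_scene(n=5), template="nope")

    def test_embedded_json_round_trips_scene_records(self):
        scene = _scene(n=60, with_metadata=True)
        doc = render_html(scene)
        records, _ = extract_records(doc.text)
        assert records == json.loads(json.dumps(scene.records))

    def test_segment_switch_changes_only_the_two_numerals(self):
        scene32 = _scene(n=40)
        scene16 = _scene(n=40, config=SceneConfig(sphere_segments=(16, 16)))
        doc32 = render_html(scene32).text
        doc16 = render_html(scene16).text
        assert doc32 != doc16
        assert doc32.replace("SphereGeometry(1.0, 32, 32)",
                             "SphereGeometry(1.0, 16, 16)") == doc16

    def test_ids_appear_exactly_once_none_invented(self):
        scene = _scene(n=45)
        records, _ = extract_records(render_html(scene).text)
        assert [r["id"] for r in records] == [r["id"] for r in scene.records]

    def test_culling_toggle_leaves_embedded_data_unchanged(self):
        plain = render_html(_scene(n=25))
        culled = render_html(_scene(n=25, config=SceneConfig(cull_offscreen=True)))
        assert extract_records(plain.text)[0] == extract_records(culled.text)[0]
        assert "frustum" in culled.text.lower()
        assert "frustum" not in plain.text.lower()

    def test_document_size_grows_linearly(self):
        sizes = {n: len(render_html(_scene(n=n)).text) for n in (100, 200, 400)}
        growth_1 = sizes[200] - sizes[100]
        growth_2 = sizes[400] - sizes[200]
        assert growth_2 < 2.5 * growth_1  # no per-point template duplication

    def test_offline_mode_rewrites_script_sources(self, tmp_path):
        doc = render_html(_scene(n=5), offline=True)
        _, tree = extract_records(doc.text)
        assert tree.xpath("//script/@src") == ["./three.min.js", "./OrbitControls.js"]
        report = validate_html(doc)
        assert report.ok, report.messages


class TestValidateHtml:
    def test_fresh_document_passes_all_checks(self):
        report = validate_html(render_html(_scene(n=15)))
        assert report.ok
        assert report.checks["well_formed"]
        assert report.checks["record_count"]

    def test_deleted_script_tag_flagged(self):
        doc = render_html(_scene(n=15))
        broken = doc.text.replace(f'<script src="{CDN_MANIFEST[0][1]}"></script>', "")
        from dataclasses import replace

        report = validate_html(replace(doc, text=broken))
        assert not report.ok
        assert not report.checks["dependency:three.min.js"]

    def test_thousand_point_count_matches(self):
        doc = render_html(_scene(n=1000))
        assert validate_html(doc).checks["record_count"]
        records, _ = extract_records(doc.text)
        assert len(records) == 1000 == doc.point_count
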