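"""Blender script bundle: batching, emission, static replay, deletion."""

import ast

import numpy as np
import pytest

from clusterscape import PointCloud
from clusterscape.blenderview import (
    BlenderSceneConfig,
    emit_bundle,
    emit_deletion_script,
    emit_generation_script,
    emit_keyframe_scripts,
    emit_scene_setup,
    object_name_for,
    plan_batches,
    replay_keyframe_scripts,
    simulate_deletion,
    validate_script,
)
from clusterscape.cluster import ClusterLabels
from clusterscape.synthetic import make_trajectory


def _cloud(n, seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    return PointCloud(ids=np.array([f"g{i:05d}" for i in range(n)], dtype=object),
                      coords=rng.normal(scale=scale, size=(n, 3)))


def _labels(cloud, k=3):
    return ClusterLabels(ids=cloud.ids.copy(),
                         labels=np.arange(cloud.n_points) % k)


class TestPlanBatches:
    def test_12000_points_batches_5000_5000_2000(self):
        plan = plan_batches(12_000, 5_000)
        assert plan.sizes == [5000, 5000, 2000]
        assert plan.batches[0] == (0, 5000)
        assert plan.batches[2] == (10_000, 2000)
        assert not plan.group_as_single_object

    def test_single_point(self):
        plan = plan_batches(1)
        assert plan.sizes == [1]

    def test_grouping_above_50000(self):
        assert plan_batches(60_000).group_as_single_object
        assert not plan_batches(50_000).group_as_single_object

    def test_batches_partition_contiguously(self):
        plan = plan_batches(12_345, 1000)
        starts = [s for s, _ in plan.batches]
        counts = [c for _, c in plan.batches]
        assert starts == list(np.cumsum([0] + counts[:-1]))
        assert sum(counts) == 12_345

    def test_invalid_batch_size(self):
        with pytest.raises(ValueError):
            plan_batches(10, 0)


class TestGenerationScript:
    def test_single_point_at_origin(self):
        cloud = PointCloud(ids=np.array(["g1"], dtype=object), coords=[[0.0, 0.0, 0.0]])
        script = emit_generation_script(cloud, _labels(cloud, k=1))
        validate_script(script)
        assert script.count("primitive_uv_sphere_add") == 1
        assert "location=(0.0, 0.0, 0.0)" in script

    def test_one_material_statement_per_cluster(self):
        cloud = _cloud(30)
        script = emit_generation_script(cloud, _labels(cloud, k=3))
        assert script.count("bpy.data.materials.new") == 3

    def test_batch_sections(self):
        cloud = _cloud(12_000)
        plan = plan_batches(12_000, 5_000)
        script = emit_generation_script(cloud, _labels(cloud), plan)
        assert script.count("# --- batch") == 3
        assert script.count("primitive_uv_sphere_add") == 12_000
        validate_script(script)

    def test_grouping_emits_join_and_warning(self):
        cloud = _cloud(120)
        from clusterscape.blenderview import BatchPlan

        plan = BatchPlan(batches=[(0, 60), (60, 60)], batch_size=60,
                         group_as_single_object=True)
        script = emit_generation_script(cloud, _labels(cloud), plan)
        validate_script(script)
        assert script.count("bpy.ops.object.join()") == 2
        assert "per-point animation" in script

    def test_name_collision_is_error(self):
        cloud = PointCloud(ids=np.array(["a b", "a:b"], dtype=object),
                           coords=[[0.0, 0, 0], [1.0, 1, 1]])
        with pytest.raises(ValueError, match="collision"):
            emit_generation_script(cloud, _labels(cloud, k=1))

    def test_sanitization_deterministic(self):
        assert object_name_for("AT1G01010") == "pt_AT1G01010"
        assert object_name_for("a b/c") == "pt_a_b_c"


class TestKeyframeScripts:
    def test_single_snapshot_first_script_only(self):
        cloud = _cloud(20)
        traj = make_trajectory(cloud, n_snapshots=2, seed=1)
        traj.snapshots = traj.snapshots[:1]
        scripts, table = emit_keyframe_scripts(traj, frames_per_iteration=10)
        assert len(scripts) == 1
        assert table.n_rows == 20
        assert table.max_frame == 0

    def test_5_snapshots_100_points_500_rows(self):
        cloud = _cloud(100)
        traj = make_trajectory(cloud, n_snapshots=5, seed=2)
        scripts, table = emit_keyframe_scripts(traj, frames_per_iteration=10)
        assert len(scripts) == 5
        assert table.n_rows == 500
        assert table.max_frame == 40

    def test_snapshot_3_lands_on_frame_30(self):
        cloud = _cloud(10)
        traj = make_trajectory(cloud, n_snapshots=5, seed=3)
        _, table = emit_keyframe_scripts(traj, frames_per_iteration=10)
        frames = sorted(table.rows["frame"].unique())
        assert frames == [0, 10, 20, 30, 40]
        snap3 = table.rows[table.rows["frame"] == 30]
        assert len(snap3) == 10
        assert np.array_equal(snap3[["x", "y", "z"]].to_numpy(),
                              traj.snapshots[3].cloud.coords)

    def test_id_mismatch_lists_offenders(self):
        cloud = _cloud(5)
        traj = make_trajectory(cloud, n_snapshots=2, seed=4)
        with pytest.raises(ValueError, match="g00004"):
            emit_keyframe_scripts(traj, expected_ids=[f"g{i:05d}" for i in range(4)])

    def test_replay_reproduces_table_exactly(self):
        cloud = _cloud(60, scale=25.0)
        traj = make_trajectory(cloud, n_snapshots=4, seed=5)
        scripts, table = emit_keyframe_scripts(traj, frames_per_iteration=12)
        replayed = replay_keyframe_scripts(scripts, list(cloud.ids))
        assert replayed.equals(table)

    def test_emission_is_deterministic(self):
        cloud = _cloud(15)
        traj = make_trajectory(cloud, n_snapshots=3, seed=6)
        a, _ = emit_keyframe_scripts(traj)
        b, _ = emit_keyframe_scripts(traj)
        assert a == b


class TestDeletionScript:
    @pytest.fixture
    def table_and_ids(self):
        cloud = _cloud(30)
        traj = make_trajectory(cloud, n_snapshots=3, seed=7)
        _, table = emit_keyframe_scripts(traj, frames_per_iteration=10)
        return table, list(cloud.ids)

    def test_range_covering_nothing_changes_nothing(self, table_and_ids):
        table, ids = table_and_ids
        script = emit_deletion_script(ids, (100, 200))
        assert simulate_deletion(script, table, ids).equals(table)

    def test_delete_snapshot_2_removes_n_points_rows(self, table_and_ids):
        table, ids = table_and_ids
        script = emit_deletion_script(ids, (20, 20))
        out = simulate_deletion(script, table, ids)
        assert out.n_rows == table.n_rows - 30
        assert 20 not in out.rows["frame"].tolist()

    def test_subset_of_ids_only(self, table_and_ids):
        table, ids = table_and_ids
        script = emit_deletion_script(ids[:5], (0, 100))
        out = simulate_deletion(script, table, ids)
        assert out.n_rows == table.n_rows - 5 * 3
        assert not out.rows["id"].isin(ids[:5]).any()

    def test_warning_comment_present(self, table_and_ids):
        _, ids = table_and_ids
        script = emit_deletion_script(ids, (0, 10))
        assert "WARNING" in script and "crash" in script

    def test_empty_id_list_refused(self):
        with pytest.raises(ValueError, match="empty id list"):
            emit_deletion_script([], (0, 10))


class TestSceneSetup:
    def test_exactly_one_hdri_path(self):
        script = emit_scene_setup()
        validate_script(script)
        assert script.count("bpy.data.images.load") == 1

    def test_frame_range_covers_last_keyframe(self):
        cloud = _cloud(10)
        traj = make_trajectory(cloud, n_snapshots=5, seed=8)
        bundle = emit_bundle(traj, _labels(cloud), frames_per_iteration=10)
        assert "scene.frame_end = 40" in bundle.scene_setup_script

    def test_orbit_adds_camera_keyframes_at_both_ends(self):
        script = emit_scene_setup(BlenderSceneConfig(camera_orbit=True, frame_end=40))
        validate_script(script)
        assert 'keyframe_insert(data_path="location", frame=0)' in script
        assert 'keyframe_insert(data_path="location", frame=40)' in script
        assert emit_scene_setup(BlenderSceneConfig(frame_end=40)).count("keyframe_insert") == 0


class TestBundle:
    def test_all_scripts_parse_without_execution(self):
        cloud = _cloud(50)
        traj = make_trajectory(cloud, n_snapshots=4, seed=9)
        bundle = emit_bundle(traj, _labels(cloud))
        for script in bundle.all_scripts:
            ast.parse(script)  # static syntax check only; Blender never runs

    def test_bundle_save_writes_members_and_manifest(self, tmp_path):
        cloud = _cloud(25)
        traj = make_trajectory(cloud, n_snapshots=3, seed=10)
        bundle = emit_bundle(traj, _labels(cloud))
        manifest_path = bundle.save(tmp_path / "bundle")
        import json

        manifest = json.loads(manifest_path.read_text())
        for name in manifest["scripts"]:
            assert (tmp_path / "bundle" / name).exists()
        assert (tmp_path / "bundle" / "keyframes.csv").exists()
        assert manifest["n_keyframe_rows"] == 75
        assert manifest["max_frame"] == 20

    def test_byte_identical_emission(self):
        cloud = _cloud(20)
        traj = make_trajectory(cloud, n_snapshots=3, seed=11)
        a = emit_bundle(traj, _labels(cloud))
        b = emit_bundle(traj, _labels(cloud))
        assert a.all_scripts == b.all_scripts
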