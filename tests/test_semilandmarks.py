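import numpy as np
import pytest
from scipy.optimize import minimize

import callimorph as cm
from callimorph.landmarks import Role
from callimorph.semilandmarks import (
    DegenerateCurveError,
    _tangent_matrix,
    build_sliding_plan,
    closest_point_on_mesh,
)
from callimorph.tps import ThinPlateSpline

from conftest import rigid_copy


class TestResampleCurve:
    def test_straight_segment_equal_spacing(self):
        poly = np.array([[0, 0, 0], [10, 0, 0]], float)
        out = cm.resample_curve(poly, 6)
        np.testing.assert_allclose(out[:, 0], [0, 2, 4, 6, 8, 10], atol=1e-12)

    def test_endpoints_preserved_exactly(self, rng):
        poly = np.cumsum(rng.normal(size=(15, 3)), axis=0)
        out = cm.resample_curve(poly, 7)
        assert np.array_equal(out[0], poly[0])
        assert np.array_equal(out[-1], poly[-1])

    def test_semicircle_equal_arc_gaps(self):
        t = np.linspace(0, np.pi, 2000)
        poly = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        out = cm.resample_curve(poly, 11)
        gaps = np.linalg.norm(np.diff(out, axis=0), axis=1)
        # chord gaps of equal arc segments of a dense semicircle
        assert np.abs(gaps - gaps.mean()).max() < 1e-3 * np.pi / 10

    def test_zero_length_rejected(self):
        with pytest.raises(DegenerateCurveError):
            cm.resample_curve(np.zeros((3, 3)), 4)


class TestMeshProjection:
    def test_projection_matches_dense_sampling(self, atlas, rng):
        import trimesh

        mesh = atlas.template_mesh
        pts = np.asarray(mesh.vertices)[rng.choice(len(mesh.vertices), 8)]
        pts = pts + rng.normal(0, 0.4, pts.shape)
        cp, _ = closest_point_on_mesh(mesh, pts)
        d = np.linalg.norm(cp - pts, axis=1)
        samp, _ = trimesh.sample.sample_surface(mesh, 150000, seed=0)
        from scipy.spatial import cKDTree

        dd, _ = cKDTree(samp).query(pts)
        assert np.all(d <= dd + 1e-9)  # true closest distance is a lower bound
        assert np.abs(d - dd).max() < 0.1  # within sampling resolution

    def test_vertices_project_to_themselves(self, atlas):
        v = np.asarray(atlas.template_mesh.vertices)[:20]
        cp, _ = closest_point_on_mesh(atlas.template_mesh, v)
        np.testing.assert_allclose(cp, v, atol=1e-10)


class TestPlacePatch:
    def test_identical_specimen_recovers_template(self, atlas):
        tmpl = atlas.template_config
        out = cm.place_patch(atlas, tmpl, atlas.template_mesh)
        np.testing.assert_allclose(out.points, tmpl.points, atol=1e-6)

    def test_rigidly_moved_specimen(self, atlas, rng):
        tmpl = atlas.template_config
        import trimesh

        from conftest import random_rotation

        R = random_rotation(rng)
        shift = rng.normal(0, 10, 3)
        moved_cfg = tmpl.with_points(tmpl.points @ R + shift)
        moved_mesh = trimesh.Trimesh(
            np.asarray(atlas.template_mesh.vertices) @ R + shift,
            atlas.template_mesh.faces.copy(),
            process=False,
        )
        out = cm.place_patch(atlas, moved_cfg, moved_mesh)
        np.testing.assert_allclose(out.points, tmpl.points @ R + shift, atol=1e-6)

    def test_patched_points_lie_on_specimen_mesh(self, atlas, small_dataset):
        cfg = small_dataset.configs[0]
        mesh = small_dataset.meshes[cfg.specimen_id]
        out = cm.place_patch(atlas, cfg, mesh)
        surf = out.points[out.indices(Role.SURFACE)]
        cp, _ = closest_point_on_mesh(mesh, surf)
        diag = np.linalg.norm(mesh.bounds[1] - mesh.bounds[0])
        assert np.linalg.norm(cp - surf, axis=1).max() < 1e-6 * diag

    def test_missing_mesh_rejected(self, atlas):
        with pytest.raises(IOError):
            cm.place_patch(atlas, atlas.template_config, None)


def sliding_oracle(specimen, reference):
    """Minimize the bending-energy objective over sliding amplitudes with a
    generic numerical optimizer (no projection), as an independent check of
    the closed-form GLS solution."""
    plan = build_sliding_plan(specimen, None)
    opa = cm.ordinary_procrustes(reference, specimen.points, allow_scale=True)
    x = opa.apply(reference)
    bem = ThinPlateSpline(x).bending_energy_matrix
    k = specimen.k
    U = _tangent_matrix(plan, k)

    def energy(t):
        pts = specimen.points + (U @ t).reshape(3, k).T
        return bem.energy(pts)

    out = minimize(energy, np.zeros(U.shape[1]), method="L-BFGS-B",
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    return out.fun, energy(np.zeros(U.shape[1]))


class TestRelaxOnce:
    def test_reference_specimen_is_fixed_point(self, small_dataset):
        cfg = small_dataset.configs[0]
        res = cm.relax_once(cfg, cfg.points, mesh=small_dataset.meshes[cfg.specimen_id])
        assert np.abs(res.config.points - cfg.points).max() < 1e-9

    def test_closed_form_matches_optimizer(self, small_dataset):
        a, b = small_dataset.configs[:2]
        res = cm.relax_once(a, b.points, mesh=None, project=False)
        oracle_min, e0 = sliding_oracle(a, b.points)
        assert res.energy_before == pytest.approx(e0, rel=1e-9)
        assert res.energy_after == pytest.approx(oracle_min, rel=1e-5, abs=1e-8)

    def test_energy_never_increases(self, small_dataset):
        for cfg in small_dataset.configs[:4]:
            ref = small_dataset.configs[-1]
            res = cm.relax_once(cfg, ref.points, mesh=small_dataset.meshes[cfg.specimen_id])
            assert res.energy_after <= res.energy_before + 1e-6 * max(res.energy_before, 1)

    def test_fixed_landmarks_bit_identical(self, small_dataset):
        cfg, ref = small_dataset.configs[:2]
        res = cm.relax_once(cfg, ref.points, mesh=small_dataset.meshes[cfg.specimen_id])
        idx = cfg.indices(Role.FIXED)
        assert np.array_equal(res.config.points[idx], cfg.points[idx])

    def test_surface_points_stay_on_mesh(self, small_dataset):
        cfg, ref = small_dataset.configs[:2]
        mesh = small_dataset.meshes[cfg.specimen_id]
        res = cm.relax_once(cfg, ref.points, mesh=mesh)
        surf = res.config.points[cfg.indices(Role.SURFACE)]
        cp, _ = closest_point_on_mesh(mesh, surf)
        diag = np.linalg.norm(mesh.bounds[1] - mesh.bounds[0])
        assert np.linalg.norm(cp - surf, axis=1).max() <= 1e-6 * diag

    def test_invariant_to_rigid_motion_of_specimen(self, small_dataset, rng):
        import trimesh
        from conftest import random_rotation

        cfg, ref = small_dataset.configs[:2]
        mesh = small_dataset.meshes[cfg.specimen_id]
        res1 = cm.relax_once(cfg, ref.points, mesh=mesh)
        R = random_rotation(rng)
        shift = rng.normal(0, 20, 3)
        moved = cfg.with_points(cfg.points @ R + shift)
        mesh2 = trimesh.Trimesh(np.asarray(mesh.vertices) @ R + shift, mesh.faces.copy(), process=False)
        res2 = cm.relax_once(moved, ref.points, mesh=mesh2)
        np.testing.assert_allclose(res2.config.points, res1.config.points @ R + shift, atol=1e-6)


class TestRelaxToConsensus:
    def test_identical_specimens_unchanged(self, atlas):
        tmpl = atlas.template_config
        configs = [tmpl.with_points(tmpl.points.copy()) for _ in range(3)]
        out, trace = cm.relax_to_consensus(configs, [atlas.template_mesh] * 3, iterations=3)
        for c in out:
            np.testing.assert_allclose(c.points, tmpl.points, atol=1e-6)

    def test_total_energy_non_increasing(self, small_dataset):
        configs = small_dataset.configs[:6]
        meshes = [small_dataset.meshes[c.specimen_id] for c in configs]
        _, trace = cm.relax_to_consensus(configs, meshes, iterations=3)
        e = trace.energies
        assert all(e[i + 1] <= e[i] * (1 + 1e-9) for i in range(len(e) - 1))

    def test_trace_serializes(self, tmp_path, small_dataset):
        configs = small_dataset.configs[:3]
        _, trace = cm.relax_to_consensus(configs, iterations=1)
        p = tmp_path / "trace.json"
        trace.to_json(p)
        import json

        data = json.loads(p.read_text())
        assert len(data["total_bending_energy"]) == 2


class TestReplicateAveraging:
    def test_average_of_identical_replicates(self, atlas, rng):
        from callimorph.semilandmarks import average_replicates
        from conftest import random_rotation

        tmpl = atlas.template_config
        rep_b = tmpl.with_points(tmpl.points @ random_rotation(rng) + rng.normal(0, 3, 3))
        avg = average_replicates(tmpl, rep_b)
        np.testing.assert_allclose(avg.points, tmpl.points, atol=1e-9)
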