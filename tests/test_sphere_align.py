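"""Unit-sphere mapping, overlap maximization and centroid-depth statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from azmetrics import (ConnectionSite, Vesicle, class_centroid_depths,
                       class_separation_anova, fine_align, map_scene,
                       map_to_unit_sphere, rib_overlap, rough_align)
from azmetrics.scene import SceneError
from azmetrics.sphere_align import (SearchParams, SphereMap,
                                    exhaustive_align_2, site_depth_table)


def _vesicle(radius=27.5):
    return Vesicle(id="v", center=np.array([10.0, -5.0, radius]),
                   radius=radius, state="docked")


def _site(ves, offset, cls="rib"):
    return ConnectionSite(vesicle_id=ves.id, filament_id="f",
                          class_label=cls,
                          position=ves.center + np.asarray(offset, float))


class TestMapToUnitSphere:
    def test_pole_and_equator(self):
        ves = _vesicle()
        m = map_to_unit_sphere(ves, [_site(ves, (0, 0, 27.5)),
                                     _site(ves, (27.5, 0, 0))])
        assert np.allclose(m.vectors[0], [0, 0, 1])
        assert np.allclose(m.vectors[1], [1, 0, 0])
        assert m.labels == ["rib", "rib"]

    def test_random_site_round_trips(self, rng):
        ves = _vesicle()
        for _ in range(20):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            site = _site(ves, 27.5 * u)
            m = map_to_unit_sphere(ves, [site])
            assert abs(np.linalg.norm(m.vectors[0]) - 1.0) < 1e-9
            back = ves.center + np.linalg.norm(site.position - ves.center) \
                * m.vectors[0]
            assert np.allclose(back, site.position, atol=1e-12)

    def test_off_surface_site_is_rejected_by_name(self):
        ves = _vesicle()
        bad = _site(ves, (33.0, 0, 0))
        with pytest.raises(SceneError, match="v"):
            map_to_unit_sphere(ves, [bad])


class TestRoughAlign:
    def test_already_facing_canonical_axis_is_identity(self):
        vecs = np.array([[1.0, 0.1, 0.0], [1.0, -0.1, 0.0]])
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        out = rough_align([SphereMap("a", vecs, ["rib", "rib"])])[0]
        assert np.allclose(out.rotation, np.eye(3), atol=1e-9)

    def test_antipodal_cluster_rotates_by_pi(self):
        vecs = np.array([[-1.0, 0.05, 0.0], [-1.0, -0.05, 0.0]])
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        out = rough_align([SphereMap("a", vecs, ["rib", "rib"])])[0]
        mean = out.rotated().mean(axis=0)
        mean /= np.linalg.norm(mean)
        assert np.allclose(mean, [1, 0, 0], atol=1e-9)
        assert Rotation.from_matrix(out.rotation).magnitude() == \
            pytest.approx(math.pi, abs=1e-6)

    def test_zero_mean_direction_falls_back_to_identity(self):
        vecs = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        with pytest.warns(UserWarning, match="antipodal"):
            out = rough_align([SphereMap("a", vecs, ["rib", "rib"])])[0]
        assert np.allclose(out.rotation, np.eye(3))

    def test_scene_contract_every_vesicle_faces_canonical_axis(
            self, small_resting_scene):
        maps = rough_align(map_scene(small_resting_scene))
        for m in maps:
            mean = m.rotated().mean(axis=0)
            mean /= np.linalg.norm(mean)
            assert np.allclose(mean, [1, 0, 0], atol=1e-9)


class TestRibOverlap:
    def test_coincident_pair_scores_one(self):
        a = SphereMap("a", np.array([[0, 0, 1.0]]), ["rib"])
        b = SphereMap("b", np.array([[0, 0, 1.0]]), ["rib"])
        assert rib_overlap([a, b], bandwidth=0.3) == pytest.approx(1.0)

    def test_antipodal_pair_closed_form(self):
        a = SphereMap("a", np.array([[0, 0, 1.0]]), ["rib"])
        b = SphereMap("b", np.array([[0, 0, -1.0]]), ["rib"])
        expected = math.exp(-math.pi ** 2 / (2 * 0.3 ** 2))
        assert rib_overlap([a, b], bandwidth=0.3) == pytest.approx(expected)

    def test_invariant_under_common_rotation_and_relabeling(self, rng):
        maps = []
        for name in "abc":
            v = rng.normal(size=(4, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            maps.append(SphereMap(name, v, ["rib"] * 4))
        base = rib_overlap(maps)
        R = Rotation.random(random_state=rng).as_matrix()
        rotated = [SphereMap(m.vesicle_id, m.vectors @ R.T, list(m.labels))
                   for m in maps]
        assert rib_overlap(rotated) == pytest.approx(base, abs=1e-9)
        assert rib_overlap(maps[::-1]) == pytest.approx(base, abs=1e-12)

    def test_no_ribs_warns_and_returns_zero(self):
        m = SphereMap("a", np.array([[0, 0, 1.0]]), ["spar"])
        with pytest.warns(UserWarning, match="no rib"):
            assert rib_overlap([m, m]) == 0.0

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            rib_overlap([], bandwidth=0.0)


class TestFineAlign:
    def _layout(self, rng, k=4):
        v = rng.normal(size=(k, 3)) + np.array([3.0, 0, 0])
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    @pytest.mark.parametrize("bandwidth", [0.2, 0.3, 0.4])
    def test_recovers_a_known_rotation(self, rng, bandwidth):
        """Two vesicles sharing one rib layout, one pre-rotated: alignment
        brings homologous sites back within 5 degrees."""
        base = self._layout(rng)
        R = Rotation.from_rotvec(np.radians(40.0) * np.array([0.2, 0.3, 0.93])
                                 / np.linalg.norm([0.2, 0.3, 0.93]))
        maps = [SphereMap("a", base, ["rib"] * 4),
                SphereMap("b", base @ R.as_matrix().T, ["rib"] * 4)]
        res = fine_align(maps, bandwidth=bandwidth,
                         search=SearchParams(grid_deg=10))
        a, b = res.maps[0].rib_vectors(), res.maps[1].rib_vectors()
        mismatch = np.degrees(np.arccos(np.clip((a * b).sum(axis=1),
                                                -1.0, 1.0)))
        assert mismatch.max() < 5.0

    def test_matches_exhaustive_grid_oracle(self, rng):
        """Coordinate-ascent objective reaches the 5-degree-grid brute-force
        optimum (small two-vesicle instance)."""
        base = self._layout(rng)
        R = Rotation.from_rotvec(np.radians(55.0) * np.array([0, 0, 1.0]))
        maps = [SphereMap("a", base, ["rib"] * 4),
                SphereMap("b", base @ R.as_matrix().T, ["rib"] * 4)]
        oracle_best, _ = exhaustive_align_2(maps, grid_deg=5.0)
        res = fine_align(maps, search=SearchParams(grid_deg=10))
        assert res.objective >= oracle_best - 1e-6

    def test_prealigned_identical_vesicles_are_a_fixed_point(self, rng):
        base = self._layout(rng)
        maps = [SphereMap(n, base.copy(), ["rib"] * 4) for n in "ab"]
        res = fine_align(maps, search=SearchParams(grid_deg=15))
        assert res.objective == pytest.approx(res.trace[0], abs=1e-9)

    def test_objective_improves_on_rough_alignment_and_trace_is_monotone(
            self, small_resting_scene):
        maps = rough_align(map_scene(small_resting_scene))
        res = fine_align(maps, search=SearchParams(grid_deg=15))
        assert res.objective > rib_overlap(maps)
        assert all(b >= a - 1e-9 for a, b in zip(res.trace, res.trace[1:]))
        assert res.converged
        for m in res.maps:
            assert np.allclose(m.rotation @ m.rotation.T, np.eye(3),
                               atol=1e-9)
            assert np.linalg.det(m.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_rib_vesicles_rejected(self):
        m = SphereMap("a", np.array([[1.0, 0, 0]]), ["rib"])
        with pytest.raises(SceneError):
            fine_align([m])


class TestCentroidDepths:
    def _scene(self):
        from azmetrics.scene import Attachment, Filament, Membrane, Scene

        ves = Vesicle(id="v", center=np.array([0.0, 0.0, 27.5]), radius=27.5,
                      state="docked")
        fils = []
        for i, (cls, z) in enumerate([("rib", 6.0), ("rib", 10.0),
                                      ("spar", 18.0)]):
            dz = z - 27.5
            rho = math.sqrt(27.5 ** 2 - dz ** 2)
            tip = np.array([rho, 0.0, z])
            fils.append(Filament(
                id=f"f{i}", class_label=cls, diameter=8.0,
                path=np.array([tip + np.array([20.0, 0, 0]), tip]),
                attachments=[Attachment(1, "vesicle", "v")]))
        return Scene(membrane=Membrane(), vesicles=[ves], filaments=fils)

    def test_rib_depth_and_spar_offset_arithmetic(self):
        d = class_centroid_depths(self._scene())
        assert d.rib_depth.mean == pytest.approx(8.0)
        assert d.offsets["spar"].mean == pytest.approx(10.0)
        assert "boom" not in d.offsets

    def test_resting_scene_recovers_depth_structure(self, resting_scene):
        d = class_centroid_depths(resting_scene)
        assert d.rib_depth.n >= 14
        assert abs(d.rib_depth.mean - 7.7) < 3 * d.rib_depth.sd / \
            math.sqrt(d.rib_depth.n)
        assert d.offsets["spar"].mean < d.offsets["boom"].mean


class TestClassSeparationAnova:
    def test_identical_constant_depths_give_zero_f(self):
        table = pd.DataFrame({"class": ["rib"] * 3 + ["spar"] * 3
                              + ["boom"] * 3, "depth": [5.0] * 9})
        f, p = class_separation_anova(table)
        assert f == 0.0 and p == 1.0

    def test_two_separated_groups_match_hand_anova(self):
        """{1,2,3} vs {11,12,13}: SSB=150 on 1 df, MSW=1 -> F=150."""
        table = pd.DataFrame({"class": ["a"] * 3 + ["b"] * 3,
                              "depth": [1, 2, 3, 11, 12, 13]})
        f, p = class_separation_anova(table)
        assert f == pytest.approx(150.0)

    def test_resting_scene_classes_are_distinct(self, resting_scene):
        table = site_depth_table(resting_scene)
        f, p = class_separation_anova(table)
        assert p < 1e-4

    def test_insufficient_data_rejected(self):
        table = pd.DataFrame({"class": ["a", "b"], "depth": [1.0, 2.0]})
        with pytest.raises(SceneError):
            class_separation_anova(table)
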