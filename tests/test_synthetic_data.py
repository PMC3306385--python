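"""Generator contracts: determinism, degenerate configs, statistical
structure of resting and activated scenes, and z-compression."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from azmetrics import (SceneConfig, apply_z_compression, connection_counts,
                       degenerate_config, estimate_compression_ratio,
                       generate_activated_scene, generate_resting_scene,
                       shortest_distance_to_membrane, validate_scene,
                       z_stretch_correct)
from azmetrics.config import BinRule, Dist
from azmetrics.sampling import matched_truncnorm
from azmetrics.sceneio import dumps_canonical, scene_to_dict


class TestDeterminism:
    def test_same_seed_is_byte_identical(self):
        cfg = SceneConfig(seed=11)
        a = dumps_canonical(scene_to_dict(generate_resting_scene(cfg)))
        b = dumps_canonical(scene_to_dict(generate_resting_scene(cfg)))
        assert a == b

    def test_different_seeds_differ(self):
        a = dumps_canonical(scene_to_dict(
            generate_resting_scene(SceneConfig(seed=1))))
        b = dumps_canonical(scene_to_dict(
            generate_resting_scene(SceneConfig(seed=2))))
        assert a != b

    def test_activated_same_seed_is_byte_identical(self):
        cfg = SceneConfig(seed=11)
        a = dumps_canonical(scene_to_dict(generate_activated_scene(cfg)))
        b = dumps_canonical(scene_to_dict(generate_activated_scene(cfg)))
        assert a == b


class TestRestingScene:
    def test_default_scene_validates_with_expected_step_count(self,
                                                              resting_scene):
        assert validate_scene(resting_scene) == []
        # 500 nm band at ~48.8 nm spacing -> on the order of 10 steps
        assert 7 <= len(resting_scene.filaments_of_class("step")) <= 14

    def test_degenerate_config_gives_exact_docked_counts(self):
        """With all SDs 0 and counts at their means, every docked vesicle has
        round(3.9)=4 ribs, 2 spars, round(2*10.6/4)=5 booms and 4 pins."""
        scene = generate_resting_scene(degenerate_config(seed=2))
        counts = connection_counts(scene)
        docked = counts[counts["state"] == "docked"]
        assert (docked["rib"] == 4).all()
        assert (docked["spar"] == 2).all()
        assert (docked["boom"] == 5).all()
        assert (docked["pin"] == 4).all()

    def test_pin_counts_stay_in_configured_range(self, resting_pool):
        counts = pd.concat(connection_counts(s) for s in resting_pool)
        docked = counts[counts["state"] == "docked"]
        assert docked["pin"].between(3, 5).all()

    def test_rib_and_pin_sites_ring_the_fusion_domain(self, resting_scene):
        """The rib+pin connection band lies below the spar-centroid depth
        (individual sites scatter with the configured depth SDs) and
        surrounds the vesicle's membrane contact point (azimuthal span
        > 180 deg)."""
        scene = resting_scene
        for ves in scene.vesicles_in_state("docked")[:8]:
            sites = scene.sites_for_vesicle(ves.id)
            by_class = {}
            for s in sites:
                by_class.setdefault(s.class_label, []).append(s.position)
            spar_depth = np.mean([p[2] for p in by_class["spar"]])
            ring = np.array(by_class["rib"] + by_class["pin"])
            assert ring[:, 2].mean() < spar_depth
            az = np.sort(np.degrees(np.arctan2(ring[:, 1] - ves.center[1],
                                               ring[:, 0] - ves.center[0])))
            gaps = np.diff(np.concatenate([az, [az[0] + 360.0]]))
            assert 360.0 - gaps.max() > 180.0

    def test_pooled_statistics_recover_configured_means(self, resting_pool):
        """Empirical means of every pipeline-measurable configured quantity
        fall within 3 standard errors of their configured values."""
        from azmetrics.morphometry import (angle_table,
                                           class_dimension_table,
                                           pin_length_by_state,
                                           step_center_spacing)
        from azmetrics.sphere_align import class_centroid_depths

        cfg = SceneConfig()

        def within_3se(values, target):
            v = np.asarray(values, dtype=float)
            se = v.std(ddof=1) / math.sqrt(len(v))
            assert abs(v.mean() - target) < 3 * se + 1e-12, \
                f"{v.mean():.3f} vs {target} (3SE={3 * se:.3f}, n={len(v)})"

        spacings = [x for s in resting_pool for x in step_center_spacing(s)]
        within_3se(spacings, cfg.step_spacing.mean)

        dims = class_dimension_table(resting_pool)
        for cls, dist in [("beam", cfg.beam_length), ("step", cfg.step_length),
                          ("mast", cfg.mast_length), ("rib", cfg.rib_length),
                          ("pin", cfg.pin_length), ("spar", cfg.spar_length),
                          ("boom", cfg.boom_length),
                          ("topmast", cfg.topmast_length)]:
            se = dims.loc[cls, "length_sd"] / math.sqrt(dims.loc[cls,
                                                                 "length_n"])
            assert abs(dims.loc[cls, "length_mean"] - dist.mean) < 3 * se

        ang = angle_table(resting_pool)
        for cls, dist in [("rib", cfg.rib_angle), ("spar", cfg.spar_angle),
                          ("boom", cfg.boom_angle)]:
            se = ang.loc[cls, "angle_sd"] / math.sqrt(ang.loc[cls, "n"])
            assert abs(ang.loc[cls, "angle_mean"] - dist.mean) < 3 * se

        counts = pd.concat(connection_counts(s) for s in resting_pool)
        docked = counts[counts["state"] == "docked"]
        within_3se(docked["rib"], cfg.ribs_per_vesicle.mean)
        within_3se(docked["spar"], cfg.spars_per_vesicle.mean)
        within_3se(docked["boom"], 2 * cfg.booms_per_mast.mean / 4)
        within_3se(docked["pin"], cfg.pins_per_vesicle.mean)

        rib_d, spar_o, boom_o = [], [], []
        for s in resting_pool:
            d = class_centroid_depths(s)
            rib_d.extend(d.rib_depth.values)
            spar_o.extend(d.offsets["spar"].values)
            boom_o.extend(d.offsets["boom"].values)
        within_3se(rib_d, cfg.rib_site_depth.mean)
        within_3se(spar_o, cfg.spar_site_offset.mean)
        within_3se(boom_o, cfg.boom_site_offset.mean)

        pins = []
        for s in resting_pool:
            pins.extend(pin_length_by_state(s)["docked"].values)
        within_3se(pins, cfg.pin_length.mean)


class TestActivatedScene:
    def test_validates_and_partitions_replacements(self, activated_scene):
        assert validate_scene(activated_scene) == []
        replaced = activated_scene.metadata["replacement_vesicles"]
        assert len(replaced) > 0
        ids = {v.id for v in activated_scene.vesicles}
        assert set(replaced) <= ids

    def test_connection_totals_decrease_with_distance(self, activated_pool):
        """Mean main-body total strictly increases far -> mid -> near."""
        from azmetrics.connectivity import bin_undocked, binned_profile

        pooled = {}
        for s in activated_pool:
            for p in binned_profile(s, bin_undocked(s)):
                pooled.setdefault(p.bin, []).extend(
                    p.values["main_body_total"].tolist())
        far = np.mean(pooled[(29.0, 42.0)])
        mid = np.mean(pooled[(17.0, 24.0)])
        near = np.mean(pooled[(4.0, 16.0)])
        assert far < mid < near

    def test_degenerate_near_bin_counts_match_rounded_means(self):
        """SD-0 bin rules give exactly round(5.6)+round(1.9)+round(3.6)
        main-body connections on every near-bin vesicle."""
        from azmetrics.connectivity import bin_undocked

        cfg = degenerate_config(seed=4)
        scene = generate_activated_scene(cfg)
        counts = connection_counts(scene)
        near = bin_undocked(scene)[(4.0, 16.0)]
        assert near, "expected near-bin vesicles"
        for v in near:
            row = counts.loc[v.id]
            assert row["boom"] == 6 and row["spar"] == 2 and row["rib"] == 4
            assert row["main_body_total"] == 12

    def test_zero_expectation_rules_give_unconnected_vesicles(self):
        zero = Dist(0.0, 0.0)
        rules = tuple(BinRule(bin=r.bin, booms=zero, spars=zero, ribs=zero,
                              pins_present=False)
                      for r in SceneConfig().bin_rules)
        cfg = SceneConfig(seed=5, bin_rules=rules, include_fused_omega=False)
        scene = generate_activated_scene(cfg)
        counts = connection_counts(scene)
        for vid in scene.metadata["replacement_vesicles"]:
            assert counts.loc[vid, "main_body_total"] == 0
            assert counts.loc[vid, "pin"] == 0

    def test_fused_omega_keeps_main_body_complement(self, activated_scene):
        fused = activated_scene.metadata["fused_omega"]
        row = connection_counts(activated_scene).loc[fused]
        assert row["rib"] > 0 and row["spar"] > 0 and row["boom"] > 0
        assert row["pin"] == 0

    def test_undocked_distances_lie_in_sampler_range(self, activated_scene):
        lo, hi = SceneConfig().undocked_distance_range
        for vid in activated_scene.metadata["replacement_vesicles"]:
            d = shortest_distance_to_membrane(
                activated_scene.vesicle_by_id(vid))
            assert lo - 1e-9 <= d <= hi + 1e-9


class TestZCompression:
    def test_identity_ratio_changes_nothing(self, small_resting_scene):
        out = apply_z_compression(small_resting_scene, 1.0)
        assert dumps_canonical(scene_to_dict(out)) == dumps_canonical(
            scene_to_dict(small_resting_scene))

    def test_vesicle_z_diameter_scales(self):
        scene = generate_resting_scene(SceneConfig(seed=6, band_length=200))
        ves = scene.vesicles[0]
        ves.radius = 27.5  # diameter 55 for the closed-form check
        ves.center[2] = 27.5
        out = apply_z_compression(scene, 0.805)
        assert 2 * out.vesicles[0].z_semi == pytest.approx(44.275)

    def test_round_trip_is_exact(self, small_resting_scene):
        ratio = 0.805
        back = z_stretch_correct(
            apply_z_compression(small_resting_scene, ratio), 1.0 / ratio)
        for a, b in zip(back.filaments, small_resting_scene.filaments):
            assert np.abs(a.path - b.path).max() < 1e-9
        for a, b in zip(back.vesicles, small_resting_scene.vesicles):
            assert abs(a.z_semi - b.z_semi) < 1e-9

    @pytest.mark.parametrize("ratio", [0.0, -0.2, 1.2])
    def test_invalid_ratio_rejected(self, small_resting_scene, ratio):
        with pytest.raises(ValueError):
            apply_z_compression(small_resting_scene, ratio)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(ratio=st.floats(0.3, 1.0))
    def test_injected_ratio_is_recovered(self, small_resting_scene, ratio):
        out = apply_z_compression(small_resting_scene, ratio)
        est = estimate_compression_ratio(out)
        assert est.mean == pytest.approx(ratio, abs=1e-9)


class TestSampling:
    @pytest.mark.parametrize("dist, low, high", [
        (Dist(10.6, 6.2), 0.0, 90.0),   # heavy lower truncation
        (Dist(8.6, 3.5), 0.0, math.inf),
        (Dist(48.8, 14.9), 10.0, math.inf),
    ])
    def test_matched_truncation_preserves_the_mean(self, dist, low, high,
                                                   rng):
        draws = matched_truncnorm(dist, rng, size=200_000, low=low, high=high)
        assert draws.min() >= low and draws.max() <= high
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - dist.mean) < 4 * se
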