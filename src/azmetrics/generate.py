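"""Seeded generators for resting and activated active-zone scenes.

The layout follows the measured organization of the frog neuromuscular
junction active zone.  A straight band of AZM runs along +y.  Beams lie
along the midline next to the membrane; steps sit on the beams at roughly
50 nm intervals, each roughly centered between a tetrad of docked
vesicles (two per row, rows mirrored in x); one mast rises from each
step.  Ribs (from beams), spars (from the two flanking steps) and booms
(from the two flanking masts) connect to each docked vesicle at
class-specific depths on its AZM-facing hemisphere; pins rise from the
membrane to the away-facing hemisphere; topmasts link mast deep ends to
undocked vesicles deep to the band; unorganized non-AZM filaments attach
to the away hemisphere.

Activated scenes vacate a configured fraction of docking sites and place
an undocked vesicle over each vacated site at a drawn membrane distance,
wired according to the distance-bin rules (booms always; spars and ribs
gated by bin; pins only within reach, with length growing with distance).

Filament paths are constructed so that three measured quantities are
exact by construction: the arc length equals the drawn class length, the
horizontal-plane direction makes the drawn approach angle with the
perpendicular to the band axis, and the vesicle endpoint sits at the
drawn connection-site depth.  The non-vesicle endpoint then lands near
its parent structure (beam/step/mast/membrane); its height is treated as
an elevation target and clamped when the drawn length cannot span it.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np

from .config import BinRule, SceneConfig
from .sampling import child_rngs, matched_truncnorm, rounded_count
from .scene import Attachment, Filament, Membrane, Scene, Vesicle

_STAGES = ("layout", "vesicles", "filaments", "activated")


# ---------------------------------------------------------------------------
# small geometric helpers
# ---------------------------------------------------------------------------

def _site_on_sphere(center: np.ndarray, radius: float, z_abs: float,
                    azimuth: float) -> np.ndarray:
    """Point on the sphere at absolute height ``z_abs`` and xy-azimuth."""
    dz = z_abs - center[2]
    dz = float(np.clip(dz, -radius + 1e-9, radius - 1e-9))
    rho = math.sqrt(radius ** 2 - dz ** 2)
    return np.array([center[0] + rho * math.cos(azimuth),
                     center[1] + rho * math.sin(azimuth),
                     center[2] + dz])


def _spread_azimuths(k: int, center: float, half_span: float,
                     rng: np.random.Generator) -> np.ndarray:
    """k azimuths spread evenly over [center-half_span, center+half_span],
    with a small jitter, so sites disperse rather than cluster."""
    if k == 1:
        base = np.array([center])
    else:
        base = center + np.linspace(-half_span, half_span, k)
    jitter = rng.uniform(-0.5, 0.5, size=k) * (half_span / max(k, 2))
    return base + jitter


@dataclass
class _Counter:
    n: int = 0

    def next(self, prefix: str) -> str:
        self.n += 1
        return f"{prefix}{self.n:04d}"


def _filament_to_site(fid: str, class_label: str, site: np.ndarray,
                      angle_deg: float, length: float, origin_z: float,
                      outward_x_sign: float, diameter: float,
                      rng: np.random.Generator, vesicle_id: str,
                      parent_kind: str, parent_id: str | None) -> Filament:
    """Straight 2-point filament ending on a vesicle surface site.

    The xy-projected direction from the non-vesicle origin to the site makes
    ``angle_deg`` with the x axis (the perpendicular to the band axis), with
    the outward x sense of the vesicle's row and a random y sign; the origin
    height targets ``origin_z``, clamped so the drawn length can span it.
    """
    theta = math.radians(angle_deg)
    sy = rng.choice([-1.0, 1.0])
    u_xy = np.array([outward_x_sign * math.cos(theta), sy * math.sin(theta), 0.0])
    v = site[2] - origin_z
    vmax = 0.95 * length
    v = float(np.clip(v, -vmax, vmax))
    h = math.sqrt(length ** 2 - v ** 2)
    origin = site - (h * u_xy + np.array([0.0, 0.0, v]))
    return Filament(
        id=fid, class_label=class_label, path=np.array([origin, site]),
        diameter=diameter,
        attachments=[Attachment(0, parent_kind, parent_id),
                     Attachment(1, "vesicle", vesicle_id)])


# ---------------------------------------------------------------------------
# resting scene
# ---------------------------------------------------------------------------

def _band_layout(cfg: SceneConfig, rng: np.random.Generator):
    """Step y positions and beam segments along the band."""
    # the last step/beam may extend past the nominal band end: censoring
    # draws at the boundary would bias the realized spacing/length small
    margin = 30.0
    step_y = [margin + matched_truncnorm(cfg.step_spacing, rng, low=10.0)]
    while step_y[-1] <= cfg.band_length - margin:
        step_y.append(step_y[-1] + matched_truncnorm(cfg.step_spacing, rng,
                                                     low=10.0))
    beam_spans = []
    y = 0.0
    while y < step_y[-1] + margin:
        L = matched_truncnorm(cfg.beam_length, rng, low=5.0)
        beam_spans.append((y, y + L))
        y += L + 2.0
    return np.array(step_y), beam_spans


def _docked_wiring(scene_parts, ves: Vesicle, cfg: SceneConfig,
                   rng: np.random.Generator, counter: _Counter,
                   flank_steps: tuple[str, str], flank_masts: tuple[str, str],
                   mast_boom_rate: tuple[float, float],
                   beam_id: str, beam_z: float, step_z: float,
                   warnings: list[str], with_pins: bool = True) -> None:
    """Ribs, spars, booms (+ pins, non-AZM) for one docked-position vesicle."""
    filaments = scene_parts
    sx = 1.0 if ves.center[0] < 0 else -1.0   # outward = away from midline
    az_facing = 0.0 if ves.center[0] < 0 else math.pi
    az_away = az_facing + math.pi
    cz, r = ves.center[2], ves.radius
    top = cz + r - 0.5

    # ribs: nearest the membrane, from the beam
    k_rib = rounded_count(cfg.ribs_per_vesicle, rng)
    rib_depths = np.atleast_1d(matched_truncnorm(cfg.rib_site_depth, rng,
                                                 size=k_rib, low=0.5))
    azs = _spread_azimuths(k_rib, az_facing, math.radians(70), rng)
    for depth, az in zip(rib_depths, azs):
        site = _site_on_sphere(ves.center, r, float(depth), float(az))
        filaments.append(_filament_to_site(
            counter.next("rib"), "rib", site,
            matched_truncnorm(cfg.rib_angle, rng, high=90.0),
            matched_truncnorm(cfg.rib_length, rng, low=1.0), beam_z, -sx,
            matched_truncnorm(cfg.rib_diameter, rng, low=0.5), rng,
            ves.id, "filament", beam_id))
    rib_centroid = float(np.mean(rib_depths)) if k_rib else cfg.rib_site_depth.mean

    # spars: from the two flanking steps, deeper than the ribs
    k_spar = rounded_count(cfg.spars_per_vesicle, rng)
    azs = _spread_azimuths(max(k_spar, 1), az_facing, math.radians(60), rng)
    for j in range(k_spar):
        depth = rib_centroid + matched_truncnorm(cfg.spar_site_offset, rng)
        depth = min(depth, top)
        site = _site_on_sphere(ves.center, r, depth, float(azs[j % len(azs)]))
        filaments.append(_filament_to_site(
            counter.next("spar"), "spar", site,
            matched_truncnorm(cfg.spar_angle, rng, high=90.0),
            matched_truncnorm(cfg.spar_length, rng, low=1.0), step_z, -sx,
            matched_truncnorm(cfg.spar_diameter, rng, low=0.5), rng,
            ves.id, "filament", flank_steps[j % 2]))

    # booms: from the two flanking masts, deepest; the per-vesicle count is
    # the sum of the two masts' per-tetrad-member rates
    k_boom = int(round(mast_boom_rate[0] + mast_boom_rate[1]))
    k_boom = max(k_boom, 0)
    azs = _spread_azimuths(max(k_boom, 1), az_facing, math.radians(65), rng)
    clipped = 0
    for j in range(k_boom):
        depth = rib_centroid + matched_truncnorm(cfg.boom_site_offset, rng)
        if depth > top:
            depth = top
            clipped += 1
        site = _site_on_sphere(ves.center, r, depth, float(azs[j % len(azs)]))
        origin_z = matched_truncnorm(cfg.boom_origin_height, rng, low=1.0)
        filaments.append(_filament_to_site(
            counter.next("boom"), "boom", site,
            matched_truncnorm(cfg.boom_angle, rng, high=90.0),
            matched_truncnorm(cfg.boom_length, rng, low=1.0), origin_z, -sx,
            matched_truncnorm(cfg.boom_diameter, rng, low=0.5), rng,
            ves.id, "filament", flank_masts[j % 2]))
    if clipped:
        warnings.append(f"{ves.id}: {clipped} boom site depth(s) clipped to "
                        "the vesicle surface")

    # pins: membrane to the away hemisphere, nearly vertical
    if with_pins:
        k_pin = rounded_count(cfg.pins_per_vesicle, rng)
        azs = _spread_azimuths(k_pin, az_away, math.radians(70), rng)
        for az in azs:
            L = matched_truncnorm(cfg.pin_length, rng, low=0.5)
            tilt = rng.uniform(0.0, math.radians(25.0))
            z_s = min(L * math.cos(tilt), top)
            site = _site_on_sphere(ves.center, r, z_s, float(az))
            h = math.sqrt(max(L ** 2 - z_s ** 2, 0.0))
            u = np.array([math.cos(az), math.sin(az), 0.0])
            origin = site - h * u
            origin[2] = 0.0
            filaments.append(Filament(
                id=counter.next("pin"), class_label="pin",
                path=np.array([origin, site]),
                diameter=matched_truncnorm(cfg.pin_diameter, rng, low=0.5),
                attachments=[Attachment(0, "membrane", None),
                             Attachment(1, "vesicle", ves.id)]))

    # non-AZM filaments: unorganized, away hemisphere, blind far ends
    k_non = rounded_count(cfg.non_azm_per_vesicle, rng)
    for _ in range(k_non):
        az = az_away + rng.uniform(-1.4, 1.4)
        z_s = cz + r * rng.uniform(-0.6, 0.8)
        site = _site_on_sphere(ves.center, r, z_s, az)
        radial = (site - ves.center) / np.linalg.norm(site - ves.center)
        L = matched_truncnorm(cfg.non_azm_length, rng, low=5.0)
        if site[2] + L * radial[2] < 0.5:   # keep the blind end above the membrane
            dz = -(site[2] - 0.5) / L
            dz = max(dz, -0.9)
            sxy = math.sqrt(1 - dz ** 2)
            xy = radial[:2] / max(np.linalg.norm(radial[:2]), 1e-12)
            radial = np.array([xy[0] * sxy, xy[1] * sxy, dz])
        origin = site + L * radial
        filaments.append(Filament(
            id=counter.next("nonazm"), class_label="non_azm",
            path=np.array([origin, site]),
            diameter=matched_truncnorm(cfg.non_azm_diameter, rng, low=0.5),
            attachments=[Attachment(1, "vesicle", ves.id)]))


def generate_resting_scene(config: SceneConfig) -> Scene:
    """A resting active-zone scene with the configured statistical structure."""
    config.validate()
    rngs = child_rngs(config.seed, _STAGES)
    lay, ves_rng, fil_rng = rngs["layout"], rngs["vesicles"], rngs["filaments"]
    warnings: list[str] = []
    counter = _Counter()

    step_y, beam_spans = _band_layout(config, lay)
    n_steps = len(step_y)
    if n_steps < 2:
        raise ValueError("band_length too short for two steps")

    filaments: list[Filament] = []
    beam_ids = []
    beam_z = config.beam_diameter.mean / 2.0
    for (y0, y1) in beam_spans:
        bid = counter.next("beam")
        prev = beam_ids[-1] if beam_ids else None
        atts = [Attachment(0, "filament", prev)] if prev else []
        filaments.append(Filament(
            id=bid, class_label="beam",
            path=np.array([[0.0, y0, beam_z], [0.0, y1, beam_z]]),
            diameter=matched_truncnorm(config.beam_diameter, lay, low=1.0),
            attachments=atts))
        beam_ids.append(bid)

    def _beam_for(y: float) -> str:
        for (span, bid) in zip(beam_spans, beam_ids):
            if span[0] <= y <= span[1]:
                return bid
        return beam_ids[-1]

    step_ids, mast_ids, step_zs, mast_tops = [], [], [], []
    beam_top = config.beam_diameter.mean
    for i, y in enumerate(step_y):
        dv = matched_truncnorm(config.step_diameter_vertical, lay, low=1.0)
        dh = matched_truncnorm(config.step_diameter_horizontal, lay, low=1.0)
        Ls = matched_truncnorm(config.step_length, lay, low=5.0)
        z_step = beam_top + dv / 2.0
        sid = counter.next("step")
        filaments.append(Filament(
            id=sid, class_label="step",
            path=np.array([[0.0, y - Ls / 2, z_step], [0.0, y + Ls / 2, z_step]]),
            diameter=dh, diameter_vertical=dv,
            attachments=[Attachment(0, "filament", _beam_for(y))]))
        step_ids.append(sid)
        step_zs.append(z_step)

        Lm = matched_truncnorm(config.mast_length, lay, low=5.0)
        base = z_step + dv / 2.0
        mid = counter.next("mast")
        filaments.append(Filament(
            id=mid, class_label="mast",
            path=np.array([[0.0, y, base], [0.0, y, base + Lm]]),
            diameter=matched_truncnorm(config.mast_diameter, lay, low=1.0),
            n_strands=int(lay.integers(config.mast_strands[0],
                                       config.mast_strands[1] + 1)),
            attachments=[Attachment(0, "filament", sid)]))
        mast_ids.append(mid)
        mast_tops.append(base + Lm)

    # per-mast boom totals (kept continuous; rounding happens per vesicle so
    # each docked vesicle's count is the rounded sum of its two flanking
    # masts' per-tetrad-member rates, drawn total / 4)
    bpm = config.booms_per_mast
    mast_boom_total = [max(fil_rng.normal(bpm.mean, bpm.sd), 0.0)
                       if bpm.sd > 0 else bpm.mean for _ in range(n_steps)]

    dlo, dhi = config.vesicle_diameter
    vesicles: list[Vesicle] = []
    docked_meta = []  # (vesicle, gap index)
    for g in range(n_steps - 1):
        ym = 0.5 * (step_y[g] + step_y[g + 1])
        for side, sign in (("left", -1.0), ("right", 1.0)):
            r = ves_rng.uniform(dlo, dhi) / 2.0
            v = Vesicle(id=f"v{g:03d}{side[0].upper()}",
                        center=np.array([sign * (config.band_half_width + r),
                                         ym, r]),
                        radius=r, state="docked", row_side=side)
            vesicles.append(v)
            docked_meta.append((v, g))

    for v, g in docked_meta:
        flank = (step_ids[g], step_ids[g + 1])
        masts = (mast_ids[g], mast_ids[g + 1])
        rate = (mast_boom_total[g] / 4.0, mast_boom_total[g + 1] / 4.0)
        _docked_wiring(filaments, v, config, fil_rng, counter, flank, masts,
                       rate, _beam_for(v.center[1]), beam_z,
                       step_zs[g], warnings)

    # topmasts: mast deep ends to undocked vesicles deep to the band
    for i, (mid, top) in enumerate(zip(mast_ids, mast_tops)):
        k_top = int(fil_rng.integers(config.topmasts_per_mast[0],
                                     config.topmasts_per_mast[1] + 1))
        for j in range(k_top):
            r = fil_rng.uniform(dlo, dhi) / 2.0
            dist = fil_rng.uniform(45.0, 75.0)
            center = np.array([fil_rng.uniform(-15.0, 15.0),
                               step_y[i] + fil_rng.uniform(-20.0, 20.0),
                               dist + r])
            uv = Vesicle(id=f"u{i:03d}t{j}", center=center, radius=r,
                         state="undocked")
            vesicles.append(uv)
            mast_top = np.array([0.0, step_y[i], top])
            d = center - mast_top
            site = center - r * d / np.linalg.norm(d)
            L = matched_truncnorm(config.topmast_length, fil_rng, low=2.0)
            u = (site - mast_top) / np.linalg.norm(site - mast_top)
            origin = site - L * u
            filaments.append(Filament(
                id=counter.next("topmast"), class_label="topmast",
                path=np.array([origin, site]),
                diameter=matched_truncnorm(config.topmast_diameter, fil_rng,
                                           low=0.5),
                attachments=[Attachment(0, "filament", mid),
                             Attachment(1, "vesicle", uv.id)]))

    scene = Scene(
        membrane=Membrane(extent_x=400.0, extent_y=config.band_length + 100.0),
        vesicles=vesicles, filaments=filaments,
        metadata={"mode": "resting", "seed": int(config.seed),
                  "config_hash": config.hash(),
                  "compression": {"ratio": 1.0}, "warnings": warnings})
    if config.compression_ratio < 1.0:
        scene = apply_z_compression(scene, config.compression_ratio)
    return scene


# ---------------------------------------------------------------------------
# activated scene
# ---------------------------------------------------------------------------

def _rule_for_distance(rules: tuple[BinRule, ...], d: float) -> BinRule | None:
    for r in rules:
        if r.bin[0] <= d <= r.bin[1]:
            return r
    return None


def _undocked_wiring(filaments: list[Filament], ves: Vesicle, rule: BinRule,
                     cfg: SceneConfig, rng: np.random.Generator,
                     counter: _Counter, flank_steps, flank_masts,
                     beam_id: str, beam_z: float, step_z: float,
                     warnings: list[str]) -> None:
    """Wire one undocked vesicle at a vacated site per its distance-bin rule."""
    from .config import CountDist

    sx = 1.0 if ves.center[0] < 0 else -1.0
    az_facing = 0.0 if ves.center[0] < 0 else math.pi
    az_away = az_facing + math.pi
    cz, r = ves.center[2], ves.radius
    dist = cz - r
    top = cz + r - 0.5

    k_rib = rounded_count(CountDist(rule.ribs.mean, rule.ribs.sd, min=0), rng)
    rib_depths = (dist + np.atleast_1d(
        matched_truncnorm(cfg.rib_site_depth, rng, size=k_rib, low=0.5))
        if k_rib else np.array([]))
    azs = _spread_azimuths(max(k_rib, 1), az_facing, math.radians(70), rng)
    for j in range(k_rib):
        site = _site_on_sphere(ves.center, r, float(rib_depths[j]), float(azs[j]))
        filaments.append(_filament_to_site(
            counter.next("rib"), "rib", site,
            matched_truncnorm(cfg.rib_angle, rng, high=90.0),
            matched_truncnorm(cfg.rib_length, rng, low=1.0), beam_z, -sx,
            matched_truncnorm(cfg.rib_diameter, rng, low=0.5), rng,
            ves.id, "filament", beam_id))
    rib_centroid = (float(np.mean(rib_depths)) if k_rib
                    else dist + cfg.rib_site_depth.mean)

    k_spar = rounded_count(CountDist(rule.spars.mean, rule.spars.sd, min=0), rng)
    azs = _spread_azimuths(max(k_spar, 1), az_facing, math.radians(60), rng)
    for j in range(k_spar):
        depth = min(rib_centroid + matched_truncnorm(cfg.spar_site_offset, rng),
                    top)
        site = _site_on_sphere(ves.center, r, depth, float(azs[j % len(azs)]))
        filaments.append(_filament_to_site(
            counter.next("spar"), "spar", site,
            matched_truncnorm(cfg.spar_angle, rng, high=90.0),
            matched_truncnorm(cfg.spar_length, rng, low=1.0), step_z, -sx,
            matched_truncnorm(cfg.spar_diameter, rng, low=0.5), rng,
            ves.id, "filament", flank_steps[j % 2]))

    k_boom = rounded_count(CountDist(rule.booms.mean, rule.booms.sd, min=0), rng)
    azs = _spread_azimuths(max(k_boom, 1), az_facing, math.radians(65), rng)
    clipped = 0
    for j in range(k_boom):
        depth = rib_centroid + matched_truncnorm(cfg.boom_site_offset, rng)
        if depth > top:
            depth = top
            clipped += 1
        site = _site_on_sphere(ves.center, r, depth, float(azs[j % len(azs)]))
        origin_z = matched_truncnorm(cfg.boom_origin_height, rng, low=1.0)
        filaments.append(_filament_to_site(
            counter.next("boom"), "boom", site,
            matched_truncnorm(cfg.boom_angle, rng, high=90.0),
            matched_truncnorm(cfg.boom_length, rng, low=1.0), origin_z, -sx,
            matched_truncnorm(cfg.boom_diameter, rng, low=0.5), rng,
            ves.id, "filament", flank_masts[j % 2]))
    if clipped:
        warnings.append(f"{ves.id}: {clipped} boom site depth(s) clipped")

    # pins reach only vesicles close to the membrane; their length grows with
    # the vesicle's distance (length = distance + nonnegative offset whose
    # mean reproduces the configured marginal mean)
    if rule.pins_present and dist <= cfg.pin_reach:
        lo = rule.bin[0]
        expected_d = 0.5 * (lo + min(cfg.pin_reach, rule.bin[1]))
        off_mean = max(cfg.undocked_pin_length.mean - expected_d, 0.5)
        var_d = (min(cfg.pin_reach, rule.bin[1]) - lo) ** 2 / 12.0
        off_sd = math.sqrt(max(cfg.undocked_pin_length.sd ** 2 - var_d, 0.25))
        k_pin = rounded_count(cfg.undocked_pins_per_vesicle, rng)
        azs = _spread_azimuths(max(k_pin, 1), az_away, math.radians(70), rng)
        for j in range(k_pin):
            from .config import Dist
            L = dist + matched_truncnorm(Dist(off_mean, off_sd), rng, low=0.0)
            alpha = rng.uniform(0.0, math.radians(30.0))
            z_s = cz - r * math.cos(alpha)
            z_s = min(z_s, L)  # the membrane anchor must be reachable
            site = _site_on_sphere(ves.center, r, z_s, float(azs[j]))
            h = math.sqrt(max(L ** 2 - z_s ** 2, 0.0))
            u = np.array([math.cos(azs[j]), math.sin(azs[j]), 0.0])
            origin = site - h * u
            origin[2] = 0.0
            filaments.append(Filament(
                id=counter.next("pin"), class_label="pin",
                path=np.array([origin, site]),
                diameter=matched_truncnorm(cfg.pin_diameter, rng, low=0.5),
                attachments=[Attachment(0, "membrane", None),
                             Attachment(1, "vesicle", ves.id)]))


def generate_activated_scene(config: SceneConfig) -> Scene:
    """An activated-terminal scene: vacated docking sites re-occupied by
    undocked vesicles wired per the distance-bin connectivity rules."""
    config.validate()
    scene = generate_resting_scene(config)
    rng = child_rngs(config.seed, _STAGES)["activated"]
    warnings = scene.metadata.setdefault("warnings", [])
    counter = _Counter()
    counter.n = 100000  # disjoint id space from the resting pass

    docked = [v for v in scene.vesicles if v.state == "docked"]
    n_vac = int(round(config.vacated_fraction * len(docked)))
    if n_vac == 0:
        scene.metadata["mode"] = "activated"
        return scene
    vac_idx = rng.choice(len(docked), size=n_vac, replace=False)
    vacated = [docked[i] for i in sorted(vac_idx)]

    # rebuild lookup of each docked vesicle's flanking structures
    step_fils = scene.filaments_of_class("step")
    mast_fils = scene.filaments_of_class("mast")
    beam_fils = scene.filaments_of_class("beam")
    step_fils.sort(key=lambda f: f.path[:, 1].mean())
    mast_fils.sort(key=lambda f: f.path[:, 1].mean())
    step_y = np.array([f.path[:, 1].mean() for f in step_fils])
    beam_z = float(np.mean([f.path[0, 2] for f in beam_fils]))

    def _flanks(y: float):
        g = int(np.searchsorted(step_y, y)) - 1
        g = max(0, min(g, len(step_fils) - 2))
        return ((step_fils[g].id, step_fils[g + 1].id),
                (mast_fils[g].id, mast_fils[g + 1].id),
                float(step_fils[g].path[0, 2]))

    def _beam_for(y: float) -> str:
        for f in beam_fils:
            if f.path[0, 1] <= y <= f.path[-1, 1]:
                return f.id
        return beam_fils[-1].id

    fused_id = None
    rules_near_first = sorted(config.bin_rules, key=lambda r: r.bin[0])
    replaced = []
    for k, old in enumerate(vacated):
        # strip the former docked vesicle and everything bound to it
        scene.filaments = [f for f in scene.filaments
                           if not any(a.kind == "vesicle" and a.target == old.id
                                      for a in f.attachments)]
        scene.vesicles = [v for v in scene.vesicles if v.id != old.id]
        flank_steps, flank_masts, step_z = _flanks(old.center[1])
        bid = _beam_for(old.center[1])

        if config.include_fused_omega and fused_id is None:
            # one former docked vesicle caught mid-fusion, its main-body
            # complement still attached
            fv = Vesicle(id=f"omega{k}", center=old.center.copy(),
                         radius=old.radius, state="fused_omega",
                         row_side=old.row_side)
            scene.vesicles.append(fv)
            rate = (config.booms_per_mast.mean / 4.0,
                    config.booms_per_mast.mean / 4.0)
            _docked_wiring(scene.filaments, fv, config, rng, counter,
                           flank_steps, flank_masts, rate, bid, beam_z,
                           step_z, warnings, with_pins=False)
            fused_id = fv.id
            continue

        rule = rules_near_first[len(replaced) % len(rules_near_first)]
        lo, hi = rule.bin
        glo, ghi = config.undocked_distance_range
        d = rng.uniform(max(lo, glo), min(hi, ghi))
        r = rng.uniform(*config.vesicle_diameter) / 2.0
        nv = Vesicle(id=f"r{k:03d}", center=np.array([old.center[0],
                                                      old.center[1], d + r]),
                     radius=r, state="undocked", row_side=old.row_side)
        scene.vesicles.append(nv)
        _undocked_wiring(scene.filaments, nv, rule, config, rng, counter,
                         flank_steps, flank_masts, bid, beam_z, step_z,
                         warnings)
        replaced.append(nv.id)

    scene.metadata["mode"] = "activated"
    scene.metadata["replacement_vesicles"] = replaced
    scene.metadata["fused_omega"] = fused_id
    return scene


# ---------------------------------------------------------------------------
# artificial z-compression
# ---------------------------------------------------------------------------

def apply_z_compression(scene: Scene, ratio: float) -> Scene:
    """Scale all z coordinates by ``ratio``; vesicles become oblate.

    Emulates specimen thinning along the section depth axis: every z
    coordinate is multiplied by ``ratio`` and each vesicle stores a separate
    z semi-axis ``radius * ratio`` (its x-y radius is untouched).
    """
    if not 0 < ratio <= 1:
        raise ValueError(f"compression ratio {ratio} outside (0, 1]")
    out = copy.deepcopy(scene)
    if ratio == 1.0:
        return out
    for v in out.vesicles:
        v.center[2] *= ratio
        v.z_semi_axis = v.z_semi * ratio
    for f in out.filaments:
        f.path[:, 2] *= ratio
    comp = out.metadata.setdefault("compression", {"ratio": 1.0})
    comp["ratio"] = comp.get("ratio", 1.0) * ratio
    return out
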