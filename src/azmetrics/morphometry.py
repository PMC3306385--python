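"""Measurement operators applied to active-zone scenes.

These reproduce the measurement protocols used on tomographic
reconstructions: polyline arc lengths for filament dimensions,
center-to-center step spacing along the band, in-horizontal-plane angles
of approach to docked vesicles, per-vesicle connection counts, pin
lengths grouped by the bound vesicle's docking state, and the z-axis
compression estimate / stretch correction for anisotropic specimen
shrinkage.  All summary SDs are sample SDs (n-1 denominator).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scene import (MAIN_BODY_CLASSES, Filament, Scene, SceneError,
                    UndefinedAngleError)


#: the eight AZM macromolecule classes of the class-dimension summary table
TABLE1_CLASSES = ("beam", "step", "mast", "rib", "pin", "spar", "boom",
                  "topmast")


@dataclass
class GroupStats:
    """Mean / sample SD / n for one pooled group, with the raw values."""

    mean: float
    sd: float
    n: int
    values: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))

    @classmethod
    def of(cls, values) -> "GroupStats":
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            return cls(math.nan, math.nan, 0, v)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else math.nan
        return cls(float(np.mean(v)), sd, int(v.size), v)


def filament_length(filament: Filament) -> float:
    """Arc length (nm) of the filament's polyline path."""
    if len(filament.path) < 2:
        raise SceneError(f"filament {filament.id}: degenerate path")
    return float(np.linalg.norm(np.diff(filament.path, axis=0), axis=1).sum())


def step_center_spacing(scene: Scene) -> list[float]:
    """Distances between consecutive step centroids along the band axis."""
    steps = scene.filaments_of_class("step")
    if len(steps) < 2:
        return []
    cents = np.array([f.path.mean(axis=0) for f in steps])
    order = np.argsort(cents @ scene.azm_axis)
    cents = cents[order]
    return [float(np.linalg.norm(b - a)) for a, b in zip(cents, cents[1:])]


def angle_of_approach(filament: Filament, scene: Scene) -> float:
    """Unsigned in-plane angle (degrees, [0, 90]) of approach to a vesicle.

    The filament's long-axis direction (non-vesicle endpoint toward the
    vesicle-bound endpoint) is projected onto the horizontal x-y plane; the
    result is the angle between that projection and the perpendicular to
    the band axis.
    """
    att = filament.vesicle_attachment()
    if att is None:
        raise SceneError(f"filament {filament.id} has no vesicle endpoint")
    tip = filament.path[-1] if att.endpoint == 1 else filament.path[0]
    tail = filament.path[0] if att.endpoint == 1 else filament.path[-1]
    d = tip - tail
    axis = scene.azm_axis / np.linalg.norm(scene.azm_axis)
    # in-plane components along and across the band
    along = float(d @ axis)
    perp_dir = np.array([axis[1], -axis[0], 0.0])  # horizontal perpendicular
    across = float(d @ perp_dir)
    h = math.hypot(along, across)
    if h < 1e-12:
        raise UndefinedAngleError(
            f"filament {filament.id}: vertical filament, projected direction "
            "has zero length")
    return math.degrees(math.atan2(abs(along), abs(across)))


def connection_counts(scene: Scene) -> pd.DataFrame:
    """Per-vesicle per-class connection counts.

    One row per vesicle: counts of rib/spar/boom/pin/topmast/non-AZM
    connections, the main-body total (rib+spar+boom), the vesicle state and
    its shortest membrane distance.
    """
    from .scene import shortest_distance_to_membrane

    classes = ["rib", "spar", "boom", "pin", "topmast", "non_azm"]
    rows = {v.id: dict.fromkeys(classes, 0) for v in scene.vesicles}
    for s in scene.connection_sites:
        if s.class_label in classes and s.vesicle_id in rows:
            rows[s.vesicle_id][s.class_label] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "vesicle_id"
    df["main_body_total"] = df[list(MAIN_BODY_CLASSES)].sum(axis=1)
    df["state"] = [v.state for v in scene.vesicles]
    df["membrane_distance"] = [shortest_distance_to_membrane(v)
                               for v in scene.vesicles]
    return df


def pin_length_by_state(scene: Scene) -> dict[str, GroupStats]:
    """Pin arc lengths grouped by the bound vesicle's docking state."""
    groups: dict[str, list[float]] = {}
    vindex = {v.id: v for v in scene.vesicles}
    for f in scene.filaments_of_class("pin"):
        att = f.vesicle_attachment()
        if att is None or att.target not in vindex:
            continue
        groups.setdefault(vindex[att.target].state, []).append(
            filament_length(f))
    return {state: GroupStats.of(v) for state, v in groups.items()}


# ---------------------------------------------------------------------------
# z-compression handling
# ---------------------------------------------------------------------------

def estimate_compression_ratio(scene: Scene) -> GroupStats:
    """Mean over vesicles of z-diameter / x-y diameter (1.0 = isotropic)."""
    if not scene.vesicles:
        raise SceneError("no vesicles to estimate compression from")
    ratios = [v.z_semi / v.radius for v in scene.vesicles]
    return GroupStats.of(ratios)


def z_stretch_correct(scene: Scene, factor: float) -> Scene:
    """Multiply all z coordinates (and vesicle z semi-axes) by ``factor``.

    The protocol on reconstructions whose vesicles show z-axis flattening
    applies a fixed stretch factor of 1.2 along z; here the factor is an
    argument so an exact inverse (1/ratio) can also be applied.
    """
    if factor <= 0:
        raise ValueError(f"stretch factor must be positive, got {factor}")
    out = copy.deepcopy(scene)
    if factor == 1.0:
        return out
    for v in out.vesicles:
        z = v.z_semi * factor
        v.center[2] *= factor
        v.z_semi_axis = None if abs(z - v.radius) < 1e-9 else z
    for f in out.filaments:
        f.path[:, 2] *= factor
    comp = out.metadata.setdefault("compression", {"ratio": 1.0})
    comp["ratio"] = comp.get("ratio", 1.0) * factor
    comp["stretch_applied"] = comp.get("stretch_applied", 1.0) * factor
    return out


# ---------------------------------------------------------------------------
# scene summary
# ---------------------------------------------------------------------------

def class_dimension_table(scenes: list[Scene]) -> pd.DataFrame:
    """Per-class length and diameter mean/SD/n pooled over scenes.

    Mirrors the layout of a class-dimension summary table: one row per
    filament class, lengths measured as polyline arc length, diameters read
    from the diameter attribute (steps report horizontal and vertical
    separately).
    """
    lengths: dict[str, list[float]] = {}
    diams: dict[str, list[float]] = {}
    for scene in scenes:
        for f in scene.filaments:
            lengths.setdefault(f.class_label, []).append(filament_length(f))
            diams.setdefault(f.class_label, []).append(f.diameter)
            if f.class_label == "step" and f.diameter_vertical is not None:
                diams.setdefault("step_vertical", []).append(f.diameter_vertical)
    rows = []
    for cls in sorted(set(lengths) | set(diams)):
        ln = GroupStats.of(lengths.get(cls, []))
        dm = GroupStats.of(diams.get(cls, []))
        rows.append({"class": cls, "length_mean": ln.mean, "length_sd": ln.sd,
                     "length_n": ln.n, "diameter_mean": dm.mean,
                     "diameter_sd": dm.sd, "diameter_n": dm.n})
    return pd.DataFrame(rows).set_index("class")


def angle_table(scenes: list[Scene],
                classes: tuple[str, ...] = MAIN_BODY_CLASSES) -> pd.DataFrame:
    """Pooled approach angles per class over the given scenes."""
    pooled: dict[str, list[float]] = {c: [] for c in classes}
    for scene in scenes:
        for f in scene.filaments:
            if f.class_label in pooled and f.vesicle_attachment() is not None:
                pooled[f.class_label].append(angle_of_approach(f, scene))
    rows = []
    for cls, vals in pooled.items():
        g = GroupStats.of(vals)
        rows.append({"class": cls, "angle_mean": g.mean, "angle_sd": g.sd,
                     "n": g.n})
    return pd.DataFrame(rows).set_index("class")


def summarize_scenes(scenes: list[Scene]) -> dict[str, pd.DataFrame]:
    """Full morphometry bundle for a pool of scenes."""
    spacings = [s for sc in scenes for s in step_center_spacing(sc)]
    sp = GroupStats.of(spacings)
    counts = pd.concat([connection_counts(sc).assign(
        scene=sc.metadata.get("seed")) for sc in scenes])
    pins: dict[str, list[float]] = {}
    for sc in scenes:
        for state, g in pin_length_by_state(sc).items():
            pins.setdefault(state, []).extend(g.values.tolist())
    pin_df = pd.DataFrame([
        {"state": st, "length_mean": g.mean, "length_sd": g.sd, "n": g.n}
        for st, g in ((st, GroupStats.of(v)) for st, v in pins.items())
    ])
    return {
        "dimensions": class_dimension_table(scenes),
        "angles": angle_table(scenes),
        "step_spacing": pd.DataFrame(
            [{"spacing_mean": sp.mean, "spacing_sd": sp.sd, "n": sp.n}]),
        "connection_counts": counts,
        "pin_lengths": pin_df.set_index("state") if len(pin_df) else pin_df,
    }
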