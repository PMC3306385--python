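"""Domain types and elementary geometry for active-zone scenes.

An active zone is modeled in a fixed coordinate frame: the presynaptic
membrane is the plane ``z = 0`` with the cytoplasm at ``z > 0``, the long
axis of the band of active zone material (AZM) runs along ``+y``, and the
transverse axis is ``x``.  All coordinates are nanometers, double precision.

A scene holds a flat membrane, spherical (or, after z-compression,
oblate) synaptic vesicles, and classed polyline filaments.  Connection
sites -- the points where a filament terminates on a vesicle surface --
are *derived* from filament attachments, never stored independently:
there is exactly one site per (filament endpoint, vesicle) binding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

#: Tolerance (nm) for "endpoint lies on the vesicle surface" checks.
SURFACE_TOL = 0.5
#: Tolerance (nm) for "docked vesicle contacts the membrane" checks.
CONTACT_TOL = 0.5

FILAMENT_CLASSES = (
    "beam", "step", "mast", "rib", "spar", "boom", "topmast", "pin", "non_azm"
)
VESICLE_STATES = ("docked", "undocked", "fused_omega", "vacated_marker")
#: Classes whose vesicle connections form the "main body" total.
MAIN_BODY_CLASSES = ("rib", "spar", "boom")


class SceneError(ValueError):
    """Base class for scene-domain errors."""


class CoordinateConventionError(SceneError):
    """A coordinate violates the membrane-at-z=0, cytoplasm-at-+z convention."""


class UndefinedAngleError(SceneError):
    """Raised when a projected filament direction has zero length."""


@dataclass
class Membrane:
    """The presynaptic membrane: the plane z = 0 with a finite lateral extent."""

    extent_x: float = 200.0
    extent_y: float = 1000.0
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)


@dataclass
class Vesicle:
    """A synaptic vesicle: a sphere (oblate spheroid once z-compressed).

    ``z_semi_axis`` is ``None`` for a spherical vesicle; after artificial
    z-compression it stores the semi-axis along z while ``radius`` keeps
    the x-y semi-axis.
    """

    id: str
    center: np.ndarray
    radius: float
    state: str = "undocked"
    row_side: str = "none"
    z_semi_axis: Optional[float] = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)

    @property
    def z_semi(self) -> float:
        return self.radius if self.z_semi_axis is None else self.z_semi_axis

    def surface_deviation(self, point: np.ndarray) -> float:
        """Approximate signed distance (nm) of ``point`` from the surface."""
        d = np.asarray(point, dtype=float) - self.center
        if self.z_semi_axis is None:
            return float(np.linalg.norm(d) - self.radius)
        s = np.sqrt((d[0] / self.radius) ** 2 + (d[1] / self.radius) ** 2
                    + (d[2] / self.z_semi) ** 2)
        return float((s - 1.0) * min(self.radius, self.z_semi))


@dataclass
class Attachment:
    """Binding of one filament endpoint to a vesicle, a filament or the membrane.

    ``endpoint`` indexes the bound path end: 0 for the first path point,
    1 for the last.  ``target`` is the bound entity's id (``None`` for the
    membrane).
    """

    endpoint: int
    kind: str  # "vesicle" | "filament" | "membrane"
    target: Optional[str] = None


@dataclass
class Filament:
    """A classed polyline along a macromolecule's long axis.

    ``diameter`` is the class diameter attribute; steps additionally carry
    ``diameter_vertical`` (their cross-section is elongate in the horizontal
    plane).  Masts carry ``n_strands``, the number of serpentine strands
    they are composed of.
    """

    id: str
    class_label: str
    path: np.ndarray  # (n, 3), n >= 2
    diameter: float
    attachments: list[Attachment] = field(default_factory=list)
    diameter_vertical: Optional[float] = None
    n_strands: Optional[int] = None

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float)

    def endpoint(self, which: int) -> np.ndarray:
        return self.path[0] if which == 0 else self.path[-1]

    def vesicle_attachment(self) -> Optional[Attachment]:
        for a in self.attachments:
            if a.kind == "vesicle":
                return a
        return None


@dataclass
class ConnectionSite:
    """A labeled point on a vesicle surface where a filament terminates."""

    vesicle_id: str
    filament_id: str
    class_label: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class Violation:
    """One invariant violation found by :func:`validate_scene`."""

    entity_kind: str
    entity_id: str
    invariant: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.entity_kind} {self.entity_id}: {self.invariant} ({self.detail})"


@dataclass
class Scene:
    """A complete 3-D active zone in nm coordinates."""

    membrane: Membrane
    vesicles: list[Vesicle]
    filaments: list[Filament]
    azm_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.azm_axis = np.asarray(self.azm_axis, dtype=float)

    # -- lookups ---------------------------------------------------------
    def vesicle_by_id(self, vid: str) -> Vesicle:
        return self._vesicle_index()[vid]

    def filament_by_id(self, fid: str) -> Filament:
        return {f.id: f for f in self.filaments}[fid]

    def _vesicle_index(self) -> dict[str, Vesicle]:
        return {v.id: v for v in self.vesicles}

    def vesicles_in_state(self, state: str) -> list[Vesicle]:
        return [v for v in self.vesicles if v.state == state]

    def filaments_of_class(self, class_label: str) -> list[Filament]:
        return [f for f in self.filaments if f.class_label == class_label]

    # -- derived data ----------------------------------------------------
    @property
    def connection_sites(self) -> list[ConnectionSite]:
        """Sites derived bijectively from vesicle-bound filament endpoints."""
        sites = []
        for fil in self.filaments:
            for att in fil.attachments:
                if att.kind == "vesicle":
                    sites.append(ConnectionSite(
                        vesicle_id=att.target,
                        filament_id=fil.id,
                        class_label=fil.class_label,
                        position=fil.endpoint(att.endpoint).copy(),
                    ))
        return sites

    def sites_for_vesicle(self, vid: str) -> list[ConnectionSite]:
        return [s for s in self.connection_sites if s.vesicle_id == vid]


def shortest_distance_to_membrane(vesicle: Vesicle,
                                  membrane: Optional[Membrane] = None) -> float:
    """Shortest distance (nm) from the vesicle membrane to the presynaptic membrane.

    With the membrane at z = 0 this is ``max(center_z - z_semi_axis, 0)``;
    0 means the vesicle touches or interpenetrates the membrane.  A negative
    center z violates the coordinate convention.
    """
    cz = float(vesicle.center[2])
    if cz < 0:
        raise CoordinateConventionError(
            f"vesicle {vesicle.id}: center z = {cz} < 0 (cytoplasm is +z)")
    return max(cz - vesicle.z_semi, 0.0)


def validate_scene(scene: Scene,
                   surface_tol: float = SURFACE_TOL,
                   contact_tol: float = CONTACT_TOL) -> list[Violation]:
    """Check every type invariant; violations are returned as data, not raised."""
    out: list[Violation] = []
    mem = scene.membrane

    if abs(np.linalg.norm(mem.normal) - 1.0) > 1e-9:
        out.append(Violation("membrane", "membrane", "unit_normal",
                             f"norm={np.linalg.norm(mem.normal)}"))
    if mem.extent_x <= 0 or mem.extent_y <= 0:
        out.append(Violation("membrane", "membrane", "positive_extent",
                             f"{mem.extent_x} x {mem.extent_y}"))

    vindex = scene._vesicle_index()
    findex = {f.id: f for f in scene.filaments}

    seen_vids = set()
    for v in scene.vesicles:
        if v.id in seen_vids:
            out.append(Violation("vesicle", v.id, "unique_id"))
        seen_vids.add(v.id)
        if v.radius <= 0:
            out.append(Violation("vesicle", v.id, "positive_radius",
                                 f"radius={v.radius}"))
            continue
        if v.state not in VESICLE_STATES:
            out.append(Violation("vesicle", v.id, "known_state", v.state))
        cz = float(v.center[2])
        if v.state == "docked" and abs(cz - v.z_semi) > contact_tol:
            out.append(Violation("vesicle", v.id, "docked_contact",
                                 f"center z={cz}, z semi-axis={v.z_semi}"))
        if v.state == "undocked" and cz <= v.z_semi:
            out.append(Violation("vesicle", v.id, "undocked_clearance",
                                 f"center z={cz}, z semi-axis={v.z_semi}"))

    for f in scene.filaments:
        if f.class_label not in FILAMENT_CLASSES:
            out.append(Violation("filament", f.id, "known_class", f.class_label))
        if len(f.path) < 2:
            out.append(Violation("filament", f.id, "path_min_points",
                                 f"{len(f.path)} points"))
            continue
        seglens = np.linalg.norm(np.diff(f.path, axis=0), axis=1)
        if np.any(seglens == 0):
            out.append(Violation("filament", f.id, "distinct_path_points"))
        if f.diameter <= 0:
            out.append(Violation("filament", f.id, "positive_diameter",
                                 f"diameter={f.diameter}"))
        for a in f.attachments:
            p = f.endpoint(a.endpoint)
            if a.kind == "vesicle":
                ves = vindex.get(a.target)
                if ves is None:
                    out.append(Violation("filament", f.id, "vesicle_exists",
                                         f"missing vesicle {a.target}"))
                elif abs(ves.surface_deviation(p)) > surface_tol:
                    out.append(Violation(
                        "filament", f.id, "endpoint_on_vesicle_surface",
                        f"vesicle {a.target}, deviation "
                        f"{ves.surface_deviation(p):.3f} nm"))
            elif a.kind == "membrane":
                if abs(p[2]) > surface_tol:
                    out.append(Violation("filament", f.id, "endpoint_on_membrane",
                                         f"z={p[2]:.3f}"))
            elif a.kind == "filament":
                if a.target not in findex:
                    out.append(Violation("filament", f.id, "filament_exists",
                                         f"missing filament {a.target}"))
            else:
                out.append(Violation("filament", f.id, "known_attachment_kind",
                                     a.kind))

    # conservation: one site per (filament endpoint, vesicle) binding
    n_bindings = sum(1 for f in scene.filaments
                     for a in f.attachments if a.kind == "vesicle")
    sites = scene.connection_sites
    if len(sites) != n_bindings:
        out.append(Violation("scene", "scene", "site_binding_bijection",
                             f"{len(sites)} sites vs {n_bindings} bindings"))
    for s in sites:
        if s.vesicle_id not in vindex:
            out.append(Violation("connection_site", s.filament_id,
                                 "vesicle_exists", s.vesicle_id))

    if abs(np.linalg.norm(scene.azm_axis) - 1.0) > 1e-9:
        out.append(Violation("scene", "scene", "unit_azm_axis"))
    return out
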