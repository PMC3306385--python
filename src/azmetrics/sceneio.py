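"""Scene JSON serialization with structural validation and run manifests.

The scene file format is a versioned JSON document whose field names match
the domain types.  Writing is canonical -- sorted keys and fixed 6-decimal
float formatting -- so identical scenes serialize byte-identically.
Connection sites are stored for completeness but are re-derived and
cross-checked on read (they are a derived quantity).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scene import (Attachment, Filament, Membrane, Scene, Vesicle,
                    validate_scene)

SCHEMA_VERSION = "1.0"
_FLOAT_DECIMALS = 6


class SceneParseError(ValueError):
    """The file is not valid JSON."""


class SceneSchemaError(ValueError):
    """The JSON does not match the scene schema (missing/unknown fields)."""


class SceneVersionError(ValueError):
    """The file declares an unsupported schema version."""


class SceneReferenceError(ValueError):
    """An entity references a missing vesicle or filament id."""


class InvalidSceneError(ValueError):
    """Refusal to serialize a scene that fails validation."""


# ---------------------------------------------------------------------------
# canonical JSON
# ---------------------------------------------------------------------------

def _canonical(obj):
    if isinstance(obj, float):
        v = round(obj, _FLOAT_DECIMALS)
        return 0.0 if v == 0 else v  # avoid -0.0 vs 0.0 instability
    if isinstance(obj, (np.floating,)):
        return _canonical(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_canonical(x) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {k: _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    return obj


def dumps_canonical(data: dict) -> str:
    return json.dumps(_canonical(data), sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# scene <-> dict
# ---------------------------------------------------------------------------

def scene_to_dict(scene: Scene) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "membrane": {"extent_x": scene.membrane.extent_x,
                     "extent_y": scene.membrane.extent_y,
                     "normal": scene.membrane.normal},
        "azm_axis": scene.azm_axis,
        "vesicles": [{
            "id": v.id, "center": v.center, "radius": v.radius,
            "state": v.state, "row_side": v.row_side,
            "z_semi_axis": v.z_semi_axis,
        } for v in scene.vesicles],
        "filaments": [{
            "id": f.id, "class_label": f.class_label, "path": f.path,
            "diameter": f.diameter, "diameter_vertical": f.diameter_vertical,
            "n_strands": f.n_strands,
            "attachments": [{"endpoint": a.endpoint, "kind": a.kind,
                             "target": a.target} for a in f.attachments],
        } for f in scene.filaments],
        "connection_sites": [{
            "vesicle_id": s.vesicle_id, "filament_id": s.filament_id,
            "class_label": s.class_label, "position": s.position,
        } for s in scene.connection_sites],
        "metadata": scene.metadata,
    }


_TOP_FIELDS = {"schema_version", "membrane", "azm_axis", "vesicles",
               "filaments", "connection_sites", "metadata"}
_VES_FIELDS = {"id", "center", "radius", "state", "row_side", "z_semi_axis"}
_FIL_FIELDS = {"id", "class_label", "path", "diameter", "diameter_vertical",
               "n_strands", "attachments"}


def _check_fields(d: dict, allowed: set, required: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise SceneSchemaError(f"{where}: unknown fields {sorted(unknown)}")
    missing = required - set(d)
    if missing:
        raise SceneSchemaError(f"{where}: missing fields {sorted(missing)}")


def scene_from_dict(data: dict) -> Scene:
    if not isinstance(data, dict):
        raise SceneSchemaError("top level is not an object")
    _check_fields(data, _TOP_FIELDS,
                  {"schema_version", "membrane", "vesicles", "filaments"},
                  "scene")
    if data["schema_version"] != SCHEMA_VERSION:
        raise SceneVersionError(
            f"schema version {data['schema_version']!r}, "
            f"expected {SCHEMA_VERSION!r}")

    mem = data["membrane"]
    _check_fields(mem, {"extent_x", "extent_y", "normal"},
                  {"extent_x", "extent_y"}, "membrane")
    membrane = Membrane(extent_x=mem["extent_x"], extent_y=mem["extent_y"],
                        normal=np.asarray(mem.get("normal", [0, 0, 1.0]),
                                          dtype=float))
    vesicles = []
    for vd in data["vesicles"]:
        _check_fields(vd, _VES_FIELDS, {"id", "center", "radius", "state"},
                      f"vesicle {vd.get('id')}")
        vesicles.append(Vesicle(
            id=vd["id"], center=np.asarray(vd["center"], dtype=float),
            radius=float(vd["radius"]), state=vd["state"],
            row_side=vd.get("row_side", "none"),
            z_semi_axis=vd.get("z_semi_axis")))
    filaments = []
    for fd in data["filaments"]:
        _check_fields(fd, _FIL_FIELDS,
                      {"id", "class_label", "path", "diameter"},
                      f"filament {fd.get('id')}")
        atts = [Attachment(endpoint=int(a["endpoint"]), kind=a["kind"],
                           target=a.get("target"))
                for a in fd.get("attachments", [])]
        filaments.append(Filament(
            id=fd["id"], class_label=fd["class_label"],
            path=np.asarray(fd["path"], dtype=float),
            diameter=float(fd["diameter"]),
            diameter_vertical=fd.get("diameter_vertical"),
            n_strands=fd.get("n_strands"), attachments=atts))

    scene = Scene(membrane=membrane, vesicles=vesicles, filaments=filaments,
                  azm_axis=np.asarray(data.get("azm_axis", [0, 1.0, 0]),
                                      dtype=float),
                  metadata=data.get("metadata", {}))

    # referential integrity
    vids = {v.id for v in vesicles}
    fids = {f.id for f in filaments}
    for f in filaments:
        for a in f.attachments:
            if a.kind == "vesicle" and a.target not in vids:
                raise SceneReferenceError(
                    f"filament {f.id} references missing vesicle {a.target}")
            if a.kind == "filament" and a.target not in fids:
                raise SceneReferenceError(
                    f"filament {f.id} references missing filament {a.target}")
    # connection sites, if present, must match the derived set
    if "connection_sites" in data:
        stored = {(s["vesicle_id"], s["filament_id"])
                  for s in data["connection_sites"]}
        derived = {(s.vesicle_id, s.filament_id)
                   for s in scene.connection_sites}
        if stored != derived:
            raise SceneSchemaError(
                "stored connection sites do not match the vesicle-bound "
                "filament endpoints")
    return scene


# ---------------------------------------------------------------------------
# files
# ---------------------------------------------------------------------------

def write_scene(scene: Scene, path) -> None:
    """Canonical write; refuses a scene that fails validation."""
    violations = validate_scene(scene)
    if violations:
        raise InvalidSceneError(
            "refusing to write invalid scene:\n  "
            + "\n  ".join(str(v) for v in violations))
    Path(path).write_text(dumps_canonical(scene_to_dict(scene)) + "\n")


def read_scene(path) -> Scene:
    raw = Path(path).read_text()
    try:
        data = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise SceneParseError(f"{path}: {exc}") from exc
    return scene_from_dict(data)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# run manifest and CSV report bundle
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    master_seed: int
    child_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    timestamp: str = ""

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, indent=1)


def run_report(scene: Scene, outdir, seed: int | None = None) -> RunManifest:
    """Emit the morphometry summary, centroid depths and bin profiles as
    CSVs plus a manifest.  Timestamp excluded from output digests."""
    from . import __version__
    from .connectivity import bin_undocked, binned_profile
    from .morphometry import summarize_scenes
    from .sphere_align import class_centroid_depths

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = summarize_scenes([scene])
    written = {}

    def _write(name, df):
        p = outdir / name
        df.to_csv(p, float_format="%.6f")
        written[name] = file_digest(p)

    _write("dimensions.csv", summary["dimensions"])
    from .morphometry import TABLE1_CLASSES
    dims = summary["dimensions"]
    _write("table1.csv", dims.loc[[c for c in TABLE1_CLASSES if c in
                                   dims.index]])
    _write("angles.csv", summary["angles"])
    _write("step_spacing.csv", summary["step_spacing"])
    _write("connection_counts.csv", summary["connection_counts"])
    if len(summary["pin_lengths"]):
        _write("pin_lengths.csv", summary["pin_lengths"])

    depths = class_centroid_depths(scene)
    if depths.rib_depth.n:
        rows = [{"class": "rib", "depth_mean": depths.rib_depth.mean,
                 "depth_sd": depths.rib_depth.sd, "n": depths.rib_depth.n,
                 "offset_mean": 0.0, "offset_sd": 0.0}]
        for cls, g in depths.offsets.items():
            rows.append({"class": cls, "depth_mean": float("nan"),
                         "depth_sd": float("nan"), "n": g.n,
                         "offset_mean": g.mean, "offset_sd": g.sd})
        import pandas as pd
        _write("centroid_depths.csv", pd.DataFrame(rows).set_index("class"))

    if scene.metadata.get("mode") == "activated":
        import pandas as pd
        groups = bin_undocked(scene)
        profiles = binned_profile(scene, groups)
        _write("bin_profiles.csv",
               pd.DataFrame([p.as_row() for p in profiles]).set_index("n"))

    manifest = RunManifest(
        tool_version=__version__,
        config_hash=scene.metadata.get("config_hash", ""),
        master_seed=seed if seed is not None
        else scene.metadata.get("seed", -1),
        outputs=written,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
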