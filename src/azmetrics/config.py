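"""Generator configuration and its published default values.

Every distribution below defaults to a mean +/- SD measured on electron
tomographic reconstructions of frog neuromuscular-junction active zones:
filament class dimensions, per-vesicle connection counts, connection-site
depths, in-plane approach angles, and the distance-gated connectivity of
undocked vesicles at vacated docking sites in stimulated terminals.

Continuous quantities are drawn from truncated normal distributions whose
location is adjusted so the *truncated* mean equals the configured mean
(see :func:`azmetrics.sampling.matched_truncnorm`); integer counts are
drawn normal, rounded, and clipped to their stated range.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Optional


@dataclass(frozen=True)
class Dist:
    """A mean/SD pair for a (truncated-)normal draw, in the field's units."""

    mean: float
    sd: float

    def validate(self) -> None:
        if self.sd < 0:
            raise ValueError(f"negative SD: {self}")


@dataclass(frozen=True)
class CountDist:
    """A rounded-normal integer count with an optional hard range."""

    mean: float
    sd: float
    min: Optional[int] = None
    max: Optional[int] = None


@dataclass(frozen=True)
class BinRule:
    """Expected per-class connections for undocked vesicles in one distance bin.

    ``bin`` is a closed nm interval of shortest vesicle-to-membrane distance.
    """

    bin: tuple[float, float]
    booms: Dist
    spars: Dist
    ribs: Dist
    pins_present: bool = False

    def validate(self) -> None:
        lo, hi = self.bin
        if not lo <= hi:
            raise ValueError(f"empty bin {self.bin}")
        for d in (self.booms, self.spars, self.ribs):
            d.validate()
            if d.mean < 0:
                raise ValueError(f"negative expectation in {self}")


def default_bin_rules() -> tuple[BinRule, ...]:
    """Distance-gated connectivity of undocked vesicles, far to near."""
    return (
        BinRule(bin=(29.0, 42.0), booms=Dist(4.8, 0.8), spars=Dist(0.3, 0.5),
                ribs=Dist(0.0, 0.0), pins_present=False),
        BinRule(bin=(17.0, 24.0), booms=Dist(5.6, 1.0), spars=Dist(1.7, 0.6),
                ribs=Dist(1.3, 0.6), pins_present=False),
        BinRule(bin=(4.0, 16.0), booms=Dist(5.6, 1.0), spars=Dist(1.9, 0.4),
                ribs=Dist(3.6, 0.5), pins_present=True),
    )


@dataclass(frozen=True)
class SceneConfig:
    """All parameters of the synthetic active-zone generator (lengths in nm)."""

    seed: int = 0
    band_length: float = 500.0
    band_half_width: float = 25.0

    step_spacing: Dist = Dist(48.8, 14.9)
    vesicle_diameter: tuple[float, float] = (50.0, 60.0)  # uniform range

    # class lengths
    beam_length: Dist = Dist(75.1, 13.1)
    step_length: Dist = Dist(28.4, 7.6)
    mast_length: Dist = Dist(31.5, 4.5)
    rib_length: Dist = Dist(27.9, 7.7)
    pin_length: Dist = Dist(8.6, 3.5)
    spar_length: Dist = Dist(17.6, 6.5)
    boom_length: Dist = Dist(16.0, 4.8)
    topmast_length: Dist = Dist(24.6, 9.4)
    non_azm_length: Dist = Dist(30.0, 10.0)

    # class diameters (steps carry separate horizontal/vertical diameters)
    beam_diameter: Dist = Dist(10.7, 0.7)
    step_diameter_horizontal: Dist = Dist(21.8, 5.8)
    step_diameter_vertical: Dist = Dist(13.9, 2.7)
    mast_diameter: Dist = Dist(22.0, 3.0)
    rib_diameter: Dist = Dist(9.4, 1.4)
    pin_diameter: Dist = Dist(5.0, 1.0)
    spar_diameter: Dist = Dist(7.1, 1.2)
    boom_diameter: Dist = Dist(6.5, 1.3)
    topmast_diameter: Dist = Dist(6.9, 2.1)
    non_azm_diameter: Dist = Dist(7.0, 1.5)

    # per-entity counts
    ribs_per_vesicle: CountDist = CountDist(3.9, 0.6, min=0)
    spars_per_vesicle: CountDist = CountDist(2.2, 0.5, min=0)
    booms_per_mast: CountDist = CountDist(10.6, 1.8, min=0)
    pins_per_vesicle: CountDist = CountDist(4.1, 0.7, min=3, max=5)
    topmasts_per_mast: tuple[int, int] = (1, 2)  # uniform integer range
    non_azm_per_vesicle: CountDist = CountDist(10.0, 0.0, min=0)
    mast_strands: tuple[int, int] = (4, 9)  # uniform integer range

    # connection-site depth structure (z, nm from the membrane)
    rib_site_depth: Dist = Dist(7.7, 3.3)
    spar_site_offset: Dist = Dist(10.3, 4.4)   # above the vesicle's rib centroid
    boom_site_offset: Dist = Dist(24.2, 6.6)   # above the vesicle's rib centroid
    boom_origin_height: Dist = Dist(39.0, 7.7)  # boom origin on the mast

    # in-plane (horizontal projection) approach angles, degrees
    rib_angle: Dist = Dist(10.6, 6.2)
    spar_angle: Dist = Dist(23.3, 13.1)
    boom_angle: Dist = Dist(30.0, 14.7)

    # activated-terminal parameters
    vacated_fraction: float = 0.5
    undocked_distance_range: tuple[float, float] = (4.0, 42.0)
    bin_rules: tuple[BinRule, ...] = field(default_factory=default_bin_rules)
    undocked_pins_per_vesicle: CountDist = CountDist(3.8, 0.5, min=0)
    undocked_pin_length: Dist = Dist(16.5, 6.5)
    pin_reach: float = 15.0  # pins connect only to vesicles within this distance
    include_fused_omega: bool = True

    # artificial z-compression injected at generation time (1.0 = none)
    compression_ratio: float = 1.0

    # -- validation / serialization -------------------------------------
    def validate(self) -> None:
        for name, value in asdict(self).items():
            if isinstance(value, dict) and set(value) == {"mean", "sd"}:
                if value["sd"] < 0:
                    raise ValueError(f"{name}: negative SD")
        rules = sorted(self.bin_rules, key=lambda r: r.bin[0])
        for r in rules:
            r.validate()
        for a, b in zip(rules, rules[1:]):
            if a.bin[1] >= b.bin[0]:
                raise ValueError(f"overlapping bins {a.bin} and {b.bin}")
        if not 0 < self.compression_ratio <= 1:
            raise ValueError(f"compression ratio {self.compression_ratio} "
                             "outside (0, 1]")
        if not 0 <= self.vacated_fraction <= 1:
            raise ValueError("vacated_fraction outside [0, 1]")
        lo, hi = self.vesicle_diameter
        if not 0 < lo <= hi:
            raise ValueError(f"bad vesicle diameter range {self.vesicle_diameter}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SceneConfig":
        data = dict(data)

        def _dist(v):
            return Dist(**v) if isinstance(v, dict) else v

        def _count(v):
            return CountDist(**v) if isinstance(v, dict) else v

        for f in cls.__dataclass_fields__.values():
            if f.name not in data:
                continue
            v = data[f.name]
            if f.name == "bin_rules":
                data[f.name] = tuple(
                    BinRule(bin=tuple(r["bin"]), booms=_dist(r["booms"]),
                            spars=_dist(r["spars"]), ribs=_dist(r["ribs"]),
                            pins_present=r.get("pins_present", False))
                    for r in v)
            elif isinstance(v, dict) and set(v) == {"mean", "sd"}:
                data[f.name] = _dist(v)
            elif isinstance(v, dict) and {"mean", "sd"} <= set(v):
                data[f.name] = _count(v)
            elif isinstance(v, list):
                data[f.name] = tuple(v)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def with_seed(self, seed: int) -> "SceneConfig":
        return replace(self, seed=int(seed))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def degenerate_config(seed: int = 0, **overrides) -> SceneConfig:
    """A config with every SD forced to 0 (counts fixed at rounded means).

    Useful for oracle tests: with degenerate distributions every draw equals
    its mean, so emitted counts and dimensions are exactly predictable.
    """
    cfg = SceneConfig(seed=seed, **overrides)
    changes = {}
    for name, f in SceneConfig.__dataclass_fields__.items():
        v = getattr(cfg, name)
        if isinstance(v, Dist):
            changes[name] = Dist(v.mean, 0.0)
        elif isinstance(v, CountDist):
            changes[name] = CountDist(v.mean, 0.0, v.min, v.max)
    changes["bin_rules"] = tuple(
        BinRule(bin=r.bin, booms=Dist(r.booms.mean, 0.0),
                spars=Dist(r.spars.mean, 0.0), ribs=Dist(r.ribs.mean, 0.0),
                pins_present=r.pins_present)
        for r in cfg.bin_rules)
    return replace(cfg, **changes)
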