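"""Distance-binned connectivity of undocked vesicles at vacated docking sites.

Undocked vesicles in activated scenes are grouped by their shortest
membrane distance into closed nm bins (defaults keep the reported gaps:
vesicles falling between bins are reported separately, never silently
dropped), per-bin per-class connection profiles are summarized, and bins
are compared against the docked-vesicle profile with Welch t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import GroupStats, connection_counts
from .scene import MAIN_BODY_CLASSES, Scene, shortest_distance_to_membrane

DEFAULT_BINS: tuple[tuple[float, float], ...] = (
    (4.0, 16.0), (17.0, 24.0), (29.0, 42.0))

PROFILE_CLASSES = ("rib", "spar", "boom", "pin")


def _validate_bins(bins) -> list[tuple[float, float]]:
    out = [(float(lo), float(hi)) for lo, hi in bins]
    for lo, hi in out:
        if not lo <= hi:
            raise ValueError(f"empty bin ({lo}, {hi})")
    ordered = sorted(out)
    for (alo, ahi), (blo, bhi) in zip(ordered, ordered[1:]):
        if ahi >= blo:
            raise ValueError(f"overlapping bins ({alo},{ahi}) and ({blo},{bhi})")
    return out


def bin_undocked(scene: Scene, bins=DEFAULT_BINS) -> dict:
    """Partition undocked vesicles by membrane distance into closed bins.

    Returns ``{(lo, hi): [vesicles], ..., "unbinned": [vesicles]}`` -- every
    undocked vesicle lands in exactly one group.
    """
    bins = _validate_bins(bins)
    groups: dict = {b: [] for b in bins}
    groups["unbinned"] = []
    for v in scene.vesicles_in_state("undocked"):
        d = shortest_distance_to_membrane(v)
        for lo, hi in bins:
            if lo <= d <= hi:
                groups[(lo, hi)].append(v)
                break
        else:
            groups["unbinned"].append(v)
    return groups


@dataclass
class BinProfile:
    """Per-class connection statistics for one distance bin (or the docked pool)."""

    bin: tuple[float, float] | None
    n: int
    per_class: dict[str, GroupStats]
    total: GroupStats
    values: pd.DataFrame = field(repr=False, default=None)

    def as_row(self) -> dict:
        row = {"bin_lo": self.bin[0] if self.bin else math.nan,
               "bin_hi": self.bin[1] if self.bin else math.nan, "n": self.n}
        for cls, g in self.per_class.items():
            row[f"{cls}_mean"] = g.mean
            row[f"{cls}_sd"] = g.sd
        row["total_mean"] = self.total.mean
        row["total_sd"] = self.total.sd
        return row


def _profile_from_counts(counts: pd.DataFrame,
                         bin_: tuple[float, float] | None) -> BinProfile:
    per_class = {cls: GroupStats.of(counts[cls].to_numpy())
                 for cls in PROFILE_CLASSES}
    total = GroupStats.of(counts["main_body_total"].to_numpy())
    return BinProfile(bin=bin_, n=len(counts), per_class=per_class,
                      total=total, values=counts)


def binned_profile(scene: Scene, groups: dict) -> list[BinProfile]:
    """Per-bin per-class means/SDs and main-body totals (far bins included
    with n = 0 when empty)."""
    counts = connection_counts(scene)
    profiles = []
    for key in sorted(k for k in groups if k != "unbinned"):
        ids = [v.id for v in groups[key]]
        sub = counts.loc[counts.index.isin(ids)]
        profiles.append(_profile_from_counts(sub, key))
    return profiles


def docked_profile(scene: Scene) -> BinProfile:
    """The docked-vesicle connection profile of a scene (reference pool)."""
    counts = connection_counts(scene)
    return _profile_from_counts(counts[counts["state"] == "docked"], None)


def pooled_profile(profiles: list[BinProfile],
                   bin_: tuple[float, float] | None) -> BinProfile:
    """Pool same-bin profiles from several scenes into one."""
    frames = [p.values for p in profiles if p.values is not None and p.n]
    if not frames:
        return BinProfile(bin=bin_, n=0,
                          per_class={c: GroupStats.of([]) for c in
                                     PROFILE_CLASSES},
                          total=GroupStats.of([]), values=None)
    return _profile_from_counts(pd.concat(frames), bin_)


def compare_profiles(a: BinProfile, b: BinProfile,
                     classes: tuple[str, ...] = PROFILE_CLASSES,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-test per class between two connection profiles.

    Classes with fewer than 2 observations on either side are reported as
    not testable.  Identical groups give t = 0, not significant.
    """
    rows = []
    for cls in classes:
        ga, gb = a.per_class.get(cls), b.per_class.get(cls)
        if ga is None or gb is None or ga.n < 2 or gb.n < 2:
            rows.append({"class": cls, "t": math.nan, "p": math.nan,
                         "significant": False, "testable": False})
            continue
        if (np.ptp(ga.values) == 0 and np.ptp(gb.values) == 0
                and ga.mean == gb.mean):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(ga.values, gb.values, equal_var=False)
            if math.isnan(t):
                t, p = 0.0, 1.0
        rows.append({"class": cls, "t": float(t), "p": float(p),
                     "significant": bool(p < alpha), "testable": True})
    return pd.DataFrame(rows).set_index("class")
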