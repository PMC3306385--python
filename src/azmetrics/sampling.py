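"""Random draws used by the scene generator.

The headline statistics of the source measurements are means and SDs, so
continuous quantities are modeled as normals truncated to their physical
range (lengths and depths at 0, in-plane angles at [0, 90] degrees).
Plain truncation would inflate the realized mean whenever the mean is
within a couple of SDs of a bound, which would defeat parameter-recovery
checks at large pooled n.  The location parameter is therefore solved so
that the *truncated* mean equals the configured mean while the scale stays
at the configured SD ("moment-matched" truncation).
"""

from __future__ import annotations

import functools
import math

import numpy as np
from scipy import optimize, stats

from .config import CountDist, Dist


@functools.lru_cache(maxsize=512)
def _matched_loc(mean: float, sd: float, low: float, high: float) -> float:
    """Location of a truncnorm(scale=sd) on [low, high] whose mean is ``mean``."""
    if not low < mean < high:
        raise ValueError(f"target mean {mean} outside truncation bounds "
                         f"[{low}, {high}]")

    def trunc_mean(loc: float) -> float:
        a = (low - loc) / sd
        b = (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    # the truncated mean is strictly increasing in loc and brackets the target
    lo_loc, hi_loc = mean - 12 * sd, mean + 12 * sd
    return optimize.brentq(lambda L: trunc_mean(L) - mean, lo_loc, hi_loc,
                           xtol=1e-10)


def matched_truncnorm(dist: Dist, rng: np.random.Generator, size=None,
                      low: float = 0.0, high: float = math.inf) -> np.ndarray:
    """Draw from a truncated normal whose truncated mean equals ``dist.mean``."""
    if dist.sd == 0:
        return np.full(size, dist.mean) if size is not None else float(dist.mean)
    loc = _matched_loc(dist.mean, dist.sd, low, high)
    a = (low - loc) / dist.sd
    b = (high - loc) / dist.sd
    draw = stats.truncnorm.rvs(a, b, loc=loc, scale=dist.sd, size=size,
                               random_state=rng)
    return draw if size is not None else float(draw)


def rounded_count(dist: CountDist, rng: np.random.Generator, size=None):
    """Integer count: normal draw, rounded, clipped to the stated range."""
    draw = rng.normal(dist.mean, dist.sd, size=size) if dist.sd > 0 else (
        np.full(size, dist.mean) if size is not None else dist.mean)
    k = np.rint(draw).astype(int)
    lo = dist.min if dist.min is not None else 0
    hi = dist.max if dist.max is not None else None
    k = np.clip(k, lo, hi)
    return k if size is not None else int(k)


def child_rngs(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """Deterministic per-stage generators derived from one master seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def child_seed(master_seed: int, index: int) -> int:
    """A reproducible scalar child seed below 2**31 (for per-scene seeding)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
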