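"""Cutoff sweeps: network statistics as a function of the energy cutoff e.

Interaction energies in protein energy networks mostly fall between 0 and
-35 kJ/mol, so the default grid walks e from 0 to -35 in 1 kJ/mol steps.
At each grid point the PEN is thresholded and one statistic evaluated,
producing the transition/population profiles used to compare homologues:
LCC size, cluster count (size >= 3), hub count (degree >= 4), k-clique
count, and largest clique-percolation community size.

Because the thresholded edge sets are nested (a more negative e keeps a
subset of the edges), the lcc/hubs/cliques/largest_community profiles are
non-increasing as e decreases; cluster count is not monotone — it rises
while the network fragments and falls back to zero once every component
drops below the minimum size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, TransitionUndefinedError
from .netanalysis import (count_clusters, enumerate_k_cliques, hubs,
                          largest_community_size, lcc_size)
from .pen_core import PEN, threshold

METRICS = ("lcc", "clusters", "hubs", "cliques", "largest_community")

#: Profiles at grid points more negative than this are "high energy",
#: the regime dominated by electrostatic (salt-bridge) interactions.
HIGH_ENERGY_BOUNDARY = -20.0


@dataclass(frozen=True)
class CutoffGrid:
    """Arithmetic grid of cutoffs: start, start-step, ... down to >= stop."""

    start: float = 0.0
    stop: float = -35.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ConfigurationError("step must be a positive magnitude")
        if self.start <= self.stop:
            raise ConfigurationError("start must be greater than stop")

    def values(self) -> list[float]:
        out = []
        i = 0
        while True:
            e = self.start - i * self.step  # exact per-point arithmetic,
            if e < self.stop - 1e-9:        # no cumulative drift
                break
            out.append(e)
            i += 1
        return out

    @classmethod
    def from_spec(cls, text: str) -> "CutoffGrid":
        """Parse ``start:stop:step``, e.g. ``0:-35:1``."""
        try:
            start, stop, step = (float(t) for t in text.split(":"))
        except ValueError as exc:
            raise ConfigurationError(f"bad grid spec {text!r}") from exc
        return cls(start, stop, abs(step))


@dataclass
class ProfileSeries:
    """One statistic evaluated over a cutoff grid (integer values)."""

    metric: str
    channel: str
    grid: list[float]
    values: list[int]
    k: int | None = None

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.values):
            raise ConfigurationError("grid and values lengths differ")
        if any(v < 0 for v in self.values):
            raise ConfigurationError("profile values must be non-negative")


def sweep(p: PEN, grid: CutoffGrid | None = None, metric: str = "lcc",
          channel: str = "total", k: int = 3, min_size: int = 3,
          degree_threshold: int = 4) -> ProfileSeries:
    """Evaluate one network statistic on PEN_e at every grid point.

    Exact evaluation (no sampling): each point thresholds the PEN and runs
    the statistic.  ``k`` applies to clique metrics, ``min_size`` to the
    cluster count, ``degree_threshold`` to hubs.
    """
    grid = grid or CutoffGrid()
    if metric not in METRICS:
        raise ConfigurationError(
            f"unknown metric {metric!r}; choose from {METRICS}")
    es = grid.values()
    values = []
    for e in es:
        g = threshold(p, e, channel)
        if metric == "lcc":
            v = lcc_size(g)
        elif metric == "clusters":
            v = count_clusters(g, min_size=min_size)
        elif metric == "hubs":
            v = len(hubs(g, degree_threshold=degree_threshold))
        elif metric == "cliques":
            v = len(enumerate_k_cliques(g, k))
        else:
            v = largest_community_size(g, k)
        values.append(int(v))
    return ProfileSeries(metric=metric, channel=channel, grid=es,
                         values=values,
                         k=k if metric in ("cliques", "largest_community") else None)


def transition_width(s: ProfileSeries, hi_frac: float = 0.9,
                     lo_frac: float = 0.1) -> tuple[float, float]:
    """Bracket the breakup transition of an LCC profile.

    Returns ``(e_hi, e_lo)``: the most negative grid cutoff where the
    profile still holds at least ``hi_frac`` of its maximum, and the least
    negative cutoff where it has fallen to at most ``lo_frac`` of it.
    Grid values only, no interpolation.
    """
    if not s.values or max(s.values) <= 0:
        raise TransitionUndefinedError("profile has no positive values")
    vmax = max(s.values)
    hi_idx = [i for i, v in enumerate(s.values) if v >= hi_frac * vmax]
    lo_idx = [i for i, v in enumerate(s.values) if v <= lo_frac * vmax]
    e_hi = s.grid[hi_idx[-1]]  # grid runs 0 -> negative, so last = most negative
    if not lo_idx:
        raise TransitionUndefinedError(
            f"profile never falls to {lo_frac:g} of its maximum")
    e_lo = s.grid[lo_idx[0]]
    return e_hi, e_lo


def peak(s: ProfileSeries) -> tuple[float, int]:
    """(grid position, value) of the profile maximum; ties go to the least
    negative cutoff (earliest grid point)."""
    if not s.values:
        raise ConfigurationError("cannot take the peak of an empty profile")
    vmax = max(s.values)
    i = s.values.index(vmax)
    return s.grid[i], vmax


def high_energy_peak(s: ProfileSeries,
                     boundary: float = HIGH_ENERGY_BOUNDARY) -> int:
    """Maximum profile value over the high-energy region (e < boundary)."""
    vals = [v for e, v in zip(s.grid, s.values) if e < boundary]
    return max(vals, default=0)
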