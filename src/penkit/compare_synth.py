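"""Homolog-pair comparison reports and synthetic fixtures.

The comparison mirrors how thermophile/mesophile homolog pairs are read
off profile plots — peak height and position, the breakup transition of
the LCC, and counts in the electrostatics-dominated high-energy region
(e < -20 kJ/mol) — but reports numbers only, never stability verdicts.

The synthetic generator emulates the empirical energy landscape of real
protein energy networks: a dispersion-dominated mode of weak energies
(around -5 kJ/mol), a sparser electrostatic mode of strong negative
energies (around -27 kJ/mol), a large fraction of non-interacting pairs,
and optional planted cliques, so the entire pipeline is testable without
structures or simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy_model import EnergyMatrix
from .errors import TransitionUndefinedError, ValidationError
from .profiles import ProfileSeries, high_energy_peak, peak, transition_width
from .residues import ResidueID, StructureEnsemble


# ---------------------------------------------------------------------------
# comparison

@dataclass
class MetricComparison:
    """Side-by-side summaries for one profile metric."""

    metric: str
    channel: str
    k: int | None
    series_a: ProfileSeries
    series_b: ProfileSeries
    peak_a: tuple[float, int]
    peak_b: tuple[float, int]
    high_energy_a: int
    high_energy_b: int
    difference: list[int]                      # a minus b, element-wise
    transition_a: tuple[float, float] | None = None  # LCC only
    transition_b: tuple[float, float] | None = None


@dataclass
class ComparisonReport:
    """All per-metric comparisons for a labelled pair of profile sets."""

    pair_labels: tuple[str, str]
    records: list[MetricComparison]

    def to_rows(self) -> list[tuple]:
        """(metric, statistic, a, b, a_minus_b) rows for TSV export."""
        rows = []
        for r in self.records:
            stats = [
                ("peak_e", r.peak_a[0], r.peak_b[0]),
                ("peak_value", r.peak_a[1], r.peak_b[1]),
                ("high_energy_peak", r.high_energy_a, r.high_energy_b),
            ]
            if r.transition_a is not None or r.transition_b is not None:
                for name, idx in (("transition_e_hi", 0), ("transition_e_lo", 1)):
                    a = r.transition_a[idx] if r.transition_a else math.nan
                    b = r.transition_b[idx] if r.transition_b else math.nan
                    stats.append((name, a, b))
            for name, a, b in stats:
                rows.append((r.metric, name, a, b, a - b))
        return rows

    def write_tsv(self, path) -> None:
        from pathlib import Path
        lines = [f"# pair: {self.pair_labels[0]} vs {self.pair_labels[1]}",
                 "metric\tstatistic\ta\tb\ta_minus_b"]
        for metric, stat, a, b, d in self.to_rows():
            lines.append(f"{metric}\t{stat}\t{a:g}\t{b:g}\t{d:g}")
        Path(path).write_text("\n".join(lines) + "\n")


def _series_key(s: ProfileSeries):
    return (s.metric, s.channel, s.k)


def compare_pair(a: list[ProfileSeries], b: list[ProfileSeries],
                 labels: tuple[str, str] = ("a", "b")) -> ComparisonReport:
    """Pair up profiles by (metric, channel, k) and summarize both sides.

    Both sets must cover the same metrics on identical grids.  The
    difference series is first minus second; no interpretation is added.
    """
    bmap = {_series_key(s): s for s in b}
    amap = {_series_key(s): s for s in a}
    if set(amap) != set(bmap):
        raise ValidationError(
            f"profile sets differ: {sorted(set(amap) ^ set(bmap))}")
    records = []
    for key in sorted(amap, key=str):
        sa, sb = amap[key], bmap[key]
        if sa.grid != sb.grid:
            raise ValidationError(f"grid mismatch for metric {key[0]!r}")
        trans_a = trans_b = None
        if sa.metric == "lcc":
            try:
                trans_a = transition_width(sa)
            except TransitionUndefinedError:
                pass
            try:
                trans_b = transition_width(sb)
            except TransitionUndefinedError:
                pass
        records.append(MetricComparison(
            metric=sa.metric, channel=sa.channel, k=sa.k,
            series_a=sa, series_b=sb,
            peak_a=peak(sa), peak_b=peak(sb),
            high_energy_a=high_energy_peak(sa),
            high_energy_b=high_energy_peak(sb),
            difference=[x - y for x, y in zip(sa.values, sb.values)],
            transition_a=trans_a, transition_b=trans_b))
    return ComparisonReport(pair_labels=labels, records=records)


# ---------------------------------------------------------------------------
# synthetic energy matrices

@dataclass
class SyntheticSpec:
    """Recipe for a synthetic residue-pair energy matrix.

    Defaults emulate the empirical landscape: most pairs do not interact
    (``background_fraction``); interacting pairs draw a weak dispersive
    energy near -5 kJ/mol in the LJ channel; a small fraction additionally
    draw a strong electrostatic energy near -27 kJ/mol in the Coulomb
    channel.  ``planted_cliques`` force the listed node sets' internal
    pair totals to a target energy.  The seed is mandatory.
    """

    n_residues: int = 60
    seed: int = 0
    lj_mode_mean: float = -5.0
    lj_mode_sd: float = 2.0
    elec_mode_mean: float = -27.0
    elec_mode_sd: float = 3.0
    elec_pair_fraction: float = 0.08
    background_fraction: float = 0.85
    planted_cliques: list[tuple[tuple[int, ...], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValidationError("need at least 2 residues")
        for frac in (self.elec_pair_fraction, self.background_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("fractions must lie in [0, 1]")
        if self.lj_mode_sd < 0 or self.elec_mode_sd < 0:
            raise ValidationError("mode standard deviations must be >= 0")
        for nodes, _ in self.planted_cliques:
            if any(not 0 <= v < self.n_residues for v in nodes):
                raise ValidationError(
                    f"planted clique {nodes} has nodes out of range")


def _generic_residues(n: int) -> list[ResidueID]:
    return [ResidueID("A", i + 1, None, "ALA") for i in range(n)]


def generate_synthetic_matrix(spec: SyntheticSpec) -> EnergyMatrix:
    """Deterministic synthetic energy matrix following a :class:`SyntheticSpec`."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    lj = np.zeros((n, n))
    coul = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    n_pairs = len(iu[0])
    interacting = rng.random(n_pairs) >= spec.background_fraction
    lj_draw = rng.normal(spec.lj_mode_mean, spec.lj_mode_sd, size=n_pairs)
    elec_sel = rng.random(n_pairs) < spec.elec_pair_fraction
    elec_draw = rng.normal(spec.elec_mode_mean, spec.elec_mode_sd, size=n_pairs)
    lj[iu] = np.where(interacting, lj_draw, 0.0)
    coul[iu] = np.where(interacting & elec_sel, elec_draw, 0.0)
    for nodes, target in spec.planted_cliques:
        for a, i in enumerate(nodes):
            for j in nodes[a + 1:]:
                x, y = min(i, j), max(i, j)
                lj[x, y] = target
                coul[x, y] = 0.0
    lj = lj + lj.T
    coul = coul + coul.T
    return EnergyMatrix(residues=_generic_residues(n), total=lj + coul,
                        lj=lj, coulomb=coul)


# ---------------------------------------------------------------------------
# toy coordinate ensembles

# poly-alanine atoms; every name has parameters in the bundled table
_TOY_ATOMS = ("N", "H", "CA", "CB", "C", "O")
_TOY_OFFSETS = {
    "N": np.array([-0.12, 0.04, 0.00]),
    "H": np.array([-0.14, 0.14, 0.00]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "CB": np.array([0.00, -0.15, 0.04]),
    "C": np.array([0.12, 0.04, 0.00]),
    "O": np.array([0.14, 0.14, 0.04]),
}


def generate_toy_ensemble(n_residues: int = 12, n_frames: int = 3,
                          jitter_sd: float = 0.01,
                          seed: int = 0) -> StructureEnsemble:
    """Poly-alanine chain on a helical curve with per-frame Gaussian jitter.

    CA positions follow an alpha-helix-like curve (radius 0.23 nm, rise
    0.15 nm, 100 degrees per residue); the other atoms sit at fixed small
    offsets.  ``jitter_sd`` (nm) perturbs every atom independently per
    frame; 0 makes all frames identical.  Deterministic given the seed.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if n_frames < 1:
        raise ValueError("need at least 1 frame")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    radius, rise, twist = 0.23, 0.15, math.radians(100.0)
    base = []
    for i in range(n_residues):
        ca = np.array([radius * math.cos(i * twist),
                       radius * math.sin(i * twist),
                       rise * i])
        for name in _TOY_ATOMS:
            base.append(ca + _TOY_OFFSETS[name])
    base = np.asarray(base)
    frames = [base + rng.normal(0.0, jitter_sd, size=base.shape)
              for _ in range(n_frames)]
    residues = _generic_residues(n_residues)
    return StructureEnsemble(
        residues=residues,
        atom_names=[list(_TOY_ATOMS) for _ in range(n_residues)],
        frames=frames,
        atom_elements=[[a[0] for a in _TOY_ATOMS] for _ in range(n_residues)],
    )
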