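"""Weighted Protein Energy Networks and their unweighted thresholded form.

A PEN is a complete weighted graph over a protein's residues; each
unordered pair carries three weight channels (total, LJ-only,
Coulomb-only interaction energy, kJ/mol).  Thresholding at a cutoff ``e``
keeps exactly the pairs with energy <= e (inclusive; energies are signed,
so a more negative ``e`` keeps fewer, stronger edges), giving the
unweighted graph PEN_e whose adjacency all network statistics consume.

Terminology: "low energy" = small negative magnitude (-5), "high energy"
= large negative magnitude (-25).  Repulsive (positive) weights are kept
as-is; they simply never satisfy a negative cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy_model import CHANNELS, EnergyMatrix
from .errors import ConfigurationError
from .residues import ResidueID


@dataclass
class PEN:
    """Complete weighted residue graph wrapping an :class:`EnergyMatrix`."""

    matrix: EnergyMatrix

    @property
    def residues(self) -> list[ResidueID]:
        return self.matrix.residues

    @property
    def n_residues(self) -> int:
        return self.matrix.n_residues

    def available_channels(self) -> list[str]:
        return self.matrix.available_channels()

    def weights(self, channel: str = "total") -> np.ndarray:
        w = self.matrix.channel(channel)
        if w is None:
            raise ConfigurationError(
                f"channel {channel!r} unavailable; present: "
                f"{self.available_channels()}")
        return w


@dataclass
class ThresholdedPEN:
    """Unweighted PEN_e: edge (i,j) iff channel energy(i,j) <= cutoff_e."""

    residues: list[ResidueID]
    cutoff_e: float
    channel: str
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        np.fill_diagonal(a, False)
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return len(self.residues)

    def has_edge(self, i: int, j: int) -> bool:
        return bool(self.adjacency[i, j])

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def edges(self) -> list[tuple[int, int]]:
        """Unordered adjacent pairs (i < j), sorted."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(ii.tolist(), jj.tolist()))

    def neighbors(self, i: int) -> list[int]:
        return np.nonzero(self.adjacency[i])[0].tolist()


def build_pen(m: EnergyMatrix) -> PEN:
    """Wrap an energy matrix as a PEN without modification."""
    return PEN(matrix=m)


def threshold(p: PEN, e: float, channel: str = "total") -> ThresholdedPEN:
    """PEN_e for the chosen channel: keep pairs with energy <= e (inclusive).

    All nodes are retained, including isolated ones.  Pairs excluded from
    the energy computation (e.g. sequence-adjacent neighbours) never form
    an edge, whatever the cutoff.
    """
    w = p.weights(channel)
    adj = w <= e
    if p.matrix.excluded is not None:
        adj &= ~p.matrix.excluded
    return ThresholdedPEN(residues=list(p.residues), cutoff_e=float(e),
                          channel=channel, adjacency=adj)


def edge_count(g: ThresholdedPEN) -> int:
    """Number of unordered adjacent pairs in PEN_e."""
    return int(np.triu(g.adjacency, k=1).sum())
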