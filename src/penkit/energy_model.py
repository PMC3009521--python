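"""Pairwise residue interaction energies from coordinates.

The edge weight between residues *i* and *j* is the ensemble average of

    E_ij = V_LJ(r_ij) + V_C(r_ij)

where both terms are plain pairwise sums over the atom pairs of the two
residues: 12-6 Lennard-Jones and Coulomb in a uniform relative dielectric.
No periodic boundary conditions, no solvent, no Ewald treatment — the
network only needs residue-residue energies.

Sign convention used throughout the package: "low energy" means small
negative magnitude (e.g. -5 kJ/mol, dispersive contacts), "high energy"
means large negative magnitude (e.g. -25 kJ/mol, salt bridges).

Parameters come from a bundled, self-contained OPLS-like table covering
the heavy atoms and polar hydrogens of the 20 amino acids; users may
supply their own table in the same TSV layout.  Atoms without parameters
contribute zero energy and are counted in a logged warning, never an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .residues import ResidueID, StructureEnsemble, canonical_residue_name

logger = logging.getLogger(__name__)

#: Coulomb constant 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_CONSTANT = 138.935485

CHANNELS = ("total", "lj", "coulomb")


@dataclass
class ForceFieldParams:
    """Non-bonded parameters: per-atom (charge e, sigma nm, epsilon kJ/mol).

    ``atom_params`` maps ``(residue_name, atom_name)`` to the triple; residue
    names are canonical (protonation variants resolved by the lookup).
    """

    atom_params: dict[tuple[str, str], tuple[float, float, float]]
    combining_rule: str = "lorentz-berthelot"
    coulomb_constant: float = COULOMB_CONSTANT
    relative_dielectric: float = 1.0
    distance_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.combining_rule not in ("lorentz-berthelot", "geometric"):
            raise ValidationError(
                f"unknown combining rule {self.combining_rule!r}")
        if self.coulomb_constant <= 0:
            raise ValidationError("coulomb_constant must be positive")
        if self.relative_dielectric < 1:
            raise ValidationError("relative_dielectric must be >= 1")
        for key, (q, sigma, eps) in self.atom_params.items():
            if sigma <= 0:
                raise ValidationError(f"sigma must be positive for {key}")
            if eps < 0:
                raise ValidationError(f"epsilon must be non-negative for {key}")

    def lookup(self, residue_name: str, atom_name: str):
        """Parameters for one atom, or ``None`` if the table lacks it."""
        return self.atom_params.get(
            (canonical_residue_name(residue_name), atom_name.strip().upper()))

    @classmethod
    def from_table(cls, path: str | Path, **kwargs) -> "ForceFieldParams":
        """Load a TSV with columns residue_name, atom_name, charge_e, sigma_nm, epsilon_kJmol."""
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"residue_name", "atom_name", "charge_e", "sigma_nm", "epsilon_kJmol"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"parameter table missing columns {sorted(missing)}")
        params = {
            (str(r.residue_name).upper(), str(r.atom_name).upper()):
                (float(r.charge_e), float(r.sigma_nm), float(r.epsilon_kJmol))
            for r in df.itertuples()
        }
        return cls(atom_params=params, **kwargs)

    @classmethod
    def default(cls, **kwargs) -> "ForceFieldParams":
        """The bundled simplified amino-acid parameter set."""
        ref = resources.files("penkit.data").joinpath("forcefield.tsv")
        with resources.as_file(ref) as path:
            return cls.from_table(path, **kwargs)


@dataclass
class EnergyMatrix:
    """Symmetric residue x residue interaction energies in kJ/mol.

    ``total = lj + coulomb`` element-wise whenever both component channels
    are present; the diagonal is zero; pairs excluded from the energy sum
    (sequence-adjacent neighbours by default) are zero in every channel and
    flagged in ``excluded`` so thresholding never draws an edge for them.
    A channel read from a total-only file is ``None`` (unavailable).
    """

    residues: list[ResidueID]
    total: np.ndarray | None = None
    lj: np.ndarray | None = None
    coulomb: np.ndarray | None = None
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.residues)
        for name in CHANNELS:
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m, dtype=float)
            setattr(self, name, m)
            if m.shape != (n, n):
                raise ValidationError(f"channel {name} has shape {m.shape}, expected ({n}, {n})")
            if not np.allclose(m, m.T, atol=1e-6):
                i, j = np.unravel_index(np.argmax(np.abs(m - m.T)), m.shape)
                raise ValidationError(
                    f"channel {name} asymmetric at pair ({i}, {j}): "
                    f"{m[i, j]!r} vs {m[j, i]!r}")
        if self.lj is not None and self.coulomb is not None:
            # (re)build so the decomposition identity total = lj + coulomb
            # holds bitwise
            self.total = self.lj + self.coulomb
        if all(getattr(self, c) is None for c in CHANNELS):
            raise ValidationError("matrix must carry at least one channel")
        if self.excluded is not None:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape != (n, n):
                raise ValidationError("exclusion mask shape mismatch")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def channel(self, name: str) -> np.ndarray | None:
        if name not in CHANNELS:
            raise ValidationError(f"unknown channel {name!r}")
        return getattr(self, name)

    def available_channels(self) -> list[str]:
        return [c for c in CHANNELS if getattr(self, c) is not None]


def _combine(sigma_i, sigma_j, eps_i, eps_j, rule: str):
    if rule == "lorentz-berthelot":
        sigma = (sigma_i + sigma_j) / 2.0
    elif rule == "geometric":
        sigma = np.sqrt(sigma_i * sigma_j)
    else:
        raise ValidationError(f"unknown combining rule {rule!r}")
    return sigma, np.sqrt(eps_i * eps_j)


def lj_pair(r: float, sigma_i: float, epsilon_i: float,
            sigma_j: float, epsilon_j: float,
            rule: str = "lorentz-berthelot") -> float:
    """12-6 Lennard-Jones energy 4*eps*[(sigma/r)^12 - (sigma/r)^6] in kJ/mol.

    ``sigma``/``epsilon`` are obtained from the per-atom values by the
    combining rule (Lorentz-Berthelot: arithmetic sigma, geometric epsilon;
    geometric: both geometric).  ``r`` in nm.
    """
    if r <= 0:
        raise ValueError(f"interatomic distance must be positive, got {r}")
    sigma, eps = _combine(sigma_i, sigma_j, epsilon_i, epsilon_j, rule)
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def coulomb_pair(r: float, q_i: float, q_j: float,
                 params: ForceFieldParams | None = None) -> float:
    """Coulomb energy k*q_i*q_j/(eps_r * r) in kJ/mol (r in nm, q in e)."""
    if r <= 0:
        raise ValueError(f"interatomic distance must be positive, got {r}")
    kc = params.coulomb_constant if params else COULOMB_CONSTANT
    eps_r = params.relative_dielectric if params else 1.0
    return kc * q_i * q_j / (eps_r * r)


def _atom_param_arrays(ensemble: StructureEnsemble, params: ForceFieldParams):
    """Vectorized per-residue parameter arrays (q, sigma, eps, missing count)."""
    out = []
    for res, names in zip(ensemble.residues, ensemble.atom_names):
        q = np.zeros(len(names))
        sigma = np.full(len(names), 0.1)
        eps = np.zeros(len(names))
        missing = 0
        for a, name in enumerate(names):
            p = params.lookup(res.name, name)
            if p is None:
                missing += 1
                continue
            q[a], sigma[a], eps[a] = p
        out.append((q, sigma, eps, missing))
    return out


def _pair_energy_arrays(xyz_i, xyz_j, pi, pj, params: ForceFieldParams):
    qi, si, ei, _ = pi
    qj, sj, ej, _ = pj
    d = np.linalg.norm(xyz_i[:, None, :] - xyz_j[None, :, :], axis=-1)
    if np.any(d <= 0):
        raise ValueError("coincident atoms between residues (zero distance)")
    sigma, eps = _combine(si[:, None], sj[None, :], ei[:, None], ej[None, :],
                          params.combining_rule)
    sr6 = (sigma / d) ** 6
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    coul = params.coulomb_constant * qi[:, None] * qj[None, :] / (
        params.relative_dielectric * d)
    if params.distance_cutoff is not None:
        mask = d <= params.distance_cutoff
        lj = lj * mask
        coul = coul * mask
    return float(lj.sum()), float(coul.sum())


def residue_pair_energy(ensemble: StructureEnsemble, frame: int,
                        i: int, j: int,
                        params: ForceFieldParams | None = None
                        ) -> tuple[float, float]:
    """(LJ, Coulomb) energy in kJ/mol between residues ``i`` and ``j`` of one frame.

    Sums all atom pairs within ``params.distance_cutoff`` (all pairs when the
    cutoff is ``None``).  Atoms absent from the parameter table contribute 0.
    """
    if i == j:
        raise ValueError("residue interacting with itself is undefined")
    params = params or ForceFieldParams.default()
    arrays = _atom_param_arrays(ensemble, params)
    return _pair_energy_arrays(ensemble.coords(frame, i), ensemble.coords(frame, j),
                               arrays[i], arrays[j], params)


def compute_energy_matrix(ensemble: StructureEnsemble,
                          params: ForceFieldParams | None = None,
                          exclude_adjacent: bool = True) -> EnergyMatrix:
    """Ensemble-averaged pairwise energies for every residue pair.

    LJ and Coulomb channels are arithmetic means of the per-frame pair
    energies; ``total`` is their sum.  With ``exclude_adjacent`` (default)
    sequence neighbours in the same chain are zeroed and masked: their
    energies are dominated by through-bond geometry and would connect the
    backbone as a trivial chain at every cutoff.
    """
    if ensemble.n_frames < 1:
        raise ValueError("ensemble must contain at least one frame")
    params = params or ForceFieldParams.default()
    n = ensemble.n_residues
    arrays = _atom_param_arrays(ensemble, params)

    missing = sum(m for *_, m in arrays)
    if missing:
        logger.warning(
            "%d atoms lack force-field parameters and contribute zero energy",
            missing)

    excluded = np.zeros((n, n), dtype=bool)
    if exclude_adjacent:
        for i in range(n - 1):
            a, b = ensemble.residues[i], ensemble.residues[i + 1]
            if a.chain == b.chain:
                excluded[i, i + 1] = excluded[i + 1, i] = True

    lj = np.zeros((n, n))
    coul = np.zeros((n, n))
    for f in range(ensemble.n_frames):
        coords = [ensemble.coords(f, i) for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if excluded[i, j]:
                    continue
                e_lj, e_c = _pair_energy_arrays(coords[i], coords[j],
                                                arrays[i], arrays[j], params)
                lj[i, j] += e_lj
                coul[i, j] += e_c
    lj /= ensemble.n_frames
    coul /= ensemble.n_frames
    lj = lj + lj.T
    coul = coul + coul.T
    return EnergyMatrix(residues=list(ensemble.residues), total=lj + coul,
                        lj=lj, coulomb=coul, excluded=excluded)
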