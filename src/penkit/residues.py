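"""Residue identity and coordinate-ensemble containers.

A residue is identified by its author chain, author residue number and
optional insertion code (PDB "auth" numbering).  Every structure maps its
residues to a dense 0-based internal index in file order; matrices are
indexed internally and labelled externally through :meth:`ResidueID.label`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, ValidationError

#: The 20 standard amino acids.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Common protonation/disulfide variant names mapped to their parent residue.
RESIDUE_ALIASES = {
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS",
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS",
    "CYX": "CYS", "CYM": "CYS",
    "ASH": "ASP", "GLH": "GLU", "LYN": "LYS", "ARN": "ARG",
}


def canonical_residue_name(name: str) -> str:
    """Map protonation-variant residue names onto the parent amino acid."""
    name = name.strip().upper()
    return RESIDUE_ALIASES.get(name, name)


def is_amino_acid(name: str) -> bool:
    return canonical_residue_name(name) in STANDARD_AA


@dataclass(frozen=True, order=True)
class ResidueID:
    """Identity of one residue: (chain, number, insertion code) + name.

    ``(chain, seq_number, insertion_code)`` is unique within a structure.
    """

    chain: str
    seq_number: int
    insertion_code: str | None = None
    name: str = "UNK"

    def label(self) -> str:
        """External label, e.g. ``A:42:ALA`` or ``A:42B:ALA``."""
        icode = self.insertion_code or ""
        return f"{self.chain}:{self.seq_number}{icode}:{self.name}"

    @classmethod
    def from_label(cls, text: str) -> "ResidueID":
        m = re.fullmatch(r"([^:]+):(-?\d+)([A-Za-z]?):([^:]+)", text.strip())
        if m is None:
            raise ParseError(f"unparseable residue label {text!r}")
        chain, seq, icode, name = m.groups()
        return cls(chain, int(seq), icode or None, name)


@dataclass
class StructureEnsemble:
    """An ordered residue list plus one or more coordinate frames.

    Coordinates are in nanometres.  Every frame shares the identical atom
    topology: ``atom_names[i]`` lists the atoms of residue ``i`` and each
    frame is a single ``(n_atoms_total, 3)`` array; ``atom_slice(i)``
    recovers the rows belonging to residue ``i``.
    """

    residues: list[ResidueID]
    atom_names: list[list[str]]
    frames: list[np.ndarray]
    atom_elements: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("ensemble must contain at least one frame")
        if len(self.atom_names) != len(self.residues):
            raise ValidationError("atom_names and residues lengths differ")
        counts = np.fromiter((len(a) for a in self.atom_names), dtype=int,
                             count=len(self.atom_names))
        offsets = np.concatenate([[0], np.cumsum(counts)])
        self._offsets = offsets
        total = int(offsets[-1])
        for f, xyz in enumerate(self.frames):
            if xyz.shape != (total, 3):
                raise ValidationError(
                    f"frame {f} has shape {xyz.shape}, expected ({total}, 3)")
            if not np.all(np.isfinite(xyz)):
                raise ValidationError(f"frame {f} contains non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def atom_slice(self, i: int) -> slice:
        """Row range of residue ``i`` inside any frame array."""
        return slice(int(self._offsets[i]), int(self._offsets[i + 1]))

    def coords(self, frame: int, i: int) -> np.ndarray:
        """Coordinates (nm) of residue ``i`` in one frame."""
        return self.frames[frame][self.atom_slice(i)]

    def select_frames(self, indices: list[int]) -> "StructureEnsemble":
        """New ensemble restricted to the given frame indices."""
        return StructureEnsemble(
            residues=self.residues,
            atom_names=self.atom_names,
            frames=[self.frames[i] for i in indices],
            atom_elements=self.atom_elements,
        )
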