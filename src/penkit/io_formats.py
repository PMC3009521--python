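"""Reading and writing structures, energy matrices, graphs and profiles.

Formats are deliberately few and plain: PDB for structures (via Bio.PDB),
tab-separated text for energy matrices and profiles, GraphML or a
two-column edge list for thresholded graphs.  Energies are always kJ/mol
and distances nm; there is no unit autodetection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx

from .energy_model import CHANNELS, EnergyMatrix
from .errors import ParseError, TopologyError, ValidationError
from .pen_core import ThresholdedPEN
from .residues import ResidueID, StructureEnsemble, is_amino_acid

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueID", "StructureEnsemble", "MatrixFileDialect",
    "read_structure", "write_structure",
    "read_energy_matrix", "write_energy_matrix",
    "export_graph", "import_graphml",
    "write_profile", "read_profile",
]

_SYMMETRY_TOL = 1e-6  # kJ/mol


@dataclass(frozen=True)
class MatrixFileDialect:
    """How an energy-matrix TSV is laid out.

    ``square-matrix`` files carry exactly one channel (labelled rows and
    columns); ``long-pairs`` files carry any subset of channels as columns,
    with absent pairs meaning zero energy (no interaction).
    """

    layout: str = "long-pairs"
    channel_columns: tuple[str, ...] = ("total", "lj", "coulomb")

    def __post_init__(self) -> None:
        if self.layout not in ("square-matrix", "long-pairs"):
            raise ValidationError(f"unknown matrix layout {self.layout!r}")
        bad = set(self.channel_columns) - set(CHANNELS)
        if bad:
            raise ValidationError(f"unknown channels {sorted(bad)}")
        if self.layout == "square-matrix" and len(self.channel_columns) != 1:
            raise ValidationError("square-matrix layout carries exactly one channel")


# ---------------------------------------------------------------------------
# structures

def read_structure(path: str | Path,
                   frame_selection: list[int] | None = None) -> StructureEnsemble:
    """Parse a (possibly multi-MODEL) PDB file into a coordinate ensemble.

    Only amino-acid residues are kept (waters, ions and other heteroatoms
    are dropped; non-standard residue names are skipped with a warning);
    hydrogens are retained when present.  For alternate locations only the
    highest-occupancy conformer is used.  All models must share the same
    residue/atom topology.  Coordinates are converted to nm.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        structure = parser.get_structure("s", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"malformed PDB {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise ParseError(f"{path}: no MODEL/coordinates found")
    if frame_selection is not None:
        try:
            models = [models[i] for i in frame_selection]
        except IndexError as exc:
            raise ValidationError(
                f"frame selection {frame_selection} out of range "
                f"(file has {len(structure)} models)") from exc

    def model_topology(model):
        residues, atom_names, atom_elements, coords = [], [], [], []
        for chain in model:
            for res in chain:
                hetflag, resseq, icode = res.id
                if hetflag != " ":
                    continue  # water / ions / ligands
                if not is_amino_acid(res.get_resname()):
                    logger.warning("skipping non-amino-acid residue %s %s%s",
                                   res.get_resname(), chain.id, resseq)
                    continue
                rid = ResidueID(chain.id, resseq,
                                icode.strip() or None, res.get_resname())
                names, elems = [], []
                for atom in res:  # DisorderedAtom delegates to the
                    names.append(atom.get_name())        # highest-occupancy child
                    elems.append(atom.element or "")
                    coords.append(atom.get_coord())
                residues.append(rid)
                atom_names.append(names)
                atom_elements.append(elems)
        return residues, atom_names, atom_elements, np.asarray(coords, dtype=float)

    residues, atom_names, atom_elements, first = model_topology(models[0])
    if not residues:
        raise ParseError(f"{path}: no amino-acid residues found")
    frames = [first / 10.0]  # angstrom -> nm
    for m in models[1:]:
        r2, a2, _, xyz = model_topology(m)
        if r2 != residues or a2 != atom_names:
            bad = next((x for x, y in zip(r2, residues) if x != y),
                       residues[min(len(r2), len(residues)) - 1])
            raise TopologyError(
                f"{path}: model {m.id} topology diverges at residue {bad.label()}")
        frames.append(xyz / 10.0)
    return StructureEnsemble(residues=residues, atom_names=atom_names,
                             frames=frames, atom_elements=atom_elements)


def write_structure(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-MODEL PDB file (coordinates nm -> A)."""
    lines = []
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 1
        for i, rid in enumerate(ensemble.residues):
            xyz = ensemble.coords(f, i) * 10.0
            elems = (ensemble.atom_elements[i]
                     if ensemble.atom_elements else None)
            for a, name in enumerate(ensemble.atom_names[i]):
                x, y, z = xyz[a]
                el = (elems[a] if elems else name[0]).rjust(2)
                nm = name if len(name) >= 4 else f" {name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {nm}{'':1s}{rid.name:>3s} {rid.chain:1s}"
                    f"{rid.seq_number:4d}{rid.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el}")
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# energy matrices

def _fmt(v: float) -> str:
    return f"{v:.17g}"


def write_energy_matrix(m: EnergyMatrix, path: str | Path,
                        dialect: MatrixFileDialect | None = None) -> None:
    """Serialize an energy matrix as TSV in the given dialect.

    Long-pairs files start with a ``# residues:`` header carrying the full
    node list in order, so isolated residues survive the round trip.
    """
    dialect = dialect or MatrixFileDialect(
        channel_columns=tuple(m.available_channels()))
    channels = [c for c in dialect.channel_columns]
    for c in channels:
        if m.channel(c) is None:
            raise ValidationError(f"channel {c!r} not present in matrix")
    labels = [r.label() for r in m.residues]
    lines = []
    if dialect.layout == "square-matrix":
        w = m.channel(channels[0])
        lines.append("label\t" + "\t".join(labels))
        for i, lab in enumerate(labels):
            lines.append(lab + "\t" + "\t".join(_fmt(v) for v in w[i]))
    else:
        lines.append("# residues: " + ",".join(labels))
        lines.append("res_i\tres_j\t" + "\t".join(channels))
        n = m.n_residues
        mats = [m.channel(c) for c in channels]
        for i in range(n):
            for j in range(i + 1, n):
                lines.append(labels[i] + "\t" + labels[j] + "\t"
                             + "\t".join(_fmt(w[i, j]) for w in mats))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_float(text: str, where: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"non-numeric cell {text!r} at {where}") from exc


def read_energy_matrix(path: str | Path,
                       dialect: MatrixFileDialect | None = None) -> EnergyMatrix:
    """Read an energy-matrix TSV; the layout is sniffed when no dialect given."""
    raw = Path(path).read_text().splitlines()
    residues_header: list[ResidueID] | None = None
    lines = []
    for ln in raw:
        if ln.startswith("# residues:"):
            residues_header = [ResidueID.from_label(t)
                               for t in ln.split(":", 1)[1].split(",") if t.strip()]
        elif ln.strip() and not ln.startswith("#"):
            lines.append(ln)
    if not lines:
        raise ParseError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    if dialect is None:
        if header[:2] == ["res_i", "res_j"]:
            dialect = MatrixFileDialect("long-pairs", tuple(header[2:]))
        else:
            dialect = MatrixFileDialect("square-matrix", ("total",))

    if dialect.layout == "square-matrix":
        labels = header[1:]
        residues = [ResidueID.from_label(t) for t in labels]
        n = len(residues)
        w = np.zeros((n, n))
        if len(lines) - 1 != n:
            raise ValidationError(
                f"{path}: square matrix has {len(lines) - 1} rows for {n} columns")
        for i, ln in enumerate(lines[1:]):
            cells = ln.split("\t")
            if len(cells) != n + 1:
                raise ParseError(f"{path}: row {i + 2} has {len(cells)} cells")
            for j, cell in enumerate(cells[1:]):
                w[i, j] = _parse_float(cell, f"{path} row {i + 2} col {j + 2}")
        bad = np.argwhere(np.abs(w - w.T) > _SYMMETRY_TOL)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"{path}: asymmetric at pair ({labels[i]}, {labels[j]}): "
                f"{w[i, j]!r} vs {w[j, i]!r}")
        w = (w + w.T) / 2.0
        channel = dialect.channel_columns[0]
        kwargs = {channel: w} if channel != "total" else {}
        return EnergyMatrix(residues=residues,
                            total=w if channel == "total" else None, **kwargs)

    # long-pairs
    channels = list(dialect.channel_columns)
    if header != ["res_i", "res_j"] + channels:
        raise ParseError(f"{path}: header {header} does not match dialect")
    pairs: dict[tuple[str, str], list[float]] = {}
    order: list[str] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != 2 + len(channels):
            raise ParseError(f"{path}: line {lineno} has {len(cells)} cells")
        a, b = cells[0], cells[1]
        vals = [_parse_float(c, f"{path} line {lineno}") for c in cells[2:]]
        key = (a, b) if a <= b else (b, a)
        if key in pairs:
            if any(abs(x - y) > _SYMMETRY_TOL for x, y in zip(pairs[key], vals)):
                raise ValidationError(
                    f"{path}: duplicate pair ({a}, {b}) with conflicting values")
        pairs[key] = vals
        for lab in (a, b):
            if lab not in order:
                order.append(lab)
    if residues_header is not None:
        residues = residues_header
    else:
        residues = sorted((ResidueID.from_label(t) for t in order))
    index = {r.label(): i for i, r in enumerate(residues)}
    n = len(residues)
    mats = {c: np.zeros((n, n)) for c in channels}
    for (a, b), vals in pairs.items():
        if a not in index or b not in index:
            raise ValidationError(f"{path}: pair ({a}, {b}) not in residue header")
        i, j = index[a], index[b]
        for c, v in zip(channels, vals):
            mats[c][i, j] = mats[c][j, i] = v
    return EnergyMatrix(residues=residues,
                        total=mats.get("total"),
                        lj=mats.get("lj"), coulomb=mats.get("coulomb"))


# ---------------------------------------------------------------------------
# graphs

def export_graph(g: ThresholdedPEN, path: str | Path,
                 format: str = "graphml") -> None:
    """Write PEN_e as GraphML (with node/graph attributes) or an edge list."""
    labels = [r.label() for r in g.residues]
    if format == "graphml":
        G = nx.Graph(cutoff_e=g.cutoff_e, channel=g.channel)
        for i, r in enumerate(g.residues):
            G.add_node(labels[i], index=i, chain=r.chain,
                       seq_number=r.seq_number, name=r.name)
        for i, j in g.edges():
            G.add_edge(labels[i], labels[j])
        nx.write_graphml(G, str(path))
    elif format == "edge-list":
        lines = ["res_i\tres_j"]
        lines += [f"{labels[i]}\t{labels[j]}" for i, j in g.edges()]
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown graph format {format!r}")


def import_graphml(path: str | Path) -> ThresholdedPEN:
    """Re-import a GraphML file written by :func:`export_graph`."""
    G = nx.read_graphml(str(path))
    nodes = sorted(G.nodes(data=True), key=lambda nd: nd[1]["index"])
    residues = [ResidueID(d["chain"], int(d["seq_number"]), None, d["name"])
                for _, d in nodes]
    pos = {label: d["index"] for label, d in nodes}
    n = len(residues)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in G.edges():
        adj[pos[a], pos[b]] = adj[pos[b], pos[a]] = True
    return ThresholdedPEN(residues=residues,
                          cutoff_e=float(G.graph.get("cutoff_e", 0.0)),
                          channel=str(G.graph.get("channel", "total")),
                          adjacency=adj)


# ---------------------------------------------------------------------------
# profiles

def write_profile(p, path: str | Path) -> None:
    """Serialize a ProfileSeries as TSV: metadata comments, then e/value rows."""
    if len(p.grid) != len(p.values):
        raise ValidationError("profile grid and values lengths differ")
    lines = [f"# metric: {p.metric}", f"# channel: {p.channel}"]
    if p.k is not None:
        lines.append(f"# k: {p.k}")
    lines.append("e\tvalue")
    for e, v in zip(p.grid, p.values):
        lines.append(f"{e:.3f}\t{int(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path):
    """Read a profile TSV written by :func:`write_profile`."""
    from .profiles import ProfileSeries

    meta: dict[str, str] = {}
    grid: list[float] = []
    values: list[int] = []
    body = False
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if ln.startswith("#"):
            key, _, val = ln[1:].partition(":")
            meta[key.strip()] = val.strip()
        elif ln.strip() == "e\tvalue":
            body = True
        elif ln.strip():
            if not body:
                raise ParseError(f"{path}: line {lineno} before header")
            e, v = ln.split("\t")
            grid.append(_parse_float(e, f"{path} line {lineno}"))
            values.append(int(v))
    return ProfileSeries(metric=meta.get("metric", "lcc"),
                         channel=meta.get("channel", "total"),
                         k=int(meta["k"]) if "k" in meta else None,
                         grid=grid, values=values)
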