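"""Reading and writing protein models in PDB format, and point-cloud conversion.

Models are held as plain coordinate containers (chains -> residues -> atoms,
coordinates in Angstrom). Only the fixed-column ATOM records of the first MODEL
are used; HETATM records and hydrogens are skipped by default. For descriptor
extraction a model is flattened into a :class:`PointCloud` — one 3D point per
selected atom, in file order — with an anchor index locating each residue's
C-alpha point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "ProteinModel",
    "PointCloud",
    "read_pdb",
    "write_pdb",
    "to_point_cloud",
]

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Residue:
    number: int  # PDB residue sequence number, unique within a chain
    name: str  # 3-letter code
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class ProteinModel:
    model_id: str
    chains: list[Chain] = field(default_factory=list)

    def iter_residues(self):
        for chain in self.chains:
            for res in chain.residues:
                yield chain.chain_id, res

    def iter_atoms(self):
        for chain_id, res in self.iter_residues():
            for atom in res.atoms:
                yield chain_id, res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    @property
    def n_residues(self) -> int:
        return sum(1 for _ in self.iter_residues())

    def coords(self) -> np.ndarray:
        """All atom coordinates in file order, shape (n_atoms, 3)."""
        return np.array([a.coord for _, _, a in self.iter_atoms()], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinModel":
        """A copy with every atom mapped through x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        chains = []
        for chain in self.chains:
            residues = []
            for res in chain.residues:
                atoms = []
                for a in res.atoms:
                    nx, ny, nz = rotation @ a.coord + translation
                    atoms.append(Atom(a.name, a.element, float(nx), float(ny), float(nz)))
                residues.append(Residue(res.number, res.name, atoms))
            chains.append(Chain(chain.chain_id, residues))
        return ProteinModel(self.model_id, chains)

    def validate(self) -> None:
        if self.n_atoms < 1:
            raise ValueError(f"model {self.model_id!r} has no atoms")
        coords = self.coords()
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"model {self.model_id!r} has non-finite coordinates")
        for chain in self.chains:
            numbers = [r.number for r in chain.residues]
            if len(numbers) != len(set(numbers)):
                raise ValueError(
                    f"model {self.model_id!r} chain {chain.chain_id!r}: "
                    "duplicate residue numbers"
                )


@dataclass
class PointCloud:
    """Ordered 3D points (one per selected atom) with optional unit normals.

    ``anchor_index`` maps a residue key ``(chain_id, residue_number)`` to the
    index of that residue's C-alpha point within ``points``.
    """

    points: np.ndarray  # (n, 3)
    normals: np.ndarray | None = None  # (n, 3), unit vectors
    anchor_index: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def validate(self) -> None:
        if self.n_points < 1:
            raise ValueError("point cloud is empty")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud has non-finite coordinates")
        if self.normals is not None:
            if len(self.normals) != self.n_points:
                raise ValueError("normals and points differ in length")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("normals are not unit length")


def _element_from_record(line: str, atom_name: str) -> str:
    element = line[76:78].strip() if len(line) >= 78 else ""
    if element:
        return element.upper()
    # Fall back to the atom-name convention: first alphabetic character,
    # ignoring leading digits (e.g. "1HB " is a hydrogen).
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _parse_float(text: str, what: str, line_number: int) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(
            f"malformed {what} field {text.strip()!r} on line {line_number}"
        ) from exc


def read_pdb(path: str | Path, model_id: str | None = None,
             skip_hydrogens: bool = True) -> ProteinModel:
    """Parse the ATOM records of the first MODEL of a PDB file.

    HETATM records are ignored. Hydrogens (and deuteriums) are skipped unless
    ``skip_hydrogens`` is False. Alternate locations are resolved by keeping
    the highest-occupancy record; ties go to altLoc 'A'.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    if model_id is None:
        model_id = path.stem

    # (chain, resnum, atom_name) -> (occupancy, altloc_rank, order, Atom, res_name)
    best: dict[tuple[str, int, str], tuple] = {}
    order_counter = 0
    in_first_model = True
    saw_model_record = False

    with open(path) as handle:
        for line_number, line in enumerate(handle, start=1):
            record = line[:6]
            if record.startswith("MODEL"):
                if saw_model_record:
                    break  # start of MODEL 2: only the first model is read
                saw_model_record = True
                continue
            if record.startswith("ENDMDL"):
                in_first_model = False
                continue
            if not in_first_model or record != "ATOM  ":
                continue
            atom_name = line[12:16].strip()
            alt_loc = line[16]
            res_name = line[17:20].strip()
            chain_id = line[21]
            res_seq_text = line[22:26].strip()
            try:
                res_seq = int(res_seq_text)
            except ValueError as exc:
                raise ValueError(
                    f"malformed residue number {res_seq_text!r} on line {line_number}"
                ) from exc
            x = _parse_float(line[30:38], "x coordinate", line_number)
            y = _parse_float(line[38:46], "y coordinate", line_number)
            z = _parse_float(line[46:54], "z coordinate", line_number)
            occ_text = line[54:60].strip()
            occupancy = float(occ_text) if occ_text else 1.0
            element = _element_from_record(line, atom_name)
            if skip_hydrogens and element in _HYDROGEN_ELEMENTS:
                continue
            atom = Atom(atom_name, element, x, y, z)
            key = (chain_id, res_seq, atom_name)
            # altLoc resolution: highest occupancy wins; ties prefer 'A'/blank.
            alt_rank = 0 if alt_loc in (" ", "A") else 1
            candidate = (occupancy, alt_rank)
            if key in best:
                prev_occ, prev_rank, prev_order, _, _ = best[key]
                if occupancy > prev_occ or (occupancy == prev_occ and alt_rank < prev_rank):
                    best[key] = (occupancy, alt_rank, prev_order, atom, res_name)
            else:
                best[key] = (occupancy, alt_rank, order_counter, atom, res_name)
                order_counter += 1

    if not best:
        raise ValueError(f"no ATOM records in {path}")

    model = ProteinModel(model_id)
    chain_map: dict[str, Chain] = {}
    res_map: dict[tuple[str, int], Residue] = {}
    for (chain_id, res_seq, _), (_, _, _, atom, res_name) in sorted(
        best.items(), key=lambda item: item[1][2]
    ):
        if chain_id not in chain_map:
            chain_map[chain_id] = Chain(chain_id)
            model.chains.append(chain_map[chain_id])
        rkey = (chain_id, res_seq)
        if rkey not in res_map:
            res_map[rkey] = Residue(res_seq, res_name)
            chain_map[chain_id].residues.append(res_map[rkey])
        res_map[rkey].atoms.append(atom)
    model.validate()
    return model


def write_pdb(model: ProteinModel, path: str | Path) -> None:
    """Write a model as fixed-column ATOM records (coordinates to 3 decimals).

    Residue numbers above 9999 or atom serials above 99999 exceed the format's
    field widths and raise an error rather than being silently truncated.
    """
    model.validate()
    path = Path(path)
    lines = []
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            if res.number > 9999 or res.number < -999:
                raise ValueError(
                    f"residue number {res.number} does not fit the PDB format"
                )
            for atom in res.atoms:
                serial += 1
                if serial > 99999:
                    raise ValueError("atom serial exceeds the PDB format limit (99999)")
                # Atom names of short elements start in column 14.
                if len(atom.name) < 4 and len(atom.element) == 1:
                    name_field = f" {atom.name:<3s}"
                else:
                    name_field = f"{atom.name:<4s}"
                lines.append(
                    f"ATOM  {serial:5d} {name_field} {res.name:>3s} {chain.chain_id}"
                    f"{res.number:4d}    {atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n"
                )
        lines.append("TER\n")
    lines.append("END\n")
    with open(path, "w") as handle:
        handle.writelines(lines)


def to_point_cloud(model: ProteinModel, selection: str = "all_heavy") -> PointCloud:
    """Flatten a model into a point cloud.

    selection "all_heavy" keeps every non-hydrogen atom; "calpha" keeps only
    atoms named CA. Point order follows atom order in the file. The anchor
    index maps each residue with a C-alpha to that point's index.
    """
    if selection not in ("all_heavy", "calpha"):
        raise ValueError(f"unknown selection {selection!r}")
    points = []
    anchor_index: dict[tuple[str, int], int] = {}
    for chain_id, res, atom in model.iter_atoms():
        if atom.element in _HYDROGEN_ELEMENTS:
            continue
        if selection == "calpha" and atom.name != "CA":
            continue
        if atom.name == "CA" and (chain_id, res.number) not in anchor_index:
            anchor_index[(chain_id, res.number)] = len(points)
        points.append(atom.coord)
    if not points:
        raise ValueError(
            f"model {model.model_id!r}: no atoms selected under {selection!r}"
        )
    cloud = PointCloud(points=np.array(points, dtype=float), anchor_index=anchor_index)
    cloud.validate()
    return cloud


def read_pdb_dir(directory: str | Path, skip_hydrogens: bool = True) -> list[ProteinModel]:
    """Read all ``*.pdb`` files of a directory in lexicographic order."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.pdb"))
    if not paths:
        raise FileNotFoundError(f"no .pdb files in {directory}")
    return [read_pdb(p, skip_hydrogens=skip_hydrogens) for p in paths]
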