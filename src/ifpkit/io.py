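"""Structure readers and writers.

PDB is read and written natively (multi-model files stand in for frame
sequences; CONECT records carry the bond graph, columns 79-80 the formal
charges).  SDF and MOL2 are read through RDKit, which supplies bond orders,
charges and aromaticity.  Coordinates are Angstrom; atom indices are 0-based
everywhere (PDB serials are preserved separately on each atom).

PDB carries no aromaticity flags, so reading applies an optional, documented
perception rule: a 5/6-membered ring of C/N/O/S atoms, each with at most
three bonds, that is planar to within 0.1 A is flagged aromatic.  Disable
with ``perceive_aromaticity=False`` if your inputs encode aromaticity
elsewhere.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .chem_model import Atom, ResidueId, Structure
from .errors import FileFormatError
from .geometry import ring_normal

__all__ = ["read_structure", "read_frames", "write_pdb"]

_PLANARITY_TOL = 0.1
_AROMATIC_CANDIDATES = {"C", "N", "O", "S"}


def write_pdb(structures, path) -> None:
    """Write one Structure or a sequence of frames as a (multi-model) PDB.

    Element symbols go in columns 77-78 and formal charges in 79-80; bonds
    are emitted as CONECT records (shared by all models).
    """
    frames = [structures] if isinstance(structures, Structure) else list(structures)
    if not frames:
        raise ValueError("no structures to write")
    lines = []
    multi = len(frames) > 1
    for model_no, struct in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {model_no:4d}")
        for atom in struct.atoms:
            rid = atom.residue or ResidueId("UNL", 1, "")
            serial = atom.index + 1
            name = (atom.name or atom.element)[:4]
            charge = ""
            if atom.formal_charge:
                charge = f"{abs(atom.formal_charge)}{'+' if atom.formal_charge > 0 else '-'}"
            x, y, z = atom.coords
            lines.append(
                f"HETATM{serial:5d} {name:<4.4s}{rid.name[:3]:>4.3s} "
                f"{(rid.chain or ' ')[:1]}{rid.number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{atom.element.upper():>2.2s}{charge:<2s}"
            )
        if multi:
            lines.append("ENDMDL")
    for i, j in frames[0].bond_pairs():
        lines.append(f"CONECT{i + 1:5d}{j + 1:5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_element(line: str, lineno: int) -> str:
    el = line[76:78].strip() if len(line) >= 78 else ""
    if not el:
        el = "".join(c for c in line[12:16] if c.isalpha())[:2]
    if not el:
        raise FileFormatError(f"line {lineno}: cannot determine element: {line!r}")
    return el.capitalize() if len(el) == 2 else el.upper()


def _parse_charge(line: str) -> int:
    token = line[78:80].strip() if len(line) >= 80 else ""
    if not token:
        return 0
    sign = -1 if token.endswith("-") else 1
    digits = token.strip("+-") or "1"
    return sign * int(digits)


def _read_pdb(path, perceive_aromaticity: bool):
    models: list[list[Atom]] = []
    current: list[Atom] | None = None
    conect: list[tuple[int, int]] = []
    serial_maps: list[dict] = []
    seen_model_kw = False

    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        record = line[:6].strip()
        if record == "MODEL":
            seen_model_kw = True
            current = []
            models.append(current)
            serial_maps.append({})
        elif record in ("ATOM", "HETATM"):
            if current is None:
                current = []
                models.append(current)
                serial_maps.append({})
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip() if len(line) > 21 else ""
                resnum = int(line[22:26])
                coords = (
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                )
            except (ValueError, IndexError) as exc:
                raise FileFormatError(
                    f"{path}: line {lineno}: malformed atom record: {line!r}"
                ) from exc
            atom = Atom(
                index=len(current),
                element=_parse_element(line, lineno),
                coords=np.asarray(coords),
                formal_charge=_parse_charge(line),
                residue=ResidueId(resname or "UNL", resnum, chain),
                name=name,
                serial=serial,
            )
            serial_maps[-1][serial] = atom.index
            current.append(atom)
        elif record == "ENDMDL":
            current = None
        elif record == "CONECT":
            fields = line[6:].split()
            try:
                serials = [int(f) for f in fields]
            except ValueError as exc:
                raise FileFormatError(
                    f"{path}: line {lineno}: malformed CONECT: {line!r}"
                ) from exc
            for other in serials[1:]:
                conect.append((serials[0], other))

    if not models or not any(models):
        raise FileFormatError(f"{path}: no atom records found")

    structures = []
    for frame_id, (atoms, smap) in enumerate(zip(models, serial_maps)):
        for s1, s2 in conect:
            if s1 in smap and s2 in smap:
                i, j = smap[s1], smap[s2]
                if j not in atoms[i].bonded_indices:
                    atoms[i].bonded_indices.append(j)
                if i not in atoms[j].bonded_indices:
                    atoms[j].bonded_indices.append(i)
        for a in atoms:
            a.bonded_indices.sort()
        struct = Structure(atoms, frame_id=frame_id)
        if perceive_aromaticity:
            _perceive_aromatic_rings(struct)
        structures.append(struct)
    return structures


def _perceive_aromatic_rings(structure: Structure) -> None:
    """Flag planar 5/6-rings of low-valence C/N/O/S atoms as aromatic."""
    g = nx.Graph()
    for atom in structure.atoms:
        if atom.element in _AROMATIC_CANDIDATES and len(atom.bonded_indices) <= 3:
            for j in atom.bonded_indices:
                other = structure.atoms[j]
                if other.element in _AROMATIC_CANDIDATES and len(other.bonded_indices) <= 3:
                    g.add_edge(atom.index, j)
    if g.number_of_edges() == 0:
        return
    for cycle in nx.simple_cycles(g, length_bound=6):
        if len(cycle) not in (5, 6):
            continue
        pts = structure.coords[sorted(cycle)]
        try:
            normal = ring_normal(pts)
        except ValueError:
            continue
        centred = pts - pts.mean(axis=0)
        if np.abs(centred @ normal).max() <= _PLANARITY_TOL:
            for idx in cycle:
                structure.atoms[idx].is_aromatic = True


def _from_rdkit(mol, frame_id: int = 0) -> Structure:
    conf = mol.GetConformer()
    atoms = []
    for rd_atom in mol.GetAtoms():
        idx = rd_atom.GetIdx()
        pos = conf.GetAtomPosition(idx)
        info = rd_atom.GetPDBResidueInfo()
        if info is not None:
            rid = ResidueId(
                info.GetResidueName().strip() or "UNL",
                info.GetResidueNumber(),
                info.GetChainId().strip(),
            )
            name = info.GetName().strip()
        else:
            rid = ResidueId("UNL", 1, "")
            name = rd_atom.GetSymbol()
        atoms.append(
            Atom(
                index=idx,
                element=rd_atom.GetSymbol(),
                coords=np.array([pos.x, pos.y, pos.z]),
                formal_charge=rd_atom.GetFormalCharge(),
                is_aromatic=rd_atom.GetIsAromatic(),
                bonded_indices=sorted(
                    n.GetIdx() for n in rd_atom.GetNeighbors()
                ),
                residue=rid,
                name=name,
            )
        )
    return Structure(atoms, frame_id=frame_id)


def _read_sdf(path):
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    structures = []
    for record, mol in enumerate(supplier):
        if mol is None:
            raise FileFormatError(f"{path}: record {record + 1}: unparseable SDF block")
        structures.append(_from_rdkit(mol, frame_id=record))
    if not structures:
        raise FileFormatError(f"{path}: no molecules found")
    return structures


def _read_mol2(path):
    from rdkit import Chem

    mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=True)
    if mol is None:
        raise FileFormatError(f"{path}: unparseable MOL2 file")
    return [_from_rdkit(mol)]


def read_frames(path, fmt: str | None = None, perceive_aromaticity: bool = True) -> list:
    """Read a structure file as a list of frames (always a list)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return _read_pdb(path, perceive_aromaticity)
    if fmt == "sdf":
        return _read_sdf(path)
    if fmt == "mol2":
        return _read_mol2(path)
    raise FileFormatError(f"unsupported format {fmt!r} (supported: pdb, sdf, mol2)")


def read_structure(path, fmt: str | None = None, perceive_aromaticity: bool = True):
    """Read a structure file; returns a Structure, or a list for multi-model
    / multi-record inputs."""
    frames = read_frames(path, fmt=fmt, perceive_aromaticity=perceive_aromaticity)
    return frames[0] if len(frames) == 1 else frames
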