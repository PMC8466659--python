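"""Molecular data model, per-residue fragmentation, and moiety matching.

Structures are plain graphs of :class:`Atom` objects carrying element,
coordinates, formal charge, aromaticity flags and bonds.  The input contract
is explicit: hydrogens, formal charges and aromatic flags must already be
present (no perception is attempted here).  A structure is carved into
:class:`ResidueFragment` units keyed by residue name, number and chain, and
moieties (charged atoms, aromatic rings, donor/acceptor groups...) are
located inside each fragment with :func:`match_moiety`.

Built-in moiety definitions are implemented as graph predicates with
documented element/charge semantics; user-supplied patterns may instead be
SMARTS strings, compiled and matched through RDKit.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence, Union

import networkx as nx
import numpy as np

from .errors import PatternError, StructureError

__all__ = [
    "Atom",
    "ResidueId",
    "ResidueFragment",
    "Structure",
    "MoietyPattern",
    "PatternRegistry",
    "fragment_by_residue",
    "match_moiety",
    "builtin_patterns",
    "default_pattern_registry",
    "register_pattern",
]

# Element vocabularies used by the built-in moiety predicates.
XB_HALOGENS = frozenset({"Cl", "Br", "I", "At"})
METALS = frozenset({"Ca", "Cd", "Co", "Cu", "Fe", "Mg", "Mn", "Ni", "Zn"})
HYDROPHOBIC_ELEMENTS = frozenset({"C", "S", "F", "Cl", "Br", "I", "At"})
XB_DONOR_HEAVY = frozenset({"C", "N", "Si", "F", "Cl", "Br", "I"})
XB_ACCEPTOR_ELEMENTS = frozenset({"N", "O", "P", "S", "Se", "Te"})
HB_ACCEPTOR_ELEMENTS = frozenset({"N", "O", "F"})
HB_DONOR_HEAVY = frozenset({"N", "O", "S"})
METAL_LIGAND_ELEMENTS = frozenset({"O", "N"})


@functools.total_ordering
@dataclass(frozen=True)
class ResidueId:
    """Identity of one residue: name, number and (possibly empty) chain.

    Total order is (chain, number, name); it fixes fragment ordering and the
    bitvector layout everywhere downstream.
    """

    name: str
    number: int
    chain: str = ""

    @property
    def sort_key(self) -> tuple:
        return (self.chain, self.number, self.name)

    def __lt__(self, other: "ResidueId") -> bool:
        if not isinstance(other, ResidueId):
            return NotImplemented
        return self.sort_key < other.sort_key

    def __str__(self) -> str:
        label = f"{self.name}{self.number}"
        return f"{label}.{self.chain}" if self.chain else label


@dataclass
class Atom:
    """One atom: 0-based index within its parent container."""

    index: int
    element: str
    coords: np.ndarray
    formal_charge: int = 0
    is_aromatic: bool = False
    bonded_indices: list = field(default_factory=list)
    residue: ResidueId | None = None
    name: str = ""
    serial: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise StructureError(f"atom {self.index}: coords must be length 3")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.index}: non-finite coordinates")
        if not self.element:
            raise StructureError(f"atom {self.index}: empty element symbol")


class Structure:
    """A molecular structure (one frame): atoms plus residue assignment.

    Parameters
    ----------
    atoms:
        Atoms with ``index`` equal to their position, symmetric
        ``bonded_indices`` and (for fragmentation) a ``residue`` id.
    frame_id:
        Non-negative frame/pose number.
    """

    def __init__(self, atoms: Sequence[Atom], frame_id: int = 0):
        self.atoms: list[Atom] = list(atoms)
        if frame_id < 0:
            raise StructureError("frame_id must be >= 0")
        self.frame_id = int(frame_id)
        self._validate()
        self._coords: np.ndarray | None = None
        self._residues: list[ResidueFragment] | None = None

    def _validate(self) -> None:
        n = len(self.atoms)
        for pos, atom in enumerate(self.atoms):
            if atom.index != pos:
                raise StructureError(
                    f"atom at position {pos} has index {atom.index}"
                )
            for j in atom.bonded_indices:
                if not (0 <= j < n):
                    raise StructureError(
                        f"atom {pos}: bonded index {j} out of range"
                    )
                if pos not in self.atoms[j].bonded_indices:
                    raise StructureError(
                        f"bond {pos}-{j} is not symmetric"
                    )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            self._coords = np.array([a.coords for a in self.atoms], dtype=float)
        return self._coords

    @property
    def elements(self) -> list:
        return [a.element for a in self.atoms]

    def bond_pairs(self) -> list:
        """Unique bonds as sorted (i, j) tuples with i < j."""
        pairs = set()
        for atom in self.atoms:
            for j in atom.bonded_indices:
                pairs.add((min(atom.index, j), max(atom.index, j)))
        return sorted(pairs)

    @property
    def residues(self) -> list:
        if self._residues is None:
            self._residues = fragment_by_residue(self)
        return self._residues

    def has_hydrogens(self) -> bool:
        return any(a.element == "H" for a in self.atoms)

    def __repr__(self) -> str:
        return f"<Structure frame={self.frame_id} n_atoms={self.n_atoms}>"


@dataclass
class ResidueFragment:
    """A connected-by-residue atom set carved from a parent structure.

    ``atoms`` are re-indexed locally (0..n-1) with bonds restricted to the
    fragment; ``parent_indices[i]`` maps local atom ``i`` back to its parent
    index.  Detection results always report parent indices.
    """

    residue_id: ResidueId
    atoms: list
    parent_indices: tuple

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"empty fragment {self.residue_id}")
        if len(set(self.parent_indices)) != len(self.parent_indices):
            raise StructureError(
                f"fragment {self.residue_id}: parent_indices not injective"
            )
        self._coords: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            self._coords = np.array([a.coords for a in self.atoms], dtype=float)
        return self._coords

    @property
    def elements(self) -> list:
        return [a.element for a in self.atoms]

    def to_parent(self, local_indices: Iterable[int]) -> tuple:
        """Map local atom indices to parent (absolute) indices."""
        return tuple(self.parent_indices[i] for i in local_indices)

    def __repr__(self) -> str:
        return f"<ResidueFragment {self.residue_id} n_atoms={self.n_atoms}>"


def fragment_by_residue(structure: Structure) -> list:
    """Split a structure into per-residue fragments.

    Fragments partition the atom set and are ordered by the ResidueId total
    order.  Bonds internal to a residue are preserved with local indices;
    inter-residue bonds are cut.

    Raises
    ------
    StructureError
        If any atom lacks residue metadata.
    """
    groups: dict[ResidueId, list[int]] = {}
    for atom in structure.atoms:
        if atom.residue is None:
            raise StructureError(
                f"atom {atom.index} lacks residue metadata"
            )
        groups.setdefault(atom.residue, []).append(atom.index)

    fragments = []
    for rid in sorted(groups):
        parent_idx = sorted(groups[rid])
        local_of = {p: i for i, p in enumerate(parent_idx)}
        local_atoms = []
        for i, p in enumerate(parent_idx):
            src = structure.atoms[p]
            local_atoms.append(
                Atom(
                    index=i,
                    element=src.element,
                    coords=src.coords.copy(),
                    formal_charge=src.formal_charge,
                    is_aromatic=src.is_aromatic,
                    bonded_indices=sorted(
                        local_of[j] for j in src.bonded_indices if j in local_of
                    ),
                    residue=rid,
                    name=src.name,
                    serial=src.serial,
                )
            )
        fragments.append(
            ResidueFragment(
                residue_id=rid,
                atoms=local_atoms,
                parent_indices=tuple(parent_idx),
            )
        )
    return fragments


# ---------------------------------------------------------------------------
# Moiety patterns
# ---------------------------------------------------------------------------

Query = Union[str, Callable]


@dataclass(frozen=True)
class MoietyPattern:
    """A named substructure query.

    ``query`` is either a SMARTS string (matched via RDKit) or a callable
    ``fragment -> list of local atom-index tuples``.  ``arity`` is the number
    of atoms captured per match; ``None`` means variable (aromatic rings
    capture 5 or 6 atoms).
    """

    name: str
    query: Query
    arity: int | None = 1

    def __post_init__(self) -> None:
        if self.arity is not None and self.arity < 1:
            raise PatternError(f"pattern {self.name!r}: arity must be >= 1")
        if isinstance(self.query, str):
            _compile_smarts(self.name, self.query)  # fail fast on parse errors


@functools.lru_cache(maxsize=256)
def _compile_smarts(name: str, smarts: str):
    from rdkit import Chem

    query = Chem.MolFromSmarts(smarts)
    if query is None:
        raise PatternError(f"pattern {name!r}: cannot parse SMARTS {smarts!r}")
    return query


def _fragment_to_rdkit(fragment: ResidueFragment):
    """Build a minimal RDKit molecule mirroring the fragment graph.

    Only element, formal charge, aromatic flags and connectivity are
    transferred; no sanitization beyond ring perception is performed, since
    the input contract guarantees these attributes are already correct.
    """
    from rdkit import Chem

    rw = Chem.RWMol()
    for atom in fragment.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        a.SetIsAromatic(atom.is_aromatic)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for atom in fragment.atoms:
        for j in atom.bonded_indices:
            if atom.index < j:
                both_aromatic = atom.is_aromatic and fragment.atoms[j].is_aromatic
                btype = (
                    Chem.BondType.AROMATIC if both_aromatic else Chem.BondType.SINGLE
                )
                bond = rw.AddBond(atom.index, j, btype)
                if both_aromatic:
                    rw.GetBondWithIdx(bond - 1).SetIsAromatic(True)
    mol = rw.GetMol()
    Chem.FastFindRings(mol)
    return mol


def _aromatic_ring_sets(fragment: ResidueFragment) -> list:
    """5/6-membered rings of mutually bonded aromatic atoms, as sorted tuples.

    Rings matched at both sizes (or through symmetry-equivalent traversals)
    are deduplicated as atom sets.
    """
    g = nx.Graph()
    for atom in fragment.atoms:
        if not atom.is_aromatic:
            continue
        for j in atom.bonded_indices:
            if fragment.atoms[j].is_aromatic:
                g.add_edge(atom.index, j)
    rings = set()
    if g.number_of_edges() == 0:
        return []
    for cycle in nx.simple_cycles(g, length_bound=6):
        if len(cycle) in (5, 6):
            rings.add(tuple(sorted(cycle)))
    return sorted(rings)


def _charged_atoms(fragment: ResidueFragment, predicate: Callable) -> list:
    return [(a.index,) for a in fragment.atoms if predicate(a)]


def _match_anion(frag):
    return _charged_atoms(frag, lambda a: a.formal_charge <= -1)


def _match_cation(frag):
    return _charged_atoms(frag, lambda a: a.formal_charge >= 1)


def _match_hb_acceptor(frag):
    # (element in {N,O,F} or anionic) and not cationic
    return [
        (a.index,)
        for a in frag.atoms
        if (a.element in HB_ACCEPTOR_ELEMENTS or a.formal_charge <= -1)
        and a.formal_charge < 1
    ]


def _match_hb_donor(frag):
    out = []
    for a in frag.atoms:
        if a.element in HB_DONOR_HEAVY:
            for j in a.bonded_indices:
                if frag.atoms[j].element == "H":
                    out.append((a.index, j))
    return out


def _match_xb_acceptor(frag):
    out = []
    for a in frag.atoms:
        if (a.element in XB_ACCEPTOR_ELEMENTS or a.is_aromatic) and a.formal_charge < 1:
            for j in a.bonded_indices:
                out.append((a.index, j))
    return out


def _match_xb_donor(frag):
    out = []
    for a in frag.atoms:
        if a.element in XB_DONOR_HEAVY:
            for j in a.bonded_indices:
                if frag.atoms[j].element in XB_HALOGENS:
                    out.append((a.index, j))
    return out


def _match_metal(frag):
    return [(a.index,) for a in frag.atoms if a.element in METALS]


def _match_metal_ligand(frag):
    return [
        (a.index,)
        for a in frag.atoms
        if (a.element in METAL_LIGAND_ELEMENTS or a.formal_charge <= -1)
        and a.formal_charge < 1
    ]


def _match_hydrophobic(frag):
    return [
        (a.index,)
        for a in frag.atoms
        if a.element in HYDROPHOBIC_ELEMENTS and a.formal_charge == 0
    ]


def builtin_patterns() -> list:
    """The default moiety registry contents.

    Charge-constrained names (Anion, Cation, the "not cationic" guards)
    are implemented as formal-charge predicates: anionic means formal
    charge <= -1, cationic means >= +1.
    """
    return [
        MoietyPattern("Anion", _match_anion, 1),
        MoietyPattern("Cation", _match_cation, 1),
        MoietyPattern("Aromatic", _aromatic_ring_sets, None),
        MoietyPattern("HBAcceptor", _match_hb_acceptor, 1),
        MoietyPattern("HBDonor", _match_hb_donor, 2),
        MoietyPattern("XBAcceptor", _match_xb_acceptor, 2),
        MoietyPattern("XBDonor", _match_xb_donor, 2),
        MoietyPattern("Metal", _match_metal, 1),
        MoietyPattern("MetalLigand", _match_metal_ligand, 1),
        MoietyPattern("Hydrophobic", _match_hydrophobic, 1),
    ]


class PatternRegistry:
    """Name -> MoietyPattern mapping with collision control."""

    def __init__(self, patterns: Iterable[MoietyPattern] = ()):
        self._patterns: dict[str, MoietyPattern] = {}
        for p in patterns:
            self.register(p)

    def register(self, pattern: MoietyPattern, overwrite: bool = False) -> None:
        if pattern.name in self._patterns and not overwrite:
            raise PatternError(
                f"pattern {pattern.name!r} already registered "
                "(pass overwrite=True to replace it)"
            )
        self._patterns[pattern.name] = pattern

    def __getitem__(self, name: str) -> MoietyPattern:
        try:
            return self._patterns[name]
        except KeyError:
            raise PatternError(
                f"unknown moiety pattern {name!r}; known: {sorted(self._patterns)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._patterns

    def __len__(self) -> int:
        return len(self._patterns)

    def names(self) -> list:
        return sorted(self._patterns)

    def copy(self) -> "PatternRegistry":
        return PatternRegistry(self._patterns.values())


def default_pattern_registry() -> PatternRegistry:
    """A fresh registry holding the built-in patterns."""
    return PatternRegistry(builtin_patterns())


def register_pattern(
    registry: PatternRegistry, pattern: MoietyPattern, overwrite: bool = False
) -> PatternRegistry:
    """Register (or overwrite) a pattern; returns the registry for chaining."""
    registry.register(pattern, overwrite=overwrite)
    return registry


def match_moiety(fragment: ResidueFragment, pattern: MoietyPattern) -> list:
    """All matches of ``pattern`` inside ``fragment``.

    Returns fragment-local atom-index tuples, deduplicated and sorted
    (ascending lexicographic), so matching order is deterministic.
    SMARTS queries are matched through RDKit; callable queries are invoked
    directly.
    """
    if callable(pattern.query):
        raw = pattern.query(fragment)
    else:
        mol = _fragment_to_rdkit(fragment)
        query = _compile_smarts(pattern.name, pattern.query)
        raw = [tuple(m) for m in mol.GetSubstructMatches(query, uniquify=True)]
    matches = sorted(set(tuple(m) for m in raw))
    if pattern.arity is not None:
        bad = [m for m in matches if len(m) != pattern.arity]
        if bad:
            raise PatternError(
                f"pattern {pattern.name!r}: match {bad[0]} has arity "
                f"{len(bad[0])}, expected {pattern.arity}"
            )
    return matches
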