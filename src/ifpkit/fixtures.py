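"""Parametric synthetic complexes at exact geometries.

Every builder emits a two-residue (or three, for the tripeptide) Structure
whose requested geometric parameter — re-measured from the emitted
coordinates — matches the request to better than 1e-6, which makes
threshold-boundary tests exact rather than approximate.  Fixtures are
geometric probes, not chemistry: elements, charges and bonds are chosen so
the intended moiety patterns match, nothing more.

All builders are deterministic; :func:`jitter` adds seeded Gaussian noise
for randomized property suites.
"""

from __future__ import annotations

import math

import numpy as np

from .chem_model import Atom, ResidueId, Structure
from .errors import StructureError

__all__ = [
    "make_hbond_pair",
    "make_xbond_pair",
    "make_ion_pair",
    "make_metal_site",
    "make_ring_dimer",
    "make_hydrophobic_pair",
    "make_tripeptide",
    "small_molecule",
    "split_chains",
    "jitter",
]

_OH = 0.96   # donor O-H bond length
_CO = 1.23   # carbonyl C=O
_CX = 1.90   # C-Br
_CC = 1.39   # aromatic C-C radius (benzene circumradius)
_CH_AR = 2.47  # benzene H circumradius
_CH = 1.09   # aliphatic C-H


def _structure(atom_specs, bonds, frame_id=0) -> Structure:
    """atom_specs: (element, coords, charge, aromatic, residue, name)."""
    atoms = [
        Atom(
            index=i,
            element=el,
            coords=np.asarray(xyz, dtype=float),
            formal_charge=charge,
            is_aromatic=aromatic,
            bonded_indices=[],
            residue=res,
            name=name,
        )
        for i, (el, xyz, charge, aromatic, res, name) in enumerate(atom_specs)
    ]
    for i, j in bonds:
        atoms[i].bonded_indices.append(j)
        atoms[j].bonded_indices.append(i)
    for a in atoms:
        a.bonded_indices.sort()
    return Structure(atoms, frame_id=frame_id)


def make_hbond_pair(d_DA: float, theta_DHA: float) -> Structure:
    """Water-like donor (O-H) facing a carbonyl-like acceptor (C=O).

    ``d_DA`` is the donor-oxygen...acceptor-oxygen distance; ``theta_DHA``
    the angle at H between H->D and H->A (linear arrangement = 180).
    """
    if d_DA <= 1.0:
        raise StructureError(f"d_DA must be > 1.0 A, got {d_DA}")
    if not (0.0 <= theta_DHA <= 180.0):
        raise StructureError(f"theta_DHA must be in [0, 180], got {theta_DHA}")
    d_atom = np.array([0.0, 0.0, 0.0])
    h_atom = np.array([_OH, 0.0, 0.0])
    theta = math.radians(theta_DHA)
    # Direction of H->A making angle theta with H->D = (-1, 0, 0).
    u = np.array([-math.cos(theta), math.sin(theta), 0.0])
    hu = float(np.dot(h_atom, u))
    disc = hu * hu - float(np.dot(h_atom, h_atom)) + d_DA * d_DA
    if disc < 0:
        raise StructureError(
            f"H placement impossible for d_DA={d_DA}, theta={theta_DHA}"
        )
    s = -hu + math.sqrt(disc)
    a_atom = h_atom + s * u
    c_atom = a_atom + _CO * (u if np.linalg.norm(u) > 0 else np.array([1.0, 0, 0]))
    don = ResidueId("DON", 1, "L")
    acc = ResidueId("ACC", 1, "P")
    return _structure(
        [
            ("O", d_atom, 0, False, don, "OD"),
            ("H", h_atom, 0, False, don, "HD"),
            ("O", a_atom, 0, False, acc, "OA"),
            ("C", c_atom, 0, False, acc, "CA"),
        ],
        bonds=[(0, 1), (2, 3)],
    )


def make_xbond_pair(d_XA: float, theta_X: float, theta_A: float) -> Structure:
    """C-Br donor facing a carbonyl O acceptor.

    ``d_XA`` is the halogen...acceptor distance, ``theta_X`` the angle at the
    halogen between X->D and X->A, and ``theta_A`` the angle at the acceptor
    between A->X and A->R (R = the carbonyl carbon).
    """
    if d_XA <= 0:
        raise StructureError(f"d_XA must be > 0, got {d_XA}")
    for label, theta in (("theta_X", theta_X), ("theta_A", theta_A)):
        if not (0.0 <= theta <= 180.0):
            raise StructureError(f"{label} must be in [0, 180], got {theta}")
    x_atom = np.array([0.0, 0.0, 0.0])
    d_atom = np.array([_CX, 0.0, 0.0])
    tx = math.radians(theta_X)
    # X->A at angle theta_X from X->D = (+1, 0, 0).
    u = np.array([math.cos(tx), math.sin(tx), 0.0])
    a_atom = x_atom + d_XA * u
    # A->R at angle theta_A from A->X = -u, rotated within the xy-plane.
    ta = math.radians(theta_A)
    ax = -u
    perp = np.array([-ax[1], ax[0], 0.0])
    v = math.cos(ta) * ax + math.sin(ta) * perp
    r_atom = a_atom + _CO * v
    don = ResidueId("XBD", 1, "L")
    acc = ResidueId("ACC", 1, "P")
    return _structure(
        [
            ("C", d_atom, 0, False, don, "CD"),
            ("Br", x_atom, 0, False, don, "BR"),
            ("O", a_atom, 0, False, acc, "OA"),
            ("C", r_atom, 0, False, acc, "CR"),
        ],
        bonds=[(0, 1), (2, 3)],
    )


def make_ion_pair(d: float) -> Structure:
    """Carboxylate-like anion (O, charge -1) at ``d`` from an ammonium-like
    cation (N, charge +1).  The charged atoms sit on the x axis."""
    if d <= 0:
        raise StructureError(f"d must be > 0, got {d}")
    ani = ResidueId("ACT", 1, "L")
    cat = ResidueId("AMM", 1, "P")
    return _structure(
        [
            ("C", (-1.25, 0.0, 0.0), 0, False, ani, "C"),
            ("O", (0.0, 0.0, 0.0), -1, False, ani, "O1"),
            ("N", (d, 0.0, 0.0), 1, False, cat, "N"),
            ("H", (d + 0.5, 0.87, 0.0), 0, False, cat, "H1"),
            ("H", (d + 0.5, -0.44, 0.76), 0, False, cat, "H2"),
            ("H", (d + 0.5, -0.44, -0.76), 0, False, cat, "H3"),
        ],
        bonds=[(0, 1), (2, 3), (2, 4), (2, 5)],
    )


def make_metal_site(d: float) -> Structure:
    """Mg(2+) at ``d`` from a carbonyl oxygen."""
    if d <= 0:
        raise StructureError(f"d must be > 0, got {d}")
    met = ResidueId("MG", 1, "L")
    ace = ResidueId("ACE", 1, "P")
    return _structure(
        [
            ("Mg", (0.0, 0.0, 0.0), 2, False, met, "MG"),
            ("O", (d, 0.0, 0.0), 0, False, ace, "O"),
            ("C", (d + _CO, 0.0, 0.0), 0, False, ace, "C"),
        ],
        bonds=[(1, 2)],
    )


def _benzene_atoms(center, tilt_deg, residue, offset_idx):
    """Benzene (C6H6) centred at ``center``, in the z=0 plane rotated by
    ``tilt_deg`` about the x axis through its centroid; a vertex points +x."""
    tilt = math.radians(tilt_deg)
    rot = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, math.cos(tilt), -math.sin(tilt)],
            [0.0, math.sin(tilt), math.cos(tilt)],
        ]
    )
    center = np.asarray(center, dtype=float)
    specs, bonds = [], []
    for k in range(6):
        ang = math.radians(60.0 * k)
        c_local = np.array([_CC * math.cos(ang), _CC * math.sin(ang), 0.0])
        h_local = np.array([_CH_AR * math.cos(ang), _CH_AR * math.sin(ang), 0.0])
        specs.append(("C", center + rot @ c_local, 0, True, residue, f"C{k+1}"))
        specs.append(("H", center + rot @ h_local, 0, False, residue, f"H{k+1}"))
    base = offset_idx
    for k in range(6):
        bonds.append((base + 2 * k, base + 2 * ((k + 1) % 6)))  # C-C ring
        bonds.append((base + 2 * k, base + 2 * k + 1))          # C-H
    return specs, bonds


def make_ring_dimer(gap: float, lateral_offset: float = 0.0, tilt: float = 0.0) -> Structure:
    """Two benzene residues: ring A in the z=0 plane centred at the origin,
    ring B centred at (lateral_offset, 0, gap) and tilted by ``tilt`` degrees
    about the x axis.  Centroid-centroid distance is
    sqrt(gap^2 + lateral_offset^2)."""
    if gap <= 0:
        raise StructureError(f"gap must be > 0, got {gap}")
    res_a = ResidueId("BNA", 1, "L")
    res_b = ResidueId("BNB", 1, "P")
    specs_a, bonds_a = _benzene_atoms((0.0, 0.0, 0.0), 0.0, res_a, 0)
    specs_b, bonds_b = _benzene_atoms((lateral_offset, 0.0, gap), tilt, res_b, 12)
    return _structure(specs_a + specs_b, bonds_a + bonds_b)


def make_hydrophobic_pair(d: float) -> Structure:
    """Two methane molecules with carbons ``d`` apart on the x axis."""
    if d <= 0:
        raise StructureError(f"d must be > 0, got {d}")
    t = _CH / math.sqrt(3.0)
    h_local = [(t, t, t), (t, -t, -t), (-t, t, -t), (-t, -t, t)]
    res_a = ResidueId("MTA", 1, "L")
    res_b = ResidueId("MTB", 1, "P")
    specs, bonds = [], []
    for base, (cx, res) in enumerate(((0.0, res_a), (d, res_b))):
        c_idx = len(specs)
        specs.append(("C", (cx, 0.0, 0.0), 0, False, res, "C"))
        for n, (hx, hy, hz) in enumerate(h_local):
            specs.append(("H", (cx + hx, hy, hz), 0, False, res, f"H{n+1}"))
            bonds.append((c_idx, c_idx + n + 1))
    return _structure(specs, bonds)


def make_tripeptide() -> Structure:
    """A minimal glycine-like tripeptide (N, CA, C, O backbone per residue,
    amide H on residues 2-3), chained along x, for fragmentation tests."""
    specs, bonds = [], []
    prev_c = None
    for r in range(3):
        rid = ResidueId("GLY", r + 1, "A")
        x0 = 3.8 * r
        n_idx = len(specs)
        specs.append(("N", (x0, 0.0, 0.0), 0, False, rid, "N"))
        specs.append(("C", (x0 + 1.2, 0.9, 0.0), 0, False, rid, "CA"))
        specs.append(("C", (x0 + 2.5, 0.1, 0.0), 0, False, rid, "C"))
        specs.append(("O", (x0 + 2.6, -1.1, 0.0), 0, False, rid, "O"))
        bonds += [(n_idx, n_idx + 1), (n_idx + 1, n_idx + 2), (n_idx + 2, n_idx + 3)]
        if r > 0:
            h_idx = len(specs)
            specs.append(("H", (x0 - 0.4, -0.85, 0.0), 0, False, rid, "H"))
            bonds.append((n_idx, h_idx))
        if prev_c is not None:
            bonds.append((prev_c, n_idx))  # peptide bond, cut on fragmentation
        prev_c = n_idx + 2
    return _structure(specs, bonds)


def small_molecule(kind: str, residue: ResidueId | None = None) -> Structure:
    """Single-residue reference molecules for moiety truth tables.

    kinds: benzene, methane, methanol, ammonium, methylammonium, acetate,
    chlorobenzene, mg_ion, cf4.
    """
    rid = residue or ResidueId("UNL", 1, "")
    t = _CH / math.sqrt(3.0)
    h_tet = [(t, t, t), (t, -t, -t), (-t, t, -t), (-t, -t, t)]

    if kind == "benzene":
        specs, bonds = _benzene_atoms((0.0, 0.0, 0.0), 0.0, rid, 0)
        return _structure(specs, bonds)
    if kind == "chlorobenzene":
        specs, bonds = _benzene_atoms((0.0, 0.0, 0.0), 0.0, rid, 0)
        # replace H1 (index 1) by Cl further out along +x
        el, xyz, q, ar, res, name = specs[1]
        specs[1] = ("Cl", (2.96, 0.0, 0.0), 0, False, res, "CL")
        return _structure(specs, bonds)
    if kind == "methane":
        specs = [("C", (0.0, 0.0, 0.0), 0, False, rid, "C")]
        bonds = []
        for n, h in enumerate(h_tet):
            specs.append(("H", h, 0, False, rid, f"H{n+1}"))
            bonds.append((0, n + 1))
        return _structure(specs, bonds)
    if kind == "cf4":
        specs = [("C", (0.0, 0.0, 0.0), 0, False, rid, "C")]
        bonds = []
        for n, h in enumerate(h_tet):
            specs.append(("F", tuple(1.3 * v for v in h), 0, False, rid, f"F{n+1}"))
            bonds.append((0, n + 1))
        return _structure(specs, bonds)
    if kind == "methanol":
        return _structure(
            [
                ("C", (0.0, 0.0, 0.0), 0, False, rid, "C"),
                ("O", (1.43, 0.0, 0.0), 0, False, rid, "O"),
                ("H", (1.43 + _OH * math.cos(1.9), _OH * math.sin(1.9), 0.0), 0,
                 False, rid, "HO"),
                ("H", h_tet[1], 0, False, rid, "H1"),
                ("H", h_tet[2], 0, False, rid, "H2"),
                ("H", h_tet[3], 0, False, rid, "H3"),
            ],
            bonds=[(0, 1), (1, 2), (0, 3), (0, 4), (0, 5)],
        )
    if kind == "ammonium":
        specs = [("N", (0.0, 0.0, 0.0), 1, False, rid, "N")]
        bonds = []
        for n, h in enumerate(h_tet):
            specs.append(("H", h, 0, False, rid, f"H{n+1}"))
            bonds.append((0, n + 1))
        return _structure(specs, bonds)
    if kind == "methylammonium":
        specs = [
            ("C", (0.0, 0.0, 0.0), 0, False, rid, "C"),
            ("N", (1.49, 0.0, 0.0), 1, False, rid, "N"),
        ]
        bonds = [(0, 1)]
        for n, h in enumerate(h_tet[1:]):
            specs.append(("H", h, 0, False, rid, f"HC{n+1}"))
            bonds.append((0, len(specs) - 1))
        for n, h in enumerate(h_tet[1:]):
            specs.append(("H", tuple(1.49 + v if i == 0 else -v for i, v in enumerate(h)),
                          0, False, rid, f"HN{n+1}"))
            bonds.append((1, len(specs) - 1))
        return _structure(specs, bonds)
    if kind == "acetate":
        return _structure(
            [
                ("C", (0.0, 0.0, 0.0), 0, False, rid, "CH3"),
                ("C", (1.52, 0.0, 0.0), 0, False, rid, "C"),
                ("O", (2.15, 1.06, 0.0), 0, False, rid, "O1"),
                ("O", (2.15, -1.06, 0.0), -1, False, rid, "O2"),
                ("H", h_tet[1], 0, False, rid, "H1"),
                ("H", h_tet[2], 0, False, rid, "H2"),
                ("H", h_tet[3], 0, False, rid, "H3"),
            ],
            bonds=[(0, 1), (1, 2), (1, 3), (0, 4), (0, 5), (0, 6)],
        )
    if kind == "mg_ion":
        return _structure([("Mg", (0.0, 0.0, 0.0), 2, False, rid, "MG")], bonds=[])
    raise ValueError(f"unknown small molecule kind {kind!r}")


def split_chains(structure: Structure, lig_chains=("L",)) -> tuple:
    """Split a combined fixture into (ligand, protein) Structures by chain.

    Atoms are re-indexed per side; bonds crossing the split are dropped
    (fixtures never have any).
    """
    lig_chains = set(lig_chains)
    sides: dict[bool, list] = {True: [], False: []}
    for atom in structure.atoms:
        sides[atom.residue.chain in lig_chains].append(atom)

    def rebuild(atoms):
        local_of = {a.index: i for i, a in enumerate(atoms)}
        return Structure(
            [
                Atom(
                    index=i,
                    element=a.element,
                    coords=a.coords.copy(),
                    formal_charge=a.formal_charge,
                    is_aromatic=a.is_aromatic,
                    bonded_indices=sorted(
                        local_of[j] for j in a.bonded_indices if j in local_of
                    ),
                    residue=a.residue,
                    name=a.name,
                    serial=a.serial,
                )
                for i, a in enumerate(atoms)
            ],
            frame_id=structure.frame_id,
        )

    if not sides[True] or not sides[False]:
        raise StructureError("split_chains: one side is empty")
    return rebuild(sides[True]), rebuild(sides[False])


def jitter(structure: Structure, sigma: float, seed: int) -> Structure:
    """Seeded Gaussian coordinate noise (std ``sigma`` A per component)."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(structure.n_atoms, 3))
    atoms = []
    for atom, delta in zip(structure.atoms, noise):
        atoms.append(
            Atom(
                index=atom.index,
                element=atom.element,
                coords=atom.coords + delta,
                formal_charge=atom.formal_charge,
                is_aromatic=atom.is_aromatic,
                bonded_indices=list(atom.bonded_indices),
                residue=atom.residue,
                name=atom.name,
                serial=atom.serial,
            )
        )
    return Structure(atoms, frame_id=structure.frame_id)
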