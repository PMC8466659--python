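"""Shared structure builders for tests."""

from __future__ import annotations

import math

import numpy as np

from ifpkit.chem_model import Atom, ResidueId, Structure
from ifpkit.fixtures import _benzene_atoms  # deterministic benzene template


def cation_ring(dist: float, angle_deg: float) -> Structure:
    """Benzene (chain P) plus an ammonium-like N+ (chain L).

    The cation sits ``dist`` from the ring centroid, at ``angle_deg`` from
    the ring normal (0 = directly above the centroid, 90 = in-plane).
    """
    ring_res = ResidueId("BNZ", 1, "P")
    cat_res = ResidueId("AMM", 1, "L")
    specs, bonds = _benzene_atoms((0.0, 0.0, 0.0), 0.0, ring_res, 0)
    theta = math.radians(angle_deg)
    pos = (dist * math.sin(theta), 0.0, dist * math.cos(theta))
    specs.append(("N", pos, 1, False, cat_res, "N"))
    atoms = [
        Atom(index=i, element=el, coords=np.asarray(xyz, float),
             formal_charge=q, is_aromatic=ar, bonded_indices=[], residue=res,
             name=name)
        for i, (el, xyz, q, ar, res, name) in enumerate(specs)
    ]
    for i, j in bonds:
        atoms[i].bonded_indices.append(j)
        atoms[j].bonded_indices.append(i)
    for a in atoms:
        a.bonded_indices.sort()
    return Structure(atoms)


def two_point_structure(el1, el2, d, res1=("AAA", 1, "L"), res2=("BBB", 1, "P"),
                        charge1=0, charge2=0) -> Structure:
    """Two lone atoms ``d`` apart on the x axis, one residue each."""
    r1, r2 = ResidueId(*res1), ResidueId(*res2)
    atoms = [
        Atom(index=0, element=el1, coords=np.array([0.0, 0.0, 0.0]),
             formal_charge=charge1, residue=r1, name=el1),
        Atom(index=1, element=el2, coords=np.array([d, 0.0, 0.0]),
             formal_charge=charge2, residue=r2, name=el2),
    ]
    return Structure(atoms)
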