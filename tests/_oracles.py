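"""Independent brute-force oracles for the detection geometry.

Everything here is deliberately naive and self-contained: per-atom predicate
loops, exhaustive pair enumeration, eigendecomposition plane fits and
hard-coded default thresholds.  It shares no code path with the package
detectors it is used to check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

HALOGENS = {"Cl", "Br", "I", "At"}
METALS = {"Ca", "Cd", "Co", "Cu", "Fe", "Mg", "Mn", "Ni", "Zn"}
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52}


def dist(p, q):
    return math.dist(tuple(p), tuple(q))


def angle_at(a, vertex, b):
    u = np.asarray(a, float) - np.asarray(vertex, float)
    v = np.asarray(b, float) - np.asarray(vertex, float)
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def vec_angle(u, v, fold=False):
    u, v = np.asarray(u, float), np.asarray(v, float)
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    theta = math.degrees(math.acos(max(-1.0, min(1.0, c))))
    if fold and theta > 90.0:
        theta = 180.0 - theta
    return theta


def plane_normal(points):
    pts = np.asarray(points, float)
    centred = pts - pts.mean(axis=0)
    _, vecs = np.linalg.eigh(centred.T @ centred)
    return vecs[:, 0]  # eigenvector of the smallest eigenvalue


def _connected(nodes, adj):
    nodes = set(nodes)
    stack = [next(iter(nodes))]
    seen = set()
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        stack.extend((adj[n] & nodes) - seen)
    return seen == nodes


def rings(frag):
    """Aromatic 5/6-rings by exhaustive subset enumeration."""
    arom = [a.index for a in frag.atoms if a.is_aromatic]
    adj = {
        a.index: {j for j in a.bonded_indices if frag.atoms[j].is_aromatic}
        for a in frag.atoms
    }
    found = set()
    for size in (5, 6):
        for combo in combinations(arom, size):
            s = set(combo)
            if all(len(adj[i] & s) == 2 for i in combo) and _connected(s, adj):
                found.add(tuple(sorted(combo)))
    return sorted(found)


# -- moiety atom lists ------------------------------------------------------

def anions(frag):
    return [a.index for a in frag.atoms if a.formal_charge <= -1]


def cations(frag):
    return [a.index for a in frag.atoms if a.formal_charge >= 1]


def hb_donors(frag):
    out = []
    for a in frag.atoms:
        if a.element in {"N", "O", "S"}:
            for j in a.bonded_indices:
                if frag.atoms[j].element == "H":
                    out.append((a.index, j))
    return out


def hb_acceptors(frag):
    return [
        a.index
        for a in frag.atoms
        if (a.element in {"N", "O", "F"} or a.formal_charge <= -1)
        and a.formal_charge < 1
    ]


def xb_donors(frag):
    out = []
    for a in frag.atoms:
        if a.element in {"C", "N", "Si", "F", "Cl", "Br", "I"}:
            for j in a.bonded_indices:
                if frag.atoms[j].element in HALOGENS:
                    out.append((a.index, j))
    return out


def xb_acceptors(frag):
    out = []
    for a in frag.atoms:
        if (a.element in {"N", "O", "P", "S", "Se", "Te"} or a.is_aromatic) \
                and a.formal_charge < 1:
            for j in a.bonded_indices:
                out.append((a.index, j))
    return out


def metals(frag):
    return [a.index for a in frag.atoms if a.element in METALS]


def metal_ligands(frag):
    return [
        a.index
        for a in frag.atoms
        if (a.element in {"O", "N"} or a.formal_charge <= -1) and a.formal_charge < 1
    ]


def hydrophobics(frag):
    return [
        a.index
        for a in frag.atoms
        if a.element in {"C", "S", "F", "Cl", "Br", "I", "At"} and a.formal_charge == 0
    ]


# -- naive detectors --------------------------------------------------------

def _dist_pair(lig, prot, lsel, psel, cutoff):
    return any(
        dist(lig.coords[i], prot.coords[j]) <= cutoff
        for i in lsel(lig)
        for j in psel(prot)
    )


def _hbond(donor, acceptor):
    for d, h in hb_donors(donor):
        for a in hb_acceptors(acceptor):
            if dist(donor.coords[d], acceptor.coords[a]) <= 3.5 and \
                    angle_at(donor.coords[d], donor.coords[h], acceptor.coords[a]) >= 130.0:
                return True
    return False


def _xbond(donor, acceptor):
    for d, x in xb_donors(donor):
        for a, r in xb_acceptors(acceptor):
            if dist(donor.coords[x], acceptor.coords[a]) > 3.5:
                continue
            if not (130.0 <= angle_at(donor.coords[d], donor.coords[x],
                                      acceptor.coords[a]) <= 180.0):
                continue
            if not (80.0 <= angle_at(donor.coords[x], acceptor.coords[a],
                                     acceptor.coords[r]) <= 140.0):
                continue
            return True
    return False


def _stacking(lig, prot, ctd_max, angle_lo, angle_hi):
    for lr in rings(lig):
        lpts = lig.coords[list(lr)]
        for pr in rings(prot):
            ppts = prot.coords[list(pr)]
            if dist(lpts.mean(axis=0), ppts.mean(axis=0)) > ctd_max:
                continue
            theta = vec_angle(plane_normal(lpts), plane_normal(ppts), fold=True)
            if not (angle_lo <= theta <= angle_hi):
                continue
            min_d = min(dist(p, q) for p in lpts for q in ppts)
            if min_d <= 3.8:
                return True
    return False


def _pi_cation(cation_frag, ring_frag):
    for c in cations(cation_frag):
        cp = cation_frag.coords[c]
        for r in rings(ring_frag):
            pts = ring_frag.coords[list(r)]
            ctd = pts.mean(axis=0)
            if dist(cp, ctd) > 4.5:
                continue
            if vec_angle(plane_normal(pts), cp - ctd, fold=True) <= 30.0:
                return True
    return False


def _vdw(lig, prot):
    for i, a in enumerate(lig.atoms):
        for j, b in enumerate(prot.atoms):
            cutoff = VDW_RADII[a.element] + VDW_RADII[b.element] + 0.6
            if dist(lig.coords[i], prot.coords[j]) <= cutoff:
                return True
    return False


def detect(name, lig, prot) -> bool:
    """Naive presence for any built-in interaction name."""
    if name == "Anionic":
        return _dist_pair(lig, prot, anions, cations, 4.5)
    if name == "Cationic":
        return _dist_pair(lig, prot, cations, anions, 4.5)
    if name == "Hydrophobic":
        return _dist_pair(lig, prot, hydrophobics, hydrophobics, 4.5)
    if name == "MetalDonor":
        return _dist_pair(lig, prot, metals, metal_ligands, 2.8)
    if name == "MetalAcceptor":
        return _dist_pair(lig, prot, metal_ligands, metals, 2.8)
    if name == "HBDonor":
        return _hbond(lig, prot)
    if name == "HBAcceptor":
        return _hbond(prot, lig)
    if name == "XBDonor":
        return _xbond(lig, prot)
    if name == "XBAcceptor":
        return _xbond(prot, lig)
    if name == "PiStacking":
        return _stacking(lig, prot, 6.0, 0.0, 90.0)
    if name == "EdgeToFace":
        return _stacking(lig, prot, 6.0, 50.0, 90.0)
    if name == "FaceToFace":
        return _stacking(lig, prot, 4.5, 0.0, 40.0)
    if name == "CationPi":
        return _pi_cation(lig, prot)
    if name == "PiCation":
        return _pi_cation(prot, lig)
    if name == "VdWContact":
        return _vdw(lig, prot)
    raise KeyError(name)
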