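"""Pure geometry kernels: centroids, ring normals, angles, distances, radii.

All lengths are in Angstrom, all angles in degrees.  Ring-plane normals come
from an SVD plane fit and carry an arbitrary sign, so angle comparisons that
involve a normal must be folded to [0, 90] by the caller (``fold_to_90``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "centroid",
    "ring_normal",
    "angle_between",
    "min_pairwise_distance",
    "VdwRadiusTable",
    "vdw_sum",
]

_DEGENERACY_RATIO = 1e-8


def _as_points(points, name: str) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name}: empty point list")
    arr = arr.reshape(-1, 3)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite coordinates")
    return arr


def centroid(points) -> np.ndarray:
    """Arithmetic mean of a nonempty list of 3D points."""
    return _as_points(points, "centroid").mean(axis=0)


def ring_normal(points) -> np.ndarray:
    """Unit normal of the least-squares plane through >= 3 points.

    The sign of the returned vector is unspecified.  Raises ``ValueError``
    for fewer than 3 points or (near-)collinear input.
    """
    arr = _as_points(points, "ring_normal")
    if arr.shape[0] < 3:
        raise ValueError("ring_normal: need at least 3 points")
    centred = arr - arr.mean(axis=0)
    _, s, vh = np.linalg.svd(centred, full_matrices=False)
    if s[0] == 0.0 or s[1] / s[0] < _DEGENERACY_RATIO:
        raise ValueError("ring_normal: points are collinear or degenerate")
    return vh[2]


def angle_between(u, v, fold_to_90: bool = False) -> float:
    """Angle between two nonzero vectors, in degrees.

    Result lies in [0, 180]; with ``fold_to_90`` angles above 90 are mapped
    to ``180 - angle``, which absorbs the sign ambiguity of plane normals.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle_between: zero-length vector")
    cosine = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosine)))
    if fold_to_90 and angle > 90.0:
        angle = 180.0 - angle
    return angle


def min_pairwise_distance(a, b) -> float:
    """Exact minimum distance over all pairs of two nonempty point sets."""
    pa = _as_points(a, "min_pairwise_distance")
    pb = _as_points(b, "min_pairwise_distance")
    diff = pa[:, None, :] - pb[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


@dataclass
class VdwRadiusTable:
    """Element -> van der Waals radius (Angstrom) plus a default tolerance.

    The bundled table (``data/vdw_radii.txt``) uses the Bondi radii with
    Batsanov values for transition metals absent from that set; it is fully
    overridable because published radius sets differ and the choice shifts
    contact cutoffs.
    """

    radii: dict = field(default_factory=dict)
    default_tolerance: float = 0.6

    def __post_init__(self) -> None:
        for el, r in self.radii.items():
            if r <= 0:
                raise ValueError(f"vdW radius for {el!r} must be > 0, got {r}")

    def __getitem__(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} not in vdW radius table"
            ) from None

    def __contains__(self, element: str) -> bool:
        return element in self.radii

    @classmethod
    def from_file(cls, path, default_tolerance: float = 0.6) -> "VdwRadiusTable":
        """Load a two-column (element, radius in Angstrom) text table.

        Blank lines and ``#`` comments are ignored.
        """
        radii: dict[str, float] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'element radius', got {line!r}"
                )
            radii[parts[0]] = float(parts[1])
        return cls(radii=radii, default_tolerance=default_tolerance)

    @classmethod
    def default(cls) -> "VdwRadiusTable":
        """The bundled radius table."""
        ref = resources.files("ifpkit").joinpath("data/vdw_radii.txt")
        with resources.as_file(ref) as path:
            return cls.from_file(path)


def vdw_sum(
    el1: str, el2: str, table: VdwRadiusTable, tolerance: float | None = None
) -> float:
    """r1 + r2 + tolerance; tolerance defaults to the table's default."""
    if tolerance is None:
        tolerance = table.default_tolerance
    return table[el1] + table[el2] + tolerance
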