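"""Geometric interaction detectors.

Each detector implements the ``detect`` contract: given a ligand fragment and
a protein fragment it returns a :class:`DetectionResult` — a Boolean plus the
parent atom indices responsible on each side.  Detectors stop at the first
match pair satisfying all constraints (deterministic under the moiety match
order); ``detect_all`` enumerates every satisfying pair for atom-frequency
statistics.

Angle conventions (documented because they vary between tools):

* Hydrogen bond — the angle is measured AT the hydrogen, between H->D and
  H->A, so a linear D-H...A arrangement is ~180 deg and the window is
  [130, 180].  The governing distance is donor...acceptor (heavy atoms).
* Halogen bond — both windows constrain one geometry: [130, 180] at the
  halogen (X->D vs X->A) and [80, 140] at the acceptor (A->X vs A->R).
* Ring-plane and normal-vs-direction angles are folded to [0, 90] before
  range tests (plane normals have arbitrary sign).

All "<=" thresholds are inclusive.  A tiny epsilon (1e-9 A / deg) guards the
comparisons against float rounding in coordinates constructed exactly at a
boundary; it is far below any physically meaningful resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator

import numpy as np

from .chem_model import (
    PatternRegistry,
    ResidueFragment,
    default_pattern_registry,
)
from .errors import DetectionContractError, PatternError
from .geometry import (
    VdwRadiusTable,
    angle_between,
    centroid,
    min_pairwise_distance,
    ring_normal,
    vdw_sum,
)

__all__ = [
    "EPS",
    "DetectionResult",
    "InteractionDefinition",
    "Interaction",
    "CustomInteraction",
    "VdWContact",
    "InteractionRegistry",
    "builtin_definitions",
    "builtin_interactions",
    "default_interaction_registry",
    "configure",
    "register_interaction",
    "DEFAULT_INTERACTIONS",
    "save_definitions",
    "load_definitions",
]

#: Inclusive-comparison guard for float rounding at exact boundaries.
EPS = 1e-9

#: Interactions evaluated by default by the fingerprint engine.
DEFAULT_INTERACTIONS = (
    "Hydrophobic",
    "PiStacking",
    "PiCation",
    "CationPi",
    "Anionic",
    "Cationic",
    "HBDonor",
    "HBAcceptor",
)

_TWINS = {
    "HBDonor": "HBAcceptor",
    "HBAcceptor": "HBDonor",
    "XBDonor": "XBAcceptor",
    "XBAcceptor": "XBDonor",
    "Anionic": "Cationic",
    "Cationic": "Anionic",
    "CationPi": "PiCation",
    "PiCation": "CationPi",
    "MetalDonor": "MetalAcceptor",
    "MetalAcceptor": "MetalDonor",
}


@dataclass(frozen=True)
class DetectionResult:
    """Boolean presence plus responsible parent atom indices per side."""

    present: bool
    ligand_atoms: tuple = ()
    protein_atoms: tuple = ()

    def __post_init__(self) -> None:
        if self.present and (not self.ligand_atoms or not self.protein_atoms):
            raise DetectionContractError(
                "present=True requires nonempty atom index lists"
            )
        if not self.present and (self.ligand_atoms or self.protein_atoms):
            raise DetectionContractError(
                "present=False requires empty atom index lists"
            )

    def __bool__(self) -> bool:
        return self.present


ABSENT = DetectionResult(False)


@dataclass(frozen=True)
class InteractionDefinition:
    """A named geometric rule pairing two moiety roles with thresholds.

    ``angle_ranges`` maps a labelled angle (detector-specific) to an
    inclusive [lo, hi] window in degrees.  ``ring_min_distance_max`` is the
    extra minimum ring-ring interatomic distance cutoff used by the stacking
    variants.  ``symmetric_inverse`` names the role-swapped twin, if any.
    """

    name: str
    ligand_moiety: str | None
    protein_moiety: str | None
    distance_max: float
    angle_ranges: tuple = ()
    ring_min_distance_max: float | None = None
    symmetric_inverse: str | None = None

    def __post_init__(self) -> None:
        if self.distance_max <= 0:
            raise ValueError(
                f"{self.name}: distance_max must be > 0, got {self.distance_max}"
            )
        for label, (lo, hi) in self.angle_ranges:
            if not (0 <= lo <= hi <= 180):
                raise ValueError(
                    f"{self.name}: bad angle window {label}=[{lo}, {hi}]"
                )
        if self.ring_min_distance_max is not None and self.ring_min_distance_max <= 0:
            raise ValueError(f"{self.name}: ring_min_distance_max must be > 0")

    def angle_window(self, label: str) -> tuple:
        for key, window in self.angle_ranges:
            if key == label:
                return window
        raise KeyError(f"{self.name}: no angle window {label!r}")


def _in_window(value: float, window: tuple) -> bool:
    lo, hi = window
    return (lo - EPS) <= value <= (hi + EPS)


def _within(value: float, cutoff: float) -> bool:
    return value <= cutoff + EPS


class Matcher:
    """Resolves moiety matches, with per-run caching keyed by fragment."""

    def __init__(self, patterns: PatternRegistry | None = None):
        self.patterns = patterns if patterns is not None else default_pattern_registry()
        self._cache: dict = {}

    def matches(self, fragment: ResidueFragment, name: str) -> list:
        from .chem_model import match_moiety

        key = (id(fragment), name)
        if key not in self._cache:
            self._cache[key] = match_moiety(fragment, self.patterns[name])
        return self._cache[key]


class Interaction:
    """Base detector; subclasses implement ``_iter_hits``.

    ``_iter_hits`` yields (ligand_local_indices, protein_local_indices)
    tuples for every satisfying match pair, in deterministic order.
    """

    def __init__(self, definition: InteractionDefinition):
        self.definition = definition

    @property
    def name(self) -> str:
        return self.definition.name

    def _iter_hits(
        self, lig: ResidueFragment, prot: ResidueFragment, matcher: Matcher
    ) -> Iterator[tuple]:
        raise NotImplementedError

    def detect(
        self,
        lig: ResidueFragment,
        prot: ResidueFragment,
        matcher: Matcher | None = None,
    ) -> DetectionResult:
        """First satisfying pair, or an absent result."""
        matcher = matcher or Matcher()
        for lig_local, prot_local in self._iter_hits(lig, prot, matcher):
            return DetectionResult(
                True, lig.to_parent(lig_local), prot.to_parent(prot_local)
            )
        return ABSENT

    def detect_all(
        self,
        lig: ResidueFragment,
        prot: ResidueFragment,
        matcher: Matcher | None = None,
    ) -> list:
        """Every satisfying pair (exhaustive mode for atom statistics)."""
        matcher = matcher or Matcher()
        return [
            DetectionResult(
                True, lig.to_parent(lig_local), prot.to_parent(prot_local)
            )
            for lig_local, prot_local in self._iter_hits(lig, prot, matcher)
        ]

    def configured(self, overrides: dict | None = None, **kw) -> "Interaction":
        """A copy of this detector with a re-configured definition."""
        merged = dict(overrides or {})
        merged.update(kw)
        return type(self)(configure(self.definition, merged))

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.name}>"


class DistancePairInteraction(Interaction):
    """Presence iff some (ligand moiety atom, protein moiety atom) pair is
    within ``distance_max``.  Covers ionic, metal and hydrophobic rules."""

    def _iter_hits(self, lig, prot, matcher):
        defn = self.definition
        for lt in matcher.matches(lig, defn.ligand_moiety):
            lp = lig.coords[lt[0]]
            for pt in matcher.matches(prot, defn.protein_moiety):
                d = float(np.linalg.norm(lp - prot.coords[pt[0]]))
                if _within(d, defn.distance_max):
                    yield (lt[:1], pt[:1])


class HBondInteraction(Interaction):
    """Hydrogen bond: D...A distance plus the angle at H (H->D vs H->A).

    ``donor_side`` selects which fragment carries the donor moiety.
    """

    def __init__(self, definition: InteractionDefinition, donor_side: str):
        super().__init__(definition)
        if donor_side not in ("ligand", "protein"):
            raise ValueError("donor_side must be 'ligand' or 'protein'")
        self.donor_side = donor_side

    def configured(self, overrides=None, **kw):
        merged = dict(overrides or {})
        merged.update(kw)
        return type(self)(configure(self.definition, merged), self.donor_side)

    def _iter_hits(self, lig, prot, matcher):
        defn = self.definition
        window = defn.angle_window("DHA")
        if self.donor_side == "ligand":
            donor, acceptor = lig, prot
            donor_name, acc_name = defn.ligand_moiety, defn.protein_moiety
        else:
            donor, acceptor = prot, lig
            donor_name, acc_name = defn.protein_moiety, defn.ligand_moiety
        for dt in matcher.matches(donor, donor_name):
            d_xyz = donor.coords[dt[0]]
            h_xyz = donor.coords[dt[1]]
            for at in matcher.matches(acceptor, acc_name):
                a_xyz = acceptor.coords[at[0]]
                if not _within(float(np.linalg.norm(d_xyz - a_xyz)), defn.distance_max):
                    continue
                theta = angle_between(d_xyz - h_xyz, a_xyz - h_xyz)
                if _in_window(theta, window):
                    if self.donor_side == "ligand":
                        yield (dt, at[:1])
                    else:
                        yield (at[:1], dt)


class XBondInteraction(Interaction):
    """Halogen bond: X...A distance, angle at X and angle at A."""

    def __init__(self, definition: InteractionDefinition, donor_side: str):
        super().__init__(definition)
        if donor_side not in ("ligand", "protein"):
            raise ValueError("donor_side must be 'ligand' or 'protein'")
        self.donor_side = donor_side

    def configured(self, overrides=None, **kw):
        merged = dict(overrides or {})
        merged.update(kw)
        return type(self)(configure(self.definition, merged), self.donor_side)

    def _iter_hits(self, lig, prot, matcher):
        defn = self.definition
        w_x = defn.angle_window("DXA")
        w_a = defn.angle_window("XAR")
        if self.donor_side == "ligand":
            donor, acceptor = lig, prot
            donor_name, acc_name = defn.ligand_moiety, defn.protein_moiety
        else:
            donor, acceptor = prot, lig
            donor_name, acc_name = defn.protein_moiety, defn.ligand_moiety
        for dt in matcher.matches(donor, donor_name):
            d_xyz = donor.coords[dt[0]]
            x_xyz = donor.coords[dt[1]]
            for at in matcher.matches(acceptor, acc_name):
                a_xyz = acceptor.coords[at[0]]
                r_xyz = acceptor.coords[at[1]]
                if not _within(float(np.linalg.norm(x_xyz - a_xyz)), defn.distance_max):
                    continue
                if not _in_window(angle_between(d_xyz - x_xyz, a_xyz - x_xyz), w_x):
                    continue
                if not _in_window(angle_between(x_xyz - a_xyz, r_xyz - a_xyz), w_a):
                    continue
                if self.donor_side == "ligand":
                    yield (dt, at)
                else:
                    yield (at, dt)


class PiStackingInteraction(Interaction):
    """Aromatic stacking: centroid distance, folded plane angle, and minimum
    ring-ring interatomic distance.  The three stacking variants differ only
    in thresholds."""

    def _iter_hits(self, lig, prot, matcher):
        defn = self.definition
        window = defn.angle_window("planes")
        for lring in matcher.matches(lig, defn.ligand_moiety):
            lpts = lig.coords[list(lring)]
            lctd = centroid(lpts)
            lnorm = ring_normal(lpts)
            for pring in matcher.matches(prot, defn.protein_moiety):
                ppts = prot.coords[list(pring)]
                pctd = centroid(ppts)
                if not _within(float(np.linalg.norm(lctd - pctd)), defn.distance_max):
                    continue
                if not _in_window(
                    angle_between(lnorm, ring_normal(ppts), fold_to_90=True), window
                ):
                    continue
                if defn.ring_min_distance_max is not None and not _within(
                    min_pairwise_distance(lpts, ppts), defn.ring_min_distance_max
                ):
                    continue
                yield (lring, pring)


class PiCationInteraction(Interaction):
    """Cation near a ring centroid, along the ring normal.

    Presence iff cation...centroid distance is within the cutoff and the
    folded angle between the ring normal and the centroid->cation vector is
    inside the window; with several rings any satisfying ring counts.
    """

    def __init__(self, definition: InteractionDefinition, cation_side: str):
        super().__init__(definition)
        if cation_side not in ("ligand", "protein"):
            raise ValueError("cation_side must be 'ligand' or 'protein'")
        self.cation_side = cation_side

    def configured(self, overrides=None, **kw):
        merged = dict(overrides or {})
        merged.update(kw)
        return type(self)(configure(self.definition, merged), self.cation_side)

    def _iter_hits(self, lig, prot, matcher):
        defn = self.definition
        window = defn.angle_window("normal_centroid")
        if self.cation_side == "ligand":
            cat_frag, ring_frag = lig, prot
            cat_name, ring_name = defn.ligand_moiety, defn.protein_moiety
        else:
            cat_frag, ring_frag = prot, lig
            cat_name, ring_name = defn.protein_moiety, defn.ligand_moiety
        for ct in matcher.matches(cat_frag, cat_name):
            c_xyz = cat_frag.coords[ct[0]]
            for ring in matcher.matches(ring_frag, ring_name):
                pts = ring_frag.coords[list(ring)]
                ctd = centroid(pts)
                if not _within(float(np.linalg.norm(c_xyz - ctd)), defn.distance_max):
                    continue
                theta = angle_between(ring_normal(pts), c_xyz - ctd, fold_to_90=True)
                if _in_window(theta, window):
                    if self.cation_side == "ligand":
                        yield (ct, ring)
                    else:
                        yield (ring, ct)


class VdWContact(Interaction):
    """Any-atom contact: distance <= r1 + r2 + tolerance (element-wise radii).

    Moiety-free: every atom pair is a candidate.  ``distance_max`` on the
    definition is only the upper bound used by the engine's pair prefilter.
    """

    def __init__(
        self,
        definition: InteractionDefinition | None = None,
        table: VdwRadiusTable | None = None,
        tolerance: float | None = None,
    ):
        self.table = table if table is not None else VdwRadiusTable.default()
        self.tolerance = (
            tolerance if tolerance is not None else self.table.default_tolerance
        )
        if definition is None:
            max_r = max(self.table.radii.values())
            definition = InteractionDefinition(
                name="VdWContact",
                ligand_moiety=None,
                protein_moiety=None,
                distance_max=2 * max_r + self.tolerance,
            )
        super().__init__(definition)

    def configured(self, overrides=None, **kw):
        merged = dict(overrides or {})
        merged.update(kw)
        tolerance = merged.pop("tolerance", self.tolerance)
        table = merged.pop("table", self.table)
        defn = configure(self.definition, merged) if merged else self.definition
        return type(self)(defn, table=table, tolerance=tolerance)

    def _iter_hits(self, lig, prot, matcher):
        for i, la in enumerate(lig.atoms):
            for j, pa in enumerate(prot.atoms):
                cutoff = vdw_sum(la.element, pa.element, self.table, self.tolerance)
                d = float(np.linalg.norm(lig.coords[i] - prot.coords[j]))
                if _within(d, cutoff):
                    yield ((i,), (j,))


class CustomInteraction(Interaction):
    """Wraps a user-supplied ``detect`` callable into the detect contract.

    The callable receives (lig_fragment, prot_fragment) and returns a
    :class:`DetectionResult` (or a (present, lig_atoms, prot_atoms) triple).
    """

    def __init__(self, name: str, func: Callable, distance_max: float = 6.0):
        definition = InteractionDefinition(
            name=name, ligand_moiety=None, protein_moiety=None,
            distance_max=distance_max,
        )
        super().__init__(definition)
        self.func = func

    def detect(self, lig, prot, matcher=None):
        out = self.func(lig, prot)
        if not isinstance(out, DetectionResult):
            present, lig_atoms, prot_atoms = out
            out = DetectionResult(bool(present), tuple(lig_atoms), tuple(prot_atoms))
        return out

    def detect_all(self, lig, prot, matcher=None):
        out = self.detect(lig, prot, matcher)
        return [out] if out.present else []


# ---------------------------------------------------------------------------
# Built-in definitions
# ---------------------------------------------------------------------------

def builtin_definitions() -> dict:
    """Default rule set: name -> InteractionDefinition.

    The "ligand"/"protein" roles are conventional; every rule applies to any
    molecular pairing.  Distances in Angstrom, angles in degrees, all
    inclusive.
    """
    defs = [
        InteractionDefinition(
            "Anionic", "Anion", "Cation", 4.5, symmetric_inverse="Cationic"
        ),
        InteractionDefinition(
            "Cationic", "Cation", "Anion", 4.5, symmetric_inverse="Anionic"
        ),
        InteractionDefinition(
            "CationPi", "Cation", "Aromatic", 4.5,
            angle_ranges=(("normal_centroid", (0.0, 30.0)),),
            symmetric_inverse="PiCation",
        ),
        InteractionDefinition(
            "PiCation", "Aromatic", "Cation", 4.5,
            angle_ranges=(("normal_centroid", (0.0, 30.0)),),
            symmetric_inverse="CationPi",
        ),
        InteractionDefinition(
            "PiStacking", "Aromatic", "Aromatic", 6.0,
            angle_ranges=(("planes", (0.0, 90.0)),),
            ring_min_distance_max=3.8,
        ),
        InteractionDefinition(
            "EdgeToFace", "Aromatic", "Aromatic", 6.0,
            angle_ranges=(("planes", (50.0, 90.0)),),
            ring_min_distance_max=3.8,
        ),
        InteractionDefinition(
            "FaceToFace", "Aromatic", "Aromatic", 4.5,
            angle_ranges=(("planes", (0.0, 40.0)),),
            ring_min_distance_max=3.8,
        ),
        InteractionDefinition(
            "HBAcceptor", "HBAcceptor", "HBDonor", 3.5,
            angle_ranges=(("DHA", (130.0, 180.0)),),
            symmetric_inverse="HBDonor",
        ),
        InteractionDefinition(
            "HBDonor", "HBDonor", "HBAcceptor", 3.5,
            angle_ranges=(("DHA", (130.0, 180.0)),),
            symmetric_inverse="HBAcceptor",
        ),
        InteractionDefinition(
            "XBAcceptor", "XBAcceptor", "XBDonor", 3.5,
            angle_ranges=(("DXA", (130.0, 180.0)), ("XAR", (80.0, 140.0))),
            symmetric_inverse="XBDonor",
        ),
        InteractionDefinition(
            "XBDonor", "XBDonor", "XBAcceptor", 3.5,
            angle_ranges=(("DXA", (130.0, 180.0)), ("XAR", (80.0, 140.0))),
            symmetric_inverse="XBAcceptor",
        ),
        InteractionDefinition(
            "MetalAcceptor", "MetalLigand", "Metal", 2.8,
            symmetric_inverse="MetalDonor",
        ),
        InteractionDefinition(
            "MetalDonor", "Metal", "MetalLigand", 2.8,
            symmetric_inverse="MetalAcceptor",
        ),
        InteractionDefinition("Hydrophobic", "Hydrophobic", "Hydrophobic", 4.5),
    ]
    return {d.name: d for d in defs}


def _build_detector(defn: InteractionDefinition) -> Interaction:
    name = defn.name
    if name in ("HBDonor", "HBAcceptor") or any(
        k == "DHA" for k, _ in defn.angle_ranges
    ):
        return HBondInteraction(
            defn, donor_side="ligand" if defn.ligand_moiety == "HBDonor" else "protein"
        )
    if name in ("XBDonor", "XBAcceptor") or any(
        k == "DXA" for k, _ in defn.angle_ranges
    ):
        return XBondInteraction(
            defn, donor_side="ligand" if defn.ligand_moiety == "XBDonor" else "protein"
        )
    if defn.ligand_moiety == "Aromatic" and defn.protein_moiety == "Aromatic":
        return PiStackingInteraction(defn)
    if "Aromatic" in (defn.ligand_moiety, defn.protein_moiety) and "Cation" in (
        defn.ligand_moiety,
        defn.protein_moiety,
    ):
        return PiCationInteraction(
            defn, cation_side="ligand" if defn.ligand_moiety == "Cation" else "protein"
        )
    return DistancePairInteraction(defn)


def builtin_interactions(vdw_table: VdwRadiusTable | None = None) -> dict:
    """All built-in detectors (the default rule set plus VdWContact)."""
    out = {name: _build_detector(d) for name, d in builtin_definitions().items()}
    out["VdWContact"] = VdWContact(table=vdw_table)
    return out


class InteractionRegistry:
    """Name -> Interaction mapping used by the fingerprint engine."""

    def __init__(self, interactions: Iterable[Interaction] = ()):
        self._interactions: dict[str, Interaction] = {}
        for inter in interactions:
            self.register(inter)

    def register(self, interaction: Interaction, overwrite: bool = False) -> None:
        if not hasattr(interaction, "detect") or not hasattr(interaction, "name"):
            raise DetectionContractError(
                "interaction must expose .name and .detect(lig, prot)"
            )
        if interaction.name in self._interactions and not overwrite:
            raise PatternError(
                f"interaction {interaction.name!r} already registered "
                "(pass overwrite=True to replace it)"
            )
        self._interactions[interaction.name] = interaction

    def __getitem__(self, name: str) -> Interaction:
        try:
            return self._interactions[name]
        except KeyError:
            raise PatternError(
                f"unknown interaction {name!r}; known: {sorted(self._interactions)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._interactions

    def __len__(self) -> int:
        return len(self._interactions)

    def names(self) -> list:
        return sorted(self._interactions)

    def copy(self) -> "InteractionRegistry":
        return InteractionRegistry(self._interactions.values())


def default_interaction_registry(
    vdw_table: VdwRadiusTable | None = None,
) -> InteractionRegistry:
    return InteractionRegistry(builtin_interactions(vdw_table).values())


def register_interaction(
    registry: InteractionRegistry,
    interaction: Interaction,
    overwrite: bool = False,
) -> InteractionRegistry:
    """Register a detector (built-in or custom); returns the registry."""
    registry.register(interaction, overwrite=overwrite)
    return registry


_CONFIGURABLE = {
    "distance_max",
    "angle_ranges",
    "ligand_moiety",
    "protein_moiety",
    "ring_min_distance_max",
}


def configure(
    defn: InteractionDefinition, overrides: dict | None = None, **kw
) -> InteractionDefinition:
    """A new definition with thresholds/moieties overridden.

    Unknown keys raise ``KeyError``; invariant violations (e.g. a negative
    distance) raise ``ValueError``.  The original definition is untouched.
    """
    merged = dict(overrides or {})
    merged.update(kw)
    unknown = set(merged) - _CONFIGURABLE
    if unknown:
        raise KeyError(
            f"{defn.name}: unknown configure keys {sorted(unknown)}; "
            f"allowed: {sorted(_CONFIGURABLE)}"
        )
    if "angle_ranges" in merged:
        merged["angle_ranges"] = tuple(
            (str(label), (float(lo), float(hi)))
            for label, (lo, hi) in merged["angle_ranges"]
        )
    return replace(defn, **merged)


# ---------------------------------------------------------------------------
# Definition serialization (reproducible threshold overrides)
# ---------------------------------------------------------------------------

def save_definitions(definitions: Iterable[InteractionDefinition], path) -> None:
    """Write definitions to a JSON config file."""
    payload = {
        d.name: {
            "ligand_moiety": d.ligand_moiety,
            "protein_moiety": d.protein_moiety,
            "distance_max": d.distance_max,
            "angle_ranges": [[label, list(window)] for label, window in d.angle_ranges],
            "ring_min_distance_max": d.ring_min_distance_max,
            "symmetric_inverse": d.symmetric_inverse,
        }
        for d in definitions
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_definitions(path) -> dict:
    """Read definitions from a JSON config file: name -> definition."""
    payload = json.loads(Path(path).read_text())
    out = {}
    for name, spec in payload.items():
        out[name] = InteractionDefinition(
            name=name,
            ligand_moiety=spec.get("ligand_moiety"),
            protein_moiety=spec.get("protein_moiety"),
            distance_max=float(spec["distance_max"]),
            angle_ranges=tuple(
                (label, (float(lo), float(hi)))
                for label, (lo, hi) in spec.get("angle_ranges", [])
            ),
            ring_min_distance_max=spec.get("ring_min_distance_max"),
            symmetric_inverse=spec.get("symmetric_inverse"),
        )
    return out
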