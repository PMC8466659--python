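"""Fingerprint engine: run detectors over frames, store and analyse results.

The engine evaluates each requested interaction for every (ligand residue,
protein residue) pair in every frame and stores present detections together
with the responsible atom indices.  Three consistent views are offered:
per-frame bitvectors over the full (residue x interaction) key space, a
boolean table (frames x observed columns), and per-pair frequencies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_model import ResidueId, Structure
from .errors import DetectionContractError, MissingHydrogensError
from .interactions import (
    DEFAULT_INTERACTIONS,
    DetectionResult,
    Interaction,
    InteractionRegistry,
    Matcher,
    default_interaction_registry,
)

__all__ = [
    "Fingerprint",
    "FingerprintResult",
    "BitVector",
    "run",
    "tanimoto",
]

#: Extra margin added to the largest interaction cutoff by the residue-pair
#: distance prefilter.  Ring criteria are centroid-based, so atom-atom
#: distances can exceed the nominal cutoff by up to two ring radii (~2.9 A);
#: 3.0 A covers that with slack.  A property test verifies the prefilter
#: never changes results.
PREFILTER_MARGIN = 3.0


@dataclass(frozen=True)
class BitVector:
    """Ordered booleans over the fingerprint key space for one frame."""

    bits: np.ndarray
    key: tuple  # tuple of (lig ResidueId | None, prot ResidueId, interaction)

    def __post_init__(self):
        if len(self.bits) != len(self.key):
            raise ValueError("bits and key must have equal length")

    def __len__(self) -> int:
        return len(self.bits)

    def on_bits(self) -> list:
        return [self.key[i] for i in np.flatnonzero(self.bits)]


def tanimoto(a: np.ndarray, b: np.ndarray, empty_value: float = 1.0) -> float:
    """|a AND b| / |a OR b| for boolean vectors; both-empty -> empty_value."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return empty_value
    return int(np.count_nonzero(a & b)) / union


@dataclass
class FingerprintResult:
    """Frame-indexed store of present detections.

    ``entries`` maps (frame, lig ResidueId, prot ResidueId, interaction) to
    the DetectionResult; absent combinations are simply not stored.  The
    interaction order and the residue key space are fixed across frames.
    """

    interaction_names: tuple
    frames: tuple
    lig_residues: tuple
    prot_residues: tuple
    entries: dict = field(default_factory=dict)
    single_ligand: bool = True
    empty_tanimoto: float = 1.0

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    # -- key space ---------------------------------------------------------

    def bit_key(self) -> tuple:
        """Deterministic bit layout: residues in total order, interactions in
        registration order.  The ligand is collapsed to one unit when it is a
        single residue."""
        if self.single_ligand:
            return tuple(
                (None, prot, name)
                for prot in self.prot_residues
                for name in self.interaction_names
            )
        return tuple(
            (lig, prot, name)
            for lig in self.lig_residues
            for prot in self.prot_residues
            for name in self.interaction_names
        )

    def _entry_key_to_bit_key(self, frame_key: tuple) -> tuple:
        _, lig, prot, name = frame_key
        return (None if self.single_ligand else lig, prot, name)

    # -- views -------------------------------------------------------------

    def to_bitvector(self, frame: int) -> BitVector:
        if frame not in self.frames:
            raise KeyError(f"unknown frame {frame}; frames: {self.frames}")
        key = self.bit_key()
        pos = {k: i for i, k in enumerate(key)}
        bits = np.zeros(len(key), dtype=bool)
        for (f, lig, prot, name), dr in self.entries.items():
            if f == frame and dr.present:
                bits[pos[(None if self.single_ligand else lig, prot, name)]] = True
        return BitVector(bits=bits, key=key)

    def to_table(self) -> pd.DataFrame:
        """Boolean table: rows = frames, columns = (ligand, protein,
        interaction) combinations observed at least once."""
        columns = sorted(
            {(lig, prot, name) for (_, lig, prot, name) in self.entries},
            key=lambda k: (k[0].sort_key, k[1].sort_key, self.interaction_names.index(k[2])),
        )
        index = pd.Index(self.frames, name="Frame")
        if not columns:
            return pd.DataFrame(index=index)
        data = np.zeros((len(self.frames), len(columns)), dtype=bool)
        frame_pos = {f: i for i, f in enumerate(self.frames)}
        col_pos = {c: j for j, c in enumerate(columns)}
        for (f, lig, prot, name), dr in self.entries.items():
            if dr.present:
                data[frame_pos[f], col_pos[(lig, prot, name)]] = True
        cols = pd.MultiIndex.from_tuples(
            [(str(l), str(p), n) for l, p, n in columns],
            names=["ligand", "protein", "interaction"],
        )
        return pd.DataFrame(data, index=index, columns=cols)

    def frequencies(self) -> dict:
        """(lig, prot, interaction) -> fraction of frames present, in [0,1]."""
        if self.n_frames == 0:
            raise ValueError("frequencies undefined for a 0-frame result")
        counts: dict[tuple, int] = {}
        for (f, lig, prot, name), dr in self.entries.items():
            if dr.present:
                counts[(lig, prot, name)] = counts.get((lig, prot, name), 0) + 1
        return {k: v / self.n_frames for k, v in sorted(
            counts.items(),
            key=lambda kv: (kv[0][0].sort_key, kv[0][1].sort_key, kv[0][2]),
        )}

    def residue_frequencies(self) -> dict:
        """protein ResidueId -> fraction of frames with ANY interaction."""
        if self.n_frames == 0:
            raise ValueError("frequencies undefined for a 0-frame result")
        seen: dict[ResidueId, set] = {}
        for (f, _, prot, _), dr in self.entries.items():
            if dr.present:
                seen.setdefault(prot, set()).add(f)
        return {
            rid: len(frames) / self.n_frames
            for rid, frames in sorted(seen.items(), key=lambda kv: kv[0].sort_key)
        }

    def tanimoto_matrix(self) -> np.ndarray:
        """Symmetric n_frames x n_frames matrix of pairwise Tanimoto values."""
        vectors = [self.to_bitvector(f).bits for f in self.frames]
        n = len(vectors)
        mat = np.ones((n, n), dtype=float)
        for i in range(n):
            for j in range(i, n):
                t = tanimoto(vectors[i], vectors[j], empty_value=self.empty_tanimoto)
                mat[i, j] = mat[j, i] = t
        return mat

    def to_csv(self, path) -> None:
        """Long-format CSV: frame, ligand, protein, interaction, present,
        lig_atoms, prot_atoms.  Row order fully deterministic."""
        rows = sorted(
            (
                (f, str(lig), str(prot), name,
                 " ".join(map(str, dr.ligand_atoms)),
                 " ".join(map(str, dr.protein_atoms)))
                for (f, lig, prot, name), dr in self.entries.items()
                if dr.present
            ),
        )
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["frame", "ligand", "protein", "interaction", "present",
                 "lig_atoms", "prot_atoms"]
            )
            for f, lig, prot, name, la, pa in rows:
                writer.writerow([f, lig, prot, name, True, la, pa])


class Fingerprint:
    """Configurable engine evaluating a set of interactions over frames.

    Parameters
    ----------
    interactions:
        Interaction names (resolved against ``registry``) and/or Interaction
        instances.  Defaults to the standard set: Hydrophobic, PiStacking,
        PiCation, CationPi, Anionic, Cationic, HBDonor, HBAcceptor.
    registry:
        InteractionRegistry used to resolve names (default: built-ins).
    patterns:
        PatternRegistry for moiety matching (default: built-ins).
    prefilter:
        Skip residue pairs whose closest atoms are beyond every cutoff
        (pure optimization; results are provably unchanged).
    """

    def __init__(
        self,
        interactions: Sequence | None = None,
        registry: InteractionRegistry | None = None,
        patterns=None,
        prefilter: bool = True,
        empty_tanimoto: float = 1.0,
    ):
        registry = registry or default_interaction_registry()
        if interactions is None:
            interactions = list(DEFAULT_INTERACTIONS)
        resolved: list[Interaction] = []
        for item in interactions:
            resolved.append(registry[item] if isinstance(item, str) else item)
        names = [i.name for i in resolved]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate interaction names: {names}")
        self.interactions = resolved
        self.patterns = patterns
        self.prefilter = prefilter
        self.empty_tanimoto = empty_tanimoto

    @property
    def interaction_names(self) -> tuple:
        return tuple(i.name for i in self.interactions)

    def _max_cutoff(self) -> float:
        return max(i.definition.distance_max for i in self.interactions)

    def run(
        self,
        lig_frames: Sequence[Structure] | Structure,
        prot_frames: Sequence[Structure] | Structure,
        selection=None,
    ) -> FingerprintResult:
        """Evaluate all interactions for every residue pair in every frame.

        ``lig_frames`` and ``prot_frames`` must be index-aligned sequences of
        equal length (a bare Structure counts as one frame).  Passing the
        identical sequence (or frame objects) on both sides switches to
        intramolecular mode: each unordered residue pair is evaluated once
        and self-pairs are skipped.  ``selection`` optionally restricts
        protein residues (an iterable of ResidueId or a predicate).
        """
        intra = lig_frames is prot_frames
        if isinstance(lig_frames, Structure):
            lig_frames = [lig_frames]
        if isinstance(prot_frames, Structure):
            prot_frames = [prot_frames]
        lig_frames = list(lig_frames)
        prot_frames = list(prot_frames)
        if len(lig_frames) != len(prot_frames):
            raise ValueError(
                f"mismatched frame counts: {len(lig_frames)} ligand vs "
                f"{len(prot_frames)} protein"
            )
        intra = intra or all(
            l is p for l, p in zip(lig_frames, prot_frames)
        ) and len(lig_frames) > 0

        if selection is not None and not callable(selection):
            wanted = set(selection)
            selection = lambda rid: rid in wanted  # noqa: E731

        needs_h = any(
            inter.name in ("HBDonor", "HBAcceptor") for inter in self.interactions
        )
        if needs_h and lig_frames:
            if not (lig_frames[0].has_hydrogens() or prot_frames[0].has_hydrogens()):
                raise MissingHydrogensError(
                    "H-bond detection requested but no explicit hydrogens "
                    "found in either structure; prepare inputs with explicit H"
                )

        matcher = Matcher(self.patterns)
        entries: dict = {}
        lig_resids: set = set()
        prot_resids: set = set()
        cutoff = self._max_cutoff() + PREFILTER_MARGIN

        for frame_idx, (ligs, prots) in enumerate(zip(lig_frames, prot_frames)):
            lig_fragments = ligs.residues
            prot_fragments = prots.residues
            lig_resids.update(f.residue_id for f in lig_fragments)
            for pf in prot_fragments:
                if selection is None or selection(pf.residue_id):
                    prot_resids.add(pf.residue_id)
            for lf in lig_fragments:
                for pf in prot_fragments:
                    if selection is not None and not selection(pf.residue_id):
                        continue
                    if intra:
                        if lf.residue_id == pf.residue_id:
                            continue
                        if pf.residue_id < lf.residue_id:
                            continue  # evaluate each unordered pair once
                    if self.prefilter and _min_dist(lf, pf) > cutoff:
                        continue
                    for inter in self.interactions:
                        dr = inter.detect(lf, pf, matcher)
                        _check_contract(inter.name, dr)
                        if dr.present:
                            entries[
                                (frame_idx, lf.residue_id, pf.residue_id, inter.name)
                            ] = dr

        return FingerprintResult(
            interaction_names=self.interaction_names,
            frames=tuple(range(len(lig_frames))),
            lig_residues=tuple(sorted(lig_resids)),
            prot_residues=tuple(sorted(prot_resids)),
            entries=entries,
            single_ligand=len(lig_resids) <= 1,
            empty_tanimoto=self.empty_tanimoto,
        )


def _min_dist(lf, pf) -> float:
    diff = lf.coords[:, None, :] - pf.coords[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def _check_contract(name: str, dr: DetectionResult) -> None:
    if not isinstance(dr, DetectionResult):
        raise DetectionContractError(
            f"detector {name!r} returned {type(dr).__name__}, "
            "expected DetectionResult"
        )


def run(
    lig_frames,
    prot_frames,
    interactions: Sequence | None = None,
    selection=None,
    **kw,
) -> FingerprintResult:
    """Convenience wrapper: build a Fingerprint and run it."""
    return Fingerprint(interactions=interactions, **kw).run(
        lig_frames, prot_frames, selection=selection
    )
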