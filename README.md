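# ifpkit

Geometric interaction fingerprints for molecular complexes.

`ifpkit` detects noncovalent interactions — hydrogen and halogen bonds,
ionic pairs, aromatic stacking (parallel, edge-to-face, face-to-face),
pi-cation, metal coordination, hydrophobic and van der Waals contacts —
between every pair of residues of two 3D structures (or within one
structure), on a per-frame basis. Results are stored per (ligand residue,
protein residue, interaction) with the responsible atom indices, and can be
viewed as bitvectors, boolean tables, frequencies, Tanimoto similarity
matrices, and interaction-network graphs.

## Design in one paragraph

Structures must arrive with explicit hydrogens, formal charges and aromatic
flags (PDB inputs get a documented, optional planar-ring aromaticity
perception). Each structure is fragmented into residues keyed by (name,
number, chain); chemical moieties (anion, cation, aromatic ring,
donor/acceptor groups, metals, hydrophobes) are matched inside each fragment
by built-in predicates or user SMARTS (via RDKit); each interaction is a
rule pairing two moiety roles with inclusive distance cutoffs and angle
windows. All detectors satisfy one contract: two fragments in, a Boolean
plus atom indices out. Every threshold is configurable, and custom patterns
and detectors are first-class.

Angle conventions: the H-bond angle is measured **at the hydrogen** between
H→D and H→A (linear D–H…A ≈ 180°); halogen bonds constrain both the angle at
the halogen ([130, 180]°) and at the acceptor ([80, 140]°); all angles
involving a ring normal are folded to [0, 90]° before range tests.

## Library quick start

```python
from ifpkit import Fingerprint, read_frames, lig_network
from ifpkit.fixtures import make_hbond_pair, split_chains

lig, prot = split_chains(make_hbond_pair(2.9, 180.0), ("L",))
result = Fingerprint().run([lig], [prot])     # default interaction set
result.to_table()                              # frames x interactions (pandas)
result.frequencies()                           # per-pair frame fractions
result.tanimoto_matrix()                       # frame-frame similarity
graph = lig_network(result, threshold=0.3)     # ligand interaction network
```

The default interaction set is Hydrophobic, PiStacking, PiCation, CationPi,
Anionic, Cationic, HBDonor, HBAcceptor; EdgeToFace, FaceToFace, XBDonor,
XBAcceptor, MetalDonor, MetalAcceptor and VdWContact are available by name.
Thresholds are overridable per detector
(`registry["HBDonor"].configured(distance_max=4.1)`) and serializable to
JSON for reproducible runs.

`ifpkit.fixtures` generates small synthetic complexes at exact geometries
(donor–acceptor pairs, ring dimers, ion pairs, metal sites…) so every
threshold and angle window is testable without external data.

## Command line

```bash
ifpkit --ligand lig.pdb --protein prot.pdb \
       --out-table fp.csv --out-similarity sim.csv \
       --out-network net.graphml --threshold 0.3
```

Multi-model PDB files are treated as frame sequences; a single-frame side is
broadcast against a multi-frame side. A JSON run manifest (inputs,
thresholds, versions, seed) is written next to the first output. Outputs are
byte-identical across reruns.

## Notes

- All "≤" thresholds are inclusive; a 1e-9 epsilon guards comparisons
  against float rounding of coordinates constructed exactly at a boundary.
- The bundled van der Waals radius table (Bondi, with Batsanov values for
  transition metals) lives in `src/ifpkit/data/vdw_radii.txt` and can be
  replaced via `VdwRadiusTable.from_file`.
- Atom indices are 0-based everywhere; PDB serials are preserved separately.
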