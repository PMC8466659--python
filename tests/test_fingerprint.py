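import numpy as np
import pytest

from ifpkit.chem_model import ResidueId
from ifpkit.errors import MissingHydrogensError
from ifpkit.fingerprint import BitVector, Fingerprint, FingerprintResult, run, tanimoto
from ifpkit.fixtures import (
    jitter,
    make_hbond_pair,
    make_ion_pair,
    make_ring_dimer,
    make_tripeptide,
    split_chains,
)
from ifpkit.interactions import DetectionResult


def hb_frames(distances, theta=180.0):
    ligs, prots = [], []
    for d in distances:
        lig, prot = split_chains(make_hbond_pair(d, theta), ("L",))
        ligs.append(lig)
        prots.append(prot)
    return ligs, prots


def synthetic_result(frame_bits, interaction_names=("A", "B")):
    """Build a FingerprintResult from a list of per-frame on-bit sets.

    frame_bits: list of sets of (prot_name, interaction) pairs.
    """
    lig = ResidueId("UNL", 1, "L")
    prots = sorted({ResidueId(p, 1, "P") for bits in frame_bits for p, _ in bits}
                   | {ResidueId("RES", 1, "P")})
    entries = {}
    for f, bits in enumerate(frame_bits):
        for prot_name, inter in bits:
            entries[(f, lig, ResidueId(prot_name, 1, "P"), inter)] = DetectionResult(
                True, (0,), (0,)
            )
    return FingerprintResult(
        interaction_names=tuple(interaction_names),
        frames=tuple(range(len(frame_bits))),
        lig_residues=(lig,),
        prot_residues=tuple(prots),
        entries=entries,
    )


class TestRun:
    def test_single_hb_frame_default_set(self):
        ligs, prots = hb_frames([2.9])
        result = run(ligs, prots)
        present = [(k[1], k[2], k[3]) for k in result.entries]
        assert present == [
            (ResidueId("DON", 1, "L"), ResidueId("ACC", 1, "P"), "HBDonor")
        ]
        dr = list(result.entries.values())[0]
        assert dr.ligand_atoms == (0, 1)
        assert dr.protein_atoms == (0,)

    def test_zero_frames_keeps_interaction_key(self):
        result = run([], [])
        assert result.n_frames == 0
        assert result.interaction_names == (
            "Hydrophobic", "PiStacking", "PiCation", "CationPi",
            "Anionic", "Cationic", "HBDonor", "HBAcceptor",
        )
        assert result.entries == {}

    def test_three_identical_frames_deterministic(self):
        ligs, prots = hb_frames([2.9, 2.9, 2.9])
        result = run(ligs, prots)
        per_frame = [
            {k[1:] for k in result.entries if k[0] == f} for f in range(3)
        ]
        assert per_frame[0] == per_frame[1] == per_frame[2]
        assert len(per_frame[0]) == 1

    def test_mismatched_frame_counts_error(self):
        ligs, prots = hb_frames([2.9, 2.9])
        with pytest.raises(ValueError, match="frame count"):
            run(ligs, prots[:1])

    def test_missing_hydrogens_diagnostic(self):
        lig, prot = split_chains(make_ion_pair(4.0), ("L",))
        # strip all H atoms
        from ifpkit.chem_model import Atom, Structure

        def strip_h(struct):
            keep = [a for a in struct.atoms if a.element != "H"]
            remap = {a.index: i for i, a in enumerate(keep)}
            return Structure([
                Atom(index=i, element=a.element, coords=a.coords.copy(),
                     formal_charge=a.formal_charge, is_aromatic=a.is_aromatic,
                     bonded_indices=sorted(remap[j] for j in a.bonded_indices
                                           if j in remap),
                     residue=a.residue, name=a.name)
                for i, a in enumerate(keep)
            ])

        with pytest.raises(MissingHydrogensError):
            run([strip_h(lig)], [strip_h(prot)])

    def test_selection_filters_protein_residues(self):
        s = make_tripeptide()
        result = Fingerprint(interactions=["HBDonor", "HBAcceptor"]).run(
            s, s, selection=[ResidueId("GLY", 3, "A")]
        )
        assert all(k[2] == ResidueId("GLY", 3, "A") for k in result.entries)

    def test_intramolecular_skips_self_pairs(self):
        s = make_tripeptide()
        result = Fingerprint(interactions=["HBDonor", "HBAcceptor"]).run(s, s)
        for _, lig_r, prot_r, _ in result.entries:
            assert lig_r != prot_r

    def test_prefilter_does_not_change_results(self):
        pairs = []
        rng = np.random.default_rng(5)
        for seed in range(30):
            d = rng.uniform(2.5, 9.0)
            pairs.append(split_chains(jitter(make_hbond_pair(d, 175.0), 0.05, seed),
                                      ("L",)))
            g = rng.uniform(3.0, 8.0)
            pairs.append(split_chains(jitter(make_ring_dimer(g, 1.0, 10.0), 0.05,
                                             seed + 1000), ("L",)))
        ligs = [p[0] for p in pairs]
        prots = [p[1] for p in pairs]
        fast = Fingerprint(prefilter=True).run(ligs, prots)
        slow = Fingerprint(prefilter=False).run(ligs, prots)
        assert set(fast.entries) == set(slow.entries)


class TestBitVector:
    def test_no_interactions_all_false(self):
        ligs, prots = hb_frames([5.5])
        result = run(ligs, prots)
        bv = result.to_bitvector(0)
        assert len(bv) == len(result.prot_residues) * len(result.interaction_names)
        assert not bv.bits.any()

    def test_hb_frame_single_true_bit(self):
        ligs, prots = hb_frames([2.9])
        result = run(ligs, prots)
        bv = result.to_bitvector(0)
        on = bv.on_bits()
        assert on == [(None, ResidueId("ACC", 1, "P"), "HBDonor")]

    def test_layout_identical_across_frames(self):
        ligs, prots = hb_frames([2.9, 5.0, 3.1])
        result = run(ligs, prots)
        keys = [result.to_bitvector(f).key for f in result.frames]
        assert keys[0] == keys[1] == keys[2]

    def test_unknown_frame_errors(self):
        ligs, prots = hb_frames([2.9])
        result = run(ligs, prots)
        with pytest.raises(KeyError):
            result.to_bitvector(7)

    def test_length_key_mismatch_rejected(self):
        with pytest.raises(ValueError):
            BitVector(bits=np.zeros(2, dtype=bool), key=((None, None, "X"),))


class TestTable:
    def test_empty_result(self):
        result = run([], [])
        table = result.to_table()
        assert table.shape == (0, 0)

    def test_hb_fixture_one_by_one(self):
        ligs, prots = hb_frames([2.9])
        table = run(ligs, prots).to_table()
        assert table.shape == (1, 1)
        assert bool(table.iloc[0, 0]) is True
        assert table.columns.tolist() == [("DON1.L", "ACC1.P", "HBDonor")]

    def test_table_bitvector_consistency(self):
        ligs, prots = hb_frames([2.9, 5.0, 3.2, 2.7])
        result = run(ligs, prots)
        table = result.to_table()
        for f in result.frames:
            on_table = {
                (prot, inter)
                for (lig, prot, inter), v in table.loc[f].items()
                if v
            }
            on_bits = {(str(p), i) for (_, p, i) in result.to_bitvector(f).on_bits()}
            assert on_table == on_bits


class TestFrequencies:
    def test_half_frequency(self):
        result = synthetic_result([{("RES", "A")}, set(), {("RES", "A")}, set()])
        freqs = result.frequencies()
        assert freqs[(ResidueId("UNL", 1, "L"), ResidueId("RES", 1, "P"), "A")] == 0.5

    def test_always_present(self):
        result = synthetic_result([{("RES", "A")}] * 3)
        assert list(result.frequencies().values()) == [1.0]

    def test_ten_frame_hand_count(self):
        # HBDonor present exactly when d <= 3.5: frames 0-5 yes, 6-9 no
        distances = [2.8, 3.0, 3.2, 3.4, 3.45, 3.5, 3.6, 4.0, 4.5, 5.0]
        ligs, prots = hb_frames(distances)
        result = run(ligs, prots)
        freqs = result.frequencies()
        key = (ResidueId("DON", 1, "L"), ResidueId("ACC", 1, "P"), "HBDonor")
        assert freqs[key] == pytest.approx(0.6)
        res_freqs = result.residue_frequencies()
        assert res_freqs[ResidueId("ACC", 1, "P")] == pytest.approx(0.6)

    def test_invariant_under_frame_permutation(self):
        distances = [2.8, 5.0, 3.0, 4.2, 2.9]
        ligs, prots = hb_frames(distances)
        shuffled = [distances[i] for i in (3, 1, 4, 0, 2)]
        ligs2, prots2 = hb_frames(shuffled)
        assert run(ligs, prots).frequencies() == run(ligs2, prots2).frequencies()

    def test_zero_frames_error(self):
        result = run([], [])
        with pytest.raises(ValueError):
            result.frequencies()


class TestTanimoto:
    def test_identical_frames_unit(self):
        ligs, prots = hb_frames([2.9, 2.9])
        mat = run(ligs, prots).tanimoto_matrix()
        assert np.allclose(mat, 1.0)

    def test_disjoint_bits_zero(self):
        result = synthetic_result([{("RES", "A")}, {("RES", "B")}])
        mat = result.tanimoto_matrix()
        assert mat[0, 1] == 0.0

    def test_closed_form_one_third(self):
        result = synthetic_result(
            [{("RES", "A"), ("RES", "B")}, {("RES", "B"), ("OTH", "A")}]
        )
        assert result.tanimoto_matrix()[0, 1] == pytest.approx(1 / 3)

    def test_empty_frames_convention(self):
        result = synthetic_result([set(), set()])
        assert result.tanimoto_matrix()[0, 1] == 1.0
        result.empty_tanimoto = 0.0
        assert result.tanimoto_matrix()[0, 1] == 0.0

    def test_symmetric_unit_diagonal_in_range(self):
        rng = np.random.default_rng(9)
        bits = rng.random((8, 20)) < 0.3
        vals = [[tanimoto(bits[i], bits[j]) for j in range(8)] for i in range(8)]
        mat = np.array(vals)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)
        assert ((0.0 <= mat) & (mat <= 1.0)).all()

    def test_brute_force_set_agreement(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            a = rng.random(30) < 0.4
            b = rng.random(30) < 0.4
            sa, sb = set(np.flatnonzero(a)), set(np.flatnonzero(b))
            expected = 1.0 if not (sa | sb) else len(sa & sb) / len(sa | sb)
            assert tanimoto(a, b) == pytest.approx(expected)


class TestCsvExport:
    def test_long_format_round_data(self, tmp_path):
        ligs, prots = hb_frames([2.9, 5.0])
        result = run(ligs, prots)
        out = tmp_path / "fp.csv"
        result.to_csv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "frame,ligand,protein,interaction,present,lig_atoms,prot_atoms"
        assert len(lines) == 2  # header + single present row (frame 0)
        assert lines[1].startswith("0,DON1.L,ACC1.P,HBDonor,True")
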