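import numpy as np
import pytest

from ifpkit.errors import DetectionContractError, PatternError
from ifpkit.fingerprint import Fingerprint
from ifpkit.fixtures import (
    jitter,
    make_hbond_pair,
    make_hydrophobic_pair,
    make_ion_pair,
    make_metal_site,
    make_ring_dimer,
    make_xbond_pair,
    split_chains,
)
from ifpkit.geometry import VdwRadiusTable
from ifpkit.interactions import (
    CustomInteraction,
    DetectionResult,
    InteractionDefinition,
    VdWContact,
    builtin_definitions,
    configure,
    default_interaction_registry,
    register_interaction,
)

import _oracles
from _helpers import cation_ring, two_point_structure


def frags(structure):
    lig, prot = structure.residues
    return lig, prot


class TestDistanceOnly:
    def test_ionic_within_cutoff(self, registry):
        lig, prot = frags(make_ion_pair(4.4))
        result = registry["Anionic"].detect(lig, prot)
        assert result.present
        assert result.ligand_atoms == (1,)   # the O(-)
        assert result.protein_atoms == (2,)  # the N(+), parent index

    def test_ionic_beyond_cutoff(self, registry):
        lig, prot = frags(make_ion_pair(4.6))
        assert not registry["Anionic"].detect(lig, prot).present

    def test_metal_within_cutoff_reports_atoms(self, registry):
        lig, prot = frags(make_metal_site(2.7))
        result = registry["MetalDonor"].detect(lig, prot)
        assert result.present
        assert result.ligand_atoms == (0,)   # Mg
        assert result.protein_atoms == (1,)  # carbonyl O

    def test_metal_beyond_cutoff(self, registry):
        lig, prot = frags(make_metal_site(2.9))
        assert not registry["MetalDonor"].detect(lig, prot).present

    def test_hydrophobic(self, registry):
        lig, prot = frags(make_hydrophobic_pair(4.5))
        assert registry["Hydrophobic"].detect(lig, prot).present
        lig, prot = frags(make_hydrophobic_pair(4.51))
        assert not registry["Hydrophobic"].detect(lig, prot).present

    def test_unknown_pattern_name_errors(self):
        defn = configure(builtin_definitions()["Anionic"], ligand_moiety="NoSuch")
        from ifpkit.interactions import DistancePairInteraction

        lig, prot = frags(make_ion_pair(4.0))
        with pytest.raises(PatternError, match="NoSuch"):
            DistancePairInteraction(defn).detect(lig, prot)


class TestHBond:
    def test_linear_present(self, registry):
        lig, prot = frags(make_hbond_pair(2.9, 180.0))
        result = registry["HBDonor"].detect(lig, prot)
        assert result.present
        assert result.ligand_atoms == (0, 1)  # (D, H)
        assert result.protein_atoms == (2,)   # acceptor O

    def test_angle_below_window_absent(self, registry):
        lig, prot = frags(make_hbond_pair(2.9, 120.0))
        assert not registry["HBDonor"].detect(lig, prot).present

    def test_distance_beyond_cutoff_absent(self, registry):
        lig, prot = frags(make_hbond_pair(3.6, 180.0))
        assert not registry["HBDonor"].detect(lig, prot).present

    def test_acceptor_twin_swaps_roles(self, registry):
        lig, prot = frags(make_hbond_pair(2.9, 180.0))
        assert registry["HBAcceptor"].detect(prot, lig).present
        assert not registry["HBAcceptor"].detect(lig, prot).present

    def test_donor_without_h_skipped(self, registry):
        # carbonyl-only pair: no donor H anywhere -> absent, never an error
        lig, prot = frags(make_metal_site(2.0))
        assert not registry["HBDonor"].detect(lig, prot).present


class TestXBond:
    def test_reference_geometry_present(self, registry):
        lig, prot = frags(make_xbond_pair(3.2, 175.0, 110.0))
        result = registry["XBDonor"].detect(lig, prot)
        assert result.present
        assert result.ligand_atoms == (0, 1)   # (C donor, Br)
        assert result.protein_atoms == (2, 3)  # (O acceptor, C substituent)

    def test_acceptor_angle_outside_window_absent(self, registry):
        lig, prot = frags(make_xbond_pair(3.2, 175.0, 70.0))
        assert not registry["XBDonor"].detect(lig, prot).present

    def test_distance_beyond_cutoff_absent(self, registry):
        lig, prot = frags(make_xbond_pair(3.6, 175.0, 110.0))
        assert not registry["XBDonor"].detect(lig, prot).present

    def test_halogen_angle_outside_window_absent(self, registry):
        lig, prot = frags(make_xbond_pair(3.2, 100.0, 110.0))
        assert not registry["XBDonor"].detect(lig, prot).present


class TestPiStacking:
    def test_parallel_displaced_present(self, registry):
        gap = 2.5
        offset = np.sqrt(5.9**2 - gap**2)
        lig, prot = frags(make_ring_dimer(gap, offset, 0.0))
        assert _oracles._stacking(lig, prot, 6.0, 0, 90)  # oracle sanity
        result = registry["PiStacking"].detect(lig, prot)
        assert result.present
        assert len(result.ligand_atoms) == 6  # full ring reported
        assert len(result.protein_atoms) == 6

    def test_t_shaped_edge_to_face(self, registry):
        lig, prot = frags(make_ring_dimer(4.7, 0.0, 90.0))
        assert registry["EdgeToFace"].detect(lig, prot).present
        assert not registry["FaceToFace"].detect(lig, prot).present

    def test_cofacial_min_distance_gate(self, registry):
        # aligned sandwich: min interatomic distance equals the gap
        lig, prot = frags(make_ring_dimer(4.0, 0.0, 0.0))
        assert not registry["FaceToFace"].detect(lig, prot).present
        lig, prot = frags(make_ring_dimer(3.7, 0.0, 0.0))
        assert registry["FaceToFace"].detect(lig, prot).present

    def test_face_to_face_implies_pi_stacking(self, registry):
        rng = np.random.default_rng(11)
        hits = 0
        for seed in range(120):
            gap = rng.uniform(3.0, 4.6)
            offset = rng.uniform(0.0, 2.5)
            tilt = rng.uniform(0.0, 60.0)
            s = jitter(make_ring_dimer(gap, offset, tilt), 0.04, seed)
            lig, prot = frags(s)
            ftf = registry["FaceToFace"].detect(lig, prot).present
            if ftf:
                hits += 1
                assert registry["PiStacking"].detect(lig, prot).present
        assert hits > 5  # the battery exercised the implication


class TestPiCation:
    def test_above_centroid_present(self, registry):
        lig, prot = frags(cation_ring(4.0, 0.0))
        result = registry["CationPi"].detect(lig, prot)
        assert result.present
        assert result.ligand_atoms == (12,)      # the N+ (ligand side)
        assert len(result.protein_atoms) == 6    # ring atoms

    def test_in_plane_absent(self, registry):
        lig, prot = frags(cation_ring(4.0, 90.0))
        assert not registry["CationPi"].detect(lig, prot).present

    def test_beyond_distance_absent(self, registry):
        lig, prot = frags(cation_ring(4.6, 0.0))
        assert not registry["CationPi"].detect(lig, prot).present

    def test_angle_boundary_30_degrees(self, registry):
        lig, prot = frags(cation_ring(4.0, 30.0))
        assert registry["CationPi"].detect(lig, prot).present
        lig, prot = frags(cation_ring(4.0, 30.5))
        assert not registry["CationPi"].detect(lig, prot).present


class TestVdWContact:
    def test_carbon_pair(self):
        det = VdWContact()
        lig, prot = frags(two_point_structure("C", "C", 3.9))
        assert det.detect(lig, prot).present  # 3.9 <= 1.7+1.7+0.6
        lig, prot = frags(two_point_structure("C", "C", 4.1))
        assert not det.detect(lig, prot).present

    def test_boundary_inclusive_at_zero_tolerance(self):
        det = VdWContact(tolerance=0.0)
        lig, prot = frags(two_point_structure("C", "C", 3.4))
        assert det.detect(lig, prot).present  # exactly r1 + r2

    def test_unknown_element_errors(self):
        det = VdWContact(table=VdwRadiusTable(radii={"C": 1.7}))
        lig, prot = frags(two_point_structure("C", "N", 3.0))
        with pytest.raises(KeyError, match="N"):
            det.detect(lig, prot)


class TestConfigure:
    def test_longer_hbond_cutoff_detects_farther_pair(self, registry):
        lig, prot = frags(make_hbond_pair(3.8, 180.0))
        assert not registry["HBDonor"].detect(lig, prot).present
        relaxed = registry["HBDonor"].configured(distance_max=4.1)
        assert relaxed.detect(lig, prot).present

    def test_no_overrides_identity(self, registry):
        base = registry["HBDonor"]
        same = base.configured()
        for d, theta in [(2.9, 180.0), (3.4, 150.0), (3.6, 180.0), (2.9, 120.0)]:
            lig, prot = frags(make_hbond_pair(d, theta))
            assert base.detect(lig, prot).present == same.detect(lig, prot).present

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            configure(builtin_definitions()["HBDonor"], distance_max=-1.0)

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError, match="colour"):
            configure(builtin_definitions()["HBDonor"], colour="red")

    def test_original_untouched(self, registry):
        base = registry["HBDonor"]
        before = base.definition.distance_max
        base.configured(distance_max=4.1)
        assert base.definition.distance_max == before


class TestRegistryAndCustom:
    def test_register_close_contact_appears_in_fingerprint(self, registry):
        def close_contact(lig, prot):
            for i in range(lig.n_atoms):
                for j in range(prot.n_atoms):
                    if np.linalg.norm(lig.coords[i] - prot.coords[j]) <= 3.0:
                        return DetectionResult(True, lig.to_parent([i]),
                                               prot.to_parent([j]))
            return DetectionResult(False)

        reg = registry.copy()
        register_interaction(reg, CustomInteraction("CloseContact", close_contact))
        fp = Fingerprint(interactions=["CloseContact"], registry=reg)
        s = make_hbond_pair(2.9, 180.0)
        lig, prot = split_chains(s, ("L",))
        result = fp.run([lig], [prot])
        assert "CloseContact" in result.interaction_names
        assert any(k[3] == "CloseContact" for k in result.entries)

    def test_contract_violation_detected(self):
        bad = CustomInteraction("Bad", lambda lig, prot: (True, (), ()))
        lig, prot = frags(make_ion_pair(4.0))
        with pytest.raises(DetectionContractError):
            bad.detect(lig, prot)

    def test_name_collision_needs_overwrite(self, registry):
        reg = registry.copy()
        with pytest.raises(PatternError, match="Hydrophobic"):
            register_interaction(
                reg, CustomInteraction("Hydrophobic", lambda l, p: (False, (), ()))
            )
        register_interaction(
            reg,
            CustomInteraction("Hydrophobic", lambda l, p: DetectionResult(False)),
            overwrite=True,
        )
        lig, prot = frags(make_hydrophobic_pair(4.0))
        assert not reg["Hydrophobic"].detect(lig, prot).present  # new rule used


TWINS = [
    ("HBDonor", "HBAcceptor"),
    ("XBDonor", "XBAcceptor"),
    ("Anionic", "Cationic"),
    ("CationPi", "PiCation"),
    ("MetalDonor", "MetalAcceptor"),
]


class TestRoleSwapSymmetry:
    @pytest.mark.parametrize("name,twin", TWINS)
    def test_twins_agree_under_swap(self, registry, name, twin):
        rng = np.random.default_rng(sum(map(ord, name)))
        for seed in range(40):
            if name.startswith("HB"):
                base = make_hbond_pair(rng.uniform(2.4, 4.2), rng.uniform(90, 180))
            elif name.startswith("XB"):
                base = make_xbond_pair(rng.uniform(2.6, 4.2), rng.uniform(120, 180),
                                       rng.uniform(60, 150))
            elif name in ("Anionic", "Cationic"):
                base = make_ion_pair(rng.uniform(3.0, 6.0))
            elif name in ("CationPi", "PiCation"):
                base = cation_ring(rng.uniform(3.0, 6.0), rng.uniform(0, 90))
            else:
                base = make_metal_site(rng.uniform(1.8, 3.5))
            s = jitter(base, 0.03, seed)
            lig, prot = s.residues
            assert (
                registry[name].detect(lig, prot).present
                == registry[twin].detect(prot, lig).present
            ), (name, seed)


class TestThresholdMonotonicity:
    @pytest.mark.parametrize(
        "maker,name,lo,hi",
        [
            (make_ion_pair, "Anionic", 3.0, 6.0),
            (lambda d: make_hbond_pair(d, 180.0), "HBDonor", 2.5, 5.0),
            (make_metal_site, "MetalDonor", 1.5, 4.0),
            (make_hydrophobic_pair, "Hydrophobic", 3.0, 6.0),
        ],
    )
    def test_presence_flips_once(self, registry, maker, name, lo, hi):
        grid = np.round(np.arange(lo, hi + 1e-9, 0.05), 2)
        states = []
        for d in grid:
            lig, prot = frags(maker(float(d)))
            states.append(registry[name].detect(lig, prot).present)
        flips = sum(1 for a, b in zip(states, states[1:]) if a != b)
        assert states[0] and not states[-1]
        assert flips == 1


class TestDefinitionSerialization:
    def test_round_trip(self, tmp_path):
        from ifpkit.interactions import load_definitions, save_definitions

        defs = builtin_definitions()
        path = tmp_path / "defs.json"
        save_definitions(defs.values(), path)
        loaded = load_definitions(path)
        assert set(loaded) == set(defs)
        for name in defs:
            assert loaded[name] == defs[name]
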