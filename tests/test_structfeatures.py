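"""Contacts, CDR3 geometry, conformation classifier, SASA/BSA — with
independent brute-force oracles for every geometric operation."""

import math
import warnings

import numpy as np
import pytest

from cdr3scope.structfeatures import (
    VDW_RADII,
    buried_surface_area,
    classify_conformation,
    contact_residues,
    fr2_cdr3_dis,
    interface_summary,
    residue_centroid,
    segment_interaction_profile,
    shrake_rupley_sasa,
    ss_usage,
    surface_hydrophobicity,
)
from cdr3scope.structure_io import AtomRecord, ComplexModel
from cdr3scope.synthetic import StructureRecipe, generate_structures


def toy_model(residue_points, chain="A", antigen_points=None, start=105):
    """Single-atom residues at given coordinates (CDR3 positions by default)."""
    atoms = []
    for k, pt in enumerate(residue_points):
        atoms.append(AtomRecord(chain, start + k, "", "G", "CA", "C", tuple(pt)))
    antigen = ()
    if antigen_points is not None:
        for k, pt in enumerate(antigen_points):
            atoms.append(AtomRecord("B", k + 1, "", "A", "CA", "C", tuple(pt)))
        antigen = ("B",)
    return ComplexModel(atoms, vhh_chain=chain, antigen_chains=antigen)


def brute_force_contacts(m, threshold, mode):
    """O(n^2) all-pairs oracle over residues and atoms."""
    if mode == "vhh_antigen":
        keys_a, keys_b = m.vhh_residues(), m.antigen_residues()
        pairs = [(a, b) for a in keys_a for b in keys_b]
    else:
        keys = m.vhh_residues()
        order = {k: i for i, k in enumerate(keys)}
        pairs = [(a, b) for a in keys for b in keys if order[a] < order[b] - 1]
    out = {}
    for ka, kb in pairs:
        d = min(math.dist(x.xyz, y.xyz) for x in m.atoms_of(ka) for y in m.atoms_of(kb))
        if d <= threshold:
            out[(ka, kb)] = d
    return out


class TestContacts:
    def test_threshold_boundary(self):
        m = toy_model([(0, 0, 0), (10, 0, 0), (3.9, 0, 0)], antigen_points=[])
        m2 = toy_model([(0, 0, 0)], antigen_points=[(3.9, 0, 0)])
        assert len(contact_residues(m2, 4.0, "vhh_antigen")) == 1
        m3 = toy_model([(0, 0, 0)], antigen_points=[(4.1, 0, 0)])
        assert contact_residues(m3, 4.0, "vhh_antigen") == []

    def test_adjacent_residues_excluded_intra(self):
        m = toy_model([(0, 0, 0), (1.0, 0, 0), (2.0, 0, 0)])
        recs = contact_residues(m, 4.0, "intra_vhh")
        assert [(r.residue_a[1], r.residue_b[1]) for r in recs] == [(105, 107)]

    @pytest.mark.parametrize("mode", ["vhh_antigen", "intra_vhh"])
    def test_matches_brute_force_on_random_fixtures(self, mode, rng):
        for trial in range(25):
            n = int(rng.integers(20, 50))
            pts = rng.uniform(0, 25, size=(n, 3))
            n_ag = int(rng.integers(5, 15))
            ag = rng.uniform(0, 25, size=(n_ag, 3))
            atoms = []
            for k, pt in enumerate(pts):
                for j in range(int(rng.integers(1, 4))):
                    atoms.append(AtomRecord("A", 105 + k % 13, "" if k < 13 else chr(65 + k // 13),
                                            "G", f"C{j}", "C", tuple(pt + rng.normal(0, 1, 3))))
            for k, pt in enumerate(ag):
                atoms.append(AtomRecord("B", k + 1, "", "A", "CA", "C", tuple(pt)))
            m = ComplexModel(atoms, "A", ("B",))
            got = {(r.residue_a, r.residue_b): r.min_distance
                   for r in contact_residues(m, 4.0, mode)}
            oracle = brute_force_contacts(m, 4.0, mode)
            assert set(got) == set(oracle)
            for pair, d in oracle.items():
                assert got[pair] == pytest.approx(d, abs=1e-9)


class TestFr2Cdr3Dis:
    def _model_with_anchor(self, cdr3_points, anchor=(0.0, 0.0, 0.0)):
        atoms = [AtomRecord("A", 42, "", "Q", "CA", "C", tuple(anchor))]
        for k, pt in enumerate(cdr3_points):
            atoms.append(AtomRecord("A", 105 + k, "", "G", "CA", "C", tuple(pt)))
        return ComplexModel(atoms, "A")

    def test_minimum_over_trimmed_residues(self):
        # trimmed centroids at 5, 7, 9 A; the flanking pairs are nearer but excluded
        pts = [(1, 0, 0), (2, 0, 0), (5, 0, 0), (7, 0, 0), (9, 0, 0), (2, 0, 0), (1, 0, 0)]
        assert fr2_cdr3_dis(self._model_with_anchor(pts)) == pytest.approx(5.0)

    def test_five_residue_loop_uses_middle(self):
        pts = [(1, 0, 0), (1, 0, 0), (6.5, 0, 0), (1, 0, 0), (1, 0, 0)]
        assert fr2_cdr3_dis(self._model_with_anchor(pts)) == pytest.approx(6.5)

    def test_short_loop_is_missing(self):
        pts = [(1, 0, 0)] * 4
        assert math.isnan(fr2_cdr3_dis(self._model_with_anchor(pts)))

    def test_missing_anchor_is_error(self):
        m = toy_model([(0, 0, 0)] * 6)
        with pytest.raises(ValueError, match="42"):
            fr2_cdr3_dis(m)

    def test_matches_independent_centroid_arithmetic(self, rng):
        for _ in range(10):
            atoms = [AtomRecord("A", 42, "", "Q", f"C{j}", "C", tuple(rng.uniform(0, 5, 3)))
                     for j in range(4)]
            n = int(rng.integers(6, 14))
            coords_per_res = []
            for k in range(n):
                res_atoms = [tuple(rng.uniform(0, 30, 3)) for _ in range(3)]
                coords_per_res.append(res_atoms)
                for j, xyz in enumerate(res_atoms):
                    atoms.append(AtomRecord("A", 105 + k, "", "G", f"C{j}", "C", xyz))
            m = ComplexModel(atoms, "A")
            anchor = np.mean([a.xyz for a in atoms[:4]], axis=0)
            oracle = min(
                float(np.linalg.norm(np.mean(res, axis=0) - anchor))
                for res in coords_per_res[2:-2]
            )
            assert fr2_cdr3_dis(m) == pytest.approx(oracle, abs=1e-9)

    def test_rigid_transform_invariance(self, structure_set, rng):
        from scipy.spatial.transform import Rotation

        m = structure_set[0][0]
        R = Rotation.random(random_state=7).as_matrix()
        shift = rng.uniform(-50, 50, 3)
        moved = ComplexModel(
            [AtomRecord(a.chain, a.imgt_position, a.insertion, a.residue, a.atom_name,
                        a.element, tuple(R @ np.asarray(a.xyz) + shift)) for a in m.atoms],
            m.vhh_chain, m.antigen_chains)
        assert fr2_cdr3_dis(moved) == pytest.approx(fr2_cdr3_dis(m), abs=1e-9)

    def test_appending_a_residue_never_increases_minimum(self):
        pts = [(1, 0, 0), (2, 0, 0), (8, 0, 0), (9, 0, 0), (7, 0, 0), (2, 0, 0), (1, 0, 0)]
        base = fr2_cdr3_dis(self._model_with_anchor(pts))
        extended = pts[:5] + [(4, 0, 0)] + pts[5:]
        assert fr2_cdr3_dis(self._model_with_anchor(extended)) <= base


class TestSegmentProfile:
    def test_structure_without_cdr3_is_all_zero(self):
        atoms = [AtomRecord("A", 39 + k, "", "W", "CA", "C", (float(k), 0, 0)) for k in range(10)]
        m = ComplexModel(atoms, "A")
        profile = segment_interaction_profile(m)
        assert all(v == 0 for v in profile.values())

    def test_bent_and_extended_generator_geometry(self, structure_set):
        models, sidecar = structure_set
        for m, truth in zip(models, sidecar["structures"]):
            profile = segment_interaction_profile(m)
            if truth["conformation"] == "bent":
                assert profile["FR2"] > 0 and profile["CDR2"] > 0
            else:
                assert profile["CDR2"] == 0
            assert profile["CDR3_internal"] > 0


class TestClassifyConformation:
    def test_well_separated_mixture(self):
        rng = np.random.default_rng(17)
        vals = np.concatenate([rng.normal(7, 1, 250), rng.normal(15, 1, 250)])
        res = classify_conformation(vals)
        assert res.bimodal and 9 < res.threshold < 13
        truth = np.array(["bent"] * 250 + ["extended"] * 250)
        assert np.mean(np.array(res.labels) == truth) >= 0.99

    def test_unimodal_warning_path(self):
        rng = np.random.default_rng(18)
        with pytest.warns(UserWarning, match="unimodal"):
            res = classify_conformation(rng.normal(10, 1, 500))
        assert res.threshold is None and not res.bimodal
        assert len(set(res.labels)) == 1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            classify_conformation([5.0, 15.0])

    def test_generator_labels_recovered(self, structure_set):
        models, sidecar = structure_set
        vals = [fr2_cdr3_dis(m) for m in models]
        res = classify_conformation(vals)
        truth = [t["conformation"] for t in sidecar["structures"]]
        assert np.mean(np.array(res.labels) == np.array(truth)) >= 0.95


def grid_sasa_two_spheres(r1, r2, d, probe, n_grid=400_000):
    """Fine-grid numeric oracle for the exposed area of sphere 1 of an
    overlapping pair (uniform random surface points, large n)."""
    rng = np.random.default_rng(0)
    u = rng.normal(size=(n_grid, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = (r1 + probe) * u
    other = np.array([d, 0.0, 0.0])
    exposed = np.linalg.norm(pts - other, axis=1) > (r2 + probe)
    return 4 * math.pi * (r1 + probe) ** 2 * exposed.mean()


class TestSasa:
    def _single_atom(self, element="C"):
        return ComplexModel([AtomRecord("A", 42, "", "Q", "CA", element, (0, 0, 0))], "A")

    def test_isolated_sphere_closed_form(self):
        m = self._single_atom()
        area = shrake_rupley_sasa(m)[("A", 42, "")]
        expected = 4 * math.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert area == pytest.approx(expected, rel=0.005)

    def test_distant_atoms_do_not_occlude(self):
        atoms = [AtomRecord("A", 42, "", "Q", "CA", "C", (0, 0, 0)),
                 AtomRecord("A", 50, "", "A", "CA", "O", (100, 0, 0))]
        m = ComplexModel(atoms, "A")
        sasa = shrake_rupley_sasa(m)
        assert sasa[("A", 42, "")] == pytest.approx(4 * math.pi * (1.70 + 1.4) ** 2, rel=0.005)
        assert sasa[("A", 50, "")] == pytest.approx(4 * math.pi * (1.52 + 1.4) ** 2, rel=0.005)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0])
    def test_overlapping_pair_matches_grid_oracle(self, d):
        atoms = [AtomRecord("A", 42, "", "Q", "CA", "C", (0, 0, 0)),
                 AtomRecord("A", 50, "", "A", "CA", "O", (d, 0, 0))]
        m = ComplexModel(atoms, "A")
        sasa = shrake_rupley_sasa(m, n_points=960)
        oracle = grid_sasa_two_spheres(VDW_RADII["C"], VDW_RADII["O"], d, 1.4)
        assert sasa[("A", 42, "")] == pytest.approx(oracle, rel=0.02)

    def test_unknown_element_is_error(self):
        m = self._single_atom(element="ZZ")
        with pytest.raises(ValueError, match="element"):
            shrake_rupley_sasa(m)

    def test_rigid_transform_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        pts = rng.uniform(0, 8, size=(30, 3))
        atoms = [AtomRecord("A", 42 + k, "", "Q", "CA", "C", tuple(p)) for k, p in enumerate(pts)]
        m = ComplexModel(atoms, "A")
        R = Rotation.random(random_state=3).as_matrix()
        moved = ComplexModel(
            [AtomRecord(a.chain, a.imgt_position, a.insertion, a.residue, a.atom_name,
                        a.element, tuple(R @ np.asarray(a.xyz) + 20.0)) for a in atoms], "A")
        s1 = shrake_rupley_sasa(m, n_points=10_000)
        s2 = shrake_rupley_sasa(moved, n_points=10_000)
        total1, total2 = sum(s1.values()), sum(s2.values())
        assert total2 == pytest.approx(total1, rel=0.001)


class TestBsaAndHydrophobicity:
    def test_distant_chains_have_no_interface(self):
        atoms = [AtomRecord("A", 42, "", "Q", "CA", "C", (0, 0, 0)),
                 AtomRecord("B", 1, "", "A", "CA", "C", (100, 0, 0))]
        m = ComplexModel(atoms, "A", ("B",))
        bsa = buried_surface_area(m)
        assert abs(bsa["interface_bsa"]) < 1.0

    def test_bookkeeping_identity_on_docked_pair(self, structure_set):
        m = structure_set[0][0]
        bsa = buried_surface_area(m, n_points=240)
        assert bsa["interface_bsa"] > 50
        assert bsa["interface_bsa"] == pytest.approx(
            bsa["paratope_bsa"] + bsa["epitope_bsa"], rel=0.01)

    def test_non_interface_residue_is_local(self, structure_set):
        m = structure_set[0][1]
        bsa = buried_surface_area(m, n_points=240)
        # drop a far-away FR1 residue (first in chain order)
        drop = m.vhh_residues()[0]
        reduced = ComplexModel([a for a in m.atoms if a.key != drop],
                               m.vhh_chain, m.antigen_chains)
        bsa2 = buried_surface_area(reduced, n_points=240)
        assert abs(bsa2["interface_bsa"] - bsa["interface_bsa"]) < 1.0

    def test_single_residue_type_factorizes(self):
        atoms = [AtomRecord("A", 42 + k, "", "G", "CA", "C", (4.0 * k, 0, 0)) for k in range(4)]
        m = ComplexModel(atoms, "A")
        sasa = shrake_rupley_sasa(m)
        score = surface_hydrophobicity(m, sasa=sasa)
        assert score == pytest.approx(sum(sasa.values()) * (-0.4))  # h(G) = -0.4

    def test_buried_core_scores_lower(self):
        # same composition; buried variant hides the I (h=4.5) in a C-cage
        cage = [(2.5 * x, 2.5 * y, 2.5 * z) for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)]
        buried = [AtomRecord("A", 42, "", "I", "CA", "C", (0, 0, 0))]
        buried += [AtomRecord("A", 43 + k, "", "G", "CA", "C", p) for k, p in enumerate(cage)]
        exposed = [AtomRecord("A", 42, "", "I", "CA", "C", (30, 0, 0))]
        exposed += [AtomRecord("A", 43 + k, "", "G", "CA", "C", p) for k, p in enumerate(cage)]
        mb, me = ComplexModel(buried, "A"), ComplexModel(exposed, "A")
        assert surface_hydrophobicity(mb) < surface_hydrophobicity(me)

    def test_empty_model_scores_zero(self):
        m = ComplexModel([], "A")
        assert surface_hydrophobicity(m) == 0.0


class TestInterfaceSummary:
    def test_small_epitope_rejected(self):
        vhh = [(0.0, 0.0, float(k)) for k in range(8)]
        ag = [(3.0, 0.0, float(k)) for k in range(5)]
        m = toy_model(vhh, antigen_points=ag)
        assert interface_summary(m).rejected

    def test_fr2_involvement_flag(self, structure_set):
        models, sidecar = structure_set
        for m, truth in zip(models, sidecar["structures"]):
            s = interface_summary(m)
            assert not s.rejected
            assert s.fr2_involved == truth["fr2_involved"]

    def test_segment_counts_sum_to_paratope(self, structure_set):
        for m in structure_set[0][:10]:
            s = interface_summary(m)
            assert sum(s.paratope_counts.values()) == len(s.paratope)


class TestSsUsage:
    def _labelled_model(self, labels):
        atoms = [AtomRecord("A", 105 + k, "", "G", "CA", "C", (float(k), 0, 0))
                 for k in range(len(labels))]
        ss = {("A", 105 + k, ""): code for k, code in enumerate(labels)}
        return ComplexModel(atoms, "A", ss_labels=ss)

    def test_counting(self):
        usage = ss_usage(self._labelled_model("CCEEETTCC"), "CDR3")
        assert usage["E"] == pytest.approx(3 / 9)
        assert usage["T"] == pytest.approx(2 / 9)
        assert usage["C"] == pytest.approx(4 / 9)
        assert sum(usage.values()) == pytest.approx(1.0)

    def test_all_coil(self):
        assert ss_usage(self._labelled_model("CCCC"), "CDR3")["C"] == 1.0

    def test_missing_labels_unavailable(self):
        m = toy_model([(0, 0, 0)] * 5)
        assert ss_usage(m, "CDR3") is None

    def test_bent_set_richer_in_bend_and_coil(self, structure_set):
        models, sidecar = structure_set
        fracs = {"bent": [], "extended": []}
        for m, truth in zip(models, sidecar["structures"]):
            u = ss_usage(m, "CDR3")
            fracs[truth["conformation"]].append(u["S"] + u["C"])
        assert np.mean(fracs["bent"]) > np.mean(fracs["extended"])
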