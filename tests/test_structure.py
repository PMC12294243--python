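"""Structure I/O, universal residue labels, superposition, contacts, pore."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from chanvar.structure import (SegmentDefinition, SegmentMap, assign_plic, compare_states,
                               detect_contacts, invert_plic, kabsch_superpose,
                               pore_constriction, read_structure, render_state_flags,
                               write_structure)
from chanvar.synthetic import gen_helix_bundle
from conftest import make_model

KV71_SEGMENTS = SegmentMap(segments=[
    SegmentDefinition("S1", "1", 122, 147, 133, 550),
    SegmentDefinition("S4", "4", 218, 243, 231, 550),
    SegmentDefinition("S5", "5", 244, 295, 277, 550),
    SegmentDefinition("P-loop", "5", 296, 325, 313, 850),
])


class TestSegmentMapAndLabels:
    @pytest.mark.parametrize("pos,label", [
        (234, "4.553"),      # S4, three past the reference arginine
        (228, "4.547"),
        (231, "4.550"),      # the reference residue itself
        (312, "5.849"),      # P-loop: 850-series numbering
        (133, "1.550"),
    ])
    def test_reference_offset_labelling(self, pos, label):
        assert assign_plic(pos, KV71_SEGMENTS).render() == label

    def test_chain_prefix_and_uncovered_position(self):
        assert assign_plic(228, KV71_SEGMENTS, chain="A").render() == "A4.547"
        assert assign_plic(400, KV71_SEGMENTS) is None

    def test_assignment_inverts_on_covered_positions(self):
        for pos in list(range(122, 148)) + list(range(218, 326)):
            label = assign_plic(pos, KV71_SEGMENTS)
            assert invert_plic(label, KV71_SEGMENTS) == pos

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SegmentMap(segments=[SegmentDefinition("a", "1", 1, 10, 5, 550),
                                 SegmentDefinition("b", "2", 8, 20, 10, 550)])

    def test_reference_must_lie_in_range(self):
        with pytest.raises(ValueError):
            SegmentDefinition("a", "1", 1, 10, 11, 550)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "seg.yaml"
        KV71_SEGMENTS.to_yaml(path)
        assert SegmentMap.from_yaml(path) == KV71_SEGMENTS


def random_model(seed, n_res=30, chains=("A", "B")):
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_res):
        chain = chains[i % len(chains)]
        ca = rng.uniform(0, 25, 3)
        name = "GLY" if rng.random() < 0.15 else "ALA"
        atoms = {"N": ca + rng.normal(0, .5, 3), "CA": ca, "C": ca + rng.normal(0, .5, 3)}
        if name != "GLY":
            for j in range(int(rng.integers(1, 4))):
                atoms[f"C{'BGD'[j]}"] = ca + rng.uniform(-2, 2, 3)
        entries.append((chain, i // len(chains) + 1, name, atoms))
    return make_model(entries)


class TestStructureIO:
    def test_write_read_round_trip(self, tmp_path):
        model = random_model(3)
        path = tmp_path / "m.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert set(back.residues) == set(model.residues)
        for key, res in model.residues.items():
            for name, xyz in res.atoms.items():
                np.testing.assert_allclose(back.residues[key].atoms[name], xyz, atol=2e-3)

    def test_altloc_resolves_to_highest_occupancy(self, tmp_path):
        pdb = (
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60 10.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.40 10.00           C\n"
            "END\n")
        path = tmp_path / "alt.pdb"
        path.write_text(pdb)
        model = read_structure(path)
        assert model.get("A", 1).atoms["CA"][0] == pytest.approx(1.0)

    def test_renumber_map_and_incomplete_flag(self, tmp_path):
        pdb = ("ATOM      1  CB  ALA A  10       1.000   2.000   3.000  1.00 10.00           C\n"
               "END\n")
        path = tmp_path / "r.pdb"
        path.write_text(pdb)
        model = read_structure(path, renumber_map={("A", 10): 110})
        res = model.get("A", 110)
        assert res is not None and res.incomplete

    def test_toy_bundle_has_four_chains(self, tmp_path):
        bundle = gen_helix_bundle()
        path = tmp_path / "bundle.pdb"
        write_structure(bundle.up, path)
        assert read_structure(path).chains == ["A", "B", "C", "D"]


def rigid(model, rotvec, translation):
    R = Rotation.from_rotvec(rotvec).as_matrix()
    return model.transformed(R, np.asarray(translation, float))


def optimizer_rmsd(mobile, reference):
    """Independent oracle: generic numerical minimization over rigid motions."""
    keys = sorted(set(mobile.residues) & set(reference.residues))
    X = np.array([mobile.residues[k].ca for k in keys])
    Y = np.array([reference.residues[k].ca for k in keys])

    def cost(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        return np.sqrt((((R @ X.T).T + p[3:] - Y) ** 2).sum(axis=1).mean())

    best = np.inf
    for s in range(4):
        rng = np.random.default_rng(s)
        res = minimize(cost, np.concatenate([rng.normal(0, 1, 3), Y.mean(0) - X.mean(0)]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = min(best, res.fun)
    return best


class TestSuperposition:
    def test_identical_models_align_exactly(self):
        model = random_model(1)
        result, moved = kabsch_superpose(model, model)
        assert result.rmsd < 1e-9
        np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-9)

    def test_recovers_rigid_motion(self):
        reference = random_model(2)
        mobile = rigid(reference, [0, 0, math.radians(30)], [5.0, -3.0, 2.0])
        result, moved = kabsch_superpose(mobile, reference)
        assert result.rmsd < 1e-6
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)
        np.testing.assert_allclose(moved.coords(), reference.coords(), atol=1e-6)

    def test_rmsd_invariant_under_prerotation_of_mobile(self):
        reference = random_model(4)
        rng = np.random.default_rng(0)
        mobile = random_model(5)
        r0 = kabsch_superpose(mobile, reference)[0].rmsd
        for _ in range(3):
            pre = rigid(mobile, rng.normal(0, 1, 3), rng.normal(0, 10, 3))
            assert kabsch_superpose(pre, reference)[0].rmsd == pytest.approx(r0, abs=1e-9)

    def test_perturbed_model_matches_optimizer_oracle(self):
        reference = random_model(6, n_res=12)
        rng = np.random.default_rng(7)
        mobile = rigid(reference, [0.3, -0.2, 0.5], [1, 2, 3])
        for key in mobile.residues:
            mobile.residues[key].atoms = {
                n: x + rng.normal(0, 0.4, 3) for n, x in mobile.residues[key].atoms.items()}
        got = kabsch_superpose(mobile, reference)[0].rmsd
        assert got == pytest.approx(optimizer_rmsd(mobile, reference), abs=1e-6)

    def test_too_few_or_collinear_pairs_error(self):
        two = make_model([("A", i, "ALA", {"CA": [i, 0, 0]}) for i in (1, 2)])
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_superpose(two, two)
        line = make_model([("A", i, "ALA", {"CA": [i, 0, 0]}) for i in range(1, 6)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


SEGMAP_TWO = SegmentMap(segments=[SegmentDefinition("H1", "1", 1, 10, 5, 550),
                                  SegmentDefinition("H2", "2", 11, 20, 15, 550)])


class TestContacts:
    def planted(self, gap):
        return make_model([
            ("A", 1, "LEU", {"CA": [0, 0, 0], "CB": [1.5, 0, 0]}),
            ("A", 12, "LEU", {"CA": [1.5 + gap + 10, 0, 0], "CB": [1.5 + gap, 0, 0]}),
        ])

    def test_pair_below_cutoff_is_contact(self):
        contacts = detect_contacts(self.planted(4.8), SEGMAP_TWO)
        assert len(contacts) == 1
        c = contacts[0]
        assert c.min_distance == pytest.approx(4.8)
        assert (c.plic_a.render(), c.plic_b.render()) == ("A1.546", "A2.547")

    def test_pair_above_cutoff_is_not(self):
        assert detect_contacts(self.planted(5.2), SEGMAP_TWO) == []

    def test_same_segment_pairs_excluded(self):
        model = make_model([
            ("A", 1, "LEU", {"CA": [0, 0, 0], "CB": [1, 0, 0]}),
            ("A", 2, "LEU", {"CA": [2, 0, 0], "CB": [3, 0, 0]}),
        ])
        assert detect_contacts(model, SEGMAP_TWO) == []

    def test_glycine_contacts_through_ca(self):
        model = make_model([
            ("A", 1, "GLY", {"N": [0, -1, 0], "CA": [0, 0, 0], "C": [0, 1, 0]}),
            ("B", 1, "LEU", {"CA": [6, 0, 0], "CB": [4.5, 0, 0]}),
        ])
        (c,) = detect_contacts(model, SEGMAP_TWO)
        assert c.min_distance == pytest.approx(4.5)

    def test_matches_brute_force_on_random_model(self):
        model = random_model(11, n_res=120, chains=("A", "B", "C"))
        got = {(c.pair, round(c.min_distance, 9)) for c in detect_contacts(model, None)}
        assert got == brute_force_contacts(model, 5.0)

    def test_invariant_under_rigid_transform(self):
        model = random_model(13, n_res=60)
        moved = rigid(model, [0.4, 1.2, -0.7], [30, -4, 12])
        ref = {c.pair for c in detect_contacts(model, None)}
        assert {c.pair for c in detect_contacts(moved, None)} == ref


def brute_force_contacts(model, cutoff):
    """O(n^2) all-pairs oracle re-deriving the sidechain-atom rule."""
    out = set()
    keys = sorted(model.residues)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            if ka[0] == kb[0]:
                continue
            ra, rb = model.residues[ka], model.residues[kb]
            sa = {n: x for n, x in ra.atoms.items() if n not in "N CA C O OXT".split()}
            sb = {n: x for n, x in rb.atoms.items() if n not in "N CA C O OXT".split()}
            if not sa and ra.name == "GLY" and "CA" in ra.atoms:
                sa = {"CA": ra.atoms["CA"]}
            if not sb and rb.name == "GLY" and "CA" in rb.atoms:
                sb = {"CA": rb.atoms["CA"]}
            if not sa or not sb:
                continue
            d = min(float(np.linalg.norm(x - y)) for x in sa.values() for y in sb.values())
            if d <= cutoff:
                out.add(((ka, kb), round(d, 9)))
    return out


class TestStateComparison:
    def test_planted_two_state_bundle_flags(self):
        from chanvar.synthetic import PlantedContact
        bundle = gen_helix_bundle(planted_contacts=[
            PlantedContact("A", 1, "B", 5, frozenset({"up"})),
            PlantedContact("A", 10, "B", 11, frozenset({"down"})),
            PlantedContact("B", 1, "C", 1, frozenset({"up", "down"})),
        ])
        flagged = compare_states({
            "up": detect_contacts(bundle.up, bundle.segmap),
            "down": detect_contacts(bundle.down, bundle.segmap)})
        assert {c.pair: c.state_flags for c in flagged} == bundle.contacts

    def test_union_partition_property(self):
        up = detect_contacts(random_model(21, n_res=80, chains=("A", "B")), None)
        down = detect_contacts(random_model(22, n_res=80, chains=("A", "B")), None)
        flagged = compare_states({"up": up, "down": down})
        assert {c.pair for c in flagged} == {c.pair for c in up} | {c.pair for c in down}
        up_flagged = {c.pair for c in flagged if "up" in c.state_flags}
        assert up_flagged == {c.pair for c in up}

    def test_state_glyph_rendering(self):
        assert render_state_flags(frozenset({"down"})) == "↓"
        assert render_state_flags(frozenset({"up", "down"})) == "↓↑"
        assert render_state_flags(frozenset({"open"})) == "o"


class TestPoreConstriction:
    def symmetric_pore(self, sidechain_sign):
        # four CAs at radius 8 around the z axis; sidechain 2 Å inward/outward
        entries = []
        for k, chain in enumerate("ABCD"):
            angle = math.pi / 2 * k
            u = np.array([math.cos(angle), math.sin(angle), 0.0])
            ca = 8.0 * u
            entries.append((chain, 349, "SER", {"CA": ca, "OG": ca + 2.0 * sidechain_sign * -u}))
        return make_model(entries)

    def test_analytic_radius_of_symmetric_bundle(self):
        assert pore_constriction(self.symmetric_pore(+1), 349) == pytest.approx(6.0)

    def test_inward_rotamers_constrict_more_than_outward(self):
        inward = pore_constriction(self.symmetric_pore(+1), 349)
        outward = pore_constriction(self.symmetric_pore(-1), 349)
        assert inward < outward
        assert outward == pytest.approx(10.0)

    def test_too_few_chains_errors(self):
        model = make_model([("A", 349, "SER", {"CA": [8, 0, 0], "OG": [6, 0, 0]})])
        with pytest.raises(ValueError, match=">= 3"):
            pore_constriction(model, 349)


class TestCrossref:
    def _dataset(self):
        from chanvar.variants import VariantRecord, assemble_broad_dataset
        from chanvar.aminoacids import parse_protein_change
        from chanvar.variants import ClinicalClass
        recs = [
            VariantRecord(gene="KCNQ1", change=parse_protein_change("A10G"),
                          clinical_class=ClinicalClass.VUS),
            VariantRecord(gene="KCNQ1", change=parse_protein_change("L20P"),
                          clinical_class=ClinicalClass.P),
            VariantRecord(gene="KCNQ1", change=parse_protein_change("S30T"),
                          clinical_class=ClinicalClass.VUS),
            VariantRecord(gene="KCNQ1", change=parse_protein_change("K40N"),
                          clinical_class=ClinicalClass.NP),
        ]
        return assemble_broad_dataset([recs])

    def _calls(self, positions):
        from chanvar.aminoacids import parse_protein_change
        from chanvar.consensus import LikelyDamagingCall
        from chanvar.conservation import ParalogueEvidence
        from chanvar.variants import ClinicalClass, VariantRecord
        return [LikelyDamagingCall(
            variant=VariantRecord(gene="KCNQ1",
                                  change=parse_protein_change(f"A{p}G"),
                                  clinical_class=ClinicalClass.VUS),
            tool_name="t", tool_score=0.9,
            evidence=ParalogueEvidence(target_position=p, cs=0.8, entries=[]))
            for p in positions]

    def _contact(self, pos_a, pos_b):
        from chanvar.structure import ContactRecord
        return ContactRecord(chain_a="A", pos_a=pos_a, chain_b="B", pos_b=pos_b,
                             min_distance=4.0)

    def test_partner_categories(self):
        from chanvar.structure import (CATEGORY_CIP_NP, CATEGORY_PLP, CATEGORY_VUS_LD,
                                       crossref_variants)
        ds = self._dataset()
        calls = self._calls([10, 30])
        rows = crossref_variants(
            [self._contact(10, 20), self._contact(10, 30), self._contact(10, 40)],
            ds, calls, gene="KCNQ1")
        by_partner = {r["partner_position"]: r["category"] for r in rows
                      if r["ld_position"] == 10}
        assert by_partner[20] == CATEGORY_PLP        # partner has a P/LP variant
        assert by_partner[30] == CATEGORY_VUS_LD     # partner VUS is itself LD-called
        assert by_partner[40] == CATEGORY_CIP_NP

    def test_no_variants_anywhere_yields_empty_report(self):
        from chanvar.structure import crossref_variants
        ds = self._dataset()
        rows = crossref_variants([self._contact(100, 200)], ds, self._calls([100]))
        assert rows == []


def test_compare_states_rejects_mismatched_numbering():
    a = make_model([("A", i, "ALA", {"CA": [i, 0, 0], "CB": [i, 1, 0]})
                    for i in (1, 2, 3)])
    b = make_model([("A", i, "ALA", {"CA": [i, 0, 0], "CB": [i, 1, 0]})
                    for i in (1, 2, 9)])
    with pytest.raises(ValueError, match="numbering differs"):
        compare_states({"up": [], "down": []}, models={"up": a, "down": b})
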