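"""Template matching, nest and cavity detection, evidence integration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from funcsite.geometry import kabsch_superpose, relative_sasa, shrake_rupley_sasa
from funcsite.site import (detect_cavities, detect_nests, exposed_aromatics,
                           extract_template, integrate_evidence, match_template,
                           SiteTemplate)
from funcsite.structure import Atom, Residue, Structure
from funcsite.synthetic import (build_helix, make_cavity_shell,
                                make_nest_backbone, plant_triad)


def rigid_move(struct: Structure, seed: int) -> Structure:
    rng = np.random.default_rng(seed)
    rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
    shift = rng.normal(scale=10.0, size=3)
    for res in struct.residues():
        for atom in res.atoms:
            atom.coords = rot @ atom.coords + shift
    return struct


class TestExtractTemplate:
    def test_members_and_atoms(self, triad_template):
        assert len(triad_template.members) == 3
        assert sum(len(m.coords) for m in triad_template.members) == 9

    def test_asp_glu_equivalence_encoded(self, triad_template):
        for member in triad_template.members:
            assert set(member.classes) == {"ASP", "GLU"}

    def test_missing_functional_atom_errors(self, triad_structure):
        broken = Structure()
        res = Residue(name="ASP", number=1, atoms=[
            Atom(name="CG", element="C", coords=[0, 0, 0]),
            Atom(name="OD1", element="O", coords=[1, 0, 0])])
        broken.add_residue("A", res)
        with pytest.raises(ValueError, match="OD2"):
            extract_template(broken, [("A", 1, "")])

    def test_json_round_trip(self, triad_template, tmp_path):
        path = tmp_path / "t.json"
        triad_template.save(path)
        back = SiteTemplate.from_json(path)
        assert len(back.members) == 3
        for m1, m2 in zip(triad_template.members, back.members):
            assert np.allclose(m1.coords, m2.coords, atol=1e-3)


class TestMatchTemplate:
    def test_self_match_first_at_zero(self, triad_structure, triad_template):
        hits = match_template(triad_structure, triad_template)
        assert hits[0].residues == [("A", 10, ""), ("A", 11, ""), ("A", 12, "")]
        assert hits[0].rmsd == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [3, 7, 11])
    def test_planted_triad_matches_oracle(self, triad_template, seed):
        from tests.conftest import oracle_hit_rmsd
        base = build_helix(40)
        planted, truth = plant_triad(base, triad_template, noise_sigma=0.2,
                                     seed=seed)
        hits = match_template(planted, triad_template)
        assert hits, "planted triad not found"
        assert set(hits[0].residues) == set(truth.payload["residues"])
        oracle = oracle_hit_rmsd(truth, triad_template, hits[0])
        assert hits[0].rmsd == pytest.approx(oracle, abs=1e-6)
        # and never worse than the planted labelling itself
        planted_rmsd = kabsch_superpose(truth.payload["coords"],
                                        truth.payload["template_coords"]).rmsd
        assert hits[0].rmsd <= planted_rmsd + 1e-9

    def test_heavy_noise_yields_no_hit(self, triad_template):
        planted, _ = plant_triad(build_helix(40), triad_template,
                                 noise_sigma=3.0, seed=5)
        assert match_template(planted, triad_template) == []

    def test_rigid_motion_invariance(self, triad_template):
        planted, _ = plant_triad(build_helix(40), triad_template,
                                 noise_sigma=0.3, seed=2)
        base_hits = match_template(planted, triad_template)
        moved_hits = match_template(rigid_move(planted, 9), triad_template)
        assert [h.residues for h in moved_hits] == [h.residues for h in base_hits]
        for h1, h2 in zip(base_hits, moved_hits):
            assert h2.rmsd == pytest.approx(h1.rmsd, abs=1e-6)


class TestDetectNests:
    def test_helix_has_no_nest(self):
        assert detect_nests(build_helix(20), "A") == []

    @pytest.mark.parametrize("pattern,expected_span", [
        ("RL", 3), ("RLRL", 5), ("LRL", 4)])
    def test_planted_patterns(self, pattern, expected_span):
        nests = detect_nests(make_nest_backbone(pattern), "A")
        assert len(nests) == 1
        assert nests[0].n_residues == expected_span
        assert nests[0].pattern == pattern

    def test_non_alternating_run_is_not_a_nest(self):
        assert detect_nests(make_nest_backbone("RRRR"), "A") == []

    def test_rigid_motion_invariance(self):
        nb = make_nest_backbone("RLR")
        base = detect_nests(nb, "A")
        moved = detect_nests(rigid_move(nb, 4), "A")
        assert [(n.start, n.end, n.pattern) for n in moved] == \
            [(n.start, n.end, n.pattern) for n in base]


class TestDetectCavities:
    def test_helix_has_no_large_cavity(self):
        assert detect_cavities(build_helix(20), spacing=0.9) == []

    def test_shell_volume_within_15_percent(self):
        shell, truth = make_cavity_shell(6.0)
        cavs = detect_cavities(shell, spacing=0.9)
        assert len(cavs) == 1
        assert cavs[0].volume == pytest.approx(truth.payload["volume"], rel=0.15)

    def test_volume_converges_with_spacing(self):
        shell, truth = make_cavity_shell(6.0)
        errors = []
        for spacing in (1.2, 0.9, 0.6):
            cavs = detect_cavities(shell, spacing=spacing)
            errors.append(abs(cavs[0].volume - truth.payload["volume"]))
        assert errors[0] > errors[1] > errors[2]

    def test_rigid_motion_approximate_invariance(self):
        shell, _ = make_cavity_shell(6.0)
        base = detect_cavities(shell, spacing=0.9)[0].volume
        moved = detect_cavities(rigid_move(shell, 13), spacing=0.9)[0].volume
        assert moved == pytest.approx(base, rel=0.10)

    def test_lining_residues_are_shell_atoms(self):
        shell, _ = make_cavity_shell(5.0)
        cav = detect_cavities(shell, spacing=0.9)[0]
        assert len(cav.lining_residues) > 50
        assert np.linalg.norm(cav.centroid) < 1.5

    def test_empty_structure_errors(self):
        with pytest.raises(ValueError):
            detect_cavities(Structure())


class TestExposedAromatics:
    def test_exposed_trp_reported(self):
        s = build_helix(3, phi=-120.0, psi=120.0)
        s.chains["A"][1].name = "TRP"
        _, per_res = shrake_rupley_sasa(s)
        rel = relative_sasa(s, per_res)
        assert ("A", 2, "") in exposed_aromatics(s, rel)

    def test_buried_trp_not_reported(self):
        from tests.conftest import make_buried_atom
        caged = make_buried_atom(res_name="TRP")
        _, per_res = shrake_rupley_sasa(caged)
        rel = relative_sasa(caged, per_res)
        assert ("B", 1, "") not in exposed_aromatics(caged, rel)

    def test_sorted_by_exposure(self):
        rel = {("A", 1, ""): 0.9, ("A", 2, ""): 0.5, ("A", 3, ""): 0.1}
        s = Structure()
        for i in range(1, 4):
            s.add_residue("A", Residue(name="TYR", number=i, atoms=[]))
        assert exposed_aromatics(s, rel) == [("A", 1, ""), ("A", 2, "")]


class TestIntegrateEvidence:
    def test_all_evidence_cavity_ranks_first(self, triad_template):
        shell, _ = make_cavity_shell(6.0)
        planted, truth = plant_triad(shell, triad_template, noise_sigma=0.1,
                                     seed=21, center=[0.0, 0.0, 0.0])
        cavs = detect_cavities(planted, spacing=0.9)
        hits = match_template(planted, triad_template)
        report = integrate_evidence(planted, cavs, hits=hits)
        assert report.sites[0].cavity.rank == 1
        assert report.sites[0].template_hits, "triad hit not attached to cavity"

    def test_no_evidence_scores_reflect_volume_only(self):
        shell, _ = make_cavity_shell(6.0)
        cavs = detect_cavities(shell, spacing=0.9)
        report = integrate_evidence(shell, cavs)
        for site in report.sites:
            expected = site.cavity.volume / cavs[0].volume
            assert site.score == pytest.approx(expected)

    def test_score_monotone_in_conservation(self):
        from funcsite.conservation import ConservationProfile
        shell, _ = make_cavity_shell(6.0)
        cavs = detect_cavities(shell, spacing=0.9)
        low = ConservationProfile(
            column_scores=np.zeros(1), gap_fraction=np.zeros(1),
            residue_scores={k: 0.2 for k in cavs[0].lining_residues})
        high = ConservationProfile(
            column_scores=np.zeros(1), gap_fraction=np.zeros(1),
            residue_scores={k: 0.9 for k in cavs[0].lining_residues})
        s_low = integrate_evidence(shell, cavs, profile=low).sites[0].score
        s_high = integrate_evidence(shell, cavs, profile=high).sites[0].score
        assert s_high > s_low

    def test_bad_weight_vector(self):
        shell, _ = make_cavity_shell(6.0)
        cavs = detect_cavities(shell, spacing=0.9)
        with pytest.raises(ValueError):
            integrate_evidence(shell, cavs, weights=(1.0, 2.0))

    def test_report_json_serialisable(self, triad_template):
        import json
        shell, _ = make_cavity_shell(6.0)
        cavs = detect_cavities(shell, spacing=0.9)
        report = integrate_evidence(shell, cavs)
        assert json.loads(json.dumps(report.to_json()))["sites"]
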