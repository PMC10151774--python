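import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import make_structure

from msmdock import (
    ACTIVE_SITE_REGION,
    FLAP_REGION,
    HINGE_REGION,
    PoseRecord,
    best_pose_per_state,
    classify_pose,
    enrichment_analysis,
    filter_high_quality,
    find_contacts,
    msm_weighted_site_score,
    read_poses_csv,
    residue_contact_frequency,
    write_poses_csv,
)
from msmdock.ligsite import ResiduePocketScore
from msmdock.pose_analysis import SITE_CATEGORIES


def pose(coords, compound="c1", state=0, site="box", dock=-7.0, quality=0.8, pki=None):
    return PoseRecord(
        compound_id=compound,
        state_id=state,
        site_label=site,
        ligand_atoms=np.atleast_2d(coords),
        docking_score=dock,
        quality_score=quality,
        predicted_pki=pki,
    )


@pytest.fixture
def five_residue_structure():
    return make_structure(
        [(r, "CA", "C", (4.0 * r, 0.0, 0.0)) for r in range(1, 6)]
    )


class TestFindContacts:
    def test_cutoff_boundary_inclusive(self):
        s = make_structure([(1, "CA", "C", (0.0, 0.0, 0.0))])
        assert find_contacts(pose([3.9, 0.0, 0.0]), s, cutoff=4.0) == {1}
        assert find_contacts(pose([4.1, 0.0, 0.0]), s, cutoff=4.0) == set()

    def test_hydrogens_ignored(self):
        s = make_structure(
            [(1, "CA", "C", (10.0, 0.0, 0.0)), (1, "HA", "H", (0.0, 0.0, 0.0))]
        )
        assert find_contacts(pose([1.0, 0.0, 0.0]), s, cutoff=4.0) == set()

    def test_matches_all_pairs_oracle(self, five_residue_structure, rng):
        s = five_residue_structure
        for _ in range(10):
            lig = rng.uniform(-2, 22, size=(4, 3))
            got = find_contacts(pose(lig), s, cutoff=4.0)
            want = set()
            for rid, atom in zip(s.res_id, s.coord):
                if np.linalg.norm(lig - atom, axis=1).min() <= 4.0:
                    want.add(int(rid))
            assert got == want


class TestClassifyPose:
    def classify(self, contacts):
        return classify_pose(contacts, FLAP_REGION, HINGE_REGION, ACTIVE_SITE_REGION).category

    def test_flap_and_hinge_is_interface(self):
        assert self.classify({157, 280}) == "flap_hinge_interface"

    def test_flap_only(self):
        assert self.classify({260}) == "flap_only"

    def test_hinge_only(self):
        assert self.classify({160}) == "hinge_only"

    def test_active_site(self):
        assert self.classify({105}) == "active_site"

    def test_outside_all_regions_is_other(self):
        assert self.classify({500}) == "other"
        assert self.classify(set()) == "other"

    def test_interface_beats_active_site(self):
        assert self.classify({157, 280, 105}) == "flap_hinge_interface"

    def test_active_site_with_single_flank_is_active_site(self):
        assert self.classify({280, 105}) == "active_site"

    @settings(derandomize=True, max_examples=200)
    @given(st.frozensets(st.integers(min_value=0, max_value=600), max_size=12))
    def test_total_function_over_contact_sets(self, contacts):
        assert self.classify(contacts) in SITE_CATEGORIES


class TestFilterAndBestPose:
    def test_threshold_inclusive(self):
        poses = [pose([0, 0, 0], quality=q) for q in (0.49, 0.5, 0.9)]
        assert len(filter_high_quality(poses, 0.5)) == 2
        assert len(filter_high_quality(poses, 0.0)) == 3
        assert filter_high_quality(poses, 1.0) == []

    def test_best_pose_by_quality_then_docking(self):
        a = pose([0, 0, 0], quality=0.4)
        b = pose([0, 0, 0], quality=0.7)
        assert best_pose_per_state([a, b])[("c1", 0)] is b
        c = pose([0, 0, 0], quality=0.6, dock=-7.1)
        d = pose([0, 0, 0], quality=0.6, dock=-6.0)
        assert best_pose_per_state([d, c])[("c1", 0)] is c

    def test_keys_are_compound_state_pairs(self):
        poses = [
            pose([0, 0, 0], compound="a", state=0),
            pose([0, 0, 0], compound="a", state=1),
            pose([0, 0, 0], compound="b", state=0),
        ]
        assert set(best_pose_per_state(poses)) == {("a", 0), ("a", 1), ("b", 0)}


class TestContactFrequency:
    def test_single_pose_counts_once(self, five_residue_structure):
        freq = residue_contact_frequency(
            [pose([4.0, 0.0, 0.0])], five_residue_structure
        )
        assert freq[1] == 1.0 and freq[3] == 0.0

    def test_two_pose_counting(self):
        s = make_structure(
            [(1, "CA", "C", (0.0, 0.0, 0.0)), (2, "CA", "C", (6.0, 0.0, 0.0))]
        )
        poses = [pose([-1.0, 0.0, 0.0]), pose([3.0, 0.0, 0.0])]  # {1} and {1, 2}
        freq = residue_contact_frequency(poses, s)
        assert freq[1] == 1.0 and freq[2] == 0.5

    def test_matches_recount_oracle(self, five_residue_structure, rng):
        poses = [pose(rng.uniform(0, 20, size=(3, 3))) for _ in range(10)]
        freq = residue_contact_frequency(poses, five_residue_structure)
        for rid in five_residue_structure.residue_ids():
            count = sum(
                1
                for p in poses
                if int(rid) in find_contacts(p, five_residue_structure)
            )
            assert freq[int(rid)] == pytest.approx(count / 10)

    def test_empty_pose_list_rejected(self, five_residue_structure):
        with pytest.raises(ValueError):
            residue_contact_frequency([], five_residue_structure)


class TestMsmWeightedSiteScore:
    def test_single_state_identity(self):
        out = msm_weighted_site_score({"flap_only": {0: 0.8}}, np.array([1.0]))
        assert out["flap_only"] == pytest.approx(0.8)

    def test_absent_state_contributes_zero(self):
        out = msm_weighted_site_score(
            {"flap_only": {0: 0.8}}, np.array([0.5, 0.5])
        )
        assert out["flap_only"] == pytest.approx(0.4)

    def test_matches_dot_product_oracle(self, rng):
        pi = rng.dirichlet(np.ones(4))
        scores = dict(enumerate(rng.uniform(0, 1, size=4)))
        out = msm_weighted_site_score({"x": scores}, pi)
        assert out["x"] == pytest.approx(float(pi @ np.array(list(scores.values()))))

    def test_bounded_by_state_scores_when_all_present(self, rng):
        pi = rng.dirichlet(np.ones(5))
        vals = rng.uniform(0, 1, size=5)
        out = msm_weighted_site_score({"x": dict(enumerate(vals))}, pi)
        assert vals.min() - 1e-12 <= out["x"] <= vals.max() + 1e-12

    def test_unnormalized_pi_rejected(self):
        with pytest.raises(ValueError):
            msm_weighted_site_score({"x": {0: 1.0}}, np.array([0.4, 0.4]))


def scores_from(mapping):
    return [ResiduePocketScore(r, s) for r, s in mapping.items()]


class TestEnrichment:
    def test_reference_only_ensemble_all_deltas_zero(self):
        ref = {10: 0.2, 11: 0.5}
        table, open_state = enrichment_analysis({0: scores_from(ref)}, scores_from(ref))
        assert (table["delta"] == 0.0).all()
        assert open_state == 0

    def test_max_minus_reference_with_argmax(self):
        ref = scores_from({280: 0.1})
        table, open_state = enrichment_analysis(
            {0: scores_from({280: 0.1}), 3: scores_from({280: 0.6})}, ref
        )
        row = table.set_index("residue_number").loc[280]
        assert row["delta"] == pytest.approx(0.5)
        assert row["argmax_state_id"] == 3
        assert open_state == 3

    def test_matches_bruteforce_recompute(self, rng):
        residues = list(range(100, 110))
        ref = {r: float(rng.uniform(0, 1)) for r in residues}
        per_state = {
            s: {r: float(rng.uniform(0, 1)) for r in residues} for s in range(3)
        }
        table, open_state = enrichment_analysis(
            {s: scores_from(m) for s, m in per_state.items()}, scores_from(ref)
        )
        t = table.set_index("residue_number")
        for r in residues:
            vals = [per_state[s][r] for s in range(3)]
            assert t.loc[r, "ensemble_max_score"] == pytest.approx(max(vals))
            assert t.loc[r, "delta"] == pytest.approx(max(vals) - ref[r])
            assert per_state[int(t.loc[r, "argmax_state_id"])][r] == pytest.approx(max(vals))
            # the argmax state's score equals reference + delta exactly
            assert t.loc[r, "delta"] >= -ref[r]
        gains = [
            sum(max(per_state[s][r] - ref[r], 0.0) for r in residues) for s in range(3)
        ]
        assert open_state == int(np.argmax(gains))

    def test_residue_mismatch_rejected(self):
        with pytest.raises(ValueError):
            enrichment_analysis(
                {0: scores_from({1: 0.5})}, scores_from({1: 0.1, 2: 0.2})
            )


class TestPoseCsvRoundTrip:
    def test_round_trip_preserves_records(self, tmp_path, rng):
        poses = [
            pose(rng.normal(size=(3, 3)), compound=f"c{i%3}", state=i % 4,
                 site="siteA", dock=-6.5 - i, quality=0.1 * (i % 10), pki=5.0 + i)
            for i in range(8)
        ]
        path = tmp_path / "poses.csv"
        write_poses_csv(poses, path)
        back = read_poses_csv(path)
        assert len(back) == len(poses)
        for a, b in zip(poses, back):
            assert (a.compound_id, a.state_id, a.site_label) == (
                b.compound_id, b.state_id, b.site_label
            )
            np.testing.assert_allclose(a.ligand_atoms, b.ligand_atoms)
            assert a.quality_score == pytest.approx(b.quality_score)
            assert a.predicted_pki == pytest.approx(b.predicted_pki)
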