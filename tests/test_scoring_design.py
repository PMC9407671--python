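import numpy as np
import pytest

from fibrilcap import RigidTransform, group_layers
from fibrilcap.backbone import STRAND_PHI_PSI, build_from_dihedrals
from fibrilcap.capping_dock import BindingSite, DockedPose, graft_scaffold
from fibrilcap.errors import ScoreError
from fibrilcap.scaffold_builder import Scaffold, TopologyClass
from fibrilcap.scoring_design import (
    FunnelConfig,
    InterfaceScore,
    ddg_surrogate,
    detect_backbone_hbonds,
    interface_atom_count,
    interface_positions,
    load_centroid_radii,
    load_contact_table,
    load_rama_propensities,
    mutate_and_rescore,
    optimize_interface_sequence,
    paap_score,
    rank_designs,
    rebuild_amide_hydrogens,
    replace_sequence,
    score_pose,
    tip_hbond_satisfaction,
    _participants_from_chain,
)
from fibrilcap.synthetic_fixtures import (
    FibrilSpec,
    _layer_to_chain,
    make_complementary_capper,
    make_ideal_fibril,
)


def _brute_hbonds(donors, acceptors, dist=3.5, angle=120.0):
    bonds = []
    for key_d, N, H in donors:
        best = None
        for key_a, O in acceptors:
            if key_a[0] == key_d[0] and abs(key_a[1] - key_d[1]) <= 1:
                continue
            d = np.linalg.norm(O - N)
            if d > dist:
                continue
            hn = N - H
            ho = O - H
            cosang = hn @ ho / (np.linalg.norm(hn) * np.linalg.norm(ho))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang < angle:
                continue
            cand = (d, key_a[1], key_a[0])
            if best is None or cand < best[0]:
                best = (cand, (key_d, key_a))
        if best:
            bonds.append(best[1])
    return bonds


class TestHBondDetection:
    def test_matches_brute_force_on_stacked_strand_pair(self):
        """Parallel in-register strands at the cross-beta rise."""
        base = build_from_dihedrals(np.array([STRAND_PHI_PSI] * 10))
        m, _ = make_ideal_fibril(FibrilSpec(n_layers=3))
        c0, c1 = m.chains[0], m.chains[1]
        d0, a0 = _participants_from_chain("0", c0)
        d1, a1 = _participants_from_chain("1", c1)
        fast = detect_backbone_hbonds(d0 + d1, a0 + a1)
        brute = _brute_hbonds(d0 + d1, a0 + a1)
        assert len(fast) > 0
        assert {(b.donor, b.acceptor) for b in fast} == set(brute)

    def test_distant_strands_have_no_bonds(self, model):
        c0 = model.chains[0]
        far = c0.transformed(RigidTransform(np.eye(3), np.array([0.0, 0.0, 20.0])))
        far.chain_id = "X"
        d0, a0 = _participants_from_chain("0", c0)
        d1, a1 = _participants_from_chain("X", far)
        inter = [
            b for b in detect_backbone_hbonds(d0 + d1, a0 + a1)
            if b.donor[0] != b.acceptor[0]
        ]
        assert inter == []

    def test_angle_criterion_rejects_perpendicular_geometry(self):
        # acceptor at the right distance but at 90 degrees off the N-H axis
        donors = [(("d", 5), np.array([0.0, 0, 0]), np.array([0.0, 0, -1.01]))]
        acceptors = [(("a", 50), np.array([3.0, 0.0, -1.01]))]
        assert detect_backbone_hbonds(donors, acceptors) == []
        # same acceptor straight below the H: near-linear, accepted
        acceptors = [(("a", 50), np.array([0.0, 0.0, -3.0]))]
        assert len(detect_backbone_hbonds(donors, acceptors)) == 1

    def test_one_best_acceptor_per_donor(self):
        donors = [(("d", 5), np.array([0.0, 0, 0]), np.array([0.0, 0, -1.01]))]
        acceptors = [
            (("a", 1), np.array([0.0, 0.0, -3.2])),
            (("a", 2), np.array([0.0, 0.0, -2.9])),
        ]
        bonds = detect_backbone_hbonds(donors, acceptors)
        assert len(bonds) == 1 and bonds[0].acceptor == ("a", 2)

    def test_proline_and_first_residue_donate_nothing(self, model):
        chain = model.chains[0]
        donors, _ = _participants_from_chain("t", chain)
        keys = {k for k, _, _ in donors}
        assert ("t", 0) not in keys

    def test_rebuilt_amide_hydrogen_geometry(self, model):
        bb = model.chains[0].backbone_coords()
        H = rebuild_amide_hydrogens(bb)
        assert np.all(np.isnan(H[0]))
        for i in range(1, bb.shape[0]):
            assert np.linalg.norm(H[i] - bb[i, 0]) == pytest.approx(1.01, abs=1e-9)


class TestTipSatisfaction:
    def test_perfect_capper_fills_the_window(self, assembly, capper_pose):
        sat, unsat = tip_hbond_satisfaction(assembly, capper_pose)
        assert unsat == 0
        assert sat > 0

    def test_displaced_scaffold_satisfies_nothing(self, assembly, capper_pose):
        off = RigidTransform(np.eye(3), np.array([15.0, 0.0, 0.0]))
        displaced = DockedPose(
            "off", capper_pose.scaffold, capper_pose.site, capper_pose.strand_choice,
            off.compose(capper_pose.transform), capper_pose.graft_rmsd,
            0, 0, capper_pose.orientation,
        )
        sat, unsat = tip_hbond_satisfaction(assembly, displaced)
        assert sat == 0

    def test_conservation_of_the_dangling_inventory(self, assembly, capper_pose):
        """satisfied + unsatisfied is a pose-independent site property."""
        sat, unsat = tip_hbond_satisfaction(assembly, capper_pose)
        off = RigidTransform(np.eye(3), np.array([15.0, 0.0, 0.0]))
        displaced = DockedPose(
            "off", capper_pose.scaffold, capper_pose.site, capper_pose.strand_choice,
            off.compose(capper_pose.transform), capper_pose.graft_rmsd,
            0, 0, capper_pose.orientation,
        )
        sat2, unsat2 = tip_hbond_satisfaction(assembly, displaced)
        assert sat + unsat == sat2 + unsat2


def _tiny_pose(backbone, sequence, site=None):
    n = backbone.shape[0]
    sc = Scaffold(backbone, "E" * n, sequence, 0, TopologyClass("HEE"))
    site = site or BindingSite(0, "plus", (1, 7), 0)
    return DockedPose("tiny", sc, site, 0, RigidTransform.identity(), 0.0, 0, 0, "parallel")


class TestInterfaceAtoms:
    def test_far_scaffold_counts_zero(self, assembly, capper_pose):
        off = RigidTransform(np.eye(3), np.array([60.0, 0.0, 0.0]))
        far = DockedPose(
            "far", capper_pose.scaffold, capper_pose.site, 0,
            off.compose(capper_pose.transform), 0.0, 0, 0, "parallel",
        )
        assert interface_atom_count(far, assembly) == 0

    def test_boundary_is_closed(self, assembly, model):
        anchor = model.chains[0].residues[0].atom("N").pos
        bb = np.zeros((1, 4, 3))
        bb[0, :, :] = anchor + np.array([0.0, 0.0, -60.0])  # far away
        bb[0, 0, :] = anchor + np.array([0.0, 0.0, -5.0])   # exactly 5.0 A
        pose = _tiny_pose(bb, "A")
        assert interface_atom_count(pose, assembly) == 1

    def test_matches_brute_force_on_random_poses(self, assembly, capper_pose):
        fib, _ = assembly.model.heavy_coords_and_elements()
        rng = np.random.default_rng(1)
        for _ in range(20):
            shift = RigidTransform(np.eye(3), rng.uniform(-8, 8, size=3))
            pose = DockedPose(
                "r", capper_pose.scaffold, capper_pose.site, 0,
                shift.compose(capper_pose.transform), 0.0, 0, 0, "parallel",
            )
            atoms = pose.posed_backbone().reshape(-1, 3)
            brute = sum(
                1 for a in atoms if np.min(np.linalg.norm(fib - a, axis=1)) <= 5.0
            )
            assert interface_atom_count(pose, assembly) == brute


class TestDdgSurrogate:
    def test_no_pairs_in_range_scores_zero(self, assembly, capper_pose):
        off = RigidTransform(np.eye(3), np.array([60.0, 0.0, 0.0]))
        far = DockedPose(
            "far", capper_pose.scaffold, capper_pose.site, 0,
            off.compose(capper_pose.transform), 0.0, 0, 0, "parallel",
        )
        assert ddg_surrogate(far, assembly) == 0.0

    def test_single_pair_equals_table_entry(self, model):
        """One Leu-Leu pair inside the 8 A shell scores the packaged (L,L)."""
        from fibrilcap.structure_io import Atom, Chain, Residue, StructureModel

        strand = build_from_dihedrals(np.array([STRAND_PHI_PSI] * 4))
        fib_chainA = _layer_to_chain(strand, "A")
        fib_chainB = _layer_to_chain(strand + np.array([0.0, 0.0, 4.75]), "B")
        for c in (fib_chainA, fib_chainB):
            for r in c.residues:
                r.name = "LEU"
        fmodel = StructureModel([fib_chainA, fib_chainB], "tiny")
        asm = group_layers(fmodel)

        bb = np.zeros((1, 4, 3))
        bb[0] = strand[0] + np.array([0.0, 0.0, 200.0])
        # place the scaffold residue so only residue A1 is within 8 A of its CB
        from fibrilcap.backbone import virtual_cbeta

        cb0 = virtual_cbeta(strand[0, 0], strand[0, 1], strand[0, 2])
        bb[0] = strand[0] + (cb0 - strand[0, 1]) + np.array([6.0, 0.0, 0.0])
        pose = _tiny_pose(bb, "L")
        table = load_contact_table()
        got = ddg_surrogate(pose, asm, table)
        cb_pose = virtual_cbeta(bb[0, 0], bb[0, 1], bb[0, 2])
        n_pairs = 0
        for c in fmodel.chains:
            for r in c.residues:
                rc = virtual_cbeta(*[r.atom(x).pos for x in ("N", "CA", "C")])
                if np.linalg.norm(rc - cb_pose) <= 8.0:
                    n_pairs += 1
        assert n_pairs >= 1
        assert got == pytest.approx(n_pairs * table[("L", "L")])

    def test_additivity_over_disjoint_interfaces(self, assembly, capper_pose):
        """Scoring two residues at disjoint contacts equals the sum of parts."""
        posed = capper_pose.posed_backbone()
        bb2 = np.stack([posed[0], posed[5]])
        pose2 = _tiny_pose(bb2, "AV")
        bbA = posed[0:1]
        bbB = posed[5:6]
        total = ddg_surrogate(pose2, assembly)
        partA = ddg_surrogate(_tiny_pose(bbA, "A"), assembly)
        partB = ddg_surrogate(_tiny_pose(bbB, "V"), assembly)
        assert total == pytest.approx(partA + partB)

    def test_unknown_residue_rejected(self, assembly, capper_pose):
        bad = replace_sequence(
            capper_pose.scaffold, "X" * len(capper_pose.scaffold)
        )
        pose = DockedPose("bad", bad, capper_pose.site, 0, capper_pose.transform,
                          0.0, 0, 0, "parallel")
        with pytest.raises(ScoreError):
            ddg_surrogate(pose, assembly)


class TestPaap:
    def test_glycine_beats_valine_in_left_handed_bin(self):
        pp = np.array([(60.0, 40.0)] * 8)
        bb = build_from_dihedrals(pp)
        g = Scaffold(bb, "L" * 8, "G" * 8, 0, TopologyClass("HEE"))
        v = Scaffold(bb, "L" * 8, "V" * 8, 0, TopologyClass("HEE"))
        assert paap_score(g) > paap_score(v)

    def test_single_residue_chain_flagged(self):
        bb = np.zeros((1, 4, 3))
        bb[0] = build_from_dihedrals(np.array([STRAND_PHI_PSI]))[0]
        sc = Scaffold(bb, "E", "A", 0, TopologyClass("HEE"))
        assert np.isnan(paap_score(sc))

    def test_native_like_sequences_beat_shuffles(self):
        """Beta-branched residues on strands: shuffling rarely helps."""
        from fibrilcap.scaffold_builder import build_backbone
        from fibrilcap.scaffold_builder import Blueprint

        bp = Blueprint((("H", 12), ("L", 4), ("E", 7), ("L", 5), ("E", 7)))
        rng = np.random.default_rng(9)
        wins = 0
        trials = 0
        seed = 0
        while trials < 50:
            try:
                sc = build_backbone(bp, seed=seed)
            except Exception:
                seed += 1
                continue
            seed += 1
            seq = []
            for k in sc.ss:
                if k == "E":
                    seq.append("VI"[rng.integers(2)])
                elif k == "H":
                    seq.append("AL"[rng.integers(2)])
                else:
                    seq.append("GS"[rng.integers(2)])
            native = replace_sequence(sc, "".join(seq))
            shuffled_seq = list(seq)
            rng.shuffle(shuffled_seq)
            shuffled = replace_sequence(sc, "".join(shuffled_seq))
            if paap_score(shuffled) <= paap_score(native) + 1e-12:
                wins += 1
            trials += 1
        assert wins / trials >= 0.8


class TestGreedyDesign:
    def test_zero_interface_positions_is_identity(self, assembly, capper_pose):
        off = RigidTransform(np.eye(3), np.array([60.0, 0.0, 0.0]))
        far = DockedPose(
            "far", capper_pose.scaffold, capper_pose.site, 0,
            off.compose(capper_pose.transform), 0.0, 0, 0, "parallel",
        )
        new, traj = optimize_interface_sequence(far, assembly)
        assert new.scaffold.sequence == capper_pose.scaffold.sequence
        assert len(traj) == 1

    def test_trajectory_monotone_non_increasing(self, assembly, capper_pose):
        _, traj = optimize_interface_sequence(capper_pose, assembly)
        assert all(b <= a + 1e-9 for a, b in zip(traj, traj[1:]))

    def test_single_position_matches_exhaustive_minimum(self, assembly, capper_pose):
        pos = interface_positions(capper_pose, assembly)[0]
        new, traj = optimize_interface_sequence(capper_pose, assembly, mutable=[pos])
        table = load_contact_table()
        best = None
        from fibrilcap.scoring_design import DESIGN_AA, _centroid_clashes, load_centroid_radii

        fib, fel = assembly.model.heavy_coords_and_elements()
        posed = capper_pose.posed_backbone()
        radii = load_centroid_radii()
        seq = list(capper_pose.scaffold.sequence)
        for aa in DESIGN_AA:
            hard, _ = _centroid_clashes(posed[pos:pos + 1], aa, fib, fel, radii)
            if hard > 0:
                continue
            trial = seq.copy()
            trial[pos] = aa
            s = ddg_surrogate(capper_pose, assembly, table, sequence="".join(trial))
            if best is None or s < best[0]:
                best = (s, aa)
        assert traj[-1] == pytest.approx(best[0])
        assert new.scaffold.sequence[pos] == best[1]


class TestMutations:
    def test_null_mutation_changes_nothing(self, assembly, capper_pose):
        aa = capper_pose.scaffold.sequence[0]
        deltas = mutate_and_rescore(capper_pose, assembly, [f"{aa}1{aa}"])
        assert all(v == 0 for v in deltas.values())

    def test_reference_mismatch_rejected(self, assembly, capper_pose):
        seq = capper_pose.scaffold.sequence
        wrong = "W" if seq[0] != "W" else "F"
        with pytest.raises(ScoreError):
            mutate_and_rescore(capper_pose, assembly, [f"{wrong}1R"])
        with pytest.raises(ScoreError):
            mutate_and_rescore(capper_pose, assembly, ["A999R"])

    def test_arginine_at_buried_position_never_reduces_soft_clashes(
        self, assembly, capper_pose
    ):
        seq = capper_pose.scaffold.sequence
        for pos in interface_positions(capper_pose, assembly)[:4]:
            if seq[pos] != "A":
                continue
            d = mutate_and_rescore(capper_pose, assembly, [f"A{pos + 1}R"])
            assert d["d_soft_clashes"] >= 0

    def test_double_mutant_at_least_single(self, assembly, capper_pose):
        seq = capper_pose.scaffold.sequence
        pos = [i for i in interface_positions(capper_pose, assembly) if seq[i] == "A"]
        assert len(pos) >= 2
        p1, p2 = pos[0], pos[1]
        single = mutate_and_rescore(capper_pose, assembly, [f"A{p1 + 1}R"])
        m2 = f"{seq[p2]}{p2 + 1}Y"
        double = mutate_and_rescore(capper_pose, assembly, [f"A{p1 + 1}R", m2])
        assert double["d_soft_clashes"] >= single["d_soft_clashes"]


class TestRanking:
    @staticmethod
    def _score(i, ddg, hard=0, unsat=0, atoms=50, sat=5):
        return InterfaceScore(f"d{i}", sat, unsat, atoms, ddg, -3.0, 0, hard)

    def test_lower_ddg_ranks_first(self):
        table = rank_designs([self._score(1, -3.0), self._score(2, -5.0)])
        assert list(table["design_id"]) == ["d2", "d1"]

    def test_hard_clash_excluded_regardless_of_score(self):
        table = rank_designs([self._score(1, -50.0, hard=1), self._score(2, -1.0)])
        assert list(table["design_id"]) == ["d2"]

    def test_funnel_thresholds(self):
        cfg = FunnelConfig(hb_unsat_max=2, interface_atoms_min=40)
        scores = [
            self._score(1, -5.0, unsat=3),
            self._score(2, -5.0, atoms=39),
            self._score(3, -4.0),
        ]
        table = rank_designs(scores, cfg)
        assert list(table["design_id"]) == ["d3"]

    def test_permutation_invariant_total_order(self):
        rng = np.random.default_rng(3)
        scores = [
            self._score(i, float(rng.choice([-5.0, -4.0, -3.0])), sat=int(rng.integers(0, 6)))
            for i in range(20)
        ]
        ref = list(rank_designs(list(scores))["design_id"])
        rng.shuffle(scores)
        assert list(rank_designs(scores)["design_id"]) == ref

    def test_empty_input(self):
        assert len(rank_designs([])) == 0


def test_packaged_tables_are_consistent():
    table = load_contact_table()
    for a in "ACDEFGHIKLMNPQRSTVWY":
        for b in "ACDEFGHIKLMNPQRSTVWY":
            assert table[(a, b)] == table[(b, a)]
            assert np.isfinite(table[(a, b)])
    rama = load_rama_propensities()
    for bin_name in ["alphaR", "beta", "alphaL", "ppii", "other"]:
        assert sum(rama[aa][bin_name] for aa in rama) == pytest.approx(1.0, abs=1e-3)
    radii = load_centroid_radii()
    assert radii["A"] < radii["V"] < radii["Y"] <= radii["W"]
    assert radii["A"] < radii["R"]
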