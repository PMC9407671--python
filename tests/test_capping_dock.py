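import numpy as np
import pytest

from fibrilcap import RigidTransform, StructureModel, group_layers
from fibrilcap.capping_dock import (
    BindingSite,
    clash_counts,
    enumerate_binding_sites,
    graft_scaffold,
)
from fibrilcap.errors import DockError
from fibrilcap.scaffold_builder import Scaffold, TopologyClass
from fibrilcap.synthetic_fixtures import (
    FibrilSpec,
    make_complementary_capper,
    make_ideal_fibril,
)

VDW = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}


def _brute_clashes(A, ea, B, eb):
    hard = soft = 0
    for i in range(len(A)):
        for j in range(len(B)):
            d = np.linalg.norm(A[i] - B[j])
            if d < 2.5:
                hard += 1
            elif d < 0.8 * (VDW[ea[i]] + VDW[eb[j]]):
                soft += 1
    return hard, soft


class TestSiteEnumeration:
    def test_sliding_window_count_matches_closed_form(self):
        ss = "E" * 8 + "L" * 2 + "E" * 6 + "L" * 3 + "E" * 5
        sites = enumerate_binding_sites(ss, window=5)
        assert len(sites) == (8 - 5 + 1) + (6 - 5 + 1) + (5 - 5 + 1)
        for s in sites:
            lo, hi = s.window
            assert set(ss[lo:hi]) == {"E"}

    def test_window_longer_than_all_runs(self):
        ss = "E" * 8 + "L" * 2 + "E" * 6 + "L" * 3 + "E" * 5
        assert enumerate_binding_sites(ss, window=9) == []

    def test_per_strand_mode(self):
        ss = "E" * 8 + "L" * 2 + "E" * 6 + "L" * 3 + "E" * 5
        sites = enumerate_binding_sites(ss, window=4, mode="per_strand")
        assert [s.window for s in sites] == [(0, 8), (10, 16), (19, 24)]

    def test_no_strands_gives_empty(self):
        assert enumerate_binding_sites("L" * 20, window=4) == []

    def test_window_minimum_enforced(self):
        with pytest.raises(DockError):
            enumerate_binding_sites("E" * 10, window=3)


class TestClashCounts:
    def test_far_apart(self):
        h, s = clash_counts(np.array([[0.0, 0, 0]]), ["C"], np.array([[10.0, 0, 0]]), ["C"])
        assert (h, s) == (0, 0)

    def test_hard_threshold_arithmetic(self):
        h, s = clash_counts(np.array([[0.0, 0, 0]]), ["C"], np.array([[2.0, 0, 0]]), ["C"])
        assert (h, s) == (1, 0)
        # 0.8 * (1.7 + 1.7) = 2.72: a 2.6 A carbon pair is soft, not hard
        h, s = clash_counts(np.array([[0.0, 0, 0]]), ["C"], np.array([[2.6, 0, 0]]), ["C"])
        assert (h, s) == (0, 1)

    def test_grid_equals_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        elements = list(VDW)
        for _ in range(20):
            na, nb = rng.integers(20, 80, size=2)
            A = rng.uniform(0, 15, size=(na, 3))
            B = rng.uniform(0, 15, size=(nb, 3))
            ea = [elements[k] for k in rng.integers(0, 4, na)]
            eb = [elements[k] for k in rng.integers(0, 4, nb)]
            assert clash_counts(A, ea, B, eb) == _brute_clashes(A, ea, B, eb)

    def test_empty_inputs_rejected(self):
        with pytest.raises(DockError):
            clash_counts(np.empty((0, 3)), [], np.array([[0.0, 0, 0]]), ["C"])


class TestGraft:
    def test_perfect_capper_graft(self, capper_pose):
        assert capper_pose.graft_rmsd < 1e-6
        assert capper_pose.hard_clashes == 0
        assert capper_pose.passes_clash_filter

    def test_transform_is_single_source_of_placement(self, capper_pose):
        posed = capper_pose.posed_backbone()
        manual = capper_pose.transform.apply(
            capper_pose.scaffold.backbone.reshape(-1, 3)
        ).reshape(posed.shape)
        np.testing.assert_array_equal(posed, manual)

    def test_docking_invariant_under_global_rigid_motion(self, truth, plus_sites):
        site = plus_sites[0]
        capper = make_complementary_capper(site, truth)

        model, _ = make_ideal_fibril(FibrilSpec())
        asm = group_layers(model)
        ref = graft_scaffold(capper, 0, site, asm, "ref")

        shift = RigidTransform(np.eye(3), np.array([10.0, 0.0, 0.0]))
        moved = StructureModel([c.transformed(shift) for c in model.chains], "moved")
        asm2 = group_layers(moved)
        capper2 = Scaffold(
            shift.apply(capper.backbone.reshape(-1, 3)).reshape(capper.backbone.shape),
            capper.ss, capper.sequence, capper.seed, capper.class_id,
        )
        moved_pose = graft_scaffold(capper2, 0, site, asm2, "moved")
        assert moved_pose.graft_rmsd == pytest.approx(ref.graft_rmsd, abs=1e-9)
        assert (moved_pose.hard_clashes, moved_pose.soft_clashes) == (
            ref.hard_clashes, ref.soft_clashes,
        )

    def test_clash_decoy_is_rejected(self, assembly, truth, plus_sites):
        """A capper whose body is pushed into the fibril reports hard clashes."""
        site = plus_sites[0]
        capper = make_complementary_capper(site, truth)
        decoy_bb = capper.backbone.copy()
        n_strand = capper.strand_elements()[0][1]
        # center the body on the scaffold's own graft strand: after any
        # registration the body then overlaps the tip layer the strand
        # stacks against
        strand_centroid = decoy_bb[:n_strand, 1, :].mean(axis=0)
        body = decoy_bb[n_strand:]
        decoy_bb[n_strand:] = body - body.reshape(-1, 3).mean(axis=0) + strand_centroid
        decoy = Scaffold(decoy_bb, capper.ss, capper.sequence, capper.seed, capper.class_id)
        pose = graft_scaffold(decoy, 0, site, assembly, "decoy")
        assert pose.hard_clashes > 0
        assert not pose.passes_clash_filter

    def test_strand_shorter_than_window_errors(self, assembly, truth):
        site = BindingSite(0, "plus", (1, 7), 0)
        capper = make_complementary_capper(site, truth)
        with pytest.raises(DockError):
            graft_scaffold(capper, 1, BindingSite(0, "plus", (0, 8), 1), assembly)

    def test_unknown_strand_choice(self, assembly, truth, plus_sites):
        capper = make_complementary_capper(plus_sites[0], truth)
        with pytest.raises(DockError):
            graft_scaffold(capper, 5, plus_sites[0], assembly)
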