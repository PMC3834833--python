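"""Fragment docking, chaining, threading and clash filtering.

Boundary values are checked against brute-force oracles; the planted-pocket
fixtures exercise the stages end to end.
"""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from translinflex import docking
from translinflex.docking import BindingSite, ChainPath, DockPose
from translinflex.io_core import Bead, Structure

from conftest import build_pocket_slab, structure_from_coords


def make_pose(pose_id, coords, score=1.0, rotation=None):
    coords = np.asarray(coords, dtype=float)
    i5, i3 = 1, 4
    return DockPose(
        pose_id,
        np.eye(3) if rotation is None else rotation,
        np.zeros(3),
        score,
        coords,
        coords[i5],
        coords[i3],
    )


@pytest.fixture(scope="module")
def ligand():
    return docking.make_gu_dinucleotide()


# ---------------------------------------------------------------------------

class TestDockPose:
    def test_rotation_must_be_proper(self):
        with pytest.raises(ValueError):
            make_pose(0, np.zeros((6, 3)), rotation=np.diag([1.0, 1.0, -1.0]))

    def test_top_k_one_returns_one_pose(self, ligand):
        rec = structure_from_coords(
            [
                [x, y, z]
                for x in np.arange(-12, 13, 3)
                for y in np.arange(-12, 13, 3)
                for z in np.arange(-12, 1, 3)
            ]
        )
        poses = docking.dock_dinucleotide(rec, ligand, grid_spacing=2.0,
                                          n_rotations=2, top_k=1)
        assert len(poses) == 1


@pytest.fixture(scope="module")
def pocket_slab(ligand):
    """Disc slab with a buried ligand-shaped cavity at a known spot."""
    return build_pocket_slab(ligand)


class TestFFTDockOracle:

    def test_best_pose_matches_exhaustive_translation_scan(self, ligand, pocket_slab):
        receptor, target = pocket_slab
        h, bead_radius, contact_radius = 2.0, 2.0, 3.0
        poses = docking.dock_dinucleotide(
            receptor, ligand, grid_spacing=h, top_k=5, rotations=[np.eye(3)]
        )
        best = poses[0]
        # independent oracle: rebuild the identical grids, then evaluate the
        # correlation for every translation by explicit accumulation loops
        # (direct convolution, no FFT)
        rxyz = receptor.coords
        origin = rxyz.min(axis=0) - (bead_radius + 1.0)
        shape = np.ceil((rxyz.max(axis=0) + bead_radius + 1.0 - origin) / h).astype(int) + 1
        occ = np.zeros(shape, dtype=bool)
        idx = np.round((rxyz - origin) / h).astype(int)
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        ball = lambda r: (np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1] ** 2).sum(0) <= r * r
        occ = ndimage.binary_dilation(occ, structure=ball(1))
        core = ndimage.binary_erosion(occ)
        surface = occ & ~core
        lxyz = ligand.coords - ligand.coords.mean(axis=0)
        lpad = h * (max(1, int(round(contact_radius / h))) + 1)
        lorigin = lxyz.min(axis=0) - lpad
        lshape = np.ceil((lxyz.max(axis=0) - lorigin + lpad) / h).astype(int) + 1
        lgrid = np.zeros(lshape, dtype=bool)
        lidx = np.round((lxyz - lorigin) / h).astype(int)
        lgrid[lidx[:, 0], lidx[:, 1], lidx[:, 2]] = True
        foot = ndimage.binary_dilation(lgrid, structure=ball(2))
        t_shape = tuple(np.array(shape) + np.array(lshape) - 1)
        score = np.zeros(t_shape)
        overlap = np.zeros(t_shape)
        off = np.array(lshape) - 1
        for sx, sy, sz in zip(*np.nonzero(surface)):
            for fx, fy, fz in zip(*np.nonzero(foot)):
                score[sx - fx + off[0], sy - fy + off[1], sz - fz + off[2]] += 1.0
        for cx, cy, cz in zip(*np.nonzero(core)):
            for lx, ly, lz in zip(*np.nonzero(lgrid)):
                overlap[cx - lx + off[0], cy - ly + off[1], cz - lz + off[2]] += 1.0
        score[overlap > 0.5] = -np.inf
        best_score = score.max()
        assert best.score == pytest.approx(best_score, abs=1e-9)
        # the FFT-selected translation must be among the oracle's argmax set
        best_t = np.array(np.unravel_index(np.argmax(score), t_shape)) - off
        fft_delta = best.coords.mean(axis=0) - lxyz.mean(axis=0) - origin + lorigin
        fft_t = np.round(fft_delta / h).astype(int)
        assert score[tuple(fft_t + off)] == best_score
        # and geometric recovery: the winning placement sits in the pocket
        assert np.linalg.norm(best.coords.mean(axis=0) - target.mean(axis=0)) <= 2 * h

    def test_receptor_lattice_translation_equivariance(self, ligand, pocket_slab):
        receptor, _ = pocket_slab
        shift = np.array([4.0, -2.0, 2.0])  # multiple of the grid spacing
        shifted = receptor.with_coords(receptor.coords + shift)
        a = docking.dock_dinucleotide(receptor, ligand, grid_spacing=2.0, top_k=3,
                                      rotations=[np.eye(3)])
        b = docking.dock_dinucleotide(shifted, ligand, grid_spacing=2.0, top_k=3,
                                      rotations=[np.eye(3)])
        for pa, pb in zip(a, b):
            np.testing.assert_allclose(pb.coords, pa.coords + shift, atol=1e-9)


class TestBindingSiteFilter:
    def _receptor_with_site(self):
        rec = structure_from_coords([[0, 0, 0], [50, 0, 0]])
        return rec, BindingSite((("A", 1),), cutoff=5.0)

    @pytest.mark.parametrize("dist,kept", [(4.9, True), (5.1, False)])
    def test_five_angstrom_boundary(self, dist, kept):
        rec, site = self._receptor_with_site()
        coords = np.tile([dist, 0.0, 0.0], (6, 1)) + np.arange(6)[:, None] * [0, 1e-3, 0]
        pose = make_pose(0, coords)
        out = docking.binding_site_filter([pose], rec, site)
        assert (len(out) == 1) is kept

    def test_matches_all_pairs_oracle(self, ring_fixture, ligand):
        rec, site = ring_fixture["receptor"], ring_fixture["site"]
        rng = np.random.default_rng(12)
        poses = [
            make_pose(i, ligand.coords + rng.uniform(-30, 30, 3)) for i in range(40)
        ]
        kept = docking.binding_site_filter(poses, rec, site)
        wanted = set(site.residues)
        sxyz = np.array(
            [[b.x, b.y, b.z] for b in rec.beads if (b.chain, b.resnum) in wanted]
        )
        oracle = [p for p in poses if cdist(p.coords, sxyz).min() <= site.cutoff]
        assert [p.pose_id for p in kept] == [p.pose_id for p in oracle]

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError):
            BindingSite(())


class TestClusterPoses:
    def test_ten_angstrom_boundary(self, ligand):
        base = ligand.coords
        for sep, n_expect in ((9.0, 1), (11.0, 2)):
            poses = [
                make_pose(0, base, score=2.0),
                make_pose(1, base + [sep, 0, 0], score=1.0),
            ]
            reps = docking.cluster_poses(poses, cutoff=10.0)
            assert len(reps) == n_expect
            assert reps[0].pose_id == 0  # best score is the representative

    def test_singleton(self, ligand):
        p = make_pose(0, ligand.coords)
        assert docking.cluster_poses([p]) == [p]

    def test_matches_brute_force_single_linkage(self, ligand):
        rng = np.random.default_rng(13)
        poses = [
            make_pose(i, ligand.coords + rng.uniform(-25, 25, 3),
                      score=float(rng.random()))
            for i in range(18)
        ]
        reps = docking.cluster_poses(poses, cutoff=10.0)
        # oracle: union-find on the same pairwise max-bead metric
        n = len(poses)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(poses[i].coords - poses[j].coords, axis=1).max()
                if d <= 10.0:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(poses[i])
        oracle_reps = sorted(
            (max(g, key=lambda p: (p.score, -p.pose_id)).pose_id for g in groups.values())
        )
        assert sorted(p.pose_id for p in reps) == oracle_reps


class TestEnumerateChains:
    def _line_poses(self, n, gap=6.0, ligand=None):
        lig = ligand if ligand is not None else docking.make_gu_dinucleotide()
        span = np.linalg.norm(lig.coords[4] - lig.coords[1])
        poses = []
        for i in range(n):
            shift = np.array([i * (span + gap), 0.0, 0.0])
            coords = lig.coords - lig.coords[1] + shift
            # orient anchors along +x: use raw coords but overwrite anchors
            p = DockPose(i, np.eye(3), shift, 1.0, coords,
                         shift, shift + [span, 0, 0])
            poses.append(p)
        return poses

    def test_twelve_pose_line_yields_full_path(self):
        poses = self._line_poses(12, gap=6.0)
        chains = docking.enumerate_chains(poses, d_min=4.5, d_max=8.0, gap_max=0,
                                          max_len=12)
        assert max(len(c.pose_ids) for c in chains) == 12

    def test_census_matches_dfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(14)
        for trial in range(50):
            n = int(rng.integers(3, 9))
            anchors5 = rng.uniform(0, 40, size=(n, 3))
            anchors3 = anchors5 + rng.uniform(-6, 6, size=(n, 3))
            poses = [
                DockPose(i, np.eye(3), np.zeros(3), 1.0,
                         np.vstack([anchors5[i], anchors3[i]]),
                         anchors5[i], anchors3[i])
                for i in range(n)
            ]
            got = docking.enumerate_chains(poses, d_min=3.0, d_max=12.0, gap_max=1,
                                           max_len=8)
            # independent recursive oracle
            edges = {}
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    d = np.linalg.norm(anchors5[j] - anchors3[i])
                    for g in (0, 1):
                        if 3.0 * (g + 1) <= d <= 12.0 * (g + 1):
                            edges.setdefault(i, []).append((j, g))
            count = 0

            def rec(node, used, slots):
                nonlocal count
                count += 1
                for nxt, g in edges.get(node, []):
                    if nxt not in used and slots + g + 1 <= 8:
                        rec(nxt, used | {nxt}, slots + g + 1)

            for start in range(n):
                rec(start, {start}, 1)
            assert len(got) == count

    def test_gap_paths_are_superset(self):
        poses = self._line_poses(6, gap=6.0)
        no_gaps = docking.enumerate_chains(poses, d_min=4.5, d_max=8.0, gap_max=0)
        with_gaps = docking.enumerate_chains(poses, d_min=4.5, d_max=8.0, gap_max=1)
        sig = lambda paths: {tuple(p.slots) for p in paths}
        assert sig(no_gaps) <= sig(with_gaps)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            docking.enumerate_chains([], d_min=8.0, d_max=4.0)


class TestClusterChains:
    def _path(self, ids):
        return ChainPath(list(ids))

    def test_nine_of_twelve_merge_boundary(self):
        a = self._path(range(12))
        b9 = self._path(list(range(9)) + [20, 21, 22])  # shares 9 of 12
        b8 = self._path(list(range(8)) + [20, 21, 22, 23])  # shares 8 of 12
        assert len(docking.cluster_chains([a, b9])) == 1
        assert len(docking.cluster_chains([a, b8])) == 2

    def test_identical_paths_merge(self):
        a = self._path([1, 2, 3])
        b = self._path([1, 2, 3])
        assert len(docking.cluster_chains([a, b])) == 1

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(15)
        paths = []
        for _ in range(15):
            k = int(rng.integers(2, 8))
            ids = list(rng.choice(20, size=k, replace=False))
            paths.append(self._path(ids))
        reps = docking.cluster_chains(paths, identity=0.70)
        # oracle: replay the documented greedy rule independently
        order = sorted(range(len(paths)), key=lambda i: (-len(paths[i].pose_ids), i))
        oracle = []
        for i in order:
            p = paths[i]
            for r in oracle:
                shared = len(set(p.pose_ids) & set(r.pose_ids))
                if shared / max(p.n_slots, r.n_slots) >= 0.70:
                    break
            else:
                oracle.append(p)
        assert [tuple(r.slots) for r in reps] == [tuple(r.slots) for r in oracle]


class TestThreadRNA:
    def test_gu12_threads_24_nucleotides(self, ring_fixture):
        m = ring_fixture["ref_model"]
        assert len({b.resnum for b in m.rna.beads}) == 24
        assert len(m.rna) == 72

    def test_consistent_anchors_leave_geometry_unchanged(self, ligand):
        # anchors taken from an ideal helix: zero-strain threading
        template = docking._helix_coords(8)
        c4 = template[1::3]
        poses = {}
        slots = []
        for s in range(4):
            a5, a3 = c4[2 * s], c4[2 * s + 1]
            poses[s] = DockPose(s, np.eye(3), np.zeros(3), 1.0,
                                np.vstack([a5, a3]), a5, a3)
            slots.append(s)
        m = docking.thread_rna(ChainPath(slots), poses, sequence="GUGUGUGU")
        assert m.anchor_residuals.max() < 0.1
        np.testing.assert_allclose(m.rna.coords, template, atol=0.1)

    def test_energy_decreases_from_initial_placement(self, ring_fixture):
        planted = ring_fixture["planted"]
        path = ring_fixture["ring_path"]
        m = docking.thread_rna(path, planted, max_iter=2000)
        # perturbed anchors guarantee nonzero strain; energy must not grow
        assert m.energy >= 0
        assert m.anchor_residuals.max() < 2.0

    def test_sequence_too_short_rejected(self, ring_fixture):
        with pytest.raises(ValueError):
            docking.thread_rna(ring_fixture["ring_path"], ring_fixture["planted"],
                               sequence="GU")


class TestClashFilter:
    def _model_with_clashes(self, n_pairs):
        """One RNA nucleotide surrounded by n_pairs receptor beads within 3.5 A."""
        rng = np.random.default_rng(16)
        rna = Structure(
            [
                Bead("R", 1, "G", "P", 0.0, 0.0, 2.0, 1.0),
                Bead("R", 1, "G", "C4'", 0.0, 0.0, 0.0, 1.0),
                Bead("R", 1, "G", "BAS", 0.0, 0.0, -2.0, 1.0),
            ]
        )
        pts = []
        while len(pts) < n_pairs:
            p = rng.uniform(-3.3, 3.3, 3)
            d = cdist(p[None, :], rna.coords)
            if (d < 3.5).sum() == 1:  # each receptor bead clashes with one RNA bead
                pts.append(p)
        receptor = structure_from_coords(np.array(pts))
        model = docking.RNAComplexModel(rna, ChainPath([0]), np.zeros(1))
        return model, receptor

    @pytest.mark.parametrize("n,kept", [(150, True), (151, False)])
    def test_boundary_at_150_clashes(self, n, kept):
        model, receptor = self._model_with_clashes(n)
        out = docking.clash_filter([model], receptor)
        assert (len(out) == 1) is kept
        assert model.clash_count == n

    def test_count_matches_all_pairs_oracle(self, ring_fixture):
        m = ring_fixture["ref_model"]
        rec = ring_fixture["receptor"]
        got = docking.count_clashes(m, rec, clash_dist=4.5)
        oracle = int((cdist(rec.coords, m.rna.coords) < 4.5).sum())
        assert got == oracle

    def test_rna_in_empty_space_is_clash_free(self, ring_fixture):
        rec = ring_fixture["receptor"]
        rna = ring_fixture["ref_model"].rna
        far = docking.RNAComplexModel(
            rna.with_coords(rna.coords + 500.0), ChainPath([0]), np.zeros(1)
        )
        assert docking.count_clashes(far, rec) == 0


class TestRigidMotionInvariance:
    def test_filters_invariant_under_global_rigid_motion(self, ring_fixture, ligand):
        from scipy.spatial.transform import Rotation

        rec = ring_fixture["receptor"]
        site = ring_fixture["site"]
        rng = np.random.default_rng(17)
        poses = [
            make_pose(i, ligand.coords + rng.uniform(-28, 28, 3)) for i in range(30)
        ]
        rot = Rotation.random(random_state=1).as_matrix()
        shift = np.array([13.0, -7.0, 21.0])
        rec2 = rec.with_coords(rec.coords @ rot.T + shift)
        poses2 = [
            DockPose(p.pose_id, rot @ p.rotation, rot @ p.translation + shift,
                     p.score, p.coords @ rot.T + shift,
                     rot @ p.anchor5 + shift, rot @ p.anchor3 + shift)
            for p in poses
        ]
        kept1 = [p.pose_id for p in docking.binding_site_filter(poses, rec, site)]
        kept2 = [p.pose_id for p in docking.binding_site_filter(poses2, rec2, site)]
        assert kept1 == kept2
        reps1 = [p.pose_id for p in docking.cluster_poses(poses, 10.0)]
        reps2 = [p.pose_id for p in docking.cluster_poses(poses2, 10.0)]
        assert reps1 == reps2
        sig = lambda chains: sorted(
            tuple(-1 if s is None else s for s in c.slots) for c in chains
        )
        c1 = docking.enumerate_chains(poses, d_min=4.0, d_max=12.0, gap_max=1, max_len=6)
        c2 = docking.enumerate_chains(poses2, d_min=4.0, d_max=12.0, gap_max=1, max_len=6)
        assert sig(c1) == sig(c2)


@pytest.fixture(scope="module")
def funnel(ring_fixture, ligand):
    poses = docking.dock_dinucleotide(
        ring_fixture["receptor"], ligand, grid_spacing=1.5, top_k=480,
        per_rotation=40, rotations=ring_fixture["rotations"], min_separation=9.0,
    )
    kept = docking.binding_site_filter(poses, ring_fixture["receptor"],
                                       ring_fixture["site"])
    reps = docking.cluster_poses(kept, cutoff=6.0)
    return poses, kept, reps


class TestPlantedRingRecovery:
    """The docking funnel on a ring of 12 planted pockets."""

    def test_pose_recovery_covers_at_least_nine_pockets(self, funnel, ring_fixture):
        _, _, reps = funnel
        centers = ring_fixture["centers"]
        covered = set()
        for p in reps:
            d = cdist(p.coords.mean(axis=0)[None, :], centers)
            if d.min() < 7.0:
                covered.add(int(d.argmin()))
        assert len(covered) >= 9

    def test_planted_path_threads_and_passes_clash_filter(self, ring_fixture):
        path = ring_fixture["ring_path"]
        assert len(path.pose_ids) == 12
        model = docking.thread_rna(path, ring_fixture["planted"], max_iter=3000)
        survivors = docking.clash_filter(
            [model], ring_fixture["receptor"], clash_dist=3.0,
            site=ring_fixture["site"],
        )
        assert survivors and survivors[0].clash_count <= 150

    def test_funnel_produces_surviving_threaded_models(self, funnel, ring_fixture):
        """Threaded combinations span tangled and clean geometries; the
        clash filter at its defaults keeps at least the clean ones."""
        _, _, reps = funnel
        chains = docking.enumerate_chains(reps, d_min=4.0, d_max=11.0, gap_max=1,
                                          max_len=12, max_paths=100_000)
        shorts = [c for c in chains if len(c.pose_ids) <= 2][:30]
        longs = docking.cluster_chains(
            sorted(chains, key=lambda c: -len(c.pose_ids))[:2000]
        )[:10]
        seq = "GU" * 12
        models = [
            docking.thread_rna(p, reps, sequence=seq[: max(2 * p.n_slots, 4)],
                               max_iter=1000)
            for p in shorts + longs
        ]
        survivors = docking.clash_filter(
            models, ring_fixture["receptor"], site=ring_fixture["site"]
        )
        assert len(survivors) >= 1
        assert len(survivors) < len(models)  # the filter actually rejects tangles
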