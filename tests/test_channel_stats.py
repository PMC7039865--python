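import numpy as np
import pytest

from porekit import channel_stats as cs
from porekit import pore_profile as pp
from porekit import synthetic_data as sd
from porekit import tunnel_search as ts
from porekit.exceptions import AnalysisError
from porekit.io_core import AtomRecord, Frame, Topology, Trajectory
from porekit.tunnel_search import OpenConformation, Tunnel


from oracles import chain_trajectory as _chain_trajectory
from oracles import stub_conf as _stub_conf
from oracles import ward_oracle as _ward_oracle


class TestLiningResidues:
    def _single_atom_top(self):
        atoms = [AtomRecord(0, "CA", "C", 1.7, 1, "ALA", "A", "protein")]
        return Topology(atoms)

    @pytest.mark.parametrize(
        "atom_distance,expected", [(4.5, True), (5.2, False)]
    )
    def test_surface_gap_criterion(self, atom_distance, expected):
        """Gap = center distance − sphere radius, compared to 3.0 Å."""
        top = self._single_atom_top()
        frame = Frame(0, np.array([[atom_distance, 0.0, 0.0]]))
        tunnel = Tunnel(0, np.array([[0.0, 0.0, 0.0, 2.0]]), cost=1.0)
        lining = cs.lining_residues(tunnel, frame, top)
        assert (1 in lining) is expected

    def test_synthetic_channel_rings(self, constant_channel, channel_slab):
        """The axial tunnel touches exactly the rings along its span."""
        ch = constant_channel
        frame = ch.trajectory.frames[0]
        tunnels = ts.search_tunnels(
            frame, ch.trajectory.topology, np.array([40.0, 40.0, 65.0])
        )
        ts.classify_tunnels(tunnels, channel_slab)
        tunnel = tunnels[0]
        lining = cs.lining_residues(tunnel, frame, ch.trajectory.topology)
        # oracle: ring k (z = 50 + k) lines iff its atoms are within
        # 3.0 of some sphere surface; verify per ring with direct geometry
        zs = ch.spec.slice_z()
        for ring_id, z in enumerate(zs):
            ring_atoms = ch.trajectory.topology.select(
                residue_indices=[ring_id + 1]
            )
            coords = frame.coordinates[ring_atoms]
            d = np.sqrt(
                ((coords[:, None, :] - tunnel.spheres[None, :, :3]) ** 2)
                .sum(axis=2)
            )
            gap = (d - tunnel.spheres[None, :, 3]).min()
            assert ((ring_id + 1) in lining) is bool(gap < 3.0)


class TestLiningFrequency:
    def test_normalization_to_max(self):
        traj = _chain_trajectory([np.zeros((4, 3))] * 10)
        # residue 1 lined in all 10 frames, residue 2 in 5
        confs = []
        for f in range(10):
            xyz = (0.0, 0.0, 0.0) if f < 5 else (100.0, 100.0, 100.0)
            confs.append(_stub_conf(f, sphere_xyz=xyz, radius=0.5))
        # atoms: residue k at (3.8*(k-1), 0, 0); sphere at origin radius .5
        coords = np.zeros((4, 3))
        coords[:, 0] = [0.0, 2.0, 50.0, 60.0]
        traj = _chain_trajectory([coords] * 10)
        table = cs.lining_frequency(confs, traj)
        by_res = table.set_index("residue_index")
        assert by_res.loc[1, "raw_count"] == 5
        assert by_res.loc[2, "raw_count"] == 5
        assert by_res.loc[1, "frequency"] == 1.0

    def test_full_and_half_frequency(self):
        coords = np.zeros((4, 3))
        coords[:, 0] = [0.0, 30.0, 60.0, 90.0]
        traj = _chain_trajectory([coords] * 10)
        confs = [
            _stub_conf(f, sphere_xyz=(0.0 if f < 10 else 30.0, 0, 0),
                       radius=0.5)
            for f in range(10)
        ]
        # make residue 2 line only 5 frames via a second tunnel position
        for f in range(5):
            confs[f] = _stub_conf(f, sphere_xyz=(15.0, 0.0, 0.0), radius=14.0)
        table = cs.lining_frequency(confs, traj).set_index("residue_index")
        assert table.loc[1, "frequency"] == 1.0
        assert table.loc[2, "frequency"] == 0.5
        assert table.loc[1, "raw_count"] == 10 and table.loc[2, "raw_count"] == 5

    def test_n_open_normalization(self):
        coords = np.zeros((4, 3))
        traj = _chain_trajectory([coords] * 4)
        confs = [_stub_conf(f) for f in range(4)]
        table = cs.lining_frequency(confs, traj, normalization="n_open")
        assert (table["frequency"] == 1.0).all()

    def test_no_open_frames_errors(self):
        traj = _chain_trajectory([np.zeros((4, 3))])
        with pytest.raises(AnalysisError):
            cs.lining_frequency([], traj)


class TestClusterChannels:
    def _confs_and_traj(self, frame_coords):
        traj = _chain_trajectory(frame_coords, n_res=frame_coords[0].shape[0])
        confs = [_stub_conf(f) for f in range(len(frame_coords))]
        return confs, traj

    def test_identical_frames_single_cluster(self):
        coords = np.random.default_rng(0).normal(size=(4, 3))
        confs, traj = self._confs_and_traj([coords, coords.copy()])
        clusters, link = cs.cluster_channels(confs, traj, threshold=4.5)
        assert len(clusters) == 1
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_displaced_families(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(4, 3))
        shifted = base + np.array([3.0, 0.0, 0.0])
        frames = [base, base + rng.normal(0, 0.05, (4, 3)),
                  shifted, shifted + rng.normal(0, 0.05, (4, 3))]
        confs, traj = self._confs_and_traj(frames)
        clusters, _ = cs.cluster_channels(confs, traj, threshold=2.0)
        assert len(clusters) == 2
        families = sorted(tuple(sorted(c.members)) for c in clusters)
        assert families == [(0, 1), (2, 3)]

    def test_threshold_above_max_height_single_cluster(self):
        rng = np.random.default_rng(2)
        frames = [rng.normal(size=(4, 3)) for _ in range(5)]
        confs, traj = self._confs_and_traj(frames)
        clusters, link = cs.cluster_channels(confs, traj, threshold=1e6)
        assert len(clusters) == 1

    def test_merge_order_matches_lance_williams_oracle(self):
        rng = np.random.default_rng(3)
        frames = [rng.normal(size=(5, 3)) * 2 for _ in range(12)]
        confs, traj = self._confs_and_traj(frames)
        _, link = cs.cluster_channels(confs, traj, threshold=0.1)
        dist = cs._lining_rmsd_matrix(confs, traj, 3.0)
        oracle = _ward_oracle(dist)
        # replay scipy's linkage into member sets
        members = {i: frozenset([i]) for i in range(12)}
        for k, row in enumerate(link):
            a, b, h, _ = row
            sets = {members[int(a)], members[int(b)]}
            assert sets == {oracle[k][0], oracle[k][1]}
            assert h == pytest.approx(oracle[k][2], rel=1e-9)
            members[12 + k] = members[int(a)] | members[int(b)]

    def test_permutation_invariant_partition(self):
        rng = np.random.default_rng(4)
        frames = [rng.normal(size=(4, 3)) for _ in range(6)]
        confs, traj = self._confs_and_traj(frames)
        clusters_a, _ = cs.cluster_channels(confs, traj, threshold=3.0)
        perm = [3, 1, 5, 0, 4, 2]
        confs_p = [_stub_conf(f) for f in perm]
        traj_p = _chain_trajectory([frames[p] for p in perm], n_res=4)
        # relabel stub frame indices to 0..5 in permuted order
        confs_p = [_stub_conf(i) for i in range(6)]
        clusters_b, _ = cs.cluster_channels(confs_p, traj_p, threshold=3.0)
        part_a = sorted(
            tuple(sorted(perm.index(m) for m in c.members))
            for c in clusters_a
            if True
        )
        # map cluster members of A into permuted positions for comparison
        pos_of_frame = {f: i for i, f in enumerate(perm)}
        part_a = sorted(
            tuple(sorted(pos_of_frame[m] for m in c.members))
            for c in clusters_a
        )
        part_b = sorted(tuple(sorted(c.members)) for c in clusters_b)
        assert part_a == part_b

    def test_single_frame_trivial_cluster(self):
        confs, traj = self._confs_and_traj([np.zeros((4, 3))])
        clusters, _ = cs.cluster_channels(confs, traj)
        assert clusters[0].members == [0]

    def test_cluster_count_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(5)
        frames = [rng.normal(size=(4, 3)) * 3 for _ in range(8)]
        confs, traj = self._confs_and_traj(frames)
        counts = [
            len(cs.cluster_channels(confs, traj, threshold=t)[0])
            for t in (0.5, 1.5, 3.0, 6.0, 12.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestRadiusProfileZ:
    def _conf_with_spheres(self, spheres):
        arr = np.asarray(spheres, dtype=float)
        t = Tunnel(0, arr, cost=1.0, endpoint="intracellular")
        u = Tunnel(0, arr[:1], cost=1.0, endpoint="extracellular")
        return OpenConformation(0, [t, u], (t, u))

    def test_constant_radius(self):
        spheres = [[0, 0, z, 2.5] for z in np.arange(50.0, 60.0, 0.5)]
        conf = self._conf_with_spheres(spheres)
        prof = cs.radius_profile_z([conf], bin_width=1.0)
        filled = prof[prof.n_spheres > 0]
        assert (filled.mean_radius == 2.5).all()

    def test_mixed_radii_average(self):
        t1 = Tunnel(0, np.array([[0, 0, 50.2, 2.0]]), 1.0, "intracellular")
        t2 = Tunnel(0, np.array([[0, 0, 50.7, 3.0]]), 1.0, "extracellular")
        conf = OpenConformation(0, [t1, t2], (t1, t2))
        prof = cs.radius_profile_z([conf], bin_width=1.0)
        filled = prof[prof.n_spheres > 0]
        assert len(filled) == 1
        assert filled.iloc[0].mean_radius == pytest.approx(2.5)

    def test_sphere_count_conserved(self, constant_channel, channel_slab):
        ch = constant_channel
        frame = ch.trajectory.frames[0]
        tunnels = ts.search_tunnels(
            frame, ch.trajectory.topology, np.array([40.0, 40.0, 65.0])
        )
        ts.classify_tunnels(tunnels, channel_slab)
        confs = ts.select_open_conformations({0: tunnels})
        prof = cs.radius_profile_z(confs)
        expected = sum(t.spheres.shape[0] for t in confs[0].selected_pair)
        assert prof.n_spheres.sum() == expected

    def test_hourglass_profile_recovered(self, channel_slab):
        spec = sd.ChannelSpec(
            radius_profile=lambda z, f: sd.hourglass(65.0, 4.0, 2.2, 12.0)(z),
            n_slices=30,
        )
        ch = sd.make_channel_trajectory(spec, 1)
        frame = ch.trajectory.frames[0]
        tunnels = ts.search_tunnels(
            frame, ch.trajectory.topology, np.array([40.0, 40.0, 65.0]),
            grid_step=0.5,
        )
        ts.classify_tunnels(tunnels, channel_slab)
        confs = ts.select_open_conformations({0: tunnels})
        assert confs
        prof = cs.radius_profile_z(confs, bin_width=1.0)
        for _, row in prof[prof.n_spheres > 0].iterrows():
            z = row.z_center
            if channel_slab.z_lower + 1 < z < channel_slab.z_upper - 1:
                truth = ch.true_radius(z, 0)
                # grid discretization + bin averaging tolerance
                assert row.mean_radius == pytest.approx(truth, abs=0.5 + 0.5)

    def test_empty_pool_errors(self):
        with pytest.raises(AnalysisError):
            cs.radius_profile_z([])
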