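import numpy as np
import pytest

from sercatools.contacts import (
    DistanceSeries,
    HBondCriteria,
    contact_rmsd_correlation,
    distance_series,
    hbond_occupancy,
    hbond_satisfied_frame,
    histogram,
    occupancy,
)
from sercatools.core import (
    Atom,
    CardinalityError,
    EmptyInputError,
    Frame,
    SelectionError,
    SercatoolsError,
    Topology,
)
from sercatools.selection import select
from sercatools.synth import DistanceProcessSpec, make_distance_process

from conftest import make_trajectory


def two_point_traj(offsets, box=None):
    """One pair of atoms separated along z by the given per-frame offsets."""
    atoms = (Atom(1, "NE2", "N", "GLN", 108, "A", "protein"),
             Atom(2, "P", "P", "POPC", 1001, "L", "lipid"))
    top = Topology(atoms)
    coords = np.zeros((len(offsets), 2, 3))
    coords[:, 1, 2] = offsets
    traj = make_trajectory(coords, topology=top)
    if box is not None:
        for fr in traj.frames:
            fr.box = np.asarray(box, dtype=float)
    return traj, top


class TestDistanceSeries:
    def test_named_atom_constant_pair(self):
        traj, top = two_point_traj([0.5] * 4)
        s = distance_series(traj, select(top, "name NE2"),
                            select(top, "name P"), mode="named-atom")
        assert np.allclose(s.values, 0.5)

    def test_named_atom_requires_singletons(self, glu_topology):
        traj = make_trajectory(np.zeros((1, 5, 3)) + np.arange(5)[:, None],
                               topology=glu_topology)
        with pytest.raises(CardinalityError):
            distance_series(traj, select(glu_topology, "name OE1 OE2"),
                            select(glu_topology, "resid 1001"),
                            mode="named-atom")

    def test_empty_selection_rejected(self, glu_topology):
        traj = make_trajectory(np.arange(15).reshape(1, 5, 3) / 10,
                               topology=glu_topology)
        with pytest.raises(SelectionError):
            distance_series(traj, select(glu_topology, "name XX"),
                            select(glu_topology, "name OE1"))

    def test_min_heavy_atom_matches_brute_force(self):
        rng = np.random.default_rng(0)
        n_a, n_b, n_frames = 5, 7, 50
        atoms = tuple(
            Atom(i + 1, "C", "C", "GLY", 1 if i < n_a else 2, "A", "protein")
            for i in range(n_a + n_b)
        )
        top = Topology(atoms)
        coords = rng.uniform(0, 2, size=(n_frames, n_a + n_b, 3))
        traj = make_trajectory(coords, topology=top)
        s = distance_series(traj, select(top, "resid 1"), select(top, "resid 2"),
                            mode="min-heavy-atom")
        for k in range(n_frames):
            want = min(
                np.linalg.norm(coords[k, i] - coords[k, j])
                for i in range(n_a) for j in range(n_a, n_a + n_b)
            )
            assert s.values[k] == pytest.approx(want, abs=1e-9)

    def test_minimum_image_convention(self):
        traj, top = two_point_traj([0.6], box=(1.0, 1.0, 1.0))
        s = distance_series(traj, select(top, "name NE2"),
                            select(top, "name P"), mode="named-atom")
        assert s.values[0] == pytest.approx(0.4, abs=1e-12)

    def test_center_of_geometry_mode(self, glu_topology):
        coords = np.zeros((1, 5, 3))
        coords[0, 0] = (0, 0, 0)    # OE1
        coords[0, 1] = (0, 0, 0.2)  # OE2 -> COG at z=0.1
        coords[0, 3] = (0, 0, 1.0)
        coords[0, 4] = (0, 0, 1.4)  # waters COG at z=1.2
        traj = make_trajectory(coords, topology=glu_topology)
        s = distance_series(traj, select(glu_topology, "name OE1 OE2"),
                            select(glu_topology, "category water"),
                            mode="center-of-geometry")
        assert s.values[0] == pytest.approx(1.1, abs=1e-12)


class TestOccupancy:
    def test_boundary_is_inclusive(self):
        s = DistanceSeries(np.full(10, 0.5))
        assert occupancy(s, (0.0, 0.5)).fraction == 1.0

    def test_interval_outside_data_is_zero(self):
        s = DistanceSeries(np.linspace(0.1, 0.8, 100))
        assert occupancy(s, (0.9, 1.0)).fraction == 0.0

    def test_partition_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        s = DistanceSeries(rng.uniform(0.0, 1.0, 10_000))
        edges = [0.0, 0.25, 0.5, 0.75, 1.0001]
        total = sum(
            occupancy(s, (edges[i], np.nextafter(edges[i + 1], 0))).fraction
            for i in range(4)
        )
        # half-open partition emulated with nextafter; closed [0, inf) = 1
        assert total == pytest.approx(1.0, abs=1e-12)
        assert occupancy(s, (0.0, np.inf)).fraction == 1.0

    def test_empty_series_rejected(self):
        with pytest.raises(EmptyInputError):
            occupancy(DistanceSeries(np.array([])), (0.0, 1.0))

    def test_recovers_planted_two_state_occupancy(self):
        spec = DistanceProcessSpec((0.5, 0.8), (0.03, 0.03), (0.6, 0.4),
                                   transition_rate=0.5, n_frames=10_000, seed=4)
        res = make_distance_process(spec)
        occ = occupancy(DistanceSeries(res.values), (0.35, 0.65))
        assert occ.fraction == pytest.approx(0.60, abs=0.03)


class TestHBonds:
    @staticmethod
    def donor_acceptor_frame(d_da, h_offset=None):
        atoms = [Atom(1, "OG1", "O", "THR", 316, "A", "protein"),
                 Atom(2, "O1P", "O", "POPC", 1001, "L", "lipid")]
        coords = [(0.0, 0.0, 0.0), (0.0, 0.0, d_da)]
        if h_offset is not None:
            atoms.append(Atom(3, "HG1", "H", "THR", 316, "A", "protein"))
            coords.append(h_offset)
        top = Topology(tuple(atoms))
        return top, np.array([coords])

    def test_collinear_hydrogen_satisfies(self):
        top, coords = self.donor_acceptor_frame(0.28, h_offset=(0, 0, 0.1))
        traj = make_trajectory(coords, topology=top)
        occ = hbond_occupancy(traj, select(top, "name OG1"),
                              select(top, "name O1P"))
        assert occ.fraction == 1.0
        assert "angle" in occ.criterion

    def test_distance_over_cutoff_fails(self):
        top, coords = self.donor_acceptor_frame(0.36, h_offset=(0, 0, 0.1))
        traj = make_trajectory(coords, topology=top)
        occ = hbond_occupancy(traj, select(top, "name OG1"),
                              select(top, "name O1P"))
        assert occ.fraction == 0.0

    def test_bad_angle_fails_with_hydrogens_present(self):
        # H at right angle to the D..A axis: D-H..A angle ~45 deg < 150
        top, coords = self.donor_acceptor_frame(0.30, h_offset=(0.1, 0, 0))
        traj = make_trajectory(coords, topology=top)
        occ = hbond_occupancy(traj, select(top, "name OG1"),
                              select(top, "name O1P"))
        assert occ.fraction == 0.0

    def test_no_hydrogen_fallback_recorded(self):
        top, coords = self.donor_acceptor_frame(0.30)
        traj = make_trajectory(coords, topology=top)
        occ = hbond_occupancy(traj, select(top, "name OG1"),
                              select(top, "name O1P"))
        assert occ.fraction == 1.0
        assert "fallback" in occ.criterion

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(6)
        n_d, n_a = 3, 4
        atoms = (
            [Atom(i + 1, "OD", "O", "ASP", 1, "A", "protein") for i in range(n_d)]
            + [Atom(n_d + i + 1, "H", "H", "ASP", 1, "A", "protein")
               for i in range(n_d)]
            + [Atom(2 * n_d + i + 1, "OA", "O", "HOH", 2 + i, "W", "water")
               for i in range(n_a)]
        )
        top = Topology(tuple(atoms))
        crit = HBondCriteria()
        donors = select(top, "name OD").indices
        acceptors = select(top, "name OA").indices
        mismatches = 0
        for _ in range(300):
            coords = rng.uniform(0, 0.8, size=(top.n_atoms, 3))
            # put each H near its donor so the covalent assignment is defined
            for i in range(n_d):
                coords[n_d + i] = coords[i] + rng.normal(0, 0.02, 3)
            fr = Frame(coords=coords)
            got = hbond_satisfied_frame(top, fr, donors, acceptors, crit, True)
            want = self.brute_force(top, coords, donors, acceptors, crit)
            mismatches += got != want
        assert mismatches == 0

    @staticmethod
    def brute_force(top, coords, donors, acceptors, crit):
        h_idx = [i for i, e in enumerate(top.elements) if e == "H"]
        for d in donors:
            hs = [h for h in h_idx
                  if np.linalg.norm(coords[h] - coords[d]) <= crit.dh_max]
            for a in acceptors:
                if np.linalg.norm(coords[a] - coords[d]) > crit.d_max:
                    continue
                for h in hs:
                    v1 = coords[d] - coords[h]
                    v2 = coords[a] - coords[h]
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= crit.angle_min:
                        return True
        return False


class TestHistogram:
    def test_single_value_density(self):
        s = DistanceSeries(np.full(1000, 0.5))
        h = histogram(s, bin_width=0.025)
        nz = h.densities[h.densities > 0]
        assert len(nz) == 1
        assert nz[0] == pytest.approx(40.0)

    def test_two_planted_peaks_located(self):
        spec = DistanceProcessSpec((0.5, 0.8), (0.03, 0.03), (0.5, 0.5),
                                   n_frames=50_000, seed=2)
        res = make_distance_process(spec)
        h = histogram(DistanceSeries(res.values), bin_width=0.025)
        d = h.densities
        local_max = [
            h.centers[i] for i in range(1, len(d) - 1)
            if d[i] >= d[i - 1] and d[i] >= d[i + 1] and d[i] > 0.5 * d.max()
        ]
        assert any(abs(c - 0.5) <= 0.025 for c in local_max)
        assert any(abs(c - 0.8) <= 0.025 for c in local_max)

    def test_normalization(self):
        rng = np.random.default_rng(0)
        s = DistanceSeries(rng.gamma(2.0, 0.2, size=3000))
        h = histogram(s, bin_width=0.01)
        assert np.sum(h.densities * np.diff(h.bin_edges)) == pytest.approx(1.0, abs=1e-9)


class TestCorrelation:
    def test_perfect_correlation(self):
        x = np.linspace(0, 1, 50)
        assert contact_rmsd_correlation(x, x).r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.linspace(0, 1, 50)
        assert contact_rmsd_correlation(x, -x).r == pytest.approx(-1.0)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        assert abs(contact_rmsd_correlation(x, y).r) < 0.03

    def test_zero_variance_rejected(self):
        with pytest.raises(SercatoolsError, match="zero variance"):
            contact_rmsd_correlation(np.ones(10), np.arange(10.0))
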