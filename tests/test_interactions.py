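import numpy as np
import pytest

from bindsight import interactions as ia
from bindsight import presets
from bindsight import synthetic as syn
from bindsight.structio import Selection, Structure, Trajectory

from conftest import hexagon, make_atom, random_rotation

LIG_SEL = Selection.make(resnames=["LIG"], heavy_only=True)


def brute_force_contacts(traj, lig_idx, groups, cutoff):
    """O(n^2) per-frame contact oracle, independent of the library path."""
    out = {key: 0 for key in groups}
    for frame in traj.frames:
        for key, idx in groups.items():
            hit = False
            for i in idx:
                for j in lig_idx:
                    if np.linalg.norm(frame[i] - frame[j]) <= cutoff:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                out[key] += 1
    return {k: v / traj.n_frames for k, v in out.items()}


class TestContactProfile:
    def test_agrees_with_brute_force_oracle(self, rng):
        """Random small system: library profile equals the pairwise scan."""
        atoms = [make_atom(i + 1, "C1", "LIG", "L", 900, rng.normal(0, 2, 3))
                 for i in range(4)]
        serial = 5
        for resseq in range(1, 11):
            for name in ("CB", "CG"):
                atoms.append(
                    make_atom(serial, name, "ALA", "A", resseq, rng.normal(0, 5, 3))
                )
                serial += 1
        top = Structure(atoms=atoms)
        frames = [top.coords + rng.normal(0, 1.5, size=(len(atoms), 3))
                  for _ in range(20)]
        traj = Trajectory(topology=top, frames=frames)
        profile = ia.contact_profile(traj, LIG_SEL)
        lig_idx = [i for i, a in enumerate(top.atoms) if a.resname == "LIG"]
        groups = {}
        for i, a in enumerate(top.atoms):
            if a.resname != "LIG":
                groups.setdefault((a.chain, a.resseq), []).append(i)
        oracle = brute_force_contacts(traj, lig_idx, groups, 4.0)
        for row in profile.rows:
            assert row.contact_probability == pytest.approx(
                oracle[(row.chain, row.resseq)]
            )

    def test_planted_fractions_recovered_exactly(self):
        traj = syn.make_planted_contact_trajectory(
            100, {10: 0.5, 11: 0.0, 12: 1.0}, seed=1
        )
        profile = ia.contact_profile(traj, LIG_SEL)
        assert profile.probability("A", 10) == 0.50
        assert profile.probability("A", 11) == 0.0
        assert profile.probability("A", 12) == 1.0

    def test_stable_threshold_is_strict(self):
        """Contact 40% of the time is not 'stable'; 41% is."""
        traj = syn.make_planted_contact_trajectory(
            100, {20: 0.40, 21: 0.41}, seed=2
        )
        profile = ia.contact_profile(traj, LIG_SEL)
        rows = {r.resseq: r for r in profile.rows}
        assert rows[20].contact_probability == 0.40 and not rows[20].stable
        assert rows[21].contact_probability == 0.41 and rows[21].stable

    def test_frame_permutation_and_duplication(self):
        traj = syn.make_planted_contact_trajectory(50, {10: 0.3}, seed=3)
        base = ia.contact_profile(traj, LIG_SEL).probability("A", 10)
        perm = np.random.default_rng(0).permutation(50)
        shuffled = Trajectory(
            topology=traj.topology, frames=[traj.frames[i] for i in perm]
        )
        assert ia.contact_profile(shuffled, LIG_SEL).probability("A", 10) == base
        doubled = Trajectory(
            topology=traj.topology, frames=traj.frames + traj.frames
        )
        assert ia.contact_profile(doubled, LIG_SEL).probability("A", 10) == base

    def test_empty_ligand_selection_rejected(self):
        traj = syn.make_planted_contact_trajectory(10, {10: 0.5})
        with pytest.raises(ValueError):
            ia.contact_profile(traj, Selection.make(resnames=["XXX"]))


class TestTopCoordinating:
    @staticmethod
    def _profile(probs):
        rows = [
            ia.ContactRow("A", resseq, "ALA", p, p > 0.4)
            for resseq, p in probs.items()
        ]
        return ia.ContactProfile(rows=rows, n_frames=100, cutoff=4.0, stable_threshold=0.4)

    def test_descending_order_and_k(self):
        profile = self._profile({1: 0.2, 2: 0.9, 3: 0.5, 4: 0.7})
        top = ia.top_coordinating_residues(profile, k=3)
        assert [r.resseq for r in top] == [2, 4, 3]

    def test_ties_broken_by_residue_number(self):
        profile = self._profile({7: 0.5, 3: 0.5, 5: 0.9})
        top = ia.top_coordinating_residues(profile, k=3)
        assert [r.resseq for r in top] == [5, 3, 7]

    def test_k_larger_than_profile_returns_all(self):
        profile = self._profile({1: 0.1, 2: 0.2})
        assert len(ia.top_coordinating_residues(profile, k=15)) == 2


class TestRingGeometry:
    def test_hexagon_normal_and_com(self):
        atoms = hexagon((0, 0, 0))
        coords = np.array([a.position for a in atoms])
        com, normal = ia.ring_geometry(coords, ["C"] * 6)
        assert np.allclose(com, 0.0, atol=1e-9)
        assert abs(normal @ np.array([0, 0, 1.0])) == pytest.approx(1.0, abs=1e-9)

    def test_tilted_hexagon_normal(self):
        atoms = hexagon((0, 0, 0), normal_tilt_deg=30.0)
        coords = np.array([a.position for a in atoms])
        _, normal = ia.ring_geometry(coords, ["C"] * 6)
        angle = np.degrees(np.arccos(abs(normal @ np.array([0, 0, 1.0]))))
        assert angle == pytest.approx(30.0, abs=1e-6)

    def test_collinear_atoms_rejected(self):
        coords = np.outer(np.arange(5, dtype=float), [1, 0, 0])
        with pytest.raises(ValueError):
            ia.ring_geometry(coords, ["C"] * 5)

    def test_ringspec_resolves_indole_and_reports_missing(self):
        top = syn.make_stacked_rings_trajectory(1, 1.0).topology
        ring, _ = presets.default_ring_specs(trp_chain="A", ligand_chain="L")
        assert len(ring.resolve(top)) == 9
        bad = ia.RingSpec(chain="A", resseq=84, atom_names=("CG", "CD1", "NE1", "CE2", "XX9"))
        with pytest.raises(ValueError, match="XX9"):
            bad.resolve(top)


class TestStacking:
    @staticmethod
    def _rings(fraction, n=100, dist=3.5, angle=0.0, seed=0):
        traj = syn.make_stacked_rings_trajectory(
            n, fraction, distance_when_stacked=dist,
            angle_when_stacked=angle, seed=seed,
        )
        ra, rb = presets.default_ring_specs(trp_chain="A", ligand_chain="L")
        return traj, ra, rb

    def test_parallel_close_rings_always_stacked(self):
        traj, ra, rb = self._rings(1.0, dist=3.5)
        series = ia.stacking_series(traj, ra, rb)
        assert series.occupancy == 1.0
        assert np.allclose(series.com_distance, 3.5, atol=1e-9)

    def test_com_distance_beyond_cutoff_never_stacked(self):
        traj, ra, rb = self._rings(1.0, dist=5.5)
        assert ia.stacking_series(traj, ra, rb).occupancy == 0.0

    def test_angle_threshold_bracketing(self):
        traj44, ra, rb = self._rings(0.6, dist=4.0, angle=44.0, seed=5)
        traj46, _, _ = self._rings(0.6, dist=4.0, angle=46.0, seed=5)
        assert ia.stacking_series(traj44, ra, rb).occupancy == pytest.approx(0.6)
        assert ia.stacking_series(traj46, ra, rb).occupancy == 0.0

    def test_normal_sign_invariance(self):
        """Reversing one ring's atom order flips its normal but not occupancy."""
        traj, ra, rb = self._rings(0.8, dist=4.5, angle=20.0, seed=6)
        base = ia.stacking_series(traj, ra, rb)
        rb_rev = ia.RingSpec(rb.chain, rb.resseq, tuple(reversed(rb.atom_names)))
        flipped = ia.stacking_series(traj, ra, rb_rev)
        assert flipped.occupancy == base.occupancy
        assert np.allclose(flipped.normal_angle, base.normal_angle, atol=1e-9)

    def test_invariant_under_rigid_motion_of_frames(self):
        traj, ra, rb = self._rings(0.7, dist=4.0, angle=30.0, seed=7)
        base = ia.stacking_series(traj, ra, rb)
        R = random_rotation(11)
        t = np.array([5.0, -3.0, 8.0])
        moved = Trajectory(
            topology=traj.topology,
            frames=[f @ R.T + t for f in traj.frames],
        )
        res = ia.stacking_series(moved, ra, rb)
        assert res.occupancy == base.occupancy
        assert np.allclose(res.com_distance, base.com_distance, atol=1e-9)


class TestHbond:
    @staticmethod
    def _hbond_traj(n_good, n_bad, good_da=2.8, good_angle=175.0, bad_da=4.0):
        atoms = [
            make_atom(1, "N2", "MRS", "L", 901, (0, 0, 0), element="N"),
            make_atom(2, "H2", "MRS", "L", 901, (0, 0, 1.0), element="H"),
            make_atom(3, "O", "LYS", "A", 384, (0, 0, 2.8), element="O"),
        ]
        top = Structure(atoms=atoms)
        frames = []
        for _ in range(n_good):
            a = np.radians(180.0 - good_angle)
            acceptor = np.array(
                [np.sin(a) * (good_da - 1.0), 0.0, 1.0 + np.cos(a) * (good_da - 1.0)]
            )
            # D at origin, H at (0,0,1): D-H-A angle = 180 - a by construction
            frames.append(np.array([[0, 0, 0], [0, 0, 1.0], acceptor]))
        for _ in range(n_bad):
            frames.append(np.array([[0, 0, 0], [0, 0, 1.0], [0, 0, bad_da]]))
        return Trajectory(topology=top, frames=frames)

    def test_good_geometry_present(self):
        traj = self._hbond_traj(5, 0)
        series = ia.hbond_series(
            traj, ("L", 901, "N2"), ("A", 384, "O"), hydrogen=("L", 901, "H2")
        )
        assert series.occupancy == 1.0
        assert np.all(series.da_distance < 3.0)
        assert np.all(series.dha_angle > 170.0)

    def test_long_distance_absent(self):
        traj = self._hbond_traj(0, 5, bad_da=4.0)
        series = ia.hbond_series(
            traj, ("L", 901, "N2"), ("A", 384, "O"), hydrogen=("L", 901, "H2")
        )
        assert series.occupancy == 0.0

    def test_occupancy_fraction(self):
        traj = self._hbond_traj(70, 30)
        series = ia.hbond_series(
            traj, ("L", 901, "N2"), ("A", 384, "O"), hydrogen=("L", 901, "H2")
        )
        assert series.occupancy == pytest.approx(0.70)

    def test_distance_only_mode_without_hydrogen(self):
        traj = self._hbond_traj(3, 2)
        series = ia.hbond_series(traj, ("L", 901, "N2"), ("A", 384, "O"))
        assert series.dha_angle is None
        assert series.occupancy == pytest.approx(0.6)

    def test_missing_atom_rejected(self):
        traj = self._hbond_traj(1, 1)
        with pytest.raises(ValueError):
            ia.hbond_series(traj, ("L", 901, "N9"), ("A", 384, "O"))


class TestMoietyRmsf:
    @staticmethod
    def _traj(sig_by_group, n_frames=400, seed=0):
        rng = np.random.default_rng(seed)
        fit_atoms = [
            make_atom(i + 1, "CA", "GLY", "F", i + 1, p)
            for i, p in enumerate([(0, 0, 0), (10, 0, 0), (0, 10, 0), (0, 0, 10)])
        ]
        moiety_atoms = []
        serial = 5
        for g, (name, sig, count) in enumerate(sig_by_group):
            for j in range(count):
                moiety_atoms.append(
                    make_atom(serial, f"{name}{j}", "LIG", "L", 900, (5 + g, 5, 5 + j))
                )
                serial += 1
        top = Structure(atoms=fit_atoms + moiety_atoms)
        ref = top.coords
        frames = []
        for _ in range(n_frames):
            f = ref.copy()
            i = 4
            for name, sig, count in sig_by_group:
                for _j in range(count):
                    f[i] += rng.normal(0, sig, 3)
                    i += 1
            frames.append(f)
        return Trajectory(topology=top, frames=frames)

    def test_frozen_trajectory_zero_everywhere(self):
        traj = self._traj([("A", 0.0, 3), ("B", 0.0, 2)], n_frames=4)
        out = ia.moiety_rmsf(
            traj,
            Selection.make(chain="F"),
            {
                "a": Selection.make(atom_names=["A0", "A1", "A2"]),
                "b": Selection.make(atom_names=["B0", "B1"]),
            },
        )
        assert out["a"] == pytest.approx(0.0, abs=1e-12)
        assert out["b"] == pytest.approx(0.0, abs=1e-12)

    def test_group_means_ordered_by_planted_noise(self):
        traj = self._traj([("A", 0.2, 5), ("B", 0.6, 5)], seed=9)
        out = ia.moiety_rmsf(
            traj,
            Selection.make(chain="F"),
            {
                "quiet": Selection.make(atom_names=[f"A{j}" for j in range(5)]),
                "loud": Selection.make(atom_names=[f"B{j}" for j in range(5)]),
            },
        )
        assert out["quiet"] < out["loud"]

    def test_single_atom_moiety_equals_atom_rmsf(self):
        traj = self._traj([("A", 0.3, 1)], seed=2)
        fit = Selection.make(chain="F")
        single = Selection.make(atom_names=["A0"])
        from bindsight.geometry import rmsf_per_atom

        assert ia.moiety_rmsf(traj, fit, {"one": single})["one"] == pytest.approx(
            float(rmsf_per_atom(traj, fit, single)[0])
        )

    def test_empty_group_rejected(self):
        traj = self._traj([("A", 0.1, 1)], n_frames=3)
        with pytest.raises(ValueError):
            ia.moiety_rmsf(
                traj, Selection.make(chain="F"), {"none": Selection.make(chain="Q")}
            )


REF_SEL = Selection.make(resnames=["REF"])
SOL_SEL = Selection.make(resnames=["SOL"])


class TestRdf:
    def test_ideal_gas_is_flat_at_unity(self):
        traj = syn.make_ideal_gas_box(5000, (30, 30, 30), n_frames=50, seed=10)
        rdf = ia.radial_distribution(traj, REF_SEL, SOL_SEL, r_max=12.0, dr=0.5)
        window = (rdf.r >= 4.0) & (rdf.r <= 10.0)
        assert np.all(np.abs(rdf.g[window] - 1.0) < 0.05)

    def test_exclusion_zone_has_zero_density(self):
        traj = syn.make_ideal_gas_box(
            2000, (30, 30, 30), n_frames=10, exclusion_radius=2.5, seed=11
        )
        rdf = ia.radial_distribution(traj, REF_SEL, SOL_SEL, r_max=10.0, dr=0.25)
        assert np.all(rdf.g[rdf.r < 2.4] == 0.0)

    def test_planted_shell_peak_position(self, rng):
        """Probes concentrated at 3 Å produce a g(r) maximum in that bin."""
        box = np.array([25.0, 25.0, 25.0])
        center = box / 2
        n_shell, n_bg = 300, 200
        atoms = [make_atom(1, "C1", "REF", "R", 1, center)]
        for i in range(n_shell + n_bg):
            atoms.append(make_atom(i + 2, "O", "SOL", "S", i + 2, center))
        top = Structure(atoms=atoms)
        frames = []
        for _ in range(20):
            u = rng.normal(size=(n_shell, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            shell = center + 3.0 * u
            bg = rng.uniform(0, box, size=(n_bg, 3))
            frames.append(np.vstack([center[None, :], shell, bg]))
        traj = Trajectory(topology=top, frames=frames, box=tuple(box))
        rdf = ia.radial_distribution(traj, REF_SEL, SOL_SEL, r_max=10.0, dr=0.4)
        assert abs(rdf.r[np.argmax(rdf.g)] - 3.0) <= 0.4

    def test_integral_counts_neighbors(self):
        """rho * integral g(r) 4 pi r^2 dr recovers the in-range probe count."""
        traj = syn.make_ideal_gas_box(4000, (30, 30, 30), n_frames=20, seed=12)
        r_max, dr = 10.0, 0.25
        rdf = ia.radial_distribution(traj, REF_SEL, SOL_SEL, r_max=r_max, dr=dr)
        rho = 4000 / 30.0**3
        integral = float(np.sum(rho * rdf.g * 4 * np.pi * rdf.r**2 * dr))
        expected = rho * 4.0 / 3.0 * np.pi * r_max**3
        assert integral == pytest.approx(expected, rel=0.05)

    def test_density_doubling_leaves_g_unchanged(self):
        lo = syn.make_ideal_gas_box(1500, (30, 30, 30), n_frames=20, seed=13)
        hi = syn.make_ideal_gas_box(3000, (30, 30, 30), n_frames=20, seed=13)
        g_lo = ia.radial_distribution(lo, REF_SEL, SOL_SEL, 10.0, 0.5).g
        g_hi = ia.radial_distribution(hi, REF_SEL, SOL_SEL, 10.0, 0.5).g
        window = slice(8, None)  # beyond tiny-r sampling noise
        assert np.allclose(g_lo[window], g_hi[window], atol=0.12)

    def test_missing_box_rejected(self):
        traj = syn.make_ideal_gas_box(200, (20, 20, 20), n_frames=2, seed=1)
        traj.box = None
        with pytest.raises(ValueError):
            ia.radial_distribution(traj, REF_SEL, SOL_SEL, 8.0, 0.5)
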