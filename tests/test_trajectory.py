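"""Trajectory primitives: I/O round trips, Kabsch superposition, RMSD/RMSF/SSR."""

import numpy as np
import pytest

from krasdyn.trajectory import (
    DegenerateFitError,
    ResidueRegionMap,
    TrajectoryFormatError,
    read_trajectory,
    rmsd_series,
    rmsf_profile,
    ssr_from_profile,
    superpose,
    write_trajectory,
)

from conftest import make_ensemble, make_structure, random_rotation


class TestRegionMap:
    def test_default_regions_are_the_conventional_kras_bounds(self):
        m = ResidueRegionMap()
        assert m.regions["p_loop"] == (10, 17)
        assert m.regions["switch1"] == (30, 38)
        assert m.regions["switch2"] == (59, 76)
        assert m.regions["allosteric_lobe"] == (87, 166)

    def test_switch_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ResidueRegionMap({"switch1": (30, 40), "switch2": (38, 60)})

    def test_mask_is_union_of_named_intervals(self):
        m = ResidueRegionMap()
        ids = np.arange(1, 170)
        mask = m.mask(ids, ["switch1", "switch2"])
        assert mask.sum() == 9 + 18
        assert mask[29] and mask[37] and not mask[38]


class TestIO:
    def test_multimodel_pdb_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        ens = make_ensemble(rng.normal(size=(3, 5, 3)) * 10)
        path = tmp_path / "t.pdb"
        write_trajectory(ens, path, "pdb_multimodel")
        back = read_trajectory(path, "pdb_multimodel")
        assert back.n_frames == 3 and back.n_residues == 5
        # PDB stores 3 decimals
        assert np.allclose(back.coords, ens.coords, atol=5e-4)

    def test_frames_table_round_trip_is_bit_identical(self, tmp_path):
        rng = np.random.default_rng(1)
        ens = make_ensemble(rng.normal(size=(2, 4, 3)))
        path = tmp_path / "t.csv"
        write_trajectory(ens, path, "frames_table")
        back = read_trajectory(path, "frames_table")
        assert np.array_equal(back.coords, ens.coords)
        # and a second round trip produces identical bytes
        path2 = tmp_path / "t2.csv"
        write_trajectory(back, path2, "frames_table")
        assert path.read_bytes() == path2.read_bytes()

    def test_missing_residue_in_model_names_the_model(self, tmp_path):
        rng = np.random.default_rng(2)
        ens = make_ensemble(rng.normal(size=(3, 5, 3)))
        path = tmp_path / "bad.pdb"
        text = []
        for f in range(3):
            text.append(f"MODEL     {f + 1}")
            for i in range(5):
                if f == 1 and i == 4:
                    continue  # model 2 loses residue 5
                x, y, z = ens.coords[f, i]
                text.append(
                    f"ATOM  {i + 1:>5d}  CA  ALA A{i + 1:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
                )
            text.append("ENDMDL")
        path.write_text("\n".join(text) + "\nEND\n")
        with pytest.raises(TrajectoryFormatError, match="model 2"):
            read_trajectory(path, "pdb_multimodel")

    def test_empty_frames_table_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(TrajectoryFormatError, match="empty"):
            read_trajectory(path, "frames_table")


class TestSuperpose:
    regions = ResidueRegionMap({"tail": (4, 4)})

    def test_identity_when_already_aligned(self):
        ref = make_structure([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)])
        ens = make_ensemble(np.repeat(ref.coords[None], 2, axis=0))
        out = superpose(ens, ref, exclude_regions=(), region_map=self.regions)
        assert np.allclose(out.coords, ens.coords, atol=1e-12)

    def test_recovers_rigid_rototranslation(self):
        rng = np.random.default_rng(3)
        ref = make_structure(rng.normal(size=(6, 3)) * 5)
        Rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)  # 90° about z
        moved = ref.coords @ Rz.T + np.array([5.0, 0.0, 0.0])
        ens = make_ensemble(np.repeat(moved[None], 2, axis=0))
        out = superpose(ens, ref, exclude_regions=(), region_map=self.regions)
        rmsd = np.sqrt(np.mean(np.sum((out.coords[0] - ref.coords) ** 2, axis=1)))
        assert rmsd <= 1e-8

    def test_excluded_residue_keeps_its_displacement(self):
        # Hand-derived: fit set (residues 1-3) identical → identity transform,
        # residue 4 keeps its +0.4 Å x displacement.
        ref = make_structure([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)])
        mobile = ref.coords.copy()
        mobile[3, 0] += 0.4
        ens = make_ensemble(np.repeat(mobile[None], 2, axis=0))
        out = superpose(ens, ref, exclude_regions=("tail",), region_map=self.regions)
        fit_rmsd = np.sqrt(np.mean(np.sum((out.coords[0, :3] - ref.coords[:3]) ** 2, axis=1)))
        assert fit_rmsd <= 1e-10
        assert np.isclose(np.linalg.norm(out.coords[0, 3] - ref.coords[3]), 0.4)

    def test_idempotence(self):
        rng = np.random.default_rng(4)
        ref = make_structure(rng.normal(size=(8, 3)) * 4)
        ens = make_ensemble(rng.normal(size=(3, 8, 3)) * 4)
        regions = ResidueRegionMap({"none": (100, 100)})
        once = superpose(ens, ref, (), regions)
        twice = superpose(once, ref, (), regions)
        assert np.allclose(once.coords, twice.coords, atol=1e-9)

    def test_too_few_fit_residues_raises(self):
        ref = make_structure([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)])
        ens = make_ensemble(np.repeat(ref.coords[None], 2, axis=0))
        wide = ResidueRegionMap({"most": (1, 2)})
        with pytest.raises(DegenerateFitError):
            superpose(ens, ref, exclude_regions=("most",), region_map=wide)


class TestRMSD:
    def test_zero_for_identical_frames(self):
        ref = make_structure(np.arange(27, dtype=float).reshape(9, 3))
        ens = make_ensemble(np.repeat(ref.coords[None], 3, axis=0))
        assert np.allclose(rmsd_series(ens, ref), 0.0)

    def test_single_displaced_residue_among_nine(self):
        ref = make_structure(np.zeros((9, 3)))
        frames = np.zeros((2, 9, 3))
        frames[1, 0, 0] = 3.0  # 3 Å on one of nine residues → RMSD = 1
        ens = make_ensemble(frames)
        out = rmsd_series(ens, ref)
        assert np.allclose(out, [0.0, 1.0])

    def test_follows_frame_order(self):
        ref = make_structure(np.zeros((4, 3)))
        frames = np.zeros((3, 4, 3))
        frames[0, 0, 0] = 2.0
        frames[2, 0, 0] = 4.0
        ens = make_ensemble(frames)
        fwd = rmsd_series(ens, ref)
        rev = rmsd_series(make_ensemble(frames[::-1]), ref)
        assert np.allclose(fwd, rev[::-1])

    def test_empty_selection_rejected(self):
        ref = make_structure(np.zeros((4, 3)))
        ens = make_ensemble(np.zeros((2, 4, 3)))
        with pytest.raises(ValueError, match="selection"):
            rmsd_series(ens, ref, selection=np.zeros(4, dtype=bool))

    def test_invariant_under_joint_rototranslation(self):
        rng = np.random.default_rng(5)
        ref = make_structure(rng.normal(size=(6, 3)))
        frames = rng.normal(size=(4, 6, 3))
        ens = make_ensemble(frames)
        base = rmsd_series(ens, ref)
        R = random_rotation(rng)
        t = np.array([1.0, -2.0, 3.0])
        moved = rmsd_series(
            make_ensemble(frames @ R.T + t),
            make_structure(ref.coords @ R.T + t),
        )
        assert np.allclose(base, moved, atol=1e-8)


class TestRMSF:
    def test_static_trajectory_gives_zero_profile(self):
        frames = np.repeat(np.arange(12, dtype=float).reshape(1, 4, 3), 5, axis=0)
        prof = rmsf_profile([make_ensemble(frames)])
        assert np.allclose(prof.rmsf, 0.0)

    def test_alternating_displacement_closed_form(self):
        d = 0.7
        frames = np.zeros((2, 3, 3))
        frames[0, 1, 0] = +d
        frames[1, 1, 0] = -d
        prof = rmsf_profile([make_ensemble(frames)])
        assert np.allclose(prof.rmsf, [0.0, d, 0.0])

    def test_iid_gaussian_noise_gives_sigma_sqrt3(self):
        sigma = 0.5
        rng = np.random.default_rng(6)
        frames = sigma * rng.standard_normal((10_000, 5, 3))
        prof = rmsf_profile([make_ensemble(frames)])
        assert np.allclose(prof.rmsf, sigma * np.sqrt(3), rtol=0.02)

    def test_replicate_average_is_arithmetic_mean(self):
        d1, d2 = 0.4, 0.8
        def alt(d):
            f = np.zeros((2, 2, 3))
            f[0, 0, 0], f[1, 0, 0] = d, -d
            return make_ensemble(f)
        prof = rmsf_profile([alt(d1), alt(d2)])
        assert np.isclose(prof.rmsf[0], (d1 + d2) / 2)
        assert prof.replicate_averaged

    def test_no_replicates_rejected(self):
        with pytest.raises(ValueError):
            rmsf_profile([])

    def test_single_frame_ensemble_cannot_exist(self):
        with pytest.raises(ValueError, match="2 frames"):
            make_ensemble(np.zeros((1, 3, 3)))


class TestSSR:
    def _prof(self, values):
        from krasdyn.trajectory import FlexibilityProfile

        values = np.asarray(values, dtype=float)
        return FlexibilityProfile(np.arange(1, len(values) + 1), values)

    def test_identical_profiles_give_zero(self):
        p = self._prof([0.5, 1.0, 1.5])
        assert ssr_from_profile(p, p) == 0.0

    def test_uniform_offset_closed_form(self):
        # 169 residues each differing by 0.1 Å → SSR = 169 × 0.01 = 1.69 Å²
        a = self._prof(np.ones(169))
        b = self._prof(np.ones(169) + 0.1)
        assert np.isclose(ssr_from_profile(a, b), 1.69)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = self._prof(rng.random(20))
        b = self._prof(rng.random(20))
        assert np.isclose(ssr_from_profile(a, b), ssr_from_profile(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            ssr_from_profile(self._prof([1.0, 2.0]), self._prof([1.0]))
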