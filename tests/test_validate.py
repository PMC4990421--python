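"""Quality metrics: correlations, FSC/iFSC, RMSF, B-factors, binning, reports."""

import json
import math

import numpy as np
import pytest

from mapfit import density_maps as dm
from mapfit.md_engine import KB, SimConfig, Trajectory, run_dynamics
from mapfit.structures import Structure, build_topology, read_structure
from mapfit.synthetic import make_halfmaps, make_localres_map
from mapfit.validate import (BFACTOR_PER_RMSF2, FSCCurve, RMSFProfile,
                             ValidationReport, bfactor_from_rmsf,
                             bin_rmsf_by_local_resolution, fsc, gcc,
                             halfmap_crossvalidate, integrated_fsc, lcc,
                             rmsf_profile, sharpen_scan, write_bfactors_to_pdb,
                             write_report)


class TestGCC:
    def test_self_consistency(self, toy_map, toy_structure):
        assert gcc(toy_map, toy_structure, 3.0) >= 0.99

    def test_displaced_model_has_no_overlap(self, toy_map, toy_structure):
        far = toy_structure.with_positions(toy_structure.xyz + 300.0)
        assert abs(gcc(toy_map, far, 3.0)) <= 0.05

    def test_affine_invariance_of_map_values(self, toy_map, toy_structure):
        scaled = toy_map.copy(toy_map.values * 4.2)
        assert gcc(scaled, toy_structure, 3.0) == pytest.approx(
            gcc(toy_map, toy_structure, 3.0), abs=1e-9)

    def test_negated_map_anticorrelates(self, toy_map, toy_structure):
        """Rendering against the sign-flipped map gives correlation near -1."""
        flipped = toy_map.copy(toy_map.values.max() - toy_map.values)
        assert gcc(flipped, toy_structure, 3.0) < -0.9


class TestLCC:
    def test_self_consistency_per_residue(self, toy_map, toy_structure):
        assert lcc(toy_map, toy_structure, 3.0, residue_id=5) >= 0.95

    def test_displaced_residue_scores_low(self, toy_map, toy_structure):
        moved = toy_structure.copy()
        sel = moved.res_index == 30
        moved.xyz[sel] += [0.0, 10.0, 0.0]
        assert lcc(toy_map, moved, 3.0, residue_id=30) < 0.3

    def test_lcc_distribution_consistent_with_gcc(self, toy_map, toy_structure):
        g = gcc(toy_map, toy_structure, 3.0)
        vals = [lcc(toy_map, toy_structure, 3.0, r) for r in (1, 20, 64, 100, 124)]
        assert min(vals) > g - 0.1

    def test_missing_residue_rejected(self, toy_map, toy_structure):
        with pytest.raises(ValueError):
            lcc(toy_map, toy_structure, 3.0, residue_id=9999)


class TestFSC:
    def test_self_correlation_is_one(self, toy_map):
        curve = fsc(toy_map, toy_map)
        assert np.all(curve.correlation > 0.999)

    def test_independent_noise_has_null_correlation(self, rng):
        shape = (32, 32, 32)
        m1 = dm.DensityMap([0, 0, 0], [1, 1, 1], rng.normal(size=shape))
        m2 = dm.DensityMap([0, 0, 0], [1, 1, 1], rng.normal(size=shape))
        curve = fsc(m1, m2)
        idx, centers = dm.fourier_shells(shape, np.ones(3))
        counts = np.bincount(idx.ravel(), minlength=centers.size)
        high = curve.freq > 0.25
        bound = 3.0 / np.sqrt(counts[np.isin(centers, curve.freq[high])])
        assert np.all(np.abs(curve.correlation[high]) < np.maximum(bound, 0.2))

    def test_one_voxel_shift_matches_phase_ramp(self, toy_map):
        """FSC of a map against its shifted copy follows <cos(2 pi f_x dx)>."""
        shifted = toy_map.copy(np.roll(toy_map.values, 1, axis=0))
        curve = fsc(toy_map, shifted)
        # independent prediction: amplitude-weighted shell mean of the phase ramp
        F = np.abs(np.fft.rfftn(toy_map.values)) ** 2
        fx = np.fft.fftfreq(toy_map.dims[0], d=toy_map.voxel[0])
        ramp = np.cos(2 * np.pi * fx * toy_map.voxel[0])[:, None, None]
        idx, centers = dm.fourier_shells(toy_map.dims, toy_map.voxel)
        num = np.bincount(idx.ravel(), weights=(F * ramp).ravel(),
                          minlength=centers.size)
        den = np.bincount(idx.ravel(), weights=F.ravel(), minlength=centers.size)
        with np.errstate(invalid="ignore"):
            predicted = num / den
        sel = (centers > 0) & (centers < 0.25) & np.isfinite(predicted)
        measured = np.interp(centers[sel], curve.freq, curve.correlation)
        np.testing.assert_allclose(measured, predicted[sel], atol=0.02)

    def test_grid_mismatch_rejected(self, toy_map):
        other = dm.DensityMap([0, 0, 0], [1, 1, 1], np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            fsc(toy_map, other)


class TestIntegratedFSC:
    def test_perfect_curve_gives_range_width(self):
        curve = FSCCurve(np.linspace(0.05, 0.4, 80), np.ones(80))
        assert integrated_fsc(curve, 5.0, 10.0) == pytest.approx(5.0, abs=1e-9)

    def test_zero_curve_gives_zero(self):
        curve = FSCCurve(np.linspace(0.05, 0.4, 80), np.zeros(80))
        assert integrated_fsc(curve, 5.0, 10.0) == 0.0

    def test_half_curve_linearity(self):
        curve = FSCCurve(np.linspace(0.05, 0.4, 80), np.full(80, 0.5))
        assert integrated_fsc(curve, 3.4, 10.0) == pytest.approx(3.3, abs=1e-9)

    def test_monotone_in_the_curve(self, rng):
        freq = np.linspace(0.05, 0.4, 50)
        lo = rng.uniform(0.0, 0.8, size=50)
        hi = lo + rng.uniform(0.0, 0.2, size=50)
        a = integrated_fsc(FSCCurve(freq, lo), 4.0, 12.0)
        b = integrated_fsc(FSCCurve(freq, hi), 4.0, 12.0)
        assert b >= a

    def test_out_of_support_rejected(self):
        curve = FSCCurve(np.linspace(0.05, 0.4, 80), np.ones(80))
        with pytest.raises(ValueError):
            integrated_fsc(curve, 1.0, 10.0)


class TestHalfmapCrossvalidation:
    def test_identical_halfmaps_give_equal_ifsc(self, toy_structure):
        h1, h2 = make_halfmaps(toy_structure, 3.0, 1.0, noise_sd=0.0, seed=0)
        table = halfmap_crossvalidate(toy_structure, h1, h2, 3.0)
        assert table["overfit"].abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_null_fit_shows_no_overfitting(self, toy_structure):
        """A model fitted to signal scores both half-maps alike."""
        h1, h2 = make_halfmaps(toy_structure, 3.0, 1.0, noise_sd=0.05, seed=2)
        table = halfmap_crossvalidate(toy_structure, h1, h2, 3.0)
        assert table["overfit"].abs().max() < 0.2

    def test_noise_fit_positive_control(self, toy_structure, toy_map):
        """A model chasing half-map-1 noise scores the held-out map much worse."""
        signal = toy_map
        rng1 = np.random.default_rng(101)
        rng2 = np.random.default_rng(202)
        # correlated (blob-scale) noise fields that the model can genuinely fit
        def blobs(rng):
            white = dm.DensityMap(signal.origin, signal.voxel,
                                  rng.normal(size=signal.dims))
            return dm.gaussian_blur(white, 2.0).values

        n1, n2 = blobs(rng1), blobs(rng2)
        h1 = signal.copy(signal.values * 0.3 + n1)
        h2 = signal.copy(signal.values * 0.3 + n2)
        # couple the model strongly to half-map 1's noise field ALONE
        noise_map = signal.copy(np.maximum(n1, 0.0))
        thr = dm.positive_percentile_threshold(noise_map.values, 50.0)
        pot = dm.potential_from_map(noise_map, 5.0, thr)
        topo = build_topology(toy_structure)
        cfg = SimConfig(seed=3, n_steps=4000, zeta=5.0)
        traj = run_dynamics(toy_structure, topo, None, pot, cfg)
        noise_model = toy_structure.with_positions(traj.frames[-1])
        table = halfmap_crossvalidate(noise_model, h1, h2, 3.0,
                                      d_ranges=((4.0, 10.0),))
        row = table.iloc[0]
        # far above the null fixture's < 0.2 A band, and direct >> cross
        assert row["overfit"] > 0.4
        assert row["ifsc_direct"] > 2.0 * row["ifsc_cross"]

    def test_grid_mismatch_rejected(self, toy_structure, toy_map):
        small = dm.DensityMap([0, 0, 0], [1, 1, 1], np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            halfmap_crossvalidate(toy_structure, toy_map, small, 3.0)


class TestRMSF:
    def test_frozen_trajectory_is_zero(self, toy_structure):
        frames = np.repeat(toy_structure.xyz[None], 10, axis=0)
        traj = Trajectory(frames, np.arange(10.0), [None] * 10)
        prof = rmsf_profile(traj, window=1.0)
        assert np.all(prof.rmsf < 1e-12)
        assert prof.overall < 1e-12

    def test_two_frame_symmetric_displacement(self):
        base = np.zeros((1, 3))
        frames = np.stack([base + [0.7, 0, 0], base - [0.7, 0, 0]])
        traj = Trajectory(frames, np.array([0.0, 1.0]), [None, None])
        prof = rmsf_profile(traj, window=1.0)
        assert prof.rmsf[0] == pytest.approx(0.7, abs=1e-12)

    def test_harmonic_bead_equipartition(self):
        """RMSF^2 of a thermal bond matches kB T / (2 k) per the radial mode."""
        chain = Structure.from_xyz([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0],
                                    [3.8, 3.8, 3.8]])
        topo = build_topology(chain)
        cfg = SimConfig(timestep=5.0, friction=2.0, temperature=300.0, seed=21,
                        n_steps=50_000, stride=10)
        traj = run_dynamics(chain, topo, config=cfg)
        d = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1)
        var = np.var(d[len(d) // 5:])
        assert var == pytest.approx(KB * 300.0 / (2 * topo.params.bond_k), rel=0.10)

    def test_short_window_rejected(self, toy_structure):
        frames = toy_structure.xyz[None]
        traj = Trajectory(frames, np.array([0.0]), [None])
        with pytest.raises(ValueError):
            rmsf_profile(traj)


class TestBFactors:
    def test_unit_rmsf_constant(self):
        prof = RMSFProfile(np.array([1.0]), np.array([1]), 2)
        assert bfactor_from_rmsf(prof)[0] == pytest.approx(26.319, abs=5e-4)

    def test_quadratic_scaling(self):
        prof = RMSFProfile(np.array([0.0, 1.0, math.sqrt(1.73)]), np.arange(3), 2)
        b = bfactor_from_rmsf(prof)
        assert b[0] == 0.0
        assert b[2] == pytest.approx(BFACTOR_PER_RMSF2 * 1.73, rel=1e-12)
        assert b[2] == pytest.approx(45.53, abs=0.01)

    def test_written_to_pdb_column(self, tmp_path, toy_structure):
        b = np.linspace(10, 90, toy_structure.n_beads)
        path = tmp_path / "b.pdb"
        write_bfactors_to_pdb(toy_structure, b, path)
        back = read_structure(path)
        np.testing.assert_allclose(back.b_factor, b, atol=1e-2)

    def test_overflow_clipped_with_warning(self, tmp_path, toy_structure):
        b = np.full(toy_structure.n_beads, 5000.0)
        path = tmp_path / "clip.pdb"
        with pytest.warns(UserWarning):
            write_bfactors_to_pdb(toy_structure, b, path)
        back = read_structure(path)
        assert back.b_factor.max() <= 999.99


class TestSharpenScan:
    def test_single_value_returned(self, fitting_fixture):
        cfg = SimConfig(seed=2, n_steps=400)
        table, argmin = sharpen_scan(fitting_fixture["target"],
                                     fitting_fixture["map"], [-40.0], cfg)
        assert argmin == -40.0
        assert len(table) == 1

    def test_blur_equivalent_optimum(self, fitting_fixture):
        """Blurring by sigma* shifts the RMSF minimum to about -8 pi^2 sigma*^2.

        The bead rendering width sets an intrinsic deconvolution scale of
        8 pi^2 s_b^2 (about 130 A^2), so the scan uses a grid step of the same
        order -- the optimum cannot be localized more finely on a bead-level
        map.
        """
        sigma_star = 2.5
        degraded = dm.gaussian_blur(fitting_fixture["map"], sigma_star)
        b_opt = -8 * math.pi**2 * sigma_star**2      # about -493 A^2
        step = 125.0
        b_grid = list(np.arange(b_opt - 3 * step, b_opt + 3 * step + 1, step))
        cfg = SimConfig(seed=6, n_steps=3000, stride=10)
        table, argmin = sharpen_scan(fitting_fixture["target"], degraded, b_grid, cfg)
        assert abs(argmin - b_opt) <= step + 1e-9
        # parabolic trend: extremes exceed the minimum
        rmsfs = table["rmsf"].to_numpy()
        assert rmsfs[0] > rmsfs.min() and rmsfs[-1] > rmsfs.min()
        # the Guinier estimate names the same optimum
        b_guinier = dm.guinier_bfactor(degraded, 4.0, 10.0) - dm.guinier_bfactor(
            fitting_fixture["map"], 4.0, 10.0)
        assert abs(argmin + b_guinier) <= step + 1e-9


@pytest.fixture(scope="module")
def two_zone(toy_structure):
    density, localres = make_localres_map(toy_structure, 3.0, 9.0, 1.0)
    topo = build_topology(toy_structure)
    thr = dm.positive_percentile_threshold(density.values)
    pot = dm.potential_from_map(density, 0.3, thr)
    cfg = SimConfig(seed=8, n_steps=3000, stride=5)
    traj = run_dynamics(toy_structure, topo, None, pot, cfg)
    prof = rmsf_profile(traj, template=toy_structure)
    return density, localres, prof


class TestLocalResolutionBinning:

    def test_periphery_fluctuates_more_than_core(self, toy_structure, two_zone):
        _, localres, prof = two_zone
        table, slope, r2 = bin_rmsf_by_local_resolution(prof, localres,
                                                        toy_structure,
                                                        min_population=10,
                                                        bin_width=1.0)
        kept = table[table["population"] >= 10]
        assert kept["mean_rmsf"].iloc[-1] > kept["mean_rmsf"].iloc[0]
        assert slope > 0

    def test_populations_sum_to_bead_count(self, toy_structure, two_zone):
        _, localres, prof = two_zone
        table, _, _ = bin_rmsf_by_local_resolution(prof, localres, toy_structure,
                                                   min_population=1, bin_width=1.0)
        assert table["population"].sum() == toy_structure.n_beads

    def test_uniform_volume_is_degenerate(self, toy_structure, two_zone):
        _, _, prof = two_zone
        uniform = dm.render_map(toy_structure, 3.0, 2.0, pad=6.0)
        uniform = uniform.copy(np.full(uniform.dims, 4.0))
        table, slope, r2 = bin_rmsf_by_local_resolution(prof, uniform,
                                                        toy_structure,
                                                        min_population=10)
        assert slope is None and r2 is None
        assert len(table) == 1


class TestReports:
    def test_report_round_trip(self, tmp_path):
        rep = ValidationReport(gcc=0.87, ifsc=[{"d_min": 5, "d_max": 10,
                                                "value": 4.2}],
                               rmsf_overall=0.9,
                               bfactors=np.array([1.0, 2.0]),
                               metadata={"seed": 3})
        path = tmp_path / "report.json"
        write_report(rep, path)
        data = json.loads(path.read_text())
        assert data["gcc"] == 0.87
        assert data["bfactors"] == [1.0, 2.0]
        assert data["metadata"]["seed"] == 3
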