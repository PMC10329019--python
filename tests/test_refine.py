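"""Alignment, symmetrized averaging, exclusion, iterative refinement."""

import numpy as np
import pytest

from memsta.geometry import Orientation, angular_difference, cn_rotations, compose
from memsta.particles import ParticleRecord
from memsta.refine import (
    RefinementConfig,
    SubtomogramRefiner,
    align_to_reference,
    average_with_symmetry,
    exclude_worst,
    global_orientation_grid,
    local_orientation_grid,
    refine_iterate,
    symmetrize,
)
from memsta.simulate import DatasetSpec, PhantomSpec, build_phantom, simulate_dataset
from memsta.volume import DensityMap, normalized_cc, rotate_map

from conftest import BOX, PIXEL


def small_grid():
    # 13 well-separated orientations: identity + axis tilts + in-plane spins
    grid = [Orientation.identity()]
    for ax in ([1, 0, 0], [0, 1, 0]):
        for ang in (8.0, -8.0):
            grid.append(Orientation.from_axis_angle(ax, ang))
    for spin in (4.0, 8.0, 12.0, 16.0, -4.0, -8.0, -12.0, -16.0):
        grid.append(Orientation.from_axis_angle([0, 0, 1], spin))
    return grid


class TestAlign:
    def test_self_alignment(self, phantom):
        o, shift, score = align_to_reference(phantom, phantom, grid=small_grid())
        assert o == Orientation.identity()
        assert score >= 0.999

    def test_planted_grid_rotation_recovered(self, phantom):
        grid = small_grid()
        planted = grid[3]
        vol = rotate_map(phantom, planted)
        o, _, _ = align_to_reference(vol, phantom, grid=grid, n_sym=15)
        assert angular_difference(o, planted, "full", 15) < 1e-6

    def test_agreement_with_brute_force_oracle(self, phantom, rng):
        # independent oracle: naive loop of rotate + NCC over the same grid
        grid = small_grid()
        for case in range(20):
            planted = grid[int(rng.integers(len(grid)))]
            vol = DensityMap(
                rotate_map(phantom, planted).grid + rng.normal(0, 0.3, phantom.shape),
                PIXEL,
            )
            best_naive, best_score = None, -np.inf
            for cand in grid:
                s = normalized_cc(vol.grid, rotate_map(phantom, cand).grid)
                if s > best_score:
                    best_naive, best_score = cand, s
            o, _, score = align_to_reference(vol, phantom, grid=grid)
            assert o == best_naive
            assert score == pytest.approx(best_score, abs=1e-4)

    def test_empty_grid_rejected(self, phantom):
        with pytest.raises(ValueError):
            align_to_reference(phantom, phantom, grid=[])

    def test_local_mode_recovers_perturbation(self, phantom):
        delta = Orientation.from_axis_angle([1, 0, 0], 4.0)
        start = Orientation.from_axis_angle([0.2, 0.5, 1.0], 30.0)
        vol = rotate_map(phantom, compose(start, delta))
        o, _, _ = align_to_reference(
            vol, phantom, mode="local", start=start, max_step=6.0, step=2.0
        )
        assert angular_difference(o, compose(start, delta), "full", 1) <= 2.1

    def test_translation_search_finds_shift(self, phantom):
        shifted = DensityMap(np.roll(phantom.grid, (0, 2, -1), axis=(0, 1, 2)), PIXEL)
        o, shift, score = align_to_reference(
            shifted, phantom, grid=[Orientation.identity()], translation_search=3
        )
        # shift returned as (x, y, z)
        assert tuple(shift) == (-1.0, 2.0, 0.0)
        assert score > 0.999

    def test_true_orientation_beats_neighbors_noiseless(self, phantom):
        planted = Orientation.from_axis_angle([0, 1, 0], 8.0)
        vol = rotate_map(phantom, planted)
        grid = small_grid()
        scores = {}
        for cand in grid:
            s = normalized_cc(vol.grid, rotate_map(phantom, cand).grid)
            scores[cand] = s
        assert max(scores, key=scores.get) == planted


class TestAveraging:
    def test_single_particle_identity_c1(self, phantom):
        rec = ParticleRecord(0, 0, np.zeros(3), Orientation.identity())
        avg = average_with_symmetry([phantom], [rec], n_sym=1)
        assert np.allclose(avg.grid, phantom.grid, atol=1e-12)

    def test_symmetrized_average_is_cn_invariant(self, phantom):
        sym = symmetrize(phantom, 15)
        rot = rotate_map(sym, Orientation.from_axis_angle([0, 0, 1], 24.0))
        assert normalized_cc(sym.grid, rot.grid) > 0.999

    def test_averaging_gives_sqrt_n_snr_gain(self, phantom, rng):
        sigma = phantom.grid.max()
        n = 100
        vols, recs = [], []
        single_corrs = []
        for i in range(n):
            noisy = DensityMap(phantom.grid + rng.normal(0, sigma, phantom.shape), PIXEL)
            vols.append(noisy)
            recs.append(ParticleRecord(i, 0, np.zeros(3), Orientation.identity()))
            single_corrs.append(normalized_cc(noisy.grid, phantom.grid))
        avg = average_with_symmetry(vols, recs, n_sym=1)
        rho_s = float(np.mean(single_corrs))
        rho_a = normalized_cc(avg.grid, phantom.grid)
        snr_gain = np.sqrt((rho_a**2 / (1 - rho_a**2)) / (rho_s**2 / (1 - rho_s**2)))
        assert snr_gain == pytest.approx(10.0, rel=0.3)

    def test_connector_diluted_by_symmetrization(self):
        # a connector occupying one symmetry unit is smeared over all 15
        # units by C15 averaging: peak connector density drops ~15-fold
        from memsta.relax import azimuth_occupancy_profile
        from memsta.simulate import connector_radius

        spec = PhantomSpec(connector_arc=24.0)
        m = build_phantom(spec, BOX, PIXEL)
        bare = build_phantom(PhantomSpec(connector_arc=0.0), BOX, PIXEL)
        sym = symmetrize(m, 15)
        zc = int(round((spec.gate_z + 5.0) / PIXEL))
        band = (zc - 2, zc + 2)
        args = (connector_radius(spec), 10.0, band)
        _, p1 = azimuth_occupancy_profile(m, *args)
        _, p15 = azimuth_occupancy_profile(sym, *args)
        _, pb = azimuth_occupancy_profile(bare, *args)
        dilution = (p15 - pb).max() / (p1 - pb).max()
        assert 1.0 / 20.0 < dilution < 1.0 / 10.0

    def test_all_excluded_rejected(self, phantom):
        rec = ParticleRecord(0, 0, np.zeros(3), Orientation.identity(), excluded=True)
        with pytest.raises(ValueError):
            average_with_symmetry([phantom], [rec], 1)


class TestExcludeWorst:
    @staticmethod
    def records_with_scores(scores):
        return [
            ParticleRecord(i, 0, np.zeros(3), Orientation.identity(), score=s)
            for i, s in enumerate(scores)
        ]

    def test_exact_fraction_removed(self, rng):
        recs = self.records_with_scores(rng.permutation(100).astype(float))
        out = exclude_worst(recs, 0.8)
        assert sum(not r.excluded for r in out) == 80
        dropped = {r.particle_id for r in out if r.excluded}
        worst20 = {r.particle_id for r in sorted(recs, key=lambda r: r.score)[:20]}
        assert dropped == worst20

    def test_keep_all(self):
        out = exclude_worst(self.records_with_scores([1.0, 2.0, 3.0]), 1.0)
        assert not any(r.excluded for r in out)

    def test_tie_break_by_particle_id(self):
        out = exclude_worst(self.records_with_scores([0.5] * 10), 0.8)
        assert {r.particle_id for r in out if r.excluded} == {0, 1}

    def test_previously_excluded_re_eligible(self):
        recs = self.records_with_scores([float(i) for i in range(10)])
        out1 = exclude_worst(recs, 0.8)
        for r in out1:
            r.score = float(10 - r.particle_id)  # reverse the ranking
        out2 = exclude_worst(out1, 0.8)
        assert {r.particle_id for r in out2 if r.excluded} == {8, 9}

    def test_unscored_rejected(self):
        with pytest.raises(ValueError):
            exclude_worst(self.records_with_scores([np.nan, 1.0]), 0.5)


class TestRefineIterate:
    def test_invalid_config(self):
        with pytest.raises(ValueError):
            RefinementConfig(n_iterations=0)
        with pytest.raises(ValueError):
            RefinementConfig(keep_fraction=0.0)

    def test_planted_noiseless_recovery(self, phantom_spec):
        # scaled-down version of the planted-recovery benchmark (40 particles
        # instead of 200 to stay inside the suite's runtime budget)
        ds = DatasetSpec(
            n_particles=40, membrane_attach="none", wedge=None, noise_sigma=0.0,
            azimuth_offsets=True, record_model="coarse", seed=7,
        )
        vols, recs, truth = simulate_dataset(phantom_spec, ds, BOX, PIXEL)
        for r in recs:
            r.orientation = Orientation.identity()
        ref = build_phantom(phantom_spec, BOX, PIXEL)
        cfg = RefinementConfig(
            n_sym=15, n_iterations=2, keep_fraction=1.0, wedge=None,
            polish=True, polish_range=2.25, polish_step=0.75,
        )
        out_map, out_recs, fsc, log = refine_iterate(vols, recs, cfg, initial_reference=ref)
        errs = [
            angular_difference(r.orientation, t.orientation, "full", 15)
            for r, t in zip(out_recs, truth)
        ]
        assert max(errs) <= 2.0  # within the local grid step
        assert normalized_cc(out_map.grid, ref.grid) > 0.99
        assert log["mean_score"][-1] >= log["mean_score"][0] - 1e-6

    def test_seeded_bit_reproducibility(self, phantom_spec):
        ds = DatasetSpec(n_particles=8, wedge=None, noise_sigma=0.1, seed=3)
        vols, recs, _ = simulate_dataset(phantom_spec, ds, BOX, PIXEL)
        cfg = RefinementConfig(
            n_sym=15, n_iterations=1, keep_fraction=1.0, search_mode="local", wedge=None
        )
        m1, r1, _, _ = refine_iterate(vols, recs, cfg)
        m2, r2, _, _ = refine_iterate(vols, recs, cfg)
        assert np.array_equal(m1.grid, m2.grid)
        assert all(a.orientation == b.orientation for a, b in zip(r1, r2))

    def test_estimator_interface(self, phantom_spec):
        ds = DatasetSpec(n_particles=6, wedge=None, noise_sigma=0.0, seed=2)
        vols, recs, _ = simulate_dataset(phantom_spec, ds, BOX, PIXEL)
        est = SubtomogramRefiner(
            n_sym=15, n_iterations=1, keep_fraction=1.0, search_mode="local", wedge=None
        )
        assert est.get_params()["n_sym"] == 15
        est.set_params(keep_fraction=0.9)
        est.fit(vols, recs)
        assert est.map_.shape == (BOX, BOX, BOX)
        assert len(est.records_) == 6
        assert np.isfinite(est.resolution_)
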