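"""Focused refinement, per-particle tilt readout, trajectory sectioning."""

import numpy as np
import pytest

from memsta.flexibility import FocusedRefiner, focused_refine, tilt_trajectory
from memsta.geometry import Orientation, angular_difference, cn_rotations, compose
from memsta.simulate import DatasetSpec, build_phantom, simulate_dataset
from memsta.volume import cylinder_mask, normalized_cc, rotate_map

from conftest import BOX, PIXEL


@pytest.fixture(scope="module")
def protein_mask(phantom_spec_module=None):
    return cylinder_mask(BOX, PIXEL, radius=85.0, z_min=-60.0, z_max=85.0, soft_width=2.0)


class TestFocusedRefine:
    def test_rigid_dataset_returns_global_orientations(self, phantom_spec, protein_mask):
        ds = DatasetSpec(n_particles=12, tilt_model="none", noise_sigma=0.0, wedge=None, seed=3)
        vols, recs, _ = simulate_dataset(phantom_spec, ds, BOX, PIXEL)
        ref = build_phantom(phantom_spec, BOX, PIXEL)
        foc = focused_refine(vols, recs, protein_mask, ref, max_step=6.0, step=0.5)
        for f, r in zip(foc, recs):
            assert angular_difference(r.orientation, f, "axis_only") < 0.5

    def test_planted_tilts_recovered_within_local_step(self, phantom_spec, protein_mask):
        ds = DatasetSpec(
            n_particles=20, tilt_model="uniform", tilt_amplitude=3.0,
            noise_sigma=0.0, wedge=None, seed=11,
        )
        vols, recs, truth = simulate_dataset(phantom_spec, ds, BOX, PIXEL)
        ref = build_phantom(phantom_spec, BOX, PIXEL)
        foc = focused_refine(vols, recs, protein_mask, ref, max_step=6.0, step=0.5)
        for f, r, t in zip(foc, recs, truth):
            recovered = angular_difference(r.orientation, f, "axis_only")
            assert abs(recovered - t.tilt_degrees) <= 0.5

    def test_whole_box_mask_reduces_to_plain_local_alignment(self, phantom_spec):
        from memsta.refine import align_to_reference
        from memsta.volume import Mask

        ds = DatasetSpec(
            n_particles=4, tilt_model="uniform", tilt_amplitude=2.0,
            noise_sigma=0.0, wedge=None, membrane_attach="none", seed=6,
        )
        vols, recs, _ = simulate_dataset(phantom_spec, ds, BOX, PIXEL)
        ref = build_phantom(phantom_spec, BOX, PIXEL)
        full_mask = Mask(np.ones((BOX,) * 3), PIXEL)
        foc = focused_refine(
            vols, recs, full_mask, ref, max_step=4.0, step=1.0, exact_polish=False
        )
        for v, r, f in zip(vols, recs, foc):
            o, _, _ = align_to_reference(
                v, ref, mode="local", start=r.orientation, max_step=4.0, step=1.0
            )
            # the two searches use differently laid-out 1° grids, so the
            # optima may sit on neighboring nodes
            assert angular_difference(f, o, "axis_only") <= 2.0

    def test_tiny_mask_rejected(self, phantom_spec):
        from memsta.volume import Mask

        ds = DatasetSpec(n_particles=1, seed=1)
        vols, recs, _ = simulate_dataset(phantom_spec, ds, BOX, PIXEL)
        ref = build_phantom(phantom_spec, BOX, PIXEL)
        tiny = np.zeros((BOX,) * 3)
        tiny[0, 0, 0] = 1.0
        with pytest.raises(ValueError):
            focused_refine(vols, recs, Mask(tiny, PIXEL), ref)


class TestTiltTrajectory:
    def test_all_zero_tilts(self):
        o = [Orientation.identity()] * 10
        tilts, classes, (ea, eb, sep) = tilt_trajectory(o, o, n_intervals=4)
        assert np.all(tilts == 0)
        populated = [c for c in classes if c.member_ids]
        assert len(populated) == 1
        assert sep == 0.0

    def test_uniform_tilts_fill_classes_evenly(self, rng):
        n, n_int = 500, 5
        tilt_values = rng.uniform(0.0, 5.0, size=n)
        glob = [Orientation.identity()] * n
        foc = [
            Orientation.from_axis_angle(
                [np.cos(a), np.sin(a), 0.0], t
            )
            for t, a in zip(tilt_values, rng.uniform(0, 2 * np.pi, n))
        ]
        _, classes, _ = tilt_trajectory(glob, foc, n_intervals=n_int)
        sizes = np.array([len(c.member_ids) for c in classes])
        expected = n / n_int
        se = np.sqrt(n * (1 / n_int) * (1 - 1 / n_int))
        assert np.all(np.abs(sizes - expected) <= 3 * se)

    def test_partition_property(self, rng):
        n = 100
        glob = [Orientation.identity()] * n
        foc = [
            Orientation.from_axis_angle([1, 0, 0], float(t))
            for t in rng.uniform(0, 4, size=n)
        ]
        _, classes, _ = tilt_trajectory(glob, foc, n_intervals=6)
        all_ids = sorted(i for c in classes for i in c.member_ids)
        assert all_ids == list(range(n))

    def test_tilt_invariant_under_cn_composition(self, rng):
        cn = cn_rotations(15)
        g = Orientation.from_axis_angle([0.3, 0.2, 0.9], 25.0)
        f = compose(g, Orientation.from_axis_angle([1, 0, 0], 2.5))
        t0 = angular_difference(g, f, "axis_only")
        for k in (1, 7, 14):
            assert angular_difference(compose(g, cn[k]), f, "axis_only") == pytest.approx(
                t0, abs=1e-7
            )

    def test_equal_population_scheme(self, rng):
        glob = [Orientation.identity()] * 90
        foc = [
            Orientation.from_axis_angle([0, 1, 0], float(t))
            for t in rng.uniform(0.1, 3.0, size=90)
        ]
        _, classes, _ = tilt_trajectory(glob, foc, n_intervals=3, scheme="equal_population")
        sizes = [len(c.member_ids) for c in classes]
        assert max(sizes) - min(sizes) <= 2

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tilt_trajectory([Orientation.identity()], [], n_intervals=2)


class TestEndpointConformations:
    def test_two_endpoint_class_averages_differ_by_planted_rotation(self, phantom_spec):
        # swing about a fixed particle-frame axis; in the membrane frame the
        # endpoint class averages are related by the planted rigid rotation
        amp = 2.86
        # membrane-free: the membrane does not swing with the protein, so the
        # rigid-rotation identity between endpoint averages holds for the
        # protein density only
        ds = DatasetSpec(
            n_particles=60, tilt_model="two_endpoint", tilt_amplitude=amp,
            tilt_mixing=0.5, tilt_axis_azimuth=90.0, noise_sigma=0.0,
            membrane_attach="none", wedge=None, seed=29,
        )
        vols, recs, truth = simulate_dataset(phantom_spec, ds, BOX, PIXEL)
        ref = build_phantom(phantom_spec, BOX, PIXEL)
        mask = cylinder_mask(BOX, PIXEL, radius=85.0, z_min=-60.0, z_max=85.0, soft_width=2.0)
        est = FocusedRefiner(
            protein_mask=mask, reference=ref, n_intervals=5, build_class_averages=False
        )
        est.fit(vols, recs)
        assert est.endpoint_separation_ == pytest.approx(amp, abs=0.3)

        # membrane-frame class averages (erected at the *global* orientations)
        from memsta.volume import DensityMap, rotate_grid

        planted = np.array([t.tilt_degrees for t in truth])
        acc_a = np.zeros((BOX,) * 3)
        acc_b = np.zeros((BOX,) * 3)
        for v, r, t in zip(vols, recs, truth):
            g = rotate_grid(v.grid, r.orientation.inverse())
            if t.tilt_degrees == 0:
                acc_a += g
            else:
                acc_b += g
        avg_a = DensityMap(acc_a / (planted == 0).sum(), PIXEL)
        avg_b = DensityMap(acc_b / (planted > 0).sum(), PIXEL)
        rotated_b = rotate_map(avg_b, Orientation.from_axis_angle([0, 1, 0], amp).inverse())
        from memsta.volume import null_resample_blur

        # equalize the extra resampling blur the rotation adds to B
        assert normalized_cc(rotated_b.grid, null_resample_blur(avg_a.grid)) > 0.98
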