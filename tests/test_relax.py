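"""Symmetry relaxation: unit assignment, C1 recovery, arc occupancy."""

import numpy as np
import pytest

from memsta.geometry import Orientation, angular_difference, cn_rotations
from memsta.relax import (
    SymmetryRelaxer,
    arc_occupancy,
    azimuth_occupancy_profile,
    relax_symmetry,
    seed_c1_reference,
)
from memsta.refine import symmetrize
from memsta.simulate import (
    DatasetSpec,
    PhantomSpec,
    build_phantom,
    connector_radius,
    simulate_dataset,
)
from memsta.volume import DensityMap, Mask, normalized_cc, rotate_map, soft_mask_from_binary, _physical_coords

from conftest import BOX, PIXEL


@pytest.fixture(scope="module")
def connector_spec():
    return PhantomSpec(connector_arc=100.0)


@pytest.fixture(scope="module")
def connector_mask(connector_spec):
    r0 = connector_radius(connector_spec)
    z, y, x = _physical_coords(BOX, PIXEL)
    r = np.hypot(x, y)
    binary = (
        (r > r0 - 15.0)
        & (r < r0 + 15.0)
        & (z > connector_spec.gate_z - 15.0)
        & (z < connector_spec.gate_z + 25.0)
    )
    return soft_mask_from_binary(np.broadcast_to(binary, (BOX,) * 3).copy(), PIXEL, 2.0)


@pytest.fixture(scope="module")
def rim_band(connector_spec):
    zc = int(round((connector_spec.gate_z + 5.0) / PIXEL))
    return dict(rim_radius=connector_radius(connector_spec), z_band=(zc - 2, zc + 2))


class TestRelaxSymmetry:
    def test_noiseless_assignment_is_perfect(self, connector_spec, connector_mask):
        # wedge-free: the planted unit is the forced argmax (the ±50° wedge
        # adds a separate, characterized azimuth ambiguity of ~10%)
        ds = DatasetSpec(
            n_particles=30, azimuth_offsets=True, noise_sigma=0.0, wedge=None, seed=19
        )
        vols, recs, truth = simulate_dataset(connector_spec, ds, BOX, PIXEL)
        ref = build_phantom(connector_spec, BOX, PIXEL)
        assignments, _ = relax_symmetry(vols, recs, ref, connector_mask, 15)
        assert all(a.unit_index == t.unit_index for a, t in zip(assignments, truth))

    def test_noisy_assignment_accuracy(self, connector_spec, connector_mask, snr05_sigma):
        ds = DatasetSpec(
            n_particles=200, azimuth_offsets=True, noise_sigma=snr05_sigma,
            wedge=None, seed=19,
        )
        vols, recs, truth = simulate_dataset(connector_spec, ds, BOX, PIXEL)
        ref = build_phantom(connector_spec, BOX, PIXEL)
        assignments, _ = relax_symmetry(vols, recs, ref, connector_mask, 15)
        acc = np.mean([a.unit_index == t.unit_index for a, t in zip(assignments, truth)])
        assert acc >= 0.95

    def test_axis_direction_untouched(self, connector_spec, connector_mask):
        ds = DatasetSpec(n_particles=10, azimuth_offsets=True, noise_sigma=0.2, seed=2)
        vols, recs, _ = simulate_dataset(connector_spec, ds, BOX, PIXEL)
        ref = build_phantom(connector_spec, BOX, PIXEL)
        assignments, _ = relax_symmetry(vols, recs, ref, connector_mask, 15)
        cn = cn_rotations(15)
        from memsta.geometry import compose

        for r, a in zip(recs, assignments):
            assigned = compose(r.orientation, cn[a.unit_index])
            assert angular_difference(r.orientation, assigned, "axis_only") < 1e-7

    def test_reference_rotation_equivariance(self, connector_spec, connector_mask):
        ds = DatasetSpec(n_particles=12, azimuth_offsets=True, noise_sigma=0.0, seed=8)
        vols, recs, _ = simulate_dataset(connector_spec, ds, BOX, PIXEL)
        ref = build_phantom(connector_spec, BOX, PIXEL)
        a0, _ = relax_symmetry(vols, recs, ref, connector_mask, 15)
        j = 4
        cn = cn_rotations(15)
        ref_rot = rotate_map(ref, cn[j])
        mask_rot = Mask(rotate_map(DensityMap(connector_mask.grid, PIXEL), cn[j]).grid, PIXEL)
        a_rot, _ = relax_symmetry(vols, recs, ref_rot, mask_rot, 15)
        # rotating the C1 reference by element j shifts every assignment by -j
        # (the particle now needs j fewer units to reach the reference frame)
        shifts = {(a.unit_index - b.unit_index) % 15 for a, b in zip(a0, a_rot)}
        assert shifts == {j}

    def test_forced_zero_assignment_reproduces_symmetrized_map(self, connector_spec):
        ds = DatasetSpec(n_particles=60, azimuth_offsets=True, noise_sigma=0.0, seed=14)
        vols, recs, _ = simulate_dataset(connector_spec, ds, BOX, PIXEL)
        from memsta.refine import average_with_symmetry

        c1_forced = average_with_symmetry(vols, recs, n_sym=1)  # all units k=0
        cn_map = average_with_symmetry(vols, recs, n_sym=15)
        assert normalized_cc(c1_forced.grid, cn_map.grid) > 0.99

    def test_empty_mask_rejected(self, connector_spec):
        ds = DatasetSpec(n_particles=2, seed=1)
        vols, recs, _ = simulate_dataset(connector_spec, ds, BOX, PIXEL)
        ref = build_phantom(connector_spec, BOX, PIXEL)
        with pytest.raises(ValueError):
            relax_symmetry(vols, recs, ref, Mask(np.zeros((BOX,) * 3), PIXEL), 15)

    def test_c1_average_shows_one_sided_connector(
        self, connector_spec, connector_mask, rim_band, snr05_sigma
    ):
        ds = DatasetSpec(
            n_particles=120, azimuth_offsets=True, noise_sigma=snr05_sigma, seed=21
        )
        vols, recs, _ = simulate_dataset(connector_spec, ds, BOX, PIXEL)
        ref = build_phantom(connector_spec, BOX, PIXEL)
        relaxer = SymmetryRelaxer(n_sym=15, c1_reference=ref, focus_mask=connector_mask)
        relaxer.fit(vols, recs)
        occ_c1 = arc_occupancy(relaxer.c1_map_, threshold=0.5, **rim_band)
        sym_map = symmetrize(relaxer.c1_map_, 15)
        _, p_cn = azimuth_occupancy_profile(
            sym_map, rim_band["rim_radius"], 10.0, rim_band["z_band"]
        )
        assert occ_c1 < 180.0
        # once symmetrized the connector forms a near-uniform ring: no
        # azimuth falls below half of the band maximum
        assert p_cn.min() / p_cn.max() > 0.5


class TestArcOccupancy:
    def test_full_ring(self, connector_spec, rim_band):
        # lobe-free so the rim band is azimuthally uniform
        full = PhantomSpec(connector_arc=360.0, lobe_amplitude=0.0)
        m = build_phantom(full, BOX, PIXEL)
        assert arc_occupancy(m, threshold=0.5, **rim_band) == 360.0

    def test_planted_arc_within_one_bin(self, connector_spec, rim_band):
        m = build_phantom(connector_spec, BOX, PIXEL)
        occ = arc_occupancy(m, threshold=0.5, bin_degrees=2.0, **rim_band)
        assert occ == pytest.approx(100.0, abs=2.0)

    def test_threshold_monotonicity(self, connector_spec, rim_band):
        m = build_phantom(connector_spec, BOX, PIXEL)
        occs = [arc_occupancy(m, threshold=t, **rim_band) for t in (0.3, 0.5, 0.7)]
        assert occs[0] >= occs[1] >= occs[2]

    def test_band_outside_grid(self, connector_spec):
        m = build_phantom(connector_spec, BOX, PIXEL)
        with pytest.raises(ValueError):
            arc_occupancy(m, rim_radius=400.0)


def test_seed_c1_reference_prefers_asymmetric_split(connector_spec, connector_mask):
    ds = DatasetSpec(n_particles=24, azimuth_offsets=False, noise_sigma=0.0, seed=3)
    vols, recs, _ = simulate_dataset(connector_spec, ds, BOX, PIXEL)
    seeded = seed_c1_reference(vols, recs, connector_mask, n_splits=4, seed=0)
    assert seeded.shape == (BOX, BOX, BOX)
    # with no planted offsets the connector is coherent: the seed must show it
    prof_mask = connector_mask.grid > 0.5
    assert seeded.grid[prof_mask].max() > 0.3
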