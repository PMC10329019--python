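"""Symmetry relaxation: recover C1 features from a Cn-symmetrized refinement.

A Cn refinement defines each particle's orientation only up to a symmetry
element, so any one-sided feature (here the membrane-connector arc) is
averaged around the axis and appears at ~1/n occupancy.  Relaxation keeps
each particle's symmetry-axis direction fixed and searches, for one
iteration, which of the n discrete symmetry units best matches a C1
reference under a focus mask; re-averaging at the assigned orientations
without symmetrization restores the asymmetric feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .geometry import Orientation, compose, cn_rotations
from .particles import ParticleRecord
from .volume import DensityMap, Mask, normalized_cc, rotate_grid

__all__ = [
    "UnitAssignment",
    "relax_symmetry",
    "arc_occupancy",
    "azimuth_occupancy_profile",
    "seed_c1_reference",
    "SymmetryRelaxer",
]


@dataclass
class UnitAssignment:
    particle_id: int
    unit_index: int
    score: float


def assignments_to_frame(assignments: list[UnitAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            particle_id=[a.particle_id for a in assignments],
            unit_index=[a.unit_index for a in assignments],
            score=[a.score for a in assignments],
        )
    )


def relax_symmetry(
    vols: list[DensityMap],
    records: list[ParticleRecord],
    c1_reference: DensityMap,
    focus_mask: Mask,
    n_sym: int,
    wedge=None,
) -> tuple[list[UnitAssignment], DensityMap]:
    """Assign each particle its best-fitting symmetry unit and re-average in C1.

    For each particle the n candidate orientations are its converged Cn
    orientation composed with each symmetry element; candidates are scored
    by mask-weighted normalized CC between the erected particle and the C1
    reference, with the reference and mask counter-rotated per unit.  The
    symmetry-axis direction of every particle is untouched by construction.
    """
    if focus_mask.grid.sum() <= 0:
        raise ValueError("focus mask is empty")
    if c1_reference.shape != vols[0].shape:
        raise ValueError("reference/volume shape mismatch")
    cn = cn_rotations(n_sym)
    # unit k means the particle's true orientation is record ∘ cn[k]; erecting
    # by record⁻¹ then shows the reference rotated by cn[k].
    from .volume import null_resample_blur

    ref_base = null_resample_blur(c1_reference.grid)  # match rotated units' blur
    mask_base = null_resample_blur(focus_mask.grid)
    refs = [rotate_grid(ref_base, c) for c in cn]
    masks = [rotate_grid(mask_base, c) for c in cn]

    assignments = []
    acc = np.zeros_like(vols[0].grid)
    n_avg = 0
    for v, r in zip(vols, records):
        erected = rotate_grid(v.grid, r.orientation.inverse())
        if wedge is not None:
            # the particle's missing wedge smears the connector azimuthally in
            # the erected frame; imprinting the same wedge on each candidate
            # keeps adjacent symmetry units separable
            from .simulate import rotated_wedge_mask

            wm = rotated_wedge_mask(v.shape[0], v.pixel_size, wedge, r.orientation)
            cands = [np.fft.ifftn(np.fft.fftn(ref_k) * wm).real for ref_k in refs]
        else:
            cands = refs
        scores = [normalized_cc(erected, cands[k], weights=masks[k]) for k in range(n_sym)]
        k_best = int(np.argmax(scores))
        assignments.append(UnitAssignment(r.particle_id, k_best, float(scores[k_best])))
        if not r.excluded:
            # erect at the assigned orientation: rotate by (record ∘ cn[k])⁻¹
            acc += rotate_grid(v.grid, compose(r.orientation, cn[k_best]).inverse())
            n_avg += 1
    if n_avg == 0:
        raise ValueError("all particles excluded")
    return assignments, DensityMap(acc / n_avg, vols[0].pixel_size)


def azimuth_occupancy_profile(
    m: DensityMap,
    rim_radius: float,
    radial_halfwidth: float = 10.0,
    z_band: tuple[int, int] = (-6, 0),
    bin_degrees: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean density per azimuth bin on a rim band (radius ± halfwidth Å,
    z offsets in voxels from the grid center).  Returns (bin_centers°, profile)."""
    m.require_cubic()
    from scipy.ndimage import map_coordinates

    n = m.shape[0]
    c = (n - 1) / 2.0
    radii = np.arange(
        np.ceil((rim_radius - radial_halfwidth) / m.pixel_size),
        np.floor((rim_radius + radial_halfwidth) / m.pixel_size) + 1,
    )
    if radii.size == 0 or radii.max() > n / 2.0 - 1:
        raise ValueError("rim band outside the grid")
    z_offsets = np.arange(z_band[0], z_band[1] + 1)
    if np.abs(z_offsets).max() > c:
        raise ValueError("z band outside the grid")
    n_bins = int(round(360.0 / bin_degrees))
    phi = np.deg2rad(np.arange(n_bins) * bin_degrees)
    prof = np.zeros(n_bins)
    cnt = 0
    for dz in z_offsets:
        for rv in radii:
            zz = np.full(n_bins, c + dz)
            yy = c + rv * np.sin(phi)
            xx = c + rv * np.cos(phi)
            prof += map_coordinates(m.grid, [zz, yy, xx], order=1, mode="constant")
            cnt += 1
    centers = np.arange(n_bins) * bin_degrees
    return centers, prof / cnt


def arc_occupancy(
    m: DensityMap,
    rim_radius: float,
    z_band: tuple[int, int] = (-6, 0),
    threshold: float = 0.5,
    bin_degrees: float = 2.0,
    radial_halfwidth: float = 10.0,
) -> float:
    """Angular occupancy (degrees) of density on the rim band.

    The azimuthal profile is thresholded at ``threshold`` x its maximum
    (after subtracting the profile minimum as baseline); the occupancy is the
    total angular measure of bins above threshold.  The value is threshold
    dependent by nature and should always be reported with it.
    """
    _, prof = azimuth_occupancy_profile(m, rim_radius, radial_halfwidth, z_band, bin_degrees)
    base = prof.min()
    span = prof.max() - base
    if prof.max() <= 0:
        return 0.0
    if span < 0.05 * abs(prof.max()):
        # near-uniform ring: grid-sampling ripple is all that remains, so the
        # whole band sits at its maximum for any meaningful threshold
        return 360.0
    above = (prof - base) >= threshold * span
    return float(above.sum() * bin_degrees)


def seed_c1_reference(
    vols: list[DensityMap],
    records: list[ParticleRecord],
    focus_mask: Mask,
    n_splits: int = 8,
    seed: int = 0,
) -> DensityMap:
    """Focused-classification style C1 seed: random half-splits averaged
    without symmetry; the split average with the largest masked variance
    (the most asymmetric candidate) is returned."""
    rng = np.random.default_rng(seed)
    best = None
    best_var = -np.inf
    w = focus_mask.grid
    for _ in range(n_splits):
        pick = rng.random(len(vols)) < 0.5
        if not pick.any():
            continue
        acc = np.zeros_like(vols[0].grid)
        cnt = 0
        for v, r, p in zip(vols, records, pick):
            if p:
                acc += rotate_grid(v.grid, r.orientation.inverse())
                cnt += 1
        avg = acc / cnt
        var = float(np.sum(w * (avg - np.average(avg, weights=w + 1e-12)) ** 2))
        if var > best_var:
            best_var, best = var, avg
    return DensityMap(best, vols[0].pixel_size)


class SymmetryRelaxer(BaseEstimator):
    """Per-particle symmetry-unit search + C1 re-averaging as an estimator.

    Fitted attributes: ``assignments_`` (one per particle), ``c1_map_``.
    """

    def __init__(self, n_sym: int = 15, c1_reference=None, focus_mask=None, wedge=None) -> None:
        self.n_sym = n_sym
        self.c1_reference = c1_reference
        self.focus_mask = focus_mask
        self.wedge = wedge

    def fit(self, vols: list[DensityMap], records: list[ParticleRecord]) -> "SymmetryRelaxer":
        if self.c1_reference is None or self.focus_mask is None:
            raise ValueError("c1_reference and focus_mask are required")
        self.assignments_, self.c1_map_ = relax_symmetry(
            vols, records, self.c1_reference, self.focus_mask, self.n_sym, wedge=self.wedge
        )
        return self

    def predict(self, vols=None, records=None) -> np.ndarray:
        if not hasattr(self, "assignments_"):
            raise RuntimeError("fit must be called first")
        return np.array([a.unit_index for a in self.assignments_])
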