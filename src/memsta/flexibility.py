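"""Focused refinement and swing-trajectory analysis.

A particle that swings on its membrane anchor cannot satisfy both the
membrane plane and the protein body in a single rigid alignment: the global
refinement is dominated by the membrane, while a focused refinement against
a protein-only masked reference follows the protein.  The per-particle
angle between the two symmetry-axis directions is the protein tilt; binning
the tilts into intervals and averaging each interval's members reconstructs
the swing trajectory, whose first and last populated classes are the
endpoint conformations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .geometry import Orientation, angular_difference, compose
from .particles import ParticleRecord
from .refine import CandidateStack, local_orientation_grid
from .simulate import wedge_mask
from .volume import DensityMap, Mask, rotate_grid

__all__ = ["TrajectoryClass", "focused_refine", "tilt_trajectory", "FocusedRefiner"]


@dataclass
class TrajectoryClass:
    """One tilt interval [tilt_low, tilt_high) of the swing trajectory."""

    tilt_low: float
    tilt_high: float
    member_ids: list[int]
    class_average: DensityMap | None
    representative_tilt: float  # interval midpoint


def focused_refine(
    vols: list[DensityMap],
    records: list[ParticleRecord],
    protein_mask: Mask,
    reference: DensityMap,
    max_step: float = 6.0,
    step: float = 0.5,
    n_directions: int = 24,
    wedge=None,
    exact_polish: bool = True,
) -> list[Orientation]:
    """One local alignment iteration against the masked reference.

    Exactly one iteration is run (no convergence loop).  The search grid
    covers axis tilts up to ``max_step`` at ``step`` resolution with no
    in-plane component (the focused question is the axis direction).

    The fast pass scores a shared erected-reference stack; because erecting
    re-interpolates the particle, it carries a few-tenths-of-a-degree grid
    bias, so by default a second, exact pass rescores a small neighborhood
    of the fast optimum with per-particle rotated (and wedge-filtered)
    candidates against the raw volume.  Returns per-particle focused
    orientations; the input records are untouched.
    """
    if protein_mask.grid.sum() < 0.01 * protein_mask.grid.size:
        raise ValueError("protein mask covers less than 1% of the box")
    if reference.shape != vols[0].shape:
        raise ValueError("reference/volume shape mismatch")
    masked_ref = DensityMap(reference.grid * protein_mask.grid, reference.pixel_size)
    deltas = local_orientation_grid(max_step, step, n_directions=n_directions)
    stack = CandidateStack(masked_ref, deltas, equalize_blur=True, wedge_correct=wedge)
    n_box = reference.shape[0]
    wmask_r = (
        wedge_mask(n_box, reference.pixel_size, wedge)[:, :, : n_box // 2 + 1]
        if wedge is not None
        else np.ones((n_box, n_box, n_box // 2 + 1), dtype=bool)
    )
    polish_dirs = np.arange(0.0, 360.0, 45.0)
    polish_mags = np.array([step, 2.0 * step, 3.0 * step])
    out = []
    for v, r in zip(vols, records):
        erected = DensityMap(rotate_grid(v.grid, r.orientation.inverse()), v.pixel_size)
        d, _ = stack.best(erected, r.orientation)
        best = compose(r.orientation, d)
        if exact_polish:
            # Rescore in the tomogram frame: the candidate reference is
            # rotated exactly like the rendering path and wedge-limited in
            # Fourier space, so no re-interpolation of the particle biases
            # the optimum.  Scored directly in Fourier (Parseval, rfft
            # layout with the hermitian-redundant bins double-weighted).
            fv = np.fft.rfftn(v.grid)
            fv[0, 0, 0] = 0.0
            fvw = fv * _rfft_weights(v.grid.shape)
            nv = np.sqrt(float(np.sum((fv * np.conj(fvw)).real)))

            def exact_score(cand_o):
                fc = np.fft.rfftn(rotate_grid(masked_ref.grid, cand_o))
                fc[0, 0, 0] = 0.0
                fc *= wmask_r
                nc = np.sqrt(
                    float(np.sum((fc * np.conj(fc)).real * _rfft_weights(v.grid.shape)))
                )
                if nc == 0 or nv == 0:
                    return -np.inf
                return float(np.sum((fvw * np.conj(fc)).real)) / (nv * nc)

            s0 = exact_score(best)
            scores = {}
            for psi in polish_dirs:
                axis = [np.cos(np.deg2rad(psi)), np.sin(np.deg2rad(psi)), 0.0]
                for mag in polish_mags:
                    cand_o = compose(best, Orientation.from_axis_angle(axis, mag))
                    scores[(psi, mag)] = (exact_score(cand_o), cand_o)
            best_key = max(scores, key=lambda k: scores[k][0])
            if scores[best_key][0] > s0:
                psi, mag = best_key
                s_best, best_o = scores[best_key]
                # parabolic sub-grid refinement of the tilt magnitude along
                # the winning direction: breaks the step-size quantization
                # that otherwise clusters downstream tilt statistics
                m_lo, m_hi = mag - step, mag + step
                s_lo = s0 if m_lo < polish_mags[0] else scores[(psi, m_lo)][0]
                if m_hi <= polish_mags[-1]:
                    s_hi = scores[(psi, m_hi)][0]
                else:
                    axis = [np.cos(np.deg2rad(psi)), np.sin(np.deg2rad(psi)), 0.0]
                    s_hi = exact_score(
                        compose(best, Orientation.from_axis_angle(axis, m_hi))
                    )
                denom = s_lo - 2.0 * s_best + s_hi
                if denom < 0:
                    frac = 0.5 * (s_lo - s_hi) / denom
                    m_star = mag + np.clip(frac, -0.5, 0.5) * step
                    axis = [np.cos(np.deg2rad(psi)), np.sin(np.deg2rad(psi)), 0.0]
                    best = compose(best, Orientation.from_axis_angle(axis, float(m_star)))
                else:
                    best = best_o
            # winner = start itself: keep it (sub-step tilts around zero are
            # below the measurement resolution)
        out.append(best)
    return out


def _rfft_weights(shape) -> np.ndarray:
    """Multiplicities of rfftn bins for Parseval sums over the full spectrum."""
    n = shape[-1]
    w = np.full(n // 2 + 1, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    return w[None, None, :]


def tilt_trajectory(
    global_orientations: list[Orientation],
    focused_orientations: list[Orientation],
    n_intervals: int = 5,
    particle_ids: list[int] | None = None,
    vols: list[DensityMap] | None = None,
    scheme: str = "equal_width",
) -> tuple[np.ndarray, list[TrajectoryClass], tuple[TrajectoryClass, TrajectoryClass, float]]:
    """Per-particle tilts, trajectory classes, and endpoint conformations.

    The tilt is the symmetry-axis angle between the global and the focused
    orientation of each particle.  Intervals partition [0, max tilt]
    (equal-width by default; ``scheme='equal_population'`` uses quantile
    edges).  Class averages are built at the focused orientations when
    ``vols`` is given.  The endpoints are the first and last non-empty
    classes; the endpoint separation is the difference of their mean tilts.
    """
    if len(global_orientations) != len(focused_orientations):
        raise ValueError("global/focused orientation lists differ in length")
    if n_intervals < 2:
        raise ValueError("n_intervals must be >= 2")
    ids = particle_ids if particle_ids is not None else list(range(len(global_orientations)))
    if len(ids) != len(global_orientations):
        raise ValueError("particle id list does not pair with the orientations")
    tilts = np.array(
        [
            angular_difference(g, f, mode="axis_only")
            for g, f in zip(global_orientations, focused_orientations)
        ]
    )
    t_max = float(tilts.max())
    if t_max == 0.0:
        edges = np.array([0.0] + [np.finfo(float).eps * (i + 1) for i in range(n_intervals)])
    elif scheme == "equal_width":
        edges = np.linspace(0.0, t_max, n_intervals + 1)
    elif scheme == "equal_population":
        edges = np.quantile(tilts, np.linspace(0.0, 1.0, n_intervals + 1))
        edges[0], edges[-1] = 0.0, t_max
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    which = np.clip(np.searchsorted(edges, tilts, side="right") - 1, 0, n_intervals - 1)
    classes = []
    for i in range(n_intervals):
        members = [j for j in range(len(tilts)) if which[j] == i]
        avg = None
        if vols is not None and members:
            acc = np.zeros_like(vols[0].grid)
            for j in members:
                acc += rotate_grid(vols[j].grid, focused_orientations[j].inverse())
            avg = DensityMap(acc / len(members), vols[0].pixel_size)
        classes.append(
            TrajectoryClass(
                tilt_low=float(edges[i]),
                tilt_high=float(edges[i + 1]),
                member_ids=[ids[j] for j in members],
                class_average=avg,
                representative_tilt=float((edges[i] + edges[i + 1]) / 2.0),
            )
        )
    populated = [c for c in classes if c.member_ids]
    ep_a, ep_b = populated[0], populated[-1]
    id_to_idx = {pid: j for j, pid in enumerate(ids)}
    mean_a = float(np.mean([tilts[id_to_idx[p]] for p in ep_a.member_ids]))
    mean_b = float(np.mean([tilts[id_to_idx[p]] for p in ep_b.member_ids]))
    separation = mean_b - mean_a
    return tilts, classes, (ep_a, ep_b, separation)


class FocusedRefiner(BaseEstimator):
    """Focused refinement + trajectory sectioning as an estimator.

    ``fit(vols, records)`` stores ``focused_orientations_``, ``tilts_``,
    ``classes_``, ``endpoints_`` and ``endpoint_separation_``.
    """

    def __init__(
        self,
        protein_mask: Mask | None = None,
        reference: DensityMap | None = None,
        max_step: float = 6.0,
        step: float = 0.5,
        n_intervals: int = 5,
        scheme: str = "equal_width",
        build_class_averages: bool = True,
        wedge=None,
    ) -> None:
        self.protein_mask = protein_mask
        self.reference = reference
        self.max_step = max_step
        self.step = step
        self.n_intervals = n_intervals
        self.scheme = scheme
        self.build_class_averages = build_class_averages
        self.wedge = wedge

    def fit(self, vols: list[DensityMap], records: list[ParticleRecord]) -> "FocusedRefiner":
        if self.protein_mask is None or self.reference is None:
            raise ValueError("protein_mask and reference are required")
        self.focused_orientations_ = focused_refine(
            vols, records, self.protein_mask, self.reference, self.max_step, self.step,
            wedge=self.wedge,
        )
        self.tilts_, self.classes_, (ep_a, ep_b, sep) = tilt_trajectory(
            [r.orientation for r in records],
            self.focused_orientations_,
            n_intervals=self.n_intervals,
            particle_ids=[r.particle_id for r in records],
            vols=vols if self.build_class_averages else None,
            scheme=self.scheme,
        )
        self.endpoints_ = (ep_a, ep_b)
        self.endpoint_separation_ = sep
        return self

    def tilt_table(self, records: list[ParticleRecord]) -> pd.DataFrame:
        if not hasattr(self, "tilts_"):
            raise RuntimeError("fit must be called first")
        return pd.DataFrame(
            dict(
                particle_id=[r.particle_id for r in records],
                tilt_degrees=self.tilts_,
            )
        )
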