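"""Membrane-geometry-assisted 180° orientation disambiguation.

A cylindrical channel viewed along its axis looks nearly the same from the
top and the bottom, so a fraction of particles ends up aligned upside down.
The cell, however, is a closed surface: every particle picked from one
tomogram should face a consistent side of the pick cloud's centroid.  The
correction draws a vector from each particle position to that center (or
away from it if ``invert`` is set) and flips any particle whose refined
symmetry axis does not face the same side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .geometry import SymmetryGroup, flip_180
from .particles import ParticleRecord

__all__ = ["FlipDecision", "tomogram_center", "correct_flips", "MembraneFlipCorrector"]

_PERP_TOL = 1e-9


@dataclass
class FlipDecision:
    particle_id: int
    center_vector: np.ndarray  # unit vector particle -> center (tomogram frame)
    facing_sign: int  # sign of dot(vector, axis image); 0 = undecidable
    flipped: bool


def tomogram_center(picks) -> np.ndarray:
    """Arithmetic centroid of pick coordinates (the per-tomogram 'center')."""
    picks = np.atleast_2d(np.asarray(picks, dtype=float))
    if picks.size == 0:
        raise ValueError("no picks given")
    return picks.mean(axis=0)


def correct_flips(
    records: list[ParticleRecord],
    center: np.ndarray,
    invert: bool = False,
    sym: SymmetryGroup | int = 1,
) -> tuple[list[ParticleRecord], list[FlipDecision]]:
    """Flip every record whose axis does not face its center vector.

    Idempotent: a corrected set passes through unchanged.  Particles sitting
    exactly at the center, or exactly perpendicular to their vector, are
    undecidable: they are left unflipped and flagged with facing_sign 0.
    """
    center = np.asarray(center, dtype=float)
    out_records = []
    decisions = []
    for r in records:
        v = center - r.center
        norm = np.linalg.norm(v)
        r2 = r.copy()
        if norm < _PERP_TOL:
            decisions.append(FlipDecision(r.particle_id, np.zeros(3), 0, False))
            out_records.append(r2)
            continue
        v = v / norm
        if invert:
            v = -v
        d = float(np.dot(v, r.orientation.axis_image))
        if abs(d) < _PERP_TOL:
            decisions.append(FlipDecision(r.particle_id, v, 0, False))
            out_records.append(r2)
            continue
        flip = d < 0
        if flip:
            r2.orientation = flip_180(r.orientation)
        decisions.append(FlipDecision(r.particle_id, v, 1 if d > 0 else -1, flip))
        out_records.append(r2)
    return out_records, decisions


def decisions_to_frame(decisions: list[FlipDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            particle_id=[d.particle_id for d in decisions],
            vx=[d.center_vector[0] for d in decisions],
            vy=[d.center_vector[1] for d in decisions],
            vz=[d.center_vector[2] for d in decisions],
            facing_sign=[d.facing_sign for d in decisions],
            flipped=[int(d.flipped) for d in decisions],
        )
    )


class MembraneFlipCorrector(BaseEstimator):
    """Per-tomogram centroid + facing-test flip correction as a transformer.

    ``fit(records)`` computes one centroid per tomogram id (or uses
    ``center_override``); ``transform(records)`` returns corrected records
    and stores the decisions in ``decisions_``.
    """

    def __init__(self, invert: bool = False, sym: int = 1, center_override=None) -> None:
        self.invert = invert
        self.sym = sym
        self.center_override = center_override

    def fit(self, records: list[ParticleRecord], y=None) -> "MembraneFlipCorrector":
        self.centers_ = {}
        for tomo in sorted({r.tomogram_id for r in records}):
            if self.center_override is not None:
                self.centers_[tomo] = np.asarray(self.center_override, dtype=float)
            else:
                self.centers_[tomo] = tomogram_center(
                    [r.center for r in records if r.tomogram_id == tomo]
                )
        return self

    def transform(self, records: list[ParticleRecord]) -> list[ParticleRecord]:
        if not hasattr(self, "centers_"):
            raise RuntimeError("fit must be called first")
        out = []
        self.decisions_ = []
        for tomo in sorted({r.tomogram_id for r in records}):
            group = [r for r in records if r.tomogram_id == tomo]
            corrected, dec = correct_flips(group, self.centers_[tomo], self.invert, self.sym)
            out.extend(corrected)
            self.decisions_.extend(dec)
        order = {r.particle_id: i for i, r in enumerate(records)}
        out.sort(key=lambda r: order[r.particle_id])
        self.decisions_.sort(key=lambda d: order[d.particle_id])
        self.n_undecidable_ = sum(1 for d in self.decisions_ if d.facing_sign == 0)
        return out

    def fit_transform(self, records: list[ParticleRecord], y=None) -> list[ParticleRecord]:
        return self.fit(records).transform(records)
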