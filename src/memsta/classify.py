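"""Two-reference classification of 180°-flipped particle populations.

A dataset can mix particles inserted in opposite directions (e.g. channels
on the outer vs the inner membrane).  After one alignment round, each
particle is locally aligned to two references related by a 180° flip about
the x axis and assigned to the better-scoring one; the score margin is kept
as a per-particle confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .geometry import flip_180
from .particles import ParticleRecord
from .refine import CandidateStack, local_orientation_grid
from .volume import DensityMap, normalized_cc, rotate_map

__all__ = ["ClassLabel", "two_reference_classify", "TwoReferenceClassifier"]

_FLIP_AXIS = [1.0, 0.0, 0.0]


@dataclass
class ClassLabel:
    particle_id: int
    label: int  # 0 = reference A, 1 = flipped reference B
    margin: float  # score(assigned) - score(other), >= 0
    score_a: float
    score_b: float


def labels_to_frame(labels: list[ClassLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            particle_id=[l.particle_id for l in labels],
            label=[l.label for l in labels],
            margin=[l.margin for l in labels],
            score_a=[l.score_a for l in labels],
            score_b=[l.score_b for l in labels],
        )
    )


def two_reference_classify(
    vols: list[DensityMap],
    records: list[ParticleRecord],
    reference: DensityMap,
    local_range: float = 8.0,
    step: float = 2.0,
    wedge=None,
) -> list[ClassLabel]:
    """Assign each aligned particle to the reference or its 180° flip.

    Reference B is reference A rotated 180° about the x axis through the
    box center.  Each particle is erected at its record orientation and
    scored against local perturbations (±``local_range``°) of both
    references; ties go to class 0 (deterministic).
    """
    from .geometry import Orientation

    ref_b = rotate_map(reference, Orientation.from_axis_angle(_FLIP_AXIS, 180.0))
    if normalized_cc(reference.grid, ref_b.grid) > 0.99:
        warnings.warn(
            "reference is self-similar under a 180° flip; classes are unidentifiable",
            RuntimeWarning,
        )
    deltas = local_orientation_grid(
        local_range, step, inplane_range=local_range, inplane_step=2.0 * step
    )
    stack_a = CandidateStack(reference, deltas, equalize_blur=True, wedge_correct=wedge)
    stack_b = CandidateStack(ref_b, deltas, equalize_blur=True, wedge_correct=wedge)
    labels = []
    for v, r in zip(vols, records):
        erected = DensityMap(
            rotate_map(v, r.orientation.inverse()).grid, v.pixel_size
        )
        sa = float(stack_a.scores(erected, r.orientation).max())
        sb = float(stack_b.scores(erected, r.orientation).max())
        label = 0 if sa >= sb else 1
        labels.append(
            ClassLabel(
                particle_id=r.particle_id,
                label=label,
                margin=abs(sa - sb),
                score_a=sa,
                score_b=sb,
            )
        )
    return labels


class TwoReferenceClassifier(BaseEstimator):
    """Two-population flip classifier in the sklearn idiom.

    ``fit(vols, records)`` computes labels against ``reference`` and its
    flip; fitted attributes are ``labels_``, ``margins_`` and ``counts_``
    (class sizes).  ``predict`` returns the stored labels.
    """

    def __init__(
        self,
        reference: DensityMap | None = None,
        local_range: float = 8.0,
        step: float = 2.0,
        wedge=None,
    ) -> None:
        self.reference = reference
        self.local_range = local_range
        self.step = step
        self.wedge = wedge

    def fit(self, vols: list[DensityMap], records: list[ParticleRecord]) -> "TwoReferenceClassifier":
        if self.reference is None:
            raise ValueError("a reference map is required")
        self.class_labels_ = two_reference_classify(
            vols, records, self.reference, self.local_range, self.step, wedge=self.wedge
        )
        self.labels_ = np.array([l.label for l in self.class_labels_])
        self.margins_ = np.array([l.margin for l in self.class_labels_])
        self.counts_ = np.bincount(self.labels_, minlength=2)
        return self

    def predict(self, vols=None, records=None) -> np.ndarray:
        if not hasattr(self, "labels_"):
            raise RuntimeError("fit must be called first")
        return self.labels_
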