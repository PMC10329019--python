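"""Rotation algebra for subtomogram orientations.

Orientations are unit quaternions ``(w, x, y, z)`` mapping particle-frame
vectors into tomogram-frame vectors.  Cyclic (Cn) symmetry about the
particle-frame +z axis is first-class: angular comparisons can be taken
modulo the symmetry group, and the 180° "flip" that exchanges a particle's
membrane-proximal and membrane-distal ends is a fixed rotation about the
particle-frame x axis (for a Cn particle any in-plane axis is equivalent up
to a symmetry element; fixing x makes results deterministic).

Internally everything is quaternion based; rotation matrices and Euler
angles appear only at conversion boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Orientation",
    "SymmetryGroup",
    "compose",
    "angular_difference",
    "cn_rotations",
    "flip_180",
]

_UNIT_TOL = 1e-9


class InvalidOrientationError(ValueError):
    """Raised for non-finite or zero-norm quaternion input."""


def _canonical(q: np.ndarray) -> np.ndarray:
    """Normalize and fix the sign ambiguity: w >= 0, tie broken by the
    first nonzero component being positive."""
    q = np.asarray(q, dtype=float)
    if q.shape != (4,) or not np.all(np.isfinite(q)):
        raise InvalidOrientationError(f"invalid quaternion {q!r}")
    n = float(np.linalg.norm(q))
    if n < _UNIT_TOL:
        raise InvalidOrientationError("zero-norm quaternion")
    q = q / n
    if q[0] < 0:
        q = -q
    elif q[0] == 0:
        for c in q[1:]:
            if c != 0:
                if c < 0:
                    q = -q
                break
    return q


@dataclass(frozen=True)
class Orientation:
    """A rigid rotation stored as a canonical unit quaternion (w, x, y, z)."""

    q: np.ndarray

    def __init__(self, q) -> None:
        object.__setattr__(self, "q", _canonical(q))

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "Orientation":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]))

    @classmethod
    def from_axis_angle(cls, axis, degrees: float) -> "Orientation":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0 or not np.isfinite(n):
            raise InvalidOrientationError("zero or non-finite rotation axis")
        rot = Rotation.from_rotvec(axis / n * np.deg2rad(degrees))
        return cls.from_scipy(rot)

    @classmethod
    def from_matrix(cls, m) -> "Orientation":
        return cls.from_scipy(Rotation.from_matrix(np.asarray(m, dtype=float)))

    @classmethod
    def from_scipy(cls, rot: Rotation) -> "Orientation":
        x, y, z, w = rot.as_quat()
        return cls(np.array([w, x, y, z]))

    # -- conversions --------------------------------------------------
    def as_scipy(self) -> Rotation:
        w, x, y, z = self.q
        return Rotation.from_quat([x, y, z, w])

    def as_matrix(self) -> np.ndarray:
        return self.as_scipy().as_matrix()

    def apply(self, vec) -> np.ndarray:
        """Rotate a particle-frame vector into the tomogram frame."""
        return self.as_matrix() @ np.asarray(vec, dtype=float)

    @property
    def axis_image(self) -> np.ndarray:
        """Tomogram-frame image of the particle +z (symmetry) axis."""
        return self.as_matrix()[:, 2]

    def inverse(self) -> "Orientation":
        w, x, y, z = self.q
        return Orientation(np.array([w, -x, -y, -z]))

    def angle_to(self, other: "Orientation") -> float:
        """Geodesic angle in degrees between two rotations."""
        d = abs(float(np.dot(self.q, other.q)))
        return float(np.rad2deg(2.0 * np.arccos(min(d, 1.0))))

    def __eq__(self, other) -> bool:  # exact canonical-form equality
        return isinstance(other, Orientation) and bool(np.array_equal(self.q, other.q))

    def __hash__(self) -> int:
        return hash(self.q.tobytes())

    def __repr__(self) -> str:
        w, x, y, z = self.q
        return f"Orientation(w={w:.6f}, x={x:.6f}, y={y:.6f}, z={z:.6f})"


@dataclass(frozen=True)
class SymmetryGroup:
    """Cyclic group Cn about the particle-frame +z axis."""

    order: int

    def __post_init__(self) -> None:
        if not isinstance(self.order, (int, np.integer)) or self.order < 1:
            raise ValueError(f"symmetry order must be a positive integer, got {self.order!r}")

    @property
    def step_degrees(self) -> float:
        return 360.0 / self.order

    def elements(self) -> list[Orientation]:
        return cn_rotations(self)


C1 = SymmetryGroup(1)

_FLIP_X = Orientation(np.array([0.0, 1.0, 0.0, 0.0]))  # 180° about particle x


def compose(a: Orientation, b: Orientation) -> Orientation:
    """Rotation "apply b, then a" (matrix product Ra·Rb)."""
    w1, x1, y1, z1 = a.q
    w2, x2, y2, z2 = b.q
    return Orientation(
        np.array(
            [
                w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
                w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
                w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
                w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
            ]
        )
    )


def cn_rotations(sym: SymmetryGroup | int) -> list[Orientation]:
    """The n elements of Cn: rotations by k·360/n degrees about +z, k ascending."""
    if isinstance(sym, (int, np.integer)):
        sym = SymmetryGroup(int(sym))
    return [
        Orientation.from_axis_angle([0.0, 0.0, 1.0], k * sym.step_degrees)
        for k in range(sym.order)
    ]


def angular_difference(
    a: Orientation,
    b: Orientation,
    mode: str = "full",
    sym: SymmetryGroup | int = C1,
) -> float:
    """Angle in degrees separating two orientations.

    mode="full": geodesic rotation angle, minimized over the Cn-equivalent
    versions of ``b`` (b composed with each symmetry element).
    mode="axis_only": angle between the tomogram-frame images of the
    particle +z axis — the tilt of the symmetry axis, invariant under Cn
    by construction.
    """
    if isinstance(sym, (int, np.integer)):
        sym = SymmetryGroup(int(sym))
    if mode == "axis_only":
        za, zb = a.axis_image, b.axis_image
        # atan2 form: well conditioned for nearly parallel axes
        return float(
            np.rad2deg(np.arctan2(np.linalg.norm(np.cross(za, zb)), np.dot(za, zb)))
        )
    if mode == "full":
        return min(a.angle_to(compose(b, c)) for c in cn_rotations(sym))
    raise ValueError(f"unknown mode {mode!r}")


def flip_180(o: Orientation) -> Orientation:
    """Compose with a 180° rotation about the particle-frame x axis.

    Sends the particle +z axis to the opposite tomogram-frame direction;
    an involution up to Cn equivalence (exactly, for the fixed x axis).
    """
    return compose(o, _FLIP_X)
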