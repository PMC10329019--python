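"""Per-particle metadata: records, ground truth, and TSV round trips.

A :class:`ParticleRecord` is one pick: tomogram id, center (tomogram voxel
coordinates, 0-based x, y, z), orientation, alignment score, exclusion flag
and gold-standard half-set label.  Orientations are serialized as four text
columns (w, x, y, z) at 9 significant digits so metadata round trips are
byte-stable (quaternions are sign-canonicalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import Orientation

__all__ = [
    "ParticleRecord",
    "GroundTruthRecord",
    "records_to_frame",
    "records_from_frame",
    "write_records_tsv",
    "read_records_tsv",
    "truth_to_frame",
    "write_truth_tsv",
    "read_truth_tsv",
]

_QFMT = "%.9g"


@dataclass
class ParticleRecord:
    particle_id: int
    tomogram_id: int
    center: np.ndarray  # (x, y, z) tomogram voxels
    orientation: Orientation
    score: float = float("nan")
    excluded: bool = False
    half_set: str = "A"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector (x, y, z)")
        if self.half_set not in ("A", "B"):
            raise ValueError(f"half_set must be 'A' or 'B', got {self.half_set!r}")

    def copy(self) -> "ParticleRecord":
        return replace(self, center=self.center.copy())


@dataclass
class GroundTruthRecord:
    """Planted truth for one generated particle."""

    particle_id: int
    orientation: Orientation  # pose used to render the protein density
    flipped: bool
    tilt_degrees: float
    unit_index: int
    membrane_side: str  # 'toward' / 'away' relative to the tomogram center
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))


def _check_unique_ids(ids) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("particle_id values must be unique")


def records_to_frame(records: list[ParticleRecord]) -> pd.DataFrame:
    _check_unique_ids(r.particle_id for r in records)
    rows = []
    for r in records:
        w, x, y, z = (float(_QFMT % v) for v in r.orientation.q)
        rows.append(
            dict(
                particle_id=r.particle_id,
                tomogram_id=r.tomogram_id,
                cx=r.center[0],
                cy=r.center[1],
                cz=r.center[2],
                qw=w,
                qx=x,
                qy=y,
                qz=z,
                score=r.score,
                excluded=int(r.excluded),
                half_set=r.half_set,
            )
        )
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[ParticleRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ParticleRecord(
                particle_id=int(row.particle_id),
                tomogram_id=int(row.tomogram_id),
                center=np.array([row.cx, row.cy, row.cz], dtype=float),
                orientation=Orientation(np.array([row.qw, row.qx, row.qy, row.qz])),
                score=float(row.score),
                excluded=bool(row.excluded),
                half_set=str(row.half_set),
            )
        )
    return out


def write_records_tsv(path, records: list[ParticleRecord]) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format=_QFMT)


def read_records_tsv(path) -> list[ParticleRecord]:
    return records_from_frame(pd.read_csv(path, sep="\t"))


def truth_to_frame(truth: list[GroundTruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truth:
        w, x, y, z = (float(_QFMT % v) for v in t.orientation.q)
        rows.append(
            dict(
                particle_id=t.particle_id,
                qw=w,
                qx=x,
                qy=y,
                qz=z,
                flipped=int(t.flipped),
                tilt_degrees=t.tilt_degrees,
                unit_index=t.unit_index,
                membrane_side=t.membrane_side,
                cx=t.center[0],
                cy=t.center[1],
                cz=t.center[2],
            )
        )
    return pd.DataFrame(rows)


def write_truth_tsv(path, truth: list[GroundTruthRecord]) -> None:
    truth_to_frame(truth).to_csv(path, sep="\t", index=False, float_format=_QFMT)


def read_truth_tsv(path) -> list[GroundTruthRecord]:
    out = []
    for row in pd.read_csv(path, sep="\t").itertuples(index=False):
        out.append(
            GroundTruthRecord(
                particle_id=int(row.particle_id),
                orientation=Orientation(np.array([row.qw, row.qx, row.qy, row.qz])),
                flipped=bool(row.flipped),
                tilt_degrees=float(row.tilt_degrees),
                unit_index=int(row.unit_index),
                membrane_side=str(row.membrane_side),
                center=np.array([row.cx, row.cy, row.cz], dtype=float),
            )
        )
    return out
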