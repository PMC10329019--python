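"""Density-map containers, MRC I/O, filtering, rotation, masks and FSC.

The :class:`DensityMap` is the universal volume currency: a 3D scalar grid
indexed (z, y, x) — slowest-to-fastest, matching MRC section order — with an
isotropic pixel size in Å.  Files are MRC2014 (float32, pixel size in the
``cella`` header fields); computation is float64.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import mrcfile
import numpy as np
from scipy import ndimage

from .geometry import Orientation

__all__ = [
    "DensityMap",
    "Mask",
    "FscCurve",
    "read_mrc",
    "write_mrc",
    "lowpass_filter",
    "rotate_map",
    "fsc_curve",
    "fsc_resolution",
    "soft_mask_from_binary",
    "cylinder_mask",
    "normalized_cc",
]


class MrcFormatError(ValueError):
    """Malformed MRC header or contents."""


@dataclass
class DensityMap:
    """3D voxel grid (z, y, x) with a physical pixel size in Å/voxel.

    The voxel (0, 0, 0) sits at the array corner; the geometric center used
    for rotations and radial measurements is ``(N - 1) / 2`` on each axis.
    """

    grid: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got ndim={self.grid.ndim}")
        if min(self.grid.shape) < 4:
            raise ValueError(f"all dimensions must be >= 4, got {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")
        self.pixel_size = float(self.pixel_size)
        if not (self.pixel_size > 0 and np.isfinite(self.pixel_size)):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape

    @property
    def is_cubic(self) -> bool:
        return len(set(self.grid.shape)) == 1

    @property
    def center(self) -> np.ndarray:
        """Geometric center in voxel index units, (z, y, x) order."""
        return (np.asarray(self.grid.shape, dtype=float) - 1.0) / 2.0

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.pixel_size)

    def require_cubic(self) -> None:
        if not self.is_cubic:
            raise ValueError(f"cubic grid required, got shape {self.grid.shape}")


@dataclass
class Mask:
    """Soft mask in [0, 1], same geometry as the map it modulates."""

    grid: np.ndarray
    pixel_size: float
    soft_edge_width: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.clip(np.asarray(self.grid, dtype=float), 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape

    def apply(self, m: DensityMap) -> DensityMap:
        if m.shape != self.shape:
            raise ValueError("mask/map shape mismatch")
        return DensityMap(m.grid * self.grid, m.pixel_size)


@dataclass
class FscCurve:
    """Fourier shell correlation: per-shell spatial frequency (1/Å) and CC."""

    shell_frequency: np.ndarray
    correlation: np.ndarray

    def __post_init__(self) -> None:
        self.shell_frequency = np.asarray(self.shell_frequency, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)


# ---------------------------------------------------------------- MRC I/O


def read_mrc(path: str | os.PathLike) -> DensityMap:
    """Read an MRC2014 volume; pixel size taken from the header cella fields."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        with mrcfile.open(path, permissive=False) as f:
            data = np.asarray(f.data, dtype=float)
            px = float(f.voxel_size.x)
    except ValueError as e:
        raise MrcFormatError(f"{path}: {e}") from e
    if px <= 0:
        px = 1.0  # headers written without cella default to 1 Å
    return DensityMap(data, px)


def write_mrc(path: str | os.PathLike, m: DensityMap) -> None:
    """Write a volume as float32 MRC2014 with the pixel size in the header.

    The creation-time header label is cleared so identical maps produce
    byte-identical files (runs are hash-compared for reproducibility).
    """
    with mrcfile.new(path, overwrite=True) as f:
        f.set_data(m.grid.astype(np.float32))
        f.voxel_size = m.pixel_size
        f.header.label[0] = b""
        f.header.nlabl = 0


# ---------------------------------------------------------------- filtering


def _gaussian_lowpass(arr: np.ndarray, pixel_size: float, cutoff: float) -> np.ndarray:
    """Gaussian low-pass with half-maximum amplitude at frequency 1/cutoff.

    Works for any dimensionality; DC gain is exactly 1 so the mean is kept.
    """
    freqs = np.meshgrid(
        *[np.fft.fftfreq(n, d=pixel_size) for n in arr.shape], indexing="ij", sparse=True
    )
    f2 = sum(f**2 for f in freqs)
    h = np.exp(-np.log(2.0) * f2 * cutoff**2)
    return np.fft.ifftn(np.fft.fftn(arr) * h).real


def lowpass_filter(m: DensityMap, cutoff: float) -> DensityMap:
    """Low-pass a map; ``cutoff`` is the wavelength (Å) of half-maximum response."""
    if cutoff <= 2.0 * m.pixel_size:
        raise ValueError(
            f"cutoff {cutoff} Å must exceed the Nyquist wavelength {2 * m.pixel_size} Å"
        )
    return DensityMap(_gaussian_lowpass(m.grid, m.pixel_size, cutoff), m.pixel_size)


# ---------------------------------------------------------------- rotation


def _affine_params(o: Orientation, shape: tuple[int, ...]):
    # ndimage maps output index -> input index; our arrays are (z,y,x) so the
    # xyz rotation matrix is conjugated by the axis reversal.
    r_inv = o.as_matrix().T
    m_idx = r_inv[::-1, ::-1]
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    offset = center - m_idx @ center
    return m_idx, offset


def rotate_map(m: DensityMap, o: Orientation) -> DensityMap:
    """Resample a cubic map rotated by ``o`` about the grid center.

    Trilinear interpolation; voxels pulled from outside the grid are zero.
    """
    m.require_cubic()
    m_idx, offset = _affine_params(o, m.shape)
    out = ndimage.affine_transform(
        m.grid, m_idx, offset=offset, order=1, mode="constant", cval=0.0, prefilter=False
    )
    return DensityMap(out, m.pixel_size)


def null_resample_blur(grid: np.ndarray) -> np.ndarray:
    """Two opposite half-voxel trilinear shifts: zero net displacement, one
    rotation-resample's worth of blur (triangular [1/4, 1/2, 1/4] kernel per
    axis).  Used to give the un-rotated member of a candidate stack the same
    interpolation character as its rotated peers."""
    g = ndimage.shift(grid, 0.5, order=1, mode="nearest")
    return ndimage.shift(g, -0.5, order=1, mode="nearest")


def rotate_grid(grid: np.ndarray, o: Orientation) -> np.ndarray:
    """Raw-array variant of :func:`rotate_map` (hot path for alignment stacks)."""
    m_idx, offset = _affine_params(o, grid.shape)
    return ndimage.affine_transform(
        grid, m_idx, offset=offset, order=1, mode="constant", cval=0.0, prefilter=False
    )


# ---------------------------------------------------------------- masks


def soft_mask_from_binary(binary: np.ndarray, pixel_size: float, width: float = 3.0) -> Mask:
    """Soft mask from a boolean support: cosine falloff over ``width`` voxels."""
    binary = np.asarray(binary, dtype=bool)
    if width <= 0:
        return Mask(binary.astype(float), pixel_size, 0.0)
    d = ndimage.distance_transform_edt(~binary)
    edge = 0.5 * (1.0 + np.cos(np.pi * np.clip(d / width, 0.0, 1.0)))
    grid = np.where(binary, 1.0, edge)
    grid[d > width] = 0.0
    return Mask(grid, pixel_size, width)


def cylinder_mask(
    box: int,
    pixel_size: float,
    radius: float,
    z_min: float,
    z_max: float,
    soft_width: float = 3.0,
) -> Mask:
    """Soft cylindrical mask; radius and the z interval are in Å about the center."""
    z, y, x = _physical_coords(box, pixel_size)
    binary = (np.hypot(x, y) <= radius) & (z >= z_min) & (z <= z_max)
    return soft_mask_from_binary(binary, pixel_size, soft_width)


def _physical_coords(box: int, pixel_size: float):
    """Sparse (z, y, x) physical coordinate grids in Å, origin at grid center."""
    c = (box - 1) / 2.0
    ax = (np.arange(box) - c) * pixel_size
    return np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)


# ---------------------------------------------------------------- FSC


def fsc_curve(a: DensityMap, b: DensityMap) -> FscCurve:
    """Per-shell normalized cross-correlation of Fourier coefficients."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    n = a.shape[0]
    fa = np.fft.fftn(a.grid)
    fb = np.fft.fftn(b.grid)
    freqs = np.meshgrid(
        *[np.fft.fftfreq(s, d=a.pixel_size) for s in a.shape], indexing="ij", sparse=True
    )
    fmag = np.sqrt(sum(f**2 for f in freqs))
    shell_width = 1.0 / (n * a.pixel_size)
    shell = np.rint(fmag / shell_width).astype(int)
    n_shells = n // 2 + 1
    valid = shell < n_shells
    sh = shell[valid]
    num = np.bincount(sh, weights=(fa * np.conj(fb)).real[valid], minlength=n_shells)
    pa = np.bincount(sh, weights=np.abs(fa[valid]) ** 2, minlength=n_shells)
    pb = np.bincount(sh, weights=np.abs(fb[valid]) ** 2, minlength=n_shells)
    den = np.sqrt(pa * pb)
    cc = np.divide(num, den, out=np.zeros(n_shells), where=den > 0)
    freq = np.arange(n_shells) * shell_width
    return FscCurve(freq, cc)


def fsc_resolution(
    a: DensityMap, b: DensityMap, threshold: float = 0.143
) -> tuple[FscCurve, float]:
    """Resolution (Å) where the FSC first crosses below ``threshold``.

    Linear interpolation between shells; a curve that never crosses reports
    the Nyquist wavelength (2 × pixel size).
    """
    curve = fsc_curve(a, b)
    cc, freq = curve.correlation, curve.shell_frequency
    for s in range(1, len(cc)):
        if cc[s] < threshold <= cc[s - 1]:
            frac = (cc[s - 1] - threshold) / (cc[s - 1] - cc[s])
            f_cross = freq[s - 1] + frac * (freq[s] - freq[s - 1])
            return curve, float(1.0 / f_cross)
    return curve, 2.0 * a.pixel_size


# ---------------------------------------------------------------- scoring


def normalized_cc(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Real-space normalized cross-correlation, optionally weighted by a mask."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if weights is None:
        da = a - a.mean()
        db = b - b.mean()
        den = np.linalg.norm(da) * np.linalg.norm(db)
        return float(da @ db / den) if den > 0 else 0.0
    w = np.asarray(weights, dtype=float).ravel()
    ws = w.sum()
    if ws <= 0:
        return 0.0
    da = a - (w @ a) / ws
    db = b - (w @ b) / ws
    num = np.sum(w * da * db)
    den = np.sqrt(np.sum(w * da * da) * np.sum(w * db * db))
    return float(num / den) if den > 0 else 0.0
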