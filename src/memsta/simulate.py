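"""Synthetic cryo-ET data: phantoms, membranes, missing wedge, full datasets.

The phantom emulates a membrane-embedded secretin-like channel: a hollow
spool-shaped cylinder (larger diameter at both ends), sealed by a gate disc
at the low-z end, with optional azimuthal surface lobes carrying exact Cn
texture and an optional one-sided membrane-connector arc at the gate-end
rim.  Datasets composite a per-particle rotated phantom with a planar
bilayer (two Gaussian-profile sheets), apply the acquisition missing wedge,
and add white Gaussian noise; every sampled latent (flip state, swing tilt,
symmetry-unit offset, membrane side) is recorded as ground truth.

All randomness flows from a single integer seed; identical seeds give
byte-identical volumes and metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Orientation, compose, cn_rotations, flip_180
from .particles import GroundTruthRecord, ParticleRecord
from .volume import DensityMap, _physical_coords

__all__ = [
    "PhantomSpec",
    "AcquisitionGeometry",
    "DatasetSpec",
    "build_phantom",
    "membrane_density",
    "wedge_mask",
    "apply_missing_wedge",
    "simulate_dataset",
    "noiseless_composite",
    "noise_sigma_for_snr",
]

DEFAULT_BOX = 48
DEFAULT_PIXEL = 5.0  # Å/voxel; box extent 240 Å comfortably holds phantom + bilayer

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


class GeometryError(ValueError):
    """Phantom or band geometry does not fit the requested grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Spool-shaped hollow Cn cylinder with a sealed gate end.

    Dimensions are in Å.  ``wall_radius`` is the mid-radius of the cylinder
    wall; both ends flare out to ``flare_radius``.  ``lobe_amplitude`` > 0
    adds ``lobe_count`` azimuthal surface lobes (default one per symmetry
    unit), giving the wall exact Cn texture.  ``connector_arc`` > 0 adds a
    one-sided rim density at the gate end spanning that arc, centered on
    azimuth 0°.
    """

    n_sym: int = 15
    wall_radius: float = 55.0
    flare_radius: float = 75.0
    height: float = 160.0
    wall_thickness: float = 20.0
    gate: bool = True
    connector_arc: float = 0.0
    lobe_count: int | None = None
    lobe_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if not (self.flare_radius > self.wall_radius > self.wall_thickness):
            raise ValueError("require flare_radius > wall_radius > wall_thickness")
        if not (0.0 <= self.connector_arc <= 360.0):
            raise ValueError("connector_arc must lie in [0, 360] degrees")
        if self.n_sym < 1:
            raise ValueError("n_sym must be >= 1")

    @property
    def gate_z(self) -> float:
        return -self.height / 2.0


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Single-axis tilt scheme; the default is the ±50°, 5°-step collection."""

    tilt_min: float = -50.0
    tilt_max: float = 50.0
    tilt_step: float = 5.0
    wedge_axis: str = "y"

    def __post_init__(self) -> None:
        if not self.tilt_min < self.tilt_max:
            raise ValueError("tilt_min must be < tilt_max")
        if self.tilt_step <= 0:
            raise ValueError("tilt_step must be positive")
        if self.wedge_axis != "y":
            raise ValueError("only the tomogram y tilt axis is supported")


@dataclass(frozen=True)
class DatasetSpec:
    """Statistical model of one synthetic particle population.

    flip_fraction / flip_mode:
      * ``misalignment`` — every particle's rendered pose keeps its gate end
        on the membrane (consistent with the cell geometry); the planted flip
        corrupts the *record* orientation by 180°, emulating top/bottom-view
        misalignment that membrane-assisted correction should undo.
      * ``population`` — the flip is composed into the rendered pose (and the
        membrane follows it): a genuine mixture of oppositely inserted
        particles, as in an inner/outer-membrane mixed dataset.

    tilt_model: ``none`` | ``two_endpoint`` (Bernoulli(tilt_mixing) choice of
    0° or ``tilt_amplitude``) | ``uniform`` (uniform on [0, tilt_amplitude]);
    the swing axis direction is uniform in the membrane plane.

    record_model: ``coarse`` records carry the placement rotation only (no
    swing tilt, no symmetry-unit offset — the state a converged Cn refinement
    reports); ``truth`` records carry the full rendering pose.

    noise_sigma is the white-noise standard deviation as a fraction of the
    phantom peak density.
    """

    n_particles: int = 500
    flip_fraction: float = 0.0
    flip_exact_count: int | None = None  # plant exactly this many flips
    flip_mode: str = "misalignment"
    tilt_model: str = "none"
    tilt_amplitude: float = 0.0
    tilt_mixing: float = 0.5
    tilt_axis_azimuth: float | None = None  # fixed particle-frame swing axis; None = random
    azimuth_offsets: bool = False
    membrane_attach: str = "one_side_arc"  # one_side_arc | full_ring | none
    membrane_z: float | None = None  # proximal leaflet center, Å (default gate_z + 8)
    membrane_separation: float = 40.0
    membrane_sheet_fwhm: float = 15.0
    membrane_amplitude: float = 1.0
    noise_sigma: float = 0.0
    wedge: AcquisitionGeometry | None = field(default_factory=AcquisitionGeometry)
    record_model: str = "coarse"
    cell_radius: float = 400.0  # voxels, virtual cell surface for pick placement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        for name in ("flip_fraction", "tilt_mixing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.flip_mode not in ("misalignment", "population"):
            raise ValueError(f"unknown flip_mode {self.flip_mode!r}")
        if self.tilt_model not in ("none", "two_endpoint", "uniform"):
            raise ValueError(f"unknown tilt_model {self.tilt_model!r}")
        if self.membrane_attach not in ("one_side_arc", "full_ring", "none"):
            raise ValueError(f"unknown membrane_attach {self.membrane_attach!r}")
        if self.record_model not in ("coarse", "truth"):
            raise ValueError(f"unknown record_model {self.record_model!r}")


# ---------------------------------------------------------------- phantom


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def build_phantom(
    spec: PhantomSpec, box: int = DEFAULT_BOX, pixel: float = DEFAULT_PIXEL
) -> DensityMap:
    """Render the analytic phantom onto a cubic grid.

    Peak wall density is ~1 (modulated by the lobes); the gate cap and the
    connector share that unit amplitude.
    """
    if 2.0 * spec.flare_radius + 4.0 * pixel >= box * pixel:
        raise GeometryError(
            f"phantom flare diameter {2 * spec.flare_radius} Å does not fit box "
            f"{box} x {pixel} Å"
        )
    z, y, x = _physical_coords(box, pixel)
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)
    h2 = spec.height / 2.0
    sigma_w = spec.wall_thickness / _FWHM

    z_env = np.clip((h2 - np.abs(z)) / pixel + 0.5, 0.0, 1.0)
    flare_len = 0.15 * spec.height
    g = _smoothstep((np.abs(z) - (h2 - flare_len)) / flare_len)
    r_mid = spec.wall_radius + (spec.flare_radius - spec.wall_radius) * g
    wall = np.exp(-((r - r_mid) ** 2) / (2.0 * sigma_w**2)) * z_env
    if spec.lobe_amplitude > 0:
        lc = spec.lobe_count if spec.lobe_count is not None else spec.n_sym
        wall = wall * (1.0 + spec.lobe_amplitude * np.cos(lc * phi))

    density = wall
    if spec.gate:
        z_cap = spec.gate_z + spec.wall_thickness / 2.0
        radial_in = np.clip(
            ((spec.wall_radius - sigma_w) - r) / (2.0 * pixel) + 0.5, 0.0, 1.0
        )
        density = density + np.exp(-((z - z_cap) ** 2) / (2.0 * sigma_w**2)) * radial_in

    if spec.connector_arc > 0:
        phid = np.rad2deg(phi)
        if spec.connector_arc >= 360.0:
            w_az = np.ones_like(phid)
        else:
            # linear edge over 4° in azimuth -> half-maximum exactly at the arc edge
            w_az = np.clip((spec.connector_arc / 2.0 - np.abs(phid)) / 4.0 + 0.5, 0.0, 1.0)
        conn = (
            np.exp(-((r - connector_radius(spec)) ** 2) / (2.0 * 8.0**2))
            * np.exp(-((z - (spec.gate_z + 5.0)) ** 2) / (2.0 * 8.0**2))
            * w_az
        )
        density = density + conn

    return DensityMap(density, pixel)


def connector_radius(spec: PhantomSpec) -> float:
    """Radial center (Å) of the membrane-connector density band."""
    return spec.flare_radius + 15.0


def membrane_density(
    box: int,
    pixel: float,
    base: Orientation,
    z_leaflet: float,
    separation: float = 40.0,
    sheet_fwhm: float = 15.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Planar bilayer: two Gaussian-profile sheets normal to the particle axis.

    ``base`` is the particle's anchor orientation (no swing tilt); the sheets
    are rendered analytically in the tomogram frame, centered at signed
    distances ``z_leaflet`` and ``z_leaflet - separation`` along the axis
    image, so no interpolation error is introduced.
    """
    nvec = base.axis_image
    z, y, x = _physical_coords(box, pixel)
    s = x * nvec[0] + y * nvec[1] + z * nvec[2]
    sigma = sheet_fwhm / _FWHM
    return amplitude * (
        np.exp(-((s - z_leaflet) ** 2) / (2.0 * sigma**2))
        + np.exp(-((s - (z_leaflet - separation)) ** 2) / (2.0 * sigma**2))
    )


# ---------------------------------------------------------------- wedge


def wedge_mask(box: int, pixel: float, geom: AcquisitionGeometry) -> np.ndarray:
    """Boolean Fourier mask (unshifted FFT layout) of the sampled wedge.

    Tilting about the tomogram y axis sweeps measurement planes through the
    x–z Fourier plane; a coefficient is sampled iff the angle of (kx, kz)
    from the kx axis, folded to [-90°, 90°), lies within the tilt range.
    """
    f = np.fft.fftfreq(box, d=pixel)
    kz = f[:, None, None]
    kx = f[None, None, :]
    ang = np.rad2deg(np.arctan2(kz, kx))
    ang = np.mod(ang + 90.0, 180.0) - 90.0
    keep = (ang >= geom.tilt_min) & (ang <= geom.tilt_max)
    if geom.tilt_max - geom.tilt_min >= 180.0 - 1e-9:
        keep = np.ones_like(keep, dtype=bool)
    return np.broadcast_to(keep, (box, box, box)).copy()


def rotated_wedge_mask(
    box: int, pixel: float, geom: AcquisitionGeometry, orient
) -> np.ndarray:
    """Wedge support as seen in a particle frame erected by ``orient``⁻¹.

    A frequency k of the erected volume corresponds to the tomogram-frame
    frequency R·k, so the mask is evaluated analytically on rotated
    coordinates — no interpolation.  ``orient`` is the particle's tomogram
    orientation; the returned boolean mask is in unshifted FFT layout.
    """
    f = np.fft.fftfreq(box, d=pixel)
    kz = f[:, None, None]
    ky = f[None, :, None]
    kx = f[None, None, :]
    r = orient.as_matrix()
    # tomogram-frame components of the rotated frequency vector
    kx_t = r[0, 0] * kx + r[0, 1] * ky + r[0, 2] * kz
    kz_t = r[2, 0] * kx + r[2, 1] * ky + r[2, 2] * kz
    ang = np.rad2deg(np.arctan2(kz_t, kx_t))
    ang = np.mod(ang + 90.0, 180.0) - 90.0
    keep = (ang >= geom.tilt_min) & (ang <= geom.tilt_max)
    if geom.tilt_max - geom.tilt_min >= 180.0 - 1e-9:
        keep = np.ones_like(keep, dtype=bool)
    return keep


def apply_missing_wedge(m: DensityMap, geom: AcquisitionGeometry) -> DensityMap:
    """Zero Fourier coefficients outside the sampled wedge; idempotent."""
    m.require_cubic()
    mask = wedge_mask(m.shape[0], m.pixel_size, geom)
    out = np.fft.ifftn(np.fft.fftn(m.grid) * mask).real
    return DensityMap(out, m.pixel_size)


# ---------------------------------------------------------------- dataset


def _align_z_to(direction: np.ndarray) -> Orientation:
    """Minimal rotation taking the particle +z axis onto ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    zhat = np.array([0.0, 0.0, 1.0])
    axis = np.cross(zhat, d)
    s = np.linalg.norm(axis)
    c = float(np.dot(zhat, d))
    if s < 1e-12:
        if c > 0:
            return Orientation.identity()
        return Orientation.from_axis_angle([1.0, 0.0, 0.0], 180.0)
    return Orientation.from_axis_angle(axis, np.rad2deg(np.arctan2(s, c)))


def _effective_phantom_spec(pspec: PhantomSpec, dspec: DatasetSpec) -> PhantomSpec:
    if dspec.membrane_attach == "full_ring":
        return replace(pspec, connector_arc=360.0)
    if dspec.membrane_attach == "none":
        return replace(pspec, connector_arc=0.0)
    return pspec


def noiseless_composite(
    pspec: PhantomSpec,
    dspec: DatasetSpec,
    box: int = DEFAULT_BOX,
    pixel: float = DEFAULT_PIXEL,
) -> DensityMap:
    """Membrane-composited phantom at the identity pose (no wedge, no noise)."""
    eff = _effective_phantom_spec(pspec, dspec)
    grid = build_phantom(eff, box, pixel).grid.copy()
    if dspec.membrane_attach != "none":
        z_leaf = dspec.membrane_z if dspec.membrane_z is not None else pspec.gate_z + 8.0
        grid += membrane_density(
            box,
            pixel,
            Orientation.identity(),
            z_leaf,
            dspec.membrane_separation,
            dspec.membrane_sheet_fwhm,
            dspec.membrane_amplitude,
        )
    return DensityMap(grid, pixel)


def noise_sigma_for_snr(
    pspec: PhantomSpec,
    dspec: DatasetSpec,
    snr: float,
    box: int = DEFAULT_BOX,
    pixel: float = DEFAULT_PIXEL,
) -> float:
    """Noise sigma (fraction of phantom peak) giving var(signal)/var(noise)=snr.

    Signal variance is taken over the full noiseless membrane-composited box.
    """
    comp = noiseless_composite(pspec, dspec, box, pixel)
    peak = build_phantom(_effective_phantom_spec(pspec, dspec), box, pixel).grid.max()
    sigma = np.sqrt(comp.grid.var() / snr)
    return float(sigma / peak)


def simulate_dataset(
    pspec: PhantomSpec,
    dspec: DatasetSpec,
    box: int = DEFAULT_BOX,
    pixel: float = DEFAULT_PIXEL,
) -> tuple[list[DensityMap], list[ParticleRecord], list[GroundTruthRecord]]:
    """Generate subtomograms, particle records and ground truth.

    Particles are placed on a virtual spherical cell surface around a
    per-tomogram center so the geometric (tomogram-center) flip test is
    meaningful; unflipped particles point their +z axis toward the center.
    Each subtomogram is the rotated phantom plus the analytic bilayer,
    wedge-filtered, with white noise added last.
    """
    from .volume import rotate_map  # local import to keep module load light

    eff = _effective_phantom_spec(pspec, dspec)
    phantom = build_phantom(eff, box, pixel)
    peak = float(phantom.grid.max())
    z_leaf = dspec.membrane_z if dspec.membrane_z is not None else pspec.gate_z + 8.0
    rng = np.random.default_rng(dspec.seed)
    wmask = (
        wedge_mask(box, pixel, dspec.wedge) if dspec.wedge is not None else None
    )
    tomo_center = np.full(3, 1000.0)
    cn = cn_rotations(pspec.n_sym)

    if dspec.flip_exact_count is not None:
        chosen = rng.choice(dspec.n_particles, size=dspec.flip_exact_count, replace=False)
        flip_flags = np.zeros(dspec.n_particles, dtype=bool)
        flip_flags[chosen] = True
    else:
        flip_flags = rng.random(dspec.n_particles) < dspec.flip_fraction

    vols: list[DensityMap] = []
    records: list[ParticleRecord] = []
    truth: list[GroundTruthRecord] = []
    for i in range(dspec.n_particles):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        position = tomo_center + dspec.cell_radius * u
        roll = rng.uniform(0.0, 360.0)
        q_place = compose(_align_z_to(-u), Orientation.from_axis_angle([0, 0, 1], roll))

        flipped = bool(flip_flags[i])
        if dspec.tilt_model == "none":
            tilt = 0.0
        elif dspec.tilt_model == "two_endpoint":
            tilt = dspec.tilt_amplitude if rng.random() < dspec.tilt_mixing else 0.0
        else:
            tilt = float(rng.uniform(0.0, dspec.tilt_amplitude))
        psi = (
            dspec.tilt_axis_azimuth
            if dspec.tilt_axis_azimuth is not None
            else rng.uniform(0.0, 360.0)
        )
        k = int(rng.integers(pspec.n_sym)) if dspec.azimuth_offsets else 0

        base = q_place
        if flipped and dspec.flip_mode == "population":
            base = flip_180(base)
        q_protein = base
        if tilt != 0.0:
            axis = [np.cos(np.deg2rad(psi)), np.sin(np.deg2rad(psi)), 0.0]
            q_protein = compose(q_protein, Orientation.from_axis_angle(axis, tilt))
        if k:
            q_protein = compose(q_protein, cn[k])

        grid = rotate_map(phantom, q_protein).grid
        if dspec.membrane_attach != "none":
            grid = grid + membrane_density(
                box,
                pixel,
                base,
                z_leaf,
                dspec.membrane_separation,
                dspec.membrane_sheet_fwhm,
                dspec.membrane_amplitude,
            )
        if wmask is not None:
            grid = np.fft.ifftn(np.fft.fftn(grid) * wmask).real
        if dspec.noise_sigma > 0:
            grid = grid + rng.normal(0.0, dspec.noise_sigma * peak, size=grid.shape)
        vols.append(DensityMap(grid, pixel))

        rec_orient = q_protein if dspec.record_model == "truth" else q_place
        if flipped and dspec.flip_mode == "misalignment":
            rec_orient = flip_180(rec_orient)
        axis_img = q_protein.axis_image
        side = "toward" if float(np.dot(tomo_center - position, axis_img)) > 0 else "away"
        records.append(
            ParticleRecord(
                particle_id=i,
                tomogram_id=0,
                center=position,
                orientation=rec_orient,
                half_set="A" if i % 2 == 0 else "B",
            )
        )
        truth.append(
            GroundTruthRecord(
                particle_id=i,
                orientation=q_protein,
                flipped=flipped,
                tilt_degrees=tilt,
                unit_index=k,
                membrane_side=side,
                center=position.copy(),
            )
        )
    return vols, records, truth
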