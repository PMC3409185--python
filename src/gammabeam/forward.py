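"""Sensor geometry, source grids, and spherical-conductor lead fields.

The forward model is shared by the synthetic-data generator and the
beamformer: a homogeneous conducting sphere with point magnetometers on an
outer shell.  For MEG the sphere admits a closed-form solution (Sarvas) in
which radial dipole components are magnetically silent, so each source
location carries a two-column lead field spanning the tangential plane.

Units: sensor positions and head geometry in meters (SI); source-grid
coordinates in millimeters (MNI convention, RAS axes); lead fields in tesla
per unit dipole moment (A*m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GeometryError

MU0 = 4.0e-7 * np.pi  # vacuum permeability, T*m/A

#: Default exclusion radius (mm) around the sphere center.  Lead fields
#: vanish at the center (every direction is radial), so nearby points have
#: near-singular weights and are dropped from the grid.
CENTER_EXCLUSION_MM = 20.0

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SensorArray:
    """Point-magnetometer array: positions (m), unit coil normals, names."""

    positions: np.ndarray  # (n_ch, 3) meters
    orientations: np.ndarray  # (n_ch, 3) unit vectors
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ori = np.asarray(self.orientations, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape != ori.shape:
            raise GeometryError("positions and orientations must be (n_ch, 3)")
        if pos.shape[0] < 8:
            raise GeometryError(f"need at least 8 sensors, got {pos.shape[0]}")
        norms = np.linalg.norm(ori, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise GeometryError("sensor orientations must be unit vectors")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class HeadModel:
    """Spherical conductor: center (m, MNI-aligned) and radius (m)."""

    center: np.ndarray = field(
        default_factory=lambda: np.array([0.0, -0.02, 0.01])
    )
    radius: float = 0.085

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        if not self.radius > 0:
            raise GeometryError("head radius must be positive")
        object.__setattr__(self, "center", c)

    @property
    def center_mm(self) -> np.ndarray:
        return self.center * 1000.0

    @property
    def radius_mm(self) -> float:
        return self.radius * 1000.0


@dataclass(frozen=True)
class SourceGrid:
    """Isotropic lattice of candidate source points (mm, MNI space).

    Points are stored in lexicographic (x, y, z) order so that maps from
    different runs and subjects are voxel-wise comparable.
    """

    points: np.ndarray  # (n_points, 3) mm
    spacing: float  # mm

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise GeometryError("grid points must be (n_points, 3)")
        if not self.spacing > 0:
            raise ConfigurationError("grid spacing must be positive")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class LeadField:
    """Per-point N_ch x 2 lead fields on an orthonormal tangential basis."""

    matrix: np.ndarray  # (n_points, n_ch, 2), tesla per A*m
    basis: np.ndarray  # (n_points, 2, 3) tangential unit vectors
    grid: SourceGrid

    @property
    def n_points(self) -> int:
        return self.matrix.shape[0]


def build_sensor_array(
    n_sensors: int = 248,
    shell_radius: float = 0.12,
    head: HeadModel | None = None,
    seed: int | None = None,
    jitter: float = 0.0,
) -> SensorArray:
    """Quasi-uniform upper-hemisphere magnetometer array.

    Sensors are laid out on a Fibonacci spiral over the hemisphere above the
    head center, at ``shell_radius`` from it, with coil normals pointing
    radially inward.  The layout is deterministic; optional seeded tangential
    jitter (fraction of the inter-sensor distance) breaks exact symmetry.
    """
    head = head or HeadModel()
    if n_sensors < 8:
        raise GeometryError("need at least 8 sensors")
    if shell_radius <= head.radius:
        raise GeometryError(
            f"sensor shell ({shell_radius} m) must lie outside the head "
            f"sphere ({head.radius} m)"
        )
    i = np.arange(n_sensors)
    cos_theta = (i + 0.5) / n_sensors  # z in (0, 1): upper hemisphere
    theta = np.arccos(cos_theta)
    phi = i * _GOLDEN_ANGLE
    unit = np.column_stack(
        [
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            cos_theta,
        ]
    )
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        step = jitter * np.sqrt(2.0 * np.pi / n_sensors)
        unit = unit + step * rng.standard_normal(unit.shape)
        unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    positions = head.center + shell_radius * unit
    orientations = -unit  # radially inward
    names = tuple(f"MAG{k:03d}" for k in range(n_sensors))
    return SensorArray(positions, orientations, names)


def build_source_grid(
    spacing: float,
    head: HeadModel | None = None,
    margin: float = 5.0,
    center_exclusion: float = CENTER_EXCLUSION_MM,
) -> SourceGrid:
    """Axis-aligned isotropic lattice covering the head sphere (mm, MNI).

    Points are kept when at least ``margin`` mm inside the sphere surface and
    at least ``center_exclusion`` mm from the center, and ordered
    lexicographically by (x, y, z).
    """
    head = head or HeadModel()
    if spacing <= 0:
        raise ConfigurationError("spacing must be positive")
    if margin < 0:
        raise ConfigurationError("margin must be non-negative")
    c = head.center_mm
    r = head.radius_mm
    n_half = int(np.floor(r / spacing))
    offsets = spacing * np.arange(-n_half, n_half + 1)
    x, y, z = np.meshgrid(
        c[0] + offsets, c[1] + offsets, c[2] + offsets, indexing="ij"
    )
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    d = np.linalg.norm(pts - c, axis=1)
    keep = (d <= r - margin) & (d >= center_exclusion)
    pts = pts[keep]
    if pts.shape[0] == 0:
        raise ConfigurationError(
            f"empty grid: spacing {spacing} mm, margin {margin} mm on a "
            f"{r:.0f} mm sphere"
        )
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    return SourceGrid(pts[order], spacing)


def warp_grid(grid: SourceGrid, affine: np.ndarray) -> SourceGrid:
    """Map every grid point through a 4x4 affine (homogeneous coordinates).

    Point count and ordering are preserved, so warped per-subject grids stay
    voxel-wise comparable with the template grid.
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ConfigurationError("affine must be 4x4")
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ConfigurationError("affine is singular")
    homog = np.column_stack([grid.points, np.ones(grid.n_points)])
    warped = homog @ affine.T
    return SourceGrid(warped[:, :3] / warped[:, 3:4], grid.spacing)


def apply_affine(points_mm: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Apply a 4x4 affine to (..., 3) points in mm."""
    affine = np.asarray(affine, dtype=float)
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    homog = np.column_stack([pts, np.ones(len(pts))])
    out = homog @ affine.T
    return (out[:, :3] / out[:, 3:4]).reshape(np.shape(points_mm))


def tangential_basis(points_mm: np.ndarray, head: HeadModel) -> np.ndarray:
    """Orthonormal tangential unit vectors at each point, shape (P, 2, 3).

    The basis spans the plane orthogonal to the radial direction from the
    sphere center.  e1 = normalize(z x rhat) (x-axis fallback near the
    poles), e2 = rhat x e1.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    rel = pts - head.center_mm
    rnorm = np.linalg.norm(rel, axis=1, keepdims=True)
    if np.any(rnorm < 1e-9):
        raise GeometryError("tangential basis undefined at the sphere center")
    rhat = rel / rnorm
    zaxis = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(np.broadcast_to(zaxis, rhat.shape), rhat)
    n1 = np.linalg.norm(e1, axis=1, keepdims=True)
    polar = n1[:, 0] < 1e-8
    if np.any(polar):
        xaxis = np.array([1.0, 0.0, 0.0])
        e1[polar] = np.cross(np.broadcast_to(xaxis, rhat[polar].shape), rhat[polar])
        n1 = np.linalg.norm(e1, axis=1, keepdims=True)
    e1 /= n1
    e2 = np.cross(rhat, e1)
    return np.stack([e1, e2], axis=1)


def sarvas_field(
    dipole_pos_mm: np.ndarray,
    moments: np.ndarray,
    sensors: SensorArray,
    head: HeadModel,
) -> np.ndarray:
    """Magnetic field of current dipoles in a conducting sphere (Sarvas).

    Parameters
    ----------
    dipole_pos_mm : (P, 3) dipole locations, mm (MNI-aligned).
    moments : (P, 3) dipole moments, A*m.
    sensors, head : array geometry and sphere.

    Returns
    -------
    (P, n_ch, 3) field vectors in tesla at each sensor position.

    With vectors taken relative to the sphere center, ``a = r - r0``::

        F  = a (r a + r^2 - r0.r)
        dF = (a^2/r + a.r/a + 2a + 2r) r - (a + 2r + a.r/a) r0
        B  = mu0 / (4 pi F^2) * (F (Q x r0) - (Q x r0 . r) dF)

    A dipole with moment parallel to r0 yields Q x r0 = 0: radial sources
    are exactly silent.
    """
    r0 = (np.atleast_2d(dipole_pos_mm) - head.center_mm) / 1000.0  # (P,3) m
    q = np.atleast_2d(np.asarray(moments, dtype=float))  # (P,3)
    r = sensors.positions - head.center  # (S,3) m

    r0n = np.linalg.norm(r0, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(r0n >= head.radius):
        raise GeometryError("dipole outside the head sphere")
    if np.any(rn <= head.radius):
        raise GeometryError("sensor inside the head sphere")

    a = r[None, :, :] - r0[:, None, :]  # (P,S,3)
    an = np.linalg.norm(a, axis=2)  # (P,S)
    r0_dot_r = r0 @ r.T  # (P,S)
    a_dot_r = np.einsum("psk,sk->ps", a, r)  # (P,S)

    f = an * (rn[None, :] * an + rn[None, :] ** 2 - r0_dot_r)
    coef_r = an**2 / rn[None, :] + a_dot_r / an + 2.0 * an + 2.0 * rn[None, :]
    coef_r0 = an + 2.0 * rn[None, :] + a_dot_r / an
    grad_f = (
        coef_r[:, :, None] * r[None, :, :]
        - coef_r0[:, :, None] * r0[:, None, :]
    )
    qxr0 = np.cross(q, r0)  # (P,3)
    qxr0_dot_r = qxr0 @ r.T  # (P,S)
    b = (MU0 / (4.0 * np.pi * f[:, :, None] ** 2)) * (
        f[:, :, None] * qxr0[:, None, :] - qxr0_dot_r[:, :, None] * grad_f
    )
    return b


def point_lead_field(
    points_mm: np.ndarray,
    sensors: SensorArray,
    head: HeadModel,
    on_invalid: str = "raise",
) -> tuple[np.ndarray, np.ndarray]:
    """Lead fields at arbitrary interior points (not snapped to a grid).

    Returns ``(L, basis)`` with ``L`` of shape (P, n_ch, 2): the field of
    unit dipoles along the two tangential basis directions, projected onto
    the sensor coil normals.  Points inside the center exclusion zone or
    outside the sphere either raise (``on_invalid="raise"``) or get an
    all-zero lead field (``"mask"``; downstream weight computation flags
    them degenerate).
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    rel = np.linalg.norm(pts - head.center_mm, axis=1)
    valid = (rel >= CENTER_EXCLUSION_MM) & (rel < head.radius_mm)
    if not valid.all():
        if on_invalid != "mask":
            raise GeometryError(
                "point inside the center exclusion zone "
                f"({CENTER_EXCLUSION_MM:.0f} mm) or outside the sphere"
            )
        # substitute a safe interior location; its columns are zeroed below
        pts = pts.copy()
        pts[~valid] = head.center_mm + np.array(
            [0.0, 0.0, 2.0 * CENTER_EXCLUSION_MM]
        )
    basis = tangential_basis(pts, head)  # (P,2,3)
    cols = []
    for k in range(2):
        b = sarvas_field(pts, basis[:, k, :], sensors, head)  # (P,S,3)
        cols.append(np.einsum("psk,sk->ps", b, sensors.orientations))
    matrix = np.stack(cols, axis=2)  # (P, n_ch, 2)
    matrix[~valid] = 0.0
    if not np.all(np.isfinite(matrix)):
        raise GeometryError("non-finite lead field values")
    return matrix, basis


def lead_field_matrix(
    grid: SourceGrid, sensors: SensorArray, head: HeadModel
) -> LeadField:
    """Lead fields for every grid point (tangential two-column basis).

    Points a subject warp pushed into the exclusion zone or out of the
    sphere get zero lead fields; the beamformer masks them as degenerate
    so per-subject grids keep identical point counts.
    """
    matrix, basis = point_lead_field(grid.points, sensors, head,
                                     on_invalid="mask")
    return LeadField(matrix=matrix, basis=basis, grid=grid)
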