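"""Current-dipole forward model in a homogeneous conducting sphere.

The magnetic field of a current dipole inside a spherically symmetric
conductor has a closed form (the Sarvas solution): with the sphere centred at
the origin, dipole moment ``Q`` at position ``r0`` and field point ``r``,

    B(r) = (mu0 / 4 pi F^2) * (F * (Q x r0)  -  ((Q x r0) . r) * grad F)

where ``a = r - r0``, ``F = a (r a + r^2 - r0 . r)`` and

    grad F = (a^2/r + (a.r)/a + 2a + 2r) r  -  (a + 2r + (a.r)/a) r0 .

Two classical properties follow and are used as tests: a dipole at the sphere
centre, and any radially oriented dipole, produce zero external field.

Magnetometers measure the field component along their orientation; planar
gradiometers are approximated by a two-point finite difference of that
component across a fixed baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MU0_OVER_4PI = 1e-7  # T·m/A

MAGNETOMETER = "magnetometer"
PLANAR_GRADIOMETER = "planar_gradiometer"

#: Planar-gradiometer finite-difference baseline (m); Neuromag-like 17 mm.
GRADIOMETER_BASELINE = 0.017


@dataclass(frozen=True)
class ConductorModel:
    """Single-sphere homogeneous conductor."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 0.09

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError(f"conductor radius must be > 0, got {self.radius}")


@dataclass
class SensorArray:
    """Sensor geometry: positions (m, head frame), unit orientations, types."""

    positions: np.ndarray
    orientations: np.ndarray
    types: list[str]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 3)
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(norms == 0):
            raise ValueError("sensor orientations must be non-zero")
        self.orientations = self.orientations / norms[:, None]
        if self.positions.shape[0] != self.orientations.shape[0]:
            raise ValueError("positions and orientations must have equal length")
        if len(self.types) != self.positions.shape[0]:
            raise ValueError("types must have one entry per sensor")
        bad = set(self.types) - {MAGNETOMETER, PLANAR_GRADIOMETER}
        if bad:
            raise ValueError(f"unknown sensor types: {sorted(bad)}")
        if not self.names:
            self.names = [f"CH{i:03d}" for i in range(self.positions.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


def _fibonacci_cap(n: int, radius: float, max_polar_deg: float = 125.0) -> np.ndarray:
    """Quasi-uniform points on a spherical cap (helmet-like coverage)."""
    cos_min = np.cos(np.deg2rad(max_polar_deg))
    k = np.arange(n)
    # golden-angle spiral over the cap in cos(theta)
    z = 1.0 - (1.0 - cos_min) * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    pts = np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)
    return radius * pts


def default_sensor_array(
    n_channels: int = 64,
    helmet_radius: float = 0.12,
    sensor_type: str = MAGNETOMETER,
) -> SensorArray:
    """Radially oriented sensors on a helmet-shaped spherical cap.

    The desk-scale default is 64 magnetometer-like channels on a 0.12 m cap;
    306 channels (the whole-head system's count) is configuration-selectable.
    """
    pos = _fibonacci_cap(n_channels, helmet_radius)
    ori = pos / np.linalg.norm(pos, axis=1)[:, None]
    return SensorArray(pos, ori, [sensor_type] * n_channels)


def _sarvas_field(r0: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Magnetic field vector B(r) of dipole (r0, q), sphere centred at origin."""
    a_vec = r - r0
    a = np.linalg.norm(a_vec)
    rn = np.linalg.norm(r)
    if a == 0:
        raise ValueError("field point coincides with the dipole")
    f = a * (rn * a + rn**2 - r0 @ r)
    if f == 0:
        raise ValueError("degenerate geometry (F = 0) in spherical forward model")
    grad_f = (a**2 / rn + (a_vec @ r) / a + 2.0 * a + 2.0 * rn) * r - (
        a + 2.0 * rn + (a_vec @ r) / a
    ) * r0
    qxr0 = np.cross(q, r0)
    return MU0_OVER_4PI / f**2 * (f * qxr0 - (qxr0 @ r) * grad_f)


def _tangential_unit(v: np.ndarray) -> np.ndarray:
    """A unit vector orthogonal to v (deterministic choice)."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(v @ ref) > 0.9 * np.linalg.norm(v):
        ref = np.array([1.0, 0.0, 0.0])
    t = np.cross(v, ref)
    return t / np.linalg.norm(t)


def dipole_field(
    dipole_position: Sequence[float],
    dipole_moment: Sequence[float],
    sensor_point: Sequence[float],
    sensor_orientation: Sequence[float],
    conductor: ConductorModel | None = None,
    sensor_type: str = MAGNETOMETER,
) -> float:
    """Field projection of one dipole onto one sensor.

    Returns ``B · n`` (tesla) for a magnetometer, or the two-point tangential
    finite difference of ``B · n`` across :data:`GRADIOMETER_BASELINE`
    (tesla/m) for a planar gradiometer.  Linear in ``dipole_moment``.

    Raises
    ------
    ValueError
        If the dipole lies on or outside the conductor sphere.
    """
    if conductor is None:
        conductor = ConductorModel()
    r0 = np.asarray(dipole_position, dtype=float) - conductor.center
    q = np.asarray(dipole_moment, dtype=float)
    r = np.asarray(sensor_point, dtype=float) - conductor.center
    n = np.asarray(sensor_orientation, dtype=float)
    n = n / np.linalg.norm(n)
    if np.linalg.norm(r0) >= conductor.radius:
        raise ValueError(
            f"dipole at radius {np.linalg.norm(r0):.4f} m lies outside the "
            f"conductor sphere (radius {conductor.radius} m)"
        )
    if sensor_type == MAGNETOMETER:
        return float(_sarvas_field(r0, q, r) @ n)
    if sensor_type == PLANAR_GRADIOMETER:
        t = _tangential_unit(r)
        h = 0.5 * GRADIOMETER_BASELINE
        b_plus = _sarvas_field(r0, q, r + h * t) @ n
        b_minus = _sarvas_field(r0, q, r - h * t) @ n
        return float((b_plus - b_minus) / GRADIOMETER_BASELINE)
    raise ValueError(f"unknown sensor type: {sensor_type}")


def build_leadfield(atlas, array: SensorArray, conductor: ConductorModel | None = None) -> np.ndarray:
    """Leadfield matrix (channels × sources) for an atlas of oriented dipoles.

    Column *j* holds the projection of a unit dipole at atlas source *j*
    (fixed orientation) onto every sensor.  Deterministic.
    """
    if conductor is None:
        conductor = ConductorModel()
    positions, orientations = atlas.all_points()
    n_src = positions.shape[0]
    lf = np.empty((array.n_channels, n_src))
    for j in range(n_src):
        for i in range(array.n_channels):
            lf[i, j] = dipole_field(
                positions[j],
                orientations[j],
                array.positions[i],
                array.orientations[i],
                conductor,
                sensor_type=array.types[i],
            )
    return lf
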