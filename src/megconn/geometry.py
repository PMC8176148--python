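"""Spherical head geometry: sensor helmet and seed (virtual-sensor) models.

The conductor is a homogeneous sphere.  Sensors are magnetometers on a
spherical cap above the head; seeds are parcel-centroid-like points
inside the sphere, each labelled with a lobe and hemisphere so that
spectra can be averaged anatomically.  The geometry is deliberately
simple: it supports a closed-form forward model (see
:mod:`megconn.beamformer`) while reproducing the rank structure and
mixing behaviour of real MEG sensor arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LOBES = ("frontal", "temporal", "parietal", "occipital", "limbic")
HEMISPHERES = ("L", "R")


class GeometryError(ValueError):
    """Seed/sensor position inconsistent with the spherical model."""


@dataclass
class HeadModel:
    """Spherical conductor plus magnetometer array.

    Positions are in metres in head coordinates (x: left->right,
    y: posterior->anterior, z: inferior->superior).
    """

    sphere_center: np.ndarray
    sphere_radius: float
    sensor_positions: np.ndarray  # (n_sensors, 3)
    sensor_orientations: np.ndarray  # (n_sensors, 3), unit norm

    def __post_init__(self) -> None:
        self.sphere_center = np.asarray(self.sphere_center, dtype=float)
        self.sensor_positions = np.asarray(self.sensor_positions, dtype=float)
        self.sensor_orientations = np.asarray(self.sensor_orientations, dtype=float)
        norms = np.linalg.norm(self.sensor_orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise GeometryError("sensor orientations must be unit vectors")
        dist = np.linalg.norm(self.sensor_positions - self.sphere_center, axis=1)
        if np.any(dist <= self.sphere_radius):
            raise GeometryError("all sensors must lie outside the conductor sphere")

    @property
    def n_sensors(self) -> int:
        return self.sensor_positions.shape[0]


@dataclass
class SourceModel:
    """Seed locations with anatomical labels.

    Each seed carries a unique label, a lobe and a hemisphere, mirroring
    how atlas parcel centroids are used as virtual-sensor locations.
    """

    seed_positions: np.ndarray  # (n_seeds, 3), inside the sphere
    labels: list[str]
    lobe: list[str]
    hemisphere: list[str]
    tangential_frames: np.ndarray = field(default=None, repr=False)  # (n_seeds, 2, 3)

    def __post_init__(self) -> None:
        self.seed_positions = np.asarray(self.seed_positions, dtype=float)
        n = self.seed_positions.shape[0]
        if not (len(self.labels) == len(self.lobe) == len(self.hemisphere) == n):
            raise ValueError("labels/lobe/hemisphere must match seed count")
        if len(set(self.labels)) != n:
            raise ValueError("seed labels must be unique")
        bad = set(self.lobe) - set(LOBES)
        if bad:
            raise ValueError(f"unknown lobes {bad}; valid: {LOBES}")
        if set(self.hemisphere) - set(HEMISPHERES):
            raise ValueError("hemisphere must be 'L' or 'R'")

    @property
    def n_seeds(self) -> int:
        return self.seed_positions.shape[0]

    def seeds_in_lobe(self, lobe: str, hemisphere: str | None = None) -> np.ndarray:
        """Indices of seeds in a lobe (optionally restricted to one hemisphere)."""
        mask = np.array([l == lobe for l in self.lobe])
        if hemisphere is not None:
            mask &= np.array([h == hemisphere for h in self.hemisphere])
        return np.flatnonzero(mask)


def _fibonacci_directions(n: int, z_min: float = -1.0, z_max: float = 1.0) -> np.ndarray:
    """n quasi-uniform unit vectors with z components in [z_min, z_max]."""
    golden = (1 + np.sqrt(5)) / 2
    i = np.arange(n)
    z = z_max - (z_max - z_min) * (i + 0.5) / n
    phi = 2 * np.pi * i / golden
    rho = np.sqrt(np.clip(1 - z**2, 0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def tangential_frame(unit_radial: np.ndarray) -> np.ndarray:
    """Two orthonormal tangential directions for a radial unit vector.

    Radial dipoles are magnetically silent in a spherical conductor, so
    source moments are always expressed in this tangent plane.
    """
    u = unit_radial / np.linalg.norm(unit_radial)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(u, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(u, t1)
    return np.stack([t1, t2])


def default_head_model(
    n_sensors: int = 151,
    sphere_radius: float = 0.09,
    helmet_radius: float = 0.12,
    sphere_center: tuple[float, float, float] = (0.0, 0.0, 0.04),
) -> HeadModel:
    """Sensor helmet of axial magnetometers on a spherical cap.

    The cap covers polar angles up to ~115 degrees from the vertex,
    approximating a whole-head system; orientations are radial
    (outward), as for axial gradiometer inner coils.
    """
    center = np.asarray(sphere_center, dtype=float)
    dirs = _fibonacci_directions(n_sensors, z_min=np.cos(np.deg2rad(115)), z_max=1.0)
    positions = center + helmet_radius * dirs
    return HeadModel(center, sphere_radius, positions, dirs)


def _assign_lobe(u: np.ndarray) -> str:
    """Lobe from a unit direction relative to the sphere centre."""
    if u[1] < -0.45:
        return "occipital"
    if u[1] > 0.3:
        return "frontal"
    if u[2] > 0.55:
        return "parietal"
    if u[2] < -0.05 or abs(u[0]) > 0.75:
        return "temporal"
    return "limbic"


def default_source_model(
    n_seeds: int = 90,
    head_model: HeadModel | None = None,
    shell_fractions: tuple[float, ...] = (0.75, 0.5),
) -> SourceModel:
    """Seed set on concentric shells inside the conductor sphere.

    Seeds are labelled ``{lobe}_{hemisphere}_{index}`` with the lobe
    assigned from the seed's direction (posterior seeds occipital,
    anterior frontal, superior parietal, inferior/lateral temporal, deep
    central seeds limbic), so that lobe-wise averaging and
    lobe-restricted planted effects behave like their atlas
    counterparts.
    """
    hm = head_model or default_head_model()
    center, radius = hm.sphere_center, hm.sphere_radius
    n_outer = int(np.ceil(n_seeds * 2 / 3))
    counts = [n_outer, n_seeds - n_outer]
    pts = []
    for frac, cnt in zip(shell_fractions, counts):
        if cnt > 0:
            pts.append(center + frac * radius * _fibonacci_directions(cnt))
    positions = np.vstack(pts)

    labels, lobes, hemis, frames = [], [], [], []
    counters: dict[str, int] = {}
    for p in positions:
        u = (p - center) / np.linalg.norm(p - center)
        lobe = _assign_lobe(u)
        hemi = "L" if u[0] < 0 else "R"
        key = f"{lobe}_{hemi}"
        counters[key] = counters.get(key, 0) + 1
        labels.append(f"{lobe.capitalize()}_{counters[key]}_{hemi}")
        lobes.append(lobe)
        hemis.append(hemi)
        frames.append(tangential_frame(u))

    model = SourceModel(positions, labels, lobes, hemis, np.stack(frames))
    dist = np.linalg.norm(positions - center, axis=1)
    if np.any(dist >= radius):
        raise GeometryError("seed positions must lie strictly inside the sphere")
    return model
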