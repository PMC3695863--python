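"""Small geometric primitives shared across the docking protocol.

All coordinates are in Angstroms.  Random draws take an explicit
``numpy.random.Generator`` so every sampler in the package is reproducible
from a single seed.
"""

from __future__ import annotations

import numpy as np

# Rigid water geometry used when hydrogens are constructed (TIP3P-like).
WATER_OH_LENGTH = 0.9572  # Angstrom
WATER_HOH_ANGLE = 104.52  # degrees


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the unit sphere."""
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - probability ~0
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def random_in_ball(radius: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform point in the ball of given radius (rejection from the cube)."""
    if radius == 0.0:
        return np.zeros(3)
    while True:
        p = rng.uniform(-radius, radius, size=3)
        if p @ p <= radius * radius:
            return p


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via quaternion sampling."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return quat_to_matrix(q)


def random_small_rotation(max_angle_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotation about a uniform random axis by a uniform angle <= max_angle_deg."""
    if max_angle_deg == 0.0:
        return np.eye(3)
    axis = random_unit_vector(rng)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    return axis_angle_matrix(axis, angle)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a rotation of ``angle`` radians about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def rotate_about(coords: np.ndarray, center: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Rotate coordinates about ``center`` by rotation matrix ``R``."""
    return (coords - center) @ R.T + center


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in radians, in (-pi, pi]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.arctan2(y, x))


def angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in radians."""
    v1 = p0 - p1
    v2 = p2 - p1
    c = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def build_water_hydrogens(
    oxygen: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Construct two hydrogens at rigid water geometry in a random orientation.

    The orientation is drawn from ``rng``, so hydrogen construction is
    deterministic under a fixed seed.
    """
    R = random_rotation(rng)
    half = np.deg2rad(WATER_HOH_ANGLE / 2.0)
    h1_local = WATER_OH_LENGTH * np.array([np.sin(half), 0.0, np.cos(half)])
    h2_local = WATER_OH_LENGTH * np.array([-np.sin(half), 0.0, np.cos(half)])
    return oxygen + R @ h1_local, oxygen + R @ h2_local
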