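"""Planar side-chain group geometry: phenyl rings and guanidinium groups."""

from __future__ import annotations

import numpy as np

RING_CC = 1.39   # Angstrom, aromatic C-C
GUA_CN = 1.33    # Angstrom, guanidinium C-N

#: atom order produced for the ring / guanidinium coordinate blocks
RING_NAMES = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
GUA_NAMES = ["CZ", "NE", "NH1", "NH2"]


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis and angle in radians."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR with sign fix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def phenyl_ring(center: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Regular planar hexagon of 6 carbons, C-C bond 1.39 A.

    The hexagon circumradius equals the bond length.
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    # orthonormal in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    angles = np.deg2rad(60.0 * np.arange(6))
    return center + RING_CC * (
        np.cos(angles)[:, None] * e1 + np.sin(angles)[:, None] * e2
    )


def guanidinium(center: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Planar guanidinium group: central C plus 3 N at 1.33 A, 120 deg apart.

    With equal-mass nitrogens the center of mass coincides with the carbon.
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    angles = np.deg2rad(np.array([0.0, 120.0, 240.0]))
    nitrogens = center + GUA_CN * (
        np.cos(angles)[:, None] * e1 + np.sin(angles)[:, None] * e2
    )
    return np.vstack([center, nitrogens])


def stacked_pair(
    center_distance: float,
    plane_angle: float,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    ring_center: np.ndarray | None = None,
    separation_dir: np.ndarray | None = None,
    ring_normal: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build a phenyl ring + guanidinium pair with planted geometry.

    Returns (ring coords (6,3), guanidinium coords (4,3)). Before jitter the
    group centers of mass are ``center_distance`` apart and the angle between
    the two plane normals equals ``plane_angle`` (degrees).
    """
    if center_distance <= 0:
        raise ValueError("center_distance must be > 0")
    if rng is None:
        rng = np.random.default_rng()
    if ring_center is None:
        ring_center = np.zeros(3)
    if ring_normal is None:
        ring_normal = np.array([0.0, 0.0, 1.0])
    ring_normal = np.asarray(ring_normal, dtype=float)
    ring_normal = ring_normal / np.linalg.norm(ring_normal)
    if separation_dir is None:
        separation_dir = ring_normal
    separation_dir = np.asarray(separation_dir, dtype=float)
    separation_dir = separation_dir / np.linalg.norm(separation_dir)

    ring = phenyl_ring(np.asarray(ring_center, dtype=float), ring_normal)

    # tilt the guanidinium normal by plane_angle about an axis in the ring plane
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ring_normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    tilt_axis = np.cross(ring_normal, ref)
    tilt_axis /= np.linalg.norm(tilt_axis)
    gua_normal = _rotation_about(tilt_axis, np.deg2rad(plane_angle)) @ ring_normal
    gua_center = np.asarray(ring_center, dtype=float) + center_distance * separation_dir
    gua = guanidinium(gua_center, gua_normal)

    if jitter_sd > 0:
        ring = ring + rng.normal(scale=jitter_sd, size=ring.shape)
        gua = gua + rng.normal(scale=jitter_sd, size=gua.shape)
    return ring, gua
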