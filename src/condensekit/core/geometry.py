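"""Distance and periodic-boundary helpers (orthorhombic boxes only)."""

from __future__ import annotations

import numpy as np


def min_image(disp: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    if box is None:
        return disp
    box = np.asarray(box, dtype=float)
    return disp - box * np.round(disp / box)


def distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None) -> float:
    return float(np.linalg.norm(min_image(np.asarray(b) - np.asarray(a), box)))


def distance_matrix(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None
) -> np.ndarray:
    disp = a[:, None, :] - b[None, :, :]
    disp = min_image(disp, box)
    return np.sqrt((disp**2).sum(axis=-1))


def center_of_mass(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    masses = np.asarray(masses, dtype=float)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def wrap_coords(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis."""
    return np.mod(coords, np.asarray(box, dtype=float))


def unwrap_serial(points: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Make an ordered point chain whole across periodic boundaries.

    Each point is shifted by lattice vectors so that its displacement from
    its predecessor is the minimum image — a bonded-neighbor walk for linear
    chains.
    """
    if box is None:
        return points.copy()
    out = points.copy().astype(float)
    for i in range(1, len(out)):
        step = min_image(points[i] - out[i - 1], box)
        out[i] = out[i - 1] + step
    return out
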