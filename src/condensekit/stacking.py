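"""Angle-distance pair correlation for sp2-plane stacking, plus Zn geometry.

For every Phe phenyl ring and Arg guanidinium group, the pair observable is
(r, theta): r the minimum-image distance between the groups' heavy-atom
centers of mass, theta the angle between the two best-fit plane normals
folded into [0, 90] degrees. Histogram bins are corrected by the exact
integral of the r^2 sin(theta) volume element over each bin, so bins
touching theta = 0 stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from condensekit.core.chemistry import (
    GUANIDINIUM_ATOMS,
    PHENYL_RING_ATOMS,
    mass_of_element,
)
from condensekit.core.geometry import min_image
from condensekit.core.model import SystemModel

DEFAULT_R_BIN = 0.6      # Angstrom
DEFAULT_THETA_BIN = 2.5  # degrees
DEFAULT_R_MAX = 12.0     # Angstrom


def plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane (smallest principal axis).

    Raises for fewer than 3 points or (near-)collinear input. The sign of
    the returned normal is unspecified.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("plane fit needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise ValueError("atoms are collinear; plane undefined")
    return vt[2]


def normals_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two plane normals folded into [0, 90] degrees."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def pair_geometry(
    group_a: np.ndarray,
    group_b: np.ndarray,
    masses_a: np.ndarray | None = None,
    masses_b: np.ndarray | None = None,
    box: np.ndarray | None = None,
) -> tuple[float, float]:
    """(r, theta) for two planar heavy-atom groups.

    r is the minimum-image distance between mass-weighted centers of mass,
    theta the folded angle between best-fit plane normals.
    """
    group_a = np.asarray(group_a, float)
    group_b = np.asarray(group_b, float)
    ma = np.ones(len(group_a)) if masses_a is None else np.asarray(masses_a, float)
    mb = np.ones(len(group_b)) if masses_b is None else np.asarray(masses_b, float)
    com_a = (group_a * ma[:, None]).sum(axis=0) / ma.sum()
    com_b = (group_b * mb[:, None]).sum(axis=0) / mb.sum()
    r = float(np.linalg.norm(min_image(com_b - com_a, box)))
    theta = normals_angle(plane_normal(group_a), plane_normal(group_b))
    return r, theta


@dataclass
class PlanarGroup:
    """Atom indices of one planar side-chain group."""

    residue: int               # 0-based residue index
    atom_indices: np.ndarray
    masses: np.ndarray
    chain_id: str


def find_planar_groups(model: SystemModel) -> tuple[list[PlanarGroup], list[PlanarGroup]]:
    """All resolvable Phe phenyl rings and Arg guanidinium groups."""
    top = model.topology
    phe: list[PlanarGroup] = []
    arg: list[PlanarGroup] = []
    for r in model.protein_residues:
        rt = top.res_types[r]
        names = PHENYL_RING_ATOMS if rt == "PHE" else (
            GUANIDINIUM_ATOMS if rt == "ARG" else None
        )
        if names is None:
            continue
        idx = [top.find_atom(r, n) for n in names]
        if any(i is None for i in idx):
            continue
        idx = np.array(idx, dtype=int)
        masses = np.array([mass_of_element(top.elements[i]) for i in idx])
        group = PlanarGroup(int(r), idx, masses, top.res_chain[r])
        (phe if rt == "PHE" else arg).append(group)
    return phe, arg


@dataclass
class StackingHistogram:
    """2-D (r, theta) histogram with geometric pair-correlation values."""

    r_edges: np.ndarray        # Angstrom
    theta_edges: np.ndarray    # degrees
    counts: np.ndarray         # (n_r, n_theta)
    g_values: np.ndarray       # geometrically corrected, same shape
    n_f: int
    n_r_groups: int
    n_frames: int
    scale: float = 1.0         # applied so mean(g) over sampled bins == 1

    @property
    def bin_measures(self) -> np.ndarray:
        """Exact integral of r^2 sin(theta) dr dtheta over each bin."""
        dr3 = np.diff(self.r_edges**3) / 3.0
        dcos = -np.diff(np.cos(np.deg2rad(self.theta_edges)))
        return np.outer(dr3, dcos)

    def mode_bin(self) -> tuple[int, int]:
        """Indices of the bin with the largest g value."""
        return tuple(np.unravel_index(np.argmax(self.g_values), self.g_values.shape))

    def mode_center(self) -> tuple[float, float]:
        i, j = self.mode_bin()
        return (
            float((self.r_edges[i] + self.r_edges[i + 1]) / 2),
            float((self.theta_edges[j] + self.theta_edges[j + 1]) / 2),
        )

    def to_tsv(self, path: str | Path) -> None:
        rc = (self.r_edges[:-1] + self.r_edges[1:]) / 2
        tc = (self.theta_edges[:-1] + self.theta_edges[1:]) / 2
        rows = []
        for i, r in enumerate(rc):
            for j, t in enumerate(tc):
                rows.append((r, t, self.counts[i, j], self.g_values[i, j]))
        pd.DataFrame(
            rows, columns=["r_center", "theta_center", "count", "g"]
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def accumulate_g(
    model: SystemModel,
    frames: slice | None = None,
    r_max: float = DEFAULT_R_MAX,
    r_bin: float = DEFAULT_R_BIN,
    theta_bin: float = DEFAULT_THETA_BIN,
    exclude_intrachain: bool = False,
    normalize: bool = True,
) -> StackingHistogram:
    """Histogram (r, theta) over all F-R group pairs and frames.

    g in each bin is counts / (n_frames * bin measure); with ``normalize``
    the values are rescaled so their mean over sampled (nonzero) bins is 1.
    """
    r_edges = np.arange(0.0, r_max + r_bin / 2, r_bin)
    theta_edges = np.arange(0.0, 90.0 + theta_bin / 2, theta_bin)
    counts = np.zeros((len(r_edges) - 1, len(theta_edges) - 1))

    phe, arg = find_planar_groups(model)
    frame_ids = range(model.trajectory.n_frames)[frames or slice(None)]
    if not phe or not arg:
        warnings.warn("no Phe rings or no Arg guanidinium groups found")
        return StackingHistogram(
            r_edges, theta_edges, counts, counts.copy(), len(phe), len(arg), 0
        )

    rs, thetas = [], []
    for f in frame_ids:
        X = model.trajectory.frame(f)
        box = model.trajectory.frame_box(f)
        for pg in phe:
            for ag in arg:
                if exclude_intrachain and pg.chain_id == ag.chain_id:
                    continue
                r, theta = pair_geometry(
                    X[pg.atom_indices], X[ag.atom_indices],
                    pg.masses, ag.masses, box=box,
                )
                rs.append(r)
                thetas.append(theta)
    if rs:
        counts, _, _ = np.histogram2d(
            rs, thetas, bins=(r_edges, theta_edges)
        )

    hist = StackingHistogram(
        r_edges, theta_edges, counts, np.zeros_like(counts),
        len(phe), len(arg), len(frame_ids),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        g = counts / (max(len(frame_ids), 1) * hist.bin_measures)
    scale = 1.0
    if normalize and np.any(counts > 0):
        scale = 1.0 / g[counts > 0].mean()
        g = g * scale
    hist.g_values = g
    hist.scale = scale
    return hist


@dataclass
class CoordinationReport:
    """Zn-S distances and Zn-S-Cbeta angles, per frame and cysteine."""

    zn_s_distances: pd.DataFrame  # columns: frame, residue, distance
    zn_s_cb_angles: pd.DataFrame  # columns: frame, residue, angle

    def summary(self) -> dict:
        d = self.zn_s_distances["distance"]
        a = self.zn_s_cb_angles["angle"]
        return {
            "distance_min": float(d.min()),
            "distance_mean": float(d.mean()),
            "distance_max": float(d.max()),
            "angle_min": float(a.min()),
            "angle_mean": float(a.mean()),
            "angle_max": float(a.max()),
        }


def coordination_geometry(
    model: SystemModel,
    zn_atom: int,
    cys_residues: np.ndarray | list[int] | None = None,
) -> CoordinationReport:
    """Per-frame d(Zn, SG) and angle(Zn, SG, CB) for each cysteine."""
    top = model.topology
    if cys_residues is None:
        cys_residues = [
            r for r in range(top.n_residues) if top.res_types[r] == "CYS"
        ]
    pairs = []
    for r in cys_residues:
        sg = top.find_atom(int(r), "SG")
        cb = top.find_atom(int(r), "CB")
        if sg is None or cb is None:
            warnings.warn(f"cysteine residue {r}: missing SG/CB, skipped")
            continue
        pairs.append((int(r), sg, cb))
    if not pairs:
        raise ValueError("no usable cysteines (SG and CB required)")

    dist_rows, ang_rows = [], []
    for f in range(model.trajectory.n_frames):
        X = model.trajectory.frame(f)
        box = model.trajectory.frame_box(f)
        zn = X[zn_atom]
        for r, sg, cb in pairs:
            v1 = min_image(zn - X[sg], box)
            v2 = min_image(X[cb] - X[sg], box)
            d = float(np.linalg.norm(v1))
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            dist_rows.append((f, r, d))
            ang_rows.append((f, r, ang))
    return CoordinationReport(
        pd.DataFrame(dist_rows, columns=["frame", "residue", "distance"]),
        pd.DataFrame(ang_rows, columns=["frame", "residue", "angle"]),
    )
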