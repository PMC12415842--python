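"""Chain-dimension and stability metrics.

Rg / end-to-end distance with autocorrelation-based equilibration hints,
a convex-hull hydrodynamic radius, and Kabsch RMSD / RMSF. Chains are made
whole across periodic boundaries before any dimension metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from condensekit.core.geometry import center_of_mass, unwrap_serial
from condensekit.core.model import SystemModel


# ---------------------------------------------------------------------------
# basic dimensions
# ---------------------------------------------------------------------------

def radius_of_gyration(
    coords: np.ndarray, masses: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> float:
    """Rg = sqrt(sum m_i |x_i - x_com|^2 / sum m_i)."""
    coords = np.asarray(coords, float)
    if coords.shape[0] < 2:
        raise ValueError("Rg needs at least 2 atoms")
    if masses is None or not mass_weighted:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, float)
    com = center_of_mass(coords, masses)
    sq = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((masses * sq).sum() / masses.sum()))


def _chain_ca_indices(model: SystemModel, chain_id: str) -> list[int]:
    top = model.topology
    res = top.chain_residues(chain_id)
    idx = []
    for r in res:
        if model.component_labels[r] != "protein":
            continue
        ca = top.find_atom(int(r), "CA")
        if ca is not None:
            idx.append(ca)
    return idx


def end_to_end(model: SystemModel, frame: int, chain_id: str) -> float:
    """Distance between the first and last residues' Calpha atoms."""
    ca = _chain_ca_indices(model, chain_id)
    if len(ca) < 2:
        raise ValueError(f"chain {chain_id!r}: need terminal Calpha atoms")
    X = model.trajectory.frame(frame)
    box = model.trajectory.frame_box(frame)
    path = unwrap_serial(X[ca], box)
    return float(np.linalg.norm(path[-1] - path[0]))


def unwrapped_chain_coords(
    model: SystemModel, frame: int, chain_id: str
) -> tuple[np.ndarray, np.ndarray]:
    """Whole-chain heavy-atom coordinates and masses, unwrapped via a
    bonded-neighbor (residue-serial) walk."""
    top = model.topology
    X = model.trajectory.frame(frame)
    box = model.trajectory.frame_box(frame)
    res = [
        int(r) for r in top.chain_residues(chain_id)
        if model.component_labels[r] == "protein"
    ]
    anchors = np.array(
        [X[top.find_atom(r, "CA") or top.res_atom_start[r]] for r in res]
    )
    anchors_u = unwrap_serial(anchors, box)
    coords, masses = [], []
    for r, a_raw, a_unw in zip(res, anchors, anchors_u):
        atoms = top.residue_atoms(r)
        atoms = atoms[top.is_heavy[atoms]]
        local = X[atoms] - a_raw
        if box is not None:
            local = local - box * np.round(local / box)
        coords.append(a_unw + local)
        masses.append(top.masses[atoms])
    return np.vstack(coords), np.concatenate(masses)


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------

def autocorrelation(series: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Mean-removed, variance-normalized autocorrelation function.

    A constant series yields acf = [1, 0, 0, ...] with a warning.
    """
    x = np.asarray(series, float)
    n = len(x)
    if max_lag is None:
        max_lag = n - 1
    if n <= max_lag:
        raise ValueError("series must be longer than max_lag")
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        warnings.warn("constant series: ACF defined as 1 at lag 0, 0 elsewhere")
        acf = np.zeros(max_lag + 1)
        acf[0] = 1.0
        return acf
    # FFT-based full ACF, biased normalization by n
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    corr = np.fft.irfft(f * np.conjugate(f), m)[: max_lag + 1]
    return corr / corr[0]


def integrated_act(series: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time via Sokal's windowing rule.

    tau(M) = 1 + 2 sum_{k<=M} acf(k), with M the smallest window satisfying
    M >= c * tau(M).
    """
    x = np.asarray(series, float)
    acf = autocorrelation(x)
    tau = 1.0
    cumulative = np.cumsum(acf[1:])
    for m in range(1, len(acf)):
        tau = 1.0 + 2.0 * cumulative[m - 1]
        if m >= c * tau:
            return float(max(tau, 1e-12))
    return float(max(tau, 1e-12))


def suggest_equilibration(series: np.ndarray, n_grid: int = 20) -> int:
    """Smallest dropped prefix for which the remainder's running mean stays
    within one standard deviation of its final mean."""
    x = np.asarray(series, float)
    n = len(x)
    for cut in np.unique((np.linspace(0, 0.5, n_grid) * n).astype(int)):
        rest = x[cut:]
        if len(rest) < 10:
            break
        running = np.cumsum(rest) / np.arange(1, len(rest) + 1)
        sd = rest.std()
        if sd == 0 or np.all(np.abs(running - rest.mean()) <= sd):
            return int(cut)
    return int(n // 5)


@dataclass
class DimensionSeries:
    """Per-frame Rg and end-to-end distance with convergence diagnostics."""

    rg: np.ndarray
    dee: np.ndarray
    acf_rg: np.ndarray = field(default_factory=lambda: np.array([]))
    acf_dee: np.ndarray = field(default_factory=lambda: np.array([]))
    act_rg: float = np.nan
    act_dee: float = np.nan
    equilibration_frames: int = 0

    def summary(self) -> dict:
        return {
            "rg_mean": float(self.rg.mean()),
            "rg_sd": float(self.rg.std(ddof=1)) if len(self.rg) > 1 else 0.0,
            "dee_mean": float(self.dee.mean()),
            "dee_sd": float(self.dee.std(ddof=1)) if len(self.dee) > 1 else 0.0,
            "act_rg": self.act_rg,
            "act_dee": self.act_dee,
            "equilibration_frames": self.equilibration_frames,
        }


def dimension_series(
    model: SystemModel, chain_id: str | None = None, max_lag: int | None = None
) -> DimensionSeries:
    """Rg/Dee per frame for one chain (first chain by default)."""
    chain_id = chain_id or model.topology.chain_ids[0]
    n = model.trajectory.n_frames
    rg = np.empty(n)
    dee = np.empty(n)
    for f in range(n):
        coords, masses = unwrapped_chain_coords(model, f, chain_id)
        rg[f] = radius_of_gyration(coords, masses)
        dee[f] = end_to_end(model, f, chain_id)
    lag = max_lag if max_lag is not None else max(1, min(n - 1, n // 2))
    out = DimensionSeries(rg=rg, dee=dee)
    if n > 2:
        out.acf_rg = autocorrelation(rg, lag)
        out.acf_dee = autocorrelation(dee, lag)
        out.act_rg = integrated_act(rg)
        out.act_dee = integrated_act(dee)
        out.equilibration_frames = suggest_equilibration(rg)
    return out


# ---------------------------------------------------------------------------
# convex-hull hydrodynamic radius
# ---------------------------------------------------------------------------

#: hydration-shell thickness added around the hull (one water layer)
HYDRATION_SHELL = 2.8  # Angstrom


@dataclass
class HydrodynamicResult:
    rh: np.ndarray           # per-frame, Angstrom
    hull_volume: np.ndarray  # per-frame, Angstrom^3
    metadata: dict

    def mean_rh(self) -> float:
        return float(self.rh.mean())


def _perrin_translational_factor(p: float) -> float:
    """Perrin friction shape factor for a prolate ellipsoid of axial ratio p."""
    if p <= 1.0 + 1e-12:
        return 1.0
    xi = np.sqrt(p * p - 1.0)
    return float(xi / (p ** (1.0 / 3.0) * np.log(p + xi)))


def hull_rh_single(coords: np.ndarray) -> tuple[float, float, dict]:
    """Hydrodynamic radius of one heavy-atom point set.

    Convex hull volume -> hydration expansion by a one-water shell over the
    hull surface -> equivalent-sphere radius -> Perrin translational shape
    correction using the hull's maximum dimension as the major axis.
    Returns (rh, hull_volume, details).
    """
    coords = np.asarray(coords, float)
    if coords.shape[0] < 4:
        raise ValueError("hull needs at least 4 atoms")
    try:
        hull = ConvexHull(coords)
    except Exception as exc:
        raise ValueError(f"degenerate geometry (coplanar atoms?): {exc}") from exc
    v_hull = float(hull.volume)
    a_hull = float(hull.area)
    v_hyd = v_hull + a_hull * HYDRATION_SHELL
    r_sphere = (3.0 * v_hyd / (4.0 * np.pi)) ** (1.0 / 3.0)
    vertices = coords[hull.vertices]
    diffs = vertices[:, None, :] - vertices[None, :, :]
    dmax = float(np.sqrt((diffs**2).sum(axis=-1)).max())
    a_semi = dmax / 2.0 + HYDRATION_SHELL
    b_semi = np.sqrt(3.0 * v_hyd / (4.0 * np.pi * a_semi))
    p = max(a_semi / b_semi, 1.0)
    f_p = _perrin_translational_factor(p)
    rh = f_p * r_sphere
    return rh, v_hull, {
        "hull_area": a_hull,
        "hydrated_volume": v_hyd,
        "equivalent_sphere_radius": r_sphere,
        "axial_ratio": p,
        "perrin_factor": f_p,
    }


def hullrad_rh(
    model: SystemModel, atom_indices: np.ndarray | None = None
) -> HydrodynamicResult:
    """Per-frame convex-hull hydrodynamic radius over protein heavy atoms."""
    top = model.topology
    if atom_indices is None:
        atom_indices = model.component_atoms("protein")
    atom_indices = np.asarray(atom_indices, dtype=int)
    atom_indices = atom_indices[top.is_heavy[atom_indices]]
    n = model.trajectory.n_frames
    rh = np.empty(n)
    vol = np.empty(n)
    details: dict = {}
    for f in range(n):
        rh[f], vol[f], details = hull_rh_single(
            model.trajectory.frame(f)[atom_indices]
        )
    return HydrodynamicResult(
        rh, vol,
        {
            "hydration_shell_A": HYDRATION_SHELL,
            "shape_correction": "Perrin prolate, major axis = Dmax/2 + shell",
            **{k: float(v) for k, v in details.items()},
        },
    )


# ---------------------------------------------------------------------------
# superposition: RMSD / RMSF
# ---------------------------------------------------------------------------

def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det = +1) aligning centered P onto centered Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def kabsch_rmsd(
    frame_coords: np.ndarray,
    ref_coords: np.ndarray,
    fit_idx: np.ndarray | None = None,
    measure_idx: np.ndarray | None = None,
) -> float:
    """RMSD over ``measure_idx`` after least-squares fit on ``fit_idx``."""
    X = np.asarray(frame_coords, float)
    R = np.asarray(ref_coords, float)
    if X.shape != R.shape:
        raise ValueError("frame and reference must have matched atom lists")
    fit = np.arange(len(X)) if fit_idx is None else np.asarray(fit_idx, int)
    meas = fit if measure_idx is None else np.asarray(measure_idx, int)
    if len(fit) < 3:
        raise ValueError("need at least 3 fit atoms")
    xc = X[fit].mean(axis=0)
    rc = R[fit].mean(axis=0)
    rot = kabsch_rotation(X[fit] - xc, R[fit] - rc)
    moved = (X[meas] - xc) @ rot.T + rc
    return float(np.sqrt(((moved - R[meas]) ** 2).sum(axis=1).mean()))


@dataclass
class StabilityReport:
    rmsd: np.ndarray           # per-frame
    rmsf: np.ndarray           # per selected atom
    fit_atoms: np.ndarray


def rmsd_series(
    model: SystemModel,
    reference: np.ndarray,
    fit_idx: np.ndarray,
    measure_idx: np.ndarray | None = None,
) -> np.ndarray:
    out = np.empty(model.trajectory.n_frames)
    for f in range(model.trajectory.n_frames):
        out[f] = kabsch_rmsd(
            model.trajectory.frame(f), reference, fit_idx, measure_idx
        )
    return out


def rmsf(
    model: SystemModel,
    atom_indices: np.ndarray,
    fit_idx: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> np.ndarray:
    """Per-atom RMSF about the mean structure after iterative superposition.

    Frames are superposed (on ``fit_idx`` within the selection, default all
    selected atoms) onto the running mean structure until the mean stops
    moving; RMSF is then measured over all selected atoms.
    """
    idx = np.asarray(atom_indices, int)
    fit = np.arange(len(idx)) if fit_idx is None else np.asarray(fit_idx, int)
    if model.trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    frames = np.stack(
        [model.trajectory.frame(f)[idx] for f in range(model.trajectory.n_frames)]
    )
    aligned = frames - frames[:, fit].mean(axis=1, keepdims=True)
    # initial superposition onto the first frame so the mean structure is
    # meaningful even when frames carry large rigid rotations
    for f in range(1, len(aligned)):
        rot = kabsch_rotation(aligned[f][fit], aligned[0][fit])
        aligned[f] = aligned[f] @ rot.T
    prev_mean = None
    for _ in range(max_iter):
        mean = aligned.mean(axis=0)
        if prev_mean is not None and np.abs(mean - prev_mean).max() < tol:
            break
        prev_mean = mean
        mean_fit = mean[fit] - mean[fit].mean(axis=0)
        for f in range(len(aligned)):
            centered = aligned[f] - aligned[f][fit].mean(axis=0)
            rot = kabsch_rotation(centered[fit], mean_fit)
            aligned[f] = centered @ rot.T
    mean = aligned.mean(axis=0)
    return np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))


def stability_report(
    model: SystemModel,
    reference_frame: int = 0,
    fit_idx: np.ndarray | None = None,
) -> StabilityReport:
    if fit_idx is None:
        top = model.topology
        fit_idx = np.array(
            [
                top.find_atom(int(r), "CA")
                for r in model.protein_residues
                if top.find_atom(int(r), "CA") is not None
            ]
        )
    ref = model.trajectory.frame(reference_frame)
    return StabilityReport(
        rmsd=rmsd_series(model, ref, fit_idx),
        rmsf=rmsf(model, fit_idx),
        fit_atoms=np.asarray(fit_idx, int),
    )
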