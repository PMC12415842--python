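"""Slab (phase-coexistence) analysis along z.

Per-component mass-density and molar-concentration profiles, dense/dilute
phase assignment, and an electroneutrality-based prediction of small-ion
partitioning from the local concentrations of protein charged residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from condensekit.core.chemistry import ANIONIC_RES, CATIONIC_RES
from condensekit.core.model import SystemModel

#: 1 amu / A^3 in mg/mL
AMU_PER_A3_TO_MG_PER_ML = 1.66053906660e3
#: count / A^3 -> mM
PER_A3_TO_MM = 1.66053906717e6  # = 1e30 / N_A * 1e3
AVOGADRO = 6.02214076e23

DEFAULT_BIN_WIDTH = 2.5  # Angstrom


@dataclass
class DensityProfile:
    z_centers: np.ndarray                       # Angstrom
    bin_width: float
    mass_density: dict[str, np.ndarray]         # mg/mL per component
    molar: dict[str, np.ndarray]                # mM per species (Na, Cl, water)
    residue_conc: dict[str, np.ndarray]         # mM: cationic/anionic residues
    n_frames: int
    box: np.ndarray                             # (3,) mean box lengths
    total_mass: dict[str, float]                # amu per component (frame avg)

    @property
    def bin_volume(self) -> float:
        return float(self.box[0] * self.box[1] * self.bin_width)

    def to_tsv(self, path: str | Path) -> None:
        cols = {"z": self.z_centers}
        for k, v in self.mass_density.items():
            cols[f"{k}_mg_per_ml"] = v
        for k, v in self.molar.items():
            cols[f"{k}_mM"] = v
        for k, v in self.residue_conc.items():
            cols[f"{k}_residues_mM"] = v
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def density_profile(
    model: SystemModel,
    frame_range: slice | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    components: tuple[str, ...] = ("protein", "water", "Na", "Cl"),
    recenter: bool = True,
    his_cationic: bool = False,
) -> DensityProfile:
    """Mass-density / concentration profile along z.

    Each frame is first recentered so the protein center of mass sits at the
    box z-midpoint (slab drift removal), then all coordinates are wrapped
    periodically. Binning covers the whole box, so per-component mass is
    conserved exactly.
    """
    if model.trajectory.box is None:
        raise ValueError("density profile requires a box")
    top = model.topology
    frames = range(model.trajectory.n_frames)[frame_range or slice(None)]
    if len(frames) == 0:
        raise ValueError("empty frame range")

    box = model.trajectory.box[list(frames)].mean(axis=0)
    lz = float(box[2])
    n_bins = max(1, int(round(lz / bin_width)))
    width = lz / n_bins
    edges = np.linspace(0.0, lz, n_bins + 1)
    z_centers = 0.5 * (edges[:-1] + edges[1:])

    comp_atoms = {c: model.component_atoms(c) for c in components}
    prot_atoms = model.component_atoms("protein")
    prot_masses = top.masses[prot_atoms] if len(prot_atoms) else None

    mass_hist = {c: np.zeros(n_bins) for c in components}
    count_hist = {c: np.zeros(n_bins) for c in components if c != "protein"}
    cat_hist = np.zeros(n_bins)
    an_hist = np.zeros(n_bins)

    # charged-residue anchor atoms (CA or first atom); His is neutral unless
    # requested (protonation unspecified upstream)
    cationic = CATIONIC_RES | ({"HIS"} if his_cationic else set())
    cat_res = [
        int(r) for r in model.protein_residues if top.res_types[r] in cationic
    ]
    an_res = [
        int(r) for r in model.protein_residues if top.res_types[r] in ANIONIC_RES
    ]

    def _res_anchor(r: int) -> int:
        ca = top.find_atom(r, "CA")
        return ca if ca is not None else int(top.res_atom_start[r])

    cat_anchor = np.array([_res_anchor(r) for r in cat_res], dtype=int)
    an_anchor = np.array([_res_anchor(r) for r in an_res], dtype=int)

    for f in frames:
        z = model.trajectory.frame(f)[:, 2].copy()
        if recenter and len(prot_atoms):
            com_z = float(
                (z[prot_atoms] * prot_masses).sum() / prot_masses.sum()
            )
            z += lz / 2.0 - com_z
        z = np.mod(z, lz)
        bins = np.minimum((z / width).astype(int), n_bins - 1)
        for c in components:
            idx = comp_atoms[c]
            if len(idx) == 0:
                continue
            np.add.at(mass_hist[c], bins[idx], top.masses[idx])
            if c != "protein":
                np.add.at(count_hist[c], bins[idx], 1.0)
        if len(cat_anchor):
            np.add.at(cat_hist, bins[cat_anchor], 1.0)
        if len(an_anchor):
            np.add.at(an_hist, bins[an_anchor], 1.0)

    nf = len(frames)
    bin_vol = float(box[0] * box[1] * width)
    mass_density = {
        c: mass_hist[c] / nf / bin_vol * AMU_PER_A3_TO_MG_PER_ML
        for c in components
    }
    molar = {
        c: count_hist[c] / nf / bin_vol * PER_A3_TO_MM for c in count_hist
    }
    residue_conc = {
        "cationic": cat_hist / nf / bin_vol * PER_A3_TO_MM,
        "anionic": an_hist / nf / bin_vol * PER_A3_TO_MM,
    }
    total_mass = {c: float(mass_hist[c].sum() / nf) for c in components}
    return DensityProfile(
        z_centers, width, mass_density, molar, residue_conc, nf,
        np.asarray(box, float), total_mass,
    )


@dataclass
class PhaseAssignment:
    dense_interval: tuple[float, float] | None   # z range, Angstrom
    dilute_intervals: list[tuple[float, float]]
    dense_protein_mg_ml: float
    dense_water_mg_ml: float
    dense_means: dict[str, float] = field(default_factory=dict)


def assign_phases(
    profile: DensityProfile, threshold: float = 0.5
) -> PhaseAssignment:
    """Dense region = largest contiguous bin run with protein density at or
    above ``threshold`` x plateau (plateau = 90th-percentile bin density)."""
    prot = profile.mass_density.get("protein")
    if prot is None or prot.max() <= 0:
        return PhaseAssignment(None, [], 0.0, 0.0)
    plateau = float(np.percentile(prot[prot > 0], 90)) if np.any(prot > 0) else 0.0
    mask = prot >= threshold * plateau
    if not mask.any():
        return PhaseAssignment(None, [], 0.0, 0.0)

    # largest contiguous run
    best_start, best_len = 0, 0
    start = None
    for i, m in enumerate(list(mask) + [False]):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    lo, hi = best_start, best_start + best_len  # bin index range [lo, hi)
    half = profile.bin_width / 2
    z_lo = float(profile.z_centers[lo] - half)
    z_hi = float(profile.z_centers[hi - 1] + half)

    dense_slice = slice(lo, hi)
    dense_means = {
        c: float(v[dense_slice].mean()) for c, v in profile.mass_density.items()
    }
    dense_means.update(
        {f"{c}_mM": float(v[dense_slice].mean()) for c, v in profile.molar.items()}
    )
    dilute = []
    if lo > 0:
        dilute.append((float(profile.z_centers[0] - half), z_lo))
    if hi < len(profile.z_centers):
        dilute.append((z_hi, float(profile.z_centers[-1] + half)))
    return PhaseAssignment(
        (z_lo, z_hi),
        dilute,
        dense_means.get("protein", 0.0),
        dense_means.get("water", 0.0),
        dense_means,
    )


@dataclass
class IonPartitionPrediction:
    """Electroneutrality closure: each phase carries the bulk salt plus
    counter-ions matching the local fixed protein charge."""

    predicted_na: np.ndarray    # mM per bin
    predicted_cl: np.ndarray
    bulk_salt: float            # mM
    cationic: np.ndarray        # protein cationic-residue mM per bin
    anionic: np.ndarray

    def electroneutrality_residual(self) -> np.ndarray:
        """(Cl - Na) - (cationic - anionic); identically zero by closure."""
        return (self.predicted_cl - self.predicted_na) - (
            self.cationic - self.anionic
        )


def predict_ion_partition(
    profile: DensityProfile, bulk_salt_mm: float
) -> IonPartitionPrediction:
    """Predicted Na+/Cl- profiles from charged-residue concentrations.

    predicted_Na(z) = bulk + c_anionic(z); predicted_Cl(z) = bulk +
    c_cationic(z), so (Cl - Na) matches the local fixed protein charge
    identically. Whether His counts as cationic is decided when the profile
    is built (``density_profile(his_cationic=...)``).
    """
    cat = profile.residue_conc["cationic"]
    an = profile.residue_conc["anionic"]
    return IonPartitionPrediction(
        predicted_na=bulk_salt_mm + an,
        predicted_cl=bulk_salt_mm + cat,
        bulk_salt=bulk_salt_mm,
        cationic=cat,
        anionic=an,
    )
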