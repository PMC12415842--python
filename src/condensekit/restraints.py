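"""Flat-bottom distance restraints.

The pair potential is zero on a flat bottom [r0, r1], harmonic just outside
on both sides, and linear beyond r2 — the unique C1-continuous reading of
the piecewise definition:

    V(r) = 1/2 k (r - r0)^2                     r < r0
         = 0                                    r0 <= r <= r1
         = 1/2 k (r - r1)^2                     r1 < r <= r2
         = 1/2 k (r2 - r1) (2 r - r2 - r1)      r > r2

Distances are in nm and k in kcal mol^-1 nm^-2 (restraint parameters are
conventionally printed in nm; conversion from the package-internal Angstrom
happens at this module's boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from condensekit.core.model import SystemModel


@dataclass(frozen=True)
class RestraintParams:
    k: float = 20.0    # kcal mol^-1 nm^-2
    r0: float = 0.27   # nm
    r1: float = 0.30   # nm
    r2: float = 0.35   # nm

    def __post_init__(self) -> None:
        if not (0 < self.r0 < self.r1 < self.r2):
            raise ValueError("require 0 < r0 < r1 < r2")
        if self.k <= 0:
            raise ValueError("k must be > 0")


def flat_bottom_potential(
    r: float | np.ndarray, params: RestraintParams | None = None
) -> float | np.ndarray:
    """Potential energy (kcal/mol) at distance r (nm)."""
    p = params or RestraintParams()
    r = np.asarray(r, dtype=float)
    v = np.where(
        r < p.r0,
        0.5 * p.k * (r - p.r0) ** 2,
        np.where(
            r <= p.r1,
            0.0,
            np.where(
                r <= p.r2,
                0.5 * p.k * (r - p.r1) ** 2,
                0.5 * p.k * (p.r2 - p.r1) * (2.0 * r - p.r2 - p.r1),
            ),
        ),
    )
    return float(v) if v.ndim == 0 else v


def flat_bottom_force(
    r: float | np.ndarray, params: RestraintParams | None = None
) -> float | np.ndarray:
    """dV/dr (kcal mol^-1 nm^-1); constant slope k (r2 - r1) beyond r2."""
    p = params or RestraintParams()
    r = np.asarray(r, dtype=float)
    dv = np.where(
        r < p.r0,
        p.k * (r - p.r0),
        np.where(
            r <= p.r1,
            0.0,
            np.where(r <= p.r2, p.k * (r - p.r1), p.k * (p.r2 - p.r1)),
        ),
    )
    return float(dv) if dv.ndim == 0 else dv


@dataclass
class Restraint:
    donor: int       # donor heavy-atom index (0-based)
    acceptor: int    # acceptor heavy-atom index
    params: RestraintParams = field(default_factory=RestraintParams)


@dataclass
class RestraintSet:
    pairs: list[Restraint]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for p in self.pairs:
            key = (p.donor, p.acceptor)
            if key in seen:
                raise ValueError(f"duplicate restraint pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    def sorted(self) -> "RestraintSet":
        return RestraintSet(
            sorted(self.pairs, key=lambda p: (p.donor, p.acceptor)),
            dict(self.provenance),
        )


# ---------------------------------------------------------------------------
# hydrogen-bond pair derivation
# ---------------------------------------------------------------------------

def derive_hbond_pairs(
    model: SystemModel,
    distance_cutoff: float = 3.5,        # Angstrom, donor-acceptor heavy atoms
    angle_cutoff: float = 120.0,         # degrees, D-H...A when H present
    scope: str = "backbone",             # backbone | all
    min_model_fraction: float = 0.5,
    params: RestraintParams | None = None,
    min_sequence_separation: int = 2,
) -> RestraintSet:
    """Detect hydrogen-bond donor/acceptor heavy-atom pairs in a structure.

    Donors are N (and O in ``all`` scope) atoms; acceptors are O (and N in
    ``all`` scope). Without hydrogens a purely geometric criterion is used:
    d(D, A) <= cutoff plus a C-D...A angle filter (>= 90 deg) to reject
    covalent-geometry artifacts. With multi-model input, pairs present in at
    least ``min_model_fraction`` of the models are kept.
    """
    if scope not in ("backbone", "all"):
        raise ValueError("scope must be 'backbone' or 'all'")
    top = model.topology
    params = params or RestraintParams()

    donor_names = {"N"} if scope == "backbone" else None
    acceptor_names = {"O"} if scope == "backbone" else None

    donors, acceptors = [], []
    for r in model.protein_residues:
        for a in top.residue_atoms(int(r)):
            name, elem = top.names[a], top.elements[a]
            if elem == "N" and (donor_names is None or name in donor_names):
                donors.append((int(a), int(r)))
            if elem == "O" and (acceptor_names is None or name in acceptor_names):
                acceptors.append((int(a), int(r)))
            if scope == "all" and elem == "O" and name not in ("O",):
                donors.append((int(a), int(r)))  # hydroxyls can donate

    n_models = model.trajectory.n_frames
    votes: dict[tuple[int, int], int] = {}
    for f in range(n_models):
        X = model.trajectory.frame(f)
        for d_atom, d_res in donors:
            for a_atom, a_res in acceptors:
                if d_atom == a_atom:
                    continue
                if top.res_chain[d_res] == top.res_chain[a_res] and abs(
                    int(top.res_seq[d_res]) - int(top.res_seq[a_res])
                ) < min_sequence_separation:
                    continue
                d = float(np.linalg.norm(X[d_atom] - X[a_atom]))
                if d > distance_cutoff:
                    continue
                if not _geometry_ok(model, f, d_atom, a_atom, angle_cutoff):
                    continue
                votes[(d_atom, a_atom)] = votes.get((d_atom, a_atom), 0) + 1

    kept = [
        Restraint(d, a, params)
        for (d, a), v in sorted(votes.items())
        if v >= min_model_fraction * n_models
    ]
    if not kept:
        warnings.warn("no hydrogen-bond candidate pairs found")
    return RestraintSet(
        kept,
        provenance={
            "distance_cutoff_A": distance_cutoff,
            "angle_cutoff_deg": angle_cutoff,
            "scope": scope,
            "n_models": n_models,
            "min_model_fraction": min_model_fraction,
        },
    )


def _geometry_ok(
    model: SystemModel, frame: int, d_atom: int, a_atom: int, angle_cutoff: float
) -> bool:
    """D-H...A angle filter when a hydrogen bonded to D exists; otherwise a
    loose heavy-atom C-D...A angle filter (>= 90 deg)."""
    top = model.topology
    X = model.trajectory.frame(frame)
    r = int(top.atom_resindex[d_atom])
    hydrogens = [
        a for a in top.residue_atoms(r)
        if top.elements[a] == "H"
        and np.linalg.norm(X[a] - X[d_atom]) < 1.25
    ]
    if hydrogens:
        for h in hydrogens:
            v1 = X[d_atom] - X[h]
            v2 = X[a_atom] - X[h]
            c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(c, -1, 1)))
            if ang >= angle_cutoff:
                return True
        return False
    # heavy-atom-only criterion: angle at D between its bonded C and A
    neighbors = [
        a for a in top.residue_atoms(r)
        if a != d_atom
        and top.elements[a] == "C"
        and np.linalg.norm(X[a] - X[d_atom]) < 1.8
    ]
    if not neighbors:
        return True
    for c_atom in neighbors:
        v1 = X[c_atom] - X[d_atom]
        v2 = X[a_atom] - X[d_atom]
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = np.degrees(np.arccos(np.clip(c, -1, 1)))
        if ang >= 90.0:
            return True
    return False


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

_TSV_HEADER = "#donor\tacceptor\tk_kcal_mol_nm2\tr0_nm\tr1_nm\tr2_nm"


def export_restraints(
    restraints: RestraintSet, path: str | Path, dialect: str = "generic-tsv"
) -> None:
    """Write restraints deterministically (sorted by donor index)."""
    if dialect not in ("generic-tsv", "engine-table"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if not restraints.pairs:
        raise ValueError("cannot export an empty restraint set")
    rs = restraints.sorted()
    lines = []
    if dialect == "generic-tsv":
        lines.append(_TSV_HEADER)
        for p in rs.pairs:
            pr = p.params
            lines.append(
                f"{p.donor}\t{p.acceptor}\t{pr.k:g}\t{pr.r0:g}\t{pr.r1:g}\t{pr.r2:g}"
            )
    else:  # engine-table: 1-based atom serials, fixed-width
        lines.append("; flat-bottom restraints (atom serials 1-based)")
        for p in rs.pairs:
            pr = p.params
            lines.append(
                f"{p.donor + 1:>8d}{p.acceptor + 1:>8d}"
                f"{pr.r0:>10.4f}{pr.r1:>10.4f}{pr.r2:>10.4f}{pr.k:>10.3f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def import_restraints(path: str | Path) -> RestraintSet:
    """Read a generic-tsv restraint table back."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        d, a, k, r0, r1, r2 = line.split("\t")
        pairs.append(
            Restraint(
                int(d), int(a),
                RestraintParams(float(k), float(r0), float(r1), float(r2)),
            )
        )
    return RestraintSet(pairs, provenance={"source": str(path)})
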