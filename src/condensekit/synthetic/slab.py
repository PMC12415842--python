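"""Synthetic multi-chain slab systems with pseudo-water and ions.

Chains are dropped with their centers inside a dense z-region in the middle
of the box; water fills the box uniformly; ions are split into a uniform
background plus an optional dense-region excess so that ion partitioning is
plantable. Per-frame motion is a rigid jitter of each chain.
"""

from __future__ import annotations

import string

import numpy as np

from condensekit.core.chemistry import WATER_MASS, mass_of_element
from condensekit.core.model import SystemModel, Topology, TrajectoryFrameSet
from condensekit.synthetic.chains import (
    _ChainPlan,
    _sidechain_offsets,
    build_protein_topology,
    random_sequence,
)
from condensekit.synthetic.groups import random_rotation
from condensekit.synthetic.spec import SyntheticSpec

AVOGADRO = 6.02214076e23
_MIN_SPACING = 2.0  # Angstrom, crude capacity limit


def _chain_ids(n: int) -> list[str]:
    alphabet = string.ascii_uppercase + string.ascii_lowercase + string.digits
    if n > len(alphabet):
        raise ValueError(f"at most {len(alphabet)} chains supported")
    return list(alphabet[:n])


def excess_count(concentration_mm: float, volume_a3: float) -> int:
    """Number of particles for a molar concentration in an A^3 volume."""
    return int(round(concentration_mm * 1e-3 * AVOGADRO * volume_a3 * 1e-27))


def generate_slab(spec: SyntheticSpec) -> SystemModel:
    """Generate a slab SystemModel; pure function of spec (seeded RNG)."""
    if spec.slab is None:
        raise ValueError("spec.slab must be present for generate_slab")
    slab = spec.slab
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = slab.box
    box_vol = lx * ly * lz
    z_lo = lz / 2 - slab.dense_z_extent / 2
    z_hi = lz / 2 + slab.dense_z_extent / 2
    dense_vol = lx * ly * slab.dense_z_extent

    sequence = spec.sequence or random_sequence(rng, spec.chain_length)
    chain_ids = _chain_ids(spec.n_chains)
    topo_protein = build_protein_topology([sequence] * spec.n_chains, chain_ids)

    n_ex_na = excess_count(slab.dense_excess_na, dense_vol)
    n_ex_cl = excess_count(slab.dense_excess_cl, dense_vol)
    if n_ex_na > slab.n_na or n_ex_cl > slab.n_cl:
        raise ValueError("requested dense-region ion excess exceeds ion count")

    n_particles = topo_protein.n_atoms + slab.n_water + slab.n_na + slab.n_cl
    if n_particles * _MIN_SPACING**3 > box_vol:
        raise ValueError(
            f"{n_particles} particles exceed box capacity at "
            f"{_MIN_SPACING} A minimum spacing"
        )

    # ---- topology: protein chains + water + ions -------------------------
    names = list(topo_protein.names)
    elements = list(topo_protein.elements)
    masses = list(topo_protein.masses)
    res_types = list(topo_protein.res_types)
    res_seq = list(topo_protein.res_seq)
    res_chain = list(topo_protein.res_chain)
    counts = list(np.diff(np.concatenate([topo_protein.res_atom_start,
                                          [topo_protein.n_atoms]])))
    solvent = (
        [("HOH", "OW", "O", WATER_MASS)] * slab.n_water
        + [("NA", "NA", "NA", mass_of_element("NA"))] * slab.n_na
        + [("CL", "CL", "CL", mass_of_element("CL"))] * slab.n_cl
    )
    for k, (rt, aname, elem, mass) in enumerate(solvent):
        names.append(aname)
        elements.append(elem)
        masses.append(mass)
        res_types.append(rt)
        res_seq.append(k + 1)
        res_chain.append("W")
        counts.append(1)
    topology = Topology(
        names, elements, masses, res_types, res_seq, res_chain, counts
    )

    # ---- per-chain base conformations ------------------------------------
    plan = _ChainPlan(spec, rng)
    offsets = _sidechain_offsets(topo_protein.res_types[: spec.chain_length], rng)
    base_chain_coords = []
    chain_centers = []
    # z-centers stratified over the dense extent so the planted slab is
    # reasonably homogeneous even for few chains
    strata = z_lo + (np.arange(spec.n_chains) + 0.5) / spec.n_chains * (
        z_hi - z_lo
    )
    for c in range(spec.n_chains):
        ca = plan.backbone(rng)
        atoms = np.vstack(
            [ca[ri] + offsets[ri] for ri in range(spec.chain_length)]
        )
        atoms -= atoms.mean(axis=0)
        base_chain_coords.append(atoms)
        z_jitter = 0.1 * (z_hi - z_lo) / spec.n_chains
        chain_centers.append(
            np.array(
                [
                    rng.uniform(0, lx),
                    rng.uniform(0, ly),
                    strata[c] + rng.normal(scale=z_jitter),
                ]
            )
        )

    # ---- solvent base positions ------------------------------------------
    def _uniform_box(n: int) -> np.ndarray:
        return rng.uniform([0, 0, 0], [lx, ly, lz], size=(n, 3))

    def _uniform_dense(n: int) -> np.ndarray:
        return rng.uniform([0, 0, z_lo], [lx, ly, z_hi], size=(n, 3))

    water_pos = _uniform_box(slab.n_water)
    na_pos = np.vstack(
        [_uniform_dense(n_ex_na), _uniform_box(slab.n_na - n_ex_na)]
    ) if slab.n_na else np.empty((0, 3))
    cl_pos = np.vstack(
        [_uniform_dense(n_ex_cl), _uniform_box(slab.n_cl - n_ex_cl)]
    ) if slab.n_cl else np.empty((0, 3))
    solvent_pos = np.vstack([water_pos, na_pos, cl_pos])

    # ---- frames: rigid per-chain jitter, solvent resampled jitter --------
    n_atoms_chain = base_chain_coords[0].shape[0]
    coords = np.empty((spec.frames, topology.n_atoms, 3))
    for f in range(spec.frames):
        at = 0
        for c in range(spec.n_chains):
            rot = random_rotation(rng)
            drift = rng.normal(scale=0.5, size=3)
            coords[f, at : at + n_atoms_chain] = (
                base_chain_coords[c] @ rot.T + chain_centers[c] + drift
            )
            at += n_atoms_chain
        jitter = rng.normal(scale=0.25, size=solvent_pos.shape)
        coords[f, at:] = solvent_pos + jitter

    box = np.tile([lx, ly, lz], (spec.frames, 1))
    traj = TrajectoryFrameSet(coords, box=box)
    return SystemModel(topology, traj, domain_map=spec.domain_map)
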