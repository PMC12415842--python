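"""Synthetic single-chain conformations with planted structure.

Backbone: a freely-jointed chain of Calpha positions at fixed bond length.
Planted residue-residue contacts are realized as exact-bond-length bridges
so the constrained pair sits at its target Calpha separation in every frame
while all consecutive Calpha distances stay equal to the bond length.
Folded-domain ranges are emitted as a rigid template that is rotated and
translated per frame but never deformed.

Each residue is expanded to its true heavy-atom count using standard PDB
atom names; side-chain atoms sit on a deterministic local frame within
2.5 A of the Calpha. Only the Phe phenyl ring and the Arg guanidinium group
receive faithful planar geometry.
"""

from __future__ import annotations

import warnings

import numpy as np

from condensekit.core.chemistry import (
    AMINO_ACIDS_3,
    HEAVY_ATOM_NAMES,
    ONE_TO_THREE,
    element_from_atom_name,
    mass_of_element,
)
from condensekit.core.model import SystemModel, Topology, TrajectoryFrameSet
from condensekit.synthetic.groups import (
    GUA_NAMES,
    RING_NAMES,
    random_rotation,
    stacked_pair,
)
from condensekit.synthetic.spec import PlantedContact, SyntheticSpec

PROXIMITY_EXCLUSION = 4  # same-chain |i-j| <= 4 is invisible to contact stage
_SIDECHAIN_RADIUS = 2.2  # max offset of pseudo side-chain atoms from Calpha


def random_sequence(rng: np.random.Generator, n: int) -> str:
    letters = list(ONE_TO_THREE)
    return "".join(rng.choice(letters, size=n))


def build_protein_topology(
    sequences: list[str], chain_ids: list[str]
) -> Topology:
    """Topology for one or more protein chains from one-letter sequences."""
    names: list[str] = []
    elements: list[str] = []
    masses: list[float] = []
    res_types: list[str] = []
    res_seq: list[int] = []
    res_chain: list[str] = []
    counts: list[int] = []
    for seq, cid in zip(sequences, chain_ids):
        for i, one in enumerate(seq):
            rt = ONE_TO_THREE[one] if one in ONE_TO_THREE else one
            if rt not in AMINO_ACIDS_3:
                raise ValueError(f"unknown residue code {one!r}")
            atom_names = HEAVY_ATOM_NAMES[rt]
            names.extend(atom_names)
            for n in atom_names:
                e = element_from_atom_name(n, rt)
                elements.append(e)
                masses.append(mass_of_element(e))
            res_types.append(rt)
            res_seq.append(i + 1)
            res_chain.append(cid)
            counts.append(len(atom_names))
    return Topology(names, elements, masses, res_types, res_seq, res_chain, counts)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _perpendicular_unit(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = np.cross(u, _random_unit(rng))
    while np.linalg.norm(p) < 1e-8:
        p = np.cross(u, _random_unit(rng))
    return _unit(p)


def _cap_direction(
    towards: np.ndarray, cos_min: float, rng: np.random.Generator
) -> np.ndarray:
    """Random unit vector with cos(angle to ``towards``) uniform in
    [cos_min, 1] and uniform azimuth (area-uniform on the spherical cap)."""
    w = _unit(towards)
    c = rng.uniform(cos_min, 1.0)
    s = np.sqrt(max(1.0 - c * c, 0.0))
    e1 = _perpendicular_unit(w, rng)
    e2 = np.cross(w, e1)
    phi = rng.uniform(0.0, 2 * np.pi)
    return c * w + s * (np.cos(phi) * e1 + np.sin(phi) * e2)


def _random_bridge(
    start: np.ndarray,
    end: np.ndarray,
    n_steps: int,
    bond: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random path of ``n_steps`` exact-length bonds from start to end.

    Each step samples area-uniformly from the spherical cap of directions
    that keep the target reachable with the remaining bonds; the final two
    bonds close the triangle exactly. Requires |end-start| <= n_steps*bond.
    """
    d = float(np.linalg.norm(end - start))
    if d > n_steps * bond + 1e-9:
        raise ValueError(
            f"cannot bridge distance {d:.2f} with {n_steps} bonds of {bond:.2f}"
        )
    if n_steps == 1:
        if abs(d - bond) > 1e-9:
            raise ValueError("single-bond bridge requires distance == bond length")
        return np.array([end])
    pts = np.empty((n_steps, 3))
    p = start.astype(float).copy()
    for t in range(n_steps - 2):
        m = n_steps - t  # bonds remaining including this one
        w = end - p
        dist = float(np.linalg.norm(w))
        if dist < 1e-12:
            # on top of the target: any direction keeps it reachable
            u = _random_unit(rng)
        else:
            cos_min = (dist**2 + bond**2 - ((m - 1) * bond) ** 2) / (
                2.0 * bond * dist
            )
            u = _cap_direction(w, float(np.clip(cos_min, -1.0, 1.0)), rng)
        p = p + bond * u
        pts[t] = p
    # close with two bonds: isoceles triangle with apex angle from the law
    # of cosines; |end - p| <= 2*bond is guaranteed by the cap constraint
    w = end - p
    dist = float(np.linalg.norm(w))
    if dist < 1e-12:
        v = _random_unit(rng)
    else:
        cos_alpha = float(np.clip(dist / (2.0 * bond), -1.0, 1.0))
        sin_alpha = np.sqrt(max(1.0 - cos_alpha**2, 0.0))
        e1 = _perpendicular_unit(w, rng)
        v = cos_alpha * _unit(w) + sin_alpha * e1
    pts[n_steps - 2] = p + bond * v
    pts[n_steps - 1] = end
    return pts


def _helix_template(n: int, bond: float) -> np.ndarray:
    """Rigid helical Calpha template with exact consecutive bond lengths."""
    chord = 0.8 * bond
    dtheta = 2 * np.arcsin(0.5)  # 60 deg turn per residue
    radius = chord / (2 * np.sin(dtheta / 2))
    rise = np.sqrt(bond**2 - chord**2)
    t = np.arange(n)
    pts = np.stack(
        [
            radius * np.cos(dtheta * t),
            radius * np.sin(dtheta * t),
            rise * t,
        ],
        axis=1,
    )
    return pts - pts[0]


class _ChainPlan:
    """Resolved per-residue construction plan for one chain."""

    def __init__(self, spec: SyntheticSpec, rng: np.random.Generator) -> None:
        self.n = spec.chain_length
        self.bond = spec.bond_length
        # folded rigid segments
        self.rigid: list[tuple[int, int]] = []  # 0-based inclusive ranges
        for name in spec.folded_domains:
            first, last = spec.domain_map.range_of(name)
            self.rigid.append((first - 1, last - 1))
        self.rigid.sort()
        # planted constraints (contacts + stacks) as 0-based (i, j, d)
        constraints: list[tuple[int, int, float]] = []
        for pc in spec.planted_contacts:
            i, j = sorted((pc.res_i - 1, pc.res_j - 1))
            if j - i <= PROXIMITY_EXCLUSION:
                warnings.warn(
                    f"planted contact ({pc.res_i},{pc.res_j}) lies inside the "
                    f"proximity-exclusion window and will be invisible to the "
                    f"contact stage"
                )
            constraints.append((i, j, pc.target_distance))
        for ps in spec.planted_stacks:
            i, j = sorted((ps.phe_residue - 1, ps.arg_residue - 1))
            constraints.append((i, j, ps.center_distance))
        constraints.sort()
        for (i1, j1, _), (i2, j2, _) in zip(constraints, constraints[1:]):
            if i2 <= j1:
                raise ValueError(
                    "planted constraints must occupy disjoint residue ranges"
                )
        for i, j, d in constraints:
            if d > (j - i) * self.bond:
                raise ValueError(
                    f"planted distance {d} A unreachable over {j - i} bonds"
                )
            for rf, rl in self.rigid:
                if not (j < rf or i > rl):
                    raise ValueError(
                        "planted constraints may not overlap folded domains"
                    )
        self.constraints = constraints
        self.templates = {
            (rf, rl): _helix_template(rl - rf + 1, self.bond)
            for rf, rl in self.rigid
        }

    def backbone(self, rng: np.random.Generator) -> np.ndarray:
        """One frame of Calpha positions."""
        n, bond = self.n, self.bond
        pos = np.zeros((n, 3))
        rigid_start = {rf: (rf, rl) for rf, rl in self.rigid}
        constraint_start = {i: (i, j, d) for i, j, d in self.constraints}
        i = 1
        while i < n:
            if i in rigid_start:
                rf, rl = rigid_start[i]
                template = self.templates[(rf, rl)]
                rot = random_rotation(rng)
                placed = template @ rot.T
                # connect: first template residue one bond from predecessor
                anchor = pos[i - 1] + bond * _random_unit(rng)
                pos[rf : rl + 1] = placed + (anchor - placed[0])
                i = rl + 1
            elif i - 1 in constraint_start:
                ci, cj, d = constraint_start[i - 1]
                end = pos[ci] + d * _random_unit(rng)
                pos[ci + 1 : cj + 1] = _random_bridge(
                    pos[ci], end, cj - ci, bond, rng
                )
                i = cj + 1
            else:
                pos[i] = pos[i - 1] + bond * _random_unit(rng)
                i += 1
        # rigid segment starting at residue 0
        if 0 in rigid_start:
            rf, rl = rigid_start[0]
            template = self.templates[(rf, rl)]
            rot = random_rotation(rng)
            pos[rf : rl + 1] = template @ rot.T
        return pos


def _sidechain_offsets(
    res_types: list[str], rng: np.random.Generator
) -> list[np.ndarray]:
    """Fixed per-residue offsets of every heavy atom from the Calpha."""
    offsets = []
    for rt in res_types:
        atom_names = HEAVY_ATOM_NAMES[rt]
        off = np.zeros((len(atom_names), 3))
        for k, name in enumerate(atom_names):
            if name == "CA":
                continue
            if name in ("N", "C"):
                off[k] = 1.46 * _random_unit(rng)
            elif name == "O":
                off[k] = 2.2 * _random_unit(rng)
            else:
                r = rng.uniform(1.0, _SIDECHAIN_RADIUS)
                off[k] = r * _random_unit(rng)
        offsets.append(off)
    return offsets


def generate_chain(spec: SyntheticSpec) -> SystemModel:
    """Generate a synthetic single-chain ensemble; pure function of spec."""
    rng = np.random.default_rng(spec.seed)
    sequence = spec.sequence or random_sequence(rng, spec.chain_length)
    # planted stacks require the right residue types
    sequence = list(sequence)
    for ps in spec.planted_stacks:
        sequence[ps.phe_residue - 1] = "F"
        sequence[ps.arg_residue - 1] = "R"
    sequence = "".join(sequence)

    topology = build_protein_topology([sequence], ["A"])
    plan = _ChainPlan(spec, rng)
    offsets = _sidechain_offsets(topology.res_types, rng)

    coords = np.empty((spec.frames, topology.n_atoms, 3))
    for f in range(spec.frames):
        ca = plan.backbone(rng)
        frame = np.empty((topology.n_atoms, 3))
        for ri in range(topology.n_residues):
            a0 = topology.res_atom_start[ri]
            frame[a0 : topology.res_atom_stop[ri]] = ca[ri] + offsets[ri]
        _tighten_planted_contacts(spec, topology, ca, frame, rng)
        _place_planted_stacks(spec, topology, ca, frame, rng)
        coords[f] = frame
    traj = TrajectoryFrameSet(coords)
    return SystemModel(topology, traj, domain_map=spec.domain_map)


def _tighten_planted_contacts(
    spec: SyntheticSpec,
    topology: Topology,
    ca: np.ndarray,
    frame: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Cluster the satellite atoms of planted-contact residues toward each
    other so the pair carries a strong, frame-stable contact count.

    The Calpha atoms stay on the backbone (their separation is already the
    planted distance); every other heavy atom of the two residues is pulled
    toward the partner Calpha, staying within the 2.5 A side-chain radius.
    """
    for pc in spec.planted_contacts:
        i, j = pc.res_i - 1, pc.res_j - 1
        d = float(np.linalg.norm(ca[j] - ca[i]))
        reach = min(2.2, max(d / 2.0 - 0.1, 0.5))
        for ri, rj in ((i, j), (j, i)):
            toward = (ca[rj] - ca[ri]) / max(d, 1e-12)
            atoms = [
                a for a in topology.residue_atoms(ri)
                if topology.names[a] != "CA"
            ]
            for a in atoms:
                frame[a] = (
                    ca[ri] + reach * toward + rng.normal(scale=0.1, size=3)
                )


def _place_planted_stacks(
    spec: SyntheticSpec,
    topology: Topology,
    ca: np.ndarray,
    frame: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Overwrite ring/guanidinium atoms of planted stacks with exact geometry.

    The ring COM is pinned to the Phe Calpha and the guanidinium COM to the
    Arg Calpha; the backbone bridge already fixed their separation.
    """
    for ps in spec.planted_stacks:
        pi, ai = ps.phe_residue - 1, ps.arg_residue - 1
        sep = ca[ai] - ca[pi]
        sep_dir = sep / np.linalg.norm(sep)
        # shift both group centers off the Calpha positions (so the ring
        # carbons and guanidinium CZ do not collide with the CA atoms)
        # without changing the COM-COM separation
        shift = 0.5 * _perpendicular_unit(sep_dir, rng)
        ring, gua = stacked_pair(
            ps.center_distance,
            ps.plane_angle,
            jitter_sd=ps.jitter_sd,
            rng=rng,
            ring_center=ca[pi] + shift,
            separation_dir=sep_dir,
            ring_normal=_random_unit(rng),
        )
        for name, xyz in zip(RING_NAMES, ring):
            frame[topology.find_atom(pi, name)] = xyz
        for name, xyz in zip(GUA_NAMES, gua):
            frame[topology.find_atom(ai, name)] = xyz
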