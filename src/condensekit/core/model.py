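"""Topology, trajectory, and domain-map data model.

Conventions: coordinates in Angstrom, masses in amu, atom indices 0-based,
residue sequence numbers 1-based within their chain. Boxes are orthorhombic
``(Lx, Ly, Lz)`` per frame; the minimum-image convention is applied to
interatomic distances whenever a box is present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from condensekit.core.chemistry import (
    AMINO_ACIDS_3,
    ION_RES,
    WATER_RES,
)


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class Atom:
    """A single atom record."""

    index: int            # 0-based global atom index
    name: str             # PDB atom name
    element: str
    mass: float           # amu

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be > 0, got {self.mass}")


@dataclass(frozen=True)
class Residue:
    """A residue: contiguous atom span within one chain."""

    seq_index: int        # 1-based within chain
    res_type: str
    chain_id: str
    atom_start: int       # inclusive, 0-based
    atom_stop: int        # exclusive

    @property
    def atom_span(self) -> range:
        return range(self.atom_start, self.atom_stop)

    @property
    def n_atoms(self) -> int:
        return self.atom_stop - self.atom_start


@dataclass
class DomainMap:
    """Named 1-based residue ranges, e.g. per-domain segments of a chain."""

    entries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, first, last in self.entries:
            if first > last:
                raise ValueError(f"domain {name}: first ({first}) > last ({last})")
            if first < 1:
                raise ValueError(f"domain {name}: residue numbering is 1-based")

    @property
    def total_length(self) -> int:
        """Maximum residue index covered by any entry."""
        if not self.entries:
            return 0
        return max(last for _, _, last in self.entries)

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def domain_of(self, seq_index: int) -> str | None:
        """Name of the first entry containing ``seq_index``, or None."""
        for name, first, last in self.entries:
            if first <= seq_index <= last:
                return name
        return None

    def range_of(self, name: str) -> tuple[int, int]:
        for entry_name, first, last in self.entries:
            if entry_name == name:
                return first, last
        raise KeyError(f"no domain named {name!r}")


class Topology:
    """Atoms, residues and chains of one system, array-backed."""

    def __init__(
        self,
        names: Sequence[str],
        elements: Sequence[str],
        masses: Sequence[float],
        res_types: Sequence[str],
        res_seq: Sequence[int],
        res_chain: Sequence[str],
        res_atom_counts: Sequence[int],
    ) -> None:
        self.names = list(names)
        self.elements = [e.upper() for e in elements]
        self.masses = np.asarray(masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("all atom masses must be > 0")
        self.res_types = list(res_types)
        self.res_seq = np.asarray(res_seq, dtype=int)
        self.res_chain = list(res_chain)
        counts = np.asarray(res_atom_counts, dtype=int)
        if counts.sum() != len(self.names):
            raise ValueError("residue atom counts do not sum to atom count")
        self.res_atom_start = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.res_atom_stop = np.cumsum(counts)
        # per-atom residue index
        self.atom_resindex = np.repeat(np.arange(len(counts)), counts)
        self.is_heavy = np.array([e != "H" for e in self.elements], dtype=bool)
        self._validate_residue_order()

    def _validate_residue_order(self) -> None:
        seen: dict[str, int] = {}
        for seq, chain in zip(self.res_seq, self.res_chain):
            if chain in seen and seq <= seen[chain]:
                raise ValueError(
                    f"residue seq numbers must be strictly increasing within "
                    f"chain {chain!r}: {seq} after {seen[chain]}"
                )
            seen[chain] = seq

    # -- sizes ------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_residues(self) -> int:
        return len(self.res_types)

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain ids in order of first appearance."""
        out: list[str] = []
        for c in self.res_chain:
            if not out or out[-1] != c:
                if c in out:
                    raise ValueError(f"chain {c!r} is not contiguous")
                out.append(c)
        return out

    # -- object views -----------------------------------------------------
    def atom(self, i: int) -> Atom:
        return Atom(i, self.names[i], self.elements[i], float(self.masses[i]))

    def residue(self, i: int) -> Residue:
        return Residue(
            int(self.res_seq[i]),
            self.res_types[i],
            self.res_chain[i],
            int(self.res_atom_start[i]),
            int(self.res_atom_stop[i]),
        )

    def residues(self) -> Iterator[Residue]:
        for i in range(self.n_residues):
            yield self.residue(i)

    def residue_atoms(self, i: int) -> np.ndarray:
        return np.arange(self.res_atom_start[i], self.res_atom_stop[i])

    def chain_residues(self, chain_id: str) -> np.ndarray:
        return np.flatnonzero(np.array([c == chain_id for c in self.res_chain]))

    def find_atom(self, res_index: int, name: str) -> int | None:
        """Global index of the atom called ``name`` in residue ``res_index``."""
        for a in range(self.res_atom_start[res_index], self.res_atom_stop[res_index]):
            if self.names[a] == name:
                return int(a)
        return None


@dataclass
class TrajectoryFrameSet:
    """Ordered coordinate frames with optional per-frame boxes and times.

    coords: (n_frames, n_atoms, 3) Angstrom.
    box:    (n_frames, 3) orthorhombic lengths in Angstrom, or None.
    times:  (n_frames,) ps, or None.
    """

    coords: np.ndarray
    box: np.ndarray | None = None
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (n_frames, 3)")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def frame_box(self, i: int) -> np.ndarray | None:
        return None if self.box is None else self.box[i]

    def sliced(self, sl: slice) -> "TrajectoryFrameSet":
        return TrajectoryFrameSet(
            self.coords[sl],
            None if self.box is None else self.box[sl],
            None if self.times is None else self.times[sl],
        )

    def extended(self, other: "TrajectoryFrameSet") -> "TrajectoryFrameSet":
        if other.n_atoms != self.n_atoms:
            raise FormatError(
                f"atom count mismatch: {other.n_atoms} vs topology {self.n_atoms}"
            )
        box = None
        if self.box is not None and other.box is not None:
            box = np.vstack([self.box, other.box])
        times = None
        if self.times is not None and other.times is not None:
            times = np.concatenate([self.times, other.times])
        return TrajectoryFrameSet(
            np.vstack([self.coords, other.coords]), box, times
        )


COMPONENTS = ("protein", "water", "Na", "Cl", "other")


def classify_residue(res_type: str) -> str:
    """Map a residue type to its system component."""
    rt = res_type.strip().upper()
    if rt in AMINO_ACIDS_3:
        return "protein"
    if rt in WATER_RES:
        return "water"
    if rt in ION_RES:
        ion = ION_RES[rt]
        return ion if ion in ("Na", "Cl") else "other"
    return "other"


@dataclass
class SystemModel:
    """Topology + trajectory + domain map + component partition."""

    topology: Topology
    trajectory: TrajectoryFrameSet
    domain_map: DomainMap = field(default_factory=DomainMap)
    component_labels: np.ndarray | None = None  # per-residue component string

    def __post_init__(self) -> None:
        if self.trajectory.n_atoms != self.topology.n_atoms:
            raise FormatError(
                f"trajectory has {self.trajectory.n_atoms} atoms but topology "
                f"has {self.topology.n_atoms}"
            )
        if self.component_labels is None:
            labels = [classify_residue(rt) for rt in self.topology.res_types]
            unknown = {
                rt
                for rt, lab in zip(self.topology.res_types, labels)
                if lab == "other"
            }
            if unknown:
                warnings.warn(
                    f"unknown residue types excluded from protein component: "
                    f"{sorted(unknown)}"
                )
            self.component_labels = np.array(labels, dtype=object)
        else:
            self.component_labels = np.asarray(self.component_labels, dtype=object)
            if len(self.component_labels) != self.topology.n_residues:
                raise ValueError("component_labels must have one entry per residue")

    def component_residues(self, component: str) -> np.ndarray:
        return np.flatnonzero(self.component_labels == component)

    def component_atoms(self, component: str) -> np.ndarray:
        res = self.component_residues(component)
        if len(res) == 0:
            return np.array([], dtype=int)
        return np.concatenate(
            [self.topology.residue_atoms(r) for r in res]
        )

    @property
    def protein_residues(self) -> np.ndarray:
        return self.component_residues("protein")

    def with_trajectory(self, traj: TrajectoryFrameSet) -> "SystemModel":
        return SystemModel(
            self.topology, traj, self.domain_map, self.component_labels
        )
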