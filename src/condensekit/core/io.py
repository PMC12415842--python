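"""Readers/writers: multi-model PDB, XTC/DCD trajectories, domain-map TSV.

File parsing is delegated to MDAnalysis; this module adapts its output to
the package data model (Angstrom everywhere, explicit element/mass tables,
component labelling).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

import MDAnalysis as mda
from MDAnalysis.coordinates.memory import MemoryReader

from condensekit.core.chemistry import (
    WATER_MASS,
    WATER_RES,
    element_from_atom_name,
    mass_of_element,
)
from condensekit.core.model import (
    DomainMap,
    FormatError,
    SystemModel,
    Topology,
    TrajectoryFrameSet,
)

_TRAJ_READERS = {
    "xtc": "XTC",
    "dcd": "DCD",
    "pdb": "PDB",
}


def _masses_from_elements(
    elements: list[str], res_types: list[str], atom_resindex: np.ndarray,
    res_atom_counts: np.ndarray,
) -> np.ndarray:
    masses = np.array([mass_of_element(e) for e in elements], dtype=float)
    # A one-particle water residue is a pseudo-particle carrying the whole
    # molecule's mass (relevant for slab mass-density profiles).
    for ri, (rt, cnt) in enumerate(zip(res_types, res_atom_counts)):
        if rt.strip().upper() in WATER_RES and cnt == 1:
            masses[atom_resindex == ri] = WATER_MASS
    return masses


def _read_cryst1(path: Path) -> np.ndarray | None:
    """First CRYST1 record's orthorhombic box lengths, or None.

    Non-orthorhombic cells and the 1x1x1 placeholder are treated as absent.
    """
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                try:
                    lengths = np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    )
                    angles = np.array(
                        [float(line[33:40]), float(line[40:47]), float(line[47:54])]
                    )
                except ValueError:
                    return None
                if np.allclose(lengths, 1.0) or not np.allclose(angles, 90.0):
                    return None
                return lengths
            if line.startswith(("MODEL", "ATOM", "HETATM")):
                break
    return None


def read_structure(path: str | Path, format: str = "pdb") -> SystemModel:
    """Read a (multi-model) PDB file into a SystemModel.

    Each MODEL becomes one trajectory frame; all models must share one atom
    list. Elements are taken from the element column when present, else
    inferred from atom names. Unknown residue types trigger a warning and
    are excluded from the protein component.
    """
    path = Path(path)
    if format.lower() != "pdb":
        raise ValueError(f"read_structure supports pdb, got {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), to_guess=())
        n_frames = len(u.trajectory)
    except Exception as exc:  # MDAnalysis raises assorted errors on bad files
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    atoms = u.atoms
    names = [n.strip() for n in atoms.names]
    res_types = [r.strip().upper() for r in atoms.residues.resnames]
    res_atom_counts = np.array([r.atoms.n_atoms for r in atoms.residues], dtype=int)
    atom_resindex = np.repeat(np.arange(len(res_types)), res_atom_counts)

    atom_res_types = [res_types[i] for i in atom_resindex]
    if hasattr(atoms, "elements") and all(e.strip() for e in atoms.elements):
        elements = [e.strip().upper() for e in atoms.elements]
    else:
        elements = [
            element_from_atom_name(n, rt) for n, rt in zip(names, atom_res_types)
        ]
    masses = _masses_from_elements(elements, res_types, atom_resindex, res_atom_counts)

    try:
        chain_per_res = [
            (c.strip() or "A") for c in atoms.residues.chainIDs
        ]
    except (AttributeError, mda.exceptions.NoDataError):
        chain_per_res = [s.strip() or "A" for s in atoms.residues.segids]

    # renumber 1-based within chain if the file restarts numbering oddly;
    # otherwise keep numbering exactly as written
    res_seq = [int(r) for r in atoms.residues.resids]

    topology = Topology(
        names=names,
        elements=elements,
        masses=masses,
        res_types=res_types,
        res_seq=res_seq,
        res_chain=chain_per_res,
        res_atom_counts=res_atom_counts,
    )

    coords = np.empty((n_frames, topology.n_atoms, 3))
    for i, ts in enumerate(u.trajectory):
        coords[i] = ts.positions
    # PDB carries one CRYST1 for the whole file; MDAnalysis drops it for
    # multi-MODEL files, so pick it up directly.
    box = None
    cell = _read_cryst1(path)
    if cell is not None:
        box = np.tile(cell, (n_frames, 1))
    traj = TrajectoryFrameSet(coords, box=box)
    return SystemModel(topology, traj)


def write_structure(model: SystemModel, path: str | Path) -> None:
    """Write a SystemModel as a multi-model PDB (one MODEL per frame)."""
    path = Path(path)
    top = model.topology
    n_res = top.n_residues
    chain_ids = top.chain_ids
    seg_of_chain = {c: i for i, c in enumerate(chain_ids)}
    u = mda.Universe.empty(
        top.n_atoms,
        n_residues=n_res,
        n_segments=len(chain_ids),
        atom_resindex=top.atom_resindex,
        residue_segindex=[seg_of_chain[c] for c in top.res_chain],
        trajectory=True,
    )
    u.add_TopologyAttr("names", top.names)
    u.add_TopologyAttr("elements", [e.capitalize() for e in top.elements])
    u.add_TopologyAttr("resnames", top.res_types)
    u.add_TopologyAttr("resids", top.res_seq)
    u.add_TopologyAttr("segids", chain_ids)
    u.add_TopologyAttr("chainIDs", [top.res_chain[i] for i in top.atom_resindex])
    u.add_TopologyAttr("occupancies", np.ones(top.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(top.n_atoms))

    traj = model.trajectory
    if traj.box is not None:
        dims = np.hstack([traj.box, np.full((traj.n_frames, 3), 90.0)])
    else:
        dims = None
    u.load_new(traj.coords.astype(np.float32), format=MemoryReader, dimensions=dims)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, n_atoms=top.n_atoms) as w:
            for ts in u.trajectory:
                w.write(u.atoms)


def read_trajectory_frames(
    path: str | Path, format: str, convert_units: bool = True
) -> TrajectoryFrameSet:
    """Read coordinate frames from an XTC/DCD/multi-model-PDB file.

    Coordinates are converted to Angstrom (``convert_units=False`` keeps the
    file's native unit, e.g. nm for XTC — testing hook only).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in _TRAJ_READERS:
        raise ValueError(f"unsupported trajectory format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise FormatError(f"trajectory {path} is empty")
    reader_name = _TRAJ_READERS[fmt]
    reader_cls = getattr(
        getattr(mda.coordinates, reader_name), f"{reader_name}Reader"
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = reader_cls(str(path), convert_units=convert_units)
            frames = []
            boxes: list[np.ndarray] | None = []
            times = []
            for ts in reader:
                frames.append(ts.positions.copy())
                times.append(float(ts.time))
                if boxes is not None and ts.dimensions is not None and np.all(
                    ts.dimensions[:3] > 0
                ):
                    boxes.append(np.array(ts.dimensions[:3], dtype=float))
                else:
                    boxes = None
            reader.close()
    except (OSError, EOFError, ValueError) as exc:
        raise FormatError(f"cannot read trajectory {path}: {exc}") from exc
    if not frames:
        raise FormatError(f"trajectory {path} contains no frames")
    return TrajectoryFrameSet(
        np.array(frames, dtype=float),
        box=np.array(boxes) if boxes else None,
        times=np.array(times),
    )


def attach_trajectory(
    model: SystemModel, path: str | Path, format: str,
    replace: bool = False,
) -> SystemModel:
    """Append (or replace with) frames read from a trajectory file.

    The frame atom count must equal the topology atom count.
    """
    frames = read_trajectory_frames(path, format)
    if frames.n_atoms != model.topology.n_atoms:
        raise FormatError(
            f"trajectory atom count {frames.n_atoms} != topology atom count "
            f"{model.topology.n_atoms}"
        )
    new = frames if replace else model.trajectory.extended(frames)
    return model.with_trajectory(new)


def write_trajectory(model: SystemModel, path: str | Path, format: str) -> None:
    """Write the model's frames as XTC or DCD (positions handed over in A)."""
    fmt = format.lower()
    if fmt not in ("xtc", "dcd"):
        raise ValueError(f"unsupported trajectory format {format!r}")
    top = model.topology
    traj = model.trajectory
    u = mda.Universe.empty(top.n_atoms, trajectory=True)
    if traj.box is not None:
        dims = np.hstack([traj.box, np.full((traj.n_frames, 3), 90.0)])
    else:
        dims = None
    u.load_new(traj.coords.astype(np.float32), format=MemoryReader, dimensions=dims)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=top.n_atoms) as w:
            for ts in u.trajectory:
                w.write(u.atoms)


def read_domain_map(path: str | Path) -> DomainMap:
    """Read a 3-column TSV domain map: name <TAB> first <TAB> last."""
    entries: list[tuple[str, int, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(
                f"{path}:{lineno}: expected 3 tab-separated columns, "
                f"got {len(parts)}"
            )
        name, first, last = parts
        try:
            entries.append((name.strip(), int(first), int(last)))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return DomainMap(entries)


def write_domain_map(domain_map: DomainMap, path: str | Path) -> None:
    lines = ["#name\tfirst\tlast"]
    for name, first, last in domain_map.entries:
        lines.append(f"{name}\t{first}\t{last}")
    Path(path).write_text("\n".join(lines) + "\n")
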