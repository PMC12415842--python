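"""Summed heavy-atom residue-pair contact statistics.

A contact exists between two heavy atoms of different residues when their
(minimum-image) distance is strictly below the cutoff (default 4.5 A). The
residue-pair count is the *number of contacting heavy-atom pairs*, not a
binary occupancy; same-chain residue pairs separated by at most the
proximity-exclusion window (default |i-j| <= 4) contribute nothing.
Residue-pair counts are accumulated on sequence-position slots, so chains
of a multi-chain system fold onto one LxL matrix with separate
intramolecular and intermolecular channels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from MDAnalysis.lib.distances import self_capped_distance

from condensekit.core.chemistry import THREE_TO_ONE
from condensekit.core.model import SystemModel


@dataclass(frozen=True)
class ContactParams:
    cutoff: float = 4.5                # Angstrom, strict '<'
    proximity_exclusion: int = 4       # exclude same-chain |i-j| <= this
    heavy_only: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.proximity_exclusion < 0:
            raise ValueError("proximity_exclusion must be >= 0")


@dataclass
class ContactMatrix:
    """Residue-position x residue-position mean contact counts per frame."""

    intra: np.ndarray                  # (L, L), upper triangular (i <= j)
    inter: np.ndarray
    n_frames: int
    n_chains: int
    params: ContactParams
    res_types: list[str] = field(default_factory=list)  # per position

    @property
    def total(self) -> np.ndarray:
        return self.intra + self.inter

    @property
    def n_positions(self) -> int:
        return self.intra.shape[0]

    def channel(self, name: str) -> np.ndarray:
        if name not in ("intra", "inter", "total"):
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)

    def per_chain(self, name: str = "total") -> np.ndarray:
        """Channel averaged over chains instead of summed across them."""
        return self.channel(name) / self.n_chains

    def to_tsv(self, path: str | Path, channel: str = "total") -> None:
        labels = [
            f"{i + 1}{THREE_TO_ONE.get(rt, 'X') if self.res_types else ''}"
            for i, rt in enumerate(
                self.res_types or ["UNK"] * self.n_positions
            )
        ]
        pd.DataFrame(self.channel(channel), index=labels, columns=labels).to_csv(
            path, sep="\t", float_format="%.6g"
        )


def _protein_slots(model: SystemModel):
    """Per protein residue: (chain index, 0-based position); validates that
    all chains share one length."""
    top = model.topology
    prot = model.protein_residues
    chains = sorted({top.res_chain[r] for r in prot})
    chain_idx = {c: k for k, c in enumerate(chains)}
    lengths = {}
    for r in prot:
        c = top.res_chain[r]
        lengths[c] = max(lengths.get(c, 0), int(top.res_seq[r]))
    L = max(lengths.values())
    if len(set(lengths.values())) > 1:
        raise ValueError(
            "multi-chain contact analysis requires equal-length chains; "
            f"got lengths {sorted(set(lengths.values()))}"
        )
    slots = {
        int(r): (chain_idx[top.res_chain[r]], int(top.res_seq[r]) - 1)
        for r in prot
    }
    return slots, len(chains), L


def frame_contacts(
    model: SystemModel, frame: int, params: ContactParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Integer contact-count matrices (intra, inter) for one frame."""
    params = params or ContactParams()
    top = model.topology
    if not 0 <= frame < model.trajectory.n_frames:
        raise IndexError(f"frame {frame} out of range")
    slots, n_chains, L = _protein_slots(model)
    prot_res = np.array(sorted(slots))
    atom_idx = np.concatenate(
        [top.residue_atoms(r) for r in prot_res]
    ) if len(prot_res) else np.array([], dtype=int)
    if params.heavy_only:
        atom_idx = atom_idx[top.is_heavy[atom_idx]]

    intra = np.zeros((L, L))
    inter = np.zeros((L, L))
    if len(atom_idx) < 2:
        return intra, inter

    full = model.trajectory.frame(frame)
    pos = full[atom_idx].astype(np.float32)
    box = model.trajectory.frame_box(frame)
    mda_box = (
        np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float32)
        if box is not None
        else None
    )
    # candidate search in float32 with headroom, strict cutoff re-checked in
    # float64 so results match an exhaustive double-precision oracle exactly
    pairs, _ = self_capped_distance(
        pos, max_cutoff=params.cutoff * 1.001 + 1e-3, box=mda_box,
        return_distances=True,
    )
    if len(pairs):
        disp = (
            full[atom_idx[pairs[:, 0]]] - full[atom_idx[pairs[:, 1]]]
        )
        if box is not None:
            disp = disp - box * np.round(disp / box)
        d64 = np.linalg.norm(disp, axis=1)
        pairs = pairs[d64 < params.cutoff]  # strict inequality at the cutoff

    res_of = top.atom_resindex[atom_idx]
    ra = res_of[pairs[:, 0]]
    rb = res_of[pairs[:, 1]]
    keep = ra != rb
    ra, rb = ra[keep], rb[keep]
    for a, b in zip(ra, rb):
        ca, sa = slots[int(a)]
        cb, sb = slots[int(b)]
        i, j = min(sa, sb), max(sa, sb)
        if ca == cb:
            if abs(sa - sb) <= params.proximity_exclusion:
                continue
            intra[i, j] += 1
        else:
            inter[i, j] += 1
    return intra, inter


def ensemble_contact_map(
    model: SystemModel,
    frame_range: slice | None = None,
    params: ContactParams | None = None,
) -> ContactMatrix:
    """Mean per-frame contact matrix over a frame range."""
    params = params or ContactParams()
    frames = range(model.trajectory.n_frames)[frame_range or slice(None)]
    if len(frames) == 0:
        raise ValueError("empty frame range")
    slots, n_chains, L = _protein_slots(model)
    intra = np.zeros((L, L))
    inter = np.zeros((L, L))
    for f in frames:
        fi, fe = frame_contacts(model, f, params)
        intra += fi
        inter += fe
    intra /= len(frames)
    inter /= len(frames)

    top = model.topology
    res_types = [""] * L
    for r, (c, s) in slots.items():
        res_types[s] = top.res_types[r]
    return ContactMatrix(
        intra, inter, len(frames), n_chains, params, res_types
    )


def position_profile(
    matrix: ContactMatrix | np.ndarray, channel: str = "total"
) -> np.ndarray:
    """Per-position 1-D contact sums: profile(i) = sum_j counts(i, j)."""
    counts = (
        matrix.channel(channel) if isinstance(matrix, ContactMatrix) else matrix
    )
    # each pair contributes to both endpoints (a diagonal cell counts twice)
    return (counts + counts.T).sum(axis=1)


def domain_block_map(
    matrix: ContactMatrix, domain_map, channel: str = "total"
) -> pd.DataFrame:
    """Aggregate the contact matrix into domain x domain blocks.

    Positions outside every domain fall into an implicit 'unassigned' block
    (with a warning)."""
    import warnings

    counts = matrix.channel(channel)
    L = matrix.n_positions
    block_of = []
    names = list(domain_map.names)
    for i in range(L):
        d = domain_map.domain_of(i + 1)
        if d is None:
            d = "unassigned"
        block_of.append(d)
    if "unassigned" in block_of:
        warnings.warn("positions outside all domains assigned to 'unassigned'")
        if "unassigned" not in names:
            names = names + ["unassigned"]
    idx = {n: k for k, n in enumerate(names)}
    out = np.zeros((len(names), len(names)))
    for i in range(L):
        for j in range(i, L):
            if counts[i, j] == 0:
                continue
            a, b = sorted((idx[block_of[i]], idx[block_of[j]]))
            out[a, b] += counts[i, j]
    return pd.DataFrame(out, index=names, columns=names)


ALL_TYPE_PAIRS = [
    "".join(sorted(p))
    for p in itertools.combinations_with_replacement(sorted(THREE_TO_ONE.values()), 2)
]


@dataclass
class PairRatioTable:
    """Residue-type pair contact ratios and per-type normalized contacts."""

    rows: pd.DataFrame      # columns: pair, contact_ratio, rank
    per_type: pd.DataFrame  # columns: res_type, mean_contacts, aa_count, normalized

    def ratio_vector(self) -> np.ndarray:
        """Ratios over the 210 unordered type-pair bins in canonical order."""
        lookup = dict(zip(self.rows["pair"], self.rows["contact_ratio"]))
        return np.array([lookup.get(p, 0.0) for p in ALL_TYPE_PAIRS])


def pair_ratio_table(
    matrix: ContactMatrix, sequence: list[str] | None = None,
    channel: str = "total",
) -> PairRatioTable:
    """Contact ratios per unordered residue-type pair, ranked descending.

    Ratios divide each type-pair's summed contacts by the total; per-type
    normalized contacts divide the per-type sum by that type's count in the
    sequence.
    """
    res_types = sequence if sequence is not None else matrix.res_types
    if len(res_types) != matrix.n_positions:
        raise ValueError("sequence inconsistent with contact matrix size")
    one = [THREE_TO_ONE.get(rt, rt) for rt in res_types]
    counts = matrix.channel(channel)

    pair_sum: dict[str, float] = {p: 0.0 for p in ALL_TYPE_PAIRS}
    type_sum: dict[str, float] = {t: 0.0 for t in set(THREE_TO_ONE.values())}
    for i in range(matrix.n_positions):
        for j in range(i, matrix.n_positions):
            c = counts[i, j]
            if c == 0:
                continue
            key = "".join(sorted((one[i], one[j])))
            pair_sum[key] += c
            type_sum[one[i]] += c
            type_sum[one[j]] += c
    total = sum(pair_sum.values())
    ratios = {
        p: (v / total if total > 0 else 0.0) for p, v in pair_sum.items()
    }
    rows = pd.DataFrame(
        {"pair": ALL_TYPE_PAIRS, "contact_ratio": [ratios[p] for p in ALL_TYPE_PAIRS]}
    ).sort_values("contact_ratio", ascending=False, kind="stable")
    rows["rank"] = np.arange(1, len(rows) + 1)
    rows = rows.reset_index(drop=True)

    aa_count = {t: one.count(t) for t in sorted(set(THREE_TO_ONE.values()))}
    per_type = pd.DataFrame(
        {
            "res_type": list(aa_count),
            "mean_contacts": [type_sum[t] for t in aa_count],
            "aa_count": [aa_count[t] for t in aa_count],
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        per_type["normalized"] = np.where(
            per_type["aa_count"] > 0,
            per_type["mean_contacts"] / per_type["aa_count"],
            0.0,
        )
    return PairRatioTable(rows, per_type)


def contact_correlation(
    a: PairRatioTable | np.ndarray, b: PairRatioTable | np.ndarray
) -> tuple[float, float]:
    """Pearson r and fitted slope between two paired contact statistics.

    Bins where both values are zero are dropped (structural zeros would
    inflate the correlation)."""
    xa = a.ratio_vector() if isinstance(a, PairRatioTable) else np.asarray(a, float)
    xb = b.ratio_vector() if isinstance(b, PairRatioTable) else np.asarray(b, float)
    if xa.shape != xb.shape:
        raise ValueError("inputs must have the same bin structure")
    keep = ~((xa == 0) & (xb == 0))
    xa, xb = xa[keep], xb[keep]
    if len(xa) < 3:
        raise ValueError("fewer than 3 nonzero pairs; correlation undefined")
    r = float(np.corrcoef(xa, xb)[0, 1])
    slope = float(np.polyfit(xa, xb, 1)[0])
    return r, slope


def contact_timeseries(
    model: SystemModel, params: ContactParams | None = None, window: int = 1
) -> pd.DataFrame:
    """Per-frame total contact counts with a trailing running mean."""
    params = params or ContactParams()
    totals = []
    for f in range(model.trajectory.n_frames):
        intra, inter = frame_contacts(model, f, params)
        totals.append(intra.sum() + inter.sum())
    s = pd.Series(totals, name="total_contacts")
    return pd.DataFrame(
        {
            "frame": np.arange(len(totals)),
            "total_contacts": s,
            "running_mean": s.rolling(window, min_periods=1).mean(),
        }
    )
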