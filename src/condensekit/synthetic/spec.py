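"""Declarative specification of synthetic systems."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from condensekit.core.model import DomainMap


@dataclass
class PlantedContact:
    """Force residues (1-based) res_i and res_j to a Calpha separation."""

    res_i: int
    res_j: int
    target_distance: float  # Angstrom

    def __post_init__(self) -> None:
        if self.target_distance <= 0:
            raise ValueError("target_distance must be > 0")
        if self.res_i == self.res_j:
            raise ValueError("planted contact needs two distinct residues")


@dataclass
class PlantedStack:
    """Place a Phe/Arg pair with controlled plane geometry."""

    phe_residue: int
    arg_residue: int
    center_distance: float  # Angstrom between group centers of mass
    plane_angle: float      # degrees between plane normals, in [0, 90]
    jitter_sd: float = 0.0  # Angstrom, per-atom Gaussian jitter

    def __post_init__(self) -> None:
        if self.center_distance <= 0:
            raise ValueError("center_distance must be > 0")
        if not 0.0 <= self.plane_angle <= 90.0:
            raise ValueError("plane_angle must be in [0, 90] degrees")


@dataclass
class SlabSpec:
    """Slab geometry and particle content for condensed-phase systems."""

    box: tuple[float, float, float]           # Angstrom
    dense_z_extent: float                     # Angstrom, centered at Lz/2
    n_water: int = 0
    n_na: int = 0
    n_cl: int = 0
    dense_excess_na: float = 0.0              # mM above uniform, inside slab
    dense_excess_cl: float = 0.0

    def __post_init__(self) -> None:
        if self.dense_z_extent > self.box[2]:
            raise ValueError("dense-region extent exceeds box z-length")


@dataclass
class SyntheticSpec:
    """Everything needed to generate a reproducible synthetic system."""

    seed: int
    chain_length: int
    n_chains: int = 1
    sequence: str | None = None               # one-letter codes; random if None
    domain_map: DomainMap = field(default_factory=DomainMap)
    folded_domains: tuple[str, ...] = ()      # domain-map entries kept rigid
    bond_length: float = 3.8                  # Angstrom, Calpha-Calpha
    planted_contacts: list[PlantedContact] = field(default_factory=list)
    planted_stacks: list[PlantedStack] = field(default_factory=list)
    slab: SlabSpec | None = None
    frames: int = 1

    def __post_init__(self) -> None:
        if self.chain_length < 2:
            raise ValueError("chain_length must be >= 2")
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.chain_length:
            raise ValueError("sequence length must equal chain_length")

    # -- (de)serialization -------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "domain_map" in d and not isinstance(d["domain_map"], DomainMap):
            d["domain_map"] = DomainMap(
                [(str(n), int(a), int(b)) for n, a, b in d["domain_map"]]
            )
        if "folded_domains" in d:
            d["folded_domains"] = tuple(d["folded_domains"])
        if "planted_contacts" in d:
            d["planted_contacts"] = [
                pc if isinstance(pc, PlantedContact) else PlantedContact(**pc)
                for pc in d["planted_contacts"]
            ]
        if "planted_stacks" in d:
            d["planted_stacks"] = [
                ps if isinstance(ps, PlantedStack) else PlantedStack(**ps)
                for ps in d["planted_stacks"]
            ]
        if "slab" in d and d["slab"] is not None and not isinstance(d["slab"], SlabSpec):
            slab = dict(d["slab"])
            slab["box"] = tuple(float(x) for x in slab["box"])
            d["slab"] = SlabSpec(**slab)
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticSpec":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))
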