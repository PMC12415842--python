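"""Chemical reference tables: amino-acid heavy-atom layouts, element masses, charges.

All lengths in this package are Angstrom; masses are amu.
"""

from __future__ import annotations

# Standard atomic weights (amu), CODATA/IUPAC abridged.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "ZN": 65.38,
    "MG": 24.305,
    "CA": 40.078,
    "FE": 55.845,
}

#: Mass of a whole water molecule; pseudo-water particles carry this mass.
WATER_MASS = 18.015

AMINO_ACIDS_3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# Standard PDB heavy-atom names per residue type (backbone N, CA, C, O first).
_BACKBONE = ["N", "CA", "C", "O"]
HEAVY_ATOM_NAMES: dict[str, list[str]] = {
    "GLY": _BACKBONE,
    "ALA": _BACKBONE + ["CB"],
    "SER": _BACKBONE + ["CB", "OG"],
    "CYS": _BACKBONE + ["CB", "SG"],
    "THR": _BACKBONE + ["CB", "OG1", "CG2"],
    "VAL": _BACKBONE + ["CB", "CG1", "CG2"],
    "PRO": _BACKBONE + ["CB", "CG", "CD"],
    "LEU": _BACKBONE + ["CB", "CG", "CD1", "CD2"],
    "ILE": _BACKBONE + ["CB", "CG1", "CG2", "CD1"],
    "ASN": _BACKBONE + ["CB", "CG", "OD1", "ND2"],
    "ASP": _BACKBONE + ["CB", "CG", "OD1", "OD2"],
    "MET": _BACKBONE + ["CB", "CG", "SD", "CE"],
    "GLN": _BACKBONE + ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": _BACKBONE + ["CB", "CG", "CD", "OE1", "OE2"],
    "LYS": _BACKBONE + ["CB", "CG", "CD", "CE", "NZ"],
    "HIS": _BACKBONE + ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "PHE": _BACKBONE + ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "ARG": _BACKBONE + ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "TYR": _BACKBONE + ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "TRP": _BACKBONE + ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
}

#: Side-chain heavy-atom group defining the phenyl ring plane of Phe.
PHENYL_RING_ATOMS = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
#: Side-chain heavy-atom group defining the guanidinium plane of Arg.
GUANIDINIUM_ATOMS = ["CZ", "NE", "NH1", "NH2"]

CATIONIC_RES = {"ARG", "LYS"}   # His optional, handled by callers
ANIONIC_RES = {"ASP", "GLU"}

WATER_RES = {"HOH", "WAT", "SOL", "TIP3"}
ION_RES = {"NA": "Na", "SOD": "Na", "CL": "Cl", "CLA": "Cl", "ZN": "Zn"}

_TWO_LETTER_ELEMENTS = {"NA", "CL", "ZN", "MG", "FE", "BR", "MN", "CU", "SE"}


def element_from_atom_name(name: str, res_type: str | None = None) -> str:
    """Infer the element from a PDB atom name when the element column is blank.

    Ion and water residue names take precedence over the name heuristic so
    that e.g. the sodium atom ``NA`` is not read as nitrogen.
    """
    if res_type is not None:
        rt = res_type.strip().upper()
        if rt in ION_RES:
            return ION_RES[rt].upper()
        if rt in WATER_RES and name.strip().upper().startswith("O"):
            return "O"
    stripped = name.strip().upper().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if stripped[:2] in _TWO_LETTER_ELEMENTS and res_type is None:
        return stripped[:2]
    return stripped[0]


def mass_of_element(element: str) -> float:
    key = element.strip().upper()
    if key not in ELEMENT_MASSES:
        raise KeyError(f"no mass tabulated for element {element!r}")
    return ELEMENT_MASSES[key]


def heavy_atom_count(res_type: str) -> int:
    return len(HEAVY_ATOM_NAMES[res_type])
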