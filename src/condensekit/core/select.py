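"""Tiny atom-selection language.

A query is a comma-separated list of clauses, all of which must hold
(logical AND). Clauses:

    heavy                   non-hydrogen atoms
    protein | water | ions  component filters
    chain <id>
    domain <name>           residues in the named domain-map range
    res_type <AAA>          three-letter residue type
    resid <a>:<b>           1-based residue sequence range (inclusive)
    name <atom name>

Example: ``"domain RRM, heavy"``.
"""

from __future__ import annotations

import warnings

import numpy as np

from condensekit.core.model import SystemModel


class SelectionError(ValueError):
    pass


def select(model: SystemModel, query: str) -> np.ndarray:
    """Resolve a query to a sorted array of 0-based atom indices."""
    top = model.topology
    mask = np.ones(top.n_atoms, dtype=bool)
    res_of_atom = top.atom_resindex

    for raw in query.split(","):
        clause = raw.strip()
        if not clause:
            continue
        parts = clause.split()
        key = parts[0].lower()
        if key == "heavy" and len(parts) == 1:
            mask &= top.is_heavy
        elif key in ("protein", "water") and len(parts) == 1:
            res_mask = model.component_labels == key
            mask &= res_mask[res_of_atom]
        elif key == "ions" and len(parts) == 1:
            res_mask = np.isin(model.component_labels, ["Na", "Cl"])
            mask &= res_mask[res_of_atom]
        elif key == "chain" and len(parts) == 2:
            if parts[1] not in top.chain_ids:
                raise SelectionError(f"no chain {parts[1]!r}")
            res_mask = np.array([c == parts[1] for c in top.res_chain])
            mask &= res_mask[res_of_atom]
        elif key == "domain" and len(parts) == 2:
            first, last = model.domain_map.range_of(parts[1])
            res_mask = (top.res_seq >= first) & (top.res_seq <= last)
            mask &= res_mask[res_of_atom]
        elif key == "res_type" and len(parts) == 2:
            res_mask = np.array(
                [rt == parts[1].upper() for rt in top.res_types]
            )
            mask &= res_mask[res_of_atom]
        elif key == "resid" and len(parts) == 2:
            try:
                a, b = (int(x) for x in parts[1].split(":"))
            except ValueError as exc:
                raise SelectionError(f"bad resid range {parts[1]!r}") from exc
            res_mask = (top.res_seq >= a) & (top.res_seq <= b)
            mask &= res_mask[res_of_atom]
        elif key == "name" and len(parts) == 2:
            mask &= np.array([n == parts[1] for n in top.names])
        else:
            raise SelectionError(f"cannot parse clause {clause!r}")

    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        warnings.warn(f"selection {query!r} matched no atoms")
    return idx
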