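"""A small declarative atom-selection language.

Selections are conjunctions of clauses joined by ``&``. Five clause kinds
cover every selection the analyses need::

    name=CA            name=N,CA,C,O         (atom-name list)
    res_name=SDP,CHL                         (residue-name list)
    element=P,O                              (element list)
    chain=A                                  (chain list)
    res_id in [817,827]    res_id=820        (inclusive range / list)

Matching is exact and case-sensitive for names, case-insensitive for
elements. An expression that matches nothing returns an empty set; the
caller decides whether that is an error.
"""
from __future__ import annotations

import re
from typing import Union

import numpy as np

from .core import Topology

__all__ = ["select"]

_RANGE_RE = re.compile(r"^res_id\s+in\s+\[\s*(-?\d+)\s*,\s*(-?\d+)\s*\]$")
_EQ_RE = re.compile(r"^(name|res_name|element|chain|res_id)\s*=\s*(\S.*)$")


def _clause_mask(topology: Topology, clause: str) -> np.ndarray:
    clause = clause.strip()
    m = _RANGE_RE.match(clause)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if lo > hi:
            raise ValueError(f"malformed selection clause (empty range): '{clause}'")
        res_ids = np.array([a.res_id for a in topology.atoms])
        return (res_ids >= lo) & (res_ids <= hi)
    m = _EQ_RE.match(clause)
    if not m:
        raise ValueError(f"malformed selection clause: '{clause}'")
    key, raw = m.group(1), m.group(2)
    values = [v.strip() for v in raw.split(",") if v.strip()]
    if not values:
        raise ValueError(f"malformed selection clause (no values): '{clause}'")
    if key == "res_id":
        try:
            wanted = {int(v) for v in values}
        except ValueError:
            raise ValueError(f"malformed selection clause (non-integer res_id): '{clause}'")
        attr = np.array([a.res_id for a in topology.atoms])
        return np.isin(attr, list(wanted))
    getter = {
        "name": lambda a: a.name,
        "res_name": lambda a: a.res_name,
        "chain": lambda a: a.chain,
        "element": lambda a: a.element.upper(),
    }[key]
    if key == "element":
        values = [v.upper() for v in values]
    attr = np.array([getter(a) for a in topology.atoms])
    return np.isin(attr, values)


def select(topology: Topology, expr: Union[str, np.ndarray, list]) -> np.ndarray:
    """Evaluate a selection expression, returning sorted unique atom indices.

    An already-materialized index array is passed through (validated),
    so every API taking a selection accepts either form.
    """
    if not isinstance(expr, str):
        idx = np.unique(np.asarray(expr, dtype=int))
        if idx.size and (idx[0] < 0 or idx[-1] >= topology.n_atoms):
            raise ValueError("selection indices out of range")
        return idx
    clauses = [c for c in expr.split("&")]
    if not any(c.strip() for c in clauses):
        raise ValueError(f"malformed selection expression: '{expr}'")
    mask = np.ones(topology.n_atoms, dtype=bool)
    for clause in clauses:
        mask &= _clause_mask(topology, clause)
    return np.flatnonzero(mask)
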