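"""Atom-selection resolution shared by the structure/dynamics/solvation layers.

A selection is one of:

* ``None`` — every atom;
* an integer array/sequence — explicit 0-based atom indices;
* a dict with any of the keys ``species``, ``element``, ``atom_in_template``
  (resolved through a :class:`~liqprop.sysmodel.SystemMap`) and ``type_id``
  (resolved against the frame's dump type column); multiple keys AND together.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .sysmodel import SystemMap
from .trajio import Frame

Selection = Union[None, dict, np.ndarray, list, tuple]


def selection_label(sel: Selection) -> str:
    """Human-readable label used in result objects."""
    if sel is None:
        return "all"
    if isinstance(sel, dict):
        return ",".join(f"{k}={v}" for k, v in sorted(sel.items()))
    return f"indices[{len(sel)}]"


def resolve_selection(
    sel: Selection,
    n_atoms: int,
    frame: Optional[Frame] = None,
    system_map: Optional[SystemMap] = None,
) -> np.ndarray:
    """Resolve a selection to a sorted array of 0-based atom indices."""
    if sel is None:
        return np.arange(n_atoms)
    if isinstance(sel, dict):
        unknown = set(sel) - {"species", "element", "atom_in_template", "type_id"}
        if unknown:
            raise ValueError(f"unknown selection keys: {sorted(unknown)}")
        mask = np.ones(n_atoms, dtype=bool)
        map_keys = {"species", "element", "atom_in_template"} & set(sel)
        if map_keys:
            if system_map is None:
                raise ValueError(
                    f"selection keys {sorted(map_keys)} require a system map"
                )
            idx = system_map.select(
                species=sel.get("species"),
                element=sel.get("element"),
                atom_in_template=sel.get("atom_in_template"),
            )
            m = np.zeros(n_atoms, dtype=bool)
            m[idx] = True
            mask &= m
        if "type_id" in sel:
            if frame is None:
                raise ValueError("type_id selections require a frame")
            mask &= frame.types == sel["type_id"]
        out = np.flatnonzero(mask)
    else:
        out = np.asarray(sel, dtype=np.int64)
        if out.size and (out.min() < 0 or out.max() >= n_atoms):
            raise ValueError("explicit atom indices out of range")
        out = np.unique(out)
    if out.size == 0:
        raise ValueError(f"selection {selection_label(sel)!r} matches no atoms")
    return out
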