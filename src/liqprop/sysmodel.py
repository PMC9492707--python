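"""Species templates, force-field payloads, and the atom->molecule->species map.

A liquid-solution system is described as an ordered list of species
templates (one per distinct molecule or ion) plus a molecule count per
species.  Atoms are laid out in deterministic blocks: species in the given
order, molecules of a species consecutive, atoms within a molecule in
template order.  All indices are 0-based internally; 1-based ids appear only
in the data file, whose format requires them.

The force-field document schema used here (``Masses/Charges/Nonbond/Bonds/
Angles/Dihedrals/Impropers`` with explicit per-term index tuples) is this
package's own JSON dialect; see ``docs/methods.md``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ValidationError
from .trajio import BoxBounds

CHARGE_TOL = 1e-6


@dataclass
class BondedTerm:
    """One bonded interaction: atom index tuple + coefficient row."""

    atoms: Tuple[int, ...]
    coeffs: Tuple[float, ...]


@dataclass
class SpeciesTemplate:
    """Per-species topology and force-field payload.

    ``masses``, ``charges``, ``elements`` and ``nonbond`` are per *atom* (the
    writer dedups identical (mass, nonbond) rows into shared atom types).
    """

    name: str
    elements: List[str]
    masses: List[float]
    charges: List[float]
    net_charge: float = 0.0
    nonbond: Optional[List[Tuple[float, ...]]] = None
    bonds: List[BondedTerm] = field(default_factory=list)
    angles: List[BondedTerm] = field(default_factory=list)
    dihedrals: List[BondedTerm] = field(default_factory=list)
    impropers: List[BondedTerm] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.elements)
        if not (len(self.masses) == len(self.charges) == n):
            raise ValidationError(
                f"species {self.name!r}: elements/masses/charges length mismatch"
            )
        if self.nonbond is not None and len(self.nonbond) != n:
            raise ValidationError(f"species {self.name!r}: nonbond rows != atom count")
        for cls_name in ("bonds", "angles", "dihedrals", "impropers"):
            for term in getattr(self, cls_name):
                if any(i < 0 or i >= n for i in term.atoms):
                    raise ValidationError(
                        f"species {self.name!r}: {cls_name} index out of range: {term.atoms}"
                    )
        residual = sum(self.charges) - self.net_charge
        if abs(residual) > CHARGE_TOL:
            raise ValidationError(
                f"species {self.name!r}: charges sum to {sum(self.charges):.8f}, "
                f"declared net {self.net_charge:.8f} (residual {residual:.2e})"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def load_ff_spec(doc: Union[dict, str, Path]) -> SpeciesTemplate:
    """Build a validated :class:`SpeciesTemplate` from a force-field document.

    `doc` is a dict or a path to a JSON file with keys ``name``, ``Elements``,
    ``Masses``, ``Charges`` and optionally ``NetCharge``, ``Nonbond``,
    ``Bonds``, ``Angles``, ``Dihedrals``, ``Impropers``.  Each bonded entry is
    ``{"atoms": [...0-based...], "coeffs": [...]}``.  Missing coefficient
    classes are allowed (an ion has no bonded terms).
    """
    if not isinstance(doc, dict):
        with open(doc) as fh:
            doc = json.load(fh)
    try:
        kwargs = dict(
            name=doc["name"],
            elements=list(doc["Elements"]),
            masses=[float(m) for m in doc["Masses"]],
            charges=[float(q) for q in doc["Charges"]],
            net_charge=float(doc.get("NetCharge", 0.0)),
        )
    except KeyError as exc:
        raise ValidationError(f"force-field document missing key {exc}") from None
    if "Nonbond" in doc:
        kwargs["nonbond"] = [tuple(float(v) for v in row) for row in doc["Nonbond"]]
    for key, attr in (
        ("Bonds", "bonds"),
        ("Angles", "angles"),
        ("Dihedrals", "dihedrals"),
        ("Impropers", "impropers"),
    ):
        if key in doc:
            kwargs[attr] = [
                BondedTerm(
                    atoms=tuple(int(i) for i in term["atoms"]),
                    coeffs=tuple(float(v) for v in term["coeffs"]),
                )
                for term in doc[key]
            ]
    return SpeciesTemplate(**kwargs)


@dataclass
class SystemMap:
    """Deterministic atom -> (species, molecule, atom-in-template) assignment."""

    species: List[SpeciesTemplate]
    counts: List[int]
    species_index: np.ndarray = field(init=False)
    molecule_index: np.ndarray = field(init=False)
    atom_in_template: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species list must not be empty")
        if len(self.counts) != len(self.species):
            raise ValueError("species and counts lengths differ")
        if any(c <= 0 for c in self.counts):
            raise ValueError("all species counts must be positive")
        sp_idx: List[int] = []
        mol_idx: List[int] = []
        at_idx: List[int] = []
        mol = 0
        for s, (tmpl, count) in enumerate(zip(self.species, self.counts)):
            for _ in range(count):
                sp_idx.extend([s] * tmpl.n_atoms)
                mol_idx.extend([mol] * tmpl.n_atoms)
                at_idx.extend(range(tmpl.n_atoms))
                mol += 1
        self.species_index = np.array(sp_idx, dtype=np.int64)
        self.molecule_index = np.array(mol_idx, dtype=np.int64)
        self.atom_in_template = np.array(at_idx, dtype=np.int64)

    @property
    def n_atoms(self) -> int:
        return len(self.species_index)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_index[-1]) + 1

    @property
    def elements(self) -> np.ndarray:
        return np.array(
            [
                self.species[s].elements[a]
                for s, a in zip(self.species_index, self.atom_in_template)
            ]
        )

    @property
    def masses(self) -> np.ndarray:
        return np.array(
            [
                self.species[s].masses[a]
                for s, a in zip(self.species_index, self.atom_in_template)
            ]
        )

    @property
    def charges(self) -> np.ndarray:
        return np.array(
            [
                self.species[s].charges[a]
                for s, a in zip(self.species_index, self.atom_in_template)
            ]
        )

    def species_name(self, species_index: int) -> str:
        return self.species[species_index].name

    def molecules_of(self, species: Union[int, str]) -> List[np.ndarray]:
        """Atom-index arrays, one per molecule of the given species."""
        if isinstance(species, str):
            names = [t.name for t in self.species]
            species = names.index(species)
        mask = self.species_index == species
        mols = np.unique(self.molecule_index[mask])
        return [np.flatnonzero(self.molecule_index == m) for m in mols]

    def select(
        self,
        species: Optional[str] = None,
        element: Optional[str] = None,
        atom_in_template: Optional[int] = None,
    ) -> np.ndarray:
        """Atom indices matching all given predicates (AND semantics)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if species is not None:
            names = [t.name for t in self.species]
            if species not in names:
                raise ValueError(f"unknown species {species!r}; have {names}")
            mask &= self.species_index == names.index(species)
        if element is not None:
            mask &= self.elements == element
        if atom_in_template is not None:
            mask &= self.atom_in_template == atom_in_template
        return np.flatnonzero(mask)


def build_system_map(
    species: Sequence[SpeciesTemplate], counts: Sequence[int]
) -> SystemMap:
    """Block-layout system map: species in order, molecules consecutive."""
    return SystemMap(species=list(species), counts=list(counts))


# ---------------------------------------------------------------------------
# data-file writing (atom_style full)
# ---------------------------------------------------------------------------


def _dedup(rows: List[Tuple[float, ...]]) -> Tuple[List[Tuple[float, ...]], Dict[Tuple[float, ...], int]]:
    """Stable exact-equality dedup; returns (unique rows, row -> 0-based type)."""
    uniq: List[Tuple[float, ...]] = []
    index: Dict[Tuple[float, ...], int] = {}
    for row in rows:
        if row not in index:
            index[row] = len(uniq)
            uniq.append(row)
    return uniq, index


def write_lammps_data(
    system_map: SystemMap,
    coords: np.ndarray,
    box: BoxBounds,
    dest: Union[str, Path],
    title: str = "generated by liqprop",
) -> None:
    """Write an atom_style-full data file for the mapped system.

    Coefficient rows that are numerically identical (exact tuple equality)
    across species are merged into one global type.  Coordinates outside the
    box are wrapped in.  Atom/bond/angle/... ids are 1-based in the file.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (system_map.n_atoms, 3):
        raise ValueError(
            f"coords shape {coords.shape} does not match system of "
            f"{system_map.n_atoms} atoms"
        )
    lengths = box.lengths
    lows = box.lows
    coords = lows + np.mod(coords - lows, lengths)

    # global atom types: dedup (mass, nonbond row) pairs across species
    atom_type_rows: List[Tuple[float, ...]] = []
    per_species_atom_type: List[List[int]] = []
    for tmpl in system_map.species:
        local: List[int] = []
        for a in range(tmpl.n_atoms):
            nb = tuple(tmpl.nonbond[a]) if tmpl.nonbond is not None else ()
            row = (tmpl.masses[a],) + nb
            local.append(len(atom_type_rows))
            atom_type_rows.append(row)
        per_species_atom_type.append(local)
    uniq_atom, atom_index = _dedup(atom_type_rows)
    flat = [atom_index[row] for row in atom_type_rows]
    k = 0
    for s, tmpl in enumerate(system_map.species):
        for a in range(tmpl.n_atoms):
            per_species_atom_type[s][a] = flat[k]
            k += 1

    def collect(cls: str) -> Tuple[List[Tuple[float, ...]], List[Tuple[int, int, Tuple[int, ...]]]]:
        """Return (unique coeff rows, [(type, molecule-offset-agnostic)...]) per class."""
        rows: List[Tuple[float, ...]] = []
        for tmpl in system_map.species:
            for term in getattr(tmpl, cls):
                rows.append(term.coeffs)
        uniq, index = _dedup(rows)
        return uniq, index  # type: ignore[return-value]

    sections = {}
    for cls in ("bonds", "angles", "dihedrals", "impropers"):
        uniq, index = collect(cls)
        sections[cls] = (uniq, index)

    # enumerate instances
    atom_rows: List[str] = []
    term_rows: Dict[str, List[str]] = {c: [] for c in sections}
    offset = 0
    mol = 0
    for s, (tmpl, count) in enumerate(zip(system_map.species, system_map.counts)):
        for _ in range(count):
            for a in range(tmpl.n_atoms):
                gid = offset + a + 1
                x, y, z = coords[offset + a]
                atom_rows.append(
                    f"{gid} {mol + 1} {per_species_atom_type[s][a] + 1} "
                    f"{tmpl.charges[a]:.6f} {x:.6f} {y:.6f} {z:.6f}"
                )
            for cls in ("bonds", "angles", "dihedrals", "impropers"):
                _, index = sections[cls]
                for term in getattr(tmpl, cls):
                    t = index[term.coeffs] + 1
                    ids = " ".join(str(offset + i + 1) for i in term.atoms)
                    term_rows[cls].append(
                        f"{len(term_rows[cls]) + 1} {t} {ids}"
                    )
            offset += tmpl.n_atoms
            mol += 1

    header_names = {
        "bonds": "bonds",
        "angles": "angles",
        "dihedrals": "dihedrals",
        "impropers": "impropers",
    }
    section_names = {
        "bonds": ("Bond Coeffs", "Bonds"),
        "angles": ("Angle Coeffs", "Angles"),
        "dihedrals": ("Dihedral Coeffs", "Dihedrals"),
        "impropers": ("Improper Coeffs", "Impropers"),
    }

    with open(dest, "w") as fh:
        fh.write(title + "\n\n")
        fh.write(f"{system_map.n_atoms} atoms\n")
        for cls in ("bonds", "angles", "dihedrals", "impropers"):
            fh.write(f"{len(term_rows[cls])} {header_names[cls]}\n")
        fh.write(f"\n{len(uniq_atom)} atom types\n")
        for cls in ("bonds", "angles", "dihedrals", "impropers"):
            n_types = len(sections[cls][0])
            if n_types:
                fh.write(f"{n_types} {header_names[cls][:-1]} types\n")
        fh.write(f"\n{box.xlo:.6f} {box.xhi:.6f} xlo xhi\n")
        fh.write(f"{box.ylo:.6f} {box.yhi:.6f} ylo yhi\n")
        fh.write(f"{box.zlo:.6f} {box.zhi:.6f} zlo zhi\n")
        fh.write("\nMasses\n\n")
        for t, row in enumerate(uniq_atom):
            fh.write(f"{t + 1} {row[0]:.6f}\n")
        has_nonbond = any(t.nonbond is not None for t in system_map.species)
        if has_nonbond:
            fh.write("\nPair Coeffs\n\n")
            for t, row in enumerate(uniq_atom):
                fh.write(f"{t + 1} " + " ".join(f"{v:.6f}" for v in row[1:]) + "\n")
        for cls in ("bonds", "angles", "dihedrals", "impropers"):
            uniq, _ = sections[cls]
            if uniq:
                fh.write(f"\n{section_names[cls][0]}\n\n")
                for t, row in enumerate(uniq):
                    fh.write(f"{t + 1} " + " ".join(f"{v:.6f}" for v in row) + "\n")
        fh.write("\nAtoms\n\n")
        fh.write("\n".join(atom_rows) + "\n")
        for cls in ("bonds", "angles", "dihedrals", "impropers"):
            if term_rows[cls]:
                fh.write(f"\n{section_names[cls][1]}\n\n")
                fh.write("\n".join(term_rows[cls]) + "\n")


def read_lammps_data(path: Union[str, Path]) -> Dict[str, np.ndarray]:
    """Minimal data-file reader for round-trip checks.

    Returns a dict with keys ``counts`` (header numbers), ``atoms`` (id, mol,
    type, q, x, y, z rows) and, where present, ``bonds/angles/dihedrals/
    impropers`` (id, type, atom-ids rows) and the coefficient sections.
    """
    known = {
        "Masses": "masses",
        "Pair Coeffs": "pair_coeffs",
        "Bond Coeffs": "bond_coeffs",
        "Angle Coeffs": "angle_coeffs",
        "Dihedral Coeffs": "dihedral_coeffs",
        "Improper Coeffs": "improper_coeffs",
        "Atoms": "atoms",
        "Bonds": "bonds",
        "Angles": "angles",
        "Dihedrals": "dihedrals",
        "Impropers": "impropers",
    }
    out: Dict[str, list] = {"counts": {}}  # type: ignore[assignment]
    current: Optional[str] = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    for ln in lines[1:]:
        stripped = ln.split("#")[0].strip()
        if not stripped:
            continue
        if stripped in known:
            current = known[stripped]
            out[current] = []
            continue
        parts = stripped.split()
        if current is None:
            if parts[-1] in ("atoms", "bonds", "angles", "dihedrals", "impropers"):
                out["counts"][parts[-1]] = int(parts[0])  # type: ignore[index]
            elif parts[-1] == "types":
                out["counts"][" ".join(parts[1:])] = int(parts[0])  # type: ignore[index]
            continue
        out[current].append([float(p) for p in parts])
    return {
        k: (np.array(v) if isinstance(v, list) else v) for k, v in out.items()
    }
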