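"""Thermochemistry arithmetic on parsed quantum-calculation documents.

Operations: bond dissociation enthalpy (``BDE = (H_frag1 + H_frag2) -
H_principal``; ring-opening gives the single-product difference), binding
energy (``BE = E_complex - (E_1 + E_2)``, negative = exergonic), redox
state-tree planning and thermodynamic-cycle potentials (with conversion to
named reference scales, e.g. Li+/Li by subtracting 1.4 V), pKa from
solution-phase deprotonation free energies, and NMR chemical-shift
referencing (delta = sigma_ref - sigma_sample).

Energy bookkeeping follows the convention of each observable: BDE uses
enthalpies H, BE uses electronic energies E, redox and pKa use Gibbs free
energies G.  All document energies are in hartree; results are converted to
eV / volts / pKa units at the boundary.

Every operation enforces the true-minimum gate: a document whose frequency
calculation found imaginary modes (``all_freqs_real`` false) is rejected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from . import constants as c
from .errors import (
    CompletenessError,
    PhaseError,
    StoichiometryError,
    ValidationError,
    ValidityError,
)

#: default potential-scale offsets (volts subtracted from the absolute value)
DEFAULT_SCALE_OFFSETS: Dict[str, float] = {"Li+/Li": 1.4, "SHE": 4.44}


# ---------------------------------------------------------------------------
# quantum documents
# ---------------------------------------------------------------------------


@dataclass
class Shielding:
    """Isotropic magnetic shielding of one nucleus (ppm)."""

    nucleus: str
    sigma: float


@dataclass
class QMDoc:
    """One parsed quantum calculation in a definite (charge, #H, phase) state."""

    label: str
    charge: int = 0
    multiplicity: int = 1
    phase: str = "gas"
    solvent: Optional[str] = None
    level_of_theory: str = ""
    E_elec: Optional[float] = None  # hartree
    H: Optional[float] = None  # hartree
    G: Optional[float] = None  # hartree
    all_freqs_real: bool = True
    homo: Optional[float] = None  # hartree
    lumo: Optional[float] = None  # hartree
    n_h: int = 0  # transferable-hydrogen count relative to the reference
    dG_solv: Optional[float] = None  # hartree; gas->solution transfer
    shieldings: Optional[List[Shielding]] = None

    def __post_init__(self) -> None:
        if self.phase not in ("gas", "solution"):
            raise ValidationError(f"{self.label}: unknown phase {self.phase!r}")
        if self.phase == "solution" and not self.solvent:
            raise ValidationError(
                f"{self.label}: solution-phase document requires a solvent"
            )
        if self.multiplicity < 1:
            raise ValidationError(f"{self.label}: multiplicity must be positive")

    @property
    def state(self) -> Tuple[int, int, str]:
        return (self.charge, self.n_h, self.phase)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "QMDoc":
        d = dict(d)
        if d.get("shieldings"):
            d["shieldings"] = [Shielding(**s) for s in d["shieldings"]]
        return cls(**d)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "QMDoc":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _require_minimum(*docs: QMDoc) -> None:
    for d in docs:
        if not d.all_freqs_real:
            raise ValidityError(
                f"document {d.label!r} has imaginary frequencies; not a true minimum"
            )


def _require_field(doc: QMDoc, name: str) -> float:
    val = getattr(doc, name)
    if val is None:
        raise ValidationError(f"document {doc.label!r} lacks required field {name}")
    return float(val)


# ---------------------------------------------------------------------------
# BDE / BE
# ---------------------------------------------------------------------------


def compute_bde(
    principal: QMDoc,
    frag1: QMDoc,
    frag2: Optional[QMDoc] = None,
    mode: str = "break",
) -> float:
    """Bond dissociation enthalpy in eV.

    ``break`` mode: (H_frag1 + H_frag2) - H_principal, with fragment charges
    required to sum to the principal's charge.  ``ring-open`` mode: single
    product, H_open - H_principal.  Every document must pass the
    true-minimum gate.
    """
    if mode not in ("break", "ring-open"):
        raise ValueError(f"unknown BDE mode {mode!r}")
    if mode == "break":
        if frag2 is None:
            raise ValueError("break mode needs two fragment documents")
        _require_minimum(principal, frag1, frag2)
        if frag1.charge + frag2.charge != principal.charge:
            raise StoichiometryError(
                f"fragment charges {frag1.charge:+d} + {frag2.charge:+d} != "
                f"principal charge {principal.charge:+d}"
            )
        bde_ha = (
            _require_field(frag1, "H")
            + _require_field(frag2, "H")
            - _require_field(principal, "H")
        )
    else:
        if frag2 is not None:
            raise ValueError("ring-open mode takes a single product document")
        _require_minimum(principal, frag1)
        if frag1.charge != principal.charge:
            raise StoichiometryError(
                f"ring-opened product charge {frag1.charge:+d} != "
                f"reactant charge {principal.charge:+d}"
            )
        bde_ha = _require_field(frag1, "H") - _require_field(principal, "H")
    return bde_ha * c.HARTREE_EV


@dataclass
class BindingEnergy:
    """Binding energy of a two-body complex."""

    value_ev: float
    exergonic: bool


def compute_be(complex_doc: QMDoc, m1: QMDoc, m2: QMDoc) -> BindingEnergy:
    """BE = E_complex - (E_1 + E_2) in eV; negative flags exergonic binding."""
    _require_minimum(complex_doc, m1, m2)
    if m1.charge + m2.charge != complex_doc.charge:
        raise StoichiometryError(
            f"monomer charges {m1.charge:+d} + {m2.charge:+d} != "
            f"complex charge {complex_doc.charge:+d}"
        )
    be_ha = (
        _require_field(complex_doc, "E_elec")
        - _require_field(m1, "E_elec")
        - _require_field(m2, "E_elec")
    )
    value = be_ha * c.HARTREE_EV
    return BindingEnergy(value_ev=value, exergonic=value < 0.0)


# ---------------------------------------------------------------------------
# redox state tree
# ---------------------------------------------------------------------------

State = Tuple[int, int, str]  # (charge, n_H, phase)


@dataclass
class RedoxTreeSpec:
    """What the redox study should compute; drives state-tree enumeration."""

    method: str = "adiabatic"  # homo_lumo | vertical | adiabatic | pcet
    directions: Tuple[str, ...] = ("oxidation",)
    phases: Tuple[str, ...] = ("gas", "solution")
    electron_transfer: str = "single-step"  # or multi-step
    n_electrons: int = 1
    reference_charge: int = 0
    reference_n_h: int = 0
    h_sites: Tuple[int, ...] = ()
    scale_offsets: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCALE_OFFSETS)
    )
    electron_free_energy: float = 0.0  # hartree per electron, optional term
    proton_free_energy: Optional[float] = None  # G(H+, solution), hartree

    def __post_init__(self) -> None:
        if self.method not in ("homo_lumo", "vertical", "adiabatic", "pcet"):
            raise ValidationError(f"unknown redox method {self.method!r}")
        for d in self.directions:
            if d not in ("oxidation", "reduction"):
                raise ValidationError(f"unknown direction {d!r}")
        for p in self.phases:
            if p not in ("gas", "solution"):
                raise ValidationError(f"unknown phase {p!r}")
        if self.electron_transfer not in ("single-step", "multi-step"):
            raise ValidationError(
                f"unknown electron transfer mode {self.electron_transfer!r}"
            )
        if self.n_electrons < 1:
            raise ValidationError("n_electrons must be >= 1")
        if self.method == "pcet" and not self.h_sites:
            raise ValidationError("pcet requires declared hydrogen sites")


@dataclass(frozen=True)
class RedoxNode:
    """One required calculation state in the redox tree."""

    state: State
    parent: Optional[State]
    reoptimize: bool  # False for vertical children (parent geometry reused)


def plan_redox_tree(spec: RedoxTreeSpec) -> List[RedoxNode]:
    """Deterministically enumerate the calculation states the spec implies.

    The root of each phase branch is the reference state.  Charge branches
    step by +/-1 per level; ``single-step`` keeps only the reference and the
    terminal +/-n state, ``multi-step`` keeps every intermediate.  The pcet
    method interleaves hydrogen-count changes with electron transfers,
    yielding the full (electron, proton) grid up to n_electrons.  Output
    order is sorted by (phase, |charge - reference|, n_H) and is independent
    of how the spec was assembled.
    """
    q0, h0 = spec.reference_charge, spec.reference_n_h
    nodes: Dict[State, RedoxNode] = {}

    def add(state: State, parent: Optional[State], reoptimize: bool = True) -> None:
        if state not in nodes:
            nodes[state] = RedoxNode(state=state, parent=parent, reoptimize=reoptimize)

    phases = tuple(sorted(set(spec.phases)))
    for phase in phases:
        root: State = (q0, h0, phase)
        add(root, None)
        if spec.method == "homo_lumo":
            continue  # orbital energies come from the reference state alone
        child_reopt = spec.method != "vertical"
        for direction in sorted(set(spec.directions)):
            sign = +1 if direction == "oxidation" else -1
            if spec.method == "pcet":
                # electron and proton transfers interleave: enumerate the
                # (i electrons, j hydrogens) grid; a reduction gains H, an
                # oxidation loses H, one unit at a time
                # (i electron, j proton) grid up to n of each; a reduction
                # gains electrons (charge -i) and protons (charge +j, H +j),
                # an oxidation the mirror image.  Each node's parent differs
                # by exactly one transfer (the electron step when possible).
                n = spec.n_electrons
                for i in range(n + 1):
                    for j in range(n + 1):
                        if i == 0 and j == 0:
                            continue
                        charge = q0 + sign * i - sign * j
                        nh = h0 - sign * j
                        if i > 0:
                            parent: State = (q0 + sign * (i - 1) - sign * j, nh, phase)
                        else:
                            parent = (q0 - sign * (j - 1), h0 - sign * (j - 1), phase)
                        add((charge, nh, phase), parent, child_reopt)
            else:
                steps = (
                    range(1, spec.n_electrons + 1)
                    if spec.electron_transfer == "multi-step"
                    else (spec.n_electrons,)
                )
                prev = root
                for k in steps:
                    state = (q0 + sign * k, h0, phase)
                    add(state, prev, child_reopt)
                    prev = state
    return sorted(
        nodes.values(),
        key=lambda n: (
            n.state[2],
            abs(n.state[0] - q0) + abs(n.state[1] - h0),
            n.state[0],
            n.state[1],
        ),
    )


# ---------------------------------------------------------------------------
# redox potentials
# ---------------------------------------------------------------------------


@dataclass
class RedoxResult:
    """Redox potentials and free energies from a completed state tree."""

    ip_ev: Optional[float]
    ea_ev: Optional[float]
    dg_ox_ev: Dict[str, float]
    dg_red_ev: Dict[str, float]
    potentials: Dict[str, Dict[str, float]]  # direction -> {scale: volts}
    pka: Dict[str, float]  # filled when the spec carries a proton free energy
    deprotonation_dg_ev: Dict[str, float]
    n_electrons: int


def _solution_g(
    docs: Mapping[State, QMDoc], charge: int, n_h: int
) -> float:
    """Solution-phase G, via the thermodynamic cycle if no direct document.

    Prefers a directly computed solution document; otherwise assembles
    G(sol) = G(gas) + dG_solv from the gas document's solvation correction.
    """
    key_sol: State = (charge, n_h, "solution")
    if key_sol in docs:
        return _require_field(docs[key_sol], "G")
    key_gas: State = (charge, n_h, "gas")
    if key_gas in docs and docs[key_gas].dG_solv is not None:
        return _require_field(docs[key_gas], "G") + float(docs[key_gas].dG_solv)
    raise CompletenessError(
        f"no solution-phase route for state (charge={charge:+d}, n_H={n_h}): "
        "need a solution document or a gas document with dG_solv"
    )


def compute_redox(
    docs: Union[Mapping[State, QMDoc], Sequence[QMDoc]],
    spec: RedoxTreeSpec,
    temperature: float = 298.15,
) -> RedoxResult:
    """Potentials, IP/EA, and pKa values from the documents of a redox tree.

    Free energies of reaction use Gibbs G; the electron free energy (0 by
    default) enters with the stoichiometry of the released/consumed
    electrons.  Absolute potentials follow E = -dG_red/(n F); converted
    potentials subtract each registered scale offset exactly.
    """
    if not isinstance(docs, Mapping):
        docs = {d.state: d for d in docs}
    plan = plan_redox_tree(spec)
    missing = [n.state for n in plan if n.state not in docs]
    # states whose solution G is derivable through the cycle are not missing
    missing = [
        s
        for s in missing
        if not (
            s[2] == "solution"
            and (s[0], s[1], "gas") in docs
            and docs[(s[0], s[1], "gas")].dG_solv is not None
        )
    ]
    if missing:
        raise CompletenessError(
            "missing state documents: "
            + ", ".join(f"(q={q:+d}, nH={h}, {p})" for q, h, p in missing)
        )
    _require_minimum(*docs.values())

    q0, h0 = spec.reference_charge, spec.reference_n_h
    n = spec.n_electrons
    g_e = spec.electron_free_energy

    def g(charge: int, n_h: int, phase: str) -> float:
        if phase == "gas":
            return _require_field(docs[(charge, n_h, "gas")], "G")
        return _solution_g(docs, charge, n_h)

    dg_ox: Dict[str, float] = {}
    dg_red: Dict[str, float] = {}
    potentials: Dict[str, Dict[str, float]] = {}
    ip = ea = None
    for direction in sorted(set(spec.directions)):
        sign = +1 if direction == "oxidation" else -1
        for phase in sorted(set(spec.phases)):
            try:
                if direction == "oxidation":
                    dg = g(q0 + n, h0, phase) + n * g_e - g(q0, h0, phase)
                    dg_ox[phase] = dg * c.HARTREE_EV
                else:
                    dg = g(q0 - n, h0, phase) - n * g_e - g(q0, h0, phase)
                    dg_red[phase] = dg * c.HARTREE_EV
            except (KeyError, CompletenessError):
                if phase in spec.phases:
                    raise
        if "gas" in spec.phases:
            if direction == "oxidation":
                ip = dg_ox["gas"]
            else:
                ea = -dg_red["gas"]
        # the electrode potential is that of the reduction couple; for an
        # oxidation study it is the reduction of the oxidized form
        phase_for_e = "solution" if "solution" in spec.phases else "gas"
        if direction == "oxidation":
            dg_red_couple_ev = -dg_ox[phase_for_e]
        else:
            dg_red_couple_ev = dg_red[phase_for_e]
        e_abs = -dg_red_couple_ev / n
        scales = {"absolute": e_abs}
        for name, offset in sorted(spec.scale_offsets.items()):
            scales[name] = e_abs - offset
        potentials[direction] = scales

    pka: Dict[str, float] = {}
    deprot: Dict[str, float] = {}
    if spec.method == "pcet":
        # every documented solution-phase pair differing by one H is a
        # deprotonation equilibrium; the bare dG is always recorded, and a
        # pKa is derived when the spec carries the solvated-proton G
        for (q, h, p), d in sorted(docs.items()):
            partner = (q + 1, h + 1, p)
            if p == "solution" and partner in docs:
                label = f"q{q + 1:+d}_h{h + 1}->q{q:+d}_h{h}"
                ddg_ha = (_require_field(docs[(q, h, p)], "G")
                          - _require_field(docs[partner], "G"))
                deprot[label] = ddg_ha * c.HARTREE_EV
                if spec.proton_free_energy is not None:
                    pka[label] = compute_pka(
                        docs[partner], docs[(q, h, p)],
                        spec.proton_free_energy, temperature,
                    )
    return RedoxResult(
        ip_ev=ip,
        ea_ev=ea,
        dg_ox_ev=dg_ox,
        dg_red_ev=dg_red,
        potentials=potentials,
        pka=pka,
        deprotonation_dg_ev=deprot,
        n_electrons=n,
    )


# ---------------------------------------------------------------------------
# pKa and chemical shift
# ---------------------------------------------------------------------------


def compute_pka(
    protonated: QMDoc,
    deprotonated: QMDoc,
    proton_g_sol: float,
    temperature: float = 298.15,
) -> float:
    """pKa = dG_deprot / (RT ln 10) with dG in hartree.

    dG_deprot = G(deprotonated) + G(H+, solution) - G(protonated); both
    molecular documents must be solution-phase.
    """
    for d in (protonated, deprotonated):
        if d.phase != "solution":
            raise PhaseError(
                f"document {d.label!r} is gas-phase; pKa needs solution-phase G"
            )
    _require_minimum(protonated, deprotonated)
    dg_ha = (
        _require_field(deprotonated, "G")
        + float(proton_g_sol)
        - _require_field(protonated, "G")
    )
    dg_j_per_mol = dg_ha * c.HARTREE_J * c.N_A
    return dg_j_per_mol / (c.R_GAS * temperature * math.log(10.0))


def chemical_shift(
    sample: Union[Shielding, float], reference: Union[Shielding, float]
) -> float:
    """Chemical shift delta = sigma_reference - sigma_sample (ppm).

    When both arguments carry a nucleus label the labels must match.
    """
    if isinstance(sample, Shielding) and isinstance(reference, Shielding):
        if sample.nucleus != reference.nucleus:
            raise ValueError(
                f"nucleus mismatch: sample {sample.nucleus!r} vs "
                f"reference {reference.nucleus!r}"
            )
    s = sample.sigma if isinstance(sample, Shielding) else float(sample)
    r = reference.sigma if isinstance(reference, Shielding) else float(reference)
    return r - s
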