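"""Deterministic fixture generators with known ground truth.

Every generator takes an explicit integer seed, uses its own
``numpy.random.Generator`` (no global state), and returns a fixture object
bundling the data with a manifest of the parameters and the analytic ground
truth, so tests assert against the generator's declared truth instead of
re-deriving it.  Trajectory generators can also write their output in the
dump dialect :mod:`liqprop.trajio` reads, so file I/O is exercised wherever
a test wants it.

Kinds: uniform ideal gas (g(r) = 1), Brownian walkers (known D), simple
cubic lattices (known neighbor counts), rigid rotating dipole gases (known
dipole fluctuation), Markov leave-process binding pairs (known residence
decay), Ornstein-Uhlenbeck stress series (known autocorrelation integral),
and additive-energy toy molecules (every bond's dissociation enthalpy equals
its assigned strength).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .molgraph import MolGraph
from .sysmodel import SpeciesTemplate, SystemMap, build_system_map
from .thermochem import QMDoc
from .trajio import BoxBounds, Frame, ThermoTable, Trajectory, write_dump


@dataclass
class GeneratorSpec:
    """(kind, parameters, seed) triple; same spec => byte-identical output."""

    kind: str
    parameters: dict
    seed: int = 0


@dataclass
class TrajectoryFixture:
    """A generated trajectory plus its analytic ground truth."""

    trajectory: Trajectory
    manifest: dict
    system_map: Optional[SystemMap] = None
    trajectory_no_flags: Optional[Trajectory] = None
    unwrapped_positions: Optional[np.ndarray] = None

    def write(self, dump_path: Union[str, Path]) -> None:
        write_dump(self.trajectory, dump_path)


def _cubic_box(edge: float) -> BoxBounds:
    return BoxBounds(0.0, edge, 0.0, edge, 0.0, edge)


def _frames_from_positions(
    positions: np.ndarray,
    box: BoxBounds,
    wrap: bool,
    charges: Optional[np.ndarray] = None,
    types: Optional[np.ndarray] = None,
    mol_ids: Optional[np.ndarray] = None,
    with_flags: bool = True,
) -> List[Frame]:
    T, N, _ = positions.shape
    ids = np.arange(1, N + 1)
    if types is None:
        types = np.ones(N, dtype=np.int64)
    lengths = box.lengths
    lows = box.lows
    frames = []
    for t in range(T):
        pos = positions[t]
        if wrap:
            img = np.floor((pos - lows) / lengths).astype(np.int64)
            wrapped = pos - img * lengths
        else:
            img = None
            wrapped = pos
        frames.append(
            Frame(
                step=t,
                box=box,
                ids=ids,
                types=types,
                positions=wrapped,
                images=img if (wrap and with_flags) else None,
                charges=charges,
                mol_ids=mol_ids,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# ideal gas
# ---------------------------------------------------------------------------


def gen_ideal_gas(
    n_atoms: int = 500,
    box_edge: float = 20.0,
    n_frames: int = 50,
    seed: int = 0,
    unit_style: str = "real",
) -> TrajectoryFixture:
    """Uniform i.i.d. positions each frame: g(r) = 1 identically."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box_edge, size=(n_frames, n_atoms, 3))
    box = _cubic_box(box_edge)
    traj = Trajectory(
        frames=_frames_from_positions(pos, box, wrap=False),
        unit_style=unit_style,
        dt_sample=1.0,
    )
    manifest = {
        "kind": "ideal_gas",
        "seed": seed,
        "n_atoms": n_atoms,
        "box_edge": box_edge,
        "n_frames": n_frames,
        "truth": {"g": 1.0, "number_density": n_atoms / box_edge**3},
    }
    return TrajectoryFixture(trajectory=traj, manifest=manifest)


# ---------------------------------------------------------------------------
# Brownian dynamics
# ---------------------------------------------------------------------------


def gen_brownian(
    n_atoms: int = 200,
    box_edge: float = 1.0e-8,
    n_frames: int = 2000,
    D: float = 1.0e-9,
    dt: float = 1.0e-12,
    seed: int = 0,
) -> TrajectoryFixture:
    """Brownian walkers with per-axis step variance 2 D dt, SI unit style.

    The fixture carries the wrapped trajectory with exact image flags, the
    same path without flags (for unwrap-heuristic checks), and the
    ground-truth unwrapped positions.
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, box_edge, size=(n_atoms, 3))
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_frames - 1, n_atoms, 3))
    path = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    box = _cubic_box(box_edge)
    traj = Trajectory(
        frames=_frames_from_positions(path, box, wrap=True, with_flags=True),
        unit_style="si",
        dt_sample=dt,
    )
    traj_nf = Trajectory(
        frames=_frames_from_positions(path, box, wrap=True, with_flags=False),
        unit_style="si",
        dt_sample=dt,
    )
    manifest = {
        "kind": "brownian",
        "seed": seed,
        "n_atoms": n_atoms,
        "box_edge": box_edge,
        "n_frames": n_frames,
        "dt": dt,
        "truth": {"D": D},
    }
    return TrajectoryFixture(
        trajectory=traj,
        manifest=manifest,
        trajectory_no_flags=traj_nf,
        unwrapped_positions=path,
    )


# ---------------------------------------------------------------------------
# simple cubic lattice
# ---------------------------------------------------------------------------


def gen_lattice(
    n_cells: int = 5,
    spacing: float = 1.0,
    n_frames: int = 1,
    unit_style: str = "real",
) -> TrajectoryFixture:
    """Static simple-cubic lattice under periodic boundaries.

    Every site has exactly 6 nearest neighbors at the lattice spacing.
    """
    grid = np.arange(n_cells) * spacing
    xyz = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1).reshape(-1, 3)
    pos = np.repeat(xyz[None], n_frames, axis=0)
    box = _cubic_box(n_cells * spacing)
    traj = Trajectory(
        frames=_frames_from_positions(pos, box, wrap=False),
        unit_style=unit_style,
        dt_sample=1.0,
    )
    manifest = {
        "kind": "lattice",
        "n_cells": n_cells,
        "spacing": spacing,
        "truth": {"nearest_neighbors": 6, "nn_distance": spacing},
    }
    return TrajectoryFixture(trajectory=traj, manifest=manifest)


# ---------------------------------------------------------------------------
# dipole gas
# ---------------------------------------------------------------------------


def gen_dipole_gas(
    n_dipoles: int = 100,
    box_edge: float = 50.0,
    n_frames: int = 10000,
    q: float = 1.0,
    d: float = 1.0,
    seed: int = 0,
    unit_style: str = "real",
) -> TrajectoryFixture:
    """Rigid +/-q pairs with fixed centers and uniform random orientations.

    Molecular dipole magnitude is exactly q*d every frame; over independent
    orientations <M> -> 0 and <M^2> -> N (q d)^2.
    """
    rng = np.random.default_rng(seed)
    per_side = int(np.ceil(n_dipoles ** (1.0 / 3.0)))
    cell = box_edge / per_side
    grid = (np.arange(per_side) + 0.5) * cell
    centers = np.stack(
        np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1
    ).reshape(-1, 3)[:n_dipoles]
    u = rng.normal(size=(n_frames, n_dipoles, 3))
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    plus = centers[None] + 0.5 * d * u
    minus = centers[None] - 0.5 * d * u
    pos = np.empty((n_frames, 2 * n_dipoles, 3))
    pos[:, 0::2, :] = plus
    pos[:, 1::2, :] = minus
    charges = np.empty(2 * n_dipoles)
    charges[0::2] = q
    charges[1::2] = -q
    mol_ids = np.repeat(np.arange(1, n_dipoles + 1), 2)
    types = np.tile([1, 2], n_dipoles)
    box = _cubic_box(box_edge)
    traj = Trajectory(
        frames=_frames_from_positions(
            pos, box, wrap=False, charges=charges, types=types, mol_ids=mol_ids
        ),
        unit_style=unit_style,
        dt_sample=1.0,
    )
    dipole = SpeciesTemplate(
        name="dipole",
        elements=["He", "He"],
        masses=[1.0, 1.0],
        charges=[q, -q],
        net_charge=0.0,
    )
    system_map = build_system_map([dipole], [n_dipoles])
    manifest = {
        "kind": "dipole_gas",
        "seed": seed,
        "n_dipoles": n_dipoles,
        "box_edge": box_edge,
        "n_frames": n_frames,
        "q": q,
        "d": d,
        "truth": {"mu": q * d, "M2": n_dipoles * (q * d) ** 2},
    }
    return TrajectoryFixture(trajectory=traj, manifest=manifest, system_map=system_map)


# ---------------------------------------------------------------------------
# Markov binding pairs
# ---------------------------------------------------------------------------


def gen_markov_binding(
    n_pairs: int = 1600,
    n_frames: int = 120,
    p_leave: float = 0.05,
    seed: int = 0,
    bound_distance: float = 1.0,
    unbound_distance: float = 12.0,
    cell: float = 30.0,
    unit_style: str = "real",
) -> TrajectoryFixture:
    """Center-ligand pairs that start bound and leave with probability p per frame.

    Leaving is absorbing, so the continuous residence correlation is exactly
    the geometric survival (1 - p)^(t/dt) in expectation, with fitted
    residence time -dt / ln(1 - p).  Pairs sit on a sparse grid so no
    cross-pair contact ever occurs.
    """
    if not 0 < p_leave < 1:
        raise ValueError("p_leave must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    per_side = int(np.ceil(n_pairs ** (1.0 / 3.0)))
    grid = (np.arange(per_side) + 0.5) * cell
    centers = np.stack(
        np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1
    ).reshape(-1, 3)[:n_pairs]
    # bound[t, p]: still bound at frame t (absorbing leave process)
    leave = rng.uniform(size=(n_frames - 1, n_pairs)) < p_leave
    bound = np.ones((n_frames, n_pairs), dtype=bool)
    bound[1:] = ~np.cumsum(leave, axis=0).astype(bool)
    lig_offset = np.where(
        bound[:, :, None],
        np.array([bound_distance, 0.0, 0.0]),
        np.array([unbound_distance, 0.0, 0.0]),
    )
    pos = np.empty((n_frames, 2 * n_pairs, 3))
    pos[:, :n_pairs, :] = centers[None]
    pos[:, n_pairs:, :] = centers[None] + lig_offset
    box = _cubic_box(per_side * cell)
    center_t = SpeciesTemplate(
        name="center", elements=["Li"], masses=[6.94], charges=[0.0]
    )
    ligand_t = SpeciesTemplate(
        name="ligand", elements=["O"], masses=[15.999], charges=[0.0]
    )
    system_map = build_system_map([center_t, ligand_t], [n_pairs, n_pairs])
    traj = Trajectory(
        frames=_frames_from_positions(pos, box, wrap=False),
        unit_style=unit_style,
        dt_sample=1.0,
    )
    manifest = {
        "kind": "markov_binding",
        "seed": seed,
        "n_pairs": n_pairs,
        "n_frames": n_frames,
        "p_leave": p_leave,
        "cutoff": 2.0 * bound_distance,
        "truth": {"tau": -1.0 / np.log(1.0 - p_leave)},
    }
    return TrajectoryFixture(trajectory=traj, manifest=manifest, system_map=system_map)


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck stress series
# ---------------------------------------------------------------------------


@dataclass
class StressFixture:
    thermo: ThermoTable
    manifest: dict


def gen_ou_stress(
    n_samples: int = 100000,
    dt: float = 1.0,
    variance: float = 1.0,
    tau_c: float = 10.0,
    seed: int = 0,
    components: Sequence[str] = ("Pxy", "Pxz", "Pyz"),
) -> StressFixture:
    """Exact-discretization OU series: ACF(t) = variance * exp(-t/tau_c).

    The Green-Kubo integral of the ACF is variance * tau_c, so a viscosity
    estimate over this table has the closed form V * c * tau_c / (kB T).
    """
    if tau_c < dt:
        raise ValueError("tau_c must be at least the sampling interval dt")
    rng = np.random.default_rng(seed)
    a = np.exp(-dt / tau_c)
    noise_sd = np.sqrt(variance * (1.0 - a * a))
    data = {"Step": np.arange(n_samples, dtype=float)}
    for comp in components:
        x = np.empty(n_samples)
        x[0] = rng.normal(0.0, np.sqrt(variance))
        eps = rng.normal(size=n_samples - 1)
        for i in range(1, n_samples):
            x[i] = a * x[i - 1] + noise_sd * eps[i - 1]
        data[comp] = x
    thermo = ThermoTable(data=pd.DataFrame(data), run_label="ou-stress")
    manifest = {
        "kind": "ou_stress",
        "seed": seed,
        "n_samples": n_samples,
        "dt": dt,
        "variance": variance,
        "tau_c": tau_c,
        "truth": {"acf_integral": variance * tau_c},
    }
    return StressFixture(thermo=thermo, manifest=manifest)


# ---------------------------------------------------------------------------
# additive-energy toy molecules
# ---------------------------------------------------------------------------


@dataclass
class ToyMoleculeSet:
    """Additive-energy molecule: H(subgraph) = sum baselines - sum bond strengths.

    By construction the dissociation enthalpy of cutting any bridge bond
    equals that bond's assigned strength, exactly; and the binding energy of
    a complex linked by one bond is minus the linking strength.
    """

    graph: MolGraph
    bond_strengths: Dict[FrozenSet[int], float]
    atom_baselines: Dict[int, float]
    manifest: dict = field(default_factory=dict)

    def enthalpy(self, nodes: Optional[Sequence[int]] = None) -> float:
        """Additive enthalpy (hartree) of a connected node subset."""
        g = self.graph.graph
        if nodes is None:
            nodes = list(g.nodes)
        nodes = set(nodes)
        h = sum(self.atom_baselines[i] for i in nodes)
        for i, j in g.edges:
            if i in nodes and j in nodes:
                h -= self.bond_strengths[frozenset((i, j))]
        return h

    def qmdoc(self, nodes: Optional[Sequence[int]] = None, label: str = "mol",
              charge: int = 0) -> QMDoc:
        h = self.enthalpy(nodes)
        return QMDoc(
            label=label, charge=charge, phase="gas",
            E_elec=h, H=h, G=h, all_freqs_real=True,
        )

    def fragment_docs(self, bond: Tuple[int, int]) -> Tuple[QMDoc, QMDoc]:
        """QMDocs of the two components left by cutting one bridge bond."""
        import networkx as nx

        h = self.graph.graph.copy()
        h.remove_edge(*bond)
        comps = sorted(nx.connected_components(h), key=min)
        if len(comps) != 2:
            raise ValueError(f"bond {bond} is not a bridge")
        return tuple(
            self.qmdoc(sorted(cc), label=f"frag{k}") for k, cc in enumerate(comps)
        )


def gen_toy_molecules(
    graph: MolGraph,
    bond_strengths: Optional[Dict[Tuple[int, int], float]] = None,
    atom_baselines: Optional[Dict[int, float]] = None,
    seed: int = 0,
) -> ToyMoleculeSet:
    """Assign additive energies to a connected molecular graph.

    Unspecified bond strengths are drawn uniformly from [0.05, 0.30] hartree
    and baselines from [-40, -1] hartree, from the seeded generator.
    """
    import networkx as nx

    if not graph.is_connected():
        raise ValueError("toy-molecule generation requires a connected graph")
    rng = np.random.default_rng(seed)
    strengths: Dict[FrozenSet[int], float] = {}
    for i, j in graph.graph.edges:
        key = frozenset((i, j))
        strengths[key] = (
            float(bond_strengths[(i, j)])
            if bond_strengths and (i, j) in bond_strengths
            else float(bond_strengths[(j, i)])
            if bond_strengths and (j, i) in bond_strengths
            else float(rng.uniform(0.05, 0.30))
        )
    baselines = {
        i: (
            float(atom_baselines[i])
            if atom_baselines and i in atom_baselines
            else float(rng.uniform(-40.0, -1.0))
        )
        for i in graph.graph.nodes
    }
    manifest = {
        "kind": "toy_molecules",
        "seed": seed,
        "n_atoms": graph.n_atoms,
        "truth": {"bde_per_bond": {tuple(sorted(k)): v for k, v in strengths.items()}},
    }
    return ToyMoleculeSet(
        graph=graph,
        bond_strengths=strengths,
        atom_baselines=baselines,
        manifest={**manifest, "truth": {
            "bde_per_bond": {str(tuple(sorted(k))): v for k, v in strengths.items()}
        }},
    )


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

_GENERATORS = {
    "ideal_gas": gen_ideal_gas,
    "brownian": gen_brownian,
    "lattice": gen_lattice,
    "dipole_gas": gen_dipole_gas,
    "markov_binding": gen_markov_binding,
    "ou_stress": gen_ou_stress,
}


def generate(spec: GeneratorSpec):
    """Dispatch a :class:`GeneratorSpec` to its generator function."""
    if spec.kind not in _GENERATORS:
        raise ValueError(
            f"unknown generator kind {spec.kind!r}; have {sorted(_GENERATORS)}"
        )
    fn = _GENERATORS[spec.kind]
    kwargs = dict(spec.parameters)
    if spec.kind != "lattice":
        kwargs["seed"] = spec.seed
    return fn(**kwargs)
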