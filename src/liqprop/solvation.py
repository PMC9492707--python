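"""Solvation-shell cluster extraction and speciation statistics.

The bridge from classical trajectories to quantum workflows: around every
molecule of a target species, the molecules whose criterion distance
(nearest atom pair by default, centers of mass optionally) lies within a
cutoff are collected into a cluster, made whole across the periodic
boundary, translated into the center's image, and recentered on the center's
centroid.  The cutoff may be a number or ``"auto"``, in which case it is the
first minimum of the center-solvent RDF.  Cluster geometries can be written
as XYZ files (with a composition comment line) plus a JSON manifest, ready
for downstream electronic-structure input generation.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .select import Selection, resolve_selection
from .structure import compute_rdf, first_minimum, minimum_image
from .sysmodel import SystemMap
from .trajio import Trajectory, write_xyz


@dataclass
class Cluster:
    """One extracted solvation shell."""

    frame: int
    center: Tuple[str, int]  # (species name, molecule index)
    members: List[Tuple[str, int]]
    composition: Dict[str, int]
    elements: List[str]
    coords: np.ndarray  # recentered on the center molecule's centroid

    @property
    def composition_key(self) -> Tuple[Tuple[str, int], ...]:
        return tuple(sorted(self.composition.items()))

    def comment(self) -> str:
        comp = " ".join(f"{k}:{v}" for k, v in self.composition_key)
        return (
            f"frame={self.frame} center={self.center[0]}/{self.center[1]} "
            f"composition[{comp}]"
        )


@dataclass
class SpeciationTable:
    """Composition multiset frequencies over a cluster ensemble."""

    entries: Dict[Tuple[Tuple[str, int], ...], Tuple[int, float]]
    n_observations: int

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "composition": " ".join(f"{s}:{n}" for s, n in key),
                "count": cnt,
                "frequency": freq,
            }
            for key, (cnt, freq) in self.entries.items()
        ]
        return pd.DataFrame(rows)


def _whole_molecule(pos: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Unwrap one molecule's atoms into the image of its first atom."""
    ref = pos[:1]
    return ref + minimum_image(pos - ref, lengths)


def extract_clusters(
    traj: Trajectory,
    system_map: SystemMap,
    center_sel: Union[str, dict],
    cutoff: Union[float, str] = "auto",
    criterion: str = "any-atom",
    frames: Union[slice, Sequence[int], None] = None,
    out_dir: Optional[Union[str, Path]] = None,
    rdf_bin_width: float = 0.1,
) -> List[Cluster]:
    """Extract first-shell clusters around every molecule of a center species.

    Parameters
    ----------
    center_sel
        Species name (str) or a dict selection whose atoms define the center
        molecules.
    cutoff
        Shell radius in native length units, or ``"auto"`` to take the first
        minimum of the RDF between the center atoms and all other atoms
        (a :class:`~liqprop.errors.DetectionError` propagates if that RDF has
        no resolvable first shell).
    criterion
        ``"any-atom"`` (default): a molecule belongs to the shell when its
        nearest atom is within the cutoff of any center atom — this captures
        coordinating atoms of large, floppy anions.  ``"com"``: centers of
        mass within the cutoff, for coarser speciation.
    frames
        Frame indices to process (slice, index sequence, or None for all).
    out_dir
        When given, one XYZ file per cluster plus ``manifest.json`` are
        written there.
    """
    if criterion not in ("any-atom", "com"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if isinstance(center_sel, str):
        center_sel = {"species": center_sel}
    c_idx = resolve_selection(center_sel, traj.n_atoms, traj.frames[0], system_map)
    center_mols = np.unique(system_map.molecule_index[c_idx])

    if cutoff == "auto":
        others = np.setdiff1d(np.arange(traj.n_atoms), c_idx)
        rdf = compute_rdf(traj, c_idx, others, bin_width=rdf_bin_width,
                          system_map=system_map)
        cutoff = first_minimum(rdf)
    cutoff = float(cutoff)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    if frames is None:
        frame_ids = range(traj.n_frames)
    elif isinstance(frames, slice):
        frame_ids = range(*frames.indices(traj.n_frames))
    else:
        frame_ids = list(frames)

    mol_atoms = [np.flatnonzero(system_map.molecule_index == m)
                 for m in range(system_map.n_molecules)]
    mol_species = [
        system_map.species_name(int(system_map.species_index[idx[0]]))
        for idx in mol_atoms
    ]
    masses = system_map.masses
    elements_all = system_map.elements

    clusters: List[Cluster] = []
    for fi in frame_ids:
        fr = traj.frames[fi]
        lengths = fr.box.lengths
        if criterion == "com":
            coms = np.empty((system_map.n_molecules, 3))
            for m, idx in enumerate(mol_atoms):
                whole = _whole_molecule(fr.positions[idx], lengths)
                w = masses[idx]
                coms[m] = (whole * w[:, None]).sum(0) / w.sum()
        for cm in center_mols:
            cm = int(cm)
            members: List[int] = []
            if criterion == "any-atom":
                cpos = fr.positions[mol_atoms[cm]]
                for m, idx in enumerate(mol_atoms):
                    if m == cm:
                        continue
                    diff = minimum_image(
                        cpos[:, None, :] - fr.positions[idx][None, :, :], lengths
                    )
                    if np.min(np.sum(diff**2, axis=-1)) <= cutoff**2:
                        members.append(m)
            else:
                d = minimum_image(coms - coms[cm], lengths)
                dist2 = np.sum(d**2, axis=1)
                members = [
                    m for m in range(system_map.n_molecules)
                    if m != cm and dist2[m] <= cutoff**2
                ]
            comp = dict(Counter(mol_species[m] for m in members))

            center_whole = _whole_molecule(fr.positions[mol_atoms[cm]], lengths)
            centroid = center_whole.mean(axis=0)
            coords = [center_whole - centroid]
            elements = list(elements_all[mol_atoms[cm]])
            for m in members:
                whole = _whole_molecule(fr.positions[mol_atoms[m]], lengths)
                mc = whole.mean(axis=0)
                # translate the member into the center's nearest image
                shift = minimum_image(mc - centroid, lengths) - (mc - centroid)
                coords.append(whole + shift - centroid)
                elements.extend(elements_all[mol_atoms[m]])
            clusters.append(
                Cluster(
                    frame=fr.step,
                    center=(mol_species[cm], cm),
                    members=[(mol_species[m], m) for m in members],
                    composition=comp,
                    elements=elements,
                    coords=np.vstack(coords),
                )
            )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []
        for k, cl in enumerate(clusters):
            name = f"cluster_{k:05d}.xyz"
            write_xyz(cl.elements, cl.coords, cl.comment(), out / name)
            manifest.append(
                {
                    "file": name,
                    "frame": cl.frame,
                    "center": list(cl.center),
                    "composition": dict(sorted(cl.composition.items())),
                }
            )
        with open(out / "manifest.json", "w") as fh:
            json.dump({"cutoff": cutoff, "criterion": criterion,
                       "clusters": manifest}, fh, indent=2)
    return clusters


def speciation_stats(clusters: Sequence[Cluster]) -> SpeciationTable:
    """Exact composition-multiset counting over extracted clusters.

    Keys are ordered deterministically (by species name then count) so two
    permutations of the same cluster list give identical tables.
    """
    if not clusters:
        raise ValueError("speciation_stats needs at least one cluster")
    counter = Counter(cl.composition_key for cl in clusters)
    n = len(clusters)
    entries = {
        key: (cnt, cnt / n)
        for key, cnt in sorted(counter.items())
    }
    return SpeciationTable(entries=entries, n_observations=n)
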