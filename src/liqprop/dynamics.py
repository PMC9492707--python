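"""Dynamical ensemble properties.

Implements coordinate unwrapping, mean-squared displacement with multiple
time origins (direct O(T^2) and FFT routes), Einstein-relation self-diffusion
(D = slope/6), Nernst-Einstein ionic conductivity, Green-Kubo shear
viscosity from off-diagonal pressure autocorrelations, shell residence-time
correlation functions (intermittent and continuous), and the static
dielectric constant from dipole-moment fluctuations under conducting
boundary conditions.

Unit policy: trajectories stay in their native unit style; quantities that
are physical observables (sigma in S/m, eta in Pa s, epsilon) convert to SI
at this module's boundary using the trajectory's declared style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import linregress

from . import constants as c
from .errors import UnsupportedSystemError
from .select import Selection, resolve_selection, selection_label
from .structure import minimum_image
from .sysmodel import SystemMap
from .trajio import Frame, ThermoTable, Trajectory
from .units import si_factor

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# unwrapping
# ---------------------------------------------------------------------------


def unwrap(traj: Trajectory) -> Trajectory:
    """Remove periodic wrapping from a trajectory.

    When image flags are present the exact reconstruction ``r + n * L`` is
    used per frame.  Without flags, a jump heuristic folds every inter-frame
    displacement into (-L/2, L/2]; this is exact whenever no atom moves more
    than half a box edge between stored frames (a warning notes the
    assumption).
    """
    frames = []
    has_flags = all(fr.images is not None for fr in traj.frames)
    if not has_flags:
        logger.warning(
            "unwrap: no image flags; using the jump heuristic "
            "(assumes per-frame displacements < half box edge)"
        )
        prev_wrapped = None
        prev_unwrapped = None
    for fr in traj.frames:
        if has_flags:
            pos = fr.positions + fr.images * fr.box.lengths
        else:
            if prev_wrapped is None:
                pos = fr.positions.copy()
            else:
                disp = minimum_image(fr.positions - prev_wrapped, fr.box.lengths)
                pos = prev_unwrapped + disp
            prev_wrapped = fr.positions
            prev_unwrapped = pos
        frames.append(
            Frame(
                step=fr.step,
                box=fr.box,
                ids=fr.ids,
                types=fr.types,
                positions=pos,
                mol_ids=fr.mol_ids,
                images=np.zeros_like(fr.images) if fr.images is not None else None,
                charges=fr.charges,
                velocities=fr.velocities,
            )
        )
    return Trajectory(frames=frames, unit_style=traj.unit_style, dt_sample=traj.dt_sample)


def _check_unwrapped(pos: np.ndarray, lengths: np.ndarray) -> None:
    jumps = np.abs(np.diff(pos, axis=0))
    if jumps.size and jumps.max() > lengths.min() / 2.0:
        raise ValueError(
            "trajectory appears wrapped (inter-frame jump exceeds half a box "
            "edge); call dynamics.unwrap first"
        )


# ---------------------------------------------------------------------------
# mean-squared displacement
# ---------------------------------------------------------------------------


@dataclass
class MSDResult:
    """Multiple-time-origin mean-squared displacement."""

    lag: np.ndarray
    msd: np.ndarray
    method: str
    n_origins: int
    selection: str = "all"
    unit_style: str = "real"
    n_particles: int = 0


def _msd_direct(pos: np.ndarray) -> np.ndarray:
    """O(T^2) reference MSD: explicit average over all time origins."""
    T = pos.shape[0]
    out = np.zeros(T)
    for tau in range(1, T):
        diff = pos[tau:] - pos[:-tau]
        out[tau] = np.mean(np.sum(diff**2, axis=-1))
    return out


def _msd_fft(pos: np.ndarray) -> np.ndarray:
    """FFT MSD identical to the direct route (autocorrelation decomposition)."""
    T, N, _ = pos.shape
    n_fft = 1 << (2 * T - 1).bit_length()
    msd = np.zeros(T)
    norm = T - np.arange(T)
    for ax in range(3):
        x = pos[:, :, ax]
        fx = np.fft.rfft(x, n=n_fft, axis=0)
        acf = np.fft.irfft(fx * np.conj(fx), n=n_fft, axis=0)[:T]  # sum_t x_t x_{t+tau}
        d = x**2
        q = 2.0 * d.sum(axis=0)
        sab = np.empty((T, N))
        sab[0] = q
        for tau in range(1, T):
            q = q - d[tau - 1] - d[T - tau]
            sab[tau] = q
        msd += np.mean((sab - 2.0 * acf) / norm[:, None], axis=1)
    # msd(0) = 0 by definition; clamp the FFT round-off (~1e-30 scale)
    msd[0] = 0.0
    return np.maximum(msd, 0.0)


def _com_positions(
    traj: Trajectory, species: str, system_map: SystemMap
) -> np.ndarray:
    """(T, n_mol, 3) mass-weighted molecular centers of one species."""
    groups = system_map.molecules_of(species)
    masses = system_map.masses
    pos = traj.positions_array()
    coms = np.empty((traj.n_frames, len(groups), 3))
    for m, idx in enumerate(groups):
        w = masses[idx]
        coms[:, m, :] = np.einsum("tad,a->td", pos[:, idx, :], w) / w.sum()
    return coms


def compute_msd(
    traj: Trajectory,
    selection: Selection = None,
    method: str = "fft",
    system_map: Optional[SystemMap] = None,
    max_lag_fraction: float = 0.5,
) -> MSDResult:
    """MSD averaged over all time origins and selected particles.

    When `selection` is a dict naming a ``species`` (and a system map is
    supplied), displacements are of per-molecule centers of mass; otherwise
    per-atom.  The trajectory must be unwrapped (a jump larger than half a
    box edge raises ``ValueError``).

    Lags are reported up to `max_lag_fraction` of the trajectory length
    (default half): beyond that, fewer than half the time origins contribute
    and the estimate is statistically unreliable.
    """
    if traj.n_frames < 2:
        raise ValueError("MSD needs at least 2 frames")
    if method not in ("direct", "fft"):
        raise ValueError(f"unknown MSD method {method!r}")
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must lie in (0, 1]")
    if isinstance(selection, dict) and "species" in selection and system_map is not None:
        pos = _com_positions(traj, selection["species"], system_map)
    else:
        idx = resolve_selection(selection, traj.n_atoms, traj.frames[0], system_map)
        pos = traj.positions_array()[:, idx, :]
    _check_unwrapped(pos, traj.frames[0].box.lengths)
    steps = np.array([fr.step for fr in traj.frames])
    dsteps = np.diff(steps)
    if not np.all(dsteps == dsteps[0]):
        raise ValueError("MSD requires uniformly spaced frames")
    msd = _msd_fft(pos) if method == "fft" else _msd_direct(pos)
    lag = np.arange(traj.n_frames) * traj.dt_sample
    n_keep = max(2, int(np.floor(traj.n_frames * max_lag_fraction)) + 1)
    msd = msd[:n_keep]
    lag = lag[:n_keep]
    return MSDResult(
        lag=lag,
        msd=msd,
        method=method,
        n_origins=traj.n_frames,
        selection=selection_label(selection),
        unit_style=traj.unit_style,
        n_particles=pos.shape[1],
    )


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------


@dataclass
class DiffusionFit:
    """Einstein-relation diffusion coefficient from a linear MSD fit."""

    D: float
    stderr: float
    r_squared: float
    window: Tuple[float, float]
    n_points: int
    linear: bool
    unit_style: str = "real"

    @property
    def D_si(self) -> float:
        f = si_factor("length", self.unit_style) ** 2 / si_factor("time", self.unit_style)
        return self.D * f


R2_LINEAR_THRESHOLD = 0.98


def fit_diffusion(
    msd: MSDResult, window: Tuple[float, float] = (0.2, 0.6)
) -> DiffusionFit:
    """Least-squares slope of MSD over a lag window; D = slope / 6.

    `window` is a (lower, upper) fraction of the maximum lag; the default
    20%-60% band avoids both the short-time ballistic/sub-diffusive regime
    and the poorly averaged long-lag tail.  ``linear`` is False when the fit
    R^2 falls below 0.98, flagging non-diffusive MSD shapes.
    """
    lo, hi = window
    if not (0 < lo < hi <= 1):
        raise ValueError("window must satisfy 0 < lower < upper <= 1")
    t_max = msd.lag[-1]
    mask = (msd.lag >= lo * t_max) & (msd.lag <= hi * t_max)
    if mask.sum() < 5:
        raise ValueError(
            f"only {int(mask.sum())} MSD points in fit window; need at least 5"
        )
    fit = linregress(msd.lag[mask], msd.msd[mask])
    r2 = float(fit.rvalue**2)
    if r2 < R2_LINEAR_THRESHOLD:
        logger.warning("MSD fit R^2=%.4f below %.2f: not diffusive in this window",
                       r2, R2_LINEAR_THRESHOLD)
    return DiffusionFit(
        D=float(fit.slope) / 6.0,
        stderr=float(fit.stderr) / 6.0,
        r_squared=r2,
        window=window,
        n_points=int(mask.sum()),
        linear=r2 >= R2_LINEAR_THRESHOLD,
        unit_style=msd.unit_style,
    )


# ---------------------------------------------------------------------------
# conductivity
# ---------------------------------------------------------------------------


def nernst_einstein(
    D: Sequence[float],
    z: Sequence[float],
    N: Sequence[int],
    volume: float,
    temperature: float,
) -> float:
    """Nernst-Einstein conductivity sigma = e^2/(V kB T) sum_i N_i z_i^2 D_i.

    All inputs SI (D in m^2/s, volume in m^3); neutral species contribute
    nothing.  Ignores ion-ion correlations by construction.
    """
    D = np.asarray(D, dtype=float)
    z = np.asarray(z, dtype=float)
    N = np.asarray(N, dtype=float)
    if not (len(D) == len(z) == len(N)):
        raise ValueError("D, z, N must have equal lengths")
    if volume <= 0 or temperature <= 0:
        raise ValueError("volume and temperature must be positive")
    return float(
        c.E_CHARGE**2 / (volume * c.KB * temperature) * np.sum(N * z**2 * D)
    )


# ---------------------------------------------------------------------------
# Green-Kubo viscosity
# ---------------------------------------------------------------------------


@dataclass
class ViscosityResult:
    """Green-Kubo shear viscosity with its running-integral curve."""

    eta: float  # Pa s
    t: np.ndarray  # s
    running: np.ndarray  # Pa s, running integral averaged over components
    acf: np.ndarray  # Pa^2, component-averaged stress ACF
    components: Tuple[str, ...]
    plateau_window: Tuple[float, float]


def _acf_fft(x: np.ndarray) -> np.ndarray:
    """Multiple-time-origin autocorrelation <x(0)x(t)> of a 1-D series."""
    T = len(x)
    n_fft = 1 << (2 * T - 1).bit_length()
    fx = np.fft.rfft(x, n=n_fft)
    raw = np.fft.irfft(fx * np.conj(fx), n=n_fft)[:T]
    return raw / (T - np.arange(T))


def gk_viscosity(
    thermo: ThermoTable,
    volume: float,
    temperature: float,
    t_cut: float,
    dt: float,
    components: Sequence[str] = ("Pxy", "Pxz", "Pyz"),
    unit_style: str = "si",
) -> ViscosityResult:
    """Shear viscosity eta = V/(kB T) * int_0^t <P_ab(0) P_ab(t)> dt.

    The autocorrelation uses every time origin; the running integral is
    cumulative-trapezoidal; eta is the mean of the running integral over the
    plateau window [0.8 t_cut, t_cut], averaged over the available
    off-diagonal components.

    Parameters
    ----------
    volume, temperature : SI (m^3, K)
    t_cut : s — upper integration limit
    dt : s — physical time between consecutive table rows
    unit_style : style the pressure columns are expressed in
    """
    steps = thermo["Step"]
    dsteps = np.diff(steps)
    if dsteps.size and not np.all(dsteps == dsteps[0]):
        raise ValueError("Green-Kubo integration requires uniform Step spacing")
    present = [cname for cname in components if cname in thermo.columns]
    if not present:
        raise ValueError(
            f"none of the pressure components {tuple(components)} found in table"
        )
    p_si = si_factor("pressure", unit_style)
    n_cut = int(round(t_cut / dt)) + 1
    acfs = []
    for cname in present:
        x = thermo[cname] * p_si
        acfs.append(_acf_fft(x)[:n_cut])
    acf = np.mean(acfs, axis=0)
    t = np.arange(len(acf)) * dt
    running = volume / (c.KB * temperature) * cumulative_trapezoid(acf, t, initial=0.0)
    lo = 0.8 * t_cut
    mask = (t >= lo) & (t <= t_cut)
    eta = float(np.mean(running[mask]))
    return ViscosityResult(
        eta=eta,
        t=t,
        running=running,
        acf=acf,
        components=tuple(present),
        plateau_window=(lo, t_cut),
    )


# ---------------------------------------------------------------------------
# residence time
# ---------------------------------------------------------------------------


@dataclass
class ResidenceResult:
    """Shell residence correlation C(t) and its characteristic times."""

    t: np.ndarray
    C: np.ndarray
    tau_integral: float
    tau_fit: float
    definition: str
    converged: bool
    n_pairs: int


def _bound_matrix(
    traj: Trajectory,
    system_map: SystemMap,
    center_sel: Selection,
    ligand_sel: Selection,
    cutoff: float,
) -> np.ndarray:
    """(n_pairs, T) boolean: any-atom center-ligand distance <= cutoff.

    Neighbor search uses a periodic KD-tree per frame; only molecule pairs
    that are bound at least once get a row (pairs never inside the shell
    contribute nothing to C(t)).
    """
    from scipy.spatial import cKDTree

    frame0 = traj.frames[0]
    c_idx = resolve_selection(center_sel, traj.n_atoms, frame0, system_map)
    l_idx = resolve_selection(ligand_sel, traj.n_atoms, frame0, system_map)
    c_mol_of = system_map.molecule_index[c_idx]
    l_mol_of = system_map.molecule_index[l_idx]
    events: list[set] = []
    for fr in traj.frames:
        lengths = fr.box.lengths
        lows = fr.box.lows
        lpos = np.mod(fr.positions[l_idx] - lows, lengths)
        cpos = np.mod(fr.positions[c_idx] - lows, lengths)
        tree = cKDTree(lpos, boxsize=lengths)
        hits = tree.query_ball_point(cpos, r=cutoff)
        bound = set()
        for a, neigh in enumerate(hits):
            cm = c_mol_of[a]
            for j in neigh:
                lm = l_mol_of[j]
                if lm != cm:
                    bound.add((int(cm), int(lm)))
        events.append(bound)
    all_pairs = sorted(set().union(*events)) if events else []
    rows = {pair: k for k, pair in enumerate(all_pairs)}
    b = np.zeros((len(all_pairs), traj.n_frames), dtype=bool)
    for ti, bound in enumerate(events):
        for pair in bound:
            b[rows[pair], ti] = True
    return b


def residence_time(
    traj: Trajectory,
    center_sel: Selection,
    ligand_sel: Selection,
    cutoff: float,
    definition: str = "continuous",
    system_map: Optional[SystemMap] = None,
    fit_range: Tuple[float, float] = (0.1, 1.0),
    integral_floor: float = 0.05,
) -> ResidenceResult:
    """Residence correlation C(t) of ligand molecules in a center's shell.

    ``intermittent`` counts a pair as bound at lag t whenever it is bound at
    both endpoints (re-entries allowed): C(t) = <h(0)h(t)>/<h(0)>.
    ``continuous`` requires unbroken occupancy over the whole interval.

    Two characteristic times are reported: the integral of C(t) up to its
    first crossing of `integral_floor` (flagged unconverged when C never
    crosses it) and an exponential fit over C in `fit_range` — the fit value
    is the headline number.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if definition not in ("intermittent", "continuous"):
        raise ValueError(f"unknown residence definition {definition!r}")
    if system_map is None:
        raise ValueError("residence_time requires a system map")
    b = _bound_matrix(traj, system_map, center_sel, ligand_sel, cutoff)
    if not b.any():
        raise ValueError("no center-ligand pair is ever within the cutoff")
    T = b.shape[1]
    bf = b.astype(float)
    C = np.empty(T)
    if definition == "intermittent":
        for tau in range(T):
            num = np.sum(bf[:, : T - tau] * bf[:, tau:])
            den = np.sum(bf[:, : T - tau])
            C[tau] = num / den if den > 0 else 0.0
    else:
        # run length of consecutive occupancy starting at each origin
        L = np.zeros_like(b, dtype=np.int64)
        L[:, -1] = b[:, -1]
        for ti in range(T - 2, -1, -1):
            L[:, ti] = np.where(b[:, ti], L[:, ti + 1] + 1, 0)
        for tau in range(T):
            num = np.sum(L[:, : T - tau] > tau)
            den = np.sum(b[:, : T - tau])
            C[tau] = num / den if den > 0 else 0.0
    t = np.arange(T) * traj.dt_sample

    below = np.flatnonzero(C < integral_floor)
    if below.size:
        stop = int(below[0])
        tau_integral = float(np.trapezoid(C[: stop + 1], t[: stop + 1]))
        converged = True
    else:
        tau_integral = float(np.trapezoid(C, t))
        converged = False
        logger.warning(
            "residence C(t) never fell below %.2f; integral time unconverged",
            integral_floor,
        )

    lo, hi = fit_range
    mask = (C >= lo) & (C <= hi) & (C > 0)
    if mask.sum() >= 2:
        fit = linregress(t[mask], np.log(C[mask]))
        tau_fit = float(-1.0 / fit.slope) if fit.slope < 0 else float("inf")
    else:
        tau_fit = float("inf")
    return ResidenceResult(
        t=t,
        C=C,
        tau_integral=tau_integral,
        tau_fit=tau_fit,
        definition=definition,
        converged=converged,
        n_pairs=b.shape[0],
    )


# ---------------------------------------------------------------------------
# dielectric constant
# ---------------------------------------------------------------------------


@dataclass
class DielectricResult:
    """Static dielectric constant from total-dipole fluctuations."""

    epsilon: float
    M_mean: np.ndarray  # C m
    M2_mean: float  # (C m)^2
    volume: float  # m^3
    n_frames: int


def dielectric_constant(
    traj: Trajectory,
    system_map: SystemMap,
    temperature: float,
) -> DielectricResult:
    """epsilon = 1 + (<M^2> - <M>^2) / (3 eps0 V kB T), M = sum q_i r_i.

    The total dipole M is assembled from whole (molecule-wise unwrapped)
    molecules so a molecule straddling the boundary contributes its physical
    dipole.  Restricted to systems whose every species is charge-neutral:
    with net-charged species the molecular-dipole sum is origin-dependent
    and an ionic conduction contribution is missing, so such systems are
    rejected rather than silently reporting a partial answer.
    """
    for tmpl in system_map.species:
        if abs(tmpl.net_charge) > 1e-6:
            raise UnsupportedSystemError(
                f"species {tmpl.name!r} carries net charge {tmpl.net_charge:+g} e; "
                "the fluctuation formula omits the ionic conduction contribution, "
                "so ionic systems are not supported"
            )
    q_si = system_map.charges * si_factor("charge", traj.unit_style)
    len_si = si_factor("length", traj.unit_style)
    volume = traj.frames[0].box.volume * len_si**3

    # block layout: atoms of each species form contiguous (n_mol, n_atom) blocks
    M = np.zeros((traj.n_frames, 3))
    offset = 0
    for tmpl, count in zip(system_map.species, system_map.counts):
        na = tmpl.n_atoms
        sl = slice(offset, offset + count * na)
        q = q_si[sl].reshape(count, na)
        for ti, fr in enumerate(traj.frames):
            pos = fr.positions[sl].reshape(count, na, 3)
            ref = pos[:, :1, :]
            whole = ref + minimum_image(pos - ref, fr.box.lengths)
            M[ti] += np.einsum("ma,mad->d", q, whole) * len_si
        offset += count * na

    M_mean = M.mean(axis=0)
    M2_mean = float(np.mean(np.sum(M**2, axis=1)))
    fluct = M2_mean - float(np.sum(M_mean**2))
    eps = 1.0 + fluct / (3.0 * c.EPS0 * volume * c.KB * temperature)
    return DielectricResult(
        epsilon=eps,
        M_mean=M_mean,
        M2_mean=M2_mean,
        volume=volume,
        n_frames=traj.n_frames,
    )
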