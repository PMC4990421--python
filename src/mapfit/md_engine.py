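"""Minimization and Langevin dynamics under the combined fitting potential.

The total energy is ``U_total = U_MD + U_EM + U_SS``: the structure-based
internal energy, the map-coupling energy ``U_EM = sum_i w_i V(r_i)`` with ``V``
evaluated by trilinear interpolation of the fitting-potential grid, and the
secondary-structure restraint energy.  Map forces are the exact gradient of the
trilinear interpolant, so force/energy consistency holds everywhere except on
cell faces, where the interpolant itself has a kink.

Units: Angstrom, femtosecond, amu, kcal/mol; kB = 0.0019872 kcal/mol/K.
The integrator is Langevin BAOAB splitting, which reduces to velocity Verlet
at zero friction (NVE limit) and to an overdamped quench at 0 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize as _sciopt

from .density_maps import MDFFPotential, trilinear
from .errors import NumericalError
from .structures import RestraintSet, Structure, Topology

__all__ = [
    "KB",
    "SimConfig",
    "SimState",
    "Trajectory",
    "EnergyBreakdown",
    "energy_forces",
    "minimize",
    "run_dynamics",
    "anneal_refine",
    "total_energy_in_map",
    "Simulation",
    "stationary",
]

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872
#: Converts (kcal/mol/A)/amu to acceleration in A/fs^2.
ACCEL = 4.184e-4


@dataclass
class SimConfig:
    """Parameters of a dynamics run.

    ``temperature`` is either a constant (K) or a piecewise-linear schedule
    given as a list of ``(time_fs, K)`` knots.  All stochastic draws come from
    ``seed``; a fixed seed reproduces the trajectory bitwise on one platform.
    """

    timestep: float = 10.0          # fs
    friction: float = 5.0           # ps^-1
    temperature: object = 300.0     # K or [(time_fs, K), ...]
    zeta: float = 0.3               # kcal/mol, map coupling scale
    seed: int = 0
    n_steps: int = 5000
    stride: int = 5                 # steps between recorded frames
    coupled: np.ndarray | None = None   # bool mask of map-coupled beads (default all)
    stat_window: int = 200          # frames in the stationarity window
    stat_tol: float = 0.1           # A, window range of RMSD-to-window-mean
    stage_max_steps: int = 5000     # hard cap per fitting stage
    anneal_ramp_steps: int = 1500   # 300 K -> 0 K ramp length
    anneal_hold_steps: int = 1000   # 0 K hold length

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        for _, T in self.temp_schedule():
            if T < 0:
                raise ValueError("temperatures must be non-negative")

    def temp_schedule(self):
        if np.isscalar(self.temperature):
            return [(0.0, float(self.temperature))]
        return [(float(t), float(T)) for t, T in self.temperature]

    def temperature_at(self, time_fs: float) -> float:
        sched = self.temp_schedule()
        times = np.array([t for t, _ in sched])
        temps = np.array([T for _, T in sched])
        return float(np.interp(time_fs, times, temps))


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    contact: float = 0.0
    excluded: float = 0.0
    ss: float = 0.0
    em: float = 0.0

    @property
    def md(self) -> float:
        return self.bond + self.angle + self.dihedral + self.contact + self.excluded

    @property
    def total(self) -> float:
        return self.md + self.ss + self.em


@dataclass
class SimState:
    positions: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    time: float
    energies: EnergyBreakdown


@dataclass
class Trajectory:
    """Recorded frames of a run: positions, times and per-frame energy components."""

    frames: np.ndarray          # (n_frames, n_beads, 3)
    times: np.ndarray           # fs, strictly increasing
    energies: list              # EnergyBreakdown per frame
    sigma: float | None = None  # blur width of the active map, if any

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @staticmethod
    def concatenate(parts: list["Trajectory"]) -> "Trajectory":
        frames = np.concatenate([p.frames for p in parts])
        offset = 0.0
        times = []
        energies = []
        for p in parts:
            times.append(p.times + offset)
            offset = times[-1][-1] + 1e-9
            energies.extend(p.energies)
        return Trajectory(frames, np.concatenate(times), energies)


# ---------------------------------------------------------------------------
# Energies and forces
# ---------------------------------------------------------------------------

def _wrap_angle(x):
    return (x + np.pi) % (2.0 * np.pi) - np.pi


def _cross(a, b):
    """Row-wise cross product without numpy's axis bookkeeping overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _dihedral_terms(pos, idx, p0, k):
    """Harmonic dihedral energy and forces, analytic gradient, per-term energies."""
    if len(idx) == 0:
        return 0.0, np.zeros_like(pos), np.empty(0)
    p = pos[idx]
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    nb2 = np.sqrt(np.einsum("ij,ij->i", b2, b2))
    m = _cross(n1, b2 / nb2[:, None])
    phi = np.arctan2(np.sum(m * n2, axis=1), np.sum(n1 * n2, axis=1))
    dphi = _wrap_angle(phi - p0)
    e_terms = k * dphi**2
    energy = float(np.sum(e_terms))
    dEdphi = 2.0 * k * dphi
    n1sq = np.sum(n1 * n1, axis=1)
    n2sq = np.sum(n2 * n2, axis=1)
    # guard collinear geometries (dihedral undefined, zero force)
    good = (n1sq > 1e-12) & (n2sq > 1e-12)
    dphi_d1 = np.zeros_like(b1)
    dphi_d4 = np.zeros_like(b1)
    dphi_d1[good] = (nb2[good] / n1sq[good])[:, None] * n1[good]
    dphi_d4[good] = (-nb2[good] / n2sq[good])[:, None] * n2[good]
    pq1 = np.sum(b1 * b2, axis=1) / nb2**2
    pq2 = np.sum(b3 * b2, axis=1) / nb2**2
    dphi_d2 = -(1.0 + pq1)[:, None] * dphi_d1 + pq2[:, None] * dphi_d4
    dphi_d3 = pq1[:, None] * dphi_d1 - (1.0 + pq2)[:, None] * dphi_d4
    forces = np.zeros_like(pos)
    for col, grad in enumerate((dphi_d1, dphi_d2, dphi_d3, dphi_d4)):
        np.add.at(forces, idx[:, col], -dEdphi[:, None] * grad)
    return energy, forces, e_terms


def _angle_terms(pos, idx, t0, k):
    if len(idx) == 0:
        return 0.0, np.zeros_like(pos)
    p = pos[idx]
    v1 = p[:, 0] - p[:, 1]
    v2 = p[:, 2] - p[:, 1]
    r1 = np.sqrt(np.einsum("ij,ij->i", v1, v1))
    r2 = np.sqrt(np.einsum("ij,ij->i", v2, v2))
    u1 = v1 / r1[:, None]
    u2 = v2 / r2[:, None]
    cos_t = np.clip(np.sum(u1 * u2, axis=1), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-12))
    dtheta = theta - t0
    energy = float(np.sum(k * dtheta**2))
    dEdt = 2.0 * k * dtheta
    dt_d0 = (cos_t[:, None] * u1 - u2) / (r1 * sin_t)[:, None]
    dt_d2 = (cos_t[:, None] * u2 - u1) / (r2 * sin_t)[:, None]
    dt_d1 = -(dt_d0 + dt_d2)
    forces = np.zeros_like(pos)
    for col, grad in enumerate((dt_d0, dt_d1, dt_d2)):
        np.add.at(forces, idx[:, col], -dEdt[:, None] * grad)
    return energy, forces


def _pair_harmonic(pos, idx, r0, k):
    if len(idx) == 0:
        return 0.0, np.zeros_like(pos)
    d = pos[idx[:, 0]] - pos[idx[:, 1]]
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    dr = r - r0
    energy = float(np.sum(k * dr**2))
    fmag = -2.0 * k * dr / np.maximum(r, 1e-12)
    fvec = fmag[:, None] * d
    forces = np.zeros_like(pos)
    np.add.at(forces, idx[:, 0], fvec)
    np.add.at(forces, idx[:, 1], -fvec)
    return energy, forces


def _contact_terms(pos, idx, r0, eps, width):
    """Gaussian-well native contacts: finite depth, so they can break under load."""
    if len(idx) == 0:
        return 0.0, np.zeros_like(pos)
    d = pos[idx[:, 0]] - pos[idx[:, 1]]
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    dr = r - r0
    g = np.exp(-(dr**2) / (2.0 * width**2))
    energy = float(np.sum(-eps * g))
    # dE/dr = eps * dr / width^2 * g ; force = -dE/dr * d/r
    fmag = -(eps * dr / width**2) * g / np.maximum(r, 1e-12)
    fvec = fmag[:, None] * d
    forces = np.zeros_like(pos)
    np.add.at(forces, idx[:, 0], fvec)
    np.add.at(forces, idx[:, 1], -fvec)
    return energy, forces


def _excluded_terms(pos, idx, radius, k):
    """Soft repulsion below per-pair onset distances (``radius`` may be an array)."""
    if len(idx) == 0:
        return 0.0, np.zeros_like(pos)
    d = pos[idx[:, 0]] - pos[idx[:, 1]]
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    radius = np.broadcast_to(np.asarray(radius, dtype=float), r.shape)
    close = r < radius
    if not np.any(close):
        return 0.0, np.zeros_like(pos)
    idx = idx[close]
    d = d[close]
    r = r[close]
    dr = radius[close] - r
    energy = float(np.sum(k * dr**2))
    fmag = 2.0 * k * dr / np.maximum(r, 1e-12)
    fvec = fmag[:, None] * d
    forces = np.zeros_like(pos)
    np.add.at(forces, idx[:, 0], fvec)
    np.add.at(forces, idx[:, 1], -fvec)
    return energy, forces


def energy_forces(
    positions: np.ndarray,
    topology: Topology,
    restraints: RestraintSet | None = None,
    potential: MDFFPotential | None = None,
    weights: np.ndarray | None = None,
    coupled: np.ndarray | None = None,
    excluded_idx: np.ndarray | None = None,
):
    """Energy components and forces at the given coordinates.

    ``weights`` are the per-bead map-coupling weights (required with a
    potential); ``coupled`` optionally masks the coupled subset (default all).
    Beads outside the potential grid sit on the flat ``V = zeta`` plateau and
    feel no map force.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite positions")
    p = topology.params
    e = EnergyBreakdown()
    e.bond, f = _pair_harmonic(pos, topology.bond_idx, topology.bond_r0, p.bond_k)
    forces = f
    e.angle, f = _angle_terms(pos, topology.angle_idx, topology.angle_t0, p.angle_k)
    forces += f
    n_top_dih = len(topology.dihedral_idx)
    if restraints is not None and len(restraints.dihedral_idx):
        dih_idx = np.concatenate([topology.dihedral_idx, restraints.dihedral_idx])
        dih_p0 = np.concatenate([topology.dihedral_p0, restraints.dihedral_p0])
        dih_k = np.concatenate([np.full(n_top_dih, p.dihedral_k),
                                np.full(len(restraints.dihedral_idx), restraints.k)])
    else:
        dih_idx, dih_p0, dih_k = topology.dihedral_idx, topology.dihedral_p0, p.dihedral_k
    _, f, e_terms = _dihedral_terms(pos, dih_idx, dih_p0, dih_k)
    e.dihedral = float(np.sum(e_terms[:n_top_dih]))
    e_ss_dih = float(np.sum(e_terms[n_top_dih:]))
    forces += f
    e.contact, f = _contact_terms(pos, topology.contact_idx, topology.contact_r0,
                                  p.contact_epsilon, p.contact_width)
    forces += f
    if excluded_idx is None:
        excl, excl_r = topology.excluded_idx, topology.excluded_r
    else:
        excl, excl_r = excluded_idx
    e.excluded, f = _excluded_terms(pos, excl, excl_r, p.excluded_k)
    forces += f
    if restraints is not None and restraints.n_restraints:
        e_p, f = _pair_harmonic(pos, restraints.pair_idx, restraints.pair_r0, restraints.k)
        forces += f
        e.ss = e_ss_dih + e_p
    if potential is not None and potential.zeta > 0:
        if weights is None:
            raise ValueError("map coupling requires per-bead weights")
        w = np.asarray(weights, dtype=float)
        mask = np.ones(len(pos), bool) if coupled is None else np.asarray(coupled, bool)
        if np.any(mask):
            grid = potential.grid
            frac = grid.frac_coords(pos[mask])
            v, g = trilinear(grid.values, frac, fill=potential.zeta)
            wm = w[mask]
            e.em = float(np.sum(wm * v))
            fmap = -(wm[:, None] * g / grid.voxel[None, :])
            forces[mask] += fmap
    return e, forces


def total_energy_in_map(
    positions, topology, restraints, blurred_potential, weights, coupled=None
) -> float:
    """Instantaneous total energy of a configuration under a given fitting map.

    This is the quantity entering the resolution-exchange Metropolis test;
    internal and restraint terms are identical across maps and cancel in the
    exchange difference.
    """
    e, _ = energy_forces(positions, topology, restraints, blurred_potential,
                         weights=weights, coupled=coupled)
    return e.total


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------

def minimize(
    structure: Structure,
    topology: Topology,
    restraints: RestraintSet | None = None,
    potential: MDFFPotential | None = None,
    steps: int = 500,
    step_size: float = 0.05,
    coupled: np.ndarray | None = None,
) -> Structure:
    """Steepest descent with backtracking; U_total is non-increasing; deterministic."""
    if steps < 1:
        raise ValueError("steps must be at least 1")
    pos = structure.xyz.copy()
    e, forces = energy_forces(pos, topology, restraints, potential,
                              weights=structure.weight, coupled=coupled)
    energy = e.total
    if not np.isfinite(energy):
        raise NumericalError(f"initial energy not finite: {energy}")
    alpha = step_size
    for _ in range(steps):
        fmax = np.abs(forces).max()
        if fmax < 1e-8:
            break
        trial = pos + (alpha / fmax) * forces
        e_t, f_t = energy_forces(trial, topology, restraints, potential,
                                 weights=structure.weight, coupled=coupled)
        if np.isfinite(e_t.total) and e_t.total <= energy:
            pos, energy, forces = trial, e_t.total, f_t
            alpha = min(alpha * 1.2, 1.0)
        else:
            alpha *= 0.5
            if alpha < 1e-10:
                break
    if not np.isfinite(energy):
        raise NumericalError("minimization diverged to a non-finite energy")
    return structure.with_positions(pos)


# ---------------------------------------------------------------------------
# Langevin dynamics
# ---------------------------------------------------------------------------

class Simulation:
    """Mutable integrator state for BAOAB Langevin dynamics.

    Holds positions/velocities/forces; :meth:`run` integrates and records
    frames.  Used directly by the replica-exchange driver, which interleaves
    short runs with map swaps.
    """

    def __init__(self, structure, topology, restraints=None, potential=None,
                 config: SimConfig | None = None, rng: np.random.Generator | None = None):
        self.structure = structure
        self.topology = topology
        self.restraints = restraints
        self.potential = potential
        self.config = config or SimConfig()
        self.rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        self.positions = structure.xyz.copy()
        self.mass = structure.mass.copy()
        self.weights = structure.weight.copy()
        self.coupled = self.config.coupled
        self._excl_active = (topology.excluded_idx, topology.excluded_r)
        self._excl_countdown = 0
        T0 = self.config.temperature_at(0.0)
        sigma_v = np.sqrt(KB * max(T0, 0.0) * ACCEL / self.mass)
        self.velocities = self.rng.normal(size=(structure.n_beads, 3)) * sigma_v[:, None]
        self.time = 0.0
        e, f = self._eval()
        self.energies, self.forces = e, f

    #: rebuild interval (integrator steps) and skin width (A) of the
    #: excluded-volume neighbor list; displacement per interval stays well
    #: below skin/2 at the default timestep and temperatures.
    NLIST_EVERY = 20
    NLIST_SKIN = 2.0

    def _refresh_neighbor_list(self) -> None:
        idx = self.topology.excluded_idx
        if len(idx) == 0:
            return
        d = self.positions[idx[:, 0]] - self.positions[idx[:, 1]]
        r2 = np.einsum("ij,ij->i", d, d)
        cut = (self.topology.excluded_r + self.NLIST_SKIN) ** 2
        keep = r2 < cut
        self._excl_active = (idx[keep], self.topology.excluded_r[keep])
        self._excl_countdown = self.NLIST_EVERY

    def _eval(self, full: bool = False):
        if full or self._excl_countdown <= 0:
            self._refresh_neighbor_list()
        self._excl_countdown -= 1
        excl = None if full else self._excl_active
        return energy_forces(self.positions, self.topology, self.restraints,
                             self.potential, weights=self.weights, coupled=self.coupled,
                             excluded_idx=excl)

    def set_potential(self, potential) -> None:
        self.potential = potential
        self.energies, self.forces = self._eval()

    @property
    def state(self) -> SimState:
        return SimState(self.positions.copy(), self.velocities.copy(),
                        self.forces.copy(), self.time, self.energies)

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.mass[:, None] * self.velocities**2) / ACCEL)

    def step(self, n: int = 1) -> None:
        dt = self.config.timestep
        gamma = self.config.friction / 1000.0  # ps^-1 -> fs^-1
        c1 = np.exp(-gamma * dt)
        inv_m = (ACCEL / self.mass)[:, None]
        for _ in range(n):
            T = self.config.temperature_at(self.time + 0.5 * dt)
            c2 = np.sqrt((1.0 - c1**2) * KB * max(T, 0.0) * ACCEL / self.mass)[:, None]
            self.velocities += 0.5 * dt * self.forces * inv_m
            self.positions += 0.5 * dt * self.velocities
            if gamma > 0:
                self.velocities = c1 * self.velocities + c2 * self.rng.normal(
                    size=self.velocities.shape)
            self.positions += 0.5 * dt * self.velocities
            try:
                self.energies, self.forces = self._eval()
            except ValueError as exc:
                raise NumericalError(
                    "dynamics diverged (non-finite state); try a smaller timestep"
                ) from exc
            self.velocities += 0.5 * dt * self.forces * inv_m
            self.time += dt
        if not np.isfinite(self.energies.total):
            raise NumericalError(
                "dynamics diverged (non-finite energy); try a smaller timestep")
        if np.abs(self.velocities).max() * dt > 50.0:
            raise NumericalError(
                "dynamics unstable (displacement per step exceeds 50 A); "
                "try a smaller timestep")

    def run(self, n_steps: int, stride: int | None = None,
            until_stationary: bool = False) -> tuple[Trajectory, bool]:
        """Integrate, recording every ``stride`` steps.

        With ``until_stationary`` the run ends early once the RMSD of recorded
        frames to their window mean has a range below ``stat_tol`` over the
        last ``stat_window`` frames.  Returns (trajectory, converged flag);
        the flag is True when stationarity was reached (always True for plain
        fixed-length runs).
        """
        stride = stride or self.config.stride
        frames, times, energies = [self.positions.copy()], [self.time], [self.energies]
        done = 0
        converged = not until_stationary
        while done < n_steps:
            chunk = min(stride, n_steps - done)
            self.step(chunk)
            done += chunk
            frames.append(self.positions.copy())
            times.append(self.time)
            energies.append(self.energies)
            if until_stationary and len(frames) % 20 == 0:
                w = self.config.stat_window
                if len(frames) >= w and stationary(np.asarray(frames[-w:]),
                                                   self.config.stat_tol):
                    converged = True
                    break
        return Trajectory(np.asarray(frames), np.asarray(times), energies), converged


def stationary(window_frames: np.ndarray, tol: float) -> bool:
    """True when the per-frame RMSD to the window-mean structure spans < tol."""
    mean = window_frames.mean(axis=0)
    r = np.sqrt(np.mean(np.sum((window_frames - mean) ** 2, axis=2), axis=1))
    return float(r.max() - r.min()) < tol


def run_dynamics(structure, topology, restraints=None, potential=None,
                 config: SimConfig | None = None) -> Trajectory:
    """Fixed-length Langevin run from the structure's coordinates."""
    config = config or SimConfig()
    sim = Simulation(structure, topology, restraints, potential, config)
    traj, _ = sim.run(config.n_steps, config.stride)
    return traj


def anneal_refine(structure, topology, restraints=None, potential=None,
                  config: SimConfig | None = None) -> Structure:
    """Final re-refinement: full coupling, 300 K -> 0 K linear ramp, 0 K hold, quench.

    Mirrors the post-fitting schedule used after every fitting protocol: the
    potential is rescaled to zeta = 1.0, the thermostat ramps to 0 K, and a
    short minimization finishes the quench so the end-point energy never
    exceeds the start.
    """
    config = config or SimConfig()
    pot = potential.rescaled(1.0) if (potential is not None and potential.zeta > 0) else potential
    e0, _ = energy_forces(structure.xyz, topology, restraints, pot,
                          weights=structure.weight, coupled=config.coupled)
    ramp_fs = config.anneal_ramp_steps * config.timestep
    sched = [(0.0, config.temperature_at(0.0)), (ramp_fs, 0.0)]
    cfg = replace(config, temperature=sched)
    sim = Simulation(structure, topology, restraints, pot, cfg)
    if config.anneal_ramp_steps > 0:
        sim.step(config.anneal_ramp_steps)
    if config.anneal_hold_steps > 0:
        sim.step(config.anneal_hold_steps)
    out = _polish(structure.with_positions(sim.positions), topology, restraints, pot,
                  config.coupled)
    e1, _ = energy_forces(out.xyz, topology, restraints, pot,
                          weights=structure.weight, coupled=config.coupled)
    if e1.total > e0.total:
        # quench from the original coordinates instead (already near-minimal input)
        out = _polish(structure, topology, restraints, pot, config.coupled)
    return out


def _polish(structure, topology, restraints, potential, coupled,
            maxiter: int = 400) -> Structure:
    """Quasi-Newton quench to the nearest local minimum (deterministic)."""
    shape = structure.xyz.shape

    def fun(flat):
        e, f = energy_forces(flat.reshape(shape), topology, restraints, potential,
                             weights=structure.weight, coupled=coupled)
        return e.total, -f.ravel()

    res = _sciopt.minimize(fun, structure.xyz.ravel(), jac=True, method="L-BFGS-B",
                           options={"maxiter": maxiter})
    e_new = res.fun
    e_old, _ = energy_forces(structure.xyz, topology, restraints, potential,
                             weights=structure.weight, coupled=coupled)
    if not np.isfinite(e_new) or e_new > e_old.total:
        return structure.copy()
    return structure.with_positions(res.x.reshape(shape))
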