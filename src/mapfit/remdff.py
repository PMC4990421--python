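"""Resolution-exchange fitting: parallel replicas on the blur ladder.

One replica per blur half-width runs Langevin dynamics in its own fitting
potential; at a regular interval, neighboring rungs (alternating even/odd
pairings) attempt a Metropolis swap of their *maps*,

    p = min(1, exp(-[E(x_i, s_j) + E(x_j, s_i) - E(x_i, s_i) - E(x_j, s_j)] / kB T)),

where E(x, s) is the instantaneous total energy of configuration x in the
potential of blur width s.  Internal and restraint energies cancel in the
difference, so only the map-coupling terms matter.  Swapping maps rather than
coordinates is physically equivalent and keeps each trajectory contiguous.
The run ends when the energy of whichever replica holds the unblurred map is
stationary; the best unblurred-map snapshot (by map correlation) is annealed
into the final model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import density_maps as dm
from .cascade import BlurSchedule, FitResult, StageRecord, stage_potential, _gcc
from .md_engine import KB, SimConfig, Simulation, Trajectory, anneal_refine, minimize, \
    stationary, total_energy_in_map
from .structures import Structure, assign_ss_restraints, build_topology, rmsd, ss_segments

__all__ = ["ExchangeLog", "ExchangeAttempt", "Replica", "exchange_probability",
           "attempt_exchanges", "run_remdff"]


@dataclass
class ExchangeAttempt:
    time: float
    pair: tuple          # ladder indices (i, i+1)
    delta: float
    probability: float
    accepted: bool


@dataclass
class ExchangeLog:
    attempts: list = field(default_factory=list)

    def record(self, *args) -> None:
        self.attempts.append(ExchangeAttempt(*args))

    def acceptance_rates(self) -> dict:
        """Per-pair empirical acceptance rate and mean Metropolis probability."""
        out: dict = {}
        for a in self.attempts:
            acc, n, psum = out.get(a.pair, (0, 0, 0.0))
            out[a.pair] = (acc + int(a.accepted), n + 1, psum + a.probability)
        return {pair: {"rate": acc / n, "mean_p": psum / n, "n": n}
                for pair, (acc, n, psum) in out.items()}


def exchange_probability(e_i_si: float, e_i_sj: float, e_j_si: float, e_j_sj: float,
                         temperature: float) -> float:
    """Metropolis acceptance probability for swapping the maps of two replicas."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    for e in (e_i_si, e_i_sj, e_j_si, e_j_sj):
        if not math.isfinite(e):
            raise ValueError("non-finite energy in exchange test")
    delta = e_i_sj + e_j_si - e_i_si - e_j_sj
    if delta <= 0:
        return 1.0
    return math.exp(-delta / (KB * temperature))


@dataclass
class Replica:
    """One rung-holder: an integrator plus its current blur width and potential."""

    sim: Simulation
    sigma: float
    potential: dm.MDFFPotential
    ladder_pos: int   # current rung index, 0 = most blurred


def attempt_exchanges(replicas: list, parity: int, rng: np.random.Generator,
                      temperature: float, log: ExchangeLog) -> None:
    """One round of neighbor swap attempts at the given parity (0 = even pairs).

    ``replicas`` must be ordered by ladder position.  On acceptance the two
    replicas exchange sigma and potential; coordinates stay with their
    trajectory.  The sigma multiset is conserved by construction.
    """
    order = sorted(replicas, key=lambda r: r.ladder_pos)
    for k in range(parity, len(order) - 1, 2):
        ri, rj = order[k], order[k + 1]
        e_i_si = ri.sim.energies.total
        e_j_sj = rj.sim.energies.total
        e_i_sj = total_energy_in_map(ri.sim.positions, ri.sim.topology, ri.sim.restraints,
                                     rj.potential, ri.sim.weights, ri.sim.coupled)
        e_j_si = total_energy_in_map(rj.sim.positions, rj.sim.topology, rj.sim.restraints,
                                     ri.potential, rj.sim.weights, rj.sim.coupled)
        p = exchange_probability(e_i_si, e_i_sj, e_j_si, e_j_sj, temperature)
        accepted = bool(rng.random() < p)
        delta = e_i_sj + e_j_si - e_i_si - e_j_sj
        log.record(ri.sim.time, (k, k + 1), delta, p, accepted)
        if accepted:
            ri.sigma, rj.sigma = rj.sigma, ri.sigma
            ri.potential, rj.potential = rj.potential, ri.potential
            ri.ladder_pos, rj.ladder_pos = rj.ladder_pos, ri.ladder_pos
            ri.sim.set_potential(ri.potential)
            rj.sim.set_potential(rj.potential)


def run_remdff(search: Structure, density: dm.DensityMap, schedule: BlurSchedule,
               config: SimConfig | None = None, reference: Structure | None = None,
               resolution: float = 3.0, exchange_interval: int = 500,
               max_rounds: int | None = None):
    """Resolution-exchange fit: one replica per schedule rung.

    All replicas start from the minimized search model.  Dynamics advance in
    chunks of ``exchange_interval`` steps between alternating-parity swap
    rounds; the run ends when the energy series of the sigma = 0 holder is
    stationary (or the round cap is hit, recorded as a warning).  Snapshots
    taken while holding sigma = 0 are scored by map correlation; the best one
    is annealed into the final structure.

    Returns (FitResult, ExchangeLog).
    """
    config = config or SimConfig()
    topology = build_topology(search)
    restraints = assign_ss_restraints(search, ss_segments(search))
    start = minimize(search, topology, restraints, None, steps=200)
    temperature = config.temperature_at(0.0)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 14]))
    potentials = [stage_potential(density, s, config.zeta) for s in schedule]
    replicas = []
    for k, (sigma, pot) in enumerate(zip(schedule, potentials)):
        cfg = SimConfig(**{**config.__dict__, "seed": int(rng.integers(2**31))})
        sim = Simulation(start, topology, restraints, pot, cfg)
        replicas.append(Replica(sim, sigma, pot, k))
    log = ExchangeLog()
    if max_rounds is None:
        max_rounds = max(1, int(np.ceil(len(schedule) * config.stage_max_steps
                                        / exchange_interval)))
    zero_frames: list[np.ndarray] = []
    zero_energy: list[float] = []
    zero_steps = 0
    warnings: list[str] = []
    converged = False
    # the sigma=0 holder is sampled once per round, so a modest window of
    # rounds already spans several thousand integrator steps
    window = 10
    for rnd in range(max_rounds):
        for rep in replicas:
            rep.sim.step(exchange_interval)
        if len(replicas) > 1:
            attempt_exchanges(replicas, rnd % 2, rng, temperature, log)
        holder = min(replicas, key=lambda r: r.sigma)
        zero_frames.append(holder.sim.positions.copy())
        zero_energy.append(holder.sim.energies.total)
        zero_steps += exchange_interval
        if len(zero_frames) >= window and stationary(
                np.asarray(zero_frames[-window:]), config.stat_tol):
            converged = True
            break
    if not converged:
        warnings.append("round cap reached before the sigma=0 replica was stationary")
    # best sigma=0 snapshot by map correlation
    from .validate import gcc as _gcc_fn

    best, best_val = zero_frames[-1], -np.inf
    for frame in zero_frames[max(0, len(zero_frames) - 40):]:
        try:
            val = _gcc_fn(density, search.with_positions(frame), resolution)
        except ValueError:
            continue
        if val > best_val:
            best, best_val = frame, val
    current = search.with_positions(best)
    pot0 = stage_potential(density, 0.0, config.zeta)
    current = anneal_refine(current, topology, restraints, pot0, config)
    record = StageRecord(
        sigma=0.0, steps=zero_steps, converged=converged,
        rmsd_to_reference=(rmsd(current, reference) if reference is not None else None),
        gcc=_gcc(density, current, resolution),
        energies=min(replicas, key=lambda r: r.sigma).sim.energies,
    )
    traj = Trajectory(np.asarray(zero_frames),
                      np.arange(len(zero_frames), dtype=float) * exchange_interval
                      * config.timestep,
                      [record.energies] * len(zero_frames))
    result = FitResult(current, [record], traj, warnings)
    return result, log
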