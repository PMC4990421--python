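"""Cascade fitting: sequential refinement through a ladder of blurred maps.

The experimental map is blurred with a decreasing series of Gaussian
half-widths sigma_1 > sigma_2 > ... > sigma_L >= 0; the search model is fitted
to each map in turn, the fitted structure seeding the next stage, ending with
the unblurred map and a final annealed re-refinement.  Blurring removes the
corrugation of a high-resolution fitting potential, so the early stages funnel
the model across barriers that trap a direct fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import density_maps as dm
from .md_engine import SimConfig, Simulation, Trajectory, anneal_refine, minimize
from .structures import RestraintSet, Structure, Topology, TopologyParams, \
    assign_ss_restraints, build_topology, rmsd, ss_segments

__all__ = ["BlurSchedule", "FitResult", "StageRecord", "make_schedule",
           "run_cmdff", "run_direct"]

#: Density threshold percentile (of strictly positive voxels) used whenever a
#: blurred map is converted to a fitting potential.
THRESHOLD_PERCENTILE = 5.0


@dataclass
class BlurSchedule:
    """Ordered blur half-widths (A), strictly decreasing, last entry >= 0."""

    sigmas: tuple

    def __post_init__(self) -> None:
        self.sigmas = tuple(float(s) for s in self.sigmas)
        if not self.sigmas:
            raise ValueError("schedule must contain at least one sigma")
        if self.sigmas[-1] < 0:
            raise ValueError("the final sigma must be non-negative")
        if any(a <= b for a, b in zip(self.sigmas, self.sigmas[1:])):
            raise ValueError("sigmas must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.sigmas)

    def __iter__(self):
        return iter(self.sigmas)


def make_schedule(sigma_start: float, step: float) -> BlurSchedule:
    """Arithmetic blur ladder from ``sigma_start`` down to 0 inclusive.

    ``make_schedule(5, 1)`` gives (5, 4, 3, 2, 1, 0); ``make_schedule(5, 0.5)``
    gives the 11-rung ladder ending at 0.
    """
    if sigma_start <= 0:
        raise ValueError("sigma_start must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    if step > sigma_start:
        raise ValueError(f"step {step} exceeds sigma_start {sigma_start}")
    n = int(round(sigma_start / step))
    sigmas = [sigma_start - k * step for k in range(n + 1)]
    if abs(sigmas[-1]) > 1e-9:
        sigmas.append(0.0)
    sigmas[-1] = 0.0
    return BlurSchedule(tuple(sigmas))


@dataclass
class StageRecord:
    sigma: float
    steps: int
    converged: bool
    rmsd_to_reference: float | None
    gcc: float | None
    energies: object  # EnergyBreakdown at stage end


@dataclass
class FitResult:
    """Outcome of a fitting protocol: final model, per-stage records, trajectory."""

    structure: Structure
    stages: list
    trajectory: Trajectory
    warnings: list = field(default_factory=list)

    @property
    def final_rmsd(self) -> float | None:
        return self.stages[-1].rmsd_to_reference if self.stages else None


def stage_potential(density: dm.DensityMap, sigma: float, zeta: float) -> dm.MDFFPotential:
    """Blur the map by sigma and convert it to a fitting potential.

    The noise threshold is recomputed per blurred map at a fixed percentile of
    its positive voxel values, so the plateau tracks the blur level.
    """
    blurred = dm.gaussian_blur(density, sigma) if sigma > 0 else density
    thr = dm.positive_percentile_threshold(blurred.values, THRESHOLD_PERCENTILE)
    return dm.potential_from_map(blurred, zeta, thr)


def _gcc(density, structure, resolution):
    from .validate import gcc

    try:
        return gcc(density, structure, resolution)
    except ValueError:
        return None


def _run_stages(search, density, schedule, config, reference, resolution,
                topology=None, restraints=None, do_anneal=True):
    config = config or SimConfig()
    topology = topology or build_topology(search)
    if restraints is None:
        restraints = assign_ss_restraints(search, ss_segments(search))
    current = minimize(search, topology, restraints, None, steps=200)
    stages: list[StageRecord] = []
    parts: list[Trajectory] = []
    warnings: list[str] = []
    rng = np.random.default_rng(config.seed)
    for sigma in schedule:
        pot = stage_potential(density, sigma, config.zeta)
        cfg_stage = SimConfig(**{**config.__dict__,
                                 "seed": int(rng.integers(2**31))})
        sim = Simulation(current, topology, restraints, pot, cfg_stage)
        traj, converged = sim.run(config.stage_max_steps, until_stationary=True)
        traj.sigma = sigma
        parts.append(traj)
        current = current.with_positions(sim.positions)
        if not converged:
            warnings.append(f"stage sigma={sigma}: step cap reached before stationarity")
        stages.append(StageRecord(
            sigma=sigma,
            steps=int(round((traj.times[-1] - traj.times[0]) / config.timestep)),
            converged=converged,
            rmsd_to_reference=(rmsd(current, reference) if reference is not None else None),
            gcc=_gcc(density, current, resolution),
            energies=sim.energies,
        ))
    if do_anneal:
        pot0 = stage_potential(density, 0.0, config.zeta)
        current = anneal_refine(current, topology, restraints, pot0, config)
        if stages:
            stages[-1] = StageRecord(
                sigma=stages[-1].sigma, steps=stages[-1].steps,
                converged=stages[-1].converged,
                rmsd_to_reference=(rmsd(current, reference) if reference is not None else None),
                gcc=_gcc(density, current, resolution),
                energies=stages[-1].energies,
            )
    return FitResult(current, stages, Trajectory.concatenate(parts), warnings)


def run_cmdff(search: Structure, density: dm.DensityMap, schedule: BlurSchedule,
              config: SimConfig | None = None, reference: Structure | None = None,
              resolution: float = 3.0, topology: Topology | None = None,
              restraints: RestraintSet | None = None, anneal: bool = True) -> FitResult:
    """Cascade fit of the search model through the blur ladder.

    The topology is built from the *search* conformation (unless supplied), so
    fitting genuinely deforms the model against its internal energy.  Each
    stage runs to stationarity (hard step cap recorded as a warning on
    failure); the final stage uses the unblurred map, followed by an annealed
    re-refinement at full coupling.  Per-stage RMSD to the reference (if
    given) and map correlation are recorded.
    """
    return _run_stages(search, density, schedule, config, reference, resolution,
                       topology, restraints, do_anneal=anneal)


def run_direct(search: Structure, density: dm.DensityMap,
               config: SimConfig | None = None, reference: Structure | None = None,
               resolution: float = 3.0, topology: Topology | None = None,
               restraints: RestraintSet | None = None, anneal: bool = True) -> FitResult:
    """Single-stage fit against the unblurred map (the degenerate cascade)."""
    return _run_stages(search, density, BlurSchedule((0.0,)), config, reference,
                       resolution, topology, restraints, do_anneal=anneal)
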