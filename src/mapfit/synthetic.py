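"""Deterministic synthetic fixtures for fitting and validation experiments.

The central fixture is a two-domain "hinge" protein analog: two helix-hairpin
domains joined by a short flexible linker, emulating the open/closed conformer
pair used in proof-of-principle flexible-fitting experiments.  Conformers at a
prescribed RMSD from the reference are produced by hinge rotation, heating, or
region-local displacement; synthetic maps (with optional half-map noise pairs
and spatially varying resolution) are rendered from the bead model.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import density_maps as dm
from .md_engine import SimConfig, Simulation, minimize
from .structures import Structure, TopologyParams, build_topology, rmsd

__all__ = [
    "ToySpec",
    "make_toy_dimer",
    "toy_hinge_region",
    "displace_conformer",
    "make_halfmaps",
    "make_localres_map",
    "make_fixture",
]

#: Ideal alpha-helix C-alpha geometry.
HELIX_RADIUS = 2.3       # A
HELIX_RISE = 1.5         # A per residue
HELIX_TWIST = 100.0      # degrees per residue


@dataclass
class ToySpec:
    """Geometry of the two-domain toy: two helix-hairpin domains + 4-residue linker."""

    residues_per_domain: int = 60
    hinge_angle: float = 0.0     # degrees, rotation of domain B about the linker
    slide: float = 0.0           # A, translation of domain B along the bundle axis
    seed: int = 0
    helix_radius: float = HELIX_RADIUS
    helix_rise: float = HELIX_RISE
    helix_twist: float = HELIX_TWIST

    def __post_init__(self) -> None:
        if self.residues_per_domain < 20:
            raise ValueError("need at least 20 residues per domain")
        if not (0 < self.helix_radius < 10 and 0 < self.helix_rise < 5):
            raise ValueError("unphysical helix geometry")

    @property
    def n_beads(self) -> int:
        return 2 * self.residues_per_domain + 4


def _ideal_helix(n: int, spec: ToySpec) -> np.ndarray:
    """CA trace of an ideal helix along +x starting near the origin."""
    t = np.deg2rad(spec.helix_twist) * np.arange(n)
    return np.stack(
        [spec.helix_rise * np.arange(n),
         spec.helix_radius * np.cos(t),
         spec.helix_radius * np.sin(t)], axis=1)


def _hairpin_domain(n: int, spec: ToySpec) -> tuple[np.ndarray, np.ndarray]:
    """Compact three-helix bundle domain with unequal helix lengths.

    Returns (coords, ss labels).  The asymmetric, genuinely 3-D mass
    distribution keeps the domain orientation identifiable even under heavy
    map blurring, as for a real protein fold.
    """
    n_turn = 4
    n_hel_total = n - 2 * n_turn
    n1 = int(round(0.40 * n_hel_total))
    n2 = int(round(0.33 * n_hel_total))
    n3 = n_hel_total - n1 - n2
    spacing = 2.0 * spec.helix_radius + 5.5   # center-to-center helix packing
    h1 = _ideal_helix(n1, spec)
    h2 = _ideal_helix(n2, spec) * np.array([-1.0, 1.0, -1.0]) + np.array(
        [h1[-1, 0], spacing, 0.0])
    h3 = _ideal_helix(n3, spec) + np.array(
        [0.0, 0.5 * spacing, spacing * math.sin(math.pi / 3.0)])

    def _turn(start, end):
        frac = np.linspace(0, 1, n_turn + 2)[1:-1]
        pts = start[None, :] + frac[:, None] * (end - start)[None, :]
        pts[:, 0] += 2.5 * np.sin(np.pi * frac)
        return pts

    t1 = _turn(h1[-1], h2[0])
    t2 = _turn(h2[-1], h3[0])
    coords = np.concatenate([h1, t1, h2, t2, h3])
    ss = np.array(["H"] * n1 + ["C"] * n_turn + ["H"] * n2
                  + ["C"] * n_turn + ["H"] * n3)
    return coords, ss


def make_toy_dimer(spec: ToySpec) -> Structure:
    """Two helix-hairpin domains joined end-to-end by a 4-residue linker.

    ``spec.hinge_angle`` rotates domain B rigidly about a hinge axis through
    the linker midpoint; domain-internal coordinates are independent of the
    hinge angle.  Bitwise deterministic for a given spec.
    """
    n = spec.residues_per_domain
    dom, ss_dom = _hairpin_domain(n, spec)
    # domain A as built; an extended 4-residue linker continues from its end
    a = dom.copy()
    end_a = a[n - 1]
    start_b = end_a + 5 * np.array([3.6, 0.5, 0.0]) + np.array([spec.slide, 0.0, 0.0])
    frac = np.arange(1, 5)[:, None] / 5.0
    linker = end_a[None, :] + frac * (start_b - end_a)[None, :]
    # zig-zag offsets keep linker angles/dihedrals away from the collinear
    # singularity of their gradients
    linker[:, 1] += np.array([0.8, -0.8, 0.8, -0.8])
    linker[:, 2] += np.array([0.4, 0.8, -0.8, -0.4])
    # tip domain B out of domain A's plane so the dimer is genuinely 3-D
    b = _rotate_about(dom.copy(), dom[0], np.array([1.0, 0.0, 0.0]), np.deg2rad(60.0))
    b = b + (start_b - b[0])
    if spec.hinge_angle != 0.0:
        pivot = linker[-1]
        axis = np.array([0.0, 0.0, 1.0])
        b = _rotate_about(b, pivot, axis, np.deg2rad(spec.hinge_angle))
    coords = np.concatenate([a, linker, b])
    ss = np.concatenate([ss_dom, ["C"] * 4, ss_dom])
    return Structure.from_xyz(coords, chain_id="A", ss=ss)


def toy_hinge_region(spec: ToySpec) -> np.ndarray:
    """Bead indices of domain B (the moving rigid body of the toy)."""
    return np.arange(spec.residues_per_domain + 4, spec.n_beads)


def _rotate_about(coords, pivot, axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(angle * axis)
    return rot.apply(coords - pivot) + pivot


# ---------------------------------------------------------------------------
# Conformer displacement
# ---------------------------------------------------------------------------

def _relax(structure: Structure, reference: Structure, steps: int = 150) -> Structure:
    """Brief bonded relaxation (no map) restoring local geometry after displacement."""
    topo = build_topology(reference, TopologyParams())
    return minimize(structure, topo, steps=steps, step_size=0.02)


def displace_conformer(
    structure: Structure,
    target_rmsd: float,
    mode: str = "hinge",
    seed: int = 0,
    region: np.ndarray | None = None,
    tol: float = 0.2,
    pivot: np.ndarray | None = None,
    axis: np.ndarray | None = None,
) -> Structure:
    """Displaced conformer at a prescribed RMSD from the input.

    Modes
    -----
    hinge : rigid rotation of the trailing region (default: the second half of
        the chain) about a hinge axis; the rotation amplitude is solved by
        bisection so the overall RMSD lands in ``target +- tol``.  By default
        the pivot sits at the region's first bead with a random axis; an
        explicit ``pivot``/``axis`` selects a specific rigid-body coordinate
        (e.g. a spin about the domain's own long axis, which keeps the
        displaced domain inside the density envelope of the original pose).
    heat : seeded high-temperature unbiased dynamics; the first snapshot whose
        RMSD enters the target band is returned.
    local : hinge-style displacement confined to ``region`` (bead indices),
        bisected on the *in-region* RMSD; out-of-region beads stay put.

    After a hinge/local displacement a short bonded minimization restores the
    junction geometry.
    """
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be non-negative")
    if target_rmsd == 0:
        return structure.copy()
    rng = np.random.default_rng(seed)
    n = structure.n_beads

    if mode in ("hinge", "local"):
        if mode == "local":
            if region is None:
                raise ValueError("mode='local' requires a region")
            region = np.asarray(region, dtype=int)
        else:
            region = np.arange(n // 2, n) if region is None else np.asarray(region, int)
        moving = structure.xyz[region]
        if pivot is None:
            pivot = moving[0]
        if axis is None:
            # random hinge axis orthogonal to the region's long axis, for a lever arm
            long_axis = moving[-1] - moving[0]
            long_axis /= np.linalg.norm(long_axis)
            v = rng.normal(size=3)
            v -= long_axis * (v @ long_axis)
            axis = v / np.linalg.norm(v)
        else:
            axis = np.asarray(axis, dtype=float)
            axis = axis / np.linalg.norm(axis)

        def achieved(angle):
            xyz = structure.xyz.copy()
            xyz[region] = _rotate_about(moving, pivot, axis, angle)
            trial = structure.with_positions(xyz)
            if mode == "local":
                sub_r = Structure.from_xyz(structure.xyz[region])
                sub_t = Structure.from_xyz(xyz[region])
                return rmsd(sub_r, sub_t), trial
            return rmsd(structure, trial), trial

        lo, hi = 0.0, np.pi
        r_hi, _ = achieved(hi)
        if r_hi < target_rmsd - tol:
            raise ValueError(
                f"target RMSD {target_rmsd} A unreachable by hinge rotation; "
                f"maximum achievable is {r_hi:.2f} A")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            r_mid, trial = achieved(mid)
            if abs(r_mid - target_rmsd) <= 0.5 * tol:
                break
            if r_mid < target_rmsd:
                lo = mid
            else:
                hi = mid
        out = _relax(trial, structure)
        return out

    if mode == "heat":
        topo = build_topology(structure, TopologyParams())
        cfg = SimConfig(temperature=1000.0, seed=int(rng.integers(2**31)),
                        timestep=8.0, friction=10.0)
        sim = Simulation(structure, topo, config=cfg)
        r = 0.0
        for _ in range(4000):
            sim.step(10)
            r = rmsd(structure, structure.with_positions(sim.positions))
            if r >= target_rmsd - 0.5 * tol:
                # relaxation pulls the snapshot back; accept on post-relax RMSD
                cand = _relax(structure.with_positions(sim.positions), structure, steps=80)
                r_rel = rmsd(structure, cand)
                if abs(r_rel - target_rmsd) <= tol:
                    return cand
        raise ValueError(
            f"heating did not reach target RMSD {target_rmsd} A within the step budget "
            f"(last RMSD {r:.2f} A)")

    raise ValueError(f"unknown displacement mode {mode!r}")


# ---------------------------------------------------------------------------
# Synthetic maps
# ---------------------------------------------------------------------------

def make_halfmaps(structure, resolution: float, voxel: float = 1.0,
                  noise_sd: float = 0.0, seed: int = 0, pad: float = 10.0):
    """Two maps sharing the rendered signal plus independent Gaussian noise fields."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    signal = dm.render_map(structure, resolution, voxel, pad)
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    halves = []
    for s in (s1, s2):
        rng = np.random.default_rng(s)
        noise = rng.normal(scale=noise_sd, size=signal.dims) if noise_sd > 0 else 0.0
        halves.append(signal.copy(signal.values + noise))
    return halves[0], halves[1]


def make_localres_map(structure, core_resolution: float, shell_resolution: float,
                      voxel: float = 1.0, pad: float = 10.0):
    """Map with a sharp core and blurred periphery, plus the local-resolution volume.

    The nominal resolution rises linearly with distance from the structure's
    centroid, from ``core_resolution`` inside the core radius to
    ``shell_resolution`` at the outermost bead.  Beads are rendered with the
    width implied by their local resolution; the companion volume stores the
    same radial profile per voxel.
    """
    if core_resolution >= shell_resolution:
        raise ValueError("core resolution must be better (smaller) than shell resolution")
    center = structure.xyz.mean(axis=0)
    radii = np.linalg.norm(structure.xyz - center, axis=1)
    r_lo, r_hi = np.percentile(radii, 10), radii.max()

    def profile(r):
        f = np.clip((r - r_lo) / max(r_hi - r_lo, 1e-9), 0.0, 1.0)
        return core_resolution + f * (shell_resolution - core_resolution)

    widths = profile(radii) * dm.RESOLUTION_TO_SIGMA
    density = dm.render_map(structure, core_resolution, voxel, pad, widths=widths)
    # companion volume: same radial profile evaluated at voxel centers
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in density.dims], indexing="ij")
    xyz = density.origin + np.stack([ii, jj, kk], axis=-1) * density.voxel
    r_vox = np.linalg.norm(xyz - center, axis=-1)
    localres = density.copy(profile(r_vox))
    return density, localres


# ---------------------------------------------------------------------------
# Bundled fixture
# ---------------------------------------------------------------------------

def make_fixture(name: str = "codh-analog", seed: int = 1, target_rmsd: float = 7.0,
                 resolution: float = 3.0, voxel: float = 1.0, noise_sd: float = 0.0):
    """The packaged fitting fixture: target conformer, displaced search model, map.

    Returns a dict with the target and search structures, the target map
    (3 A-equivalent by default, padded enough for a 5 A blur cascade), half-map
    pair, local-resolution companion and the generating parameters.
    """
    spec = ToySpec(residues_per_domain=60, hinge_angle=25.0, seed=seed)
    target = make_toy_dimer(spec)
    # The search model is a second clean conformer of the same fold: domain B
    # is slid along its own bundle axis (a register shift) and swung about the
    # linker hinge.  The slide puts the displaced helices over neighboring
    # turns of their own density track, giving the unblurred fitting potential
    # the competing local minima that defeat single-resolution fitting, while
    # heavy blurring leaves a smooth funnel; the hinge swing supplies the rest
    # of the displacement without over-extending the linker.  Both coordinates
    # are linear in their parameters, so two probes calibrate the amplitudes.
    slide_part = 0.65 * target_rmsd
    swing_part = math.sqrt(max(target_rmsd**2 - slide_part**2, 0.0))
    probe_slide = rmsd(make_toy_dimer(replace(spec, slide=1.0)), target)
    probe_swing = rmsd(make_toy_dimer(replace(spec, hinge_angle=spec.hinge_angle + 5.0)),
                       target) / 5.0
    cand = replace(spec, slide=slide_part / probe_slide,
                   hinge_angle=spec.hinge_angle + swing_part / probe_swing)
    # secant corrections for the (small) non-orthogonality of the two modes
    for _ in range(4):
        achieved = rmsd(make_toy_dimer(cand), target)
        if abs(achieved - target_rmsd) < 0.05:
            break
        scale = target_rmsd / achieved
        cand = replace(spec, slide=cand.slide * scale,
                       hinge_angle=spec.hinge_angle
                       + (cand.hinge_angle - spec.hinge_angle) * scale)
    search = make_toy_dimer(cand)
    density = dm.render_map(target, resolution, voxel, pad=14.0)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        density = density.copy(density.values + rng.normal(scale=noise_sd, size=density.dims))
    half1, half2 = make_halfmaps(target, resolution, voxel, noise_sd=0.05, seed=seed)
    localmap, localres = make_localres_map(target, resolution, 3.0 * resolution, voxel)
    return {
        "name": name,
        "spec": spec,
        "target": target,
        "search": search,
        "map": density,
        "half1": half1,
        "half2": half2,
        "localres_map": localmap,
        "localres": localres,
        "params": {
            "seed": seed, "target_rmsd": target_rmsd, "resolution": resolution,
            "voxel": voxel, "noise_sd": noise_sd,
        },
    }
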