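"""Volumetric density maps and their transforms.

A :class:`DensityMap` is a 3-D scalar field on a regular orthogonal grid with a
physical origin and voxel spacing, both in Angstrom.  ``values[i, j, k]`` lives
at world coordinate ``origin + (i, j, k) * voxel`` (0-based indices, axis 0 = x,
axis 1 = y, axis 2 = z).  The module provides

* MRC/CCP4 I/O (mode-2 float32 volumes, orthogonal cells only),
* Gaussian blurring, which widens every Gaussian component of a map from width
  ``s`` to ``sqrt(s**2 + sigma**2)``,
* rendering of bead models into synthetic maps (one isotropic Gaussian per
  bead, FWHM equal to the nominal resolution),
* conversion of a density map into a fitting potential in which high density is
  low energy and everything below a noise threshold is a flat plateau,
* B-factor sharpening in Fourier space, and Guinier estimation of the overall
  B-factor from the radial amplitude falloff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage

from .errors import MapFormatError

__all__ = [
    "DensityMap",
    "MDFFPotential",
    "GaussianSpec",
    "read_map",
    "write_map",
    "gaussian_blur",
    "render_map",
    "render_on_grid",
    "potential_from_map",
    "sharpen",
    "guinier_bfactor",
    "positive_percentile_threshold",
    "RESOLUTION_TO_SIGMA",
]

#: Conversion from nominal map resolution (interpreted as the FWHM of the
#: point-bead response) to the Gaussian standard deviation: s = R / (2*sqrt(2 ln 2)).
RESOLUTION_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class DensityMap:
    """Scalar density on a regular orthogonal grid.

    Parameters
    ----------
    origin : (3,) array
        World coordinate of voxel (0, 0, 0), in Angstrom.
    voxel : (3,) array
        Grid spacing along x, y, z in Angstrom; strictly positive.
    values : (nx, ny, nz) array
        Density values; finite.
    """

    origin: np.ndarray
    voxel: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.voxel = np.asarray(self.voxel, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise MapFormatError("map values must be a 3-D array")
        if np.any(self.voxel <= 0):
            raise MapFormatError(f"voxel spacing must be positive, got {self.voxel}")
        if not np.all(np.isfinite(self.values)):
            raise MapFormatError("map contains non-finite values")
        if not np.all(np.isfinite(self.origin)):
            raise MapFormatError("map origin must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self, values: np.ndarray | None = None) -> "DensityMap":
        """Return a deep copy, optionally replacing the value grid (same geometry)."""
        vals = self.values.copy() if values is None else np.asarray(values, dtype=float)
        return DensityMap(self.origin.copy(), self.voxel.copy(), vals)

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(ijk, dtype=float) * self.voxel

    def frac_coords(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous grid-index coordinates of world positions."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel

    def interpolate(self, xyz: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Trilinear interpolation of the grid at world positions.

        Positions outside the grid get ``fill``.
        """
        v, _ = trilinear(self.values, self.frac_coords(np.atleast_2d(xyz)), fill)
        return v


@dataclass
class MDFFPotential:
    """Per-voxel fitting energy derived from a density map.

    Values lie in ``[0, zeta]`` kcal/mol: 0 at the density maximum, ``zeta``
    everywhere the source density falls below the noise threshold ``phi_thr``,
    and linear in between (continuous at the threshold).
    """

    grid: DensityMap
    zeta: float
    phi_thr: float

    def rescaled(self, zeta: float) -> "MDFFPotential":
        """Same potential shape with a different coupling strength."""
        if zeta < 0:
            raise ValueError("zeta must be non-negative")
        if self.zeta == 0:
            if zeta == 0:
                return MDFFPotential(self.grid.copy(), 0.0, self.phi_thr)
            raise ValueError("cannot rescale a zeta=0 potential to nonzero zeta")
        factor = zeta / self.zeta
        return MDFFPotential(self.grid.copy(self.grid.values * factor), zeta, self.phi_thr)


@dataclass
class GaussianSpec:
    """Explicit Gaussian-mixture description of a map (synthetic rendering/tests)."""

    centers: np.ndarray
    weights: np.ndarray
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if np.any(self.widths <= 0):
            raise ValueError("Gaussian widths must be strictly positive")
        if np.any(self.weights <= 0):
            raise ValueError("Gaussian weights must be strictly positive")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_map(path) -> DensityMap:
    """Read an MRC/CCP4 volume.

    The physical origin is taken from the ORIGIN header words, falling back to
    start-index times voxel spacing when the ORIGIN record is all zero.  Only
    orthogonal cells are supported.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC/CCP4 map {path!r}: {exc}") from exc
    cell = ccp4.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3 and abs(cell.gamma - 90) < 1e-3
    ):
        raise MapFormatError(
            f"non-orthogonal cell angles ({cell.alpha}, {cell.beta}, {cell.gamma}) not supported"
        )
    # normalize axis order so the array is indexed [x, y, z]
    ccp4.setup(float("nan"))
    values = np.array(ccp4.grid, copy=True)
    if values.ndim != 3:
        raise MapFormatError("map grid is not 3-dimensional")
    nx, ny, nz = values.shape
    if nx == 0 or ny == 0 or nz == 0:
        raise MapFormatError("map has an empty dimension")
    voxel = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    if np.any(voxel <= 0) or not np.all(np.isfinite(voxel)):
        raise MapFormatError(f"non-positive voxel spacing {voxel} (cell {cell.a}, {cell.b}, {cell.c})")
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=float)
    if np.all(origin == 0.0):
        nstart = np.array([ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = nstart * voxel
    if not np.all(np.isfinite(values)):
        raise MapFormatError("map values contain non-finite entries")
    return DensityMap(origin, voxel, values)


def write_map(dmap: DensityMap, path) -> None:
    """Write a map as MRC/CCP4 mode 2 (float32), origin in the ORIGIN header words."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values, dtype=np.float32))
    nx, ny, nz = dmap.dims
    vx, vy, vz = dmap.voxel
    ccp4.grid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    ccp4.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4.update_ccp4_header()
    for word, val in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(word, float(val))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def gaussian_blur(dmap: DensityMap, sigma: float) -> DensityMap:
    """Convolve the map with an isotropic Gaussian of standard deviation ``sigma`` (A).

    Zero-padded (constant) boundary handling; grid geometry is unchanged, so
    total density is conserved only when the map carries an empty border wider
    than a few sigma, which the synthetic renderers guarantee.
    """
    if sigma < 0:
        raise ValueError(f"blur sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return dmap.copy()
    sig_vox = sigma / dmap.voxel
    blurred = ndimage.gaussian_filter(dmap.values, sigma=sig_vox, mode="constant", truncate=6.0)
    return dmap.copy(blurred)


def render_gaussians(spec: GaussianSpec, origin, voxel, dims) -> DensityMap:
    """Evaluate a Gaussian mixture on a grid (each component normalized to its weight)."""
    origin = np.asarray(origin, dtype=float)
    voxel = np.asarray(voxel, dtype=float)
    values = np.zeros(tuple(dims), dtype=float)
    axes = [origin[d] + voxel[d] * np.arange(dims[d]) for d in range(3)]
    for c, w, s in zip(spec.centers, spec.weights, spec.widths):
        amp = w / ((2.0 * math.pi) ** 1.5 * s**3)
        # separable evaluation on a +-6s window around the center
        win = []
        profs = []
        for d in range(3):
            ax = axes[d]
            lo = np.searchsorted(ax, c[d] - 6.0 * s)
            hi = np.searchsorted(ax, c[d] + 6.0 * s)
            if lo >= hi:
                break
            win.append((lo, hi))
            profs.append(np.exp(-((ax[lo:hi] - c[d]) ** 2) / (2.0 * s**2)))
        else:
            block = amp * profs[0][:, None, None] * profs[1][None, :, None] * profs[2][None, None, :]
            values[win[0][0] : win[0][1], win[1][0] : win[1][1], win[2][0] : win[2][1]] += block
    return DensityMap(origin, voxel, values)


def _structure_gaussians(structure, widths) -> GaussianSpec:
    return GaussianSpec(structure.xyz, structure.weight, widths)


def render_map(structure, resolution: float, voxel: float = 1.0, pad: float = 10.0,
               widths: np.ndarray | None = None) -> DensityMap:
    """Render a bead model as a sum of Gaussians on a fresh grid.

    Each bead contributes a Gaussian of weight ``w_i`` and standard deviation
    ``resolution * RESOLUTION_TO_SIGMA`` (FWHM = nominal resolution), unless
    explicit per-bead ``widths`` are given.  The grid covers the structure plus
    ``pad`` on every side.
    """
    if structure.n_beads == 0:
        raise ValueError("cannot render an empty structure")
    if resolution <= 0 or voxel <= 0 or pad <= 0:
        raise ValueError("resolution, voxel and pad must be positive")
    xyz = structure.xyz
    lo = xyz.min(axis=0) - pad
    hi = xyz.max(axis=0) + pad
    dims = np.ceil((hi - lo) / voxel).astype(int) + 1
    if widths is None:
        widths = np.full(structure.n_beads, resolution * RESOLUTION_TO_SIGMA)
    spec = GaussianSpec(xyz, structure.weight, widths)
    return render_gaussians(spec, lo, np.full(3, float(voxel)), dims)


def render_on_grid(structure, like: DensityMap, resolution: float,
                   widths: np.ndarray | None = None) -> DensityMap:
    """Render a bead model on the grid of an existing map (for map-model correlation)."""
    if structure.n_beads == 0:
        raise ValueError("cannot render an empty structure")
    if widths is None:
        widths = np.full(structure.n_beads, resolution * RESOLUTION_TO_SIGMA)
    spec = GaussianSpec(structure.xyz, structure.weight, widths)
    return render_gaussians(spec, like.origin, like.voxel, like.dims)


def positive_percentile_threshold(values: np.ndarray, percentile: float = 5.0) -> float:
    """Noise threshold: the given percentile of the strictly positive voxel values."""
    pos = values[values > 0]
    if pos.size == 0:
        raise ValueError("map has no positive voxels; cannot set a density threshold")
    return float(np.percentile(pos, percentile))


def potential_from_map(dmap: DensityMap, zeta: float, phi_thr: float) -> MDFFPotential:
    """Convert density to fitting energy.

    ``V(r) = zeta * [1 - (phi(r) - phi_thr) / (phi_max - phi_thr)]`` above the
    threshold and ``zeta`` below it, so the density maximum is the global energy
    minimum and sub-threshold noise exerts no force.
    """
    if zeta < 0:
        raise ValueError("zeta must be non-negative")
    phi_max = float(dmap.values.max())
    if phi_thr > phi_max:
        raise ValueError(f"phi_thr={phi_thr} exceeds the map maximum {phi_max}")
    if phi_max == phi_thr:
        raise ValueError("degenerate map: phi_max equals phi_thr (flat above threshold)")
    scaled = 1.0 - (dmap.values - phi_thr) / (phi_max - phi_thr)
    energy = zeta * np.clip(scaled, 0.0, 1.0)
    return MDFFPotential(dmap.copy(energy), float(zeta), float(phi_thr))


# ---------------------------------------------------------------------------
# Fourier-space operations
# ---------------------------------------------------------------------------

def _freq_grids(dims, voxel):
    """Spatial frequency magnitudes (1/A) for an rfftn layout."""
    fx = np.fft.fftfreq(dims[0], d=voxel[0])
    fy = np.fft.fftfreq(dims[1], d=voxel[1])
    fz = np.fft.rfftfreq(dims[2], d=voxel[2])
    s2 = fx[:, None, None] ** 2 + fy[None, :, None] ** 2 + fz[None, None, :] ** 2
    return s2


def sharpen(dmap: DensityMap, B: float) -> DensityMap:
    """Scale Fourier amplitudes by ``exp(-B * s**2 / 4)``.

    Negative B amplifies high-frequency amplitudes ("sharpening" in the cryo-EM
    convention); ``B = -8 pi^2 sigma^2`` exactly undoes a Gaussian blur of
    standard deviation sigma.
    """
    if B == 0:
        return dmap.copy()
    s2 = _freq_grids(dmap.dims, dmap.voxel)
    F = np.fft.rfftn(dmap.values)
    F *= np.exp(-B * s2 / 4.0)
    out = np.fft.irfftn(F, s=dmap.dims, axes=(0, 1, 2))
    return dmap.copy(out)


def fourier_shells(dims, voxel):
    """Shell index per rfftn voxel (one shell per integer reciprocal-grid radius).

    Returns (shell_index array, shell center frequencies in 1/A).
    """
    s2 = _freq_grids(dims, voxel)
    s = np.sqrt(s2)
    ds = 1.0 / (max(d * v for d, v in zip(dims, voxel)))
    idx = np.rint(s / ds).astype(int)
    n_shells = idx.max() + 1
    centers = ds * np.arange(n_shells)
    return idx, centers


def guinier_bfactor(dmap: DensityMap, d_min: float, d_max: float) -> float:
    """Overall B-factor from the radial falloff of spherically averaged amplitudes.

    Least-squares slope of ``ln <|F|>`` versus ``s^2`` over shells with
    resolution ``d = 1/s`` in ``[d_min, d_max]``; returns ``B = -4 * slope``.
    Applying :func:`sharpen` with ``-B`` flattens the falloff.
    """
    if d_min >= d_max:
        raise ValueError(f"require d_min < d_max, got {d_min} >= {d_max}")
    if d_min < 2.0 * float(np.max(dmap.voxel)):
        raise ValueError(
            f"d_min={d_min} A is beyond the Nyquist limit {2 * np.max(dmap.voxel)} A"
        )
    F = np.abs(np.fft.rfftn(dmap.values))
    idx, centers = fourier_shells(dmap.dims, dmap.voxel)
    amps = np.bincount(idx.ravel(), weights=F.ravel(), minlength=centers.size)
    counts = np.bincount(idx.ravel(), minlength=centers.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_amp = amps / counts
    s = centers
    sel = (s > 0) & (1.0 / np.maximum(s, 1e-300) >= d_min) & (1.0 / np.maximum(s, 1e-300) <= d_max)
    sel &= np.isfinite(mean_amp) & (mean_amp > 0)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 Fourier shells in the requested resolution range")
    x = s[sel] ** 2
    y = np.log(mean_amp[sel])
    slope = np.polyfit(x, y, 1)[0]
    return float(-4.0 * slope)


# ---------------------------------------------------------------------------
# Trilinear interpolation (shared with the MD engine)
# ---------------------------------------------------------------------------

def trilinear(grid: np.ndarray, frac: np.ndarray, fill: float = 0.0):
    """Trilinear interpolation with the interpolant's exact gradient.

    Parameters
    ----------
    grid : (nx, ny, nz) array
    frac : (n, 3) continuous grid-index coordinates
    fill : value assigned outside the grid (gradient zero there)

    Returns
    -------
    values : (n,) array
    grads : (n, 3) array, gradient with respect to the *index* coordinates
        (divide by the voxel spacing to get spatial gradients).
    """
    frac = np.asarray(frac, dtype=float)
    n = frac.shape[0]
    dims = np.array(grid.shape)
    inside = np.all((frac >= 0.0) & (frac <= dims - 1), axis=1)
    values = np.full(n, fill, dtype=float)
    grads = np.zeros((n, 3), dtype=float)
    if not np.any(inside):
        return values, grads
    f = frac[inside]
    i0 = np.clip(np.floor(f).astype(int), 0, dims - 2)
    t = f - i0
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    c000 = grid[ix, iy, iz]
    c100 = grid[ix + 1, iy, iz]
    c010 = grid[ix, iy + 1, iz]
    c110 = grid[ix + 1, iy + 1, iz]
    c001 = grid[ix, iy, iz + 1]
    c101 = grid[ix + 1, iy, iz + 1]
    c011 = grid[ix, iy + 1, iz + 1]
    c111 = grid[ix + 1, iy + 1, iz + 1]
    tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]
    # interpolate along x, then y, then z
    c00 = c000 + tx * (c100 - c000)
    c01 = c001 + tx * (c101 - c001)
    c10 = c010 + tx * (c110 - c010)
    c11 = c011 + tx * (c111 - c011)
    c0 = c00 + ty * (c10 - c00)
    c1 = c01 + ty * (c11 - c01)
    values[inside] = c0 + tz * (c1 - c0)
    # gradient components
    gx00 = c100 - c000
    gx01 = c101 - c001
    gx10 = c110 - c010
    gx11 = c111 - c011
    gx0 = gx00 + ty * (gx10 - gx00)
    gx1 = gx01 + ty * (gx11 - gx01)
    gx = gx0 + tz * (gx1 - gx0)
    gy0 = (c10 - c00)
    gy1 = (c11 - c01)
    gy = gy0 + tz * (gy1 - gy0)
    gz = c1 - c0
    g = np.stack([gx, gy, gz], axis=1)
    grads[inside] = g
    return values, grads
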