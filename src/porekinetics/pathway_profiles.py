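"""Pore pathway construction and 1D profiles along it.

The conduction pathway is located from the water density: a 3D occupancy grid
is accumulated over the trajectory, the density-weighted centroid of each
z-slice is computed, a smoothing 3D spline is fit through the centroids, and
the curve is resampled at uniform arc length.  Ion densities are then binned
along the path coordinate s (s = 0 at a caller-supplied reference z, s
increasing toward the extracellular side) and Boltzmann-inverted into a free
energy profile G(s) = -ln(rho(s)/rho_bulk) in kT.

"Distance to the path" is the true perpendicular distance to the resampled
polyline (well defined for curved paths; identical to the in-plane distance
for a straight axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy.spatial import cKDTree

from .core_io import Trajectory, SPECIES_WATER, logger

#: van der Waals radii (angstrom) by element, for the simplified radius profile
VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}

#: radius reported when no protein atom lies within this distance of a node
RADIUS_CAP = 20.0


@dataclass
class DensityGrid:
    """3D occupancy-count grid over an analysis box.

    counts[i,j,k] is the number of in-box particle observations (summed over
    frames) in the half-open voxel starting at origin + (i,j,k)*spacing.
    """

    counts: np.ndarray
    origin: np.ndarray
    spacing: float
    n_frames: int
    species: str

    @property
    def edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[d] + self.spacing * np.arange(self.counts.shape[d] + 1)
                     for d in range(3))


@dataclass
class PathSpline:
    """Pore pathway resampled at uniform arc-length nodes.

    nodes : (n, 3) array of points spaced node_spacing apart along the curve;
    s : arc-length coordinate of each node, zeroed at the reference z and
    oriented so that increasing s points extracellular (+z).
    """

    nodes: np.ndarray
    s: np.ndarray
    node_spacing: float

    @property
    def s_range(self) -> tuple[float, float]:
        return float(self.s[0]), float(self.s[-1])


@dataclass
class Profile1D:
    """Values on a uniform 1D grid along the path coordinate."""

    s: np.ndarray
    values: np.ndarray
    kind: str = "density"
    bin_width: float = 0.0
    radial_cutoff: float = 0.0
    mask: np.ndarray = field(default=None)  # True where the bin is undefined

    def __post_init__(self):
        self.s = np.asarray(self.s, float)
        self.values = np.asarray(self.values, float)
        if self.mask is None:
            self.mask = np.zeros(self.s.shape, dtype=bool)
        if self.bin_width == 0.0 and self.s.size > 1:
            self.bin_width = float(self.s[1] - self.s[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s": self.s, "value": self.values, "mask": self.mask})

    def interp(self, s: np.ndarray) -> np.ndarray:
        good = ~self.mask
        return np.interp(s, self.s[good], self.values[good])


def water_density_grid(traj: Trajectory,
                       box_size: tuple[float, float, float] = (25.0, 35.0, 150.0),
                       center: np.ndarray | None = None,
                       spacing: float = 0.5,
                       species: str = SPECIES_WATER) -> DensityGrid:
    """Accumulate a 3D occupancy grid of one species over all frames.

    The analysis box (default 25x35x150 A^3, 0.5 A voxels) is centered on
    ``center`` (defaults to the origin).  Voxel assignment is
    floor((r - box_origin)/spacing) with half-open voxels.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    sel = traj.select(species)
    if not sel.any():
        raise ValueError(f"trajectory has no {species} particles")
    center = np.zeros(3) if center is None else np.asarray(center, float)
    box_size = np.asarray(box_size, float)
    origin = center - box_size / 2.0
    shape = np.floor(box_size / spacing + 0.5).astype(int)
    pts = traj.coords[:, sel, :].reshape(-1, 3)
    idx = np.floor((pts - origin) / spacing).astype(int)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    if not inside.any():
        logger.warning("analysis box contains no %s observations", species)
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, tuple(idx[inside].T), 1)
    return DensityGrid(counts=counts, origin=origin, spacing=spacing,
                       n_frames=traj.n_frames, species=species)


def _slice_centroids(grid: DensityGrid) -> tuple[np.ndarray, np.ndarray]:
    """Density-weighted (x, y) centroid of each populated z-slice."""
    nx, ny, nz = grid.counts.shape
    xc = grid.origin[0] + grid.spacing * (np.arange(nx) + 0.5)
    yc = grid.origin[1] + grid.spacing * (np.arange(ny) + 0.5)
    zc = grid.origin[2] + grid.spacing * (np.arange(nz) + 0.5)
    w = grid.counts.sum(axis=(0, 1)).astype(float)
    cx = np.full(nz, np.nan)
    cy = np.full(nz, np.nan)
    pop = w > 0
    if pop.any():
        cx[pop] = np.tensordot(grid.counts, xc, axes=([0], [0])).sum(axis=0)[pop] / w[pop]
        cy[pop] = np.tensordot(grid.counts, yc, axes=([1], [0])).sum(axis=0)[pop] / w[pop]
    if (~pop).any() and pop.sum() >= 2:
        logger.info("interpolating %d empty z-slices from populated neighbours",
                    int((~pop).sum()))
        cx[~pop] = np.interp(zc[~pop], zc[pop], cx[pop])
        cy[~pop] = np.interp(zc[~pop], zc[pop], cy[pop])
    return np.column_stack([cx, cy, zc]), pop


def pathway_spline(grid: DensityGrid, node_spacing: float = 0.5,
                   reference_z: float = 0.0,
                   residual_tol: float = 0.5) -> PathSpline:
    """Fit a smoothing 3D spline through per-slice water-density centroids.

    The spline is resampled at uniform arc length every ``node_spacing``
    angstrom; the smoothing parameter is set so the RMS residual per slice is
    at most ``residual_tol`` (one voxel by default).  The arc-length
    coordinate s is zeroed where the curve crosses ``reference_z`` and
    oriented with increasing z (extracellular positive).
    """
    centroids, populated = _slice_centroids(grid)
    if populated.sum() < 4:
        raise ValueError("fewer than 4 populated z-slices; cannot fit a pathway")
    pts = centroids[populated]
    n = len(pts)
    # parameterize by chord length, smooth each coordinate; s = n * tol^2
    # bounds the sum of squared residuals so RMS residual <= tol per slice
    tck, _ = interpolate.splprep(pts.T, s=n * residual_tol**2, k=min(3, n - 1))
    uu = np.linspace(0, 1, max(20 * n, 1000))
    dense = np.column_stack(interpolate.splev(uu, tck))
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n_nodes = int(np.floor(total / node_spacing)) + 1
    s_nodes = node_spacing * np.arange(n_nodes)
    nodes = np.column_stack([np.interp(s_nodes, arc, dense[:, k]) for k in range(3)])
    # orient with increasing z and zero s at the reference z
    if nodes[-1, 2] < nodes[0, 2]:
        nodes = nodes[::-1]
    zs = nodes[:, 2]
    if zs.min() <= reference_z <= zs.max():
        s0 = float(np.interp(reference_z, zs, s_nodes)) if np.all(np.diff(zs) > 0) \
            else float(s_nodes[np.argmin(np.abs(zs - reference_z))])
    else:
        s0 = 0.0
    return PathSpline(nodes=nodes, s=s_nodes - s0, node_spacing=node_spacing)


def straight_path(s_min: float, s_max: float, spacing: float = 0.5,
                  axis_xy: tuple[float, float] = (0.0, 0.0)) -> PathSpline:
    """A straight pathway along z (the geometry of the synthetic pore)."""
    s = np.arange(s_min, s_max + 0.5 * spacing, spacing)
    nodes = np.column_stack([np.full_like(s, axis_xy[0]),
                             np.full_like(s, axis_xy[1]), s])
    return PathSpline(nodes=nodes, s=s, node_spacing=spacing)


def project_to_path(points: np.ndarray, path: PathSpline) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length coordinate and perpendicular distance of points to the path.

    Points are projected onto the two polyline segments adjacent to the
    nearest node; ``points`` may have any leading shape ending in 3.
    """
    shape = points.shape[:-1]
    pts = points.reshape(-1, 3)
    nodes = path.nodes
    tree = cKDTree(nodes)
    _, nearest = tree.query(pts)
    s_out = np.empty(len(pts))
    d_out = np.full(len(pts), np.inf)
    for off in (-1, 0):
        j = np.clip(nearest + off, 0, len(nodes) - 2)
        a = nodes[j]
        b = nodes[j + 1]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", pts - a, ab) / np.maximum(denom, 1e-12), 0, 1)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(pts - proj, axis=1)
        better = d < d_out
        d_out[better] = d[better]
        s_out[better] = path.s[j[better]] + t[better] * path.node_spacing
    return s_out.reshape(shape), d_out.reshape(shape)


def ion_density_profile(traj: Trajectory, path: PathSpline,
                        radial_cutoff: float = 7.0, bin_width: float = 0.5,
                        species: str = "ion:Cl") -> Profile1D:
    """Ion density along the path, counted within a radial cutoff.

    Each ion observation within ``radial_cutoff`` (perpendicular distance) of
    the path is binned by its arc-length coordinate; counts are normalized per
    frame and per bin volume (pi * cutoff^2 * bin_width), giving a number
    density in particles/A^3.
    """
    if radial_cutoff <= 0:
        raise ValueError("radial cutoff must be positive")
    sel = traj.select(species)
    s_lo, s_hi = path.s_range
    edges = np.arange(s_lo, s_hi + 0.5 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if not sel.any():
        return Profile1D(s=centers, values=np.zeros(centers.size), kind="density",
                         bin_width=bin_width, radial_cutoff=radial_cutoff)
    s, d = project_to_path(traj.coords[:, sel, :], path)
    keep = d <= radial_cutoff
    counts, _ = np.histogram(s[keep], bins=edges)
    volume = np.pi * radial_cutoff**2 * bin_width
    values = counts / (traj.n_frames * volume)
    prof = Profile1D(s=centers, values=values, kind="density",
                     bin_width=bin_width, radial_cutoff=radial_cutoff)
    prof.raw_counts = counts
    return prof


def free_energy_profile(density: Profile1D,
                        bulk_width: float = 15.0,
                        bulk_region: np.ndarray | None = None) -> Profile1D:
    """Boltzmann inversion: G(s) = -ln(rho(s)/rho_bulk) in kT.

    rho_bulk is the mean density over the designated bulk bins (default: the
    outer ``bulk_width`` angstrom of the profiled range on each side).
    Zero-count bins are masked (undefined) rather than set to +inf.
    """
    s = density.s
    if bulk_region is None:
        bulk_region = (s <= s[0] + bulk_width) | (s >= s[-1] - bulk_width)
    bulk_vals = density.values[bulk_region & (density.values > 0)]
    if bulk_vals.size == 0 or density.values[bulk_region].sum() == 0:
        raise ValueError("bulk region has zero density; cannot set the zero of energy")
    rho_bulk = density.values[bulk_region].mean()
    mask = density.values <= 0
    g = np.zeros_like(density.values)
    g[~mask] = -np.log(density.values[~mask] / rho_bulk)
    return Profile1D(s=s, values=g, kind="free_energy",
                     bin_width=density.bin_width,
                     radial_cutoff=density.radial_cutoff, mask=mask)


def read_feature(profile: Profile1D, s_at: float, halfwidth: float = 1.75) -> float:
    """Profile value at a landmark, from a local quadratic fit.

    Fits a parabola to the unmasked bins within ``halfwidth`` of ``s_at`` and
    evaluates it at ``s_at``; averages out single-bin counting noise when
    reading well depths and barrier heights.  Interpolates across masked gaps
    up to 2 bins wide; wider gaps make the feature undefined (NaN).
    """
    near = np.abs(profile.s - s_at) <= halfwidth
    good = near & ~profile.mask
    n_masked = int((near & profile.mask).sum())
    if n_masked > 2 or good.sum() < 3:
        return float("nan")
    coeff = np.polyfit(profile.s[good] - s_at, profile.values[good], 2)
    return float(coeff[-1])


def radius_profile(traj: Trajectory, path: PathSpline, frame: int = 0) -> Profile1D:
    """Simplified pore-radius profile at one frame.

    At each path node the radius is min over protein atoms of
    (distance to node - vdW radius), with vdW radii looked up by element
    (first letter of the atom name) and capped at ``RADIUS_CAP`` when no atom
    is nearby.
    """
    sel = traj.select("protein")
    if not sel.any():
        raise ValueError("trajectory has no protein atoms")
    pos = traj.coords[frame, sel, :]
    if traj.atomnames is not None:
        names = traj.atomnames[sel]
        vdw = np.array([VDW_RADII.get(str(n)[0].upper(), 1.7) for n in names])
    else:
        vdw = np.full(len(pos), 1.7)
    d = np.linalg.norm(path.nodes[:, None, :] - pos[None, :, :], axis=2) - vdw[None, :]
    radii = np.minimum(d.min(axis=1), RADIUS_CAP)
    return Profile1D(s=path.s, values=radii, kind="radius",
                     bin_width=path.node_spacing)
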