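"""Brownian-dynamics generator of ion/water trajectories in a model pore.

This is the test stand-in for all-atom MD data: point ions diffuse on a
prescribed 1D free-energy landscape G(s) along the pore axis (z), inside a
periodic cylinder, under an optional transmembrane voltage applied as a
linear potential ramp across the pore region.  Dynamics are overdamped
(position) Langevin,

    x <- x - beta*D*gradU*dt + sqrt(2*D*dt)*eta,

which has the correct equilibrium (Boltzmann) statistics and drift
(Einstein) response -- the only contracts downstream analyses rely on.
Waters are non-interacting tracers on a flat landscape; ions interact through
hard-sphere rejection (excluded-volume multi-ion occupancy).

The default landscape preset ``paper2Ca`` encodes a three-site profile with
an inner well C at -2.5 kT (6 kT climbs over both flanking barriers, i.e.
3.5 kT absolute, a 3.5 kT entrance barrier from the cytoplasm), central and
outer sites B and A at the bulk level, a 2 kT A-B barrier and a 1 kT outer
entrance barrier.

Voltage sign convention: positive V (depolarized, intracellular side
positive) drives anions (z = -1) inward; the reduced potential along the pore
is psi(s) = u * (1 - d(s)) with d the fractional electrical distance from the
intracellular bulk and u = eV/kT.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .constants import reduced_voltage, DEFAULT_TEMPERATURE
from .core_io import Trajectory, SPECIES_ION_CL, SPECIES_WATER
from .pathway_profiles import Profile1D

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


@dataclass
class PoreLandscape:
    """Three-site free-energy landscape along the pore axis.

    Site C is inner (cytoplasmic, most negative s), A outer (extracellular).
    Barrier energies are absolute levels in kT (relative to bulk = 0), listed
    inner to outer: (bulk-C, C-B, B-A, A-bulk).  G(s) is the monotone cubic
    (PCHIP) interpolant through the control points and exactly 0 outside
    [s_lo, s_hi]; PCHIP places the extrema exactly at the control points.
    """

    s_sites: tuple[float, float, float] = (-10.0, 0.0, 10.0)   # (C, B, A)
    g_sites: tuple[float, float, float] = (-2.5, 0.0, 0.0)     # kT
    s_barriers: tuple[float, float, float, float] = (-15.0, -5.0, 5.0, 15.0)
    g_barriers: tuple[float, float, float, float] = (3.5, 3.5, 2.0, 1.0)  # kT
    s_lo: float = -20.0
    s_hi: float = 20.0
    name: str = "custom"

    def __post_init__(self):
        sC, sB, sA = self.s_sites
        if not (self.s_lo < self.s_barriers[0] < sC < self.s_barriers[1] < sB
                < self.s_barriers[2] < sA < self.s_barriers[3] < self.s_hi):
            raise ValueError("control points must be ordered s_lo < b < C < b < B < b < A < b < s_hi")
        gC, gB, gA = self.g_sites
        adj = [(self.g_barriers[0], 0.0, gC), (self.g_barriers[1], gC, gB),
               (self.g_barriers[2], gB, gA), (self.g_barriers[3], gA, 0.0)]
        for b, left, right in adj:
            if b < max(left, right):
                raise ValueError("barrier energies must be >= adjacent site energies")
        self._build()

    def _build(self):
        sC, sB, sA = self.s_sites
        s_pts = [self.s_lo, self.s_barriers[0], sC, self.s_barriers[1], sB,
                 self.s_barriers[2], sA, self.s_barriers[3], self.s_hi]
        g_pts = [0.0, self.g_barriers[0], self.g_sites[0], self.g_barriers[1],
                 self.g_sites[1], self.g_barriers[2], self.g_sites[2],
                 self.g_barriers[3], 0.0]
        self._interp = PchipInterpolator(s_pts, g_pts)
        self._deriv = self._interp.derivative()

    def g(self, s) -> np.ndarray:
        """Free energy G(s) in kT (0 outside the pore region)."""
        s = np.asarray(s, float)
        inside = (s >= self.s_lo) & (s <= self.s_hi)
        out = np.zeros_like(s)
        out[inside] = self._interp(s[inside])
        return out

    def dg_ds(self, s) -> np.ndarray:
        s = np.asarray(s, float)
        inside = (s > self.s_lo) & (s < self.s_hi)
        out = np.zeros_like(s)
        out[inside] = self._deriv(s[inside])
        return out

    def electrical_distance(self, s) -> np.ndarray:
        """Fraction of the voltage dropped between the intracellular bulk and s
        (linear ramp across [s_lo, s_hi]: field fractions equal geometric ones)."""
        s = np.asarray(s, float)
        return np.clip((s - self.s_lo) / (self.s_hi - self.s_lo), 0.0, 1.0)

    def min_control_spacing(self) -> float:
        sC, sB, sA = self.s_sites
        pts = np.array([self.s_lo, self.s_barriers[0], sC, self.s_barriers[1],
                        sB, self.s_barriers[2], sA, self.s_barriers[3], self.s_hi])
        return float(np.diff(pts).min())

    def to_json(self, path: str | Path) -> None:
        d = {k: v for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PoreLandscape":
        d = json.loads(Path(path).read_text())
        for k in ("s_sites", "g_sites", "s_barriers", "g_barriers"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def flat_landscape(**kw) -> PoreLandscape:
    kw.setdefault("g_sites", (0.0, 0.0, 0.0))
    kw.setdefault("g_barriers", (0.0, 0.0, 0.0, 0.0))
    kw.setdefault("name", "flat")
    return PoreLandscape(**kw)


def preset_landscape(name: str) -> PoreLandscape:
    """Named landscape presets.

    ``paper2Ca``: the doubly Ca2+-bound (fully open) profile -- site C at
    -2.5 kT, A and B at bulk level, barriers at absolute 3.5 (bulk-C), 3.5
    (C-B; a 6 kT climb from C), 2 (B-A) and 1 kT (A-bulk).

    ``paper1Ca``: the singly bound profile -- site C destabilized by +4 kT
    (to +1.5 kT) with both flanking barriers raised to 6.5 kT, A and B
    unchanged.
    """
    if name == "paper2Ca":
        return PoreLandscape(name="paper2Ca")
    if name == "paper1Ca":
        return PoreLandscape(g_sites=(1.5, 0.0, 0.0),
                             g_barriers=(6.5, 6.5, 2.0, 1.0), name="paper1Ca")
    if name == "flat":
        return flat_landscape()
    raise KeyError(f"unknown landscape preset: {name!r}")


@dataclass
class BDConfig:
    """Brownian-dynamics run configuration.

    The per-step RMS displacement sqrt(2*D*dt) must stay below a quarter of
    the narrowest barrier width (control-point spacing); violated configs
    raise at construction.
    """

    n_ions: int = 16
    n_waters: int = 16
    ion_charge: int = -1               # Cl-
    diffusion: float = 200.0           # A^2/ns (bulk Cl- at ~303 K)
    dt: float = 2e-4                   # ns
    n_steps: int = 1_000_000
    save_stride: int = 10
    pore_radius: float = 8.0           # A
    box_height: float = 60.0           # A (periodic in z)
    voltage_mV: float = 0.0
    exclusion_radius: float = 1.0      # A, ion-ion hard-sphere contact
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0
    landscape: PoreLandscape = field(default_factory=lambda: preset_landscape("paper2Ca"))

    def __post_init__(self):
        self.rms_step = math.sqrt(2.0 * self.diffusion * self.dt)
        min_width = self.landscape.min_control_spacing()
        if self.rms_step >= 0.25 * min_width:
            raise ValueError(
                f"per-step RMS displacement {self.rms_step:.3f} A exceeds a quarter "
                f"of the minimum barrier width {min_width:.3f} A; reduce dt or D")
        if self.box_height < self.landscape.s_hi - self.landscape.s_lo:
            raise ValueError("box height must contain the pore region")


class UnstableStepError(RuntimeError):
    """Deterministic drift exceeded 3x the thermal RMS step (bad force/dt)."""


@njit(cache=True)
def _bd_step_chunk(pos, is_ion, noise, force_grid, f_s0, f_ds_inv,
                   drift_scale, zmin, Lz, R2, excl2, max_drift,
                   out, out_every, out_offset):
    n_steps = noise.shape[0]
    n = pos.shape[0]
    nf = force_grid.shape[0]
    saved = 0
    for step in range(n_steps):
        for i in range(n):
            x0, y0, z0 = pos[i, 0], pos[i, 1], pos[i, 2]
            drift = 0.0
            if is_ion[i]:
                # linear interpolation of -dU/ds on the force grid
                t = (z0 - f_s0) * f_ds_inv
                if t < 0.0:
                    t = 0.0
                if t > nf - 1.000001:
                    t = nf - 1.000001
                j = int(t)
                w = t - j
                f = force_grid[j] * (1.0 - w) + force_grid[j + 1] * w
                drift = drift_scale * f
                if abs(drift) > max_drift:
                    return -1  # unstable step
            nx = x0 + noise[step, i, 0]
            ny = y0 + noise[step, i, 1]
            nz = z0 + drift + noise[step, i, 2]
            # periodic wrap in z
            nz = (nz - zmin) % Lz + zmin
            # cylinder wall: reject moves leaving the pore radius
            if nx * nx + ny * ny > R2:
                continue
            # hard-sphere rejection between ions
            if is_ion[i] and excl2 > 0.0:
                clash = False
                for k in range(n):
                    if k == i or not is_ion[k]:
                        continue
                    dx = nx - pos[k, 0]
                    dy = ny - pos[k, 1]
                    dz = nz - pos[k, 2]
                    dz -= Lz * round(dz / Lz)
                    if dx * dx + dy * dy + dz * dz < excl2:
                        clash = True
                        break
                if clash:
                    continue
            pos[i, 0] = nx
            pos[i, 1] = ny
            pos[i, 2] = nz
        if (out_offset + step + 1) % out_every == 0:
            out[(out_offset + step + 1) // out_every - 1] = pos
            saved += 1
    return saved


def _force_table(cfg: BDConfig, grid_spacing: float = 0.02) -> tuple[np.ndarray, float, float]:
    """Tabulate -dU/ds (kT/A) for ions over the full box height."""
    land = cfg.landscape
    zmin = -cfg.box_height / 2.0
    s = np.arange(zmin, zmin + cfg.box_height + grid_spacing, grid_spacing)
    du = land.dg_ds(s)
    u = reduced_voltage(cfg.voltage_mV, cfg.temperature)
    # psi(s) = u * (1 - d(s)); dpsi/ds = -u/L inside the pore
    inside = (s > land.s_lo) & (s < land.s_hi)
    du[inside] += cfg.ion_charge * (-u / (land.s_hi - land.s_lo))
    return -du, float(s[0]), grid_spacing


def _initial_positions(cfg: BDConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_ions + cfg.n_waters
    pos = np.empty((n, 3))
    r = cfg.pore_radius * np.sqrt(rng.uniform(0, 0.9, n))
    th = rng.uniform(0, 2 * np.pi, n)
    pos[:, 0] = r * np.cos(th)
    pos[:, 1] = r * np.sin(th)
    pos[:, 2] = rng.uniform(-cfg.box_height / 2, cfg.box_height / 2, n)
    return pos


def simulate(landscape: PoreLandscape | None = None,
             cfg: BDConfig | None = None) -> Trajectory:
    """Run overdamped Langevin dynamics and return the saved trajectory.

    Reproducible given ``cfg.seed``: each particle consumes its own
    counter-based noise stream (spawned from the master seed), so results do
    not depend on how many other particles are present downstream of it.
    """
    if cfg is None:
        cfg = BDConfig()
    if landscape is not None and landscape is not cfg.landscape:
        cfg = BDConfig(**{**asdict_shallow(cfg), "landscape": landscape})
    land = cfg.landscape
    n = cfg.n_ions + cfg.n_waters
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n + 1)
    rng_init = np.random.default_rng(children[0])
    particle_rngs = [np.random.default_rng(c) for c in children[1:]]

    pos = _initial_positions(cfg, rng_init)
    is_ion = np.zeros(n, dtype=np.bool_)
    is_ion[:cfg.n_ions] = True
    force_grid, f_s0, f_ds = _force_table(cfg)
    sigma = cfg.rms_step
    drift_scale = cfg.diffusion * cfg.dt  # beta*D*dt with U in kT
    max_drift = 3.0 * sigma
    n_saved = cfg.n_steps // cfg.save_stride
    out = np.empty((n_saved, n, 3))

    chunk = 50_000
    done = 0
    while done < cfg.n_steps:
        m = min(chunk, cfg.n_steps - done)
        noise = np.empty((m, n, 3))
        for i, rng in enumerate(particle_rngs):
            noise[:, i, :] = rng.standard_normal((m, 3)) * sigma
        res = _bd_step_chunk(pos, is_ion, noise, force_grid, f_s0, 1.0 / f_ds,
                             drift_scale, -cfg.box_height / 2.0, cfg.box_height,
                             cfg.pore_radius**2, cfg.exclusion_radius**2,
                             max_drift, out, cfg.save_stride, done)
        if res < 0:
            raise UnstableStepError(
                "drift displacement exceeded 3x the thermal RMS step; "
                "the landscape gradient is too steep for this dt*D")
        done += m

    times = cfg.dt * cfg.save_stride * (1.0 + np.arange(n_saved))
    species = np.array([SPECIES_ION_CL] * cfg.n_ions + [SPECIES_WATER] * cfg.n_waters)
    return Trajectory(times=times, coords=out, species=species,
                      ids=np.arange(n),
                      box=np.array([2 * cfg.pore_radius, 2 * cfg.pore_radius,
                                    cfg.box_height]))


def asdict_shallow(cfg: BDConfig) -> dict:
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}


def equilibrium_density(landscape: PoreLandscape, cfg: BDConfig | None = None,
                        bin_width: float = 0.5) -> Profile1D:
    """Analytic Boltzmann density rho(s) ~ exp(-G(s) - z*psi(s)), bulk = 1.

    The oracle for free-energy recovery: with the cylindrical geometry the
    linear density within any fixed radial cutoff is proportional to this.
    Only meaningful as an equilibrium statement at V = 0; at finite voltage it
    is the formal Boltzmann weight of the tilted (non-periodic) potential.
    """
    if cfg is None:
        cfg = BDConfig(landscape=landscape)
    zmin = -cfg.box_height / 2.0
    edges = np.arange(zmin, zmin + cfg.box_height + 0.5 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    u = reduced_voltage(cfg.voltage_mV, cfg.temperature)
    psi = u * (1.0 - landscape.electrical_distance(centers))
    g = landscape.g(centers) + cfg.ion_charge * (psi - u)  # psi(bulk_int) = u
    vals = np.exp(-(g - 0.0))
    # normalize so that the bulk (outside the pore region) value is 1
    bulk = (centers < landscape.s_lo) | (centers > landscape.s_hi)
    if u == 0 and bulk.any():
        vals /= vals[bulk].mean()
    return Profile1D(s=centers, values=vals, kind="density", bin_width=bin_width)
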