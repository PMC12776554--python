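"""Whole-cell conductance-voltage analysis.

Macroscopic conductance is the steady-state current divided by the driving
force, G = I/(V_m - E_Cl), normalized at a reference voltage and fit with the
two-state Boltzmann relation

    G(V) = G_max / (1 + exp(-(V - V_half)/k)).

A synthetic G(V) generator with Gaussian noise supports parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import CONSTANTS


@dataclass
class GVData:
    """Per-voltage conductances with optional fit results.

    table columns: V_mV, I_pA (optional), G_nS, G_norm, mask (True where G is
    undefined because |V - E_rev| is below tolerance).
    """

    table: pd.DataFrame
    e_rev_mV: float = 0.0
    v_half: float = np.nan
    slope_factor: float = np.nan
    g_max: float = np.nan
    v_half_se: float = np.nan
    slope_se: float = np.nan
    g_max_se: float = np.nan


def nernst(c_out_mM: float, c_in_mM: float, z: int = -1,
           temperature: float = 298.15) -> float:
    """Nernst (reversal) potential E = (RT/zF) ln(c_out/c_in) in mV.

    Symmetric 140 mM Cl- gives 0 mV (the recording condition's E_Cl).
    """
    if c_out_mM <= 0 or c_in_mM <= 0:
        raise ValueError("concentrations must be positive")
    rt_zf = CONSTANTS.R * temperature / (z * CONSTANTS.F)
    return float(rt_zf * np.log(c_out_mM / c_in_mM) * 1e3)


def gv_from_iv(iv: pd.DataFrame, e_rev_mV: float = 0.0,
               reference_V_mV: float = 140.0,
               mask_tol_mV: float = 2.0) -> GVData:
    """Conductances G = I/(V - E_rev), normalized at the reference voltage.

    ``iv`` needs columns V_mV and current_pA (>= 3 voltages).  Points within
    ``mask_tol_mV`` of the reversal potential are masked.  The normalization
    voltage is configurable (published G(V) analyses commonly use +140 or
    +150 mV); default +140 mV.
    """
    if iv.V_mV.nunique() < 3:
        raise ValueError("need at least 3 voltages")
    V = iv.V_mV.to_numpy(float)
    I = iv.current_pA.to_numpy(float)
    mask = np.abs(V - e_rev_mV) < mask_tol_mV
    G = np.full_like(V, np.nan)
    G[~mask] = I[~mask] / (V[~mask] - e_rev_mV)  # pA/mV = nS
    ref = np.isclose(V, reference_V_mV)
    if not ref.any() or mask[ref].all():
        raise ValueError(f"reference voltage {reference_V_mV} mV missing from data")
    g_ref = G[ref][0]
    g_norm = G / g_ref if g_ref != 0 else np.zeros_like(G)
    table = pd.DataFrame({"V_mV": V, "I_pA": I, "G_nS": G,
                          "G_norm": g_norm, "mask": mask})
    return GVData(table=table, e_rev_mV=e_rev_mV)


def _boltzmann(V, g_max, v_half, k):
    return g_max / (1.0 + np.exp(-(V - v_half) / k))


def boltzmann_fit(gv: GVData, use_normalized: bool = True) -> GVData:
    """Least-squares two-state Boltzmann fit of the G(V) relation.

    Returns a copy of ``gv`` with (V_half, k, G_max) estimates and asymptotic
    standard errors.  Requires >= 4 unmasked points spanning the rise.
    """
    t = gv.table
    good = ~t["mask"] & np.isfinite(t.G_norm if use_normalized else t.G_nS)
    V = t.V_mV[good].to_numpy(float)
    G = (t.G_norm if use_normalized else t.G_nS)[good].to_numpy(float)
    if V.size < 4:
        raise ValueError("need at least 4 unmasked points")
    order = np.argsort(V)
    V, G = V[order], G[order]
    if G[-1] <= G[0]:
        raise ValueError("degenerate data: conductance does not rise with voltage")
    g0 = G.max()
    vh0 = float(np.interp(0.5 * g0, G, V))
    k0 = max((V[-1] - V[0]) / 10.0, 1.0)
    popt, pcov = curve_fit(_boltzmann, V, G, p0=[g0, vh0, k0], maxfev=20000)
    se = np.sqrt(np.diag(pcov))
    return GVData(table=t, e_rev_mV=gv.e_rev_mV,
                  v_half=float(popt[1]), slope_factor=float(popt[2]),
                  g_max=float(popt[0]), v_half_se=float(se[1]),
                  slope_se=float(se[2]), g_max_se=float(se[0]))


def synth_gv(v_half: float = 50.0, k: float = 25.0, g_max: float = 1.0,
             e_rev_mV: float = 0.0, noise_sd: float = 0.0, seed: int = 0,
             v_grid: np.ndarray | None = None) -> GVData:
    """Synthetic Boltzmann G(V) data with iid Gaussian noise (exact at sd=0)."""
    if noise_sd < 0:
        raise ValueError("noise must be nonnegative")
    if v_grid is None:
        v_grid = np.arange(-120.0, 150.1, 10.0)
    V = np.asarray(v_grid, float)
    rng = np.random.default_rng(seed)
    G = _boltzmann(V, g_max, v_half, k) + rng.normal(0.0, noise_sd, V.size)
    table = pd.DataFrame({"V_mV": V, "I_pA": G * (V - e_rev_mV),
                          "G_nS": G, "G_norm": G, "mask": np.zeros(V.size, bool)})
    return GVData(table=table, e_rev_mV=e_rev_mV)
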