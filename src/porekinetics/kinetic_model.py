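"""Three-site, seven-state kinetic permeation model with Ca2+ gating.

The pore holds at most two Cl- ions distributed over three binding sites
(A outer/extracellular, B central, C inner/cytoplasmic), giving the seven
occupancy states {empty, A, B, C, AB, AC, BC}.  Transitions add or remove one
ion at the two bulk-facing sites (intracellular bulk <-> C, extracellular
bulk <-> A) or hop one ion between adjacent sites (A <-> B, B <-> C).

Rates are transition-state (Eyring-like) expressions with one shared attempt
prefactor k0,

    k = k0 * exp(-(E_barrier - E_origin)),

where energies (in kT) include the site/barrier free energies, a
concentration term ln(c/c_ref) for bulk exchange (c_ref = 150 mM), an
optional pairwise interaction G_int when two ions occupy the pore, and the
voltage term z*psi(d) with psi(d) = u*(1 - d), d the electrical distance
from the intracellular bulk (d = 0) to the extracellular bulk (d = 1) and
u = eV/kT.  Because the same transition-state energy is shared by the forward
and reverse rates, every edge obeys detailed balance,
k_fwd/k_rev = exp(-dG_total), by construction.

Steady-state probabilities give the single-channel current as the net ion
flux across any bond cut (flux conservation makes the cut irrelevant); the
reported current is I = z*e*J_outward, so positive (outward) current at
positive voltage is carried by inward Cl- movement.

Gating: channels bind zero, one (upper site) or two (upper+lower) Ca2+ in two
sequential voltage-dependent steps; 0-Ca channels are non-conductive, 1-Ca
channels conduct on the C-destabilized profile (outwardly rectifying) and
2-Ca channels on the full profile (Ohmic).  Ensemble currents are the
probability-weighted mixture, which reproduces the switch from outward
rectification at sub-uM Ca2+ to Ohmic behavior at saturating Ca2+.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import reduced_voltage, DEFAULT_TEMPERATURE
from .permeation_analysis import PA_PER_EVENT_PER_NS, IVCurve
from .synthetic_pore import PoreLandscape, preset_landscape

SITES = ("C", "B", "A")  # ordered intracellular -> extracellular


def enumerate_states(n_sites: int = 3, max_occupancy: int = 2) -> list[frozenset]:
    """All occupancy states with at most ``max_occupancy`` ions (7 for 3 sites)."""
    sites = SITES[:n_sites] if n_sites <= 3 else tuple(range(n_sites))
    states = []
    for k in range(max_occupancy + 1):
        states.extend(frozenset(c) for c in combinations(sites, k))
    return states


STATES = enumerate_states()
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
STATE_LABELS = ["".join(sorted(s)) if s else "empty" for s in STATES]


@dataclass
class RateSpec:
    """Everything that determines the rate matrix at one voltage.

    Energies in kT; ``d_*`` are electrical distances in [0, 1] measured from
    the intracellular bulk; barrier arrays are ordered intracellular to
    extracellular: (bulk-C, C-B, B-A, A-bulk).
    """

    g_sites: tuple[float, float, float] = (-2.5, 0.0, 0.0)       # (C, B, A)
    g_barriers: tuple[float, float, float, float] = (3.5, 3.5, 2.0, 1.0)
    d_sites: tuple[float, float, float] = (0.25, 0.5, 0.75)
    d_barriers: tuple[float, float, float, float] = (0.125, 0.375, 0.625, 0.875)
    prefactor: float = 1.0             # k0, 1/ns
    c_int_mM: float = 150.0
    c_ext_mM: float = 150.0
    c_ref_mM: float = 150.0
    ion_charge: int = -1
    g_interaction: float = 0.0         # added when two ions occupy the pore
    voltage_mV: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE
    name: str = "custom"

    def __post_init__(self):
        seq = [0.0, self.d_barriers[0], self.d_sites[0], self.d_barriers[1],
               self.d_sites[1], self.d_barriers[2], self.d_sites[2],
               self.d_barriers[3], 1.0]
        if not np.all(np.diff(seq) >= 0):
            raise ValueError("electrical distances must be monotone along the pore")
        if min(self.c_int_mM, self.c_ext_mM) <= 0:
            raise ValueError("bulk concentrations must be positive")

    @property
    def u(self) -> float:
        return reduced_voltage(self.voltage_mV, self.temperature)

    def at_voltage(self, voltage_mV: float) -> "RateSpec":
        return replace(self, voltage_mV=voltage_mV)

    @classmethod
    def from_landscape(cls, landscape: PoreLandscape, **kw) -> "RateSpec":
        """Build a spec from a pore landscape; electrical distances default to
        the landscape's linear-field (geometric) fractions, overridable via a
        potential profile from the electrostatics module."""
        d_site = tuple(float(landscape.electrical_distance(s)) for s in landscape.s_sites)
        d_barr = tuple(float(landscape.electrical_distance(s)) for s in landscape.s_barriers)
        return cls(g_sites=landscape.g_sites, g_barriers=landscape.g_barriers,
                   d_sites=d_site, d_barriers=d_barr,
                   name=kw.pop("name", landscape.name), **kw)

    def to_json(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RateSpec":
        d = json.loads(Path(path).read_text())
        for k in ("g_sites", "g_barriers", "d_sites", "d_barriers"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def preset_rate_spec(name: str, **kw) -> RateSpec:
    """Kinetic presets built from the landscape presets of the same name."""
    return RateSpec.from_landscape(preset_landscape(name), **kw)


# transition topology: (site or bulk origin, site or bulk destination, barrier index)
_MOVES = [
    ("int", "C", 0), ("C", "int", 0),
    ("C", "B", 1), ("B", "C", 1),
    ("B", "A", 2), ("A", "B", 2),
    ("A", "ext", 3), ("ext", "A", 3),
]


def _psi(d: float, u: float) -> float:
    """Reduced potential at electrical distance d (intracellular side at u)."""
    return u * (1.0 - d)


def _site_energy(spec: RateSpec, site: str, u: float) -> float:
    i = SITES.index(site)
    return spec.g_sites[i] + spec.ion_charge * _psi(spec.d_sites[i], u)


def _bulk_energy(spec: RateSpec, side: str, u: float) -> float:
    """Free energy of a bulk ion: its chemical potential +ln(c/c_ref) plus the
    electrostatic term, so entry rates are proportional to concentration."""
    if side == "int":
        return np.log(spec.c_int_mM / spec.c_ref_mM) + spec.ion_charge * _psi(0.0, u)
    return np.log(spec.c_ext_mM / spec.c_ref_mM) + spec.ion_charge * _psi(1.0, u)


def transitions(spec: RateSpec) -> list[tuple[int, int, float, str, str]]:
    """All allowed (from_state, to_state, rate, origin, destination) edges."""
    u = spec.u
    edges = []
    for si, state in enumerate(STATES):
        for origin, dest, bi in _MOVES:
            if origin in ("int", "ext"):
                if dest in state or len(state) >= 2:
                    continue
                new = state | {dest}
                e_origin = _bulk_energy(spec, origin, u)
                pair = len(state) >= 1  # entering an occupied pore
            else:
                if origin not in state:
                    continue
                if dest in ("int", "ext"):
                    new = state - {origin}
                else:
                    if dest in state:
                        continue
                    new = (state - {origin}) | {dest}
                e_origin = _site_energy(spec, origin, u) \
                    + (spec.g_interaction if len(state) == 2 else 0.0)
                pair = len(state) == 2
            e_barrier = (spec.g_barriers[bi]
                         + spec.ion_charge * _psi(spec.d_barriers[bi], u)
                         + (spec.g_interaction if pair else 0.0))
            rate = spec.prefactor * np.exp(-(e_barrier - e_origin))
            edges.append((si, STATE_INDEX[new], rate, origin, dest))
    return edges


def build_rate_matrix(spec: RateSpec) -> np.ndarray:
    """Generator matrix Q over the 7 states; column i holds rates out of i.

    Q[j, i] = k(i -> j), Q[i, i] = -sum of column, so dp/dt = Q @ p.
    Detailed balance of every edge is asserted after construction.
    """
    n = len(STATES)
    Q = np.zeros((n, n))
    for i, j, rate, _, _ in transitions(spec):
        Q[j, i] += rate
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=0))
    _assert_detailed_balance(spec)
    return Q


def _state_energy(spec: RateSpec, state: frozenset, u: float) -> float:
    """Grand-canonical free energy of a state (ions taken from the bulks)."""
    e = sum(_site_energy(spec, x, u) for x in state)
    if len(state) == 2:
        e += spec.g_interaction
    # reference: each ion came from the intracellular bulk
    e -= len(state) * _bulk_energy(spec, "int", u)
    return e


def _assert_detailed_balance(spec: RateSpec) -> None:
    u = spec.u
    rates = {}
    for i, j, rate, origin, dest in transitions(spec):
        rates[(i, j, origin, dest)] = rate
    for (i, j, origin, dest), k_f in rates.items():
        k_r = rates[(j, i, dest, origin)]
        dg = _state_energy(spec, STATES[j], u) - _state_energy(spec, STATES[i], u)
        # ions exchanged with the extracellular bulk carry its chemical
        # potential difference relative to the intracellular reference
        if origin == "ext":
            dg += _bulk_energy(spec, "int", u) - _bulk_energy(spec, "ext", u)
        if dest == "ext":
            dg -= _bulk_energy(spec, "int", u) - _bulk_energy(spec, "ext", u)
        if not np.isclose(k_f / k_r, np.exp(-dg), rtol=1e-9):
            raise AssertionError(
                f"detailed balance violated on edge {STATE_LABELS[i]}->{STATE_LABELS[j]}")


def steady_state(Q: np.ndarray) -> np.ndarray:
    """Unique stationary distribution of an irreducible generator.

    Solves Q p = 0 with sum(p) = 1, followed by one long-double iterative
    refinement so that equilibrium fluxes cancel to near machine precision
    even for stiff (large-barrier) landscapes.
    """
    n = Q.shape[0]
    A = Q.copy()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        p = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("reducible rate matrix: no unique steady state") from exc
    # iterative refinement with extended-precision residuals
    A_l = A.astype(np.longdouble)
    b_l = b.astype(np.longdouble)
    for _ in range(2):
        r = b_l - A_l @ p.astype(np.longdouble)
        p = p + np.linalg.solve(A, r.astype(np.float64))
    if np.any(p < -1e-12):
        raise ValueError("reducible rate matrix: negative steady-state weight")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _cut_flux(spec: RateSpec, p: np.ndarray, cut: int) -> tuple[float, float]:
    """Net and gross outward ion flux (1/ns) across bond cut 0..3 (int-C .. A-ext)."""
    outward_pairs = {0: ("int", "C"), 1: ("C", "B"), 2: ("B", "A"), 3: ("A", "ext")}
    o_orig, o_dest = outward_pairs[cut]
    flux = 0.0
    gross = 0.0
    for i, j, rate, origin, dest in transitions(spec):
        if (origin, dest) == (o_orig, o_dest):
            flux += p[i] * rate
            gross += p[i] * rate
        elif (origin, dest) == (o_dest, o_orig):
            flux -= p[i] * rate
            gross += p[i] * rate
    return flux, gross


def single_channel_current(spec: RateSpec) -> float:
    """Steady-state single-channel current in pA.

    I = z * e * J_outward; positive current at positive voltage corresponds to
    inward anion flux (outward current in the electrophysiological sense).
    Flux conservation across all four bond cuts is asserted.
    """
    Q = build_rate_matrix(spec)
    p = steady_state(Q)
    results = [_cut_flux(spec, p, c) for c in range(4)]
    fluxes = [f for f, _ in results]
    gross = max(g for _, g in results) + 1e-300
    if max(fluxes) - min(fluxes) > 1e-9 * gross:
        raise AssertionError(f"flux not conserved across cuts: {fluxes}")
    return spec.ion_charge * PA_PER_EVENT_PER_NS * fluxes[1]


def iv_curve(spec: RateSpec, voltages_mV: Sequence[float]) -> pd.DataFrame:
    rows = [(v, single_channel_current(spec.at_voltage(v))) for v in voltages_mV]
    return pd.DataFrame(rows, columns=["V_mV", "current_pA"])


def calibrate_prefactor(spec: RateSpec, target_g_pS: float = 4.4,
                        dV: float = 1.0) -> RateSpec:
    """Scale k0 so the small-voltage slope conductance equals the target (pS).

    The current is linear in k0, so the scaling is exact; the default target
    anchors the model to the MD-derived 4.4 pS conductance.
    """
    if target_g_pS <= 0:
        raise ValueError("target conductance must be positive")
    g = (single_channel_current(spec.at_voltage(dV))
         - single_channel_current(spec.at_voltage(-dV))) / (2 * dV) * 1e3
    if g == 0:
        raise ValueError("zero small-voltage slope; cannot calibrate")
    return replace(spec, prefactor=spec.prefactor * target_g_pS / g)


@dataclass
class CaGatingSpec:
    """Two-step sequential Ca2+ binding with weak voltage dependence.

    State weights (relative to the 0-Ca closed state):

        w1 = (ca/c_ref) * exp(-E1 + 2*delta1*u)
        w2 = w1 * (ca/c_ref) * exp(-E2 + 2*delta2*u)

    E1/E2 are the upper/lower site binding energies (kT, at the reference
    concentration), delta1/delta2 the fractions of the membrane field each
    bound Ca2+ traverses from the intracellular side (so depolarization
    favors binding), and c_ref = 1 uM.  The defaults are calibrated, not
    measured: they put P2 above 0.8 at 10 uM Ca2+ across +-150 mV.
    """

    E1: float = -1.0
    E2: float = -1.0
    delta1: float = 0.05
    delta2: float = 0.10
    c_ref_M: float = 1e-6
    temperature: float = DEFAULT_TEMPERATURE


def ca_state_probabilities(g: CaGatingSpec, voltage_mV: float,
                           ca_M: float) -> tuple[float, float, float]:
    """(P0, P1, P2) occupancies of the 0/1/2-Ca2+-bound channel states."""
    if ca_M < 0:
        raise ValueError("Ca2+ concentration must be nonnegative")
    u = reduced_voltage(voltage_mV, g.temperature)
    x = ca_M / g.c_ref_M
    w1 = x * np.exp(-g.E1 + 2.0 * g.delta1 * u)
    w2 = w1 * x * np.exp(-g.E2 + 2.0 * g.delta2 * u)
    z = 1.0 + w1 + w2
    return 1.0 / z, w1 / z, w2 / z


def ensemble_iv(gating: CaGatingSpec, spec_1ca: RateSpec, spec_2ca: RateSpec,
                voltages_mV: Sequence[float], ca_M: float) -> IVCurve:
    """Ensemble current I(V) = P1(V)*I_1Ca(V) + P2(V)*I_2Ca(V).

    The 0-Ca (apo) state is non-conductive and contributes nothing.
    """
    rows = []
    for v in voltages_mV:
        p0, p1, p2 = ca_state_probabilities(gating, v, ca_M)
        i1 = single_channel_current(spec_1ca.at_voltage(v))
        i2 = single_channel_current(spec_2ca.at_voltage(v))
        rows.append((v, p1 * i1 + p2 * i2, p0, p1, p2))
    df = pd.DataFrame(rows, columns=["V_mV", "current_pA", "P0", "P1", "P2"])
    from scipy import stats as _st
    fit = _st.linregress(df.V_mV, df.current_pA)
    table = df.assign(ci_low=df.current_pA, ci_high=df.current_pA,
                      n_events=np.nan, time_ns=np.nan)[
        ["V_mV", "current_pA", "ci_low", "ci_high", "n_events", "time_ns"]]
    curve = IVCurve(table=table, slope_pS=float(fit.slope * 1e3),
                    intercept_pA=float(fit.intercept),
                    slope_se_pS=float(fit.stderr * 1e3))
    curve.probabilities = df[["V_mV", "P0", "P1", "P2"]]
    return curve


def rectification_ratio(spec: RateSpec, voltage_mV: float = 150.0) -> float:
    """|I(+V)| / |I(-V)|; > 1 means outward rectification."""
    ip = single_channel_current(spec.at_voltage(abs(voltage_mV)))
    im = single_channel_current(spec.at_voltage(-abs(voltage_mV)))
    return abs(ip) / abs(im)
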