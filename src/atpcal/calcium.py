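"""Intracellular Ca2+ dynamics of a wall-adherent endothelial cell.

State variables (all uM): cytosolic free Ca2+ ``C``, store Ca2+ ``Cs``,
buffer-bound Ca2+ ``Cb``, and IP3 ``i``.  The cytosolic balance is

    dC/dt  = q_rel - q_res + q_in - q_out - q_buf
    dCs/dt = (Vc/Vs) * (q_res - q_rel)
    dCb/dt = q_buf
    di/dt  = k1 * phi/(Kc+phi) * C/(K1+C) - k2 * i

with store release by IP3-gated, Ca2+-sensitised channels (CICR),

    q_rel = k3 * C/(KCICR + C) * (i/(i + K2))**3 * Cs,

a SERCA-type restore pump opposed by a store leak,

    q_res = k4 * (C/(K3 + C))**2 - k5 * Cs**2,

saturating efflux q_out = k8*C/(K4+C), first-order protein buffering
q_buf = k6*C*(BT - Cb) - k7*Cb, and plasma-membrane influx

    q_in = q_in_p2x4 + q_in_trp + q_in_pass,

where P2X4 channels are gated directly by extracellular ATP,

    q_in_p2x4 = kp2x4 * (phi/(Kp2x4 + phi))**3 * (Cex - C),

and mechanosensitive TRPV4/TRPC1 channels carry a store-feedback influx

    q_in_trp = qmax * p1 * p2 * p3 * (Cs0 - Cs) * (Cex - C)

whose open probability factorises into a shear gate p1 (Boltzmann gating on
the membrane strain energy density W(tau_w)), an IP3 gate p2 (three-site
binding), and a Ca2+-dependent decay gate p3.  ``q_in_pass`` is a constant
passive influx calibrated so that the unstimulated resting state
(phi = 0, tau_w = 0) is an exact equilibrium.

The release and restore forms, the resting-store initial condition
Cs0 = sqrt(k4/k5) * C0/(K3 + C0), and the strain-energy expression

    W(tau) = (e*tau*l + sqrt(16 d**2 + e**2 tau**2 l**2) - 4 d)**2
             / (e*tau*l + sqrt(16 d**2 + e**2 tau**2 l**2))

(e = load fraction borne by the membrane, l = cell length, d = membrane
shear modulus) are the canonical forms of the antecedent endothelial
ATP + shear models this system descends from; each sits behind a named
form-variant switch so alternates can be exercised.

Units: concentrations uM, time s, shear Pa; the strain-energy exponent
fe*W / (gating_scale * kB * T * N) is dimensionless with W in J/m2 and N in
channels/m2.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Callable, Dict, Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from .transport import WallStimulus

__all__ = [
    "CalciumParams",
    "CalciumState",
    "CalciumTrajectory",
    "default_params",
    "q_rel",
    "q_res",
    "q_out",
    "q_buf",
    "strain_energy",
    "gate_p1",
    "gate_p2",
    "gate_p3",
    "q_in_p2x4",
    "q_in_trp",
    "ip3_rhs",
    "resting_store",
    "resting_passive_influx",
    "initial_state",
    "calcium_rhs",
    "simulate_calcium",
]

_log = logging.getLogger(__name__)

BOLTZMANN = 1.380649e-23  # J/K


@dataclass(frozen=True)
class CalciumParams:
    """Rate constants and sensitivities of the Ca2+ model.

    Defaults are the shipped profile (``data/calcium_default.toml``); see that
    file for per-parameter provenance notes.
    """

    # IP3 turnover
    k1: float  # max IP3 production rate (uM/s)
    k2: float  # IP3 degradation rate (1/s)
    Kc: float  # ATP sensitivity of PLC activation (uM)
    K1: float  # Ca2+ sensitivity of PLC activation (uM)
    # store release / restore / leak
    k3: float  # max CICR release rate (1/s)
    k4: float  # max SERCA restore rate (uM/s)
    k5: float  # store leak rate (1/(uM s))
    K2: float  # IP3 sensitivity of release (uM)
    K3: float  # Ca2+ sensitivity of the restore pump (uM)
    KCICR: float  # Ca2+ sensitivity of CICR (uM)
    # efflux
    k8: float  # max efflux rate (uM/s)
    K4: float  # efflux Michaelis constant (uM)
    # buffering
    k6: float  # buffering on-rate (1/(uM s))
    k7: float  # debuffering off-rate (1/s)
    BT: float  # total buffer site concentration (uM)
    # geometry / exchange
    Vc_over_Vs: float  # cytosol-to-store volume ratio
    Cex: float  # extracellular Ca2+ (uM)
    C0: float  # resting cytosolic Ca2+ (uM)
    # P2X4 influx
    kp2x4: float  # P2X4 flux rate (1/s)
    Kp2x4: float  # ATP sensitivity of P2X4 (uM)
    # TRP influx and gating
    qmax: float  # max TRP inflow rate (1/(uM s))
    alpha: float  # no-load gating constant; p1(0) = 1/(1+alpha)
    fe: float  # fraction of membrane strain energy gating the channels
    T: float  # temperature (K)
    N: float  # shear-gated channel density (1/m2)
    eps_m: float  # fraction of the load borne by the membrane
    l: float  # cell length in the flow direction (m)
    delta_m: float  # membrane shear modulus (N/m)
    gating_scale: float = 8.0  # printed "8" of the 8kTN gating denominator
    kB: float = BOLTZMANN
    # p2 / p3 gate constants
    a1: float = 4.0
    b1: float = 0.1
    Ki: float = 0.3  # uM^3 (acts on i^3)
    c1: float = 0.1
    c2: float = 0.9
    c3: float = 5.0  # 1/uM
    # calibrated passive influx; None = balance the resting state at startup
    qin_pass: Optional[float] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"CalciumParams.{f.name} must be nonnegative")
        if not 0.0 <= self.fe <= 1.0:
            raise ValueError("fe must lie in [0, 1]")
        if not 0.0 <= self.eps_m <= 1.0:
            raise ValueError("eps_m must lie in [0, 1]")
        if not self.Cex > self.C0 > 0:
            raise ValueError("require Cex > C0 > 0")


def default_params(**overrides) -> CalciumParams:
    """Load the shipped default parameter profile, optionally overriding
    individual constants by keyword."""
    text = resources.files("atpcal.data").joinpath("calcium_default.toml").read_text()
    values = tomllib.loads(text)
    values.update(overrides)
    return CalciumParams(**values)


@dataclass(frozen=True)
class CalciumState:
    C: float
    Cs: float
    Cb: float
    i: float

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.Cs, self.Cb, self.i], dtype=float)


@dataclass(frozen=True)
class CalciumTrajectory:
    t: np.ndarray
    C: np.ndarray
    Cs: np.ndarray
    Cb: np.ndarray
    i: np.ndarray
    fluxes: Optional[Dict[str, np.ndarray]] = None

    def to_csv(self, path) -> None:
        cols = [self.t, self.C, self.Cs, self.Cb, self.i]
        header = "t_s,C_uM,Cs_uM,Cb_uM,ip3_uM"
        if self.fluxes:
            for name in sorted(self.fluxes):
                cols.append(self.fluxes[name])
                header += f",{name}_uM_per_s"
        np.savetxt(path, np.column_stack(cols), delimiter=",", header=header,
                   comments="")


# ---------------------------------------------------------------------------
# fluxes

def q_rel(C, Cs, i, p: CalciumParams, form: str = "hill3"):
    """CICR store release (uM/s): IP3-gated (three binding sites) and
    Ca2+-sensitised, proportional to the store content."""
    ip3_gate = i / (i + p.K2)
    if form == "hill3":
        ip3_gate = ip3_gate**3
    elif form != "hill1":
        raise ValueError(f"unknown q_rel form {form!r}")
    return p.k3 * C / (p.KCICR + C) * ip3_gate * Cs


def q_res(C, Cs, p: CalciumParams, form: str = "squared"):
    """SERCA restore minus store leak (uM/s)."""
    pump = C / (p.K3 + C)
    if form == "squared":
        return p.k4 * pump**2 - p.k5 * np.asarray(Cs, dtype=float) ** 2
    if form == "linear":
        return p.k4 * pump - p.k5 * np.asarray(Cs, dtype=float)
    raise ValueError(f"unknown q_res form {form!r}")


def q_out(C, p: CalciumParams):
    """Saturating Ca2+ clearance (uM/s), half-maximal at C = K4."""
    return p.k8 * C / (p.K4 + C)


def q_buf(C, Cb, p: CalciumParams):
    """Net buffering flux onto cytosolic proteins (uM/s)."""
    return p.k6 * C * (p.BT - Cb) - p.k7 * Cb


def strain_energy(tau_w, p: CalciumParams, form: str = "membrane"):
    """Membrane strain energy density W(tau_w) in J/m2.

    Negative shear (reversing oscillatory flow) contributes through its
    magnitude; a notice is logged when that happens.
    """
    tau = np.asarray(tau_w, dtype=float)
    if np.any(tau < 0):
        _log.info("negative wall shear stress passed to strain_energy; "
                  "using |tau_w| (energy depends on load magnitude)")
        tau = np.abs(tau)
    if form != "membrane":
        raise ValueError(f"unknown strain_energy form {form!r}")
    etl = p.eps_m * tau * p.l
    root = np.sqrt(16.0 * p.delta_m**2 + etl**2)
    return (etl + root - 4.0 * p.delta_m) ** 2 / (etl + root)


def gate_p1(tau_w, p: CalciumParams):
    """Open probability of the shear-gated TRPV4 channels.

    Boltzmann gating on the strain energy per channel: p1 rises from
    1/(1+alpha) at rest towards 1 as tau_w grows.
    """
    w = strain_energy(tau_w, p)
    expo = p.fe * w / (p.gating_scale * p.kB * p.T * p.N)
    return 1.0 / (1.0 + p.alpha * np.exp(-expo))


def gate_p2(i, p: CalciumParams):
    """IP3-dependent open-probability factor of the TRPV4-C1 channels
    (three IP3 molecules bind); ranges over [b1, b1*(1+a1)]."""
    i3 = np.asarray(i, dtype=float) ** 3
    return p.b1 * (1.0 + p.a1 * i3 / (p.Ki + i3))


def gate_p3(C, p: CalciumParams):
    """Ca2+-dependent decay factor; falls from c1+c2 at C=0 towards c1."""
    return p.c1 + p.c2 * np.exp(-p.c3 * np.asarray(C, dtype=float))


def q_in_p2x4(phi, C, p: CalciumParams):
    """ATP-gated Ca2+ influx through P2X4 channels (uM/s)."""
    gate = phi / (p.Kp2x4 + phi)
    return p.kp2x4 * gate**3 * (p.Cex - C)


def q_in_trp(C, Cs, i, tau_w, p: CalciumParams):
    """Mechanosensitive TRP influx (uM/s) with store feedback: vanishes at
    the resting store level and reverses sign with (Cs0 - Cs)."""
    cs0 = resting_store(p)
    return (
        p.qmax
        * gate_p1(tau_w, p)
        * gate_p2(i, p)
        * gate_p3(C, p)
        * (cs0 - Cs)
        * (p.Cex - C)
    )


def ip3_rhs(i, C, phi, p: CalciumParams):
    """IP3 production (ATP- and Ca2+-dependent PLC activity) minus
    first-order degradation (uM/s)."""
    return p.k1 * (phi / (p.Kc + phi)) * (C / (p.K1 + C)) - p.k2 * i


# ---------------------------------------------------------------------------
# resting state

def resting_store(p: CalciumParams) -> float:
    """Resting store level Cs0: restore balances leak at C0."""
    return float(np.sqrt(p.k4 / p.k5) * p.C0 / (p.K3 + p.C0))


def resting_passive_influx(p: CalciumParams) -> float:
    """Passive influx that makes the unstimulated resting state an exact
    equilibrium of the assembled right-hand side."""
    if p.qin_pass is not None:
        return p.qin_pass
    cs0 = resting_store(p)
    cb0 = p.k6 * p.C0 * p.BT / (p.k7 + p.k6 * p.C0)
    imbalance = (
        q_rel(p.C0, cs0, 0.0, p)
        - q_res(p.C0, cs0, p)
        + q_in_p2x4(0.0, p.C0, p)
        + q_in_trp(p.C0, cs0, 0.0, 0.0, p)
        - q_out(p.C0, p)
        - q_buf(p.C0, cb0, p)
    )
    return float(-imbalance)


def initial_state(p: CalciumParams) -> CalciumState:
    """Resting state: C0; buffering equilibrium Cb0; store balance Cs0;
    IP3 at its zero-ATP steady state (zero)."""
    cb0 = p.k6 * p.C0 * p.BT / (p.k7 + p.k6 * p.C0)
    return CalciumState(C=p.C0, Cs=resting_store(p), Cb=cb0, i=0.0)


# ---------------------------------------------------------------------------
# assembled system

def calcium_rhs(state, phi: float, tau_w: float, p: CalciumParams,
                qin_pass: Optional[float] = None) -> np.ndarray:
    """Time derivative of (C, Cs, Cb, i) under instantaneous stimuli
    (phi in uM, tau_w in Pa)."""
    C, Cs, Cb, i = (state.as_array() if isinstance(state, CalciumState)
                    else np.asarray(state, dtype=float))
    if qin_pass is None:
        qin_pass = resting_passive_influx(p)
    terms = {
        "q_rel": q_rel(C, Cs, i, p),
        "q_res": q_res(C, Cs, p),
        "q_in_p2x4": q_in_p2x4(phi, C, p),
        "q_in_trp": q_in_trp(C, Cs, i, tau_w, p),
        "q_out": q_out(C, p),
        "q_buf": q_buf(C, Cb, p),
        "ip3": ip3_rhs(i, C, phi, p),
    }
    for name, v in terms.items():
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(f"non-finite flux {name} at state "
                                     f"C={C}, Cs={Cs}, Cb={Cb}, i={i}")
    qin = terms["q_in_p2x4"] + terms["q_in_trp"] + qin_pass
    dC = terms["q_rel"] - terms["q_res"] + qin - terms["q_out"] - terms["q_buf"]
    dCs = p.Vc_over_Vs * (terms["q_res"] - terms["q_rel"])
    dCb = terms["q_buf"]
    return np.array([dC, dCs, dCb, terms["ip3"]])


def _stimulus_interpolators(stim: WallStimulus):
    def phi(t):
        return float(np.interp(t, stim.t, stim.atp))

    def tau(t):
        return float(np.interp(t, stim.t, stim.shear))

    return phi, tau


def simulate_calcium(
    p: CalciumParams,
    stim: WallStimulus,
    t_end: Optional[float] = None,
    output_dt: float = 0.1,
    state0: Optional[CalciumState] = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "BDF",
    include_fluxes: bool = False,
) -> CalciumTrajectory:
    """Integrate the Ca2+ system driven by a wall stimulus with a stiff
    solver, reporting the state on a uniform output grid."""
    if t_end is None:
        t_end = float(stim.t[-1])
    if t_end > stim.t[-1] + 1e-12:
        raise ValueError("stimulus does not cover [0, t_end]")
    phi_fn, tau_fn = _stimulus_interpolators(stim)
    qin_pass = resting_passive_influx(p)
    y0 = (state0 or initial_state(p)).as_array()

    def rhs(t, y):
        return calcium_rhs(y, phi_fn(t), tau_fn(t), p, qin_pass=qin_pass)

    t_eval = np.arange(0.0, t_end + output_dt / 2, output_dt)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method=method, t_eval=t_eval,
                    rtol=rtol, atol=atol, max_step=max(output_dt, 1.0))
    if not sol.success:
        raise RuntimeError(
            f"stiff integration failed at t={sol.t[-1] if sol.t.size else 0.0:g} s: "
            f"{sol.message}"
        )
    C, Cs, Cb, i = sol.y
    fluxes = None
    if include_fluxes:
        phis = np.interp(sol.t, stim.t, stim.atp)
        taus = np.interp(sol.t, stim.t, stim.shear)
        fluxes = {
            "q_rel": q_rel(C, Cs, i, p),
            "q_res": q_res(C, Cs, p),
            "q_in_p2x4": q_in_p2x4(phis, C, p),
            "q_in_trp": q_in_trp(C, Cs, i, taus, p),
            "q_out": q_out(C, p),
            "q_buf": q_buf(C, Cb, p),
        }
    return CalciumTrajectory(t=sol.t, C=C, Cs=Cs, Cb=Cb, i=i, fluxes=fluxes)
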