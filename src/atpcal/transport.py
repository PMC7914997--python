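"""Depth-averaged ATP transport in the main microchannel.

After averaging over the (shallow) channel height, the ATP concentration
``phi(x, z, t)`` obeys a 2-D convection-diffusion equation with
time-dependent Taylor-Aris dispersion:

    d(phi)/dt + ubar(t) d(phi)/dz = D d2(phi)/dx2 + Deff(t) d2(phi)/dz2

where ``x`` is the transverse coordinate (0..W), ``z`` the axial coordinate
(0..L), ``ubar(t) = Q(t)/(H*W)`` the instantaneous mean velocity, and

    Deff = D * (1 + Pe^2/210 * (H/W)^2),    Pe = ubar(t)*W/D

the quasi-steady dispersion coefficient.  At the inlet (z = 0) the co-flow
imposes a linear ATP profile across the ATP stream of instantaneous width
eps(t)*W and zero beyond it; the side walls are no-flux; the outflow at z = L
is a zero-gradient truncation of the semi-infinite channel.

Numerics: operator splitting per time step — explicit first-order upwind for
the axial convection term (CFL-limited, monotone) followed by backward-Euler
solves for the transverse and axial diffusion terms (tridiagonal, monotone,
unconditionally stable).  Each substep is sign-preserving and bounded by the
inlet extremes, so the discrete field satisfies 0 <= phi <= phi0.  Implicit
diffusion matters here: with the reference parameters Deff exceeds D by more
than five orders of magnitude and an explicit diffusion step would be
prohibitively small.  First-order upwinding adds numerical axial diffusion
of order ubar*dz/2, which is negligible against Deff at the default grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.linalg import solve_banded

from .waveforms import ChannelGeometry, FlowProgram, TimeSeries, wall_shear_stress

__all__ = [
    "TransportParams",
    "Grid",
    "ConcentrationField",
    "WallStimulus",
    "StabilityError",
    "TransportNumericsError",
    "mean_velocity",
    "effective_diffusivity",
    "inlet_profile",
    "simulate_transport",
    "sample_wall_stimulus",
    "settling_time",
]


class StabilityError(ValueError):
    """The requested time step violates the advective CFL bound."""


class TransportNumericsError(RuntimeError):
    """The field became non-finite during time stepping."""


@dataclass(frozen=True)
class TransportParams:
    """Fluid / solute parameters.

    diffusivity: molecular diffusivity of ATP (m^2/s)
    viscosity:   fluid dynamic viscosity (Pa s)
    inlet_concentration: ATP stock concentration phi0 (uM)
    dispersion: 'taylor_aris' applies the Pe-dependent axial enhancement;
                'molecular' disables it (Deff = D), useful for
                advection-dominated checks.
    """

    diffusivity: float = 5e-10
    viscosity: float = 1e-3
    inlet_concentration: float = 10.0
    dispersion: str = "taylor_aris"

    def __post_init__(self) -> None:
        for name in ("diffusivity", "viscosity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.inlet_concentration < 0:
            raise ValueError("inlet_concentration must be nonnegative")
        if self.dispersion not in ("taylor_aris", "molecular"):
            raise ValueError("dispersion must be 'taylor_aris' or 'molecular'")


@dataclass(frozen=True)
class Grid:
    """Spatial/temporal discretisation.

    nx, nz: transverse and axial node counts (>= 16).
    dt: time step (s); if None, chosen from the advective CFL bound.
    t_end: simulation horizon (s).
    output_dt: spacing of stored field snapshots (s).
    """

    nx: int = 64
    nz: int = 256
    t_end: float = 10.0
    dt: Optional[float] = None
    output_dt: float = 0.1
    cfl_safety: float = 0.9

    def __post_init__(self) -> None:
        if self.nx < 16 or self.nz < 16:
            raise ValueError("nx and nz must each be at least 16")
        if self.t_end <= 0 or self.output_dt <= 0:
            raise ValueError("t_end and output_dt must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 < self.cfl_safety <= 1:
            raise ValueError("cfl_safety must be in (0, 1]")


@dataclass(frozen=True)
class ConcentrationField:
    """Depth-averaged ATP field phi(x, z, t) on a regular grid.

    values has shape (nt, nx, nz), in uM.
    """

    x: np.ndarray
    z: np.ndarray
    t: np.ndarray
    values: np.ndarray
    phi0: float

    def sample(self, x_obs: float, z_obs: float) -> np.ndarray:
        """Bilinear interpolation of phi at a point, returned as a series on
        the snapshot time grid."""
        if not (self.x[0] <= x_obs <= self.x[-1]) or not (
            self.z[0] <= z_obs <= self.z[-1]
        ):
            raise ValueError(f"observation point ({x_obs}, {z_obs}) outside channel")
        ix = min(int(np.searchsorted(self.x, x_obs, side="right") - 1), self.x.size - 2)
        iz = min(int(np.searchsorted(self.z, z_obs, side="right") - 1), self.z.size - 2)
        fx = (x_obs - self.x[ix]) / (self.x[ix + 1] - self.x[ix])
        fz = (z_obs - self.z[iz]) / (self.z[iz + 1] - self.z[iz])
        v = self.values
        return (
            (1 - fx) * (1 - fz) * v[:, ix, iz]
            + fx * (1 - fz) * v[:, ix + 1, iz]
            + (1 - fx) * fz * v[:, ix, iz + 1]
            + fx * fz * v[:, ix + 1, iz + 1]
        )


@dataclass(frozen=True)
class WallStimulus:
    """Paired ATP / shear time series at one observation point — the
    transport-to-calcium interface."""

    t: np.ndarray
    atp: np.ndarray
    shear: np.ndarray
    position: Tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.t.shape == self.atp.shape == self.shear.shape):
            raise ValueError("t, atp and shear must share one grid")
        if np.any(self.atp < 0):
            raise ValueError("ATP concentrations must be nonnegative")

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.t, self.atp, self.shear]),
            delimiter=",",
            header="t_s,atp_uM,shear_Pa",
            comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "WallStimulus":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        if data.ndim != 2 or data.shape[1] < 3:
            raise ValueError("stimulus CSV needs columns t_s,atp_uM,shear_Pa")
        return cls(
            t=data[:, 0], atp=data[:, 1], shear=data[:, 2], position=(math.nan, math.nan)
        )


def mean_velocity(program: FlowProgram, geometry: ChannelGeometry, t):
    """Mean axial velocity ubar(t) = Q(t) / (H * W)  (m/s)."""
    return program.total(t) / (geometry.height * geometry.width)


def effective_diffusivity(
    ubar, geometry: ChannelGeometry, params: TransportParams
):
    """Axial dispersion coefficient Deff (m^2/s) at mean velocity ``ubar``.

    Taylor-Aris form: Deff = D * (1 + Pe^2/210 * (H/W)^2) with Pe = ubar*W/D,
    evaluated quasi-steadily at each instant.
    """
    D = params.diffusivity
    if params.dispersion == "molecular":
        return D * np.ones_like(np.asarray(ubar, dtype=float))
    pe = np.asarray(ubar, dtype=float) * geometry.width / D
    return D * (1.0 + pe**2 / 210.0 * (geometry.height / geometry.width) ** 2)


def inlet_profile(x, eps: float, phi0: float, width: float):
    """Linear inlet ATP profile at z = 0.

    phi = phi0 * (1 - x/(eps*W)) across the ATP stream (x <= eps*W), zero in
    the perfusion stream beyond; continuous at the interface.  eps = 0 means
    the inlet is all perfusion: zero everywhere.
    """
    x = np.asarray(x, dtype=float)
    if eps <= 0.0:
        return np.zeros_like(x)
    prof = phi0 * (1.0 - x / (eps * width))
    return np.maximum(prof, 0.0)


def _banded_neumann(n: int, r: float) -> np.ndarray:
    """Banded (I - r*Lap) with mirror-ghost Neumann ends; Lap is the 1-D
    second difference (scaled by r = K*dt/dh^2)."""
    ab = np.zeros((3, n))
    ab[1, :] = 1.0 + 2.0 * r
    ab[0, 1:] = -r
    ab[2, :-1] = -r
    ab[0, 1] = -2.0 * r  # Neumann at node 0
    ab[2, -2] = -2.0 * r  # Neumann at node n-1
    return ab


def _banded_axial(n: int, r: float) -> np.ndarray:
    """Banded (I - r*Lap) in z with Dirichlet inlet (node 0) and mirror-ghost
    zero-gradient outflow (node n-1)."""
    ab = np.zeros((3, n))
    ab[1, :] = 1.0 + 2.0 * r
    ab[0, 1:] = -r
    ab[2, :-1] = -r
    # Dirichlet at the inlet row
    ab[1, 0] = 1.0
    ab[0, 1] = 0.0
    # zero-gradient closure at z = L
    ab[2, -2] = -2.0 * r
    return ab


def simulate_transport(
    geometry: ChannelGeometry,
    params: TransportParams,
    program: FlowProgram,
    grid: Grid,
    initial: Optional[np.ndarray] = None,
) -> ConcentrationField:
    """Integrate the depth-averaged transport equation and return field
    snapshots every ``grid.output_dt`` seconds.

    The channel starts ATP-free unless ``initial`` (shape (nx, nz)) is given.
    A user-supplied ``grid.dt`` violating the advective CFL bound raises
    :class:`StabilityError` carrying the computed bound.
    """
    nx, nz = grid.nx, grid.nz
    W, L, H = geometry.width, geometry.length, geometry.height
    phi0 = params.inlet_concentration
    x = np.linspace(0.0, W, nx)
    z = np.linspace(0.0, L, nz)
    dx = x[1] - x[0]
    dz = z[1] - z[0]

    umax = program.max_total(grid.t_end) / (H * W)
    cfl_dt = math.inf if umax == 0 else dz / umax
    if grid.dt is not None:
        if grid.dt > grid.cfl_safety * cfl_dt:
            raise StabilityError(
                f"dt={grid.dt:g} exceeds the advective CFL bound "
                f"{grid.cfl_safety * cfl_dt:g} s (dz={dz:g}, umax={umax:g})"
            )
        dt_target = grid.dt
    else:
        dt_target = grid.cfl_safety * cfl_dt
        period = program.q2.min_period()
        if period is not None:
            dt_target = min(dt_target, period / 50.0)
        dt_target = min(dt_target, grid.output_dt)
    # make dt divide output_dt exactly so snapshots land on the time grid
    sub = max(1, math.ceil(grid.output_dt / dt_target))
    dt = grid.output_dt / sub
    n_out = int(round(grid.t_end / grid.output_dt))

    phi = np.zeros((nx, nz)) if initial is None else np.array(initial, dtype=float)
    if phi.shape != (nx, nz):
        raise ValueError(f"initial field must have shape {(nx, nz)}")

    rx = params.diffusivity * dt / dx**2
    ab_x = _banded_neumann(nx, rx)

    t_out = np.empty(n_out + 1)
    out = np.empty((n_out + 1, nx, nz))
    # apply the t=0 inlet condition to the stored initial snapshot
    phi[:, 0] = inlet_profile(x, float(program.fraction(0.0)), phi0, W)
    t_out[0] = 0.0
    out[0] = phi

    t = 0.0
    for k_out in range(1, n_out + 1):
        for _ in range(sub):
            t_new = t + dt
            q_frac = float(program.fraction(t_new))
            ubar = float(mean_velocity(program, geometry, t_new))
            # inlet boundary (Dirichlet) at the new time
            phi[:, 0] = inlet_profile(x, q_frac, phi0, W)
            # explicit upwind advection (flow is always in +z)
            c = ubar * dt / dz
            phi[:, 1:] -= c * (phi[:, 1:] - phi[:, :-1])
            # implicit transverse diffusion (rows z >= 1; inlet row is pinned)
            phi[:, 1:] = solve_banded((1, 1), ab_x, phi[:, 1:])
            # implicit axial diffusion with quasi-steady dispersion
            deff = float(effective_diffusivity(ubar, geometry, params))
            rz = deff * dt / dz**2
            ab_z = _banded_axial(nz, rz)
            phi = solve_banded((1, 1), ab_z, phi.T).T
            t = t_new
        if not np.all(np.isfinite(phi)):
            raise TransportNumericsError(
                f"non-finite concentration encountered at t={t:g} s"
            )
        # monotone substeps bound phi by the inlet extremes; clip the
        # sub-picomolar roundoff so the stored field honours 0 <= phi <= phi0
        np.clip(phi, 0.0, phi0, out=phi)
        t_out[k_out] = k_out * grid.output_dt
        out[k_out] = phi

    return ConcentrationField(x=x, z=z, t=t_out, values=out, phi0=phi0)


def sample_wall_stimulus(
    field: ConcentrationField,
    program: FlowProgram,
    geometry: ChannelGeometry,
    viscosity: float,
    x_obs: float,
    z_obs: float,
) -> WallStimulus:
    """Extract the paired {ATP, shear} stimulus a wall-adherent cell sees at
    (x_obs, z_obs).  Shear is uniform across the floor, so it comes straight
    from the flow program."""
    atp = field.sample(x_obs, z_obs)
    shear = np.asarray(wall_shear_stress(program, geometry, viscosity, field.t), dtype=float)
    return WallStimulus(t=field.t, atp=atp, shear=shear, position=(x_obs, z_obs))


def settling_time(
    field: ConcentrationField,
    threshold_fraction: float = 1e-3,
    window: float = 1.0,
) -> float:
    """First time at which the maximum field change per ``window`` seconds
    falls below ``threshold_fraction * phi0``.

    Raises if the field never settles within the simulated horizon.
    """
    dt_out = field.t[1] - field.t[0]
    lag = int(round(window / dt_out))
    if lag < 1 or lag >= field.t.size:
        raise ValueError("snapshot spacing incompatible with the settling window")
    diffs = np.max(
        np.abs(field.values[lag:] - field.values[:-lag]), axis=(1, 2)
    ) / window
    below = diffs < threshold_fraction * field.phi0
    idx = np.argmax(below)
    if not below[idx]:
        raise RuntimeError("field did not settle within the simulated horizon")
    return float(field.t[lag + idx])
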