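"""Per-parcel force balance and trajectory integration.

The force balance per unit parcel mass is

    du_p/dt = F_D (u − u_p) + g (ρ_p − ρ)/ρ_p + F_b + F_m/m,

with F_D the drag rate (1/s), F_b the Brownian acceleration and F_m the
magnetic body force. Two drag closures are provided: Stokes drag with the
Cunningham slip correction for superparamagnetic (≲200 nm) parcels, and the
Morsi–Alexander / Haider–Levenspiel correlations for micron parcels.

Because the drag relaxation time τ = ρ_p d_p² C_e / (18µ) of every particle
class of interest (10 nm – 4 µm magnetite in blood) is below a microsecond,
the default integrator is an integrating-factor ("exponential") Euler step:
it solves the linear force balance exactly for coefficients frozen over the
step, is unconditionally stable at dt ≫ τ, and reduces to the classic
explicit Euler update as dt → 0. A classic Euler step and an adaptive RK45
path (for hypothetical inertial parcels with τ ≳ dt) are also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .hemodynamics import FlowSample

BOLTZMANN = 1.380649e-23  # J/K
MAGNETITE_DENSITY = 5230.0  # kg/m^3


class DragRegime(str, Enum):
    superparamagnetic = "superparamagnetic"
    micron = "micron"


#: Morsi–Alexander spherical-drag constants (a1, a2, a3) per Reynolds band,
#: from the original correlation (not reprinted in typical applications).
MORSI_ALEXANDER_BANDS: tuple[tuple[float, float, tuple[float, float, float]], ...] = (
    (0.0, 0.1, (0.0, 24.0, 0.0)),
    (0.1, 1.0, (3.690, 22.73, 0.0903)),
    (1.0, 10.0, (1.222, 29.1667, -3.8889)),
    (10.0, 100.0, (0.6167, 46.50, -116.67)),
    (100.0, 1000.0, (0.3644, 98.33, -2778.0)),
    (1000.0, 5000.0, (0.357, 148.62, -4.75e4)),
    (5000.0, 10000.0, (0.46, -490.546, 57.87e4)),
    (10000.0, 50000.0, (0.5191, -1662.5, 5.4167e6)),
)


def drag_coefficient_sphere(re: float) -> float:
    """Morsi–Alexander C_D = a₁ + a₂/Re + a₃/Re² for a smooth sphere."""
    if re <= 0.0:
        raise ValueError("relative Reynolds number must be positive; "
                         "use the Stokes law at zero slip")
    for lo, hi, (a1, a2, a3) in MORSI_ALEXANDER_BANDS:
        if lo < re <= hi or (re > 50000.0 and hi == 50000.0):
            return a1 + a2 / re + a3 / re**2
    raise AssertionError("unreachable")


def drag_coefficient_shape(re: float, phi: float) -> float:
    """Haider–Levenspiel drag for non-spherical particles.

    C_D = (24/Re)(1 + b₁ Re^{b₂}) + b₃ Re/(b₄ + Re) with b₁..b₄ polynomial
    exponentials in the shape factor φ = s/S ∈ (0, 1].
    """
    if re <= 0.0:
        raise ValueError("relative Reynolds number must be positive")
    if not (0.0 < phi <= 1.0):
        raise ValueError("shape factor must lie in (0, 1]")
    b1 = np.exp(2.3288 - 6.4581 * phi + 2.4486 * phi**2)
    b2 = 0.0964 + 0.5565 * phi
    b3 = np.exp(4.905 - 13.8944 * phi + 18.4222 * phi**2 - 10.2599 * phi**3)
    b4 = np.exp(1.4681 + 12.2584 * phi - 20.7322 * phi**2 + 15.8855 * phi**3)
    return float((24.0 / re) * (1.0 + b1 * re**b2) + b3 * re / (b4 + re))


def cunningham_factor(d_p: float, mean_free_path: float) -> float:
    """Cunningham slip correction C_e = 1 + (2λ/d_p)(1.257 + 0.4 e^{−1.1 d_p/2λ}).

    C_e ≥ 1, monotone in λ/d_p, and → 1 in the continuum limit λ → 0.
    """
    if d_p <= 0.0:
        raise ValueError("particle diameter must be positive")
    if mean_free_path < 0.0:
        raise ValueError("mean free path must be non-negative")
    if mean_free_path == 0.0:
        return 1.0
    kn2 = 2.0 * mean_free_path / d_p
    return float(1.0 + kn2 * (1.257 + 0.4 * np.exp(-1.1 / kn2)))


@dataclass(frozen=True)
class ParticleSpec:
    """Physical description of one particle population (a diameter class)."""

    diameter: float
    density: float = MAGNETITE_DENSITY
    shape_factor: float = 1.0
    chi: float = 1000.0
    mean_free_path: float = 1e-9  # repo default; not a published value
    regime_threshold: float = 2e-7  # d_p <= threshold -> superparamagnetic

    def __post_init__(self) -> None:
        if self.diameter <= 0.0 or self.density <= 0.0:
            raise ValueError("diameter and density must be positive")
        if not (0.0 < self.shape_factor <= 1.0):
            raise ValueError("shape factor must lie in (0, 1]")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def regime(self) -> DragRegime:
        if self.diameter <= self.regime_threshold:
            return DragRegime.superparamagnetic
        return DragRegime.micron

    @property
    def cunningham(self) -> float:
        return cunningham_factor(self.diameter, self.mean_free_path)

    @property
    def mass(self) -> float:
        return self.density * np.pi * self.diameter**3 / 6.0

    def relaxation_time(self, viscosity: float) -> float:
        """Drag relaxation time τ = ρ_p d_p² C_e / (18µ) (Stokes regime)."""
        return self.density * self.diameter**2 * self.cunningham / (18.0 * viscosity)


class ParcelStatus(str, Enum):
    in_flow = "in_flow"
    escaped = "escaped"
    captured = "captured"


@dataclass
class ParcelState:
    """State of a single computational parcel."""

    position: np.ndarray
    velocity: np.ndarray
    status: ParcelStatus = ParcelStatus.in_flow
    injected_at: float = 0.0
    class_id: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)


@dataclass(frozen=True)
class BrownianSettings:
    """Brownian-force settings: body temperature, on/off, and the exponent
    applied to the density ratio ρ_p/ρ in the spectral density.

    ``density_ratio_exponent = 2`` (default) is the standard white-noise
    spectral density, consistent with Stokes–Einstein diffusion; exponent 1
    reproduces an alternative printed form whose effective diffusivity is
    larger by exactly ρ_p/ρ.
    """

    enabled: bool = True
    temperature: float = 310.15
    boltzmann: float = BOLTZMANN
    density_ratio_exponent: int = 2

    def __post_init__(self) -> None:
        if self.temperature <= 0.0:
            raise ValueError("temperature must be positive")


def brownian_spectral_density(spec: ParticleSpec, flow: FlowSample,
                              settings: BrownianSettings) -> float:
    """White-noise spectral density S₀ of the Brownian acceleration.

    S₀ = 216 ν k_B T / (π² ρ d_p⁵ (ρ_p/ρ)^m C_e) with ν = µ/ρ and m the
    configured density-ratio exponent.
    """
    nu = flow.viscosity / flow.density
    ratio = spec.density / flow.density
    return (216.0 * nu * settings.boltzmann * settings.temperature
            / (np.pi**2 * flow.density * spec.diameter**5
               * ratio**settings.density_ratio_exponent * spec.cunningham))


def brownian_acceleration(spec: ParticleSpec, flow: FlowSample, dt: float,
                          settings: BrownianSettings, rng: np.random.Generator,
                          zeta: np.ndarray | None = None) -> np.ndarray:
    """Brownian acceleration F_b = ζ √(π S₀ / dt) per component.

    ζ are i.i.d. standard normals (drawn from ``rng`` unless supplied);
    returns zeros when disabled or for micron-regime parcels.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    if not settings.enabled or spec.regime is not DragRegime.superparamagnetic:
        return np.zeros(3)
    if zeta is None:
        zeta = rng.standard_normal(3)
    s0 = brownian_spectral_density(spec, flow, settings)
    return zeta * np.sqrt(np.pi * s0 / dt)


def drag_rate(flow: FlowSample, velocity: np.ndarray, spec: ParticleSpec) -> float:
    """Drag rate F_D (1/s) multiplying the slip velocity (u − u_p).

    Superparamagnetic: F_D = 18µ/(d_p² ρ_p C_e). Micron: F_D =
    (18µ/(ρ_p d_p²)) · C_D Re/24 with the relative Reynolds number
    Re = ρ d_p |u_p − u| / µ; at Re → 0 the factor C_D Re/24 → 1, recovering
    Stokes drag.
    """
    if spec.diameter <= 0.0:
        raise ValueError("zero particle diameter")
    mu = flow.viscosity
    stokes = 18.0 * mu / (spec.density * spec.diameter**2)
    if spec.regime is DragRegime.superparamagnetic:
        return stokes / spec.cunningham
    slip = float(np.linalg.norm(np.asarray(velocity) - flow.velocity))
    re = flow.density * spec.diameter * slip / mu
    if re <= 1e-12:
        factor = 1.0
    elif spec.shape_factor >= 1.0:
        factor = drag_coefficient_sphere(re) * re / 24.0
    else:
        factor = drag_coefficient_shape(re, spec.shape_factor) * re / 24.0
    return stokes * factor


def drag_acceleration(flow: FlowSample, state: ParcelState,
                      spec: ParticleSpec) -> np.ndarray:
    """Drag acceleration F_D (u − u_p)."""
    fd = drag_rate(flow, state.velocity, spec)
    return fd * (flow.velocity - state.velocity)


@dataclass(frozen=True)
class GravitySettings:
    """Gravity/buoyancy term g (ρ_p − ρ)/ρ_p; off by default (the model's
    orientation relative to gravity is not fixed)."""

    enabled: bool = False
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    g: float = 9.81


def gravity_acceleration(spec: ParticleSpec, fluid_density: float,
                         settings: GravitySettings) -> np.ndarray:
    if not settings.enabled:
        return np.zeros(3)
    d = np.asarray(settings.direction, dtype=float)
    d = d / np.linalg.norm(d)
    return d * settings.g * (spec.density - fluid_density) / spec.density


def exponential_step(position: np.ndarray, velocity: np.ndarray,
                     fluid_velocity: np.ndarray, beta: float,
                     external_accel: np.ndarray, dt: float):
    """One integrating-factor step of the linear force balance.

    With constant fluid velocity u, drag rate β and external acceleration a
    over the step, the exact solution of du_p/dt = β(u − u_p) + a is

        u_eq = u + a/β,
        u_p(t+dt) = u_eq + (u_p − u_eq) e^{−β dt},
        x(t+dt)  = x + u_eq dt + (u_p − u_eq)(1 − e^{−β dt})/β.

    Unconditionally stable; exact for constant coefficients.
    """
    if beta <= 0.0:
        # force-free ballistic limit
        vel = velocity + external_accel * dt
        return position + velocity * dt + 0.5 * external_accel * dt**2, vel
    u_eq = fluid_velocity + external_accel / beta
    decay = np.exp(-beta * dt)
    dv = velocity - u_eq
    new_vel = u_eq + dv * decay
    new_pos = position + u_eq * dt + dv * (1.0 - decay) / beta
    return new_pos, new_vel


def euler_step(position, velocity, fluid_velocity, beta, external_accel, dt):
    """Classic explicit Euler step (stable only for dt ≲ 2/β)."""
    accel = beta * (fluid_velocity - velocity) + external_accel
    return position + velocity * dt, velocity + accel * dt


def step_parcel(state: ParcelState, t: float, dt: float, spec: ParticleSpec,
                flow_at, magnetic_accel_at=None,
                brownian: BrownianSettings | None = None,
                gravity: GravitySettings = GravitySettings(),
                rng: np.random.Generator | None = None,
                integrator: str = "exponential") -> ParcelState:
    """Advance one parcel by dt.

    ``flow_at(position, t) -> FlowSample`` supplies the local flow;
    ``magnetic_accel_at(position) -> 3-vector`` the magnetic acceleration
    (force / parcel mass), or None for magnet off. Deterministic given the
    rng state. ``integrator``: "exponential" (default), "euler", or "rk45"
    (scipy adaptive Runge–Kutta, for inertial parcels with τ ≳ dt).
    """
    if state.status is not ParcelStatus.in_flow:
        return state
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    flow = flow_at(state.position, t)
    a_ext = gravity_acceleration(spec, flow.density, gravity)
    if magnetic_accel_at is not None:
        a_ext = a_ext + magnetic_accel_at(state.position)
    if brownian is not None and brownian.enabled:
        if rng is None:
            raise ValueError("Brownian forcing requires an rng")
        a_ext = a_ext + brownian_acceleration(spec, flow, dt, brownian, rng)
    beta = drag_rate(flow, state.velocity, spec)

    if integrator == "exponential":
        pos, vel = exponential_step(state.position, state.velocity,
                                    flow.velocity, beta, a_ext, dt)
    elif integrator == "euler":
        pos, vel = euler_step(state.position, state.velocity,
                              flow.velocity, beta, a_ext, dt)
    elif integrator == "rk45":
        from scipy.integrate import solve_ivp

        def rhs(_t, yv):
            x, v = yv[:3], yv[3:]
            fl = flow_at(x, t + (_t))
            b = drag_rate(fl, v, spec)
            a = b * (fl.velocity - v) + a_ext
            return np.concatenate([v, a])

        sol = solve_ivp(rhs, (0.0, dt),
                        np.concatenate([state.position, state.velocity]),
                        method="RK45", rtol=1e-8, atol=1e-12)
        pos, vel = sol.y[:3, -1], sol.y[3:, -1]
    else:
        raise ValueError(f"unknown integrator {integrator!r}")
    return ParcelState(position=pos, velocity=vel, status=state.status,
                       injected_at=state.injected_at, class_id=state.class_id)
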