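"""Blood rheology, pulsatile inlet waveform and analytic per-segment flow.

The flow model is deliberately reduced: each vessel is a straight rigid
cylinder carrying a quasi-steady, fully developed parabolic profile whose
cross-sectional mean follows a piecewise-polynomial cardiac waveform. Mean
flow is propagated through junctions by prescribed split fractions, so the
velocity field is divergence-free segment by segment and mass-conserving at
every junction. Outlet pressures follow a three-element Windkessel ODE.

All quantities are strict SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

BLOOD_DENSITY = 1060.0  # kg/m^3, standard literature value


class OutsideLumenError(ValueError):
    """Raised when a position does not lie inside any vessel lumen."""


# ---------------------------------------------------------------------------
# Carreau rheology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CarreauParams:
    """Carreau shear-thinning viscosity parameters.

    Defaults are the measured whole-blood fit: zero-shear viscosity
    0.056 kg/(m·s), infinite-shear viscosity 0.0035 kg/(m·s), time constant
    3.313 s and power index 0.3568.
    """

    mu_inf: float = 0.0035
    mu_zero: float = 0.056
    time_const: float = 3.313
    power_index: float = 0.3568

    def __post_init__(self) -> None:
        if not (self.mu_zero > self.mu_inf > 0.0):
            raise ValueError("require mu_zero > mu_inf > 0")
        if self.time_const <= 0.0:
            raise ValueError("time_const must be positive")
        if not (0.0 < self.power_index < 1.0):
            raise ValueError("power_index must lie in (0, 1)")


def carreau_viscosity(strain_rate, params: CarreauParams = CarreauParams()):
    """Dynamic viscosity µ(γ̇) of the Carreau model.

    µ = µ_∞ + (µ_0 − µ_∞) (1 + (λ γ̇)²)^((n−1)/2); monotone non-increasing
    in γ̇ and bounded by [µ_∞, µ_0].
    """
    gd = np.asarray(strain_rate, dtype=float)
    if np.any(gd < 0.0):
        raise ValueError("strain rate must be non-negative")
    p = params
    mu = p.mu_inf + (p.mu_zero - p.mu_inf) * (
        1.0 + (p.time_const * gd) ** 2
    ) ** ((p.power_index - 1.0) / 2.0)
    return float(mu) if np.isscalar(strain_rate) else mu


# ---------------------------------------------------------------------------
# Inlet waveform
# ---------------------------------------------------------------------------

# Cardiac-cycle mean-velocity waveform, five polynomial branches over one
# 0.8 s period, coefficients in descending powers of t (m/s). Stored exactly
# as published; branches 2 and 4 are discontinuous with their neighbours as
# published (apparent decimal loss) — see repaired_waveform_branches().
PRINTED_WAVEFORM_BRANCHES: tuple[tuple[float, float, tuple[float, ...]], ...] = (
    (0.00, 0.15, (83.33, -12.50, 0.21667, 0.1375)),
    (0.15, 0.24, (17.12, -5688.27, 1529.70, -169.61, 6.6462)),
    (0.24, 0.42, (-96.923, 100.30, -34.425, 4.1629)),
    (0.42, 0.47, (58.291, -5235.7, 1193.0)),
    (0.47, 0.80, (18.835, -36.960, 23.427, -4.60)),
)

WAVEFORM_PERIOD = 0.80  # s

#: Per-inlet scaling constants C_i of the waveform.
INLET_SCALES = {"basilar": 1.0, "left_ica": 1.4, "right_ica": 1.5}


def _hermite_coeffs(t0: float, t1: float, y0: float, y1: float,
                    dy0: float, dy1: float) -> tuple[float, ...]:
    """Cubic (descending-power) matching values and slopes at t0, t1."""
    # Solve V c = b for c3 t^3 + c2 t^2 + c1 t + c0
    V = np.array([
        [t0**3, t0**2, t0, 1.0],
        [t1**3, t1**2, t1, 1.0],
        [3 * t0**2, 2 * t0, 1.0, 0.0],
        [3 * t1**2, 2 * t1, 1.0, 0.0],
    ])
    c = np.linalg.solve(V, np.array([y0, y1, dy0, dy1]))
    return tuple(float(v) for v in c)


def repaired_waveform_branches() -> tuple[tuple[float, float, tuple[float, ...]], ...]:
    """Waveform branch set with C¹ joins at every interior breakpoint.

    Published branches 2 and 4 are discontinuous with their neighbours
    (their interiors reach −25 and −1000 m/s, physically impossible).
    They are replaced by cubic Hermite interpolants matching the value and
    slope of the adjacent published branches, which restores a physiological
    systolic peak (branch 2) and dicrotic notch (branch 4). Branches 1, 3
    and 5 are kept verbatim.
    """
    b = PRINTED_WAVEFORM_BRANCHES
    out = []
    for k, (t0, t1, coeffs) in enumerate(b):
        if k in (1, 3):
            prev_c = np.array(b[k - 1][2])
            next_c = np.array(b[k + 1][2])
            y0 = float(np.polyval(prev_c, t0))
            y1 = float(np.polyval(next_c, t1))
            dy0 = float(np.polyval(np.polyder(prev_c), t0))
            dy1 = float(np.polyval(np.polyder(next_c), t1))
            out.append((t0, t1, _hermite_coeffs(t0, t1, y0, y1, dy0, dy1)))
        else:
            out.append((t0, t1, coeffs))
    return tuple(out)


@dataclass(frozen=True)
class PiecewiseWaveform:
    """Piecewise-polynomial periodic mean-velocity waveform ū(t)·scale.

    ``branches`` is a sequence of (t_start, t_end, coeffs) with coeffs in
    descending powers of t; branch selection uses half-open [t_k, t_{k+1})
    intervals and t is reduced modulo ``period``.
    """

    branches: tuple[tuple[float, float, tuple[float, ...]], ...] = PRINTED_WAVEFORM_BRANCHES
    scale: float = 1.0
    period: float = WAVEFORM_PERIOD

    def __post_init__(self) -> None:
        starts = [b[0] for b in self.branches]
        ends = [b[1] for b in self.branches]
        if starts[0] != 0.0 or not np.isclose(ends[-1], self.period):
            raise ValueError("branches must span [0, period]")
        for k in range(1, len(self.branches)):
            if not np.isclose(ends[k - 1], starts[k]):
                raise ValueError("branches must tile [0, period) without gaps")

    def __call__(self, t):
        return self.mean_velocity(t)

    def mean_velocity(self, t):
        """Mean axial velocity ū(t) in m/s (t reduced modulo the period)."""
        tt = np.asarray(t, dtype=float) % self.period
        out = np.empty_like(tt)
        filled = np.zeros(tt.shape, dtype=bool)
        for t0, t1, coeffs in self.branches:
            m = (tt >= t0) & (tt < t1) & ~filled
            if np.any(m):
                out[m] = np.polyval(coeffs, tt[m])
                filled[m] = True
        # t exactly on the final breakpoint maps to branch 1 via the modulo
        out = self.scale * out
        return float(out) if np.isscalar(t) else out


def inlet_waveform(scale: float = 1.0, repaired: bool = False) -> PiecewiseWaveform:
    """The cardiac inlet waveform with scaling constant C_i = ``scale``."""
    branches = repaired_waveform_branches() if repaired else PRINTED_WAVEFORM_BRANCHES
    return PiecewiseWaveform(branches=branches, scale=scale)


def waveform_mean_velocity(t, w: PiecewiseWaveform):
    """Functional alias for ``w.mean_velocity(t)``."""
    return w.mean_velocity(t)


# ---------------------------------------------------------------------------
# Vessel geometry
# ---------------------------------------------------------------------------

def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``axis`` to a right-handed triad."""
    a = axis / np.linalg.norm(axis)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(a, helper)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


@dataclass
class VesselSegment:
    """Straight cylindrical vessel segment with a local cylindrical frame."""

    name: str
    start: np.ndarray
    end: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        if self.radius <= 0.0:
            raise ValueError(f"segment {self.name}: radius must be positive")
        if np.allclose(self.start, self.end):
            raise ValueError(f"segment {self.name}: start == end")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def axis(self) -> np.ndarray:
        return (self.end - self.start) / self.length

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)

    def radial_frame(self) -> tuple[np.ndarray, np.ndarray]:
        return _orthonormal_frame(self.axis)

    def local_coords(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(axial distance s from start, radial distance r) for Nx3 points."""
        p = np.atleast_2d(np.asarray(positions, dtype=float)) - self.start
        s = p @ self.axis
        radial = p - np.outer(s, self.axis)
        r = np.linalg.norm(radial, axis=1)
        return s, r

    def contains(self, positions: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
        s, r = self.local_coords(positions)
        tol = rtol * self.length
        return (s >= -tol) & (s <= self.length + tol) & (r <= self.radius * (1 + 1e-9))


@dataclass(frozen=True)
class WindkesselParams:
    """Three-element Windkessel: proximal/distal resistance and compliance.

    Defaults are repo-chosen cerebral-outlet values (the source values are
    not published with the model), set so the fixture outlet flows of
    ~1-2 ml/s produce a physiological 80-160 mmHg pressure envelope:
    R_p = 9e8 Pa·s/m³, R_d = 6.8e9 Pa·s/m³, C = 2.5e−10 m³/Pa.
    """

    r_proximal: float = 9e8
    r_distal: float = 6.8e9
    capacitance: float = 2.5e-10

    def __post_init__(self) -> None:
        if min(self.r_proximal, self.r_distal, self.capacitance) <= 0.0:
            raise ValueError("Windkessel parameters must be strictly positive")


def windkessel_advance(state_pressure: float, inflow: float, dinflow_dt: float,
                       dt: float, params: WindkesselParams) -> float:
    """Advance the outlet-pressure ODE one step of length dt.

    The ODE is (1 + R_p/R_d)·i + C·R_d·di/dt = p/R_d + C·dp/dt, a linear
    relaxation of p toward p_ss = (R_p+R_d)·i + C·R_d²·di/dt with time
    constant R_d·C. The update uses the exact exponential solution for
    inputs frozen over the step (first order in time-varying i, and exact —
    hence unconditionally stable — for constant i).
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    rp, rd, c = params.r_proximal, params.r_distal, params.capacitance
    tau = rd * c
    p_ss = (rp + rd) * inflow + c * rd**2 * dinflow_dt
    return p_ss + (state_pressure - p_ss) * np.exp(-dt / tau)


def windkessel_pressure_series(network: "VesselNetwork", outlet: str,
                               times: np.ndarray,
                               initial_pressure: float | None = None) -> np.ndarray:
    """Outlet pressure p(t) from the segment's volumetric flow history.

    Integrates the Windkessel ODE with the exponential one-step update,
    evaluating i(t) and its centered-difference derivative at each step
    midpoint. ``initial_pressure`` defaults to the steady value for the
    initial inflow.
    """
    params = network.outlets[outlet]
    times = np.asarray(times, dtype=float)
    q = np.array([network.volumetric_flow(outlet, t) for t in times])
    p = np.empty_like(q)
    p[0] = (initial_pressure if initial_pressure is not None
            else q[0] * (params.r_proximal + params.r_distal))
    for k in range(len(times) - 1):
        dt = times[k + 1] - times[k]
        i_mid = 0.5 * (q[k] + q[k + 1])
        didt = (q[k + 1] - q[k]) / dt
        p[k + 1] = windkessel_advance(p[k], i_mid, didt, dt, params)
    return p


# ---------------------------------------------------------------------------
# Network and flow sampling
# ---------------------------------------------------------------------------

@dataclass
class RegionOfInterest:
    """Axial interval of one segment where capture is scored."""

    segment: str
    s_min: float
    s_max: float

    def __post_init__(self) -> None:
        if self.s_max <= self.s_min:
            raise ValueError("ROI interval must have s_max > s_min")


@dataclass
class VesselNetwork:
    """Directed acyclic network of cylindrical segments.

    ``inlets`` maps inlet segment name -> waveform scale constant C_i.
    ``junctions`` maps parent segment name -> {child name: flow fraction};
    fractions at each junction must sum to 1. A child fed by several parents
    receives the sum of the routed flows. Each segment's mean velocity is a
    fixed linear combination of the inlet waveforms, precomputed here, so
    junction mass balance holds identically at every instant.
    """

    segments: dict[str, VesselSegment]
    inlets: dict[str, float]
    junctions: dict[str, dict[str, float]] = field(default_factory=dict)
    outlets: dict[str, WindkesselParams] = field(default_factory=dict)
    roi: RegionOfInterest | None = None
    waveform_repaired: bool = False
    custom_waveforms: dict[str, PiecewiseWaveform] | None = None

    def __post_init__(self) -> None:
        for parent, kids in self.junctions.items():
            if parent not in self.segments:
                raise ValueError(f"junction parent {parent!r} unknown")
            total = sum(kids.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(
                    f"junction {parent!r}: split fractions sum to {total}, not 1")
            for k in kids:
                if k not in self.segments:
                    raise ValueError(f"junction child {k!r} unknown")
        if self.roi is not None and self.roi.segment not in self.segments:
            raise ValueError("ROI references unknown segment")
        self._flow_factors = self._propagate_flow()
        if self.custom_waveforms is not None:
            missing = set(self.inlets) - set(self.custom_waveforms)
            if missing:
                raise ValueError(f"custom_waveforms missing inlets: {missing}")
            self._waveforms = dict(self.custom_waveforms)
        else:
            self._waveforms = {
                name: inlet_waveform(scale, repaired=self.waveform_repaired)
                for name, scale in self.inlets.items()
            }
        unreachable = [n for n, f in self._flow_factors.items() if not f]
        if unreachable:
            raise ValueError(f"segments unreachable from any inlet: {unreachable}")

    def _propagate_flow(self) -> dict[str, dict[str, float]]:
        """Per-segment {inlet: volumetric-flow coefficient} (m² units ×ū_inlet)."""
        # factor maps segment -> inlet -> Q contribution per unit ū_inlet(t)
        factors: dict[str, dict[str, float]] = {n: {} for n in self.segments}
        for inlet in self.inlets:
            if inlet not in self.segments:
                raise ValueError(f"inlet {inlet!r} unknown")
            factors[inlet][inlet] = self.segments[inlet].area
        # Kahn-style topological propagation; detects cycles.
        indeg = {n: 0 for n in self.segments}
        for parent, kids in self.junctions.items():
            for k in kids:
                indeg[k] += 1
        queue = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for child, frac in self.junctions.get(n, {}).items():
                for inlet, q in factors[n].items():
                    factors[child][inlet] = factors[child].get(inlet, 0.0) + frac * q
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if seen != len(self.segments):
            raise ValueError("vessel network contains a directed cycle")
        return factors

    def mean_velocity(self, segment: str, t) -> float:
        """Cross-sectional mean axial velocity ū(t) of a segment (m/s)."""
        seg = self.segments[segment]
        q = self.volumetric_flow(segment, t)
        return q / seg.area

    def volumetric_flow(self, segment: str, t):
        """Volumetric flow Q(t) through a segment (m³/s)."""
        q = 0.0
        for inlet, coeff in self._flow_factors[segment].items():
            q = q + coeff * self._waveforms[inlet].mean_velocity(t)
        return q

    def locate(self, position) -> str:
        """Name of the segment containing ``position`` (3-vector)."""
        pos = np.asarray(position, dtype=float)
        best, best_r = None, np.inf
        for name, seg in self.segments.items():
            if seg.contains(pos)[0]:
                _, r = seg.local_coords(pos)
                if r[0] < best_r:
                    best, best_r = name, r[0]
        if best is None:
            raise OutsideLumenError(f"position {pos} is outside every lumen")
        return best


@dataclass(frozen=True)
class FlowSample:
    """Local flow state at a point: velocity, strain rate, viscosity, density."""

    velocity: np.ndarray
    strain_rate: float
    viscosity: float
    density: float
    segment: str = ""


def axial_velocity_profile(radial_offset, t, segment: VesselSegment,
                           mean_velocity_fn) -> float:
    """Parabolic axial velocity u(y, t) = 2 ū(t) (1 − (y/R)²).

    ``mean_velocity_fn`` supplies ū(t) for this segment; zero at the wall,
    2ū on the centerline, cross-sectional average ū.
    """
    y = np.asarray(radial_offset, dtype=float)
    if np.any(np.abs(y) > segment.radius * (1 + 1e-12)):
        raise OutsideLumenError("radial offset exceeds the vessel radius")
    u = 2.0 * mean_velocity_fn(t) * (1.0 - (y / segment.radius) ** 2)
    return float(u) if np.isscalar(radial_offset) else u


def sample_flow(position, t: float, network: VesselNetwork,
                rheology: CarreauParams = CarreauParams(),
                density: float = BLOOD_DENSITY) -> FlowSample:
    """Velocity, shear rate and Carreau viscosity at one point of the network.

    The velocity is axial with parabolic magnitude; the scalar shear rate of
    the profile is γ̇ = |du/dy| = 4 ū |y| / R².
    """
    name = network.locate(position)
    seg = network.segments[name]
    _, r = seg.local_coords(position)
    r = float(r[0])
    ubar = network.mean_velocity(name, t)
    u_ax = 2.0 * ubar * (1.0 - (r / seg.radius) ** 2)
    gamma = 4.0 * abs(ubar) * r / seg.radius**2
    return FlowSample(
        velocity=u_ax * seg.axis,
        strain_rate=gamma,
        viscosity=carreau_viscosity(gamma, rheology),
        density=density,
        segment=name,
    )


def wall_shear_stress(segment_name: str, t: float, network: VesselNetwork,
                      rheology: CarreauParams = CarreauParams()) -> float:
    """Wall shear stress τ_w = µ(γ̇_w)·γ̇_w with γ̇_w = 4ū(t)/R."""
    seg = network.segments[segment_name]
    ubar = network.mean_velocity(segment_name, t)
    gamma_w = 4.0 * abs(ubar) / seg.radius
    return carreau_viscosity(gamma_w, rheology) * gamma_w


def vorticity(position, t: float, network: VesselNetwork) -> float:
    """Vorticity magnitude |∇×u| = 4 ū |y| / R² of the parabolic profile.

    Purely azimuthal for an axial parabolic profile; zero on the centerline
    and 4ū/R at the wall.
    """
    name = network.locate(position)
    seg = network.segments[name]
    _, r = seg.local_coords(position)
    ubar = network.mean_velocity(name, t)
    return 4.0 * abs(ubar) * float(r[0]) / seg.radius**2
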