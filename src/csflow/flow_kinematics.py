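"""Spin-ensemble kinematics through an anatomy-dependent 1D velocity field.

Motion is one-dimensional along the slice normal. A velocity waveform V(t)
prescribes the fluid velocity at the bottom of the first imaging slice
(x = 0); incompressibility through a compartment of varying cross-sectional
area A(x) scales the local velocity by F(x) = A_slc1 / A(x), giving the
trajectory ODE

    dx/dt = F(x) · V(t).

The ODE is separable: in the stretched coordinate
G(x) = ∫₀ˣ A_clamped(x') / A_slc1 dx' (fluid volume between 0 and x, per
unit entrance area) every trajectory is plug flow,

    G(x(t)) = G(x0) + ∫₀ᵗ V(τ) dτ,

which :class:`StretchedCoordinate` exploits to propagate whole spin
populations exactly and simultaneously. A SciPy ``solve_ivp`` route with
dense output is also provided (:func:`integrate_trajectories`) for generic
use and as a numerical cross-check.

Outside the tabulated extent of A(x) (and wherever the tabulated area is
smaller), the area is clamped to a floor (0.05 cm² by default) so that F(x)
is defined everywhere spins can travel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .acquisition import ExcitationSchedule, Protocol
from .mr_signal import ExcitationHistory

__all__ = [
    "AreaProfile",
    "VelocityWaveform",
    "StretchedCoordinate",
    "f_factor",
    "integrate_trajectories",
    "seed_positions",
    "detect_excitations",
]

DEFAULT_AREA_FLOOR = 0.05  # cm^2


@dataclass(frozen=True)
class AreaProfile:
    """Cross-sectional area A(x) of the flow compartment vs. depth.

    ``positions`` are in cm with x = 0 at the bottom of the first imaging
    slice (positive into the volume); ``areas`` in cm². Evaluation is linear
    between tabulated points and falls back to ``area_floor`` outside the
    tabulated range; areas below the floor are clamped up to it.
    """

    positions: np.ndarray
    areas: np.ndarray
    area_floor: float = DEFAULT_AREA_FLOOR

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        if pos.ndim != 1 or pos.shape != areas.shape or pos.size < 2:
            raise ValueError("positions and areas must be matching 1D arrays")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(areas)) or np.any(areas <= 0):
            raise ValueError("areas must be finite and positive")
        if self.area_floor <= 0:
            raise ValueError("area_floor must be positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "areas", areas)

    @classmethod
    def straight_tube(
        cls,
        area: float = 0.5,
        span: tuple[float, float] = (-50.0, 50.0),
        area_floor: float = DEFAULT_AREA_FLOOR,
    ) -> "AreaProfile":
        """Constant-area tube (F ≡ 1 everywhere inside the span)."""
        return cls(
            positions=np.array(span, dtype=float),
            areas=np.array([area, area], dtype=float),
            area_floor=area_floor,
        )

    def area(self, x) -> np.ndarray:
        """Clamped area A(x): interpolated inside, ``area_floor`` outside."""
        x = np.asarray(x, dtype=float)
        a = np.interp(
            x, self.positions, self.areas,
            left=self.area_floor, right=self.area_floor,
        )
        return np.maximum(a, self.area_floor)

    @property
    def a_slc1(self) -> float:
        """Area at x = 0 (bottom of the first slice)."""
        if not (self.positions[0] <= 0.0 <= self.positions[-1]):
            raise ValueError(
                "area profile does not cover x = 0; cannot define A_slc1"
            )
        return float(self.area(0.0))

    def shifted(self, dx: float) -> "AreaProfile":
        return AreaProfile(self.positions + dx, self.areas, self.area_floor)

    def scaled(self, factor: float) -> "AreaProfile":
        return AreaProfile(self.positions, self.areas * factor, self.area_floor)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "AreaProfile":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(positions=data[:, 0], areas=data[:, 1], **kwargs)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.positions, self.areas]),
            delimiter=",",
            header="position_cm,area_cm2",
            comments="",
        )


def f_factor(x, profile: AreaProfile) -> np.ndarray:
    """Dimensionless velocity scaling F(x) = A_slc1 / A_clamped(x)."""
    return profile.a_slc1 / profile.area(x)


@dataclass(frozen=True)
class VelocityWaveform:
    """Signed fluid velocity V(t) at the slice-1 entrance, cm/s.

    Sampled on a uniform time grid; positive values flow into the volume.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("times and values must be matching 1D arrays")
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("times must be uniformly sampled")
        if not np.all(np.isfinite(v)):
            raise ValueError("velocity values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def velocity(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.values)

    def displacement(self, t) -> np.ndarray:
        """Cumulative entrance-plane displacement S(t) = ∫ V dτ (cm)."""
        s = np.concatenate(
            [[0.0], cumulative_trapezoid(self.values, self.times)]
        )
        return np.interp(t, self.times, s)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VelocityWaveform":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(times=data[:, 0], values=data[:, 1])

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.values]),
            delimiter=",",
            header="time_s,velocity_cm_s",
            comments="",
        )

    @classmethod
    def from_function(
        cls, func: Callable, duration: float, dt: float = 0.01, t0: float = 0.0
    ) -> "VelocityWaveform":
        t = np.arange(t0, t0 + duration + 0.5 * dt, dt)
        return cls(times=t, values=np.asarray(func(t), dtype=float))

    @classmethod
    def constant(
        cls, v: float, duration: float, dt: float = 0.01
    ) -> "VelocityWaveform":
        return cls.from_function(lambda t: np.full_like(t, float(v)), duration, dt)


class StretchedCoordinate:
    """Exact propagator for dx/dt = F(x)V(t) via the volume coordinate G(x).

    Tabulates G on a fine grid covering ``x_range`` (including the profile's
    breakpoints, where A is piecewise linear, so the trapezoid integral is
    exact up to the grid spacing at floor crossings) and inverts it by
    interpolation; G is strictly increasing because the clamped area is
    positive.
    """

    def __init__(
        self,
        profile: AreaProfile,
        x_range: tuple[float, float],
        grid_step: float = 0.005,
    ):
        lo, hi = float(x_range[0]), float(x_range[1])
        if hi <= lo:
            raise ValueError("empty x_range")
        # A(x) is constant (the floor) outside the tabulated span, where G is
        # exactly linear, so the fine grid only needs to cover the span.
        core_lo = max(lo, float(profile.positions[0]) - grid_step)
        core_hi = min(hi, float(profile.positions[-1]) + grid_step)
        pieces = [np.array([lo, hi])]
        if core_hi > core_lo:
            pieces.append(np.arange(core_lo, core_hi + grid_step, grid_step))
            pieces.append(profile.positions[
                (profile.positions >= lo) & (profile.positions <= hi)
            ])
        if lo <= 0.0 <= hi:
            pieces.append(np.array([0.0]))
        xg = np.union1d(np.concatenate(pieces), [])
        dens = profile.area(xg) / profile.a_slc1  # dG/dx
        g = np.concatenate([[0.0], cumulative_trapezoid(dens, xg)])
        g -= np.interp(0.0, xg, g) if lo <= 0.0 <= hi else g[0]
        self.profile = profile
        self._x = xg
        self._g = g

    def g_of_x(self, x) -> np.ndarray:
        return np.interp(x, self._x, self._g)

    def x_of_g(self, g) -> np.ndarray:
        return np.interp(g, self._g, self._x)

    def propagate(self, x0, displacement) -> np.ndarray:
        """Positions after entrance-plane displacement(s) S (cm)."""
        return self.x_of_g(self.g_of_x(np.asarray(x0)) + np.asarray(displacement))


class _DenseTrajectories:
    """Dense-output wrapper over a batched solve_ivp solution."""

    def __init__(self, sol, x0s: np.ndarray):
        self._sol = sol
        self.x0s = x0s
        self.t_span = (sol.t[0], sol.t[-1])

    def __call__(self, t) -> np.ndarray:
        """Positions, shape (n_spins,) for scalar t or (n_spins, n_t)."""
        return self._sol.sol(t)


def integrate_trajectories(
    x0s: Sequence[float],
    waveform: VelocityWaveform,
    profile: AreaProfile | None,
    t_span: tuple[float, float],
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> _DenseTrajectories:
    """Integrate spin trajectories with an adaptive Runge–Kutta solver.

    ``profile=None`` means a straight tube (F ≡ 1). Returns a dense-output
    object queryable at arbitrary times within ``t_span``. Intended for
    generic trajectory queries and verification; the forward simulator uses
    the exact :class:`StretchedCoordinate` propagator instead.
    """
    x0s = np.asarray(x0s, dtype=float)
    if not np.all(np.isfinite(x0s)):
        raise ValueError("initial positions must be finite")
    if t_span[0] < waveform.times[0] - 1e-9 or t_span[1] > waveform.times[-1] + 1e-9:
        raise ValueError("waveform does not cover the requested time span")

    if profile is None:
        def rhs(t, x):
            return np.full_like(x, waveform.velocity(t))
    else:
        def rhs(t, x):
            return f_factor(x, profile) * waveform.velocity(t)

    sol = solve_ivp(
        rhs, t_span, x0s, method="RK45", rtol=rtol, atol=atol,
        dense_output=True,
    )
    if not sol.success:
        worst = int(np.argmax(~np.isfinite(sol.y[:, -1]))) if sol.y.size else 0
        raise RuntimeError(
            f"trajectory integration failed near t = {sol.t[-1]:.3f} s "
            f"(spin index {worst}): {sol.message}"
        )
    return _DenseTrajectories(sol, x0s)


def seed_positions(
    profile: AreaProfile | None,
    protocol: Protocol,
    waveform: VelocityWaveform,
    spacing: float | None = None,
    margin_pad: float | None = None,
) -> np.ndarray:
    """Uniformly spaced initial positions covering the volume plus margins.

    Margins are computed exactly from the stretched-coordinate displacement
    range (the extrema of ∫V dτ), so every position that can ever lie inside
    a slice during the simulation is reachable from some seed; a pad of one
    slice width is added on each side. Default spacing is W/100.
    """
    if spacing is None:
        spacing = protocol.slice_thickness_w / 100.0
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if margin_pad is None:
        margin_pad = protocol.slice_thickness_w
    top = protocol.n_slices * protocol.slice_thickness_w
    s = waveform.displacement(waveform.times)
    if profile is None:
        lo = 0.0 - float(np.max(s)) - margin_pad
        hi = top - float(np.min(s)) + margin_pad
    else:
        # generous bracket for the coordinate table, then exact inversion
        f_max = profile.a_slc1 / profile.area_floor
        reach = float(np.max(np.abs(s))) * max(f_max, 1.0) + top + margin_pad
        coord = StretchedCoordinate(profile, (-reach, reach))
        lo = float(coord.x_of_g(coord.g_of_x(0.0) - np.max(s))) - margin_pad
        hi = float(coord.x_of_g(coord.g_of_x(top) - np.min(s))) + margin_pad
    return np.arange(lo, hi + spacing, spacing)


def detect_excitations(
    trajectory: Callable[[float], float] | Callable[[np.ndarray], np.ndarray],
    schedule: ExcitationSchedule,
    protocol: Protocol,
) -> tuple[list[float], ExcitationHistory | None]:
    """Pulse times and resulting history for one spin trajectory.

    A spin at position x at an event time receives the pulse iff
    ``k·W ≤ x < (k+1)·W`` for some excited slice k (half-open slab, so slice
    boundaries are never double-counted). Returns the received pulse times
    and the final :class:`ExcitationHistory` (``None`` if no pulse was
    received).
    """
    w = protocol.slice_thickness_w
    pulse_times: list[float] = []
    pos = np.asarray(trajectory(schedule.times), dtype=float).reshape(-1)
    for t, x, group in zip(schedule.times, pos, schedule.groups):
        k = int(np.floor(x / w))
        if k in group and 0 <= k < protocol.n_slices:
            pulse_times.append(float(t))
    if not pulse_times:
        return [], None
    deltas = tuple(np.diff(pulse_times))
    return pulse_times, ExcitationHistory(n=len(pulse_times), deltas=deltas)
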