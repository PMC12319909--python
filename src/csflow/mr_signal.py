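"""Flow-enhanced spoiled gradient-echo signal for arbitrary excitation histories.

A spin ensemble that has received ``n`` RF pulses separated by arbitrary
intervals Δt₁..Δt₍ₙ₋₁₎ (Δt₁ oldest, Δt₍ₙ₋₁₎ most recent) carries longitudinal
magnetization just before its n-th pulse given by the spoiled-GRE recursion

    Mz ← Mz · cosθ · exp(−Δt/T1) + M_eq · (1 − exp(−Δt/T1)),

starting from equilibrium (Mz = M_eq, fresh spin). The transverse signal
observed at the echo is ``Mz · sinθ · exp(−TE/T2)``. Perfect spoiling is
assumed: no transverse coherence survives between pulses, so TE enters only
as a constant attenuation factor.

This module provides the closed-form evaluation of that signal (a sum of
relaxation-weighted recovery terms, equivalent to unrolling the recursion),
the stationary-spin steady state for constant inter-pulse spacing, and the
inflow contrast (signal minus steady state), which is the quantity the
forward simulator accumulates per slice.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .acquisition import Protocol

__all__ = [
    "ExcitationHistory",
    "transverse_signal",
    "steady_state_signal",
    "inflow_contrast",
    "fresh_spin_signal",
    "longitudinal_update",
]


@dataclass(frozen=True)
class ExcitationHistory:
    """Pulse count ``n`` and the ``n − 1`` inter-pulse intervals in seconds.

    ``deltas[k]`` is the interval between pulse ``k+1`` and pulse ``k+2``
    (1-based); the last entry is the most recent interval.
    """

    n: int
    deltas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("history requires at least one pulse (n >= 1)")
        deltas = tuple(float(d) for d in self.deltas)
        if len(deltas) != self.n - 1:
            raise ValueError("deltas must have length n - 1")
        if any(d <= 0 for d in deltas):
            raise ValueError("all inter-pulse intervals must be positive")
        object.__setattr__(self, "deltas", deltas)


def fresh_spin_signal(protocol: Protocol) -> float:
    """Signal of a spin receiving its first pulse: M_eq·sinθ·exp(−TE/T2)."""
    return (
        protocol.m_eq
        * np.sin(protocol.flip_angle)
        * np.exp(-protocol.te / protocol.t2)
    )


def transverse_signal(history: ExcitationHistory, protocol: Protocol) -> float:
    """Transverse signal M_T at the spin's n-th pulse (arbitrary units).

    Closed-form evaluation: with E_k = exp(−Δt_k/T1) and c = cosθ,

        Mz = M_eq · [ c^{n−1} ∏_{k=1}^{n−1} E_k
                      + Σ_{j=1}^{n−1} (1 − E_j) c^{n−1−j} ∏_{k=j+1}^{n−1} E_k ]
        M_T = Mz · sinθ · exp(−TE/T2)

    i.e. each recovery increment (1 − E_j) is attenuated by the flips and
    relaxation decays that follow it. Strictly positive for 0 < θ < π/2.
    """
    n = history.n
    c = np.cos(protocol.flip_angle)
    if n == 1:
        mz = protocol.m_eq
    else:
        e = np.exp(-np.asarray(history.deltas) / protocol.t1)  # E_1..E_{n-1}
        # suffix products P_j = prod_{k=j+1}^{n-1} E_k, j = 0..n-1
        suffix = np.ones(n)
        suffix[:-1] = np.cumprod(e[::-1])[::-1]
        j = np.arange(1, n)
        terms = (1.0 - e) * c ** (n - 1 - j) * suffix[1:]
        mz = protocol.m_eq * (c ** (n - 1) * suffix[0] + terms.sum())
    return float(mz * np.sin(protocol.flip_angle) * np.exp(-protocol.te / protocol.t2))


def steady_state_signal(delta_t: float, protocol: Protocol) -> float:
    """Stationary-spin steady-state signal for constant inter-pulse spacing.

    The n → ∞ fixed point of the recursion with all intervals ``delta_t``:

        M_ss = M_eq · sinθ · exp(−TE/T2) · (1 − E) / (1 − E·cosθ),
        E = exp(−delta_t / T1).

    With ``delta_t = TR`` this is the saturation baseline subtracted to form
    the inflow contrast.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    e1 = np.exp(-delta_t / protocol.t1)
    return float(
        protocol.m_eq
        * np.sin(protocol.flip_angle)
        * np.exp(-protocol.te / protocol.t2)
        * (1.0 - e1)
        / (1.0 - e1 * np.cos(protocol.flip_angle))
    )


def inflow_contrast(history: ExcitationHistory, protocol: Protocol) -> float:
    """Inflow signal: transverse signal minus the TR steady-state baseline.

    Can be marginally negative for histories containing intervals shorter
    than TR; values are returned unclipped.
    """
    return transverse_signal(history, protocol) - steady_state_signal(
        protocol.tr, protocol
    )


def longitudinal_update(
    mz_post: np.ndarray,
    dt: np.ndarray,
    protocol: Protocol,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-pulse update used by the forward simulator.

    Given post-flip longitudinal magnetization ``mz_post`` from the previous
    pulse and elapsed time ``dt`` since it, return ``(mz_pre, mz_post_new)``:
    the recovered magnetization at the new pulse and its post-flip value.
    """
    rec = np.exp(-np.asarray(dt) / protocol.t1)
    mz_pre = mz_post * rec + protocol.m_eq * (1.0 - rec)
    return mz_pre, mz_pre * np.cos(protocol.flip_angle)
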