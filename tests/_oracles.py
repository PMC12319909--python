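"""Independent analytic oracles used by the test suite.

These deliberately avoid the package's simulation engine: pulse times are
enumerated in closed form and the magnetization follows the plain scalar
recursion.
"""

import numpy as np

from csflow import Protocol, build_schedule
from csflow.mr_signal import steady_state_signal


def plug_flow_slice_means(
    v: float,
    protocol: Protocol,
    n_slices_out: int,
    n_xi: int = 400,
    settle_cycles: int = 60,
) -> np.ndarray:
    """Steady-state mean inflow contrast per slice for constant plug flow.

    For constant velocity v in a straight tube, a spin observed at in-slice
    offset xi has the deterministic position history x(t) = x - v (T - t),
    so the pulses it received from slice j are the arithmetic sequence of
    slice-j excitation times falling inside its transit window of slice j.
    The slice mean is the average over a uniform grid of xi.
    """
    w, tr = protocol.slice_thickness_w, protocol.tr
    sched = build_schedule(protocol, tr)
    offsets = sched.slice_event_offsets(protocol.n_slices)
    ss = steady_state_signal(tr, protocol)
    cos_t = np.cos(protocol.flip_angle)
    emit = np.sin(protocol.flip_angle) * np.exp(-protocol.te / protocol.t2)

    out = np.empty(n_slices_out)
    for k in range(n_slices_out):
        t_obs = settle_cycles * tr + offsets[k]  # one slice-k event time
        vals = []
        for xi in (np.arange(n_xi) + 0.5) * w / n_xi:
            x = k * w + xi
            pulses = []
            for j in range(protocol.n_slices):
                t_lo = t_obs - (x - j * w) / v
                t_hi = t_obs - (x - (j + 1) * w) / v
                m_lo = int(np.ceil((t_lo - offsets[j]) / tr - 1e-12))
                m_hi = int(np.floor((min(t_hi, t_obs + 1e-12) - offsets[j]) / tr + 1e-12))
                for m in range(m_lo, m_hi + 1):
                    t = offsets[j] + m * tr
                    if t_lo <= t < t_hi and t <= t_obs + 1e-9:
                        pulses.append(t)
            pulses.sort()
            mz = protocol.m_eq
            for d in np.diff(pulses):
                e = np.exp(-d / protocol.t1)
                mz = mz * cos_t * e + protocol.m_eq * (1.0 - e)
            vals.append(mz * emit - ss)
        out[k] = np.mean(vals)
    return out
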