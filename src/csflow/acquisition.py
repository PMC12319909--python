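"""Imaging protocol and slice excitation scheduling.

The forward model needs to know *when* each slice is excited. In a
simultaneous-multislice (SMS/multiband) EPI acquisition, ``n_slices`` slices
are excited in groups of ``mb_factor`` simultaneously excited slices, with the
``n_slices / mb_factor`` group excitations spread uniformly over one TR. The
grouping follows the standard SMS convention: group ``j`` excites slices
``{j, j + n/MB, j + 2n/MB, ...}`` (arithmetic stride). The within-TR order of
the groups is configurable because vendors differ and it is rarely reported;
the bottom slices of the volume fall in different groups, so their relative
sub-TR offsets depend on it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import yaml

__all__ = [
    "Protocol",
    "ExcitationSchedule",
    "build_schedule",
    "critical_velocity",
    "load_protocol",
]


@dataclass(frozen=True)
class Protocol:
    """Acquisition and relaxation parameters of a gradient-echo EPI protocol.

    Parameters
    ----------
    tr : float
        Repetition time in seconds (time between excitations of one slice).
    te : float
        Echo time in seconds.
    flip_angle : float
        Flip angle in radians (use :func:`load_protocol` to read degrees).
    slice_thickness_w : float
        Slice thickness W in cm.
    n_slices : int
        Number of slices in the imaging volume.
    mb_factor : int
        Multiband (SMS) factor; ``n_slices`` must be divisible by it.
    slice_order : str or sequence of int
        Within-TR order of the ``n_slices/mb_factor`` excitation groups:
        ``"sequential"``, ``"interleaved"`` (even groups then odd, the
        default), or an explicit permutation of group indices.
    t1, t2 : float
        Longitudinal / transverse relaxation time constants of the fluid, s.
    m_eq : float
        Equilibrium longitudinal magnetization (arbitrary units).
    """

    tr: float = 0.504
    te: float = 0.030
    flip_angle: float = math.radians(45.0)
    slice_thickness_w: float = 0.25
    n_slices: int = 21
    mb_factor: int = 3
    slice_order: str | tuple[int, ...] = "interleaved"
    t1: float = 4.0
    t2: float = 1.5
    m_eq: float = 1.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.te < 0:
            raise ValueError("te must be nonnegative")
        if not (0.0 < self.flip_angle <= math.pi / 2):
            raise ValueError("flip_angle must be in (0, pi/2] radians")
        if self.slice_thickness_w <= 0:
            raise ValueError("slice_thickness_w must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.mb_factor < 1:
            raise ValueError("mb_factor must be >= 1")
        if self.n_slices % self.mb_factor != 0:
            raise ValueError(
                f"n_slices ({self.n_slices}) must be divisible by "
                f"mb_factor ({self.mb_factor})"
            )
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("t1 and t2 must be positive")
        if isinstance(self.slice_order, str):
            if self.slice_order not in ("sequential", "interleaved"):
                raise ValueError(
                    "slice_order must be 'sequential', 'interleaved', or an "
                    "explicit group permutation"
                )
        else:
            order = tuple(int(i) for i in self.slice_order)
            if sorted(order) != list(range(self.n_groups)):
                raise ValueError(
                    "explicit slice_order must be a permutation of "
                    f"range({self.n_groups})"
                )
            object.__setattr__(self, "slice_order", order)

    @property
    def n_groups(self) -> int:
        """Number of excitation events per TR (= n_slices / mb_factor)."""
        return self.n_slices // self.mb_factor

    def replace(self, **kwargs) -> "Protocol":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ExcitationSchedule:
    """Periodic slice excitation schedule.

    ``times`` (s) and ``groups`` (tuples of 0-based slice indices excited
    simultaneously) are parallel arrays covering ``[0, duration)``; the
    pattern repeats with period ``cycle_length`` (= TR).
    """

    times: np.ndarray
    groups: tuple[tuple[int, ...], ...]
    cycle_length: float

    def __len__(self) -> int:
        return len(self.times)

    def slice_event_offsets(self, n_slices: int | None = None) -> np.ndarray:
        """Within-TR excitation offset (s) of each slice in cycle 0."""
        cycle = self.times < self.cycle_length
        n = n_slices if n_slices is not None else 1 + max(
            s for g in self.groups for s in g
        )
        offsets = np.full(n, np.nan)
        for t, group in zip(self.times[cycle], self.groups):
            for s in group:
                if s < n:
                    offsets[s] = t
        return offsets

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("time_s,slice_indices\n")
            for t, g in zip(self.times, self.groups):
                fh.write(f"{t:.9g},{' '.join(str(s) for s in g)}\n")


def _group_order(protocol: Protocol) -> list[int]:
    n_groups = protocol.n_groups
    if protocol.slice_order == "sequential":
        return list(range(n_groups))
    if protocol.slice_order == "interleaved":
        return list(range(0, n_groups, 2)) + list(range(1, n_groups, 2))
    return list(protocol.slice_order)


def build_schedule(protocol: Protocol, duration: float) -> ExcitationSchedule:
    """Build the slice excitation schedule covering ``[0, duration)``.

    Within each TR there are ``n_slices / mb_factor`` excitation events at
    uniform offsets ``j * TR / n_groups``; event ``j`` (in the configured
    group order) excites the multiband group ``{k, k + n/MB, k + 2n/MB, ...}``.
    Every slice is excited exactly once per TR.
    """
    if duration < protocol.tr:
        raise ValueError("duration must be at least one TR")
    n_groups = protocol.n_groups
    order = _group_order(protocol)
    offsets = np.arange(n_groups) * protocol.tr / n_groups
    groups_one_tr = [
        tuple(order[j] + i * n_groups for i in range(protocol.mb_factor))
        for j in range(n_groups)
    ]
    n_cycles = int(math.ceil(duration / protocol.tr))
    times = (
        np.arange(n_cycles)[:, None] * protocol.tr + offsets[None, :]
    ).ravel()
    keep = times < duration
    times = times[keep]
    groups = tuple(groups_one_tr[i % n_groups] for i in range(len(times)))
    return ExcitationSchedule(times=times, groups=groups, cycle_length=protocol.tr)


def critical_velocity(protocol: Protocol) -> float:
    """Critical velocity V_crit = W / TR (cm/s).

    A spin moving at V_crit traverses exactly one slice thickness per TR, so
    fluid in the first slice is always excited exactly once and the
    first-slice inflow signal saturates at the fresh-spin contrast.
    """
    return protocol.slice_thickness_w / protocol.tr


def load_protocol(path: str | Path) -> Protocol:
    """Read a Protocol from a YAML or JSON config file.

    ``flip_angle_deg`` is accepted (converted to radians); explicit
    ``slice_order`` lists are passed through.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if "flip_angle_deg" in cfg:
        cfg["flip_angle"] = math.radians(float(cfg.pop("flip_angle_deg")))
    if isinstance(cfg.get("slice_order"), list):
        cfg["slice_order"] = tuple(cfg["slice_order"])
    return Protocol(**cfg)
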