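"""Stochastic generator of velocity waveforms, anatomies, and noisy inflow
signals for training the inverse model.

Training velocities are sums of 100 sinusoids on a fixed 0.01–1.00 Hz grid.
Each sinusoid's amplitude is drawn uniformly between frequency-dependent
lower and upper bound curves built from three Gaussian bumps that mimic the
spectral content of measured CSF velocities: a slow hemodynamic component
(~0.05 Hz), a respiratory component (~0.1–0.3 Hz, with 1/3- and 1/6-weight
harmonics at twice and three times the breathing frequency), and a cardiac
component (~0.8–1.0 Hz). A quarter of the samples are drawn in "phantom
mode" — a single narrow spectral bump at 0.05/0.1/0.2 Hz, zero offset
velocity, and a straight tube — mimicking pump-driven oscillatory phantom
flow. Within human-mode samples there is additionally a 25% chance that the
breathing frequency is pinned to 0.167 Hz (the paced-breathing rate).

Each sample is pushed through the forward simulator with a randomly shifted
and scaled compartment anatomy, rescaled to a fixed maximum amplitude,
corrupted with Gaussian noise, and demeaned; the regression target is the
input velocity resampled to 1,000 points over the same wall-clock window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .acquisition import Protocol
from .flow_kinematics import AreaProfile, VelocityWaveform
from .forward_simulator import simulate_inflow

__all__ = [
    "SpectralBounds",
    "VelocitySpec",
    "TrainingSample",
    "bounds",
    "sample_velocity",
    "sample_anatomy",
    "synthetic_ventricle_curve",
    "make_sample",
    "make_dataset",
    "save_dataset",
    "load_dataset",
]

FREQ_GRID = np.round(np.arange(1, 101) * 0.01, 2)  # 0.01..1.00 Hz
SIGMA_SLOW = 0.015
SIGMA_RESP = 0.002
SIGMA_CARD = 0.0075
SIGMA_PHANTOM = 0.006
INPUT_LENGTH = 200
TARGET_LENGTH = 1000
TRIM_TRS = 40
PHANTOM_PROB = 0.25
FORCED_RESP_PROB = 0.25
FORCED_RESP_FREQ = 0.167
PHANTOM_TUBE_AREA = 0.5  # cm^2; straight plastic tube stand-in


@dataclass(frozen=True)
class SpectralBounds:
    """Gaussian-bump parameters of the amplitude bound curves.

    ``alpha_*`` are peak amplitudes (cm/s), ``mu_*`` center frequencies (Hz).
    Widths are fixed (slow 0.015, resp 0.002, cardiac 0.0075 Hz) and the
    respiratory harmonics at 2μ and 3μ carry weights 1/3 and 1/6. A phantom
    draw is represented by the single ``alpha_phantom``/``mu_phantom`` bump.
    """

    alpha_slow: float = 0.0
    mu_slow: float = 0.05
    alpha_resp: float = 0.0
    mu_resp: float = 0.2
    alpha_card: float = 0.0
    mu_card: float = 0.9
    alpha_phantom: float = 0.0
    mu_phantom: float = 0.1
    phantom: bool = False

    def envelope(self, f) -> np.ndarray:
        """Sum of the Gaussian bumps g_slow + g_resp + g_card at f (cm/s)."""
        f = np.asarray(f, dtype=float)
        if self.phantom:
            return self.alpha_phantom * np.exp(
                -0.5 * ((f - self.mu_phantom) / SIGMA_PHANTOM) ** 2
            )
        g_slow = self.alpha_slow * np.exp(
            -0.5 * ((f - self.mu_slow) / SIGMA_SLOW) ** 2
        )
        g_resp = self.alpha_resp * (
            np.exp(-0.5 * ((f - self.mu_resp) / SIGMA_RESP) ** 2)
            + np.exp(-0.5 * ((f - 2 * self.mu_resp) / SIGMA_RESP) ** 2) / 3.0
            + np.exp(-0.5 * ((f - 3 * self.mu_resp) / SIGMA_RESP) ** 2) / 6.0
        )
        g_card = self.alpha_card * np.exp(
            -0.5 * ((f - self.mu_card) / SIGMA_CARD) ** 2
        )
        return g_slow + g_resp + g_card


def bounds(f, sb: SpectralBounds) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper amplitude bounds (cm/s) at frequency f:
    B_L = 0.6·g, B_U = 1.4·g + 0.01."""
    g = sb.envelope(f)
    return 0.6 * g, 1.4 * g + 0.01


@dataclass(frozen=True)
class VelocitySpec:
    """Realized sinusoid-sum parameters of one training velocity."""

    v0: float
    freqs: np.ndarray
    amplitudes: np.ndarray
    t_shifts: np.ndarray
    bounds_draw: SpectralBounds

    def waveform(self, duration: float, dt: float = 0.02) -> VelocityWaveform:
        t = np.arange(0.0, duration + 0.5 * dt, dt)
        v = np.full_like(t, self.v0)
        for f, a, ts in zip(self.freqs, self.amplitudes, self.t_shifts):
            v += a * np.cos(2 * np.pi * f * (t - ts))
        return VelocityWaveform(times=t, values=v)


@dataclass(frozen=True)
class TrainingSample:
    """One (inputs, target) pair for the inverse model.

    ``inputs`` is 5×200: three demeaned noisy inflow slices, then the
    compartment areas (cm²) and their positions (cm, 0 at the slice-1
    bottom). ``target`` is the input velocity (cm/s) resampled to 1,000
    points over the same wall-clock window as the inflow channels.
    """

    inputs: np.ndarray
    target: np.ndarray
    phantom: bool
    seed: int


def sample_spectral_bounds(rng: np.random.Generator) -> SpectralBounds:
    """Draw the per-sample bound-curve parameters (phantom or human mode)."""
    if rng.uniform() < PHANTOM_PROB:
        return SpectralBounds(
            phantom=True,
            alpha_phantom=rng.uniform(0.0, 1.2),
            mu_phantom=float(rng.choice([0.05, 0.1, 0.2])),
        )
    mu_resp = (
        FORCED_RESP_FREQ
        if rng.uniform() < FORCED_RESP_PROB
        else rng.uniform(0.1, 0.3)
    )
    return SpectralBounds(
        alpha_slow=rng.uniform(0.0, 0.1),
        mu_slow=rng.uniform(0.035, 0.065),
        alpha_resp=rng.uniform(0.0, 1.0),
        mu_resp=mu_resp,
        alpha_card=rng.uniform(0.0, 0.2),
        mu_card=rng.uniform(0.8, 1.0),
    )


def sample_velocity(
    rng: np.random.Generator, sb: SpectralBounds | None = None
) -> VelocitySpec:
    """Draw one sinusoid-sum velocity specification.

    Offset v0 ~ U(−0.1, 0.1) cm/s (0 in phantom mode), per-frequency
    amplitudes V_i ~ U(B_L(f_i), B_U(f_i)), and time shifts uniform within
    each sinusoid's period.
    """
    if sb is None:
        sb = sample_spectral_bounds(rng)
    lo, hi = bounds(FREQ_GRID, sb)
    amps = rng.uniform(lo, hi)
    shifts = rng.uniform(0.0, 1.0 / FREQ_GRID)
    v0 = 0.0 if sb.phantom else rng.uniform(-0.1, 0.1)
    return VelocitySpec(
        v0=v0, freqs=FREQ_GRID.copy(), amplitudes=amps,
        t_shifts=shifts, bounds_draw=sb,
    )


def synthetic_ventricle_curve(
    rng: np.random.Generator, span: float = 8.0, n_points: int = 81
) -> AreaProfile:
    """Synthetic fourth-ventricle-like area–depth curve.

    A smooth unimodal Gaussian bump A(x) = A_min + (A_peak − A_min)·
    exp(−(x − x_peak)²/2σ²) with A_min ∈ [0.1, 0.4] cm², A_peak ∈ [0.8, 2.0]
    cm², σ ∈ [0.5, 1.5] cm, tabulated over a ``span``-cm window centered on
    the peak. Stands in for participant-extracted ventricle anatomy, which
    is not published as data.
    """
    a_min = rng.uniform(0.1, 0.4)
    a_peak = rng.uniform(0.8, 2.0)
    sigma = rng.uniform(0.5, 1.5)
    x_peak = 0.0
    x = np.linspace(x_peak - span / 2, x_peak + span / 2, n_points)
    a = a_min + (a_peak - a_min) * np.exp(-0.5 * ((x - x_peak) / sigma) ** 2)
    return AreaProfile(positions=x, areas=a)


def sample_anatomy(
    rng: np.random.Generator,
    curve_library: Sequence[AreaProfile],
    phantom: bool = False,
) -> AreaProfile:
    """Draw a compartment anatomy for one sample.

    Human mode: pick a random library curve, place the slice-1 bottom within
    ±1 cm of the widest location, and scale the areas by a factor in
    [0.8, 1.2] (the scale cancels in F(x) but changes the network's area
    channel). Phantom mode: straight tube.
    """
    if phantom:
        return AreaProfile.straight_tube(area=PHANTOM_TUBE_AREA, span=(-4.0, 4.0))
    if not curve_library:
        raise ValueError("curve library is empty")
    curve = curve_library[rng.integers(len(curve_library))]
    widest = float(curve.positions[int(np.argmax(curve.areas))])
    shift = rng.uniform(-1.0, 1.0)
    scale = rng.uniform(0.8, 1.2)
    # move the slice-1 origin to (widest + shift)
    return curve.shifted(-(widest + shift)).scaled(scale)


def _anatomy_channels(profile: AreaProfile, length: int = INPUT_LENGTH):
    pos = np.linspace(profile.positions[0], profile.positions[-1], length)
    return profile.area(pos), pos


def make_sample(
    rng: np.random.Generator,
    protocol: Protocol | None = None,
    curve_library: Sequence[AreaProfile] | None = None,
    *,
    n_input: int = INPUT_LENGTH,
    spacing: float | None = None,
    seed: int = 0,
) -> TrainingSample:
    """Generate one training sample through the forward model.

    Simulates ``n_input`` + 40 TRs, discards the 40-TR transient, rescales
    the three-slice signal set so its maximum equals 1 (human) or 0.25
    (phantom), adds Gaussian noise with σ ~ U(0.01, 0.1), demeans each
    inflow channel, and resamples the input velocity to 1,000 points over
    the kept window.
    """
    if protocol is None:
        protocol = Protocol()
    if curve_library is None:
        curve_library = [synthetic_ventricle_curve(rng)]
    if spacing is None:
        spacing = protocol.slice_thickness_w / 25.0

    sb = sample_spectral_bounds(rng)
    spec = sample_velocity(rng, sb)
    profile = sample_anatomy(rng, curve_library, phantom=sb.phantom)

    n_trs = n_input + TRIM_TRS
    duration = (n_trs + 1) * protocol.tr
    wf = spec.waveform(duration)
    sig = simulate_inflow(
        wf, profile, protocol, n_slices_out=3, spacing=spacing, n_trs=n_trs
    ).trimmed(TRIM_TRS)

    target_max = 0.25 if sb.phantom else 1.0
    peak = float(np.max(np.abs(sig.slice_signals)))
    scale = target_max / peak if peak > 0 else 1.0
    inflow = sig.slice_signals * scale

    sigma = rng.uniform(0.01, 0.1)
    inflow = inflow + rng.normal(0.0, sigma, size=inflow.shape)
    inflow = inflow - inflow.mean(axis=1, keepdims=True)

    areas, positions = _anatomy_channels(profile, n_input)
    inputs = np.vstack([inflow, areas[None, :], positions[None, :]])

    t0, t1 = sig.sample_times[0, 0], sig.sample_times[0, -1]
    t_target = np.linspace(t0, t1, TARGET_LENGTH)
    target = wf.velocity(t_target)

    return TrainingSample(
        inputs=inputs.astype(np.float32),
        target=target.astype(np.float32),
        phantom=sb.phantom,
        seed=seed,
    )


def make_dataset(
    n_samples: int,
    master_seed: int,
    protocol: Protocol | None = None,
    n_library_curves: int = 12,
    spacing: float | None = None,
    progress: bool = False,
) -> dict:
    """Generate a reproducible training dataset.

    The anatomy curve library and every per-sample draw derive from
    ``master_seed``, so (seed, n) → bit-identical arrays. Returns a dict of
    arrays: inputs (n, 5, 200), targets (n, 1000), phantom flags, seeds.
    """
    if protocol is None:
        protocol = Protocol()
    lib_rng = np.random.default_rng(master_seed)
    library = [synthetic_ventricle_curve(lib_rng) for _ in range(n_library_curves)]
    seed_seq = np.random.SeedSequence(master_seed)
    child_seeds = seed_seq.generate_state(n_samples)

    inputs = np.empty((n_samples, 5, INPUT_LENGTH), dtype=np.float32)
    targets = np.empty((n_samples, TARGET_LENGTH), dtype=np.float32)
    phantom = np.zeros(n_samples, dtype=bool)
    for i in range(n_samples):
        rng = np.random.default_rng(child_seeds[i])
        sample = make_sample(
            rng, protocol, library, spacing=spacing, seed=int(child_seeds[i])
        )
        inputs[i] = sample.inputs
        targets[i] = sample.target
        phantom[i] = sample.phantom
        if progress and (i + 1) % 500 == 0:
            print(f"  generated {i + 1}/{n_samples} samples")
    return {
        "inputs": inputs,
        "targets": targets,
        "phantom": phantom,
        "seeds": child_seeds.astype(np.int64),
        "master_seed": np.int64(master_seed),
        "tr": np.float64(protocol.tr),
    }


def save_dataset(dataset: dict, path: str | Path) -> None:
    """Write a dataset to .h5 (HDF5) or .npz depending on the extension."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            for key, val in dataset.items():
                fh.create_dataset(key, data=val)
    else:
        np.savez_compressed(path, **dataset)


def load_dataset(path: str | Path) -> dict:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            return {key: fh[key][()] for key in fh.keys()}
    with np.load(path) as npz:
        return {key: npz[key] for key in npz.files}
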