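"""Preprocessing of measured ROI time series and comparison statistics.

Covers the measured-data side of the pipeline: partial-volume scaling of
CSF-ROI voxels against a T1-weighted anatomical reference, standard fMRI
inflow-signal preprocessing (transient trim, lowest-decile baseline,
zero-phase low-pass), conversion of phase-contrast phase to velocity,
peak-locked cycle averaging, Welch spectra, power-law spectral fits, and
extraction of area–depth curves from labeled anatomical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.signal import butter, filtfilt, find_peaks, welch

from .flow_kinematics import AreaProfile

__all__ = [
    "RoiTimeseries",
    "PartialVolumeParams",
    "CycleAverage",
    "pv_scale",
    "preprocess_fmri",
    "phase_to_velocity",
    "cycle_average",
    "cycle_error",
    "spectral_density",
    "power_law_fit",
    "area_from_labels",
]

TRIM_SAMPLES = 40
LOWPASS_CUTOFF = 0.5  # Hz
LOWPASS_ORDER = 5


@dataclass(frozen=True)
class RoiTimeseries:
    """ROI-averaged time series: fMRI signal (a.u.), phase (rad) or velocity."""

    values: np.ndarray
    tr: float
    kind: str = "fmri_inflow"  # fmri_inflow | pc_phase | pc_velocity

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        object.__setattr__(self, "values", v)

    @property
    def fs(self) -> float:
        return 1.0 / self.tr


@dataclass(frozen=True)
class PartialVolumeParams:
    """T1-weighted reference intensities for partial-volume scaling.

    CSF is dark on the anatomical image, so ``t1w_tiss > t1w_csf > 0``.
    """

    t1w_tiss: float
    t1w_csf: float
    t1w_voxel: float

    def __post_init__(self):
        if not (self.t1w_tiss > self.t1w_csf > 0):
            raise ValueError("requires t1w_tiss > t1w_csf > 0")


@dataclass(frozen=True)
class CycleAverage:
    """Mean cycle-locked waveform, its sample grid (s), and cycle count."""

    waveform: np.ndarray
    times: np.ndarray
    n_cycles: int
    period: float


def pv_scale(params: PartialVolumeParams) -> float:
    """Partial-volume scaling factor m for one voxel.

    Linear interpolation between the tissue and CSF reference intensities:

        m = T1W_voxel · (T1W_tiss / T1W_csf − 1) / (T1W_tiss − T1W_csf).

    Equals 1 for a pure-CSF voxel (T1W_voxel = T1W_csf) and scales signals
    up as the voxel intensity approaches tissue.
    """
    p = params
    return p.t1w_voxel * (p.t1w_tiss / p.t1w_csf - 1.0) / (p.t1w_tiss - p.t1w_csf)


def preprocess_fmri(
    ts: RoiTimeseries,
    trim: int = TRIM_SAMPLES,
    lowpass: bool = True,
) -> RoiTimeseries:
    """Standard inflow-signal preprocessing.

    Drops the first ``trim`` samples (initial transient of high signal),
    subtracts the mean of the lowest 10% of values (baseline near zero), and
    zero-phase low-pass filters (Butterworth order 5) below 0.5 Hz.
    ``lowpass=False`` skips the filter, as used for network input.
    """
    v = ts.values
    if v.size <= trim:
        raise ValueError(f"series too short ({v.size} <= trim {trim})")
    v = v[trim:]
    k = max(1, int(np.ceil(0.1 * v.size)))
    baseline = float(np.mean(np.sort(v)[:k]))
    v = v - baseline
    if lowpass:
        b, a = butter(LOWPASS_ORDER, LOWPASS_CUTOFF, btype="low", fs=ts.fs)
        v = filtfilt(b, a, v)
    return RoiTimeseries(values=v, tr=ts.tr, kind=ts.kind)


def phase_to_velocity(
    phase_roi: np.ndarray,
    stationary_roi: np.ndarray,
    venc: float,
) -> np.ndarray:
    """Convert phase-contrast phase (rad) to velocity (cm/s).

    The stationary-ROI phase is subtracted as the offset, then scaled by the
    velocity-encoding limit: v = VENC · Δφ / π (a phase of π maps to VENC).
    """
    phase_roi = np.asarray(phase_roi, dtype=float)
    stationary_roi = np.asarray(stationary_roi, dtype=float)
    if phase_roi.shape != stationary_roi.shape:
        raise ValueError("phase and stationary series must have equal length")
    return venc * (phase_roi - stationary_roi) / np.pi


def cycle_average(
    ts: RoiTimeseries,
    expected_period: float,
    prominence: float = 0.1,
    upsample: int = 4,
) -> CycleAverage:
    """Peak-locked cycle averaging of an oscillatory time series.

    The series is upsampled ×4 by linear interpolation, peaks are detected
    with a minimum separation of ``expected_period − 1`` s and the given
    prominence (0.1 on cm/s for velocity, on normalized units for inflow),
    and the inter-peak segments are resampled to a common length and
    averaged.
    """
    v = ts.values
    if v.size * ts.tr < 2 * expected_period:
        raise ValueError("need at least two expected periods of data")
    dt = ts.tr / upsample
    t_up = np.arange(v.size * upsample - (upsample - 1)) * dt
    t_orig = np.arange(v.size) * ts.tr
    v_up = np.interp(t_up, t_orig, v)

    min_sep = max(1, int(round((expected_period - 1.0) / dt)))
    peaks, _ = find_peaks(v_up, distance=min_sep, prominence=prominence)
    if peaks.size < 2:
        raise ValueError("fewer than two peaks detected; cannot cycle-average")

    n_out = max(2, int(round(expected_period / dt)))
    segs = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg = v_up[a:b + 1]
        grid = np.linspace(0.0, 1.0, n_out)
        segs.append(np.interp(grid, np.linspace(0.0, 1.0, seg.size), seg))
    mean_period = float(np.mean(np.diff(peaks)) * dt)
    return CycleAverage(
        waveform=np.mean(segs, axis=0),
        times=np.linspace(0.0, mean_period, n_out),
        n_cycles=len(segs),
        period=mean_period,
    )


def cycle_error(measured: CycleAverage, simulated: CycleAverage) -> float:
    """Mean absolute difference between two cycle-averaged traces.

    Both traces are resampled to a common length (phase grid 0..1) before
    differencing; symmetric in its arguments. Inputs are expected on the
    same normalization (top-5%-of-slice-1 convention).
    """
    n = max(measured.waveform.size, simulated.waveform.size)
    grid = np.linspace(0.0, 1.0, n)
    a = np.interp(grid, np.linspace(0, 1, measured.waveform.size), measured.waveform)
    b = np.interp(grid, np.linspace(0, 1, simulated.waveform.size), simulated.waveform)
    return float(np.mean(np.abs(a - b)))


def spectral_density(
    ts: RoiTimeseries, nperseg: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density.

    Density normalization: the PSD integrates (Σ psd·Δf) to the signal
    variance up to windowing effects.
    """
    v = ts.values
    if nperseg is None:
        nperseg = min(256, v.size)
    return welch(v - v.mean(), fs=ts.fs, nperseg=nperseg)


def power_law_fit(
    freqs: np.ndarray,
    psd: np.ndarray,
    fit_band: tuple[float, float],
) -> float:
    """Power-law exponent γ of psd ∝ f^γ over ``fit_band`` (log–log slope).

    γ is typically negative; a more negative exponent means stronger
    attenuation of high frequencies.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    sel = (freqs >= fit_band[0]) & (freqs <= fit_band[1]) & (freqs > 0)
    if np.count_nonzero(sel) < 2:
        raise ValueError("fit band contains fewer than two frequencies")
    if np.any(psd[sel] <= 0):
        raise ValueError("psd must be positive on the fit band")
    slope, _ = np.polyfit(np.log(freqs[sel]), np.log(psd[sel]), 1)
    return float(slope)


def area_from_labels(
    label_volume: np.ndarray,
    t1w_volume: np.ndarray,
    voxel_dims: tuple[float, float, float],
    axis: int = 2,
    label: int | bool = 1,
) -> AreaProfile:
    """Area–depth curve from a labeled anatomical volume.

    For each slice along ``axis``, every labeled voxel contributes its
    in-plane area scaled by T1W_ref / T1W_voxel, where T1W_ref is the slice
    minimum over labeled voxels (the most CSF-filled voxel); contributions
    are summed slicewise. Voxel dims are in cm. Slices without labeled
    voxels are skipped. Depth 0 is placed at the first labeled slice.
    """
    label_volume = np.asarray(label_volume)
    t1w = np.asarray(t1w_volume, dtype=float)
    if label_volume.shape != t1w.shape:
        raise ValueError("label and intensity volumes must be aligned")
    mask = label_volume == label if not np.issubdtype(
        label_volume.dtype, np.bool_
    ) else label_volume
    in_plane = np.prod([d for i, d in enumerate(voxel_dims) if i != axis])
    depth_step = voxel_dims[axis]

    mask = np.moveaxis(mask, axis, 0)
    t1w = np.moveaxis(t1w, axis, 0)
    depths, areas = [], []
    for k in range(mask.shape[0]):
        sel = mask[k]
        if not np.any(sel):
            continue
        vals = t1w[k][sel]
        ref = float(np.min(vals))
        areas.append(float(np.sum(in_plane * ref / vals)))
        depths.append(k * depth_step)
    if len(depths) < 2:
        raise ValueError("need labeled voxels in at least two slices")
    depths = np.asarray(depths) - depths[0]
    return AreaProfile(positions=depths, areas=np.asarray(areas))
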