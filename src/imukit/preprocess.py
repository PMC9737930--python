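"""Orientation-free 1-D reduction of tri-axial recordings.

Each modality (accelerometer, gyroscope) is projected onto its first
principal component, which removes the dependence on arbitrary sensor
orientation.  The recording is split at its temporal midpoint into a
'task' and a 'rest' half according to total gyroscope magnitude.  For the
AR-HMM observation sequence the two projections are additionally wavelet
denoised (Symlets-4, soft threshold 0.04) and downsampled by 10 (with
anti-alias filtering) to 12.8 Hz, then stacked into a (T', 2) array.

Everything in this module is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .errors import DegenerateSignalError, InvalidSizeError
from .recordings import IMURecording

DENOISE_WAVELET = "sym4"
DENOISE_THRESHOLD = 0.04
DOWNSAMPLE_FACTOR = 10


@dataclass
class ProjectedSignal:
    values: np.ndarray  # (T,)
    modality: str  # accel | gyro
    loading: np.ndarray  # unit 3-vector
    task_mask: np.ndarray | None = None  # (T,) bool, True on the task half


@dataclass
class ObservationSequence:
    """Denoised, downsampled 2-D observations (columns: accel-PC1, gyro-PC1)."""

    y: np.ndarray  # (T', 2)
    fs_hz: float = 12.8


def project_first_pc(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project a (T, 3) signal onto the first principal component.

    Returns the centered projection and the unit loading vector, with the
    sign convention that the loading's largest-magnitude component is
    positive.  Raises :class:`DegenerateSignalError` on constant input.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2 or signal.shape[1] != 3 or signal.shape[0] < 2:
        raise InvalidSizeError("signal must be (T, 3) with T >= 2")
    if not np.all(np.isfinite(signal)):
        raise InvalidSizeError("signal must be finite")
    centered = signal - signal.mean(axis=0)
    cov = centered.T @ centered / (signal.shape[0] - 1)
    if np.allclose(cov, 0.0):
        raise DegenerateSignalError("constant signal has no principal component")
    eigvals, eigvecs = np.linalg.eigh(cov)
    loading = eigvecs[:, -1]
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    return centered @ loading, loading


def split_task_rest(values: np.ndarray, gyro: np.ndarray) -> np.ndarray:
    """Label the midpoint-cut half with larger summed gyro magnitude as task.

    ``values`` fixes the output length; the decision uses the per-sample
    gyro vector norms.  Ties label the first half task.
    """
    values = np.asarray(values)
    T = len(values)
    if T < 2:
        raise InvalidSizeError("need at least 2 samples to split")
    norms = np.linalg.norm(np.asarray(gyro, dtype=float), axis=1)
    mid = T // 2
    first, second = norms[:mid].sum(), norms[mid:].sum()
    mask = np.zeros(T, dtype=bool)
    if first >= second:
        mask[:mid] = True
    else:
        mask[mid:] = True
    return mask


def denoise(values: np.ndarray, threshold: float = DENOISE_THRESHOLD,
            wavelet: str = DENOISE_WAVELET) -> np.ndarray:
    """Multilevel Symlets-4 soft-threshold denoising at a fixed absolute threshold.

    All detail coefficients are soft-thresholded at ``threshold``; the
    decomposition depth is the maximum the signal length permits
    (symmetric padding).  Output length equals input length.
    """
    values = np.asarray(values, dtype=float)
    w = pywt.Wavelet(wavelet)
    if len(values) < w.dec_len:
        raise InvalidSizeError(f"signal shorter than the {wavelet} filter ({w.dec_len})")
    level = pywt.dwt_max_level(len(values), w.dec_len)
    coeffs = pywt.wavedec(values, w, mode="symmetric", level=level)
    coeffs = [coeffs[0]] + [pywt.threshold(c, threshold, mode="soft") for c in coeffs[1:]]
    out = pywt.waverec(coeffs, w, mode="symmetric")
    return out[: len(values)]


def downsample(values: np.ndarray, factor: int = DOWNSAMPLE_FACTOR) -> np.ndarray:
    """Anti-alias low-pass then keep every ``factor``-th sample (zero-phase FIR)."""
    values = np.asarray(values, dtype=float)
    if factor < 1:
        raise InvalidSizeError("factor must be >= 1")
    if factor == 1:
        return values.copy()
    return sps.decimate(values, factor, ftype="fir", zero_phase=True)


def preprocess_session(
    recording: IMURecording,
    denoise_threshold: float = DENOISE_THRESHOLD,
    downsample_factor: int = DOWNSAMPLE_FACTOR,
) -> tuple[ProjectedSignal, ProjectedSignal, ObservationSequence]:
    """Full preprocessing of one recording.

    PCA is computed per modality on the full recording; the task/rest mask
    is derived once from the raw gyro magnitudes and shared by both
    modalities.  The observation sequence is the denoised, downsampled
    stack of (accel-PC1, gyro-PC1).
    """
    acc_values, acc_loading = project_first_pc(recording.accel)
    gyr_values, gyr_loading = project_first_pc(recording.gyro)
    mask = split_task_rest(gyr_values, recording.gyro)
    accel_proj = ProjectedSignal(acc_values, "accel", acc_loading, mask)
    gyro_proj = ProjectedSignal(gyr_values, "gyro", gyr_loading, mask)
    obs = np.column_stack(
        [
            downsample(denoise(acc_values, denoise_threshold), downsample_factor),
            downsample(denoise(gyr_values, denoise_threshold), downsample_factor),
        ]
    )
    return accel_proj, gyro_proj, ObservationSequence(obs, recording.fs_hz / downsample_factor)
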