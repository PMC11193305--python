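"""Pulse-wave preprocessing: denoise, segment, resample, normalize.

Raw multi-cycle recordings are converted into per-cycle waveforms on a
common representation: wavelet denoising of the whole record, foot-to-foot
cycle segmentation, linear resampling of each cycle to exactly 100 sample
points, and affine amplitude normalization of each cycle to the range
0-100. A subject qualifies downstream only if at least five valid cycles
survive this pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.signal import find_peaks, savgol_filter

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedCycle",
    "PreprocessingParams",
    "denoise",
    "segment_cycles",
    "resample_cycle",
    "normalize_amplitude",
    "validate_subject_cycles",
    "preprocess_recording",
    "preprocess_cohort",
    "cycles_to_frame",
    "frame_to_cycles",
    "N_SAMPLES",
    "MIN_VALID_CYCLES",
]

N_SAMPLES = 100          # samples per normalized cycle
AMPLITUDE_SPAN = 100.0   # normalized amplitude range [0, 100]
MIN_VALID_CYCLES = 5     # subject-level validity criterion


@dataclass
class PreprocessingParams:
    """Tunable preprocessing settings (conventional biosignal defaults)."""

    wavelet_name: str = "db4"
    level: int = 4
    min_cycle_seconds: float = 0.4     # minimum foot-to-foot interval
    smooth_seconds: float = 0.05       # Savitzky-Golay window for foot detection
    min_foot_prominence_frac: float = 0.25  # of signal range


@dataclass
class NormalizedCycle:
    """One pulse cycle on the common 100-point, 0-100 representation.

    ``amp_min``/``amp_max`` retain the cycle's pre-normalization amplitude
    extrema so the affine map can be inverted exactly (needed wherever the
    physical amplitude scale matters, e.g. harmonic powers).
    """

    subject_id: str
    cycle_index: int
    samples: np.ndarray
    valid: bool
    amp_min: float = 0.0
    amp_max: float = AMPLITUDE_SPAN

    def denormalized(self) -> np.ndarray:
        """Undo the 0-100 amplitude normalization."""
        scale = (self.amp_max - self.amp_min) / AMPLITUDE_SPAN
        return self.samples * scale + self.amp_min


def denoise(signal, level: int = 4, wavelet_name: str = "db4") -> np.ndarray:
    """Wavelet denoising by soft universal thresholding of detail coefficients.

    Noise scale is estimated from the finest-level detail coefficients via
    the median absolute deviation; the universal threshold
    sigma * sqrt(2 ln n) is applied softly to all detail levels. The
    approximation coefficients are untouched, so smooth signals pass
    through nearly unchanged and pure noise is strongly attenuated.
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if n < 2 ** level:
        raise ValueError(
            f"signal of length {n} too short for decomposition level {level}")
    coeffs = pywt.wavedec(signal, wavelet_name, level=level, mode="periodization")
    detail_fine = coeffs[-1]
    sigma = np.median(np.abs(detail_fine)) / 0.6745
    threshold = sigma * np.sqrt(2.0 * np.log(n))
    if threshold > 0:
        coeffs = [coeffs[0]] + [
            pywt.threshold(c, threshold, mode="soft") for c in coeffs[1:]
        ]
    out = pywt.waverec(coeffs, wavelet_name, mode="periodization")
    return out[:n]


def segment_cycles(signal, sampling_rate: float,
                   params: PreprocessingParams | None = None) -> list[tuple[int, int]]:
    """Foot-to-foot segmentation of a multi-cycle pulse signal.

    Cycle feet are prominent local minima of a lightly smoothed copy of
    the signal, at least ``min_cycle_seconds`` apart. Returns ordered,
    disjoint ``(start, end)`` index intervals covering foot-to-foot
    spans, including the leading and trailing spans bounded by the
    signal edges. A signal with no discernible pulse (near-constant)
    yields an empty list.
    """
    params = params or PreprocessingParams()
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if n < 4:
        return []
    rng_amp = np.ptp(signal)
    if rng_amp < 1e-9:
        logger.warning("segment_cycles: flat signal, no cycles detected")
        return []

    window = max(5, int(round(params.smooth_seconds * sampling_rate)) | 1)
    if window < n:
        smoothed = savgol_filter(signal, window, polyorder=2)
    else:
        smoothed = signal

    distance = max(1, int(round(params.min_cycle_seconds * sampling_rate)))
    feet, _ = find_peaks(
        -smoothed,
        distance=distance,
        prominence=params.min_foot_prominence_frac * rng_amp,
    )
    boundaries = [0] + [int(f) for f in feet if 0 < f < n - 1] + [n]
    boundaries = sorted(set(boundaries))
    intervals = [
        (boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)
    ]
    return intervals


def resample_cycle(cycle) -> np.ndarray:
    """Linearly resample one cycle to exactly 100 points.

    The cycle is treated as one period: interpolation is over the
    normalized phase axis [0, 1), excluding the right endpoint (which
    periodically equals the left foot), so harmonic content is preserved
    under the common one-period Fourier convention. The first sample is
    preserved exactly, linear and monotone segments remain so, and a
    100-point input is returned unchanged.
    """
    cycle = np.asarray(cycle, dtype=float)
    n = len(cycle)
    if n < 4:
        raise ValueError("cycle too short to resample (need >= 4 samples)")
    # periodic extension closes the cycle for the final sub-interval
    src = np.arange(n + 1, dtype=float)
    ext = np.concatenate([cycle, cycle[:1]])
    dst = np.linspace(0.0, n, N_SAMPLES, endpoint=False)
    return np.interp(dst, src, ext)


def normalize_amplitude(cycle, subject_id: str = "",
                        cycle_index: int = 0) -> NormalizedCycle:
    """Affinely map a 100-point cycle onto the amplitude range [0, 100].

    A constant cycle has no defined normalization and is marked invalid.
    """
    cycle = np.asarray(cycle, dtype=float)
    if len(cycle) != N_SAMPLES:
        raise ValueError(f"expected {N_SAMPLES}-point cycle, got {len(cycle)}")
    lo, hi = float(cycle.min()), float(cycle.max())
    if not np.isfinite([lo, hi]).all() or hi - lo < 1e-12:
        return NormalizedCycle(subject_id, cycle_index, cycle.copy(), valid=False,
                               amp_min=lo, amp_max=hi)
    samples = (cycle - lo) * (AMPLITUDE_SPAN / (hi - lo))
    return NormalizedCycle(subject_id, cycle_index, samples, valid=True,
                           amp_min=lo, amp_max=hi)


def validate_subject_cycles(cycles) -> tuple[list[NormalizedCycle], bool]:
    """Keep valid cycles; the subject passes iff at least five remain."""
    valid = [c for c in cycles if c.valid]
    return valid, len(valid) >= MIN_VALID_CYCLES


def preprocess_recording(recording, params: PreprocessingParams | None = None,
                         apply_denoise: bool = True) -> list[NormalizedCycle]:
    """Full preprocessing of one recording into normalized cycles."""
    params = params or PreprocessingParams()
    signal = np.asarray(recording.signal, dtype=float)
    if apply_denoise and len(signal) >= 2 ** params.level:
        signal = denoise(signal, level=params.level,
                         wavelet_name=params.wavelet_name)
    intervals = segment_cycles(signal, recording.sampling_rate, params)
    cycles: list[NormalizedCycle] = []
    for i, (start, end) in enumerate(intervals):
        segment = signal[start:end]
        if len(segment) < 4:
            cycles.append(NormalizedCycle(recording.subject_id, i,
                                          np.full(N_SAMPLES, np.nan), valid=False))
            continue
        resampled = resample_cycle(segment)
        cycles.append(normalize_amplitude(resampled, recording.subject_id, i))
    return cycles


def preprocess_cohort(recordings: dict,
                      params: PreprocessingParams | None = None) -> dict:
    """Preprocess every recording; returns subject_id -> list of cycles."""
    return {
        sid: preprocess_recording(rec, params)
        for sid, rec in recordings.items()
    }


def cycles_to_frame(cycles_by_subject: dict) -> pd.DataFrame:
    """Wide CSV layout: subject_id, cycle_index, valid, amp_min, amp_max, s0..s99."""
    rows = []
    for sid in sorted(cycles_by_subject):
        for c in cycles_by_subject[sid]:
            row = {"subject_id": c.subject_id, "cycle_index": c.cycle_index,
                   "valid": c.valid, "amp_min": c.amp_min, "amp_max": c.amp_max}
            row.update({f"s{i}": v for i, v in enumerate(c.samples)})
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cycles(df: pd.DataFrame) -> dict:
    sample_cols = [f"s{i}" for i in range(N_SAMPLES)]
    out: dict[str, list[NormalizedCycle]] = {}
    for _, row in df.iterrows():
        cyc = NormalizedCycle(
            subject_id=str(row["subject_id"]),
            cycle_index=int(row["cycle_index"]),
            samples=row[sample_cols].to_numpy(dtype=float),
            valid=bool(row["valid"]),
            amp_min=float(row["amp_min"]),
            amp_max=float(row["amp_max"]),
        )
        out.setdefault(cyc.subject_id, []).append(cyc)
    return out
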