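"""Fetal R-peak detection on the extracted fECG by continuous wavelet transform.

The detector aggregates |CWT| magnitude over Ricker (Mexican-hat) scales
spanning the fetal QRS energy band (10-30 Hz by default), thresholds it
against a rolling median (so the threshold adapts to amplitude drift and
the whole detector is invariant to positive rescaling of the signal),
enforces a physiological refractory period, and refines each detection
to the extremum of |fECG| in a small neighbourhood. Polarity of the
input is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import find_peaks

from .errors import ValidationError
from .signal_io import AnnotationSet


@dataclass
class DetectorConfig:
    """CWT band, threshold and timing parameters of the fQRS detector."""

    wavelet: str = "mexh"
    band_low_hz: float = 10.0
    band_high_hz: float = 30.0
    n_scales: int = 8
    threshold_k: float = 3.0
    refractory_ms: float = 250.0
    rolling_window_s: float = 2.0
    refine_ms: float = 20.0

    def __post_init__(self):
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValidationError("need 0 < band_low_hz < band_high_hz")
        if self.refractory_ms <= 0:
            raise ValidationError("refractory_ms must be positive")
        if self.threshold_k <= 0:
            raise ValidationError("threshold_k must be positive")


def _cwt_magnitude(x: np.ndarray, fs: float, config: DetectorConfig) -> np.ndarray:
    """Mean |CWT| over scales mapped to the configured frequency band."""
    freqs = np.geomspace(config.band_low_hz, config.band_high_hz, config.n_scales)
    # pywt: frequency2scale expects normalized frequency (cycles/sample)
    scales = pywt.frequency2scale(config.wavelet, freqs / fs)
    coef, _ = pywt.cwt(x, scales, config.wavelet)
    return np.abs(coef).mean(axis=0)


def _rolling_median(mag: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Rolling median of the magnitude, evaluated on a coarse grid and
    linearly interpolated (the threshold needs to follow slow amplitude
    drift, not beat-scale detail)."""
    n = len(mag)
    step = max(1, int(round(0.25 * fs)))
    half = int(round(window_s * fs / 2))
    centers = np.arange(0, n, step)
    med = np.empty(len(centers))
    for i, c in enumerate(centers):
        lo, hi = max(0, c - half), min(n, c + half + 1)
        med[i] = np.median(mag[lo:hi])
    return np.interp(np.arange(n), centers, med)


def detect_fqrs(fecg_est: np.ndarray, fs: float,
                config: DetectorConfig | None = None) -> AnnotationSet:
    """Detect fetal R peaks in an extracted fECG signal.

    Pipeline: (1) |CWT| magnitude aggregated over the configured scales;
    (2) adaptive threshold = k * rolling median of the magnitude;
    (3) candidate local maxima above threshold; (4) refractory
    suppression keeping the larger peak; (5) refinement to the extremum
    of |fecg_est| within +-refine_ms.

    Returns an :class:`AnnotationSet` labelled ``detected``.
    """
    config = config or DetectorConfig()
    x = np.asarray(fecg_est, dtype=float).ravel()
    if fs <= 2 * config.band_high_hz:
        raise ValidationError(
            f"fs={fs} Hz too low for detection band up to {config.band_high_hz} Hz")
    if len(x) < 2 * int(config.rolling_window_s * fs):
        raise ValidationError(
            "signal shorter than twice the rolling threshold window")
    if not np.any(x):
        return AnnotationSet(np.empty(0, dtype=np.int64), fs=fs, label="detected")

    mag = _cwt_magnitude(x, fs, config)
    thr = config.threshold_k * _rolling_median(mag, fs, config.rolling_window_s)
    refractory = int(round(config.refractory_ms * fs / 1000.0))
    cand, _ = find_peaks(mag, height=thr)
    if cand.size == 0:
        return AnnotationSet(np.empty(0, dtype=np.int64), fs=fs, label="detected")

    # refractory suppression, larger CWT magnitude wins
    order = cand[np.argsort(mag[cand])[::-1]]
    keep: list[int] = []
    taken = np.zeros(len(x), dtype=np.bool_)
    for p in order:
        lo, hi = max(0, p - refractory), min(len(x), p + refractory + 1)
        if not taken[lo:hi].any():
            keep.append(p)
            taken[p] = True
    keep.sort()

    # refine to the |signal| extremum near the CWT peak
    refine = int(round(config.refine_ms * fs / 1000.0))
    refined = []
    for p in keep:
        lo, hi = max(0, p - refine), min(len(x), p + refine + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    refined = np.unique(np.asarray(refined, dtype=np.int64))

    # refinement may pull two candidates together; re-apply refractory
    if refined.size > 1:
        final = [int(refined[0])]
        for p in refined[1:]:
            if p - final[-1] >= refractory:
                final.append(int(p))
            elif np.abs(x[p]) > np.abs(x[final[-1]]):
                final[-1] = int(p)
        refined = np.asarray(final, dtype=np.int64)
    return AnnotationSet(refined, fs=fs, label="detected")
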