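"""Band-limiting of abdominal channels ahead of source separation.

A 3-150 Hz band captures the QRS energy of both maternal and fetal
complexes while removing isoline (baseline) drift. The filter is a
Butterworth bandpass applied forward-backward (zero phase), so R-peak
timing -- which the beat-matching evaluation depends on -- is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .signal_io import MultichannelRecord

import logging

logger = logging.getLogger(__name__)


@dataclass
class BandpassSpec:
    """Bandpass corners in Hz, Butterworth order per edge, phase handling."""

    low_hz: float = 3.0
    high_hz: float = 150.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ValidationError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")


def bandpass(record: MultichannelRecord, spec: BandpassSpec | None = None
             ) -> MultichannelRecord:
    """Apply the bandpass per channel; shape, fs and labels are unchanged.

    For low sampling rates (fs <= 300 Hz) the upper corner is clamped to
    0.45*fs with a logged warning so the design stays below Nyquist.
    """
    spec = spec or BandpassSpec()
    fs = record.fs
    if fs <= 2 * spec.low_hz:
        raise ValidationError(
            f"fs={fs} Hz leaves no passband above low corner {spec.low_hz} Hz")
    high = spec.high_hz
    if fs <= 300 and high >= 0.45 * fs:
        high = 0.45 * fs
        logger.warning("upper corner clamped to %.1f Hz for fs=%.0f Hz", high, fs)
    if high >= fs / 2:
        high = 0.45 * fs
        logger.warning("upper corner clamped to %.1f Hz for fs=%.0f Hz", high, fs)
    sos = sps.butter(spec.order, [spec.low_hz, high], btype="bandpass",
                     fs=fs, output="sos")
    out = np.empty_like(record.samples)
    # Reflect padding suppresses startup transients on 1-minute windows.
    padlen = min(record.n_samples - 1, 3 * (spec.order * 2 + 1))
    for c in range(record.n_channels):
        x = record.samples[:, c]
        if spec.zero_phase:
            out[:, c] = sps.sosfiltfilt(x=x, sos=sos, padtype="even", padlen=padlen)
        else:
            out[:, c] = sps.sosfilt(sos, x)
    return MultichannelRecord(out, fs=fs, channel_names=list(record.channel_names),
                              record_id=record.record_id)
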