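"""End-to-end hybrid extraction: bandpass -> ICA -> adaptive -> detection.

The hybrid system takes the multichannel abdominal recording, band-limits
it, separates it with ICA into maternal (mECG*), fetal-enhanced (aECG*)
and noise components, cancels the residual maternal content of aECG*
adaptively with mECG* as the reference, and detects fetal R peaks on the
resulting fECG_est. When reference annotations are available the
detections are scored (Se/PPV/F1 over 1-minute windows).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .adaptive import AdaptiveConfig, FilterRun, run_adaptive
from .detect import DetectorConfig, detect_fqrs
from .errors import FecgError
from .evaluation import windowed_counts
from .ica import ChannelSubset, assign_roles, separate
from .preprocess import BandpassSpec, bandpass
from .signal_io import AnnotationSet, EvaluationReport, MultichannelRecord

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Aggregated stage configuration; JSON-serializable and round-trip
    byte-stable."""

    preprocess: BandpassSpec = field(default_factory=BandpassSpec)
    adaptive: AdaptiveConfig = field(default_factory=AdaptiveConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    ica_seed: int = 0
    ica_max_iter: int = 500
    ica_tol: float = 1e-5
    maternal_band_bpm: tuple[float, float] = (40.0, 120.0)
    fetal_band_bpm: tuple[float, float] = (100.0, 200.0)
    tolerance_ms: float = 50.0
    window_s: float = 60.0

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        d["maternal_band_bpm"] = list(d["maternal_band_bpm"])
        d["fetal_band_bpm"] = list(d["fetal_band_bpm"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            preprocess=BandpassSpec(**d.get("preprocess", {})),
            adaptive=AdaptiveConfig(**d.get("adaptive", {})),
            detector=DetectorConfig(**d.get("detector", {})),
            ica_seed=d.get("ica_seed", 0),
            ica_max_iter=d.get("ica_max_iter", 500),
            ica_tol=d.get("ica_tol", 1e-5),
            maternal_band_bpm=tuple(d.get("maternal_band_bpm", (40.0, 120.0))),
            fetal_band_bpm=tuple(d.get("fetal_band_bpm", (100.0, 200.0))),
            tolerance_ms=d.get("tolerance_ms", 50.0),
            window_s=d.get("window_s", 60.0),
        )

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True)
                              + "\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


class StageError(FecgError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def run_extraction(record: MultichannelRecord,
                   subset: ChannelSubset | None = None,
                   config: PipelineConfig | None = None,
                   reference: AnnotationSet | None = None
                   ) -> tuple[FilterRun, AnnotationSet, EvaluationReport | None]:
    """Run the full hybrid pipeline on one recording.

    Returns ``(filter_run, detections, report)``; the report is None when
    no reference annotations are given. Stage failures are re-raised as
    :class:`StageError` carrying the stage name.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    try:
        filtered = bandpass(record, config.preprocess)
    except Exception as exc:
        raise StageError("preprocess", exc) from exc
    try:
        outputs = separate(filtered, subset, seed=config.ica_seed,
                           max_iter=config.ica_max_iter, tol=config.ica_tol)
        outputs = assign_roles(outputs, filtered.fs,
                               maternal_band_bpm=config.maternal_band_bpm,
                               fetal_band_bpm=config.fetal_band_bpm)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("ica", exc) from exc
    try:
        run = run_adaptive(config.adaptive, primary=outputs.aecg,
                           reference=outputs.mecg)
    except Exception as exc:
        raise StageError("adaptive", exc) from exc
    try:
        detections = detect_fqrs(run.fecg_est, filtered.fs, config.detector)
    except Exception as exc:
        raise StageError("detect", exc) from exc
    report = None
    if reference is not None:
        report = windowed_counts(detections, reference, fs=filtered.fs,
                                 window_s=config.window_s,
                                 tolerance_ms=config.tolerance_ms,
                                 parameters={"algorithm": config.adaptive.algorithm},
                                 record_id=record.record_id)
    logger.info("extraction of %s (%s, %d ch) took %.2f s",
                record.record_id, config.adaptive.algorithm,
                record.n_channels, time.perf_counter() - t0)
    return run, detections, report
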