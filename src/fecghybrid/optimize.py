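"""Grid-search optimization of adaptive control parameters on F1.

For a given adaptive algorithm, every (axis1, axis2) cell of a parameter
grid -- step size mu / forgetting factor lambda / learning rate eta
against filter length M / input space p -- is evaluated by running the
adaptive cancellation, detecting fetal R peaks on the error signal and
scoring F1 against the reference beats over 1-minute windows. The
resulting surface is the 3-D optimization graph whose global maximum
defines the recommended setting; plateaus of equal maxima are reported
as tie sets (parameter intervals).

Declared parameter ranges: mu in (0, 0.1] and M in [1, 100] for the LMS
family; lambda in [0.9, 1] and M in [1, 100] for RLS/FTF; eta in
(0, 0.1] and p in [1, 100] for ADALINE. Cells where the filter diverges
(notably FTF instability) are recorded as failed, excluded from the
optimum and logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .adaptive import AdaptiveConfig, run_adaptive
from .detect import DetectorConfig, detect_fqrs
from .errors import DivergenceError, InstabilityError, ValidationError
from .evaluation import windowed_counts
from .signal_io import AnnotationSet

logger = logging.getLogger(__name__)

_RANGES = {
    "lms": {"axis1": ("mu", 0.0, 0.1), "axis2": ("M", 1, 100)},
    "selms": {"axis1": ("mu", 0.0, 0.1), "axis2": ("M", 1, 100)},
    "rls": {"axis1": ("lam", 0.9, 1.0), "axis2": ("M", 1, 100)},
    "ftf": {"axis1": ("lam", 0.9, 1.0), "axis2": ("M", 1, 100)},
    "adaline": {"axis1": ("eta", 0.0, 0.1), "axis2": ("p", 1, 100)},
}


@dataclass
class ParamGrid:
    """Axis definitions of one optimization surface."""

    algorithm: str
    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray

    def __post_init__(self):
        if self.algorithm not in _RANGES:
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        spec = _RANGES[self.algorithm]
        if self.axis1_name != spec["axis1"][0] or self.axis2_name != spec["axis2"][0]:
            raise ValidationError(
                f"{self.algorithm} expects axes {spec['axis1'][0]}/{spec['axis2'][0]}")
        self.axis1_values = np.asarray(self.axis1_values, dtype=float)
        self.axis2_values = np.asarray(self.axis2_values, dtype=int)
        _, lo1, hi1 = spec["axis1"]
        _, lo2, hi2 = spec["axis2"]
        if np.any(self.axis1_values <= lo1) or np.any(self.axis1_values > hi1):
            raise ValidationError(
                f"{self.axis1_name} values must lie in ({lo1}, {hi1}]")
        if np.any(self.axis2_values < lo2) or np.any(self.axis2_values > hi2):
            raise ValidationError(
                f"{self.axis2_name} values must lie in [{lo2}, {hi2}]")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.axis1_values), len(self.axis2_values)


def default_grid(algorithm: str, fine: bool = False) -> ParamGrid:
    """Desk-scale default grid; ``fine=True`` uses step 1 on M and a dense
    first axis for interval-style optimum reporting."""
    spec = _RANGES[algorithm]
    a1, a2 = spec["axis1"][0], spec["axis2"][0]
    if a1 in ("mu", "eta"):
        ax1 = (np.round(np.arange(0.001, 0.1005, 0.001), 6) if fine
               else np.geomspace(1e-3, 0.1, 25))
    else:  # lambda
        ax1 = (np.round(np.arange(0.98, 1.0005, 0.0005), 6) if fine
               else np.linspace(0.98, 1.0, 21))
    ax2 = (np.arange(1, 101) if fine
           else np.concatenate([[1], np.arange(5, 101, 5)]))
    return ParamGrid(algorithm, a1, ax1, a2, ax2)


@dataclass
class OptimizationSurface:
    """F1 (percent) per grid cell, with counts and failure flags."""

    grid: ParamGrid
    f1: np.ndarray            # [len(axis1) x len(axis2)], NaN where failed
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    failed: np.ndarray        # bool mask
    record_id: str = ""

    def cell_params(self, i: int, j: int) -> dict:
        return {self.grid.axis1_name: float(self.grid.axis1_values[i]),
                self.grid.axis2_name: int(self.grid.axis2_values[j])}


@dataclass
class Optimum:
    """Global maximum of a surface with its plateau (tie set)."""

    params: dict
    f1: float
    ties: list[dict] = field(default_factory=list)


def _adaptive_config(algorithm: str, axis1: float, axis2: int) -> AdaptiveConfig:
    kw = {"algorithm": algorithm}
    if algorithm in ("lms", "selms"):
        kw.update(mu=float(axis1), M=int(axis2))
    elif algorithm in ("rls", "ftf"):
        kw.update(lam=float(axis1), M=int(axis2))
    else:
        kw.update(eta=float(axis1), p=int(axis2))
    return AdaptiveConfig(**kw)


def evaluate_cell(algorithm: str, axis1: float, axis2: int,
                  primary: np.ndarray, reference_signal: np.ndarray,
                  reference_annotations: AnnotationSet, fs: float,
                  detector: DetectorConfig | None = None,
                  window_s: float = 60.0):
    """Run adaptive cancellation + detection + scoring for one cell.

    Returns ``(f1_percent_or_None, EvaluationReport_or_None)``; a
    divergent/unstable run yields ``(None, None)`` rather than raising.
    """
    cfg = _adaptive_config(algorithm, axis1, axis2)
    try:
        run = run_adaptive(cfg, primary, reference_signal)
    except (DivergenceError, InstabilityError) as exc:
        logger.info("cell %s=%g %s failed: %s", algorithm, axis1, type(exc).__name__, exc)
        return None, None
    detections = detect_fqrs(run.fecg_est, fs, detector)
    report = windowed_counts(detections, reference_annotations, fs=fs,
                             window_s=window_s)
    return report.f1, report


def grid_search(grid: ParamGrid, primary: np.ndarray,
                reference_signal: np.ndarray,
                reference_annotations: AnnotationSet, fs: float,
                detector: DetectorConfig | None = None,
                window_s: float = 60.0,
                checkpoint: str | Path | None = None,
                record_id: str = "") -> OptimizationSurface:
    """Evaluate every grid cell (row-major); deterministic and resumable.

    With ``checkpoint`` set, partial results are written after each row
    and a restarted search resumes from them, yielding a surface
    identical to a fresh run.
    """
    n1, n2 = grid.shape
    f1s = np.full((n1, n2), np.nan)
    tps = np.zeros((n1, n2), dtype=np.int64)
    fps = np.zeros((n1, n2), dtype=np.int64)
    fns = np.zeros((n1, n2), dtype=np.int64)
    failed = np.zeros((n1, n2), dtype=bool)
    done_rows = 0
    ckpt = Path(checkpoint) if checkpoint is not None else None
    if ckpt is not None and ckpt.exists():
        state = json.loads(ckpt.read_text())
        if state.get("shape") == [n1, n2]:
            done_rows = state["done_rows"]
            f1s[:done_rows] = np.asarray(state["f1"])[:done_rows]
            tps[:done_rows] = np.asarray(state["tp"])[:done_rows]
            fps[:done_rows] = np.asarray(state["fp"])[:done_rows]
            fns[:done_rows] = np.asarray(state["fn"])[:done_rows]
            failed[:done_rows] = np.asarray(state["failed"])[:done_rows]
            logger.info("resuming grid search at row %d/%d", done_rows, n1)
    for i in range(done_rows, n1):
        for j in range(n2):
            f1v, report = evaluate_cell(
                grid.algorithm, grid.axis1_values[i], grid.axis2_values[j],
                primary, reference_signal, reference_annotations, fs,
                detector=detector, window_s=window_s)
            if report is None:
                failed[i, j] = True
            else:
                f1s[i, j] = np.nan if f1v is None else f1v
                tps[i, j], fps[i, j], fns[i, j] = report.tp, report.fp, report.fn
        if ckpt is not None:
            ckpt.write_text(json.dumps({
                "shape": [n1, n2], "done_rows": i + 1,
                "f1": np.where(np.isnan(f1s), None, f1s).tolist(),
                "tp": tps.tolist(), "fp": fps.tolist(), "fn": fns.tolist(),
                "failed": failed.tolist(),
            }))
    return OptimizationSurface(grid, f1s, tps, fps, fns, failed, record_id)


def find_optimum(surface: OptimizationSurface, tie_tol: float = 1e-9) -> Optimum:
    """Global maximum over non-failed cells, with its plateau.

    Ties (F1 within ``tie_tol``) are all reported; the canonical
    representative has the smallest filter length, then the most stable
    first-axis value (smallest mu/eta; largest lambda).
    """
    f1s = surface.f1
    valid = ~np.isnan(f1s)
    if not valid.any():
        raise ValidationError("all grid cells failed; no optimum exists")
    best = np.nanmax(f1s)
    ties_idx = np.argwhere(valid & (f1s >= best - tie_tol))
    ties = [surface.cell_params(i, j) for i, j in ties_idx]
    a1 = surface.grid.axis1_name
    prefer_large_axis1 = a1 == "lam"

    def key(idx):
        i, j = idx
        v1 = surface.grid.axis1_values[i]
        return (surface.grid.axis2_values[j],
                -v1 if prefer_large_axis1 else v1)

    ci, cj = min(map(tuple, ties_idx), key=key)
    return Optimum(params=surface.cell_params(ci, cj), f1=float(best), ties=ties)


def export_surface(surface: OptimizationSurface, path: str | Path,
                   figure: str | Path | None = None) -> None:
    """Write a surface to JSON; optionally render a heatmap figure."""
    path = Path(path)
    payload = {
        "algorithm": surface.grid.algorithm,
        "record_id": surface.record_id,
        "axis1_name": surface.grid.axis1_name,
        "axis1_values": surface.grid.axis1_values.tolist(),
        "axis2_name": surface.grid.axis2_name,
        "axis2_values": surface.grid.axis2_values.tolist(),
        "f1": np.where(np.isnan(surface.f1), None, surface.f1).tolist(),
        "tp": surface.tp.tolist(),
        "fp": surface.fp.tolist(),
        "fn": surface.fn.tolist(),
        "failed": surface.failed.tolist(),
    }
    path.write_text(json.dumps(payload, indent=2))
    if figure is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4.5))
        im = ax.pcolormesh(surface.grid.axis2_values, surface.grid.axis1_values,
                           surface.f1, shading="nearest", cmap="jet")
        fig.colorbar(im, ax=ax, label="F1 (%)")
        ax.set_xlabel(surface.grid.axis2_name)
        ax.set_ylabel(surface.grid.axis1_name)
        ax.set_title(f"{surface.grid.algorithm} optimization surface "
                     f"{surface.record_id}".strip())
        fig.tight_layout()
        fig.savefig(figure, dpi=120)
        plt.close(fig)


def import_surface(path: str | Path) -> OptimizationSurface:
    """Read a surface previously written by :func:`export_surface`."""
    d = json.loads(Path(path).read_text())
    grid = ParamGrid(d["algorithm"], d["axis1_name"],
                     np.asarray(d["axis1_values"]),
                     d["axis2_name"], np.asarray(d["axis2_values"]))
    f1s = np.asarray([[np.nan if v is None else v for v in row]
                      for row in d["f1"]], dtype=float)
    return OptimizationSurface(
        grid, f1s,
        np.asarray(d["tp"], dtype=np.int64),
        np.asarray(d["fp"], dtype=np.int64),
        np.asarray(d["fn"], dtype=np.int64),
        np.asarray(d["failed"], dtype=bool),
        d.get("record_id", ""),
    )
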