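"""Non-adaptive block: ICA separation of abdominal channels.

FastICA (tanh/log-cosh contrast, PCA whitening, seeded deterministic
initialization) splits the preprocessed abdominal channels into
statistically independent components. A periodicity heuristic then
assigns physiological roles:

* ``mECG*`` -- the estimated maternal component, used as the adaptive
  block's reference input;
* ``aECG*`` -- the fetal-enhanced abdominal component, used as the
  adaptive block's primary input;
* ``noise`` -- everything else.

The role heuristic rates each component by the prominence of its
autocorrelation peak (periodicity score) and by the beat rate implied by
the fundamental autocorrelation lag; components are classified against
declared maternal (40-120 bpm) and fetal (100-200 bpm) bands.

The module also hosts the electrode-combination search: with n abdominal
electrodes, every subset of size >= 2 (2^n - n - 1 subsets; 57 for n=6)
can enter the ICA, and ``best_subset`` picks the one maximizing the
downstream F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.decomposition import FastICA

from .errors import ConvergenceError, RoleAssignmentError, ValidationError
from .signal_io import MultichannelRecord

MATERNAL_BAND_BPM = (40.0, 120.0)
FETAL_BAND_BPM = (100.0, 200.0)

# Local autocorrelation maxima within this fraction of the global best are
# period candidates; the shortest such lag is the fundamental.
_FUNDAMENTAL_TOL = 0.85


@dataclass(frozen=True)
class ChannelSubset:
    """Sorted unique channel indices entering the ICA (size >= 2)."""

    indices: tuple[int, ...]

    def __post_init__(self):
        idx = tuple(sorted(set(self.indices)))
        if len(idx) < 2:
            raise ValidationError("channel subset must contain at least 2 channels")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


@dataclass
class ICAOutputs:
    """Separated components with role assignment and per-component diagnostics."""

    components: np.ndarray          # [n_samples x k], unit variance
    unmixing: np.ndarray            # [k x k] after whitening
    roles: dict[int, str] = field(default_factory=dict)
    rate_bpm: list[float] = field(default_factory=list)
    periodicity: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.components.shape[1]

    def _only(self, role: str) -> np.ndarray:
        idx = [i for i, r in self.roles.items() if r == role]
        if len(idx) != 1:
            raise RoleAssignmentError(f"expected exactly one {role} component")
        return self.components[:, idx[0]]

    @property
    def mecg(self) -> np.ndarray:
        return self._only("mECG*")

    @property
    def aecg(self) -> np.ndarray:
        return self._only("aECG*")


def select_channel_subsets(n_channels: int, min_size: int = 2) -> list[ChannelSubset]:
    """All channel subsets of size >= min_size, ordered by size then lexicographic.

    For ``min_size=2`` the count is ``2**n - n - 1`` (57 for six electrodes).
    """
    if n_channels < min_size:
        raise ValidationError(
            f"need at least {min_size} channels, got {n_channels}")
    out = []
    for size in range(min_size, n_channels + 1):
        for combo in combinations(range(n_channels), size):
            out.append(ChannelSubset(combo))
    return out


def separate(record: MultichannelRecord, subset: ChannelSubset | None = None,
             seed: int = 0, max_iter: int = 500, tol: float = 1e-5) -> ICAOutputs:
    """FastICA separation of the (preprocessed) record channels.

    Components are normalized to unit variance and their polarity flipped
    so the largest-magnitude extremum is positive. Deterministic for a
    fixed seed. Raises :class:`ConvergenceError` if FastICA does not
    converge and :class:`ValidationError` on rank-deficient input.
    """
    X = record.samples if subset is None else record.samples[:, list(subset)]
    k = X.shape[1]
    if k < 2:
        raise ValidationError("ICA needs at least 2 channels")
    Xc = X - X.mean(axis=0)
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise ValidationError("rank-deficient input: channels are linearly dependent")
    ica = FastICA(n_components=k, fun="logcosh", whiten="unit-variance",
                  max_iter=max_iter, tol=tol, random_state=seed)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("error", category=UserWarning)
        try:
            S = ica.fit_transform(X)
        except UserWarning as exc:
            raise ConvergenceError(
                f"FastICA did not converge within {max_iter} iterations",
                n_iter=max_iter) from exc
    # Unit variance + canonical polarity (largest |extremum| positive).
    S = S - S.mean(axis=0)
    S /= S.std(axis=0)
    W = ica.components_.copy()
    for j in range(k):
        col = S[:, j]
        if abs(col.min()) > abs(col.max()):
            S[:, j] = -col
            W[j, :] = -W[j, :]
    return ICAOutputs(components=S, unmixing=W)


def _fundamental_lag(x: np.ndarray, fs: float,
                     bpm_range: tuple[float, float] = (40.0, 220.0)
                     ) -> tuple[float, float]:
    """(rate_bpm, periodicity score) from the autocorrelation of x**2.

    The score is the normalized autocorrelation at the fundamental lag;
    harmonic ambiguity (lag multiples) is resolved by taking the shortest
    local-maximum lag whose value is within _FUNDAMENTAL_TOL of the best.
    """
    e = x * x
    e = e - e.mean()
    n = len(e)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(e, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    if ac[0] <= 0:
        return 0.0, 0.0
    ac = ac / ac[0]
    lag_min = int(np.floor(60.0 * fs / bpm_range[1]))
    lag_max = int(np.ceil(60.0 * fs / bpm_range[0]))
    lag_max = min(lag_max, n - 2)
    if lag_min < 1 or lag_min >= lag_max:
        return 0.0, 0.0
    seg = ac[lag_min:lag_max + 1]
    best = float(seg.max())
    if best <= 0:
        return 0.0, 0.0
    # Local maxima of the windowed autocorrelation.
    interior = (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])
    cand = np.where(interior & (seg[1:-1] >= _FUNDAMENTAL_TOL * best))[0] + 1
    if cand.size == 0:
        lag = lag_min + int(np.argmax(seg))
        return 60.0 * fs / lag, best
    lag = lag_min + int(cand[0])
    return 60.0 * fs / lag, float(seg[cand[0]])


def assign_roles(outputs: ICAOutputs, fs: float,
                 maternal_band_bpm: tuple[float, float] = MATERNAL_BAND_BPM,
                 fetal_band_bpm: tuple[float, float] = FETAL_BAND_BPM,
                 min_periodicity: float = 0.1) -> ICAOutputs:
    """Label components as mECG*, aECG* or noise (in place; returns outputs).

    mECG* is the most periodic component whose dominant rate falls in the
    maternal band; aECG* is the remaining component most periodic in the
    fetal band, falling back to the strongest residual periodicity. Ties
    break toward the lower component index. Invariant under component
    permutation and sign flips.
    """
    k = outputs.k
    rates, scores = [], []
    for j in range(k):
        r, s = _fundamental_lag(outputs.components[:, j], fs)
        rates.append(r)
        scores.append(s)
    outputs.rate_bpm = rates
    outputs.periodicity = scores

    def in_band(r, band):
        return band[0] <= r <= band[1]

    maternal_cands = [j for j in range(k)
                      if in_band(rates[j], maternal_band_bpm)
                      and scores[j] >= min_periodicity]
    if not maternal_cands:
        raise RoleAssignmentError(
            "no component shows maternal-band periodicity; try a different "
            "channel subset")
    # argmax score, ties -> lower index (max with key is stable that way)
    m_idx = max(maternal_cands, key=lambda j: (scores[j], -j))
    rest = [j for j in range(k) if j != m_idx]
    fetal_cands = [j for j in rest
                   if in_band(rates[j], fetal_band_bpm) and scores[j] >= min_periodicity]
    pool = fetal_cands if fetal_cands else rest
    a_idx = max(pool, key=lambda j: (scores[j], -j))
    outputs.roles = {j: "noise" for j in range(k)}
    outputs.roles[m_idx] = "mECG*"
    outputs.roles[a_idx] = "aECG*"
    return outputs


def best_subset(record: MultichannelRecord, annotations_ref, config=None,
                min_size: int = 2):
    """Run the full pipeline for every channel subset; return the winner.

    Returns ``(subset, f1_percent)`` maximizing aggregate F1 against the
    reference annotations; ties break toward the earlier subset in the
    deterministic enumeration order. Subsets on which any stage fails
    (e.g. no maternal candidate) score None and cannot win unless all fail.
    """
    from .pipeline import PipelineConfig, run_extraction

    config = config or PipelineConfig()
    subsets = select_channel_subsets(record.n_channels, min_size=min_size)
    best: tuple[ChannelSubset, float] | None = None
    for sub in subsets:
        try:
            _, _, report = run_extraction(record, sub, config,
                                          reference=annotations_ref)
            f1 = report.f1 if report is not None else None
        except Exception:
            f1 = None
        if f1 is None:
            continue
        if best is None or f1 > best[1]:
            best = (sub, f1)
    if best is None:
        raise RoleAssignmentError("every channel subset failed the pipeline")
    return best
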