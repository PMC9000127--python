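"""Adaptive maternal-component cancellation.

The adaptive block takes the fetal-enhanced abdominal component aECG* as
the primary input d(n) and the estimated maternal component mECG* as the
reference x(n). A transversal filter predicts the maternal content of
d(n) from the reference, y(n) = w'x_vec(n) with
x_vec(n) = [x(n), x(n-1), ..., x(n-M+1)] (zero-padded history), and the
a-priori error e(n) = d(n) - y(n) is the estimated fetal ECG, fECG_est.

Five interchangeable weight-update kernels are provided:

* ``lms``     -- standard LMS, w += mu * e * x_vec;
* ``selms``   -- sign-error LMS, w += mu * sign(e) * x_vec (sign(0)=0);
* ``adaline`` -- linear neuron with delta rule; with the bias off it is
  numerically identical to LMS with (M, mu) = (p, eta);
* ``rls``     -- exponentially weighted recursive least squares with
  inverse-correlation seed P(0) = I/init_delta;
* ``ftf``     -- fast transversal filter: an exact O(M)-per-sample RLS
  using forward/backward prediction recursions and the conversion
  (likelihood) factor gamma(n), with a soft-restart rescue when the
  recursions lose numerical consistency.

All kernels start from zero weights and are pure functions of
(config, d, x). Kernels are numba-compiled for the grid-search workload.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import DivergenceError, InstabilityError, ValidationError

_ALGORITHMS = ("lms", "selms", "adaline", "rls", "ftf")

# Allowed gap between the recursive and the directly computed conversion
# factor gamma before an FTF rescue is forced.
_FTF_GAMMA_DRIFT_TOL = 0.02


@dataclass
class AdaptiveConfig:
    """Algorithm choice and control parameters.

    ``M`` is the filter length in taps (filter order N = M - 1); ``mu``
    the LMS-family step size; ``lam`` the RLS/FTF forgetting factor;
    ``eta``/``p`` the ADALINE learning rate and input space;
    ``init_delta`` seeds the RLS inverse correlation (P(0)=I/init_delta)
    and the FTF prediction-error energies.
    """

    algorithm: str = "rls"
    M: int = 5
    mu: float = 0.01
    lam: float = 0.999
    eta: float = 0.01
    p: int = 5
    init_delta: float = 0.01
    bias: bool = False
    rescue_budget: int = 50

    def __post_init__(self):
        if self.algorithm not in _ALGORITHMS:
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        if self.M < 1 or self.p < 1:
            raise ValidationError("filter length M (and p) must be >= 1")
        if self.algorithm in ("lms", "selms") and self.mu < 0:
            raise ValidationError("step size mu must be >= 0")
        if self.algorithm in ("rls", "ftf") and not (0 < self.lam <= 1):
            raise ValidationError("forgetting factor lam must lie in (0, 1]")
        if self.algorithm == "adaline" and self.eta < 0:
            raise ValidationError("learning rate eta must be >= 0")
        if self.init_delta <= 0:
            raise ValidationError("init_delta must be positive")


@dataclass
class FilterRun:
    """Result of one adaptive run: fECG_est = a-priori error signal e(n)."""

    fecg_est: np.ndarray
    prediction: np.ndarray
    weights: np.ndarray
    algorithm: str
    rescues: int = 0
    config: AdaptiveConfig | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lms_loop(d, x, M, mu, sign_error, bias, eta_bias):
    n = d.shape[0]
    w = np.zeros(M)
    b = 0.0
    e = np.empty(n)
    y = np.empty(n)
    u = np.zeros(M)
    for i in range(n):
        for j in range(M - 1, 0, -1):
            u[j] = u[j - 1]
        u[0] = x[i]
        yi = b
        for j in range(M):
            yi += w[j] * u[j]
        y[i] = yi
        ei = d[i] - yi
        e[i] = ei
        if not np.isfinite(ei):
            return e, y, w, b, i
        if sign_error:
            g = 0.0
            if ei > 0.0:
                g = 1.0
            elif ei < 0.0:
                g = -1.0
        else:
            g = ei
        for j in range(M):
            w[j] += mu * g * u[j]
        if bias:
            b += eta_bias * g
    return e, y, w, b, -1


@njit(cache=True)
def _rls_loop(d, x, M, lam, delta):
    n = d.shape[0]
    w = np.zeros(M)
    P = np.eye(M) / delta
    u = np.zeros(M)
    e = np.empty(n)
    y = np.empty(n)
    Pu = np.empty(M)
    for i in range(n):
        for j in range(M - 1, 0, -1):
            u[j] = u[j - 1]
        u[0] = x[i]
        yi = 0.0
        for j in range(M):
            yi += w[j] * u[j]
        y[i] = yi
        ei = d[i] - yi
        e[i] = ei
        if not np.isfinite(ei):
            return e, y, w, i
        for j in range(M):
            s = 0.0
            for l in range(M):
                s += P[j, l] * u[l]
            Pu[j] = s
        denom = lam
        for j in range(M):
            denom += u[j] * Pu[j]
        for j in range(M):
            kj = Pu[j] / denom
            w[j] += kj * ei
        for j in range(M):
            kj = Pu[j] / denom
            for l in range(M):
                P[j, l] = (P[j, l] - kj * Pu[l]) / lam
        # enforce symmetry: the Riccati update drifts asymmetric in floats
        # and loses positive definiteness on long runs with lam < 1
        for j in range(M):
            for l in range(j + 1, M):
                s = 0.5 * (P[j, l] + P[l, j])
                P[j, l] = s
                P[l, j] = s
    return e, y, w, -1


@njit(cache=True)
def _ftf_loop(d, x, M, lam, delta, rescue_budget):
    """Exact fast transversal RLS; returns (e, y, w, rescues, status).

    status: -1 ok, -2 rescue budget exceeded, >=0 divergence sample.

    Derivation: with Phi_M(n) = sum lam^(n-i) u(i)u(i)' + lam^(n+1) delta I,
    the order-(M+1) correlation matrix decomposes with corner blocks
    Phi_M(n-1) (forward partition) and Phi_M(n) (backward partition), up
    to a geometrically decaying O(lam^n * delta) regularizer mismatch in
    the forward corner; propagating the gain k_M(n) = Phi_M(n)^-1 u(n)
    through both decompositions gives O(M) updates. The forward
    cross-correlation vector r_f is carried explicitly so the prediction
    error energy F(n) comes from its definition each sample instead of a
    scalar recursion.

    Stability: the conversion factor gamma(n) = 1 - u(n)'k(n) is computed
    both directly (from the freshly propagated gain) and through the
    classical order-recursion. The recursion integrates past round-off,
    so a growing gap between the two flags the (well-known) exponential
    error build-up of fast transversal algorithms; a gap beyond
    _FTF_GAMMA_DRIFT_TOL -- or gamma leaving (0, 1], or a non-positive
    prediction energy -- triggers a rescue. A rescue re-opens a fresh
    prewindowed stretch at the current sample (prediction state and
    regressor history reset) while keeping the joint-process weights.
    """
    n = d.shape[0]
    w = np.zeros(M)       # joint-process weights (kept across rescues)
    w_f = np.zeros(M)     # forward predictor
    w_b = np.zeros(M)     # backward predictor
    k = np.zeros(M)       # gain k_M(n-1)
    k_new = np.zeros(M)
    r_f = np.zeros(M)
    u_prev = np.zeros(M)  # u_M(n-1), prewindowed per stretch (gain route)
    u_cur = np.zeros(M)   # u_M(n), prewindowed per stretch (gain route)
    u_true = np.zeros(M)  # u_M(n) with the full history (joint process)
    gamma = 1.0           # recursive conversion factor
    phx = delta
    e = np.empty(n)
    y = np.empty(n)
    rescues = 0
    start = 0  # first sample of the current prewindowed stretch
    for i in range(n):
        for j in range(M - 1, 0, -1):
            u_cur[j] = u_cur[j - 1]
            u_true[j] = u_true[j - 1]
        u_cur[0] = x[i]
        u_true[0] = x[i]
        x_nM = x[i - M] if i - M >= start else 0.0

        # --- forward prediction section ---
        dot_wf_up = 0.0
        for j in range(M):
            dot_wf_up += w_f[j] * u_prev[j]
        e_f = x[i] - dot_wf_up  # a-priori forward prediction error
        for j in range(M):
            w_f[j] += k[j] * e_f
            r_f[j] = lam * r_f[j] + u_prev[j] * x[i]
        phx = lam * phx + x[i] * x[i]
        F = phx
        eps_f = x[i]
        for j in range(M):
            F -= r_f[j] * w_f[j]
            eps_f -= w_f[j] * u_prev[j]

        ok = F > 0.0 and np.isfinite(F)
        if ok:
            # extended gain k_{M+1}(n) = [0; k] + (eps_f/F)*[1; -w_f];
            # its last element c is the backward error/energy ratio
            ratio = eps_f / F
            c = k[M - 1] - ratio * w_f[M - 1]
            e_b = x_nM
            for j in range(M):
                e_b -= w_b[j] * u_cur[j]
            gamma_ext = gamma - eps_f * ratio
            denom = 1.0 - c * e_b
            ok = (denom > 1e-12 and np.isfinite(denom)
                  and gamma_ext > 0.0 and np.isfinite(gamma_ext))
        if ok:
            k_new[0] = (ratio + c * w_b[0]) / denom
            for j in range(1, M):
                k_new[j] = (k[j - 1] - ratio * w_f[j - 1]
                            + c * w_b[j]) / denom
            gamma_rec = gamma_ext / denom
            gamma_dir = 1.0
            for j in range(M):
                gamma_dir -= u_cur[j] * k_new[j]
            ok = (np.isfinite(gamma_dir) and np.isfinite(gamma_rec)
                  and 0.0 < gamma_dir <= 1.0 + 1e-9
                  and abs(gamma_rec - gamma_dir) <= _FTF_GAMMA_DRIFT_TOL)
            if ok:
                for j in range(M):
                    if not np.isfinite(k_new[j]):
                        ok = False
                        break
        if not ok:
            rescues += 1
            if rescues > rescue_budget:
                return e[:i], y[:i], w, rescues, -2
            # Re-create exactly the state a fresh prewindowed filter has
            # after consuming this one sample, so the restarted stretch
            # satisfies the recursion invariants from its first step. The
            # restart regularization is scaled to the running reference
            # power so the kept joint weights are not kicked around by
            # the near-unity gain a weakly regularized stretch would have.
            dloc = delta + (1.0 - lam) * phx
            if not np.isfinite(dloc) or dloc <= 0.0:
                dloc = delta
            for j in range(M):
                w_f[j] = 0.0
                w_b[j] = 0.0
                k[j] = 0.0
                k_new[j] = 0.0
                r_f[j] = 0.0
                u_cur[j] = 0.0
            u_cur[0] = x[i]
            phx = lam * dloc + x[i] * x[i]
            k[0] = x[i] / phx
            gamma = 1.0 - x[i] * x[i] / phx
            start = i
        else:
            for j in range(M):
                w_b[j] += k_new[j] * e_b
            gamma = gamma_rec if gamma_rec < 1.0 else 1.0
            for j in range(M):
                k[j] = k_new[j]

        # --- joint process: predicts from the true regressor history and
        # runs every sample (right after a rescue the gain is the fresh
        # stretch's single-sample gain)
        yi = 0.0
        for j in range(M):
            yi += w[j] * u_true[j]
        y[i] = yi
        ei = d[i] - yi
        e[i] = ei
        if not np.isfinite(ei):
            return e, y, w, rescues, i
        for j in range(M):
            w[j] += k[j] * ei
        for j in range(M):
            u_prev[j] = u_cur[j]
    return e, y, w, rescues, -1


# ---------------------------------------------------------------------------
# Public kernels
# ---------------------------------------------------------------------------

def _as_vec(a, name) -> np.ndarray:
    v = np.asarray(a, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError(f"{name} signal is empty")
    return v


def _run_lms_family(d, x, M, mu, sign_error=False, bias=False, eta_bias=0.0,
                    algorithm="lms", config=None) -> FilterRun:
    d = _as_vec(d, "primary")
    x = _as_vec(x, "reference")
    if d.size != x.size:
        raise ValidationError("primary and reference must have equal length")
    e, y, w, b, status = _lms_loop(d, x, int(M), float(mu), sign_error,
                                   bias, float(eta_bias))
    if status >= 0:
        raise DivergenceError(
            f"{algorithm} diverged (non-finite error) at sample {status}",
            sample_index=status)
    weights = np.append(w, b) if bias else w
    return FilterRun(e, y, weights, algorithm=algorithm, config=config)


def lms_kernel(d, x, M: int, mu: float) -> FilterRun:
    """Standard LMS: w(n+1) = w(n) + mu*e(n)*x_vec(n), zero-initial weights."""
    return _run_lms_family(d, x, M, mu, algorithm="lms")


def selms_kernel(d, x, M: int, mu: float) -> FilterRun:
    """Sign-error LMS: w(n+1) = w(n) + mu*sign(e(n))*x_vec(n); sign(0)=0."""
    return _run_lms_family(d, x, M, mu, sign_error=True, algorithm="selms")


def adaline_kernel(d, x, p: int, eta: float, bias: bool = False) -> FilterRun:
    """Linear neuron with p delayed inputs trained by the delta rule.

    With ``bias=False`` this is numerically identical to
    ``lms_kernel(d, x, M=p, mu=eta)`` (same compiled loop); with
    ``bias=True`` an extra bias weight is trained as w_b += eta*e(n).
    """
    run = _run_lms_family(d, x, p, eta, bias=bias, eta_bias=eta,
                          algorithm="adaline")
    return run


def rls_kernel(d, x, M: int, lam: float, init_delta: float = 0.01) -> FilterRun:
    """Exponentially weighted RLS with P(0) = I/init_delta.

    Emits the a-priori error; with lam=1 the terminal weights equal the
    ridge-regularized batch least-squares solution
    (X'X + init_delta*I) w = X'd exactly.
    """
    d = _as_vec(d, "primary")
    x = _as_vec(x, "reference")
    if d.size != x.size:
        raise ValidationError("primary and reference must have equal length")
    if not (0 < lam <= 1):
        raise ValidationError("forgetting factor lam must lie in (0, 1]")
    e, y, w, status = _rls_loop(d, x, int(M), float(lam), float(init_delta))
    if status >= 0:
        raise DivergenceError(f"rls diverged at sample {status}",
                              sample_index=status)
    return FilterRun(e, y, w, algorithm="rls")


def ftf_kernel(d, x, M: int, lam: float, init_delta: float = 0.01,
               rescue_budget: int = 50) -> FilterRun:
    """Fast transversal filter (exact O(M) RLS); see module docstring.

    If the conversion factor gamma(n) leaves (0, 1] or any state turns
    non-finite, the prediction state is re-initialized keeping the current
    joint-process weights; exceeding ``rescue_budget`` such rescues raises
    :class:`InstabilityError`.
    """
    d = _as_vec(d, "primary")
    x = _as_vec(x, "reference")
    if d.size != x.size:
        raise ValidationError("primary and reference must have equal length")
    if not (0 < lam <= 1):
        raise ValidationError("forgetting factor lam must lie in (0, 1]")
    e, y, w, rescues, status = _ftf_loop(d, x, int(M), float(lam),
                                         float(init_delta), int(rescue_budget))
    if status == -2:
        raise InstabilityError(
            f"FTF exceeded rescue budget ({rescue_budget})", rescue_count=rescues)
    if status >= 0:
        raise DivergenceError(f"ftf diverged at sample {status}",
                              sample_index=status)
    return FilterRun(e, y, w, algorithm="ftf", rescues=rescues)


def run_adaptive(config: AdaptiveConfig, primary, reference) -> FilterRun:
    """Dispatch to the configured kernel; fECG_est is the error signal."""
    a = config.algorithm
    if a == "lms":
        run = lms_kernel(primary, reference, config.M, config.mu)
    elif a == "selms":
        run = selms_kernel(primary, reference, config.M, config.mu)
    elif a == "adaline":
        run = adaline_kernel(primary, reference, config.p, config.eta,
                             bias=config.bias)
    elif a == "rls":
        run = rls_kernel(primary, reference, config.M, config.lam,
                         config.init_delta)
    elif a == "ftf":
        run = ftf_kernel(primary, reference, config.M, config.lam,
                         config.init_delta, config.rescue_budget)
    else:  # pragma: no cover - guarded by AdaptiveConfig
        raise ValidationError(f"unknown algorithm {a!r}")
    run.config = config
    return run
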