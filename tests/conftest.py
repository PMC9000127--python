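"""Shared fixtures: the default synthetic recording and adaptive-filter
oracle fixtures (all generated programmatically, nothing stored)."""

import numpy as np
import pytest

import fecghybrid as fh

FS = 500.0
STANDARD_FIR = np.array([0.9, 0.3, -0.2, 0.1, 0.05])


@pytest.fixture(scope="session")
def default_recording():
    """Default synthetic abdominal recording (desk-scale study conditions)."""
    spec = fh.SyntheticSpec(seed=0)
    record, fetal_ann, maternal_ann, clean_fetal = fh.generate_recording(spec)
    return {"spec": spec, "record": record, "fetal": fetal_ann,
            "maternal": maternal_ann, "clean_fetal": clean_fetal}


@pytest.fixture(scope="session")
def standard_fixture():
    """Known-FIR cancellation fixture: d = (m + sensor noise) * h + 0.25 f.

    The maternal reference carries broadband sensor noise (0.1 mV) so the
    5-tap identification problem is well conditioned; sources are
    demeaned as the pipeline's 3 Hz high-pass would do.
    """
    m0, m_ann = fh.generate_single_ecg(FS, 120.0, 75, 2.0, seed=10)
    f0, f_ann = fh.generate_single_ecg(FS, 120.0, 140, 2.0, seed=20)
    m0 = m0 - m0.mean()
    f0 = f0 - f0.mean()
    rng = np.random.default_rng(99)
    x = m0 + 0.1 * rng.standard_normal(m0.size)
    d = np.convolve(x, STANDARD_FIR)[: x.size] + 0.25 * f0
    return {"d": d, "x": x, "h": STANDARD_FIR, "maternal": m0, "fetal": f0,
            "fetal_ann": f_ann, "maternal_ann": m_ann, "fs": FS}


@pytest.fixture(scope="session")
def short_fixture():
    """Well-conditioned 500-sample white-noise fixture for exact oracles."""
    rng = np.random.default_rng(0)
    x = rng.standard_normal(500)
    d = np.convolve(x, STANDARD_FIR)[:500] + 0.05 * rng.standard_normal(500)
    return {"d": d, "x": x, "h": STANDARD_FIR}


def ridge_ls_weights(d, x, M, delta=0.01):
    """Batch least squares with the RLS initialization ridge (oracle)."""
    n = len(x)
    X = np.zeros((n, M))
    for j in range(M):
        X[j:, j] = x[: n - j]
    return np.linalg.solve(X.T @ X + delta * np.eye(M), X.T @ d)
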