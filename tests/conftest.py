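"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own linear-algebra
helpers: least squares is re-derived from the normal equations with an
explicit Gram pseudoinverse, and slice statistics are recomputed with
plain Python loops.
"""

import numpy as np
import pytest

import marss


def ols_oracle(X, Y):
    """Normal-equations least squares: pinv(X'X) X'Y; returns (coefs, residuals)."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    coefs = np.linalg.pinv(X.T @ X) @ (X.T @ Y)
    return coefs, Y - X @ coefs


def make_run(rng, shape=(6, 6, 6, 40), base=100.0, scale=1.0, **kw):
    """A finite random BoldRun for unit tests."""
    data = base + scale * rng.normal(size=shape)
    kw.setdefault("tr_s", 0.8)
    kw.setdefault("slice_thickness_mm", 2.0)
    return marss.BoldRun(data=data, **kw)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_ds():
    """A small, fully synthetic dataset (float64) shared by API-level tests."""
    spec = marss.SyntheticSpec(
        nx=20,
        ny=20,
        n_slices=12,
        n_volumes=160,
        mb_factor=4,
        noise_sd=5.0,
        dtype="float64",
        seed=101,
    )
    return marss.generate(spec)
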