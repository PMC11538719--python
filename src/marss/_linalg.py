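"""Least-squares helpers shared by the estimation and removal stages.

Every fit in the package goes through the pseudoinverse (SVD) path: it is
identical to the textbook normal-equations solution when the design has
full column rank and remains well defined when it does not. Designs whose
Gram matrix is severely ill-conditioned are flagged with a warning rather
than an error.
"""

from __future__ import annotations

import warnings

import numpy as np

COND_LIMIT = 1e12


class IllConditionedDesign(UserWarning):
    """Design matrix condition number exceeds the trusted range."""


def check_condition(X: np.ndarray, context: str = "") -> float:
    """Scale-invariant condition number of ``X^T X``; warns above ``COND_LIMIT``.

    Columns are normalized to unit Euclidean norm first, so the check
    responds to genuine collinearity rather than to regressors living on
    different physical scales (raw intensity vs. motion in mm/rad).
    """
    norms = np.linalg.norm(X, axis=0)
    Xn = X / np.where(norms > 0, norms, 1.0)
    s = np.linalg.svd(Xn, compute_uv=False)
    smin = s.min()
    cond = np.inf if smin == 0 else float((s.max() / smin) ** 2)
    if cond > COND_LIMIT:
        warnings.warn(
            f"ill-conditioned design (cond(X'X) = {cond:.3g}){' in ' + context if context else ''};"
            " falling back to the pseudoinverse solution",
            IllConditionedDesign,
            stacklevel=2,
        )
    return cond


def ols_fit(X: np.ndarray, Y: np.ndarray, context: str = "") -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of columns of ``Y`` on design ``X``.

    Returns ``(coefs, residuals)`` where ``coefs`` has shape
    (n_regressors, n_targets) and ``residuals`` matches ``Y``. Minimum-norm
    solution under rank deficiency.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    check_condition(X, context)
    coefs, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coefs
    if squeeze:
        return coefs[:, 0], resid[:, 0]
    return coefs, resid


def ols_residuals(X: np.ndarray, Y: np.ndarray, context: str = "") -> np.ndarray:
    """Residuals of ``Y`` on ``X`` (see :func:`ols_fit`)."""
    return ols_fit(X, Y, context)[1]
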