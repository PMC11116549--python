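"""Newton-Raphson maximum-likelihood fitters for the two nuisance models.

Both the multinomial logit (treatment assignment) and the binary logistic
(outcome) model are fitted by full Newton iterations with step-halving on
the log-likelihood.  Convergence is declared when the max absolute score
drops below ``tol`` or the max parameter change drops below ``xtol``.  The
fitters are deliberately lean (pure numpy, optional warm start) because the
bootstrap refits them thousands of times.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EstimationError",
    "SeparationError",
    "fit_multinomial_newton",
    "fit_logistic_newton",
    "softmax_rows",
]


class EstimationError(RuntimeError):
    """A maximum-likelihood fit could not be completed."""


class SeparationError(EstimationError):
    """Detected (quasi-)separation; advise a small ridge penalty.

    Enable with ``ridge > 0`` (an L2 penalty on all non-intercept terms),
    which is off by default.
    """


# coefficients drifting past this magnitude with a still-improving likelihood
# is the practical signature of separation in these reference-coded designs
_SEPARATION_BOUND = 40.0

# Newton safeguards: relative Levenberg damping keeps the Hessian invertible
# when a saturated cell's curvature underflows, and the step cap stops the
# resulting search direction from exploding; neither changes the optimum
_DAMP_REL = 1e-10
_STEP_CAP = 10.0


def _solve_damped(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Solve H x = g with tiny relative diagonal damping and a step cap."""
    damp = _DAMP_REL * np.abs(np.diag(H)).max()
    Hd = H + damp * np.eye(H.shape[0])
    try:
        x = np.linalg.solve(Hd, g)
    except np.linalg.LinAlgError:
        x = np.linalg.lstsq(Hd, g, rcond=None)[0]
    biggest = np.abs(x).max()
    if biggest > _STEP_CAP:
        x = x * (_STEP_CAP / biggest)
    return x


def softmax_rows(eta: np.ndarray) -> np.ndarray:
    """Row-wise softmax over ``[0, eta]`` (class 0 has logit 0).

    ``eta`` has shape (n, K-1); returns (n, K) probabilities.  Max-
    subtraction keeps the exponentials finite for any coefficient scale.
    """
    n = eta.shape[0]
    full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    np.exp(full, out=full)
    full /= full.sum(axis=1, keepdims=True)
    return full


def _multinomial_loglik(P: np.ndarray, A: np.ndarray) -> float:
    p_obs = P[np.arange(P.shape[0]), A]
    return float(np.log(np.clip(p_obs, 1e-300, None)).sum())


def fit_multinomial_newton(
    X: np.ndarray,
    A: np.ndarray,
    n_classes: int = 4,
    tol: float = 1e-8,
    xtol: float = 1e-10,
    max_iter: int = 100,
    ridge: float = 0.0,
    start: np.ndarray | None = None,
    check_arms: bool = True,
):
    """MLE of the baseline-category (class 0) multinomial logit.

    Parameters
    ----------
    X : (n, p) design matrix, first column the intercept.
    A : (n,) integer class labels in ``0..n_classes-1``.
    ridge : L2 penalty applied to every coefficient except the per-class
        intercepts; 0 disables it.
    start : optional (n_classes-1, p) warm-start coefficients.

    Returns
    -------
    betas : (n_classes-1, p), loglik : float, converged : bool, n_iter : int
    """
    X = np.asarray(X, dtype=float)
    A = np.asarray(A)
    n, p = X.shape
    K = n_classes
    if check_arms:
        counts = np.bincount(A, minlength=K)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            raise EstimationError(
                f"no observations in treatment arm(s) {empty.tolist()}; "
                "the multinomial model cannot be fitted"
            )
    # indicator matrix for classes 1..K-1
    Z = np.zeros((n, K - 1))
    for i in range(1, K):
        Z[:, i - 1] = A == i

    B = np.zeros((K - 1, p)) if start is None else np.array(start, dtype=float)
    pen = np.zeros(p)
    if ridge > 0:
        pen[1:] = ridge

    P = softmax_rows(X @ B.T)
    ll = _multinomial_loglik(P, A) - 0.5 * float((pen * B**2).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = Z - P[:, 1:]                       # (n, K-1)
        score = (X.T @ resid).T - pen * B          # (K-1, p)
        if np.abs(score).max() < tol:
            converged = True
            break
        # Hessian blocks H[i,j] = -X^T diag(P_i (d_ij - P_j)) X
        H = np.empty(((K - 1) * p, (K - 1) * p))
        for i in range(1, K):
            for j in range(i, K):
                w = P[:, i] * ((1.0 if i == j else 0.0) - P[:, j])
                blk = -(X.T * w) @ X
                if i == j:
                    blk -= np.diag(pen)
                H[(i - 1) * p:i * p, (j - 1) * p:j * p] = blk
                if i != j:
                    H[(j - 1) * p:j * p, (i - 1) * p:i * p] = blk.T
        step = _solve_damped(-H, score.ravel()).reshape(K - 1, p)
        # step-halving on the penalised log-likelihood
        lam = 1.0
        for _ in range(30):
            B_new = B + lam * step
            P_new = softmax_rows(X @ B_new.T)
            ll_new = _multinomial_loglik(P_new, A) - 0.5 * float(
                (pen * B_new**2).sum()
            )
            if ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        delta = np.abs(lam * step).max()
        B, P, ll = B_new, P_new, ll_new
        if delta < xtol:
            converged = True
            break

    if not converged:
        if np.abs(B).max() > _SEPARATION_BOUND:
            raise SeparationError(
                "multinomial fit diverging (|beta| > "
                f"{_SEPARATION_BOUND}); data may be separated — consider "
                "refitting with a small ridge penalty (ridge > 0)"
            )
        resid = Z - P[:, 1:]
        gnorm = float(np.abs((X.T @ resid).T - pen * B).max())
        raise EstimationError(
            f"multinomial fit did not converge in {max_iter} iterations "
            f"(max |score| = {gnorm:.3e}); last iterate retained in message"
        )
    return B, ll, converged, it


def _logistic_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log p(y) = y*eta - log(1+e^eta), computed stably
    return float((y * eta - np.logaddexp(0.0, eta)).sum())


def fit_logistic_newton(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    xtol: float = 1e-10,
    max_iter: int = 100,
    ridge: float = 0.0,
    start: np.ndarray | None = None,
):
    """MLE of a binary logistic regression; same contract as the multinomial fitter."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    classes = np.unique(y)
    if classes.size < 2:
        raise EstimationError(
            f"outcome takes the single value {classes[0]!r}; "
            "logistic model cannot be fitted"
        )
    beta = np.zeros(p) if start is None else np.array(start, dtype=float)
    pen = np.zeros(p)
    if ridge > 0:
        pen[1:] = ridge

    eta = X @ beta
    ll = _logistic_loglik(eta, y) - 0.5 * float((pen * beta**2).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - mu) - pen * beta
        if np.abs(score).max() < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (X.T * w) @ X + np.diag(pen)
        step = _solve_damped(H, score)
        lam = 1.0
        for _ in range(30):
            beta_new = beta + lam * step
            eta_new = X @ beta_new
            ll_new = _logistic_loglik(eta_new, y) - 0.5 * float(
                (pen * beta_new**2).sum()
            )
            if ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        delta = np.abs(lam * step).max()
        beta, eta, ll = beta_new, eta_new, ll_new
        if delta < xtol:
            converged = True
            break

    if not converged:
        if np.abs(beta).max() > _SEPARATION_BOUND:
            raise SeparationError(
                "logistic fit diverging; data may be separated — consider "
                "refitting with a small ridge penalty (ridge > 0)"
            )
        mu = 1.0 / (1.0 + np.exp(-eta))
        gnorm = float(np.abs(X.T @ (y - mu) - pen * beta).max())
        raise EstimationError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(max |score| = {gnorm:.3e})"
        )
    return beta, ll, converged, it
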