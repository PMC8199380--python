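"""Cox partial-likelihood derivatives and score tests (Efron ties).

Forward stepwise model building by score statistic needs the partial
likelihood's gradient and observed information evaluated at the current
MLE with a candidate coefficient pinned at zero.  Off-the-shelf Cox
fitters return Wald and likelihood-ratio quantities only, so the
derivative code lives here.

With tied event times handled by Efron's approximation, the log partial
likelihood over distinct event times t_j with tied death sets D_j
(|D_j| = d_j) and risk sets R_j is

    l(b) = sum_j [ sum_{i in D_j} x_i'b
                   - sum_{l=0}^{d_j-1} log( S0(R_j) - (l/d_j) S0(D_j) ) ]

where S0(A) = sum_{i in A} exp(x_i'b).  Gradient and Hessian follow by
replacing S0 with the weighted moment sums S1 (vector) and S2 (matrix).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["cox_gradient_information", "cox_score_test"]


def cox_gradient_information(
    times: np.ndarray, events: np.ndarray, X: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Score vector U(beta) and observed information I(beta) (Efron ties).

    ``X`` is (n, p); censored subjects contribute through risk sets only.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(times):
        X = X.T
    n, p = X.shape
    beta = np.asarray(beta, float).reshape(p)
    eta = X @ beta
    w = np.exp(eta)

    U = np.zeros(p)
    info = np.zeros((p, p))
    for t in np.unique(times[events]):
        at_risk = times >= t
        dead = events & (times == t)
        d = int(dead.sum())
        s0_r = w[at_risk].sum()
        s1_r = w[at_risk] @ X[at_risk]
        s2_r = (w[at_risk, None] * X[at_risk]).T @ X[at_risk]
        s0_d = w[dead].sum()
        s1_d = w[dead] @ X[dead]
        s2_d = (w[dead, None] * X[dead]).T @ X[dead]
        U += X[dead].sum(axis=0)
        for el in range(d):
            frac = el / d
            phi = s0_r - frac * s0_d
            s1 = s1_r - frac * s1_d
            s2 = s2_r - frac * s2_d
            U -= s1 / phi
            info += s2 / phi - np.outer(s1, s1) / phi**2
    return U, info


def cox_score_test(
    times: np.ndarray,
    events: np.ndarray,
    X_current: np.ndarray | None,
    beta_current: np.ndarray | None,
    z_new: np.ndarray,
) -> tuple[float, float]:
    """Score (Rao) test for adding one covariate to a fitted Cox model.

    Evaluates the partial-likelihood score at (beta_current, 0) and
    returns (chi2, p) on 1 df, using the efficient information
    I_zz - I_zb I_bb^{-1} I_bz.  With no current covariates this is the
    classic score test at the null model (which for a binary covariate on
    tie-free data equals the log-rank statistic).
    """
    z_new = np.asarray(z_new, float).reshape(-1, 1)
    if X_current is None or X_current.size == 0:
        X_full = z_new
        beta_full = np.zeros(1)
    else:
        X_current = np.atleast_2d(np.asarray(X_current, float))
        if X_current.shape[0] != len(z_new):
            X_current = X_current.T
        X_full = np.hstack([X_current, z_new])
        beta_full = np.append(np.asarray(beta_current, float), 0.0)
    U, info = cox_gradient_information(times, events, X_full, beta_full)
    p = X_full.shape[1]
    u_z = U[-1]
    if p == 1:
        v = info[0, 0]
    else:
        i_bb = info[:-1, :-1]
        i_zb = info[-1, :-1]
        v = info[-1, -1] - i_zb @ np.linalg.solve(i_bb, i_zb)
    if v <= 0:
        return 0.0, 1.0
    chi2 = float(u_z**2 / v)
    return chi2, float(stats.chi2.sf(chi2, df=1))
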