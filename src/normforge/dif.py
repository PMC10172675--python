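"""Differential item functioning by proportional-odds ordinal regression.

For each item, three nested cumulative-logit models are fitted on the
matching trait estimate theta and a binary group indicator g::

    M1:  logit P(X <= k) = alpha_k - beta1 * theta
    M2:  ... - beta1 * theta - beta2 * g
    M3:  ... - beta1 * theta - beta2 * g - beta3 * theta * g

Likelihood-ratio tests between them give the uniform (M2 vs M1, df 1),
nonuniform (M3 vs M2, df 1) and total (M3 vs M1, df 2) DIF tests.  The
effect-size gate is the change in McFadden's pseudo-R-squared between M3
and M1, with 0.02 as the critical value for flagging an item; the pure
significance tests over-flag at large n, which is why the magnitude
criterion decides.

The proportional-odds likelihood is log-concave, so the built-in Newton
/ BFGS fit is deterministic; ``statsmodels``' ``OrderedModel`` serves as an
independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist

__all__ = ["PropOddsFit", "fit_proportional_odds", "null_loglik", "olr_dif"]


@dataclass
class PropOddsFit:
    loglik: float
    alpha: np.ndarray  # ordered intercepts, length K-1
    beta: np.ndarray  # slope per predictor column
    converged: bool
    n_obs: int


def null_loglik(y: np.ndarray) -> float:
    """Intercept-only log-likelihood: multinomial entropy of the categories."""
    _, counts = np.unique(y, return_counts=True)
    n = counts.sum()
    return float(np.sum(counts * np.log(counts / n)))


def _nll_grad(params: np.ndarray, y: np.ndarray, X: np.ndarray, K: int):
    """Negative log-likelihood and gradient; intercepts via ordered gaps."""
    n_beta = X.shape[1]
    a1 = params[0]
    gaps = np.exp(params[1 : K - 1])
    alpha = np.concatenate([[a1], a1 + np.cumsum(gaps)])
    beta = params[K - 1 :]
    eta = X @ beta if n_beta else np.zeros(len(y))

    # cumulative probabilities gamma_k = P(Y <= k) = expit(alpha_k - eta)
    z = alpha[None, :] - eta[:, None]  # n x (K-1)
    gamma = expit(z)
    full = np.hstack([np.zeros((len(y), 1)), gamma, np.ones((len(y), 1))])
    upper = full[np.arange(len(y)), y + 1]
    lower = full[np.arange(len(y)), y]
    p = np.clip(upper - lower, 1e-300, None)
    nll = -float(np.sum(np.log(p)))

    # gradient: d p / d alpha_k picks out the bounding cumulative curves
    dgamma = gamma * (1 - gamma)  # d expit
    gA = np.zeros(K - 1)
    geta = np.zeros(len(y))
    for k in range(K - 1):
        contrib = np.zeros(len(y))
        contrib[y == k + 1] = -dgamma[y == k + 1, k]  # lower bound of cell k+1
        contrib[y == k] += dgamma[y == k, k]  # upper bound of cell k
        gA[k] = -np.sum(contrib / p)
        geta -= contrib / p  # d eta enters with opposite sign via (alpha - eta)
    # chain rule: eta enters every bounding curve with -1
    # (already accumulated above with the right sign)
    grad_alpha = gA
    # reparameterize: d/d a1 = sum_k grad_alpha_k; d/d log gap_j = gap_j * sum_{k>=j+1} grad_alpha_k
    g = np.zeros_like(params)
    g[0] = grad_alpha.sum()
    for jj in range(1, K - 1):
        g[jj] = gaps[jj - 1] * grad_alpha[jj:].sum()
    if n_beta:
        g[K - 1 :] = X.T @ (-geta)
    return nll, g


def fit_proportional_odds(y: np.ndarray, X: np.ndarray | None = None) -> PropOddsFit:
    """Maximum-likelihood cumulative-logit fit with ordered intercepts.

    ``y`` holds 0-based ordinal codes; ``X`` the predictor columns (may be
    None/empty for the null model, whose likelihood is closed-form).
    Deterministic given the data.
    """
    y = np.asarray(y, dtype=int)
    cats = np.unique(y)
    if cats.size < 2:
        raise ValueError("outcome shows fewer than 2 categories")
    # compress category codes to 0..K-1 in observed order
    remap = {c: i for i, c in enumerate(cats)}
    y = np.array([remap[v] for v in y])
    K = cats.size
    X = np.empty((len(y), 0)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors must be finite")

    if X.shape[1] == 0:
        ll = null_loglik(y)
        counts = np.bincount(y, minlength=K)
        cum = np.cumsum(counts)[:-1] / len(y)
        return PropOddsFit(ll, np.log(cum / (1 - cum)), np.zeros(0), True, len(y))

    # start at the marginal intercepts with zero slopes
    counts = np.bincount(y, minlength=K)
    cum = np.clip(np.cumsum(counts)[:-1] / len(y), 1e-6, 1 - 1e-6)
    alpha0 = np.log(cum / (1 - cum))
    gaps0 = np.log(np.clip(np.diff(alpha0), 1e-6, None))
    x0 = np.concatenate([[alpha0[0]], gaps0, np.zeros(X.shape[1])])

    res = minimize(
        _nll_grad, x0, args=(y, X, K), jac=True, method="BFGS",
        options={"maxiter": 500, "gtol": 1e-7},
    )
    a1 = res.x[0]
    alpha = np.concatenate([[a1], a1 + np.cumsum(np.exp(res.x[1 : K - 1]))])
    beta = res.x[K - 1 :]
    # BFGS can stop on precision loss right at the optimum; accept when the
    # scaled gradient is tiny
    grad_ok = np.max(np.abs(res.jac)) < 1e-3 * max(1.0, abs(res.fun))
    return PropOddsFit(-float(res.fun), alpha, beta, bool(res.success or grad_ok), len(y))


def olr_dif(
    items: np.ndarray,
    trait: np.ndarray,
    group: np.ndarray,
    item_ids: list[str] | None = None,
    flag_threshold: float = 0.02,
    min_group_n: int = 50,
) -> pd.DataFrame:
    """Per-item uniform/nonuniform/total DIF tests with McFadden effect sizes.

    Parameters
    ----------
    items
        Complete-case persons x items 0-based codes.
    trait
        Matching variable (EAP theta from the pooled calibration, or a rest
        score), one value per person.
    group
        Binary focal-group indicator.
    flag_threshold
        An item is flagged when the total McFadden pseudo-R-squared change
        (full model vs trait-only) reaches this value.
    """
    X = np.asarray(items)
    trait = np.asarray(trait, dtype=float)
    group = np.asarray(group, dtype=float)
    if np.any(X < 0):
        raise ValueError("DIF analysis requires complete cases")
    if np.unique(group).size != 2:
        raise ValueError("group must have exactly two levels")
    n0, n1 = int(np.sum(group == group.min())), int(np.sum(group == group.max()))
    if min(n0, n1) < min_group_n:
        raise ValueError(f"both groups need >= {min_group_n} persons (have {n0}, {n1})")
    g = (group == group.max()).astype(float)
    ids = item_ids or [f"item_{j + 1}" for j in range(X.shape[1])]

    rows = []
    for j, iid in enumerate(ids):
        y = X[:, j]
        for grp_val in (0.0, 1.0):
            if np.unique(y[g == grp_val]).size < 2:
                raise ValueError(f"item {iid!r} is constant within a group")
        ll0 = null_loglik(y)
        m1 = fit_proportional_odds(y, trait[:, None])
        m2 = fit_proportional_odds(y, np.column_stack([trait, g]))
        m3 = fit_proportional_odds(y, np.column_stack([trait, g, trait * g]))
        lr_unif = max(2 * (m2.loglik - m1.loglik), 0.0)
        lr_nonu = max(2 * (m3.loglik - m2.loglik), 0.0)
        lr_tot = max(2 * (m3.loglik - m1.loglik), 0.0)
        r2 = lambda m: 1 - m.loglik / ll0  # noqa: E731
        d_unif = max(r2(m2) - r2(m1), 0.0)
        d_nonu = max(r2(m3) - r2(m2), 0.0)
        d_tot = max(r2(m3) - r2(m1), 0.0)
        rows.append({
            "item": iid,
            "lr_uniform": lr_unif,
            "p_uniform": float(chi2_dist.sf(lr_unif, 1)),
            "lr_nonuniform": lr_nonu,
            "p_nonuniform": float(chi2_dist.sf(lr_nonu, 1)),
            "lr_total": lr_tot,
            "p_total": float(chi2_dist.sf(lr_tot, 2)),
            "dr2_uniform": d_unif,
            "dr2_nonuniform": d_nonu,
            "dr2_total": d_tot,
            "flagged": d_tot >= flag_threshold,
        })
    return pd.DataFrame(rows).set_index("item")
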