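"""Graded response model: calibration, summed-score likelihoods, EAP scoring, item fit.

The graded response model (GRM) describes the probability of an ordered item
response as a difference of logistic cumulative curves.  For item *i* with
discrimination ``a_i`` and ordered thresholds ``b_i1 < ... < b_i,K-1``::

    P(X_i >= k | theta) = logistic(a_i * (theta - b_ik))          k = 1..K-1
    P(X_i = k  | theta) = P(X_i >= k) - P(X_i >= k+1)

Calibration is marginal maximum likelihood via EM over a fixed quadrature
grid approximating a standard-normal trait prior.  Summed-score machinery
(the Lord-Wingersky recursion) supports EAP scoring conditional on the raw
sum score, which is what crosswalk tables are built from, and the
Orlando-Thissen S-X2 item-fit statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm, chi2 as chi2_dist

__all__ = [
    "GRMParams",
    "QuadratureGrid",
    "CalibrationResult",
    "ItemFitResult",
    "default_grid",
    "cumulative_prob",
    "category_probs",
    "fit_grm",
    "sumscore_likelihoods",
    "eap_sum_table",
    "eap_pattern",
    "expected_item_given_total",
    "item_fit_s_chi2",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class GRMParams:
    """Per-item discriminations and ordered thresholds on the logistic metric.

    ``a[i]`` is the discrimination of item ``item_ids[i]`` (must be positive)
    and ``b[i]`` its strictly increasing threshold array of length
    ``n_categories[i] - 1``.  No 1.7 scaling constant is applied anywhere.
    """

    item_ids: list[str]
    a: np.ndarray
    b: list[np.ndarray]

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = [np.asarray(bi, dtype=float) for bi in self.b]
        if len(self.item_ids) != len(self.b) or len(self.item_ids) != self.a.size:
            raise ValueError("item_ids, a and b must have matching lengths")
        if not np.all(np.isfinite(self.a)) or np.any(self.a <= 0):
            raise ValueError("discriminations must be positive and finite")
        for iid, bi in zip(self.item_ids, self.b):
            if bi.size == 0 or not np.all(np.diff(bi) > 0):
                raise ValueError(f"thresholds of item {iid!r} must be strictly increasing")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def n_categories(self) -> list[int]:
        return [bi.size + 1 for bi in self.b]

    @property
    def max_score(self) -> int:
        """Maximum achievable 0-based sum score."""
        return int(sum(bi.size for bi in self.b))

    def subset(self, item_ids: list[str]) -> "GRMParams":
        idx = [self.item_ids.index(i) for i in item_ids]
        return GRMParams(list(item_ids), self.a[idx], [self.b[i] for i in idx])

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            iid: {"a": float(ai), "b": [float(x) for x in bi]}
            for iid, ai, bi in zip(self.item_ids, self.a, self.b)
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GRMParams":
        ids = list(d.keys())
        return cls(ids, np.array([d[i]["a"] for i in ids]), [np.array(d[i]["b"]) for i in ids])

    def save(self, path, meta: dict | None = None) -> None:
        payload = {"items": self.to_dict()}
        if meta:
            payload["meta"] = meta
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path) -> "GRMParams":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls.from_dict(payload["items"] if "items" in payload else payload)


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed trait grid with (normalized) standard-normal prior weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("quadrature weights must be positive")
        if not np.all(np.diff(self.nodes) > 0):
            raise ValueError("quadrature nodes must be strictly increasing")
        object.__setattr__(self, "weights", w / w.sum())


def default_grid(n_nodes: int = 61, bound: float = 6.0) -> QuadratureGrid:
    """Equally spaced nodes on [-bound, bound] with normal-density weights."""
    nodes = np.linspace(-bound, bound, n_nodes)
    return QuadratureGrid(nodes, norm.pdf(nodes))


# ---------------------------------------------------------------------------
# model probabilities


def cumulative_prob(a: float, b_k: float, theta) -> np.ndarray | float:
    """P(X >= k | theta): logistic curve with slope ``a`` crossing 0.5 at ``b_k``."""
    if a <= 0:
        raise ValueError("discrimination must be positive")
    return expit(a * (np.asarray(theta, dtype=float) - b_k))


def category_probs(a: float, b: np.ndarray, theta) -> np.ndarray:
    """Category probabilities at ``theta``; shape ``theta.shape + (K,)``.

    Adjacent differences of the cumulative curves, with implicit boundary
    curves 1 (k=0) and 0 (k=K).
    """
    b = np.asarray(b, dtype=float)
    if b.ndim != 1 or (b.size > 1 and not np.all(np.diff(b) > 0)):
        raise ValueError("thresholds must be a strictly increasing vector")
    theta = np.asarray(theta, dtype=float)
    cum = expit(a * (theta[..., None] - b))  # ... x (K-1)
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    full = np.concatenate([ones, cum, zeros], axis=-1)
    return full[..., :-1] - full[..., 1:]


def _item_prob_table(params: GRMParams, grid: QuadratureGrid) -> list[np.ndarray]:
    """Per item: (n_nodes, K) category-probability table on the grid."""
    return [category_probs(ai, bi, grid.nodes) for ai, bi in zip(params.a, params.b)]


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationResult:
    params: GRMParams
    loglik: float
    iterations: int
    converged: bool
    loglik_path: list[float] = field(default_factory=list)


def _pack(a: float, b: np.ndarray) -> np.ndarray:
    """(a, b) -> unconstrained vector (log a, b_1, log successive gaps)."""
    gaps = np.diff(b)
    return np.concatenate([[np.log(a), b[0]], np.log(gaps)]) if gaps.size else np.array(
        [np.log(a), b[0]]
    )


def _unpack(x: np.ndarray) -> tuple[float, np.ndarray]:
    a = np.exp(x[0])
    b = np.concatenate([[x[1]], x[1] + np.cumsum(np.exp(x[2:]))])
    return a, b


def _item_neg_ell(x: np.ndarray, r: np.ndarray, nodes: np.ndarray) -> float:
    """Negative expected complete-data log-likelihood for one item.

    ``r`` is the (n_nodes, K) table of expected response counts at each node.
    """
    a, b = _unpack(x)
    p = category_probs(a, b, nodes)
    return -float(np.sum(r * np.log(np.clip(p, 1e-300, None))))


def fit_grm(
    responses: np.ndarray,
    item_ids: list[str] | None = None,
    grid: QuadratureGrid | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> CalibrationResult:
    """Calibrate a GRM by marginal maximum likelihood (EM over the grid).

    Parameters
    ----------
    responses
        Complete-case persons x items array of 0-based integer codes.
    item_ids
        Names for the columns; defaults to ``item_1 .. item_m``.
    grid
        Quadrature grid; 61 nodes on [-6, 6] by default.  The standard-normal
        prior on this grid identifies the latent metric.
    tol
        EM stops when the largest absolute parameter change falls below this.
    max_iter
        Cap on EM cycles; hitting it is reported via ``converged=False``.

    The E-step computes each person's posterior trait weights on the grid;
    the M-step maximizes, per item, the expected complete-data log-likelihood
    with quasi-Newton steps on (log a, b_1, log threshold gaps), which keeps
    discriminations positive and thresholds ordered by construction.
    """
    X = np.asarray(responses)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a persons x items array with at least 2 items")
    if np.any(X < 0):
        raise ValueError("calibration requires complete cases (no missing codes)")
    n, m = X.shape
    if item_ids is None:
        item_ids = [f"item_{j + 1}" for j in range(m)]
    grid = grid or default_grid()
    Q = grid.nodes.size

    n_cats = []
    for j in range(m):
        k = int(X[:, j].max()) + 1
        observed = np.unique(X[:, j])
        if observed.size < 2:
            raise ValueError(f"item {item_ids[j]!r} shows a single observed category")
        n_cats.append(k)

    # start values: a = 1, thresholds at the logits of marginal exceedance rates
    a = np.ones(m)
    b: list[np.ndarray] = []
    for j in range(m):
        props = np.array([(X[:, j] >= k).mean() for k in range(1, n_cats[j])])
        props = np.clip(props, 0.5 / n, 1 - 0.5 / n)
        # at theta=0 and a=1, P(X>=k) = expit(-b_k); invert the marginal rates
        bj = np.log((1 - props) / props)
        bj = np.maximum.accumulate(bj) + 1e-4 * np.arange(bj.size)
        b.append(bj)

    # person x node log-likelihood assembled from per-item tables each cycle
    loglik_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        tables = [category_probs(a[j], b[j], grid.nodes) for j in range(m)]
        logL = np.zeros((n, Q))
        for j in range(m):
            logL += np.log(np.clip(tables[j][:, X[:, j]].T, 1e-300, None))
        lw = logL + np.log(grid.weights)
        mx = lw.max(axis=1, keepdims=True)
        post = np.exp(lw - mx)
        marg = post.sum(axis=1)
        loglik = float(np.sum(np.log(marg) + mx.ravel()))
        loglik_path.append(loglik)
        post /= marg[:, None]

        max_change = 0.0
        for j in range(m):
            r = np.zeros((Q, n_cats[j]))
            for k in range(n_cats[j]):
                mask = X[:, j] == k
                if mask.any():
                    r[:, k] = post[mask].sum(axis=0)
            x0 = _pack(a[j], b[j])
            res = minimize(
                _item_neg_ell,
                x0,
                args=(r, grid.nodes),
                method="L-BFGS-B",
                options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
            )
            aj, bj = _unpack(res.x)
            max_change = max(max_change, abs(aj - a[j]), float(np.max(np.abs(bj - b[j]))))
            a[j], b[j] = aj, bj

        if max_change < tol:
            converged = True
            break

    params = GRMParams(list(item_ids), a, b)
    # final marginal log-likelihood at the accepted parameters
    tables = _item_prob_table(params, grid)
    logL = np.zeros((n, Q))
    for j in range(m):
        logL += np.log(np.clip(tables[j][:, X[:, j]].T, 1e-300, None))
    lw = logL + np.log(grid.weights)
    mx = lw.max(axis=1, keepdims=True)
    loglik = float(np.sum(np.log(np.exp(lw - mx).sum(axis=1)) + mx.ravel()))
    loglik_path.append(loglik)
    return CalibrationResult(params, loglik, it, converged, loglik_path)


# ---------------------------------------------------------------------------
# summed-score machinery


def sumscore_likelihoods(params: GRMParams, grid: QuadratureGrid) -> np.ndarray:
    """Lord-Wingersky recursion: P(sum = s | theta) for every achievable s.

    Returns an array of shape ``(max_score + 1, n_nodes)``; each column sums
    to 1 (the summed score is a complete partition of response patterns).
    """
    tables = _item_prob_table(params, grid)
    Q = grid.nodes.size
    L = tables[0].T.copy()  # (K0, Q) -> scores 0..K0-1
    for t in tables[1:]:
        K = t.shape[1]
        new = np.zeros((L.shape[0] + K - 1, Q))
        for k in range(K):
            new[k : k + L.shape[0]] += L * t[:, k]
        L = new
    return L


def eap_sum_table(params: GRMParams, grid: QuadratureGrid) -> "np.recarray":
    """EAP trait estimate and posterior SD for every achievable sum score.

    ``EAP(s) = sum_q theta_q L_s(theta_q) w_q / sum_q L_s(theta_q) w_q``.
    Returns a record array with fields ``score``, ``theta``, ``se`` and the
    model-implied marginal score probability ``prob``.
    """
    L = sumscore_likelihoods(params, grid)
    w = grid.weights
    post = L * w  # (S+1, Q)
    marg = post.sum(axis=1)
    theta = post @ grid.nodes / marg
    second = post @ (grid.nodes**2) / marg
    se = np.sqrt(np.maximum(second - theta**2, 0.0))
    out = np.recarray(L.shape[0], dtype=[("score", int), ("theta", float), ("se", float), ("prob", float)])
    out.score = np.arange(L.shape[0])
    out.theta = theta
    out.se = se
    out.prob = marg
    return out


def eap_pattern(
    responses: np.ndarray, params: GRMParams, grid: QuadratureGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Per-person EAP trait estimate (and posterior SD) from the full pattern."""
    X = np.asarray(responses)
    tables = _item_prob_table(params, grid)
    n = X.shape[0]
    logL = np.zeros((n, grid.nodes.size))
    for j in range(X.shape[1]):
        obs = X[:, j] >= 0
        lj = np.zeros((n, grid.nodes.size))
        lj[obs] = np.log(np.clip(tables[j][:, X[obs, j]].T, 1e-300, None))
        logL += lj
    lw = logL + np.log(grid.weights)
    mx = lw.max(axis=1, keepdims=True)
    post = np.exp(lw - mx)
    post /= post.sum(axis=1, keepdims=True)
    theta = post @ grid.nodes
    sd = np.sqrt(np.maximum(post @ grid.nodes**2 - theta**2, 0.0))
    return theta, sd


# ---------------------------------------------------------------------------
# S-X2 item fit


@dataclass
class ItemFitResult:
    item_ids: list[str]
    statistic: np.ndarray
    df: np.ndarray
    p_value: np.ndarray
    flagged: np.ndarray  # p < alpha
    alpha: float = 0.001


def _collapse_row(obs: np.ndarray, exp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent cells until every expected count is >= 1."""
    o = list(obs.astype(float))
    e = list(exp.astype(float))
    i = 0
    while i < len(e):
        if e[i] < 1.0 and len(e) > 1:
            j = i + 1 if i + 1 < len(e) else i - 1
            e[j] += e[i]
            o[j] += o[i]
            del e[i], o[i]
            if i > 0:
                i -= 1
        else:
            i += 1
    return np.array(o), np.array(e)


def expected_item_given_total(
    params: GRMParams, grid: QuadratureGrid, item_index: int
) -> np.ndarray:
    """Model-implied P(X_i = k | total = s): shape (max_score + 1, K_i).

    The numerator integrates the item's category curve against the
    Lord-Wingersky likelihood of the *remaining* items at the complementary
    rest score; rows for totals incompatible with a category are zero, and
    each achievable row sums to 1.
    """
    m = params.n_items
    j = item_index
    rest_ids = [params.item_ids[i] for i in range(m) if i != j]
    L_rest = sumscore_likelihoods(params.subset(rest_ids), grid)
    table = category_probs(params.a[j], params.b[j], grid.nodes)
    w = grid.weights
    K = table.shape[1]
    S = params.max_score
    out = np.zeros((S + 1, K))
    for s in range(S + 1):
        for k in range(K):
            if 0 <= s - k < L_rest.shape[0]:
                out[s, k] = np.sum(table[:, k] * L_rest[s - k] * w)
        tot = out[s].sum()
        if tot > 0:
            out[s] /= tot
    return out


def item_fit_s_chi2(
    responses: np.ndarray,
    params: GRMParams,
    grid: QuadratureGrid,
    alpha: float = 0.001,
) -> ItemFitResult:
    """Orlando-Thissen S-X2: observed vs expected category frequencies by sum score.

    For item *i* the model-expected probability of category *k* among persons
    with total score *s* is::

        E[k | s] = ∫ P_ik(theta) L*_{s-k}(theta) phi(theta) dtheta / P(S = s)

    where ``L*`` is the Lord-Wingersky likelihood of the remaining items
    (the rest score).  Adjacent cells with expected count < 1 are merged;
    rows left with fewer than 2 cells are dropped.  Degrees of freedom are
    the summed (cells - 1) minus the item's parameter count.
    """
    X = np.asarray(responses)
    if np.any(X < 0):
        raise ValueError("item fit requires complete cases")
    n, m = X.shape
    tables = _item_prob_table(params, grid)
    totals = X.sum(axis=1)

    stats_, dfs, ps = [], [], []
    for j in range(m):
        cond = expected_item_given_total(params, grid, j)
        K = tables[j].shape[1]
        S = params.max_score
        chi2 = 0.0
        df = 0
        for s in range(1, S):  # extreme totals carry no information about the item
            n_s = int((totals == s).sum())
            if n_s == 0:
                continue
            obs = np.array([(X[totals == s, j] == k).sum() for k in range(K)], dtype=float)
            o, e = _collapse_row(obs, n_s * cond[s])
            if e.size < 2:
                continue
            chi2 += float(np.sum((o - e) ** 2 / e))
            df += e.size - 1
        df -= 1 + (tables[j].shape[1] - 1)  # a + thresholds
        df = max(df, 1)
        stats_.append(chi2)
        dfs.append(df)
        ps.append(float(chi2_dist.sf(chi2, df)))

    stat = np.array(stats_)
    df_a = np.array(dfs)
    p = np.array(ps)
    return ItemFitResult(list(params.item_ids), stat, df_a, p, p < alpha, alpha)
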