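"""Network inference from multivariate abundance time series.

Five methods are provided, each mapping a sampled series to a directed
statistic matrix plus a p-value matrix, with entry ``(i, j)`` scoring the
effect of species ``j`` on species ``i``:

- Pearson and Spearman correlation (symmetric),
- local similarity analysis (LSA; symmetric, delay-aware),
- convergent cross mapping (CCM; asymmetric, embedding-based),
- sparse stepwise-bagging regression on log abundance ratios
  (LIMITS-style; asymmetric).

All stochastic steps (bootstraps, surrogates, bag splits) are driven by
an explicit seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .mediator_sim import SampledSeries

__all__ = [
    "InferenceResult",
    "LsaConfig",
    "CcmConfig",
    "LimitsConfig",
    "correlation_infer",
    "lsa_infer",
    "ccm_infer",
    "limits_infer",
    "infer",
    "normal_scores",
    "local_similarity",
    "cross_map_skill",
    "select_embedding_dim",
]

METHODS = ("pearson", "spearman", "lsa", "ccm", "limits")


@dataclass
class InferenceResult:
    """Directed statistic and p-value matrices from one method."""

    method: str
    stat: np.ndarray
    pval: np.ndarray
    symmetric: bool
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stat = np.asarray(self.stat, dtype=float)
        self.pval = np.asarray(self.pval, dtype=float)
        if self.stat.shape != self.pval.shape:
            raise ValueError("stat/pval shape mismatch")
        if np.any((self.pval < 0) | (self.pval > 1)):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.stat.shape[0]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "stat": self.stat.tolist(),
            "pval": self.pval.tolist(),
            "symmetric": self.symmetric,
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InferenceResult":
        return cls(
            method=d["method"],
            stat=np.asarray(d["stat"], dtype=float),
            pval=np.asarray(d["pval"], dtype=float),
            symmetric=bool(d["symmetric"]),
            config=d.get("config", {}),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "InferenceResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _series_matrix(series) -> np.ndarray:
    if isinstance(series, SampledSeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


# ---------------------------------------------------------------------------
# Pearson / Spearman
# ---------------------------------------------------------------------------


def correlation_infer(series, kind: str = "pearson") -> InferenceResult:
    """Pairwise correlation with two-sided p-values.

    Constant series yield statistic 0 and p-value 1 for every pair they
    participate in.
    """
    if kind not in ("pearson", "spearman"):
        raise ValueError("kind must be 'pearson' or 'spearman'")
    X = _series_matrix(series)
    T, n = X.shape
    if T < 3:
        raise ValueError("need at least 3 time points")
    stat = np.zeros((n, n))
    pval = np.ones((n, n))
    variable = X.std(axis=0) > 0
    for i in range(n):
        stat[i, i] = 1.0 if variable[i] else 0.0
        pval[i, i] = 0.0 if variable[i] else 1.0
        for j in range(i + 1, n):
            if not (variable[i] and variable[j]):
                continue
            if kind == "pearson":
                res = stats.pearsonr(X[:, i], X[:, j])
            else:
                res = stats.spearmanr(X[:, i], X[:, j])
            s, p = float(res.statistic), float(res.pvalue)
            if not np.isfinite(s):
                s, p = 0.0, 1.0
            stat[i, j] = stat[j, i] = s
            pval[i, j] = pval[j, i] = min(max(p, 0.0), 1.0)
    return InferenceResult(
        method=kind, stat=stat, pval=pval, symmetric=True, config={"kind": kind}
    )


# ---------------------------------------------------------------------------
# Local similarity analysis
# ---------------------------------------------------------------------------


@dataclass
class LsaConfig:
    max_delay: int = 3
    n_boot: int = 2000
    normalization: str = "normal_scores"  # rank-based inverse normal transform
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_delay < 0:
            raise ValueError("max_delay must be >= 0")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.normalization != "normal_scores":
            raise ValueError("only 'normal_scores' normalization is supported")


def normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, rank / (T + 1) quantiles."""
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x)
    return stats.norm.ppf(ranks / (len(x) + 1.0))


def _max_run_sums(products: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Maximal positive and minimal negative contiguous sums along the last
    axis (vectorized Kadane).  ``products`` may be 1-D or 2-D."""
    P = np.atleast_2d(products)
    best_pos = np.zeros(P.shape[0])
    best_neg = np.zeros(P.shape[0])
    cur_pos = np.zeros(P.shape[0])
    cur_neg = np.zeros(P.shape[0])
    for t in range(P.shape[1]):
        cur_pos = np.maximum(cur_pos + P[:, t], 0.0)
        cur_neg = np.minimum(cur_neg + P[:, t], 0.0)
        best_pos = np.maximum(best_pos, cur_pos)
        best_neg = np.minimum(best_neg, cur_neg)
    return best_pos, best_neg


def local_similarity(zx: np.ndarray, zy: np.ndarray, max_delay: int) -> float:
    """Signed maximal local similarity between two normal-score series.

    Scans every delay in ``[-max_delay, max_delay]``; within each
    alignment the strongest contiguous positive or negative sum of score
    products is found by dynamic programming.  The result is the signed
    extremum normalized by the series length.
    """
    T = len(zx)
    best = 0.0
    for d in range(-max_delay, max_delay + 1):
        if d >= 0:
            prod = zx[: T - d] * zy[d:]
        else:
            prod = zx[-d:] * zy[: T + d]
        pos, neg = _max_run_sums(prod)
        for v in (float(pos[0]), float(neg[0])):
            if abs(v) > abs(best):
                best = v
    return best / T


def _ls_batch(zx: np.ndarray, ZY: np.ndarray, max_delay: int) -> np.ndarray:
    """Local-similarity scores of one series against a batch of series."""
    T = len(zx)
    best = np.zeros(ZY.shape[0])
    for d in range(-max_delay, max_delay + 1):
        if d >= 0:
            prod = zx[None, : T - d] * ZY[:, d:]
        else:
            prod = zx[None, -d:] * ZY[:, : T + d]
        pos, neg = _max_run_sums(prod)
        take_pos = pos > -neg
        cand = np.where(take_pos, pos, neg)
        better = np.abs(cand) > np.abs(best)
        best = np.where(better, cand, best)
    return best / T


def lsa_infer(series, cfg: Optional[LsaConfig] = None) -> InferenceResult:
    """LSA on every species pair, permutation p-values.

    The p-value is the fraction of ``n_boot`` random permutations of one
    series whose absolute score reaches the observed one.  Output is
    symmetric (both delay signs are scanned, so either ordering of the
    pair gets the same score).
    """
    cfg = cfg or LsaConfig()
    X = _series_matrix(series)
    T, n = X.shape
    if T < 2 * cfg.max_delay + 3:
        raise ValueError("series too short for the configured max_delay")
    rng = np.random.default_rng(cfg.seed)
    variable = X.std(axis=0) > 0
    Z = np.zeros_like(X)
    for i in range(n):
        if variable[i]:
            Z[:, i] = normal_scores(X[:, i])
    stat = np.zeros((n, n))
    pval = np.ones((n, n))
    for i in range(n):
        if variable[i]:
            stat[i, i] = local_similarity(Z[:, i], Z[:, i], cfg.max_delay)
            pval[i, i] = 0.0
        for j in range(i + 1, n):
            if not (variable[i] and variable[j]):
                continue
            s = local_similarity(Z[:, i], Z[:, j], cfg.max_delay)
            perms = np.stack(
                [rng.permutation(Z[:, j]) for _ in range(cfg.n_boot)]
            )
            null = _ls_batch(Z[:, i], perms, cfg.max_delay)
            p = float(np.mean(np.abs(null) >= abs(s)))
            stat[i, j] = stat[j, i] = s
            pval[i, j] = pval[j, i] = p
    return InferenceResult(
        method="lsa", stat=stat, pval=pval, symmetric=True,
        config={"max_delay": cfg.max_delay, "n_boot": cfg.n_boot},
    )


# ---------------------------------------------------------------------------
# Convergent cross mapping
# ---------------------------------------------------------------------------


@dataclass
class CcmConfig:
    E_range: Tuple[int, ...] = (2, 3, 4, 5, 6)
    lag: int = 1
    n_surrogates: int = 100
    library: str = "full"  # cross-map from the full embedding library
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.E_range) < 2:
            raise ValueError("embedding dimensions must be >= 2")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.library != "full":
            raise ValueError("only 'full' library mode is supported")


def _embed(x: np.ndarray, E: int, lag: int) -> np.ndarray:
    """Delay-coordinate embedding; row t holds ``x[t], x[t-lag], ...``."""
    T = len(x)
    start = (E - 1) * lag
    idx = np.arange(start, T)[:, None] - np.arange(E)[None, :] * lag
    return x[idx]


def _knn_weights(emb: np.ndarray, k: int):
    """Leave-one-out k-nearest-neighbour indices and exponential weights."""
    d = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    idx = np.argsort(d, axis=1)[:, :k]
    dk = np.take_along_axis(d, idx, axis=1)
    dmin = dk[:, :1].copy()
    w = np.where(
        dmin > 0, np.exp(-dk / np.where(dmin > 0, dmin, 1.0)), (dk == 0).astype(float)
    )
    w_sum = w.sum(axis=1, keepdims=True)
    w_sum[w_sum == 0] = 1.0
    return idx, w / w_sum


def _skill(obs: np.ndarray, pred: np.ndarray) -> float:
    if obs.std() == 0 or pred.std() == 0:
        return 0.0
    return float(np.corrcoef(obs, pred)[0, 1])


def select_embedding_dim(
    x: np.ndarray, E_range: Sequence[int] = (2, 3, 4, 5, 6), lag: int = 1
) -> int:
    """Best embedding dimension by leave-one-out simplex self-forecast skill."""
    best_E, best_s = min(E_range), -np.inf
    for E in E_range:
        emb = _embed(x, E, lag)
        if len(emb) < E + 3:
            continue
        lib = emb[:-1]  # predict one step ahead
        target = x[(E - 1) * lag + 1 :]
        idx, w = _knn_weights(lib, E + 1)
        pred = (w * target[idx]).sum(axis=1)
        s = _skill(target, pred)
        if s > best_s:
            best_E, best_s = E, s
    return best_E


def cross_map_skill(
    source: np.ndarray, targets: np.ndarray, E: int, lag: int = 1
) -> np.ndarray:
    """Cross-map estimates of one or more target series from the
    embedding of ``source``; returns the skill per target row."""
    emb = _embed(source, E, lag)
    idx, w = _knn_weights(emb, E + 1)
    T2 = np.atleast_2d(targets)[:, (E - 1) * lag :]
    preds = np.einsum("lk,nlk->nl", w, T2[:, idx])
    return np.array([_skill(T2[i], preds[i]) for i in range(T2.shape[0])])


def ccm_infer(series, cfg: Optional[CcmConfig] = None) -> InferenceResult:
    """Cross mapping on all ordered pairs.

    ``stat[i, j]`` is the skill of reconstructing species ``j`` from the
    delay embedding of species ``i``; good reconstruction means ``j``
    drives ``i``.  P-values come from circular-shift surrogates of the
    target series, which preserve its autocorrelation.
    """
    cfg = cfg or CcmConfig()
    X = _series_matrix(series)
    T, n = X.shape
    if T < 4 * max(cfg.E_range):
        raise ValueError("series too short for the largest embedding dimension")
    rng = np.random.default_rng(cfg.seed)
    variable = X.std(axis=0) > 0
    E_sel = {
        i: select_embedding_dim(X[:, i], cfg.E_range, cfg.lag)
        for i in range(n) if variable[i]
    }
    stat = np.zeros((n, n))
    pval = np.ones((n, n))
    for i in range(n):
        if not variable[i]:
            continue
        E = E_sel[i]
        emb = _embed(X[:, i], E, cfg.lag)
        idx, w = _knn_weights(emb, E + 1)
        offset = (E - 1) * cfg.lag
        for j in range(n):
            if j == i or not variable[j]:
                continue
            y = X[:, j]
            shifts = rng.integers(1, T, size=cfg.n_surrogates)
            surro = np.stack([np.roll(y, int(s)) for s in shifts])
            batch = np.vstack([y[None, :], surro])[:, offset:]
            preds = np.einsum("lk,nlk->nl", w, batch[:, idx])
            skills = np.array(
                [_skill(batch[k], preds[k]) for k in range(batch.shape[0])]
            )
            stat[i, j] = skills[0]
            pval[i, j] = float(np.mean(skills[1:] >= skills[0]))
    return InferenceResult(
        method="ccm", stat=stat, pval=pval, symmetric=False,
        config={"E_range": list(cfg.E_range), "lag": cfg.lag,
                "n_surrogates": cfg.n_surrogates,
                "E_selected": {str(k): int(v) for k, v in E_sel.items()}},
    )


# ---------------------------------------------------------------------------
# LIMITS-style sparse regression
# ---------------------------------------------------------------------------


@dataclass
class LimitsConfig:
    n_bags: int = 500
    vote_threshold: float = 0.5
    improvement_tol: float = 1e-3
    dt_effective: float = 1.0
    floor: float = 1e-7
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_bags < 1:
            raise ValueError("n_bags must be >= 1")
        if not (0 < self.vote_threshold < 1):
            raise ValueError("vote_threshold must be in (0, 1)")


def _ols_residual_stats(Xin, yin, Xout, yout):
    coef, *_ = np.linalg.lstsq(Xin, yin, rcond=None)
    resid = yout - Xout @ coef
    return coef, float(np.mean(resid**2))


def _stepwise_bag(
    X: np.ndarray, y: np.ndarray, focal: int, in_idx, out_idx, tol: float
) -> Tuple[np.ndarray, list]:
    """One forward-stepwise fit: start from intercept + self term, greedily
    add the predictor with the largest out-of-bag error decrease while the
    relative decrease exceeds ``tol``.  Returns (coefficients over all
    predictors incl. intercept at position 0, selected indices)."""
    T, n = X.shape
    ones = np.ones(T)
    selected = [focal]
    design = np.column_stack([ones, X[:, focal]])
    coef, err = _ols_residual_stats(
        design[in_idx], y[in_idx], design[out_idx], y[out_idx]
    )
    remaining = [j for j in range(n) if j != focal]
    while remaining and err > 1e-15:
        best_j, best_err, best_coef = None, err, None
        for j in remaining:
            cand = np.column_stack([design, X[:, j]])
            c, e = _ols_residual_stats(cand[in_idx], y[in_idx], cand[out_idx], y[out_idx])
            if e < best_err:
                best_j, best_err, best_coef = j, e, c
        if best_j is None:
            break
        if err > 0 and (err - best_err) / err <= tol:
            break
        design = np.column_stack([design, X[:, best_j]])
        selected.append(best_j)
        remaining.remove(best_j)
        coef, err = best_coef, best_err
    full = np.zeros(n + 1)
    full[0] = coef[0]
    for pos, j in enumerate(selected):
        full[j + 1] = coef[pos + 1]
    return full, selected


def limits_infer(series, cfg: Optional[LimitsConfig] = None) -> InferenceResult:
    """Sparse interaction inference by stepwise regression with bagging.

    The response for focal species ``i`` is the log change per sample,
    ``ln(x_i(t+1) / x_i(t))``; predictors are the abundances at time
    ``t``.  Each bag holds out half of the transitions for model
    selection; a predictor enters the final model when selected in more
    than ``vote_threshold`` of the bags, with the median in-bag
    coefficient (rescaled to per-day units by ``dt_effective``) as its
    statistic.  ``pval[i, j]`` is the fraction of bags in which the
    coefficient was zero.
    """
    cfg = cfg or LimitsConfig()
    X = _series_matrix(series)
    X = np.maximum(X, cfg.floor)
    T, n = X.shape
    n_trans = T - 1
    if n_trans < 10:
        raise ValueError("need at least 10 usable transitions")
    rng = np.random.default_rng(cfg.seed)
    Y = np.log(X[1:] / X[:-1])  # (T-1, n)
    Xp = X[:-1]

    stat = np.zeros((n, n))
    pval = np.ones((n, n))
    half = n_trans // 2
    for i in range(n):
        coefs = np.zeros((cfg.n_bags, n))
        chosen = np.zeros((cfg.n_bags, n), dtype=bool)
        for b in range(cfg.n_bags):
            perm = rng.permutation(n_trans)
            in_idx, out_idx = perm[:half], perm[half:]
            full, selected = _stepwise_bag(
                Xp, Y[:, i], i, in_idx, out_idx, cfg.improvement_tol
            )
            coefs[b] = full[1:]
            chosen[b, selected] = True
        votes = chosen.mean(axis=0)
        for j in range(n):
            present = votes[j] > cfg.vote_threshold
            if present:
                sel = coefs[chosen[:, j], j]
                stat[i, j] = float(np.median(sel)) / cfg.dt_effective
            pval[i, j] = float(np.mean(~chosen[:, j]))
    return InferenceResult(
        method="limits", stat=stat, pval=pval, symmetric=False,
        config={"n_bags": cfg.n_bags, "vote_threshold": cfg.vote_threshold,
                "improvement_tol": cfg.improvement_tol,
                "dt_effective": cfg.dt_effective},
    )


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def infer(series, method: str, seed: Optional[int] = None, **kwargs) -> InferenceResult:
    """Run one method by name; bootstrap counts etc. via keyword overrides."""
    if method in ("pearson", "spearman"):
        return correlation_infer(series, kind=method)
    if method == "lsa":
        return lsa_infer(series, LsaConfig(seed=seed, **kwargs))
    if method == "ccm":
        return ccm_infer(series, CcmConfig(seed=seed, **kwargs))
    if method == "limits":
        return limits_infer(series, LimitsConfig(seed=seed, **kwargs))
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
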