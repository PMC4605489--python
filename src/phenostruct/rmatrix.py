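"""Between-group variance apportionment (Fst) from quantitative traits.

The phenotypic R-matrix approach treats group mean vectors as the outcome
of divergence from a common centroid.  Mean deviations are whitened by the
(heritability-scaled) pooled within-group covariance G = h²·W and averaged
over traits, giving the codivergence matrix

    c_ij = (1/t) (m_i - xbar)' G^{-1} (m_j - xbar),

with xbar the weighted grand mean.  Under the neutral-divergence model the
weighted mean of the diagonal, c̄, relates to the apportionment Fst through
r_ij = c_ij (1 - Fst)/2 and Fst = Σ w_i r_ii, whose unique solution is

    Fst = c̄ / (2 + c̄).

Phenotypic Fst is a *minimum* estimate: heritability h² < 1 deflates the
genetic signal, and a constant h² = 0.55 is the conventional compromise for
human cranial dimensions.

Two finite-sample biases affect c̄ when estimated from data and the optional
``bias_correction`` removes both (see docs/methods.md): the sampling noise
of each group mean inflates c_ii by (1-w_i)²/(h²n_i) + Σ_{j≠i} w_j²/(h²n_j)
(equal to the classical (1-w_i)/(h²n_i) under sample-size weights), and
estimating the grand mean from the same groups deflates the diagonal by the
factor (1 - 2w_i + Σw_j²).  With the correction off the estimator is the
plain contemporary-centroid form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PooledCovariance:
    """Pooled within-group covariance W with Σ(n_i - 1) degrees of freedom."""

    matrix: np.ndarray
    dof: int
    series: list[str] = field(default_factory=list)


@dataclass
class FstConfig:
    h2: float = 0.55
    weights: str = "sample_size"          # or "equal"
    bias_correction: bool = True
    negative_diagonal: str = "truncate_zero"   # or "keep"

    def __post_init__(self) -> None:
        if not 0 < self.h2 <= 1:
            raise ValueError("heritability h2 must be in (0, 1]")
        if self.weights not in {"sample_size", "equal"}:
            raise ValueError(f"unknown weighting {self.weights!r}")
        if self.negative_diagonal not in {"truncate_zero", "keep"}:
            raise ValueError(f"unknown diagonal handling {self.negative_diagonal!r}")


@dataclass
class RMatrixResult:
    labels: list[str]
    means: np.ndarray           # K x t group means
    weights: np.ndarray         # normalized w_i
    c: np.ndarray               # codivergence matrix
    r: np.ndarray               # R-matrix, r_ij = c_ij (1 - Fst) / 2
    fst: float
    se: float | None
    config: FstConfig


def group_weights(n: np.ndarray, scheme: str) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if scheme == "equal":
        return np.full(len(n), 1.0 / len(n))
    return n / n.sum()


def pooled_within_covariance(groups: dict[str, np.ndarray]) -> PooledCovariance:
    """Degrees-of-freedom-weighted average of per-group sample covariances.

    W = Σ_i (n_i - 1) S_i / Σ_i (n_i - 1), each S_i with ddof=1.
    """
    if not groups:
        raise ValueError("no groups")
    t = next(iter(groups.values())).shape[1]
    acc = np.zeros((t, t))
    dof = 0
    for label, x in groups.items():
        n = x.shape[0]
        if n < 2:
            raise ValueError(f"group {label!r} has n={n} < 2")
        acc += (n - 1) * np.cov(x, rowvar=False, ddof=1)
        dof += n - 1
    return PooledCovariance(matrix=acc / dof, dof=dof, series=list(groups))


def _solve_spd(W: np.ndarray, B: np.ndarray) -> np.ndarray:
    """W^{-1} B via Cholesky; raises a helpful error when W is singular."""
    try:
        L = np.linalg.cholesky(W)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled within-group covariance is singular; reduce the variable "
            "set or pool more series"
        ) from exc
    y = np.linalg.solve(L, B)
    return np.linalg.solve(L.T, y)


def codivergence(
    means: np.ndarray,
    W: np.ndarray,
    n: np.ndarray,
    config: FstConfig = FstConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Codivergence matrix c_ij of group means around their weighted centroid.

    Returns ``(c, weights)``.  With ``bias_correction`` on, the diagonal is
    additionally unbiased for mean-sampling noise and centroid deflation so
    that Σ w_i c_ii estimates 2F/(1-F) for true apportionment F.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    K, t = means.shape
    if K < 2:
        raise ValueError("need at least 2 groups")
    n = np.asarray(n, dtype=float)
    w = group_weights(n, config.weights)
    xbar = w @ means
    dev = means - xbar
    whitened = _solve_spd(config.h2 * np.atleast_2d(W), dev.T)   # G^{-1} dev'
    c = dev @ whitened / t

    if config.bias_correction:
        s2 = float(w @ w)
        sampling = ((1 - w) ** 2 / (config.h2 * n)
                    + (w ** 2 / (config.h2 * n)).sum()
                    - w ** 2 / (config.h2 * n))
        deflation = 1.0 - 2.0 * w + s2
        diag = (np.diag(c) - sampling) / deflation
        c = c.copy()
        np.fill_diagonal(c, diag)
    if config.negative_diagonal == "truncate_zero":
        diag = np.diag(c).copy()
        if (diag < 0).any():
            logger.warning("truncating %d negative diagonal elements to 0",
                           int((diag < 0).sum()))
        np.fill_diagonal(c, np.maximum(diag, 0.0))
    return c, w


def fst_from_codivergence(
    c: np.ndarray, weights: np.ndarray,
    labels: list[str] | None = None,
    means: np.ndarray | None = None,
    config: FstConfig = FstConfig(),
) -> RMatrixResult:
    """Fst and the R-matrix from a codivergence matrix.

    Solves Fst = Σ w_i r_ii with r_ij = c_ij (1 - Fst)/2 in closed form:
    Fst = c̄/(2 + c̄) where c̄ = Σ w_i c_ii.
    """
    c = np.asarray(c, dtype=float)
    w = np.asarray(weights, dtype=float)
    cbar = float(w @ np.diag(c))
    if cbar < 0:
        if config.negative_diagonal == "truncate_zero":
            logger.warning("negative mean codivergence %.3g clamped to 0", cbar)
            cbar = 0.0
        # keep: Fst comes out negative, caller asked for it
    fst = cbar / (2.0 + cbar)
    r = c * (1.0 - fst) / 2.0
    K = c.shape[0]
    return RMatrixResult(
        labels=list(labels) if labels is not None else [str(i) for i in range(K)],
        means=means if means is not None else np.empty((K, 0)),
        weights=w, c=c, r=r, fst=fst, se=None, config=config,
    )


def estimate_fst(
    groups: dict[str, np.ndarray],
    config: FstConfig = FstConfig(),
    W: np.ndarray | None = None,
    with_se: bool = True,
) -> RMatrixResult:
    """End-to-end Fst for a set of groups given their raw value matrices.

    ``W`` defaults to the pooled within-group covariance of these groups;
    pass a global W to use a wider pooling scope.
    """
    labels = list(groups)
    means = np.vstack([groups[g].mean(axis=0) for g in labels])
    n = np.array([groups[g].shape[0] for g in labels])
    if W is None:
        W = pooled_within_covariance(groups).matrix
    c, w = codivergence(means, W, n, config)
    result = fst_from_codivergence(c, w, labels=labels, means=means, config=config)
    if with_se and means.shape[1] >= 2:
        result = replace(result, se=fst_standard_error(means, W, n, config))
    return result


def fst_standard_error(
    means: np.ndarray, W: np.ndarray, n: np.ndarray,
    config: FstConfig = FstConfig(),
) -> float:
    """Delete-one-trait jackknife standard error of Fst.

    Fst is recomputed leaving each trait out in turn;
    SE = sqrt(((t-1)/t) Σ_k (Fst_(-k) - mean)²).
    """
    means = np.atleast_2d(means)
    t = means.shape[1]
    if t < 2:
        raise ValueError("jackknife SE needs at least 2 traits")
    W = np.atleast_2d(W)
    pseudo = np.empty(t)
    for k in range(t):
        keep = np.arange(t) != k
        c, w = codivergence(means[:, keep], W[np.ix_(keep, keep)], n, config)
        pseudo[k] = fst_from_codivergence(c, w, config=config).fst
    return float(np.sqrt((t - 1) / t * ((pseudo - pseudo.mean()) ** 2).sum()))


def pairwise_fst(
    groups: dict[str, np.ndarray],
    W_global: PooledCovariance | np.ndarray | None = None,
    config: FstConfig = FstConfig(),
) -> tuple[np.ndarray, list[str]]:
    """K x K matrix of two-group Fst values usable as distances.

    Each entry uses the *global* pooled within-group covariance (small
    archaeological series give unreliable pairwise pooled covariances), the
    pair's own weights and the pair's own grand mean.  Symmetric with a
    zero diagonal.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 series")
    if W_global is None:
        W = pooled_within_covariance(groups).matrix
    elif isinstance(W_global, PooledCovariance):
        W = W_global.matrix
    else:
        W = np.asarray(W_global, dtype=float)
    K = len(labels)
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            pair = {labels[i]: groups[labels[i]], labels[j]: groups[labels[j]]}
            fst = estimate_fst(pair, config=config, W=W, with_se=False).fst
            out[i, j] = out[j, i] = max(fst, 0.0)
    return out, labels
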