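"""Non-metric MDS of Fst distance matrices, with Procrustes bootstrap.

The pairwise-Fst matrix among series is visualised with Kruskal non-metric
multidimensional scaling: find planar coordinates whose inter-point
distances are monotonically related to the input dissimilarities, by
minimizing stress-1

    stress = sqrt( Σ_{i<j} (d_ij - δ̂_ij)² / Σ_{i<j} d_ij² )

where d are configuration distances and δ̂ are disparities from monotone
(isotonic) regression of d on the dissimilarity order.  The optimizer is
SMACOF majorization alternated with pooled-adjacent-violators, initialized
from classical (metric) scaling plus seeded random restarts.  Because the
stress-1 denominator moves with the configuration, an iteration that would
increase stress-1 terminates the run keeping the previous configuration,
so the recorded stress history is non-increasing by construction.

Confidence in an ordination is shown by bootstrap: individuals are
resampled with replacement within every series at the original sample
sizes, the pairwise-Fst matrix and its MDS are recomputed, and each
replicate configuration is Procrustes-superimposed (translation, rotation,
reflection, scaling) onto the original for overplotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .rmatrix import FstConfig, pairwise_fst

logger = logging.getLogger(__name__)


@dataclass
class MdsConfiguration:
    coords: np.ndarray          # K x dims
    stress: float
    n_iter: int
    seed: int
    converged: bool
    labels: list[str] = field(default_factory=list)
    stress_history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ProcrustesFit:
    rotation: np.ndarray        # dims x dims orthogonal
    scale: float
    translation: np.ndarray
    coords: np.ndarray          # target after superimposition
    statistic: float            # ||ref - fitted||² / ||ref centered||²


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


def classical_scaling(D: np.ndarray, dims: int = 2) -> np.ndarray:
    """Torgerson metric scaling; the deterministic NMDS starting point."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    X = vecs[:, order] * np.sqrt(lam)
    # sign convention: largest-|.| coordinate of each axis positive
    for k in range(X.shape[1]):
        i = np.argmax(np.abs(X[:, k]))
        if X[i, k] < 0:
            X[:, k] = -X[:, k]
    return X


def _disparities(d: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Monotone fit of configuration distances in dissimilarity order."""
    disp = np.empty_like(d)
    iso = IsotonicRegression(increasing=True)
    disp[order] = iso.fit_transform(np.arange(len(d)), d[order])
    return disp


def _stress1(d: np.ndarray, disp: np.ndarray) -> float:
    denom = float((d ** 2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(((d - disp) ** 2).sum() / denom))


def _smacof_run(delta: np.ndarray, X: np.ndarray, max_iter: int,
                tol: float) -> tuple[np.ndarray, float, int, bool, np.ndarray]:
    n = X.shape[0]
    # primary tie handling: within tied dissimilarities, order by current
    # distance so the monotone fit is free inside tie blocks
    d = pdist(X)
    order = np.lexsort((d, delta))
    disp = _disparities(d, order)
    stress = _stress1(d, disp)
    history = [stress]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # Guttman transform with current disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, disp / d, 0.0)
        Bflat = -squareform(ratio)
        np.fill_diagonal(Bflat, -Bflat.sum(axis=1))
        X_new = Bflat @ X / n
        d_new = pdist(X_new)
        order = np.lexsort((d_new, delta))
        disp_new = _disparities(d_new, order)
        stress_new = _stress1(d_new, disp_new)
        if stress_new > stress:            # monotone safeguard
            converged = True
            break
        X, d, disp = X_new, d_new, disp_new
        improvement = stress - stress_new
        stress = stress_new
        history.append(stress)
        if improvement < tol:
            converged = True
            break
    return X, stress, it, converged, np.asarray(history)


def nmds(
    D: np.ndarray,
    dims: int = 2,
    seed: int = 0,
    n_restarts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-6,
    labels: list[str] | None = None,
) -> MdsConfiguration:
    """Kruskal non-metric MDS of a symmetric zero-diagonal distance matrix.

    Best of ``n_restarts`` runs (classical-scaling start plus seeded random
    starts); deterministic for a fixed seed.
    """
    D = _check_distance_matrix(D)
    K = D.shape[0]
    if K < 3:
        raise ValueError("NMDS needs at least 3 points")
    delta = squareform(D, checks=False)
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            X0 = classical_scaling(D, dims)
        else:
            X0 = rng.standard_normal((K, dims)) * (delta.max() or 1.0)
        X, stress, it, conv, hist = _smacof_run(delta, X0, max_iter, tol)
        if best is None or stress < best.stress - 1e-15:
            best = MdsConfiguration(coords=X, stress=stress, n_iter=it,
                                    seed=seed, converged=conv,
                                    labels=list(labels) if labels else [],
                                    stress_history=hist)
    return best


def procrustes_superimpose(
    reference: np.ndarray,
    target: np.ndarray,
    allow_scaling: bool = True,
    allow_reflection: bool = True,
) -> ProcrustesFit:
    """Least-squares similarity superimposition of target onto reference.

    Solves min ||ref_c - s · tgt_c · R||² over rotation R (optionally with
    reflection), scale s > 0 (optional) and translation.  The statistic is
    the residual sum of squares normalized by ||ref_c||²; 0 iff the shapes
    are identical up to the allowed transforms.  Two fully degenerate
    (single-point) configurations superimpose exactly with statistic 0.
    """
    A = np.asarray(target, dtype=float)
    B = np.asarray(reference, dtype=float)
    if A.shape != B.shape:
        raise ValueError("reference and target shapes differ")
    mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - mu_a, B - mu_b
    norm_a, norm_b = float((Ac ** 2).sum()), float((Bc ** 2).sum())
    dims = A.shape[1]
    eps = np.finfo(float).eps
    if norm_b <= eps * B.shape[0]:
        stat = 0.0 if norm_a <= eps * A.shape[0] else 1.0
        return ProcrustesFit(rotation=np.eye(dims), scale=1.0,
                             translation=mu_b - mu_a,
                             coords=np.broadcast_to(mu_b, A.shape).copy(),
                             statistic=stat)
    U, sigma, Vt = np.linalg.svd(Ac.T @ Bc)
    flip = np.ones(dims)
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        flip[-1] = -1.0
    R = (U * flip) @ Vt
    trace = float(sigma @ flip)
    if allow_scaling and norm_a > 0:
        s = max(trace / norm_a, eps)
    else:
        s = 1.0
    fitted = s * Ac @ R + mu_b
    translation = mu_b - s * mu_a @ R
    stat = float(((Bc - s * Ac @ R) ** 2).sum() / norm_b)
    return ProcrustesFit(rotation=R, scale=s, translation=translation,
                         coords=fitted, statistic=stat)


def bootstrap_mds(
    groups: dict[str, np.ndarray],
    reps: int = 100,
    seed: int = 0,
    fst_config: FstConfig = FstConfig(),
    dims: int = 2,
    n_restarts: int = 4,
    distance=None,
) -> tuple[MdsConfiguration, list[MdsConfiguration], int]:
    """Original NMDS plus superimposed bootstrap replicate configurations.

    Each replicate resamples individuals with replacement within every
    series to its original n, recomputes the pairwise distance matrix
    (pairwise Fst by default; ``distance`` may supply any
    ``groups -> matrix`` callable) and its NMDS, and Procrustes-superimposes
    it onto the original configuration.  Returns
    (original, replicates, n_dropped); replicates whose pooled within-group
    covariance is singular are dropped with a warning.
    """
    if len(groups) < 3:
        raise ValueError("bootstrap ordination needs at least 3 series")
    labels = list(groups)
    if distance is None:
        def distance(g):
            return pairwise_fst(g, config=fst_config)[0]
    D0 = distance(groups)
    original = nmds(D0, dims=dims, seed=seed, n_restarts=n_restarts,
                    labels=labels)
    rng = np.random.default_rng(seed)
    replicates: list[MdsConfiguration] = []
    dropped = 0
    for _ in range(reps):
        boot = {g: x[rng.integers(0, len(x), size=len(x))]
                for g, x in groups.items()}
        try:
            D = distance(boot)
        except np.linalg.LinAlgError:
            dropped += 1
            logger.warning("bootstrap replicate dropped: singular pooled W")
            continue
        conf = nmds(D, dims=dims, seed=seed, n_restarts=n_restarts,
                    labels=labels)
        fit = procrustes_superimpose(original.coords, conf.coords)
        replicates.append(MdsConfiguration(
            coords=fit.coords, stress=conf.stress, n_iter=conf.n_iter,
            seed=seed, converged=conf.converged, labels=labels,
            stress_history=conf.stress_history))
    if dropped:
        logger.warning("%d of %d bootstrap replicates dropped", dropped, reps)
    return original, replicates, dropped
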