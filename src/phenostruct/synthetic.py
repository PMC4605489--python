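"""Synthetic craniometric-like data with known population structure.

The generator produces K series of multivariate-normal linear measurements
with a shared within-group covariance W0, group means diverged to a chosen
true apportionment F, optional sex dimorphism, and MCAR missingness — the
statistical structure the analysis pipeline assumes, with every parameter
known, so estimators can be tested closed-loop.

Generative model: group means are drawn

    mu_i ~ MVN(mu0, (2F/(1-F)) * h² * W0)

and individuals ~ MVN(mu_i ± δ/2, W0) (+δ/2 for males, -δ/2 for females).
The between-group scale 2F/(1-F) is the inverse of the R-matrix estimator's
model, so the estimator is calibrated in expectation: its corrected mean
diagonal estimates 2F/(1-F) and F is recovered through F = c̄/(2+c̄).
Each cell is masked independently with probability ``missing_rate``
(rows are re-masked if a draw leaves an individual with no measurements).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_tables import HOWELLS_VARIABLES, CraniometricTable


@dataclass
class SyntheticConfig:
    k: int = 10
    t: int = 23
    n: int | list[int] = 100
    fst: float = 0.1
    h2: float = 0.55
    w0: np.ndarray | None = None          # within-group covariance template
    mu0: np.ndarray | None = None         # grand mean (mm scale)
    dimorphism: np.ndarray | float = 0.0  # +δ/2 for M, -δ/2 for F
    sex_ratio: float = 0.5                # expected fraction of males
    missing_rate: float = 0.0
    seed: int = 0

    def sample_sizes(self) -> np.ndarray:
        n = self.n
        sizes = np.full(self.k, n) if np.isscalar(n) else np.asarray(n)
        if len(sizes) != self.k:
            raise ValueError("per-group sample sizes must have length k")
        if (sizes < 2).any():
            raise ValueError("every group needs n >= 2")
        return sizes.astype(int)

    def validate(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError("true Fst must be in [0, 1)")
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        self.sample_sizes()


@dataclass
class SyntheticTruth:
    group_means: np.ndarray       # true mu_i, K x t
    sample_means: np.ndarray      # realized per-group means of the data
    fst: float
    config: SyntheticConfig = field(repr=False, default=None)


# mm-scale grand means for the 23 cranial variables (plausible magnitudes
# for adult human crania; only the scale matters for the simulations)
_TEMPLATE_MEANS = np.array([
    180.0, 178.0, 134.0, 138.0, 115.0, 122.0, 108.0, 68.0, 51.0, 34.0,
    39.0, 117.0, 25.0, 94.0, 97.0, 16.0, 97.0, 36.0, 53.0, 23.0,
    112.0, 113.0, 97.0,
])

# mm-scale within-group standard deviations, same variable order
_TEMPLATE_SDS = np.array([
    6.2, 6.1, 5.0, 5.1, 4.9, 4.6, 4.2, 4.3, 2.9, 1.9,
    1.8, 4.4, 1.8, 4.4, 4.0, 2.1, 3.8, 2.6, 3.3, 2.4,
    4.4, 5.3, 4.9,
])


def make_within_covariance(t: int = 23, mode: str = "template",
                           seed: int = 0) -> np.ndarray:
    """A symmetric positive-definite within-group covariance.

    ``template`` returns a fixed 23-variable (or leading-t submatrix)
    covariance with millimeter-scale variances and a craniometric-like
    correlation structure: a general size factor giving a baseline
    inter-trait correlation of 0.3 plus local (module-like) AR structure,
    bit-stable across calls.  ``random`` returns a seeded random SPD matrix
    with condition number <= 1e4.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if mode == "template":
        if t > len(_TEMPLATE_SDS):
            raise ValueError("template covers at most 23 variables")
        sd = _TEMPLATE_SDS[:t]
        idx = np.arange(t)
        ar = 0.45 ** np.abs(idx[:, None] - idx[None, :])
        corr = 0.3 + 0.7 * ar          # sum of PSD parts; diagonal = 1
        return corr * np.outer(sd, sd)
    if mode == "random":
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((t, t + 2))
        S = A @ A.T / (t + 2)
        vals, vecs = np.linalg.eigh(S)
        vals = np.clip(vals, vals.max() / 1e4, None)
        sd = rng.uniform(1.5, 7.0, size=t)      # mm scale
        S = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(S))
        return (S / np.outer(d, d)) * np.outer(sd, sd)
    raise ValueError(f"unknown mode {mode!r}")


def _check_spd(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W0 must be symmetric")
    try:
        np.linalg.cholesky(W)
    except np.linalg.LinAlgError as exc:
        raise ValueError("W0 must be positive-definite") from exc
    return W


def simulate_dataset(config: SyntheticConfig) -> tuple[CraniometricTable, SyntheticTruth]:
    """Draw a multi-series dataset with known truth; reproducible from seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = config.t
    W0 = _check_spd(config.w0 if config.w0 is not None
                    else make_within_covariance(t, "template"))
    mu0 = (np.asarray(config.mu0, dtype=float) if config.mu0 is not None
           else _TEMPLATE_MEANS[:t] if t <= len(_TEMPLATE_MEANS)
           else np.full(t, 100.0))
    delta = np.broadcast_to(np.asarray(config.dimorphism, dtype=float), (t,))
    sizes = config.sample_sizes()
    alpha = 2.0 * config.fst / (1.0 - config.fst)
    if config.fst > 0:
        mu = rng.multivariate_normal(mu0, alpha * config.h2 * W0,
                                     size=config.k, method="cholesky")
    else:
        mu = np.tile(mu0, (config.k, 1))

    rows_id, rows_series, rows_sex, blocks = [], [], [], []
    for i in range(config.k):
        n_i = sizes[i]
        sex = np.where(rng.random(n_i) < config.sex_ratio, "M", "F")
        shift = np.where(sex[:, None] == "M", delta / 2.0, -delta / 2.0)
        x = rng.multivariate_normal(np.zeros(t), W0, size=n_i,
                                    method="cholesky") + mu[i] + shift
        blocks.append(x)
        rows_series += [f"G{i + 1:02d}"] * n_i
        rows_sex += list(sex)
        rows_id += [f"G{i + 1:02d}_{j + 1:03d}" for j in range(n_i)]
    values = np.vstack(blocks)
    values = np.maximum(values, np.finfo(float).eps)   # measurements are positive

    mask = np.zeros(values.shape, dtype=bool)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        for r in np.flatnonzero(mask.all(axis=1)):   # keep >= 1 observed value
            mask[r, rng.integers(0, t)] = False

    variables = list(HOWELLS_VARIABLES[:t]) if t <= 23 else \
        [f"V{j}" for j in range(t)]
    if t > 23:
        raise ValueError("at most 23 variables are supported")
    series_arr = np.array(rows_series, dtype=object)
    table = CraniometricTable(
        individual_id=np.array(rows_id, dtype=object),
        series=series_arr,
        region=np.array(["synthetic"] * len(rows_id), dtype=object),
        sex=np.array(rows_sex, dtype=object),
        values=values,
        mask=mask,
        variables=variables,
    )
    sample_means = np.vstack([values[series_arr == f"G{i + 1:02d}"].mean(axis=0)
                              for i in range(config.k)])
    return table, SyntheticTruth(group_means=mu, sample_means=sample_means,
                                 fst=config.fst, config=config)
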