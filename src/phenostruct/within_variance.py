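"""Within-series variance: covariance trace and matched-n resampling.

The scalar summary of a series' morphological variability is the trace of
the covariance matrix of its Z-scored measurements.  Because a variance
estimate depends on sample size, a small series is compared with a larger
reference series through the distribution of traces of random subsets of
the reference drawn at the small series' n (without replacement), repeated
many times (default 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class WithinVarianceResult:
    series: str
    n: int
    trace: float


@dataclass
class TraceDistribution:
    reference_series: str
    m: int                       # subset size actually used (after clamping)
    m_requested: int
    reps: int
    seed: int
    traces: np.ndarray = field(default_factory=lambda: np.empty(0))
    clamped: bool = False


def covariance_trace(z: np.ndarray) -> float:
    """Trace of the (ddof=1) covariance matrix of row-observations."""
    if z.shape[0] < 2:
        raise ValueError("trace needs at least 2 individuals")
    return float(z.var(axis=0, ddof=1).sum())


def vcv_trace(z: np.ndarray, series: np.ndarray, label: str) -> WithinVarianceResult:
    """Observed covariance trace of one series of Z-scored data."""
    rows = series == label
    n = int(rows.sum())
    if n < 2:
        raise ValueError(f"series {label!r} has n={n} < 2; variance undefined")
    return WithinVarianceResult(series=label, n=n, trace=covariance_trace(z[rows]))


def subsample_trace_distribution(
    z: np.ndarray,
    series: np.ndarray,
    reference_series: str,
    m: int,
    reps: int = 1000,
    seed: int = 0,
) -> TraceDistribution:
    """Traces of ``reps`` random subsets of size ``m`` from a reference series.

    Subsets are drawn without replacement.  When the reference series has
    fewer than ``m`` individuals the whole series is used (m clamped to n,
    flagged) — the convention for series smaller than the target series.
    Deterministic for a fixed seed.
    """
    if m < 2:
        raise ValueError("subset size m must be >= 2")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = z[series == reference_series]
    n = rows.shape[0]
    if n < 2:
        raise ValueError(f"reference series {reference_series!r} has n < 2")
    m_used, clamped = (n, True) if m > n else (m, False)
    rng = np.random.default_rng(seed)
    traces = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(n, size=m_used, replace=False)
        traces[r] = covariance_trace(rows[idx])
    return TraceDistribution(
        reference_series=reference_series, m=m_used, m_requested=m,
        reps=reps, seed=seed, traces=traces, clamped=clamped,
    )
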