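"""Missing-value regression imputation and Z-score standardization.

Archaeological cranial series routinely have broken or eroded landmarks, so
some measurements are missing.  Before any variance analysis each missing
cell is filled by ordinary least squares: the missing variable is regressed,
over complete cases, on the variables that individual *does* have, and the
fitted value is substituted.  Small series can lack enough complete cases to
support the full predictor set; the predictor set is then reduced to the
most correlated observed variables, and as a last resort the scope mean of
the variable is substituted.

Standardization converts each variable to Z-scores against a stated
reference set of individuals (by default the pooled run), which puts all
variables on a common scale so that the trace of a covariance matrix is a
meaningful scalar summary of within-group variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_tables import CraniometricTable

logger = logging.getLogger(__name__)


@dataclass
class ImputationRecord:
    individual_id: str
    variable: str
    predictors: list[str]
    fitted_value: float
    n_training: int
    method: str  # "ols" | "mean"


@dataclass
class StandardizationModel:
    """Per-variable (mean, SD) over a reference set; SD uses ddof=1."""

    variables: list[str]
    mean: np.ndarray
    sd: np.ndarray
    reference: str = "pooled"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.sd > 0).all():
            bad = [v for v, s in zip(self.variables, self.sd) if not s > 0]
            raise ValueError(f"non-positive SD for variables {bad}")


def _ols_predict(X: np.ndarray, y: np.ndarray, x_new: np.ndarray) -> float:
    """Least-squares fit of y on X (with intercept), evaluated at x_new."""
    design = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0] + x_new @ coef[1:])


def _impute_one(values, mask, row, col, scope_rows, variables, records, ind_id):
    """Fill cell (row, col) from complete cases within scope_rows."""
    observed_cols = np.flatnonzero(~mask[row])
    target_obs = scope_rows & ~mask[:, col]
    if not target_obs.any():
        raise ValueError(
            f"variable {variables[col]} has no observed values in scope"
        )

    # rank candidate predictors by |pairwise-complete correlation| with target
    def corr_with_target(c: int) -> float:
        both = target_obs & ~mask[:, c]
        if both.sum() < 3:
            return 0.0
        x, y = values[both, c], values[both, col]
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return abs(float(np.corrcoef(x, y)[0, 1]))

    ranked = sorted(observed_cols, key=corr_with_target, reverse=True)
    for k in range(len(ranked), 0, -1):
        preds = ranked[:k]
        train = target_obs & ~mask[:, preds].any(axis=1)
        train[row] = False
        # require residual degrees of freedom (>= 2k rows beyond the minimum)
        # so a near-saturated design cannot extrapolate wildly
        if train.sum() >= max(k + 2, 3 * k):
            fitted = _ols_predict(values[np.flatnonzero(train)][:, preds],
                                  values[train, col], values[row, preds])
            if np.isfinite(fitted):
                records.append(ImputationRecord(
                    individual_id=ind_id, variable=variables[col],
                    predictors=[variables[p] for p in preds],
                    fitted_value=fitted, n_training=int(train.sum()),
                    method="ols"))
                return fitted
    fitted = float(values[target_obs, col].mean())
    logger.warning("degenerate design for %s/%s; fell back to scope mean",
                   ind_id, variables[col])
    records.append(ImputationRecord(
        individual_id=ind_id, variable=variables[col], predictors=[],
        fitted_value=fitted, n_training=int(target_obs.sum()), method="mean"))
    return fitted


def impute_missing(
    table: CraniometricTable, scope: str = "per_series"
) -> tuple[CraniometricTable, list[ImputationRecord]]:
    """Fill every masked cell by multiple regression; observed cells unchanged.

    ``scope`` chooses the training pool for each regression: ``per_series``
    (the individual's own series, the unit of analysis) or ``pooled`` (all
    individuals).  Returns the completed table and one record per filled cell.
    Idempotent: a complete table is returned unchanged with no records.
    """
    if scope not in {"per_series", "pooled"}:
        raise ValueError(f"unknown scope {scope!r}")
    out = table.copy()
    records: list[ImputationRecord] = []
    if not out.mask.any():
        return out, records
    values, mask = out.values, out.mask
    filled = values.copy()
    for row in np.flatnonzero(mask.any(axis=1)):
        if scope == "per_series":
            scope_rows = out.series == out.series[row]
        else:
            scope_rows = np.ones(out.n_individuals, dtype=bool)
        for col in np.flatnonzero(mask[row]):
            filled[row, col] = _impute_one(values, mask, row, col, scope_rows,
                                           out.variables, records,
                                           str(out.individual_id[row]))
    out.values = filled
    out.mask = np.zeros_like(mask)
    # fitted values may legitimately be <= 0 only on pathological fixtures;
    # clamp to a small positive number so table invariants keep holding
    nonpos = out.values <= 0
    if nonpos.any():
        logger.warning("clamped %d non-positive imputed values", nonpos.sum())
        out.values[nonpos] = np.finfo(float).eps
    out.validate()
    return out, records


def fit_standardization(
    table: CraniometricTable, reference: np.ndarray | None = None,
    description: str = "pooled",
) -> StandardizationModel:
    """Per-variable mean and SD (ddof=1) over a reference row selection."""
    rows = np.ones(table.n_individuals, dtype=bool) if reference is None \
        else np.asarray(reference)
    vals = table.values[rows]
    msk = table.mask[rows]
    if vals.shape[0] < 2:
        raise ValueError("reference needs at least 2 individuals")
    mean = np.empty(table.n_variables)
    sd = np.empty(table.n_variables)
    for j, var in enumerate(table.variables):
        col = vals[~msk[:, j], j]
        if len(col) < 2:
            raise ValueError(f"variable {var} has < 2 observed reference values")
        mean[j] = col.mean()
        sd[j] = col.std(ddof=1)
        if sd[j] == 0:
            raise ValueError(f"variable {var} has zero variance in the reference")
    return StandardizationModel(list(table.variables), mean, sd, description)


def apply_standardization(
    table: CraniometricTable, model: StandardizationModel
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score the table's values; returns (z_matrix, mask).

    Z-scores are returned as a bare matrix (they are no longer positive
    measurements, so they do not form a valid CraniometricTable).
    """
    idx = []
    for var in table.variables:
        if var not in model.variables:
            raise ValueError(f"variable {var} missing from standardization model")
        idx.append(model.variables.index(var))
    mean = model.mean[idx]
    sd = model.sd[idx]
    return (table.values - mean) / sd, table.mask.copy()


def invert_standardization(z: np.ndarray, model: StandardizationModel,
                           variables: list[str]) -> np.ndarray:
    """Exact inverse of :func:`apply_standardization`."""
    idx = [model.variables.index(v) for v in variables]
    return z * model.sd[idx] + model.mean[idx]
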