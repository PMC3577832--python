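"""Attribution of biomarker variance to conductance scalings.

For each (condition, BCL, biomarker) the biomarker values are mean-centred
and scaled to unit standard deviation, and a linear least-squares fit against
the seven conductance scalings (plus an intercept) is computed.  Cells
flagged for alternans in APD80 or CaTD80, and cells with capture failure,
are excluded.  The coefficient of determination R^2 = 1 - SS_res/SS_tot
measures fit quality.

Predictors are standardized by default so that coefficients are comparable
across parameters and BCLs (coefficient = response SDs per predictor SD);
``standardize_x=False`` fits the raw scalings instead.  The minimizer is
computed by orthogonal decomposition (SVD-based least squares), not by
explicit normal-equations inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarkers import BIOMARKER_NAMES
from .scalings import PARAM_NAMES


def standardize(values) -> np.ndarray:
    """Mean-centre and scale to unit standard deviation.

    Raises for degenerate input (length < 2 or zero spread).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize requires a 1-d vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("standardize requires finite values")
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector (zero SD)")
    return (x - x.mean()) / sd


@dataclass
class RegressionResult:
    """Least-squares fit of one standardized biomarker on the scalings."""

    coefficients: dict          # parameter -> coefficient (response-SD units)
    intercept: float
    r_squared: float
    n_used: int
    n_excluded: int = 0
    biomarker: str = ""
    condition: str = ""
    bcl: int = 0
    standardized_x: bool = True

    def coefficient_array(self) -> np.ndarray:
        return np.array([self.coefficients[p] for p in PARAM_NAMES])


def fit_least_squares(X, y, param_names=None) -> RegressionResult:
    """Least-squares minimizer of ||X beta + b - y||^2 with explicit intercept.

    ``X`` is (n, p) without the intercept column (appended internally);
    ``y`` is the (already standardized) response.  Rank deficiency raises
    with the offending columns named.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if param_names is None:
        param_names = [f"x{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more rows ({n}) than columns ({p + 1})")
    A = np.column_stack([X, np.ones(n)])
    rank = np.linalg.matrix_rank(A)
    if rank < p + 1:
        bad = _dependent_columns(A, list(param_names) + ["intercept"])
        raise ValueError(f"design matrix is rank deficient; dependent columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ beta
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return RegressionResult(
        coefficients=dict(zip(param_names, beta[:p])),
        intercept=float(beta[p]), r_squared=r2, n_used=n)


def _dependent_columns(A, names):
    """Name columns that are (numerically) linear combinations of earlier ones."""
    bad = []
    cols = []
    for j in range(A.shape[1]):
        trial = cols + [A[:, j]]
        M = np.column_stack(trial)
        if np.linalg.matrix_rank(M) < len(trial):
            bad.append(names[j])
        else:
            cols = trial
    return bad


def exclusion_mask(table: pd.DataFrame, biomarker: str) -> pd.Series:
    """True for rows excluded from fits: alternans, capture failure, or NaN."""
    return (table["alternans_V"].astype(bool)
            | table["alternans_Ca"].astype(bool)
            | ~table["captured"].astype(bool)
            | ~np.isfinite(table[biomarker].to_numpy(dtype=float)))


def fit_biomarker(table: pd.DataFrame, condition: str, bcl: int,
                  biomarker: str, standardize_x: bool = True,
                  min_rows_factor: int = 10) -> RegressionResult | None:
    """Fit one (condition, BCL, biomarker) combination from a population table.

    Returns None (with a warning) when too few rows survive exclusion:
    fewer than ``min_rows_factor`` times the number of design columns.
    """
    sub = table[(table["condition"] == condition) & (table["bcl"] == bcl)]
    if sub.empty:
        raise ValueError(f"no rows for condition={condition!r}, bcl={bcl}")
    excl = exclusion_mask(sub, biomarker)
    kept = sub[~excl.to_numpy()]
    n_cols = len(PARAM_NAMES) + 1
    if len(kept) < max(min_rows_factor * n_cols, n_cols + 2):
        warnings.warn(
            f"skipping {condition}/{bcl}/{biomarker}: only {len(kept)} cells "
            f"after exclusions (< {min_rows_factor * n_cols})")
        return None
    X = kept[list(PARAM_NAMES)].to_numpy(dtype=float)
    if standardize_x:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    y = standardize(kept[biomarker].to_numpy(dtype=float))
    res = fit_least_squares(X, y, PARAM_NAMES)
    res.n_excluded = int(excl.sum())
    res.biomarker = biomarker
    res.condition = condition
    res.bcl = int(bcl)
    res.standardized_x = standardize_x
    return res


def regress_all(table: pd.DataFrame, biomarkers=BIOMARKER_NAMES,
                bcls=None, conditions=None, standardize_x: bool = True,
                min_rows_factor: int = 10) -> dict:
    """One fit per (condition, BCL, biomarker); skipped fits are omitted."""
    if bcls is None:
        bcls = sorted(table["bcl"].unique(), reverse=True)
    if conditions is None:
        conditions = list(pd.unique(table["condition"]))
    out = {}
    for cond in conditions:
        for bcl in bcls:
            for bm in biomarkers:
                res = fit_biomarker(table, cond, int(bcl), bm,
                                    standardize_x=standardize_x,
                                    min_rows_factor=min_rows_factor)
                if res is not None:
                    out[(cond, int(bcl), bm)] = res
    return out


def results_frame(results: dict) -> pd.DataFrame:
    """Tidy CSV-ready layout: one row per (condition, BCL, biomarker, parameter)."""
    rows = []
    for (cond, bcl, bm), res in results.items():
        for p in PARAM_NAMES:
            rows.append({
                "condition": cond, "bcl": bcl, "biomarker": bm,
                "parameter": p, "coefficient": res.coefficients[p],
                "intercept": res.intercept, "r_squared": res.r_squared,
                "n_used": res.n_used, "n_excluded": res.n_excluded,
            })
    return pd.DataFrame(rows)


def reported_coefficients(results: dict, threshold: float = 0.2) -> pd.DataFrame:
    """Coefficients whose magnitude exceeds the display threshold (|beta| > 0.2)."""
    df = results_frame(results)
    return df[df["coefficient"].abs() > threshold].reset_index(drop=True)
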