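"""Yield regression statistics.

The statistical stage relates plot-level yield to a vegetation index
(VI) and to abundance-weighted forms of it:

    plain : VI
    L     : VI * Abd_L        (leaf abundance)
    P     : VI * Abd_P        (panicle abundance)
    LP    : VI * (Abd_L - Abd_P)

Each predictor is screened by Pearson correlation, fitted by simple
linear regression (adjusted R^2, RMSE, F-test p), and the selected
models are finalized by leave-one-out cross-validation (LOOCV) whose
aggregates follow the convention

    Coef = mean_i Coef_i,  R^2 = mean_i R_i^2,  RMSE = sqrt(mean_i E_i^2),

where Coef_i and R_i^2 come from the training fit of fold i (R_i^2 is
the training coefficient of determination — with a single held-out
sample no validation R^2 exists — so the aggregate R^2 is optimistic),
and E_i is the held-out prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MODES = ("plain", "L", "P", "LP")
_MODE_LABEL = {"plain": "", "L": "Abd_L", "P": "Abd_P", "LP": "Abd_L-P"}


class DegenerateInputError(ValueError):
    pass


@dataclass
class RegressionResult:
    """Simple linear regression summary: yield = slope * x + intercept."""

    slope: float
    intercept: float
    pearson_r: float
    r2: float
    adjusted_r2: float
    rmse: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise DegenerateInputError("regression needs n >= 3")
        if self.rmse < 0 or self.adjusted_r2 > 1 + 1e-12:
            raise ValueError("inconsistent regression summary")


@dataclass
class CVResult:
    """Leave-one-out cross-validation output."""

    fold_coefficients: np.ndarray  # K x 2, (slope, intercept) per fold
    fold_r2: np.ndarray            # K training R_i^2
    fold_errors: np.ndarray        # K held-out errors E_i = predicted - observed
    coef: tuple[float, float] = field(init=False)
    r2: float = field(init=False)
    rmse: float = field(init=False)

    def __post_init__(self) -> None:
        self.fold_coefficients = np.asarray(self.fold_coefficients, dtype=float)
        self.fold_r2 = np.asarray(self.fold_r2, dtype=float)
        self.fold_errors = np.asarray(self.fold_errors, dtype=float)
        k = self.k
        if self.fold_coefficients.shape != (k, 2) or self.fold_r2.shape != (k,):
            raise ValueError("inconsistent fold arrays")
        self.coef = (float(self.fold_coefficients[:, 0].mean()),
                     float(self.fold_coefficients[:, 1].mean()))
        self.r2 = float(self.fold_r2.mean())
        self.rmse = float(np.sqrt(np.mean(self.fold_errors ** 2)))

    @property
    def k(self) -> int:
        return self.fold_errors.shape[0]


def _as_clean_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def normality_test(values) -> float:
    """Shapiro–Wilk p-value (reject normality when p < 0.05)."""
    x = _as_clean_vector(values, "values")
    if x.size < 3:
        raise DegenerateInputError("Shapiro–Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all values identical")
    return float(stats.shapiro(x).pvalue)


def combined_index(vi, table: pd.DataFrame, mode: str) -> np.ndarray:
    """Abundance-weighted predictor from plot-level VI values."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    vi = _as_clean_vector(vi, "vi")
    if len(table) != vi.size:
        raise ValueError("vi and table lengths differ")
    if mode == "plain":
        return vi.copy()
    needed = {"L": ["Abd_L"], "P": ["Abd_P"], "LP": ["Abd_L", "Abd_P"]}[mode]
    for col in needed:
        if col not in table.columns:
            raise KeyError(f"table lacks abundance column {col!r}")
    if mode == "L":
        return vi * table["Abd_L"].to_numpy(float)
    if mode == "P":
        return vi * table["Abd_P"].to_numpy(float)
    return vi * (table["Abd_L"].to_numpy(float) - table["Abd_P"].to_numpy(float))


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided t-test p-value."""
    x = _as_clean_vector(x, "x")
    y = _as_clean_vector(y, "y")
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError("need matching vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def significance_stars(p: float) -> str:
    return "**" if p < 0.01 else ("*" if p < 0.05 else "")


def correlate(table: pd.DataFrame, predictors: dict[str, np.ndarray],
              yield_col: str = "yield") -> pd.DataFrame:
    """Pearson r of each named predictor with yield, with star flags."""
    y = table[yield_col].to_numpy(float)
    rows = []
    for name, x in predictors.items():
        r, p = pearson(x, y)
        rows.append({"predictor": name, "r": r, "p": p,
                     "significance": significance_stars(p)})
    return pd.DataFrame.from_records(rows)


def fit_linear(predictor, observed) -> RegressionResult:
    """OLS simple linear regression with adjusted R^2, RMSE and F-test p.

    ``adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2)`` and
    ``RMSE = sqrt(sum(resid^2) / n)``.
    """
    x = _as_clean_vector(predictor, "predictor")
    y = _as_clean_vector(observed, "observed")
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError("need matching vectors with n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant predictor; fit is singular")
    res = stats.linregress(x, y)
    n = x.size
    resid = y - (res.slope * x + res.intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        pearson_r=float(res.rvalue), r2=r2, adjusted_r2=adj,
        rmse=float(np.sqrt(ss_res / n)),
        p_value=float(res.pvalue),  # t-test == F-test for one predictor
        n=n,
    )


def loocv_fit(predictor, observed) -> CVResult:
    """Leave-one-out cross-validation of the simple linear model.

    Each fold i refits on the other K-1 samples, records the fold
    coefficients and training R_i^2, and predicts the held-out sample.
    """
    x = _as_clean_vector(predictor, "predictor")
    y = _as_clean_vector(observed, "observed")
    if x.size != y.size or x.size < 4:
        raise DegenerateInputError("LOOCV needs matching vectors with n >= 4")
    k = x.size
    coefs = np.empty((k, 2))
    r2s = np.empty(k)
    errs = np.empty(k)
    for i in range(k):
        keep = np.ones(k, dtype=bool)
        keep[i] = False
        fit = fit_linear(x[keep], y[keep])
        coefs[i] = (fit.slope, fit.intercept)
        r2s[i] = fit.r2
        errs[i] = (fit.slope * x[i] + fit.intercept) - y[i]
    return CVResult(fold_coefficients=coefs, fold_r2=r2s, fold_errors=errs)


def rank_models(table: pd.DataFrame, vi_names, modes=MODES,
                yield_col: str = "yield",
                exclude_plots: tuple[str, ...] = ()) -> pd.DataFrame:
    """Fit the full VI x mode grid and rank by adjusted R^2 (descending)."""
    if exclude_plots:
        table = table[~table["plot_id"].astype(str).isin([str(p) for p in exclude_plots])]
    y = table[yield_col].to_numpy(float)
    rows = []
    for vi_name in vi_names:
        if vi_name not in table.columns:
            raise KeyError(f"table lacks VI column {vi_name!r}")
        vi = table[vi_name].to_numpy(float)
        for mode in modes:
            x = combined_index(vi, table, mode)
            r, p_r = pearson(x, y)
            fit = fit_linear(x, y)
            rows.append({
                "vi": vi_name, "mode": mode,
                "predictor": f"{vi_name}*{_MODE_LABEL[mode]}" if mode != "plain" else vi_name,
                "r": r, "r_significance": significance_stars(p_r),
                "adjusted_r2": fit.adjusted_r2, "rmse": fit.rmse,
                "p_value": fit.p_value, "slope": fit.slope,
                "intercept": fit.intercept, "n": fit.n,
            })
    out = pd.DataFrame.from_records(rows)
    return out.sort_values("adjusted_r2", ascending=False, ignore_index=True)
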