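"""Independent brute-force oracles used by the test suite only."""

from itertools import combinations

import numpy as np


def simplex_grid(n: int, step: float) -> np.ndarray:
    """All abundance vectors on the n-simplex with components that are
    multiples of ``step`` (stars and bars enumeration)."""
    m = round(1.0 / step)
    pts = []
    for bars in combinations(range(m + n - 1), n - 1):
        prev = -1
        comp = []
        for b in bars:
            comp.append(b - prev - 1)
            prev = b
        comp.append(m + n - 2 - prev)
        pts.append(comp)
    return np.asarray(pts, dtype=float) / m


def grid_min_objective(spectrum: np.ndarray, endmembers: np.ndarray,
                       step: float) -> float:
    """Minimum of ||rho - a^T E||^2 over the simplex grid (exhaustive)."""
    grid = simplex_grid(endmembers.shape[0], step)
    resid = grid @ endmembers - spectrum[None, :]
    return float(np.min(np.einsum("ij,ij->i", resid, resid)))


def loocv_oracle(x: np.ndarray, y: np.ndarray):
    """Plainly coded double-loop leave-one-out for the simple linear model.

    Returns (mean slope, mean intercept, mean training R^2,
    sqrt(mean squared held-out error)).
    """
    k = len(x)
    slopes, intercepts, r2s, errs = [], [], [], []
    for i in range(k):
        xs, ys = [], []
        for j in range(k):
            if j != i:
                xs.append(x[j])
                ys.append(y[j])
        xs, ys = np.asarray(xs), np.asarray(ys)
        slope, intercept = np.polyfit(xs, ys, 1)
        pred = slope * xs + intercept
        ss_res = float(np.sum((ys - pred) ** 2))
        ss_tot = float(np.sum((ys - ys.mean()) ** 2))
        slopes.append(slope)
        intercepts.append(intercept)
        r2s.append(1.0 - ss_res / ss_tot)
        errs.append(slope * x[i] + intercept - y[i])
    return (float(np.mean(slopes)), float(np.mean(intercepts)),
            float(np.mean(r2s)), float(np.sqrt(np.mean(np.square(errs)))))
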