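"""Independent brute-force re-implementations used as test oracles.

Everything here is computed from first principles with explicit arithmetic
(normal equations, hand-coded interpolated quantiles) so that it cannot
share a code path with the package implementation it checks.
"""

import numpy as np


def interp_quantile(values, p):
    """Linear-interpolation quantile at rank 1 + (n-1)p, coded by hand."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def naive_impute(x1, x2_complete, y, mask_idx, family, quartile,
                 alpha=1.0, eps=(0.9, 0.1), omega=(0.1, 0.9)):
    """Step-by-step fill -> OLS -> factor -> adjust, returning (yhat, factor)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2_complete, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x1)
    obs = np.ones(n, dtype=bool)
    obs[list(mask_idx)] = False

    fill = x2[obs].mean()
    x2f = x2.copy()
    x2f[~obs] = fill

    X = np.column_stack([np.ones(n), x1, x2f])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    yreg = X @ beta

    p = 0.25 if quartile == "q1" else 0.75
    qx1 = interp_quantile(x1, p)
    qx2 = interp_quantile(x2[obs], p)
    m1n = m1r = x1.mean()
    m2n = x2.mean()
    m2r = x2[obs].mean()

    if family == "ratio":
        f = (m2n + qx2) / (m2r + qx2)
    elif family == "chain":
        f = ((m2n + qx2) / (m2r + qx2)) ** alpha
    elif family == "mratio":
        f = eps[0] * (m1n + qx1) / (m1r + qx1) + eps[1] * (m2n + qx2) / (m2r + qx2)
    elif family == "mchain":
        f = (
            (omega[0] * (m1n + qx1) + omega[1] * (m2n + qx2))
            / (omega[0] * (m1r + qx1) + omega[1] * (m2r + qx2))
        ) ** alpha
    else:
        raise ValueError(family)

    yhat = yreg.copy()
    yhat[~obs] *= f
    return yhat, f
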