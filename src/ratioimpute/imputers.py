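"""Quartile-shifted ratio imputation estimators for a missing covariate.

The pipeline shared by all eight methods is

1. **series-mean fill** — every missing ``x2`` cell is replaced by the mean
   of the observed ``x2`` values;
2. **OLS stage** — an ordinary least-squares fit of ``y`` on
   ``(1, x1, x2_filled)`` over all n rows gives regression predictions
   ``yhat_reg``;
3. **ratio adjustment** — at the masked rows only, ``yhat_reg`` is scaled by
   a quartile-shifted ratio factor built from the drift between the mean of
   the complete auxiliary column and the mean of its responding values.

Writing ``m_n`` and ``m_r`` for the complete-column and responding means of
a covariate and ``q`` for its first or third sample quartile, the factor is

* ``ratio``   —  ``(m_n + q) / (m_r + q)``  on x2;
* ``chain``   —  the ratio factor raised to an exponent ``alpha``
  (default 0.90);
* ``mratio``  —  a convex combination ``e1 * f(x1) + e2 * f(x2)`` of the
  per-variable ratio factors, each variable shifted by its own quartile
  (default weights (0.90, 0.10));
* ``mchain``  —  ``[(w1*(m1_n+q1) + w2*(m2_n+q2)) /
  (w1*(m1_r+q1) + w2*(m2_r+q2))] ** alpha``
  (default weights (0.10, 0.90), alpha 0.10).

Because ``x1`` is never masked its responding mean equals its full mean, so
the x1 ratio term is identically 1 and ``mratio`` reduces to
``e1 + e2 * f(x2)``.  The quartile shift keeps the factor near 1, which is
what stabilises the adjustment; as ``q`` grows the factor tends to 1
monotonically.

The eight canonical method names combine the four families with the first or
third quartile: ``r-rq1``, ``r-rq3``, ``ar-crq1``, ``ar-crq3``, ``ar-mrq1``,
``ar-mrq3``, ``ar-mcrq1``, ``ar-mcrq3``.

The same algebra, applied to sample/population means instead of fitted
values, yields the classical family of population-mean ratio estimators; see
:func:`estimate_population_mean`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import (
    DegenerateDataError,
    InvalidSpecError,
    NumericDomainError,
)
from .missingness import MissingPattern, apply_pattern
from .sampling import Sample

__all__ = [
    "MethodConfig",
    "ImputationContext",
    "Predictions",
    "METHOD_NAMES",
    "default_methods",
    "series_mean_fill",
    "quartiles",
    "fit_regression",
    "build_context",
    "adjustment_factor",
    "predict_with_imputation",
    "estimate_population_mean",
    "RatioImputationRegressor",
]

_FAMILY_BY_NAME = {
    "r-rq1": ("ratio", "q1"),
    "r-rq3": ("ratio", "q3"),
    "ar-crq1": ("chain", "q1"),
    "ar-crq3": ("chain", "q3"),
    "ar-mrq1": ("mratio", "q1"),
    "ar-mrq3": ("mratio", "q3"),
    "ar-mcrq1": ("mchain", "q1"),
    "ar-mcrq3": ("mchain", "q3"),
}
METHOD_NAMES = tuple(_FAMILY_BY_NAME)

#: tuned constants that performed best in the underlying simulation study
DEFAULT_ALPHA = {"ratio": 1.0, "chain": 0.90, "mratio": 1.0, "mchain": 0.10}
DEFAULT_EPS = (0.90, 0.10)
DEFAULT_OMEGA = (0.10, 0.90)


def _check_weights(w, label):
    w = (float(w[0]), float(w[1]))
    if w[0] < 0 or w[1] < 0 or abs(w[0] + w[1] - 1.0) > 1e-9:
        raise InvalidSpecError(f"{label} weights must be non-negative and sum to 1")
    return w


@dataclasses.dataclass(frozen=True)
class MethodConfig:
    """One estimator family with its tuning constants.

    ``alpha`` is the chain exponent; ``eps_w`` the multivariate-ratio weights
    (e1, e2); ``omega_w`` the multivariate-chain weights (w1, w2).  Omitted
    constants take the family defaults.
    """

    family: str
    quartile: str = "q1"
    alpha: float | None = None
    eps_w: tuple[float, float] | None = None
    omega_w: tuple[float, float] | None = None

    def __post_init__(self):
        if self.family not in ("ratio", "chain", "mratio", "mchain"):
            raise InvalidSpecError(f"unknown family {self.family!r}")
        if self.quartile not in ("q1", "q3"):
            raise InvalidSpecError(f"quartile must be 'q1' or 'q3', got {self.quartile!r}")
        alpha = DEFAULT_ALPHA[self.family] if self.alpha is None else float(self.alpha)
        if not np.isfinite(alpha) or alpha < 0:
            raise InvalidSpecError(f"alpha must be a non-negative real, got {alpha}")
        object.__setattr__(self, "alpha", alpha)
        eps = DEFAULT_EPS if self.eps_w is None else self.eps_w
        omega = DEFAULT_OMEGA if self.omega_w is None else self.omega_w
        object.__setattr__(self, "eps_w", _check_weights(eps, "eps"))
        object.__setattr__(self, "omega_w", _check_weights(omega, "omega"))

    @property
    def name(self) -> str:
        prefix = {"ratio": "r-r", "chain": "ar-cr", "mratio": "ar-mr", "mchain": "ar-mcr"}
        return f"{prefix[self.family]}{self.quartile}"

    @classmethod
    def from_name(cls, name: str, alpha=None, eps1=None, omega1=None) -> "MethodConfig":
        """Build a config from a canonical method name with optional overrides."""
        try:
            family, quartile = _FAMILY_BY_NAME[name.lower()]
        except KeyError:
            raise InvalidSpecError(
                f"unknown method {name!r}; expected one of {', '.join(METHOD_NAMES)}"
            ) from None
        eps = None if eps1 is None else (float(eps1), 1.0 - float(eps1))
        omega = None if omega1 is None else (float(omega1), 1.0 - float(omega1))
        return cls(family, quartile, alpha=alpha, eps_w=eps, omega_w=omega)


def default_methods() -> list[MethodConfig]:
    """The eight canonical methods with their default tuning constants."""
    return [MethodConfig.from_name(name) for name in METHOD_NAMES]


@dataclasses.dataclass(frozen=True)
class ImputationContext:
    """Sufficient statistics for the adjustment factor.

    ``xbar*_n`` are means over all n rows (for x2: of the complete,
    pre-masking column), ``xbar*_r`` means over responding rows only; the
    quartiles come from the observed values of each covariate.  ``r`` counts
    responding rows and ``k`` masked rows.
    """

    xbar1_n: float
    xbar1_r: float
    xbar2_n: float
    xbar2_r: float
    q1_x1: float
    q3_x1: float
    q1_x2: float
    q3_x2: float
    r: int
    k: int

    def __post_init__(self):
        if self.r < 4:
            raise DegenerateDataError(f"need >= 4 responding rows, got {self.r}")
        if self.k < 0:
            raise InvalidSpecError("k must be non-negative")


@dataclasses.dataclass
class Predictions:
    """Output of the imputation pipeline for one sample and method."""

    coeffs: tuple[float, float, float]
    yhat_reg: np.ndarray
    yhat: np.ndarray
    factor: float


def series_mean_fill(x2, pattern: MissingPattern | None = None) -> np.ndarray:
    """Replace missing values with the mean of the observed values.

    Missing cells are NaN entries; a :class:`MissingPattern` may be supplied
    to mask additional positions explicitly.
    """
    x = np.asarray(x2, dtype=float).copy()
    if pattern is not None:
        x[pattern.mask()] = np.nan
    observed = ~np.isnan(x)
    if not observed.any():
        raise DegenerateDataError("cannot series-mean fill an all-missing vector")
    x[~observed] = x[observed].mean()
    return x


def quartiles(x) -> tuple[float, float]:
    """First and third quartile via linear interpolation at rank 1+(n-1)p."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise DegenerateDataError(f"need >= 4 values for quartiles, got {x.size}")
    q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
    return float(q1), float(q3)


def fit_regression(x1, x2_filled, y):
    """OLS of y on (1, x1, x2) over all rows.

    Returns ``(coeffs, yhat_reg)`` with ``coeffs = (b0, b1, b2)`` and the
    in-sample fitted values.  A rank-deficient design raises
    :class:`NumericDomainError`.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2_filled, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x1.shape == x2.shape == y.shape):
        raise InvalidSpecError("regression inputs must have identical shapes")
    n = x1.shape[0]
    if n < 5:
        raise DegenerateDataError(f"need n >= 5 rows for the OLS stage, got {n}")
    X = np.column_stack([np.ones(n), x1, x2])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise NumericDomainError("design matrix is rank deficient")
    yhat = X @ coef
    return (float(coef[0]), float(coef[1]), float(coef[2])), yhat


def build_context(x1, x2_complete, x2_observed, pattern: MissingPattern) -> ImputationContext:
    """Collect the means, quartiles and counts the adjustment factor needs.

    ``x2_complete`` is the pre-masking column (known to the simulator);
    ``x2_observed`` carries NaN at masked cells.  ``x1`` is never masked, so
    its full and responding means coincide by construction.
    """
    x1 = np.asarray(x1, dtype=float)
    x2c = np.asarray(x2_complete, dtype=float)
    x2o = np.asarray(x2_observed, dtype=float)
    if not (x1.shape == x2c.shape == x2o.shape) or x1.shape[0] != pattern.n:
        raise InvalidSpecError("context inputs must share the pattern's length")
    observed = ~pattern.mask()
    if int(observed.sum()) < 4:
        raise DegenerateDataError("fewer than 4 responding rows")
    xbar1 = float(x1.mean())
    q1_x1, q3_x1 = quartiles(x1)
    q1_x2, q3_x2 = quartiles(x2o[observed])
    return ImputationContext(
        xbar1_n=xbar1,
        xbar1_r=xbar1,
        xbar2_n=float(x2c.mean()),
        xbar2_r=float(x2o[observed].mean()),
        q1_x1=q1_x1,
        q3_x1=q3_x1,
        q1_x2=q1_x2,
        q3_x2=q3_x2,
        r=int(observed.sum()),
        k=pattern.k,
    )


def _ratio_term(m_n: float, m_r: float, q: float) -> float:
    denom = m_r + q
    if denom <= 0:
        raise NumericDomainError(f"non-positive ratio denominator {denom}")
    return (m_n + q) / denom


def adjustment_factor(ctx: ImputationContext, cfg: MethodConfig) -> float:
    """The multiplicative correction applied to yhat_reg at masked rows.

    The factor is index-free: one value per (sample, method), applied once to
    each of the k adjusted predictions.
    """
    if cfg.quartile == "q1":
        q1v, q2v = ctx.q1_x1, ctx.q1_x2
    else:
        q1v, q2v = ctx.q3_x1, ctx.q3_x2
    if cfg.family == "ratio":
        f = _ratio_term(ctx.xbar2_n, ctx.xbar2_r, q2v)
    elif cfg.family == "chain":
        f = _ratio_term(ctx.xbar2_n, ctx.xbar2_r, q2v) ** cfg.alpha
    elif cfg.family == "mratio":
        e1, e2 = cfg.eps_w
        f = e1 * _ratio_term(ctx.xbar1_n, ctx.xbar1_r, q1v) + e2 * _ratio_term(
            ctx.xbar2_n, ctx.xbar2_r, q2v
        )
    else:  # mchain
        w1, w2 = cfg.omega_w
        denom = w1 * (ctx.xbar1_r + q1v) + w2 * (ctx.xbar2_r + q2v)
        if denom <= 0:
            raise NumericDomainError(f"non-positive ratio denominator {denom}")
        f = ((w1 * (ctx.xbar1_n + q1v) + w2 * (ctx.xbar2_n + q2v)) / denom) ** cfg.alpha
    if f <= 0:
        raise NumericDomainError(f"adjustment factor must be positive, got {f}")
    return float(f)


class RatioImputationRegressor(RegressorMixin, BaseEstimator):
    """Regression with series-mean imputation and quartile-ratio adjustment.

    A scikit-learn style regressor.  ``X`` is an ``(n, 2)`` array whose
    second column (the auxiliary covariate x2) may contain NaN; the first
    column and ``y`` must be complete.  Fitting series-mean fills x2, runs
    OLS on all rows and computes the adjustment factor; prediction scales the
    regression prediction by that factor at rows whose x2 is missing.

    Parameters
    ----------
    method : str or MethodConfig, default "r-rq1"
        One of ``r-rq1``, ``r-rq3``, ``ar-crq1``, ``ar-crq3``, ``ar-mrq1``,
        ``ar-mrq3``, ``ar-mcrq1``, ``ar-mcrq3``, or an explicit config.
    alpha, eps1, omega1 : float, optional
        Tuning-constant overrides (chain exponent, first multivariate-ratio
        weight, first multivariate-chain weight).  Ignored when ``method`` is
        already a :class:`MethodConfig`.
    complete_mean : float, optional
        Reference mean of the complete x2 column.  In a simulation the
        generator knows it; on real data it is unknown, and when omitted the
        mean of the filled column is used, which makes the factor exactly 1.
    population_quartiles : dict, optional
        ``{"x1": (q1, q3), "x2": (q1, q3)}`` overriding the sample quartiles
        with known population ones.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (2,)
    factor_ : float
        The applied adjustment factor.
    context_ : ImputationContext
    missing_mask_ : ndarray of bool
        Rows of the training sample whose x2 was missing.
    regression_values_ : ndarray
        In-sample OLS predictions (before adjustment).
    fitted_values_ : ndarray
        In-sample predictions after adjustment at masked rows.
    """

    def __init__(
        self,
        method="r-rq1",
        alpha=None,
        eps1=None,
        omega1=None,
        complete_mean=None,
        population_quartiles=None,
    ):
        self.method = method
        self.alpha = alpha
        self.eps1 = eps1
        self.omega1 = omega1
        self.complete_mean = complete_mean
        self.population_quartiles = population_quartiles

    def _config(self) -> MethodConfig:
        if isinstance(self.method, MethodConfig):
            return self.method
        return MethodConfig.from_name(
            self.method, alpha=self.alpha, eps1=self.eps1, omega1=self.omega1
        )

    def _validate(self, X, missing_ok: bool):
        X = check_array(X, ensure_all_finite="allow-nan", dtype=float)
        if X.shape[1] != 2:
            raise InvalidSpecError(f"X must have exactly 2 columns, got {X.shape[1]}")
        if np.isnan(X[:, 0]).any():
            raise InvalidSpecError("x1 (first column) must be fully observed")
        if not missing_ok and np.isnan(X[:, 1]).any():
            raise InvalidSpecError("x2 contains NaN")
        return X

    def fit(self, X, y):
        cfg = self._config()
        X = self._validate(X, missing_ok=True)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise InvalidSpecError("X and y lengths differ")
        if np.isnan(y).any():
            raise InvalidSpecError("y must be fully observed")
        x1, x2 = X[:, 0], X[:, 1]
        mask = np.isnan(x2)
        observed = ~mask
        if int(observed.sum()) < 4:
            raise DegenerateDataError("fewer than 4 rows with observed x2")
        filled = series_mean_fill(x2)
        coeffs, yhat_reg = fit_regression(x1, filled, y)

        xbar1 = float(x1.mean())
        if self.population_quartiles is not None:
            q1_x1, q3_x1 = map(float, self.population_quartiles["x1"])
            q1_x2, q3_x2 = map(float, self.population_quartiles["x2"])
        else:
            q1_x1, q3_x1 = quartiles(x1)
            q1_x2, q3_x2 = quartiles(x2[observed])
        xbar2_n = (
            float(filled.mean()) if self.complete_mean is None else float(self.complete_mean)
        )
        ctx = ImputationContext(
            xbar1_n=xbar1,
            xbar1_r=xbar1,
            xbar2_n=xbar2_n,
            xbar2_r=float(x2[observed].mean()),
            q1_x1=q1_x1,
            q3_x1=q3_x1,
            q1_x2=q1_x2,
            q3_x2=q3_x2,
            r=int(observed.sum()),
            k=int(mask.sum()),
        )
        factor = adjustment_factor(ctx, cfg)
        yhat = yhat_reg.copy()
        yhat[mask] *= factor

        self.n_features_in_ = 2
        self.intercept_ = coeffs[0]
        self.coef_ = np.array(coeffs[1:])
        self.factor_ = factor
        self.context_ = ctx
        self.fill_value_ = float(x2[observed].mean())
        self.missing_mask_ = mask
        self.regression_values_ = yhat_reg
        self.fitted_values_ = yhat
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = self._validate(X, missing_ok=True)
        x2 = X[:, 1].copy()
        mask = np.isnan(x2)
        x2[mask] = self.fill_value_
        yhat = self.intercept_ + self.coef_[0] * X[:, 0] + self.coef_[1] * x2
        yhat[mask] *= self.factor_
        return yhat


def predict_with_imputation(
    sample: Sample,
    pattern: MissingPattern,
    cfg: MethodConfig,
    x2_complete=None,
) -> Predictions:
    """Run the full pipeline on one sample: fill, OLS, adjust at masked rows.

    ``x2_complete`` defaults to the sample's own (pre-masking) x2 column,
    which the simulator knows; its mean anchors the adjustment factor.
    """
    if x2_complete is None:
        x2_complete = sample.x2
    x2_complete = np.asarray(x2_complete, dtype=float)
    X = np.column_stack([sample.x1, apply_pattern(x2_complete, pattern)])
    est = RatioImputationRegressor(
        method=cfg, complete_mean=float(x2_complete.mean())
    ).fit(X, sample.y)
    return Predictions(
        coeffs=(est.intercept_, float(est.coef_[0]), float(est.coef_[1])),
        yhat_reg=est.regression_values_,
        yhat=est.fitted_values_,
        factor=est.factor_,
    )


def estimate_population_mean(
    ybar: float,
    mu_x: float,
    xbar: float,
    q: float = 0.0,
    family: str = "ratio",
    alpha: float = 1.0,
    weights: tuple[float, float] | None = None,
    second_var: tuple[float, float, float] | None = None,
) -> float:
    """Classical ratio-type estimators of a population mean.

    Estimates ``mu_Y`` from the sample mean ``ybar`` of the study variable,
    the known population mean ``mu_x`` and sample mean ``xbar`` of an
    auxiliary variable, optionally shifted by a quartile ``q``:

    * ``ratio``  — ``ybar * (mu_x + q) / (xbar + q)``;
    * ``chain``  — the ratio form raised to ``alpha``;
    * ``mratio`` — a ``weights``-weighted sum of the ratio forms of two
      auxiliaries, the second given as ``second_var = (mu_x2, xbar2, q2)``;
    * ``mchain`` — the weighted-pooled ratio of the two auxiliaries raised
      to ``alpha``.

    The algebra is identical under simple random and ranked-set sampling;
    only the design that produced ``ybar``/``xbar`` differs.
    """
    if family in ("mratio", "mchain"):
        if second_var is None:
            raise InvalidSpecError(f"family {family!r} needs second_var=(mu, xbar, q)")
        if weights is None:
            weights = DEFAULT_EPS if family == "mratio" else DEFAULT_OMEGA
        w = _check_weights(weights, family)
        mu2, xbar2, q2 = map(float, second_var)
    if family == "ratio":
        return ybar * _ratio_term(mu_x, xbar, q)
    if family == "chain":
        return ybar * _ratio_term(mu_x, xbar, q) ** alpha
    if family == "mratio":
        return ybar * (w[0] * _ratio_term(mu_x, xbar, q) + w[1] * _ratio_term(mu2, xbar2, q2))
    if family == "mchain":
        denom = w[0] * (xbar + q) + w[1] * (xbar2 + q2)
        if denom <= 0:
            raise NumericDomainError(f"non-positive denominator {denom}")
        return ybar * ((w[0] * (mu_x + q) + w[1] * (mu2 + q2)) / denom) ** alpha
    raise InvalidSpecError(f"unknown family {family!r}")
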