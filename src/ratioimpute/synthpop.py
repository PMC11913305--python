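"""Synthetic population generator for the two-covariate normal regression model.

The simulation study that this package implements works on populations of
independent normal draws: a covariate ``X1 ~ N(3, 2.25)``, an auxiliary
covariate ``X2 ~ N(5, 4)`` and an error term ``eps ~ N(0, sigma^2)`` with
``sigma^2`` in {1, 3, 5, 7, 9}.  The response is the linear model

    Y = beta0 + beta1 * X1 + beta2 * X2 + eps

with coefficients ``(0.5, 1.0, -0.3)``.  Populations of 100,000 units are
regenerated from a seed on demand rather than stored on disk: the three
columns are cheap to draw and carrying the error column with every unit lets
ranked-set selection operate on complete ``(x1, x2, eps)`` triples.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .exceptions import InvalidSpecError

__all__ = [
    "NormalSpec",
    "RegressionSpec",
    "PopulationTable",
    "draw_population",
    "make_response",
    "as_rng",
    "X1_SPEC",
    "X2_SPEC",
    "DEFAULT_BETA",
    "DEFAULT_POPULATION_SIZE",
]

DEFAULT_POPULATION_SIZE = 100_000


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclasses.dataclass(frozen=True)
class NormalSpec:
    """Mean/variance parameterisation of a univariate normal distribution."""

    mean: float
    variance: float

    def __post_init__(self):
        if not (math.isfinite(self.mean) and math.isfinite(self.variance)):
            raise InvalidSpecError("normal spec parameters must be finite")
        if self.variance <= 0:
            raise InvalidSpecError(f"variance must be positive, got {self.variance}")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclasses.dataclass(frozen=True)
class RegressionSpec:
    """Coefficients of the linear response model y = b0 + b1*x1 + b2*x2 + eps."""

    beta0: float
    beta1: float
    beta2: float

    def __post_init__(self):
        for name in ("beta0", "beta1", "beta2"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidSpecError(f"{name} must be finite")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.beta0, self.beta1, self.beta2)


X1_SPEC = NormalSpec(3.0, 2.25)
X2_SPEC = NormalSpec(5.0, 4.0)
DEFAULT_BETA = RegressionSpec(0.5, 1.0, -0.3)


@dataclasses.dataclass
class PopulationTable:
    """A generated population: covariate columns and the per-unit error.

    The error is a column of the table (not folded into a response) so that
    sampling designs can carry complete units and the response can be
    assembled later for whichever coefficient vector an experiment uses.
    """

    x1: np.ndarray
    x2: np.ndarray
    eps: np.ndarray

    def __post_init__(self):
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        if not (self.x1.shape == self.x2.shape == self.eps.shape):
            raise InvalidSpecError("population columns must have equal length")
        if self.x1.ndim != 1 or self.N < 2:
            raise InvalidSpecError("population must be a flat table with N >= 2")

    @property
    def N(self) -> int:
        return self.x1.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x1": self.x1, "x2": self.x2, "eps": self.eps})

    def to_csv(self, path, na_token: str = "NA") -> None:
        self.to_frame().to_csv(path, index=False, na_rep=na_token)


def draw_population(
    x1_spec: NormalSpec = X1_SPEC,
    x2_spec: NormalSpec = X2_SPEC,
    eps_spec: NormalSpec = NormalSpec(0.0, 1.0),
    size: int = DEFAULT_POPULATION_SIZE,
    seed=None,
) -> PopulationTable:
    """Draw three mutually independent i.i.d. normal columns.

    Identical seeds produce bit-identical tables.  Raises
    :class:`InvalidSpecError` for ``size < 2`` (a non-positive variance is
    rejected by :class:`NormalSpec` itself).
    """
    if size < 2:
        raise InvalidSpecError(f"population size must be >= 2, got {size}")
    rng = as_rng(seed)
    x1 = rng.normal(x1_spec.mean, x1_spec.sd, size)
    x2 = rng.normal(x2_spec.mean, x2_spec.sd, size)
    eps = rng.normal(eps_spec.mean, eps_spec.sd, size)
    return PopulationTable(x1, x2, eps)


def make_response(x1, x2, eps, beta: RegressionSpec = DEFAULT_BETA) -> np.ndarray:
    """Elementwise linear response y_i = b0 + b1*x1_i + b2*x2_i + eps_i."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if not (x1.shape == x2.shape == eps.shape):
        raise InvalidSpecError("x1, x2 and eps must have identical shapes")
    return beta.beta0 + beta.beta1 * x1 + beta.beta2 * x2 + eps
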