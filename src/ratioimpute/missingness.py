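"""MCAR missing-value patterns on the auxiliary covariate x2.

Only ``x2`` can be masked: the study design keeps ``x1`` and ``y`` fully
observed, which is what makes the ratio-type adjustments identifiable.  The
number of missing cells is ``round(n * pct)`` (half away from zero; every
grid combination used by the simulation study is an exact integer, the
rounding rule only matters for user-supplied rates) and positions are drawn
uniformly without replacement, independent of all data values.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .exceptions import DegenerateDataError, InvalidSpecError
from .synthpop import as_rng

__all__ = ["MissingPattern", "n_missing", "mcar_indices", "apply_pattern"]


@dataclasses.dataclass(frozen=True)
class MissingPattern:
    """A sorted set of masked 0-based row indices within a sample of size n."""

    indices: tuple[int, ...]
    n: int

    def __post_init__(self):
        idx = tuple(sorted(int(i) for i in self.indices))
        object.__setattr__(self, "indices", idx)
        if self.n < 1:
            raise InvalidSpecError("pattern size n must be positive")
        if len(set(idx)) != len(idx):
            raise InvalidSpecError("masked indices must be distinct")
        if idx and (idx[0] < 0 or idx[-1] >= self.n):
            raise InvalidSpecError("masked indices must lie in [0, n)")

    @property
    def k(self) -> int:
        """Number of masked rows."""
        return len(self.indices)

    @property
    def r(self) -> int:
        """Number of responding (observed) rows."""
        return self.n - self.k

    @property
    def pct(self) -> float:
        return self.k / self.n

    def mask(self) -> np.ndarray:
        """Boolean mask of length n, True at masked positions."""
        m = np.zeros(self.n, dtype=bool)
        if self.indices:
            m[list(self.indices)] = True
        return m


def n_missing(n: int, pct: float) -> int:
    """Number of missing values: ``round(n * pct)``, half away from zero."""
    if not 0 <= pct < 1:
        raise InvalidSpecError(f"missing percentage must be in [0, 1), got {pct}")
    if n < 1:
        raise InvalidSpecError("n must be positive")
    return int(math.floor(n * pct + 0.5))


def mcar_indices(n: int, count: int, seed=None) -> MissingPattern:
    """Draw ``count`` distinct masked positions uniformly, independent of data.

    At least 4 complete rows must remain so that a listwise three-coefficient
    fit stays estimable.
    """
    if count < 0:
        raise InvalidSpecError("count must be non-negative")
    if count > n - 4:
        raise DegenerateDataError(
            f"masking {count} of {n} rows leaves fewer than 4 complete rows"
        )
    rng = as_rng(seed)
    idx = rng.choice(n, size=count, replace=False)
    return MissingPattern(tuple(int(i) for i in idx), n)


def apply_pattern(x, pattern: MissingPattern) -> np.ndarray:
    """Copy of ``x`` with NaN at the pattern's masked positions."""
    x = np.asarray(x, dtype=float).copy()
    if x.shape[0] != pattern.n:
        raise InvalidSpecError("vector length does not match pattern size")
    x[pattern.mask()] = np.nan
    return x
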