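"""Sampling designs: simple random sampling and ranked-set sampling.

Both designs draw complete ``(x1, x2, eps)`` units from a generated
population and assemble the response on the sampled units.  Ranked-set
sampling (RSS) draws, for each of the ``n`` order positions, an independent
simple random set of units, ranks the set on one covariate (perfect ranking
on true values) and keeps the unit at the required order position.  The
default configuration uses one cycle of ``n`` sets of ``n`` units each,
which is the literal text-book procedure and costs ``n^2`` draws per sample;
smaller set sizes with several cycles are available through
:class:`RSSConfig`.

A multicollinearity screen retries a sampler until the drawn covariates have
``|Pearson r(x1, x2)| < threshold`` (default 0.6).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InvalidSpecError, SamplingError, ScreeningError
from .synthpop import DEFAULT_BETA, PopulationTable, RegressionSpec, as_rng, make_response

__all__ = [
    "SRS",
    "RSS",
    "Sample",
    "RSSConfig",
    "srs_draw",
    "rss_draw",
    "screened_sample",
    "pearson_r",
]

SRS = "SRS"
RSS = "RSS"


@dataclasses.dataclass
class Sample:
    """One drawn dataset of size n together with its design label."""

    x1: np.ndarray
    x2: np.ndarray
    y: np.ndarray
    design: str
    screen_attempts: int = 1

    def __post_init__(self):
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.x1.shape == self.x2.shape == self.y.shape):
            raise InvalidSpecError("sample columns must have equal length")
        # 3 regression coefficients need slack below them
        if self.n < 5:
            raise InvalidSpecError(f"sample size must be >= 5, got {self.n}")
        if self.design not in (SRS, RSS):
            raise InvalidSpecError(f"unknown design {self.design!r}")

    @property
    def n(self) -> int:
        return self.x1.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x1": self.x1, "x2": self.x2, "y": self.y})

    def to_csv(self, path, na_token: str = "NA") -> None:
        self.to_frame().to_csv(path, index=False, na_rep=na_token)


@dataclasses.dataclass(frozen=True)
class RSSConfig:
    """Ranked-set layout: ``set_size`` units ranked per set, ``cycles`` cycles.

    ``set_size * cycles`` must equal the requested sample size.  ``rank_on``
    selects the covariate used for (perfect) ranking; the auxiliary ``x2``
    carries the quartile adjustment downstream and is the default.
    """

    set_size: int
    rank_on: str = "x2"
    cycles: int = 1

    def __post_init__(self):
        if self.set_size < 1 or self.cycles < 1:
            raise ConfigError("set_size and cycles must be positive")
        if self.rank_on not in ("x1", "x2"):
            raise ConfigError(f"rank_on must be 'x1' or 'x2', got {self.rank_on!r}")


def _distinct_rows(rng: np.random.Generator, high: int, nrows: int, ncols: int) -> np.ndarray:
    """``nrows`` independent uniform without-replacement index samples.

    Each row is a sample of ``ncols`` distinct integers from ``range(high)``.
    Implemented by batch-redrawing colliding entries, which is equivalent to
    sequential rejection sampling and therefore uniform over distinct sets.
    """
    if ncols > high:
        raise SamplingError(f"cannot draw {ncols} distinct units from {high}")
    idx = rng.integers(0, high, size=(nrows, ncols))
    while True:
        order = np.argsort(idx, axis=1, kind="stable")
        svals = np.take_along_axis(idx, order, axis=1)
        dup_sorted = np.zeros(idx.shape, dtype=bool)
        dup_sorted[:, 1:] = svals[:, 1:] == svals[:, :-1]
        ndup = int(dup_sorted.sum())
        if ndup == 0:
            return idx
        dup = np.zeros_like(dup_sorted)
        np.put_along_axis(dup, order, dup_sorted, axis=1)
        idx[dup] = rng.integers(0, high, size=ndup)


def _assemble(pop: PopulationTable, idx: np.ndarray, design: str, beta: RegressionSpec) -> Sample:
    x1 = pop.x1[idx]
    x2 = pop.x2[idx]
    y = make_response(x1, x2, pop.eps[idx], beta)
    return Sample(x1, x2, y, design)


def srs_draw(
    pop: PopulationTable,
    n: int,
    seed=None,
    beta: RegressionSpec = DEFAULT_BETA,
) -> Sample:
    """Simple random sample of ``n`` distinct population rows."""
    if n > pop.N:
        raise SamplingError(f"cannot draw n={n} from population of N={pop.N}")
    rng = as_rng(seed)
    idx = _distinct_rows(rng, pop.N, 1, n)[0]
    return _assemble(pop, idx, SRS, beta)


def _rss_choose(rank_values: np.ndarray, rng: np.random.Generator, cfg: RSSConfig, N: int):
    """Select RSS unit indices; returns (chosen indices, list of set matrices).

    For each cycle, ``set_size`` independent sets of ``set_size`` units are
    drawn without replacement within a set (with replacement between sets).
    Set i contributes the unit whose ranking value is i-th smallest; ties
    break by stable sort, so the lowest within-set draw position wins.
    """
    m = cfg.set_size
    chosen = []
    set_matrices = []
    pos = np.arange(m)
    for _ in range(cfg.cycles):
        sets = _distinct_rows(rng, N, m, m)
        vals = rank_values[sets]
        order = np.argsort(vals, axis=1, kind="stable")
        chosen.append(sets[pos, order[pos, pos]])
        set_matrices.append(sets)
    return np.concatenate(chosen), set_matrices


def rss_draw(
    pop: PopulationTable,
    n: int,
    cfg: RSSConfig | None = None,
    seed=None,
    beta: RegressionSpec = DEFAULT_BETA,
) -> Sample:
    """Ranked-set sample of size ``n`` with perfect ranking on true values."""
    if cfg is None:
        cfg = RSSConfig(set_size=n, cycles=1)
    if cfg.set_size * cfg.cycles != n:
        raise ConfigError(
            f"set_size*cycles = {cfg.set_size * cfg.cycles} does not match n={n}"
        )
    if cfg.set_size > pop.N:
        raise SamplingError(f"set_size {cfg.set_size} exceeds population size {pop.N}")
    rng = as_rng(seed)
    rank_values = pop.x1 if cfg.rank_on == "x1" else pop.x2
    idx, _ = _rss_choose(rank_values, rng, cfg, pop.N)
    return _assemble(pop, idx, RSS, beta)


def pearson_r(x, y) -> float:
    """Pearson correlation of two vectors (n-1 denominators cancel)."""
    return float(np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1])


def screened_sample(draw, threshold: float = 0.6, max_tries: int = 100, rng=None) -> Sample:
    """Redraw until the sampled covariates pass the multicollinearity screen.

    ``draw`` is a closure mapping a :class:`numpy.random.Generator` to a
    :class:`Sample`.  The first sample with ``|r(x1, x2)| < threshold`` is
    returned with its attempt count recorded on ``screen_attempts``; when
    ``max_tries`` draws all fail, a :class:`ScreeningError` carrying the last
    correlation is raised.
    """
    if not 0 < threshold <= 1:
        raise InvalidSpecError(f"threshold must be in (0, 1], got {threshold}")
    if max_tries < 1:
        raise InvalidSpecError("max_tries must be positive")
    rng = as_rng(rng)
    last_r = float("nan")
    for attempt in range(1, max_tries + 1):
        sample = draw(rng)
        last_r = pearson_r(sample.x1, sample.x2)
        if abs(last_r) < threshold:
            sample.screen_attempts = attempt
            return sample
    raise ScreeningError(
        f"multicollinearity screen failed {max_tries} times; last |r|={abs(last_r):.4f}",
        last_r=last_r,
        tries=max_tries,
    )
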