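"""Run configuration and result-file plumbing.

Configurations are YAML or JSON mappings (YAML being a superset, one loader
covers both); an empty file expands to the full default grid at 1,000
replications.  Unknown keys are rejected so typos fail loudly.  Result CSVs
are written deterministically — fixed column order, sorted rows, floats at 6
significant digits, and a content hash instead of a timestamp — so repeated
runs of the same table are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.metadata
import io

import pandas as pd
import yaml

from .evaluation import DEFAULT_NS, DEFAULT_PCTS, DEFAULT_SIGMA2S, RESULT_COLUMNS
from .exceptions import ConfigError
from .imputers import METHOD_NAMES
from .sampling import RSS, SRS

__all__ = ["RunConfig", "load_config", "save_config", "write_results", "read_results"]


def _package_version() -> str:
    try:
        return importlib.metadata.version("ratioimpute")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclasses.dataclass
class RunConfig:
    """Validated simulation run configuration with grid defaults filled in."""

    designs: tuple[str, ...] = (SRS, RSS)
    ns: tuple[int, ...] = DEFAULT_NS
    pcts: tuple[float, ...] = DEFAULT_PCTS
    sigma2s: tuple[float, ...] = DEFAULT_SIGMA2S
    methods: tuple[str, ...] = METHOD_NAMES
    alpha: float | None = None
    eps1: float | None = None
    omega1: float | None = None
    reps: int = 1000
    seed: int = 0
    out: str = "results.csv"
    na_token: str = "NA"
    log_level: str = "INFO"
    jobs: int = 1

    def __post_init__(self):
        self.designs = tuple(str(d).upper() for d in self.designs)
        for d in self.designs:
            if d not in (SRS, RSS):
                raise ConfigError(f"unknown design {d!r}")
        self.ns = tuple(int(n) for n in self.ns)
        if any(n < 5 for n in self.ns):
            raise ConfigError("sample sizes must be >= 5")
        self.pcts = tuple(float(p) for p in self.pcts)
        if any(not 0 <= p < 1 for p in self.pcts):
            raise ConfigError("missing percentages must be in [0, 1)")
        self.sigma2s = tuple(float(s) for s in self.sigma2s)
        if any(s <= 0 for s in self.sigma2s):
            raise ConfigError("error variances must be positive")
        self.methods = tuple(str(m).lower() for m in self.methods)
        for m in self.methods:
            if m not in METHOD_NAMES:
                raise ConfigError(
                    f"unknown method {m!r}; expected one of {', '.join(METHOD_NAMES)}"
                )
        if int(self.reps) < 1:
            raise ConfigError(f"reps must be positive, got {self.reps}")
        self.reps = int(self.reps)
        self.seed = int(self.seed)
        if int(self.jobs) < 1:
            raise ConfigError("jobs must be positive")
        self.jobs = int(self.jobs)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("configuration must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("designs", "ns", "pcts", "sigma2s", "methods"):
            d[key] = list(d[key])
        return d


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration file."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def write_results(table: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a result table as deterministic CSV with a metadata header."""
    df = table.copy()
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            raise ConfigError(f"result table is missing column {col!r}")
    df = df[RESULT_COLUMNS].sort_values(
        ["design", "sigma2", "n", "pct", "method"], kind="stable"
    )
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.6g")
    body = buf.getvalue()
    digest = hashlib.sha256(body.encode()).hexdigest()[:16]
    header = f"# ratioimpute {_package_version()}\n"
    if seed is not None:
        header += f"# seed {seed}\n"
    header += f"# sha256 {digest}\n"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header + body)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
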