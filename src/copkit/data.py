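"""Data containers for correlate-of-protection analyses.

The package works with three levels of data:

* :class:`TwoByTwo` — arm sizes and event counts of a two-arm binary-outcome
  comparison, the minimal sufficient statistic for a treatment-only fit;
* :class:`TrialData` — subject-level records ``(Z, S, T)`` of one randomized
  trial (binary treatment, continuous surrogate, binary clinical endpoint);
* :class:`MultiSubgroupData` — subject-level records of a single trial split
  into randomized subgroups (centers, regions), the meta-analytic input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegressionData",
    "TwoByTwo",
    "TrialData",
    "MultiSubgroupData",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains missing or non-finite values; "
                         "resolve missingness upstream")
    return arr


def _check_binary(x: np.ndarray, name: str) -> np.ndarray:
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError(f"{name} must be coded 0/1")
    return x


@dataclass
class RegressionData:
    """A design matrix with named columns and an outcome vector.

    ``predictors`` must already contain an intercept column when one is
    wanted; the fitters never add one implicitly.
    """

    outcome: np.ndarray
    predictors: pd.DataFrame

    def __post_init__(self) -> None:
        self.outcome = _as_1d(self.outcome, "outcome")
        if not isinstance(self.predictors, pd.DataFrame):
            self.predictors = pd.DataFrame(np.asarray(self.predictors, dtype=float))
        if len(self.outcome) != len(self.predictors):
            raise ValueError("outcome length and predictor row count differ")
        if not np.all(np.isfinite(self.predictors.to_numpy())):
            raise ValueError("predictors contain missing or non-finite values")

    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def names(self) -> list[str]:
        return [str(c) for c in self.predictors.columns]

    @property
    def exog(self) -> np.ndarray:
        return self.predictors.to_numpy(dtype=float)


@dataclass(frozen=True)
class TwoByTwo:
    """Arm sizes and event counts: ``n_c``/``n_v`` subjects, ``e_c``/``e_v`` events."""

    n_c: int
    n_v: int
    e_c: int
    e_v: int

    def __post_init__(self) -> None:
        for f in ("n_c", "n_v", "e_c", "e_v"):
            v = getattr(self, f)
            if int(v) != v or v < 0:
                raise ValueError(f"{f} must be a nonnegative integer")
        if not (0 <= self.e_c <= self.n_c and 0 <= self.e_v <= self.n_v):
            raise ValueError("event counts must not exceed arm sizes")

    def expand(self, coding: str = "pm1") -> RegressionData:
        """Expand to subject rows with an intercept and a treatment column.

        ``coding='pm1'`` codes control as -1 and vaccinated as +1;
        ``coding='01'`` codes them 0/1.
        """
        lo = {"pm1": -1.0, "01": 0.0}
        if coding not in lo:
            raise ValueError(f"unknown coding {coding!r}; use 'pm1' or '01'")
        y = np.r_[np.ones(self.e_c), np.zeros(self.n_c - self.e_c),
                  np.ones(self.e_v), np.zeros(self.n_v - self.e_v)]
        z = np.r_[np.full(self.n_c, lo[coding]), np.ones(self.n_v)]
        X = pd.DataFrame({"intercept": np.ones_like(z), "treatment": z})
        return RegressionData(y, X)

    @staticmethod
    def read_csv(path) -> list["TwoByTwo"]:
        """Read one table per row from a CSV with columns n_c,n_v,e_c,e_v."""
        df = pd.read_csv(path)
        return [TwoByTwo(int(r.n_c), int(r.n_v), int(r.e_c), int(r.e_v))
                for r in df.itertuples()]


@dataclass
class TrialData:
    """Subject-level ``(Z, S, T)`` records of a single randomized trial."""

    z: np.ndarray
    s: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.z = _check_binary(_as_1d(self.z, "z"), "z")
        self.s = _as_1d(self.s, "s")
        self.t = _check_binary(_as_1d(self.t, "t"), "t")
        if not (len(self.z) == len(self.s) == len(self.t)):
            raise ValueError("z, s, t must have equal length")
        if self.z.min() == self.z.max():
            raise ValueError("both treatment arms must be represented")

    @property
    def n(self) -> int:
        return len(self.z)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, z: str = "z", s: str = "s",
                       t: str = "t") -> "TrialData":
        return cls(df[z].to_numpy(), df[s].to_numpy(), df[t].to_numpy())

    @classmethod
    def read_csv(cls, path, **cols) -> "TrialData":
        return cls.from_dataframe(pd.read_csv(path), **cols)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z.astype(int), "s": self.s,
                             "t": self.t.astype(int)})


@dataclass
class MultiSubgroupData:
    """Subject-level records of a trial split into randomized subgroups.

    The clinical endpoint ``t`` may be binary (for logistic/Firth/WIP
    stage-one fits) or continuous (for Gaussian fits).
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("subgroup", "z", "s", "t")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        _check_binary(_as_1d(self.frame["z"].to_numpy(), "z"), "z")
        _as_1d(self.frame["s"].to_numpy(), "s")
        _as_1d(self.frame["t"].to_numpy(), "t")

    @property
    def subgroups(self) -> list:
        return sorted(self.frame["subgroup"].unique().tolist())

    @property
    def n_subgroups(self) -> int:
        return self.frame["subgroup"].nunique()

    @property
    def t_is_binary(self) -> bool:
        return bool(np.isin(self.frame["t"].to_numpy(), (0.0, 1.0)).all())

    def iter_subgroups(self):
        for sid, grp in self.frame.groupby("subgroup", sort=True):
            yield sid, grp

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MultiSubgroupData":
        return cls(df[list(cls.REQUIRED)].copy())

    @classmethod
    def read_csv(cls, path) -> "MultiSubgroupData":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        return self.frame.copy()
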