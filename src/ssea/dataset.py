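"""Long-format factorial datasets and analysis-scale transforms.

A multiple-driver factorial experiment is stored in long format: one row per
replicate unit, with label columns identifying the experimental unit (species,
genotype, female...), an optional environmental context, the levels of the two
drivers, a replicate id, and a numeric response.  Survival proportions may
additionally carry the number of binomial trials behind each proportion
(``n_trials``), which enables the continuity adjustment used when analysing
0/1 proportions on the log or logit scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SSEAError",
    "MissingCellError",
    "ScaleSpec",
    "transform_scale",
    "FactorialDataset",
    "read_factorial_csv",
]


class SSEAError(ValueError):
    """Base error for invalid data or requests."""


class MissingCellError(SSEAError):
    """A required driver-level combination has no observations."""


#: canonical column names; ``context`` and ``n_trials`` are optional on input
REQUIRED_COLUMNS = ("unit", "driver1", "driver2", "replicate", "response")
LABEL_COLUMNS = ("unit", "context", "driver1", "driver2", "replicate")


@dataclass(frozen=True)
class ScaleSpec:
    """Analysis scale for responses.

    Parameters
    ----------
    name:
        ``"raw"`` (identity), ``"log"`` (natural log; turns a multiplicative
        joint-effect null model into an additive one) or ``"logit"``
        (log-odds of a proportion; keeps survival effects linear while
        probabilities stay bounded).
    zero_one_adjustment:
        Continuity constant ``c`` for proportions at the domain boundary.
        When per-replicate trial counts ``n`` are available, each proportion
        ``x`` is shrunk to ``(x*n + c) / (n + 2*c)`` before transforming
        (``c = 0.5`` gives the classic empirical adjustment
        ``(x*n + 0.5) / (n + 1)``).  Without trial counts no adjustment is
        applied and values must lie strictly inside the transform domain.
    """

    name: str = "raw"
    zero_one_adjustment: float = 0.5

    def __post_init__(self) -> None:
        if self.name not in ("raw", "log", "logit"):
            raise SSEAError(f"unknown scale {self.name!r}; use raw, log or logit")
        if self.zero_one_adjustment < 0:
            raise SSEAError("zero_one_adjustment must be nonnegative")


def transform_scale(
    values: Sequence[float] | np.ndarray,
    spec: ScaleSpec,
    n_trials: Sequence[float] | np.ndarray | None = None,
) -> np.ndarray:
    """Map responses onto the analysis scale defined by ``spec``.

    The transform is strictly monotone; a value outside the transform domain
    (after any continuity adjustment) raises :class:`SSEAError` naming the
    offending value and its position.
    """
    x = np.asarray(values, dtype=float)
    if spec.name == "raw":
        return x.copy()

    c = spec.zero_one_adjustment
    if n_trials is not None and c > 0:
        n = np.asarray(n_trials, dtype=float)
        if n.shape not in ((), x.shape):
            n = np.broadcast_to(n, x.shape)
        adj = (x * n + c) / (n + 2.0 * c)
    else:
        adj = x

    if spec.name == "log":
        bad = ~(adj > 0)
    else:  # logit
        bad = ~((adj > 0) & (adj < 1))
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise SSEAError(
            f"value {x.flat[i]!r} (row {i}) is outside the {spec.name} domain "
            f"after adjustment (adjusted value {adj.flat[i]!r}); supply n_trials "
            "or a positive zero_one_adjustment for boundary proportions"
        )
    if spec.name == "log":
        return np.log(adj)
    return np.log(adj / (1.0 - adj))


class FactorialDataset:
    """Replicate-level observations from an orthogonal factorial experiment.

    Wraps a :class:`pandas.DataFrame` with canonical columns ``unit``,
    ``context``, ``driver1``, ``driver2``, ``replicate``, ``response`` and the
    optional ``n_trials``.  Extra columns (e.g. ``species``, ``female``,
    ``treatment`` from the simulators) are preserved and available to the
    model-selection layer.
    """

    def __init__(self, df: pd.DataFrame, copy: bool = True) -> None:
        if copy:
            df = df.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SSEAError(f"missing required column(s): {', '.join(missing)}")
        if len(df) == 0:
            # empty datasets are legal (they decompose to an empty table)
            df = df.copy()
        if "context" not in df.columns:
            df["context"] = ""
        for col in LABEL_COLUMNS:
            df[col] = df[col].astype(str)
        resp = pd.to_numeric(df["response"], errors="coerce")
        bad = resp.isna() & df["response"].notna() | df["response"].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SSEAError(
                f"non-numeric response {df['response'].iloc[row]!r} at row {row}"
            )
        if df["response"].dtype == object:
            # exact (correctly rounded) parse so CSV round-trips bit-for-bit
            df["response"] = np.array([float(v) for v in df["response"]])
        else:
            df["response"] = resp.astype(float)
        if not np.isfinite(df["response"].to_numpy()).all():
            row = int(np.flatnonzero(~np.isfinite(df["response"].to_numpy()))[0])
            raise SSEAError(f"non-finite response at row {row}")
        if "n_trials" in df.columns:
            nt = pd.to_numeric(df["n_trials"], errors="coerce")
            if nt.isna().any():
                row = int(np.flatnonzero(nt.isna().to_numpy())[0])
                raise SSEAError(f"non-numeric n_trials at row {row}")
            df["n_trials"] = nt.astype(float)
        self._df = df.reset_index(drop=True)

    # -- basic container protocol -------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FactorialDataset):
            return NotImplemented
        return self._df.equals(other._df)

    # -- level/label accessors (order of first appearance is the declared order) --
    @property
    def units(self) -> list[str]:
        return list(pd.unique(self._df["unit"]))

    @property
    def contexts(self) -> list[str]:
        return list(pd.unique(self._df["context"]))

    @property
    def driver1_levels(self) -> list[str]:
        return list(pd.unique(self._df["driver1"]))

    @property
    def driver2_levels(self) -> list[str]:
        return list(pd.unique(self._df["driver2"]))

    def subset(
        self,
        unit: str | None = None,
        context: str | None = None,
        driver_levels: tuple[Iterable[str], Iterable[str]] | None = None,
    ) -> "FactorialDataset":
        """Restrict to one unit and/or context and/or a set of driver levels."""
        m = np.ones(len(self._df), dtype=bool)
        if unit is not None:
            m &= (self._df["unit"] == unit).to_numpy()
        if context is not None:
            m &= (self._df["context"] == context).to_numpy()
        if driver_levels is not None:
            d1, d2 = (set(map(str, lv)) for lv in driver_levels)
            m &= self._df["driver1"].isin(d1).to_numpy()
            m &= self._df["driver2"].isin(d2).to_numpy()
        return FactorialDataset(self._df.loc[m], copy=True)

    def cell(
        self, driver1_level: str, driver2_level: str,
        unit: str | None = None, context: str | None = None,
    ) -> pd.DataFrame:
        """Rows of one driver-level combination (optionally one unit/context)."""
        m = (self._df["driver1"] == str(driver1_level)) & (
            self._df["driver2"] == str(driver2_level)
        )
        if unit is not None:
            m &= self._df["unit"] == unit
        if context is not None:
            m &= self._df["context"] == context
        return self._df.loc[m]

    # -- CSV I/O -------------------------------------------------------------------
    @classmethod
    def read_csv(
        cls, path, column_map: Mapping[str, str] | None = None
    ) -> "FactorialDataset":
        """Read a long-format CSV.

        ``column_map`` maps canonical names to the file's column names, e.g.
        ``{"unit": "genotype", "driver1": "temperature"}``.
        """
        try:
            raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            raise SSEAError(f"empty input file: {path}") from None
        if column_map:
            rename = {v: k for k, v in column_map.items()}
            missing = [v for v in column_map.values() if v not in raw.columns]
            if missing:
                raise SSEAError(
                    f"mapped column(s) not found in {path}: {', '.join(missing)}"
                )
            raw = raw.rename(columns=rename)
        missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
        if missing:
            raise SSEAError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        for col in ("response", "n_trials"):
            if col in raw.columns:
                blank = raw[col].str.strip() == ""
                if col == "response" and blank.any():
                    row = int(np.flatnonzero(blank.to_numpy())[0])
                    raise SSEAError(f"{path}: blank response at row {row}")
        return cls(raw, copy=False)

    def write_csv(self, path) -> None:
        self._df.to_csv(path, index=False)


def read_factorial_csv(path, column_map: Mapping[str, str] | None = None) -> FactorialDataset:
    """Functional alias for :meth:`FactorialDataset.read_csv`."""
    return FactorialDataset.read_csv(path, column_map=column_map)
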