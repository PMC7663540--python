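"""Reading, writing and preparation of omics matrices and survival tables.

An omics layer is a samples x variables numeric matrix stored as delimited
text with a header row of variable names and a first column of sample IDs.
Survival outcomes live in a three-column table (``sample``, ``time``,
``status``) with positive times and a 0/1 event indicator (1 = observed
event, 0 = right-censored).

All downstream analysis operates on column-standardized matrices (mean 0,
sample variance 1 with the n-1 divisor), so that every covariance computed
later is a Pearson correlation and a single standardized variable has
cluster homogeneity exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "SurvivalOutcome",
    "load_omics_matrix",
    "write_omics_matrix",
    "load_survival",
    "write_survival",
    "standardize",
    "align_samples",
]

#: tolerance used when checking that a column is standardized
STANDARD_TOL = 1e-8


@dataclass
class OmicsMatrix:
    """One omics layer: a samples x variables numeric matrix with names.

    Parameters
    ----------
    layer_id : str
        Short label for the layer (e.g. ``"D"`` for DNA methylation,
        ``"MR"`` for mRNA, ``"MI"`` for miRNA).
    data : pandas.DataFrame
        Numeric matrix, index = sample IDs, columns = variable names.
    standardized : bool
        Whether every column has mean 0 and unit sample variance.
    """

    layer_id: str
    data: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample IDs in layer {self.layer_id!r}: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicated variable names in layer {self.layer_id!r}: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError(f"non-numeric values in layer {self.layer_id!r}")
        if np.isnan(values).any():
            rows, cols_ix = np.nonzero(np.isnan(values))
            where = (self.data.index[rows[0]], self.data.columns[cols_ix[0]])
            raise ValueError(
                f"missing value in layer {self.layer_id!r} at sample {where[0]!r}, "
                f"variable {where[1]!r}; impute before loading"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def variable_names(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]


@dataclass
class SurvivalOutcome:
    """Right-censored survival outcome for a set of samples.

    ``time`` must be positive (same units throughout a study); ``event`` is
    1 for an observed event and 0 for censoring.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("duplicated sample IDs in survival outcome")
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise ValueError("sample_ids, time and event must have equal length")
        if not np.all(self.time > 0):
            raise ValueError("all survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        self.event = self.event.astype(int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "status": self.event},
            index=pd.Index(self.sample_ids, name="sample"),
        )

    def subset(self, ids: list[str]) -> "SurvivalOutcome":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        ix = [pos[s] for s in ids]
        return SurvivalOutcome(list(ids), self.time[ix], self.event[ix])


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def load_omics_matrix(path: str | Path, layer_id: str, sep: str | None = None) -> OmicsMatrix:
    """Read one omics layer from delimited text.

    The delimiter is inferred from the extension (``.csv`` -> comma,
    anything else -> tab) unless ``sep`` overrides it.  The result is
    unstandardized; call :func:`standardize` before analysis.
    """
    delim = _sep_for(path, sep)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delim)[1:]
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicated variable names in {path}: {dups}")
    df = pd.read_csv(path, sep=delim, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        raise ValueError(
            f"non-numeric cell in {path}: variable {col!r}"
            + (f", sample {row[0]!r}" if len(row) else "")
        )
    return OmicsMatrix(layer_id=layer_id, data=df.astype(float))


def write_omics_matrix(m: OmicsMatrix, path: str | Path, sep: str | None = None) -> None:
    """Write a layer back to delimited text, preserving full float precision.

    Values are written as shortest round-trip representations; reading the
    file back reproduces them bit for bit.
    """
    m.data.rename_axis("sample").to_csv(path, sep=_sep_for(path, sep))


def load_survival(path: str | Path, sep: str | None = None) -> SurvivalOutcome:
    """Read a survival table with columns ``sample``, ``time``, ``status``."""
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    missing = {"sample", "time", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table {path} lacks columns: {sorted(missing)}")
    return SurvivalOutcome(
        df["sample"].astype(str).tolist(),
        df["time"].to_numpy(dtype=float),
        df["status"].to_numpy(),
    )


def write_survival(s: SurvivalOutcome, path: str | Path, sep: str | None = None) -> None:
    s.to_frame().reset_index().to_csv(path, sep=_sep_for(path, sep), index=False,
                                      float_format="%.17g")


def standardize(m: OmicsMatrix) -> OmicsMatrix:
    """Center and scale every column to mean 0, sample variance 1 (n-1 divisor).

    Idempotent up to :data:`STANDARD_TOL`.  Constant columns carry no
    correlation information and are rejected by name.
    """
    if m.n_samples < 3:
        raise ValueError("standardization requires at least 3 samples")
    values = m.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        names = [m.variable_names[i] for i in const]
        raise ValueError(f"constant column(s) in layer {m.layer_id!r}: {names}")
    out = (values - mean) / sd
    return replace(m, data=pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
                   standardized=True)


def check_standardized(values: np.ndarray, tol: float = STANDARD_TOL) -> None:
    """Raise if any column deviates from mean 0 / unit sample variance."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=1)
    if np.abs(mean).max() > tol or np.abs(var - 1).max() > 100 * tol:
        raise ValueError("input columns must be standardized (mean 0, unit sample variance)")


def align_samples(
    matrices: list[OmicsMatrix], survival: SurvivalOutcome
) -> tuple[list[OmicsMatrix], SurvivalOutcome]:
    """Restrict all layers and the survival table to their common samples.

    Samples are returned in sorted-ID order so downstream results do not
    depend on file row order.
    """
    common = set(survival.sample_ids)
    for m in matrices:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("no samples shared by all omics layers and the survival table")
    order = sorted(common)
    out = [replace(m, data=m.data.loc[order]) for m in matrices]
    return out, survival.subset(order)
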