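"""Tabular data I/O and the bundled Hald cement dataset.

The Hald data are the classical multiple-regression benchmark: heat evolved
in calories per gram of cement (Y) against the amounts of four clinker
ingredients — tricalcium aluminate (X1), tricalcium silicate (X2),
tetracalcium alumino-ferrite (X3) and dicalcium silicate (X4) — for 13
cement mixes.  Because cement chemistry requires at least two reacting
components, single-regressor candidates are conventionally excluded when
selecting among the subsets.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .criteria import CandidateModel
from .exceptions import DataLoadError, InsufficientDataError

__all__ = ["load_table", "write_table", "hald", "design_from_frame", "adjusted_r2"]


def load_table(path, response: str | None = None) -> pd.DataFrame:
    """Read a delimiter-separated numeric table (comma or tab, auto-detected).

    The table must be rectangular, fully numeric and free of missing values;
    violations raise ``DataLoadError`` naming the offending cell.  When
    ``response`` is given its presence among the columns is checked.
    """
    try:
        frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise DataLoadError(f"could not parse {path}: {exc}") from exc
    if frame.empty or frame.shape[1] < 2:
        raise DataLoadError(f"{path}: expected a header row and at least two columns")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataLoadError(
                f"{path}: non-numeric or missing value in column {col!r}, data row {row + 1}"
            )
        frame[col] = numeric.astype(float)
    if response is not None and response not in frame.columns:
        raise DataLoadError(
            f"{path}: response column {response!r} not found among {list(frame.columns)}"
        )
    return frame


def write_table(frame: pd.DataFrame, path, sep: str = "\t", header_lines=()) -> None:
    """Write a numeric table as delimiter-separated text at full precision.

    ``header_lines`` are emitted first as '#'-prefixed provenance comments.
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep=sep, index=False, float_format="%.17g")


def hald() -> pd.DataFrame:
    """The 13-observation Hald cement dataset (columns X1..X4, Y)."""
    with resources.files("picselect.data").joinpath("hald.csv").open() as fh:
        frame = pd.read_csv(fh)
    return frame.astype(float)


def design_from_frame(frame: pd.DataFrame, response: str):
    """Split a loaded table into (y, X, regressor names), response excluded."""
    if response not in frame.columns:
        raise DataLoadError(f"response column {response!r} not in table")
    names = [c for c in frame.columns if c != response]
    return frame[response].to_numpy(), frame[names].to_numpy(), names


def adjusted_r2(y, X, model: CandidateModel) -> float:
    """Adjusted R^2 of the OLS fit of a candidate submodel (with intercept)."""
    y = np.asarray(y, dtype=float).ravel()
    Xm = model.columns(np.asarray(X, dtype=float))
    n, p = Xm.shape
    if n <= p + 1:
        raise InsufficientDataError(f"need n > p + 1 = {p + 1}, got n = {n}")
    res = sm.OLS(y, sm.add_constant(Xm)).fit()
    return float(res.rsquared_adj)
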