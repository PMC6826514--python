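"""Spot-table input, validity filtering and iterative median normalization.

Two-color microarray scanners report, for every printed spot, a foreground
and a local-background intensity per channel.  This module reads such tables
(a GPR-like two-channel dialect or a generic pre-normalized one), discards
spots that cannot be trusted — control spots, locally corrupted spots, and
spots whose foreground does not rise sufficiently above background in *any*
sample — and rescales the surviving expression values by alternating
intra-array (each array's median of valid spots to 1) and inter-array
(median-of-ratios against a cross-array reference) normalization until the
largest relative change between successive iterations falls below a
tolerance.

A spot table is a tidy :class:`pandas.DataFrame` with one row per
(spot, condition, replicate) and the columns in :data:`SPOT_COLUMNS`;
``foreground_2``/``background_2`` are present only for two-channel data.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TableDialect",
    "GPR_TWO_CHANNEL",
    "PRENORMALIZED",
    "SpotFilterReport",
    "NormalizedMatrix",
    "SchemaError",
    "RaggedDesignError",
    "ConvergenceError",
    "read_spot_table",
    "filter_spots",
    "to_expression",
    "normalize_iterative",
    "write_normalized_tsv",
]

#: canonical column order of a raw spot table
SPOT_COLUMNS = [
    "spot_id",
    "transcript_id",
    "condition",
    "replicate",
    "foreground",
    "background",
    "is_control",
    "is_corrupted",
]


class SchemaError(ValueError):
    """A mandatory column is missing or has the wrong type."""


class RaggedDesignError(ValueError):
    """A spot is present in only a subset of the condition x replicate samples."""


class ConvergenceError(RuntimeError):
    """Iterative normalization did not converge; carries the error trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class TableDialect:
    """How to map a file's columns onto the canonical spot-table schema.

    ``kind`` is ``"two_channel"`` (raw foreground/background intensities,
    possibly two channels) or ``"prenormalized"`` (a single ``value`` column).
    ``channel_rule`` chooses how two channels collapse into one expression
    value: ``"single"`` (channel 1 only), ``"ratio"`` (ch1/ch2) or
    ``"geomean"`` (geometric mean), always on background-subtracted
    intensities clipped at ``floor``.
    """

    kind: str = "two_channel"
    column_map: dict = field(default_factory=dict)
    sep: str = "\t"
    channel_rule: str = "single"
    floor: float = 1e-6

    def resolve(self, name: str) -> str:
        return self.column_map.get(name, name)


#: GenePix-style two-color dialect (F635/B635 = channel 1, F532/B532 = channel 2)
GPR_TWO_CHANNEL = TableDialect(
    kind="two_channel",
    column_map={
        "foreground": "F635",
        "background": "B635",
        "foreground_2": "F532",
        "background_2": "B532",
    },
)

PRENORMALIZED = TableDialect(kind="prenormalized")


@dataclass
class SpotFilterReport:
    """Tally of the validity filter; one spot counts once, in rule order
    control -> corrupted -> low-signal."""

    n_input: int
    n_removed_control: int
    n_removed_corrupted: int
    n_removed_low_signal: int
    n_valid: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class NormalizedMatrix:
    """Normalized expression values with convergence metadata.

    ``values`` is a tidy frame (spot_id, transcript_id, condition,
    replicate, value); ``error_trace`` holds the maximum relative change
    after each iteration.
    """

    values: pd.DataFrame
    iterations: int
    final_error: float
    error_trace: list[float] = field(default_factory=list)


def _required_columns(dialect: TableDialect) -> list[str]:
    base = ["spot_id", "transcript_id", "condition", "replicate"]
    if dialect.kind == "prenormalized":
        return base + ["value"]
    cols = base + ["foreground", "background"]
    if dialect.channel_rule in ("ratio", "geomean"):
        cols += ["foreground_2", "background_2"]
    return cols


def read_spot_table(path, dialect: TableDialect = GPR_TWO_CHANNEL) -> pd.DataFrame:
    """Read a spot-level table, validating schema and numeric fields.

    Rows with unparseable numerics are dropped and reported in
    ``table.attrs["bad_rows"]`` as ``(line_number, reason)`` pairs
    (line numbers are 1-based file lines including the header).

    Raises
    ------
    SchemaError
        if a mandatory column (after dialect mapping) is absent.
    """
    if isinstance(path, (str, os.PathLike)) and not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    required = _required_columns(dialect)
    rename = {dialect.resolve(c): c for c in required if dialect.resolve(c) in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    numeric = [c for c in required if c not in ("spot_id", "transcript_id", "condition")]
    bad_rows: list[tuple[int, str]] = []
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[parsed.isna() & df[col].notna()]:
            bad_rows.append((int(idx) + 2, f"non-numeric {col}: {df.at[idx, col]!r}"))
        df[col] = parsed
    keep = df[numeric].notna().all(axis=1)
    df = df[keep].copy()

    for flag in ("is_control", "is_corrupted"):
        if flag in df.columns:
            df[flag] = (
                df[flag].astype(str).str.strip().str.lower().isin(("1", "true", "yes"))
            )
        else:
            df[flag] = False
    df["replicate"] = df["replicate"].astype(int)

    value_cols = [c for c in numeric if c != "replicate"]
    if (df[value_cols] < 0).any().any():
        raise SchemaError("negative intensity values are not allowed")

    dup = df.duplicated(subset=["condition", "replicate", "spot_id"])
    if dup.any():
        raise SchemaError("duplicate (condition, replicate, spot_id) rows")

    df = df.reset_index(drop=True)
    df.attrs["bad_rows"] = bad_rows
    df.attrs["dialect_kind"] = dialect.kind
    return df


def _check_complete_design(table: pd.DataFrame) -> pd.DataFrame:
    """Every spot must be measured in every condition x replicate sample."""
    samples = table[["condition", "replicate"]].drop_duplicates()
    n_samples = len(samples)
    counts = table.groupby("spot_id").size()
    ragged = counts[counts != n_samples]
    if len(ragged):
        raise RaggedDesignError(
            f"{len(ragged)} spot(s) missing from some samples, e.g. "
            f"{ragged.index[0]!r} seen in {ragged.iloc[0]}/{n_samples} samples"
        )
    return samples


def filter_spots(
    table: pd.DataFrame, snr_factor: float = 2.0
) -> tuple[pd.DataFrame, SpotFilterReport]:
    """Apply the spot-validity rules, removing failing spots from ALL samples.

    A spot is disqualified globally when it is a control spot, is flagged as
    corrupted in any sample, or its foreground is *strictly less than*
    ``snr_factor`` times its background in any sample (any channel).  The
    report attributes each removed spot to the first matching rule, in the
    order control -> corrupted -> low-signal.
    """
    if table.empty:
        raise ValueError("empty spot table")
    _check_complete_design(table)

    grouped = table.groupby("spot_id", sort=False)
    control = grouped["is_control"].any()
    corrupted = grouped["is_corrupted"].any()

    low = table["foreground"] < snr_factor * table["background"]
    if "foreground_2" in table.columns:
        low |= table["foreground_2"] < snr_factor * table["background_2"]
    low_signal = low.groupby(table["spot_id"], sort=False).any()

    n_control = int(control.sum())
    n_corrupted = int((corrupted & ~control).sum())
    n_low = int((low_signal & ~corrupted & ~control).sum())
    bad = control | corrupted | low_signal

    valid = table[~table["spot_id"].map(bad)].reset_index(drop=True)
    report = SpotFilterReport(
        n_input=int(len(control)),
        n_removed_control=n_control,
        n_removed_corrupted=n_corrupted,
        n_removed_low_signal=n_low,
        n_valid=int((~bad).sum()),
    )
    return valid, report


def to_expression(table: pd.DataFrame, dialect: TableDialect = GPR_TWO_CHANNEL) -> pd.DataFrame:
    """Collapse channel intensities into one positive expression value per row.

    Background-subtracted foreground, clipped at ``dialect.floor``; for
    two-channel rules the per-channel net intensities combine per
    ``dialect.channel_rule``.  Pre-normalized tables pass through.
    """
    out = table.copy()
    if dialect.kind == "prenormalized" or "value" in out.columns:
        if "value" not in out.columns:
            raise SchemaError("prenormalized dialect requires a 'value' column")
        out["value"] = out["value"].astype(float)
        return out
    net1 = np.maximum(out["foreground"] - out["background"], dialect.floor)
    if dialect.channel_rule == "single":
        value = net1
    elif dialect.channel_rule in ("ratio", "geomean"):
        net2 = np.maximum(out["foreground_2"] - out["background_2"], dialect.floor)
        value = net1 / net2 if dialect.channel_rule == "ratio" else np.sqrt(net1 * net2)
    else:
        raise ValueError(f"unknown channel rule {dialect.channel_rule!r}")
    out["value"] = value
    return out


def normalize_iterative(
    table: pd.DataFrame,
    tolerance: float = 0.05,
    max_iterations: int = 100,
) -> NormalizedMatrix:
    """Alternate intra- and inter-array median normalization to convergence.

    Each iteration (a) rescales every array (= condition x replicate sample)
    so its median over valid spots equals 1, then (b) rescales every array by
    the median of its spot-wise ratios to the cross-array median reference.
    Iteration stops when the maximum absolute relative change of any value
    between successive iterations drops below ``tolerance``.

    Deterministic for fixed input; invariant under global positive rescaling
    of the raw values (the first intra-array step removes any global factor).

    Raises
    ------
    ConvergenceError
        after ``max_iterations`` iterations; the exception carries the trace.
    ValueError
        on non-positive input values.
    """
    if "value" not in table.columns:
        raise ValueError("table lacks a 'value' column; run to_expression first")
    if (table["value"] <= 0).any():
        raise ValueError("normalization requires strictly positive values")
    _check_complete_design(table)

    wide = table.pivot_table(
        index="spot_id", columns=["condition", "replicate"], values="value", sort=False
    )
    mat = wide.to_numpy(dtype=float)

    trace: list[float] = []
    converged = False
    for _ in range(max_iterations):
        old = mat
        # inter-array: per-array median-of-ratios factor against the
        # per-spot cross-array median reference (scale-free)
        ref = np.median(mat, axis=1, keepdims=True)
        factor = np.median(mat / ref, axis=0, keepdims=True)
        mat = mat / factor
        # intra-array: median of valid spots to 1 (ends every iteration,
        # so converged output has unit array medians exactly)
        mat = mat / np.median(mat, axis=0, keepdims=True)
        err = float(np.max(np.abs(mat - old) / old))
        trace.append(err)
        if err < tolerance:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"no convergence after {max_iterations} iterations "
            f"(last error {trace[-1]:.4g} >= tolerance {tolerance})",
            trace,
        )

    norm = pd.DataFrame(mat, index=wide.index, columns=wide.columns)
    long = norm.stack(["condition", "replicate"], future_stack=True).rename("value").reset_index()
    meta = table[["spot_id", "transcript_id"]].drop_duplicates()
    long = long.merge(meta, on="spot_id", how="left")
    long = long[["spot_id", "transcript_id", "condition", "replicate", "value"]]
    return NormalizedMatrix(
        values=long,
        iterations=len(trace),
        final_error=trace[-1],
        error_trace=trace,
    )


def write_normalized_tsv(matrix: NormalizedMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index=False)
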