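"""Measurement tables, delimited I/O, log transformation and replicate-error summaries.

A :class:`MeasurementTable` holds linear measurements (in mm) for a set of
specimens, one column per variable, with one column designated the
*reference datum* -- the size axis (basal skull length in the crocodilian
dataset this package is patterned on) against which every other variable is
regressed.  :class:`LogTable` is the same shape after an elementwise
logarithm; keeping the two as distinct types prevents accidental double
transformation.

Measurement error of repeated caliper/tape measurements is summarised by
:func:`measurement_error_summary` as the average deviation (mean absolute
difference from the replicate mean) and the sample standard deviation of
each replicated (specimen, variable) record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ParseError, ValidationError

logger = logging.getLogger(__name__)

_NA_TOKENS = ("", "NA")

#: Below this raw size (mm) a measurement is assumed to have been taken with
#: digital calipers, at or above it with a fiberglass tape.
CALIPER_TAPE_THRESHOLD_MM = 150.0

INSTRUMENTS = ("caliper", "tape")


class _Table:
    """Shared behaviour of raw and log-transformed measurement tables."""

    def __init__(self, data: pd.DataFrame, reference_id: str):
        if reference_id not in data.columns:
            raise ConfigurationError(
                f"reference variable {reference_id!r} is not among the columns "
                f"{list(data.columns)}"
            )
        self._data = data
        self.reference_id = reference_id

    @property
    def data(self) -> pd.DataFrame:
        """Specimen x variable values (index = specimen ids)."""
        return self._data

    @property
    def specimen_ids(self) -> list:
        return list(self._data.index)

    @property
    def variable_ids(self) -> list:
        return list(self._data.columns)

    @property
    def non_reference_ids(self) -> list:
        return [v for v in self._data.columns if v != self.reference_id]

    @property
    def n_specimens(self) -> int:
        return len(self._data)

    def reference_values(self) -> np.ndarray:
        return self._data[self.reference_id].to_numpy(dtype=float)

    def pair(self, variable_id):
        """Pairwise complete-case (reference, variable) arrays for one variable."""
        sub = self._data[[self.reference_id, variable_id]].dropna()
        return (
            sub[self.reference_id].to_numpy(dtype=float),
            sub[variable_id].to_numpy(dtype=float),
        )

    def to_csv(self, path) -> None:
        """Write the table; missing cells become "NA", floats at full precision."""
        self._data.to_csv(path, index_label="specimen", na_rep="NA")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<{type(self).__name__} {self.n_specimens} specimens x "
            f"{len(self.variable_ids)} variables, reference={self.reference_id!r}>"
        )


class MeasurementTable(_Table):
    """Specimens x variables of positive linear measurements (mm).

    Invariants enforced at construction: every present value is strictly
    positive, and every specimen has a value for the reference variable
    (the reader drops offending rows before constructing the table).
    """

    def __init__(self, data: pd.DataFrame, reference_id: str):
        data = data.astype(float)
        super().__init__(data, reference_id)
        values = data.to_numpy(dtype=float)
        bad = np.argwhere(values <= 0)  # NaN compares False, so missing passes
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"non-positive measurement {values[r, c]!r} for specimen "
                f"{data.index[r]!r}, variable {data.columns[c]!r}"
            )
        if data[reference_id].isna().any():
            missing = data.index[data[reference_id].isna()][0]
            raise ValidationError(
                f"specimen {missing!r} is missing the reference value "
                f"{reference_id!r}; drop such rows before constructing the table"
            )
        #: Rows dropped by the reader because the reference value was missing.
        self.n_dropped_missing_reference: int = 0


class LogTable(_Table):
    """Log-transformed measurement table (dimensionless values, base recorded)."""

    def __init__(self, data: pd.DataFrame, reference_id: str, base: float):
        super().__init__(data, reference_id)
        self.base = float(base)


def read_measurement_table(path, reference_id) -> MeasurementTable:
    """Read a specimen x variable CSV into a validated :class:`MeasurementTable`.

    Layout: first column specimen id, remaining columns variable ids, missing
    cells empty or ``NA``.  Rows missing the reference value are dropped with
    a logged warning; the count is available as
    ``table.n_dropped_missing_reference``.
    """
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    raw.index.name = None  # written as "specimen"; keep round-trips exact
    if reference_id not in raw.columns:
        raise ConfigurationError(
            f"reference variable {reference_id!r} is not a column of {path}"
        )
    numeric = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        cells = raw[col].str.strip()
        missing = cells.isin(_NA_TOKENS)
        converted = pd.to_numeric(cells.where(~missing), errors="coerce")
        malformed = converted.isna() & ~missing
        if malformed.any():
            row = malformed.idxmax()
            raise ParseError(
                f"malformed numeric cell at specimen {row!r}, column {col!r}: "
                f"{raw.at[row, col]!r}"
            )
        numeric[col] = converted
    nonpos = numeric.le(0)
    if nonpos.any().any():
        col = nonpos.any().idxmax()
        row = nonpos[col].idxmax()
        raise ValidationError(
            f"non-positive measurement {numeric.at[row, col]!r} at specimen "
            f"{row!r}, column {col!r}"
        )
    missing_ref = numeric[reference_id].isna()
    n_dropped = int(missing_ref.sum())
    if n_dropped:
        logger.warning(
            "dropping %d specimen(s) missing the reference value %r",
            n_dropped,
            reference_id,
        )
    table = MeasurementTable(numeric.loc[~missing_ref], reference_id)
    table.n_dropped_missing_reference = n_dropped
    return table


def log_transform(table: MeasurementTable, base: float = 10.0) -> LogTable:
    """Elementwise logarithm of a measurement table; missing stays missing.

    Only raw :class:`MeasurementTable` inputs are accepted -- applying the
    transform twice is a type error, not a silent numerical mistake.
    """
    if isinstance(table, LogTable):
        raise TypeError("table is already log-transformed")
    if not isinstance(table, MeasurementTable):
        raise TypeError(f"expected a MeasurementTable, got {type(table).__name__}")
    base = float(base)
    if base <= 0 or base == 1:
        raise ConfigurationError(f"invalid logarithm base {base}")
    logged = np.log(table.data) / np.log(base)
    return LogTable(logged, table.reference_id, base)


def assign_instrument(magnitude_mm: float) -> str:
    """Instrument implied by a measurement's magnitude when none is recorded."""
    return "caliper" if magnitude_mm < CALIPER_TAPE_THRESHOLD_MM else "tape"


@dataclass(frozen=True)
class ReplicateRecord:
    """k >= 2 repeated measurements of one (specimen, variable) by one instrument."""

    specimen_id: str
    variable_id: str
    instrument: str
    values: tuple

    def __post_init__(self):
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if self.instrument not in INSTRUMENTS:
            raise ValidationError(
                f"unknown instrument {self.instrument!r}; expected one of {INSTRUMENTS}"
            )
        if len(self.values) < 2:
            raise ValidationError(
                f"record ({self.specimen_id!r}, {self.variable_id!r}) has "
                f"k={len(self.values)} replicates; need k >= 2"
            )


@dataclass
class ReplicateMeasurementSet:
    """A collection of replicate-measurement records."""

    records: list = field(default_factory=list)


@dataclass
class ErrorSummary:
    """Per-record and per-instrument measurement-error statistics.

    ``per_record`` columns: specimen_id, variable_id, instrument, k,
    average_deviation (mm), standard_deviation (mm), magnitude (mm).
    ``per_instrument`` columns: instrument, n_records, mean_average_deviation
    (mm), error_size_corr (Pearson r of error vs magnitude), corr_p.
    """

    per_record: pd.DataFrame
    per_instrument: pd.DataFrame


def measurement_error_summary(reps: ReplicateMeasurementSet) -> ErrorSummary:
    """Summarise replicate measurements as average deviation and sample SD.

    The average deviation of a record is the arithmetic mean of the absolute
    differences of all replicates from the replicate mean; the standard
    deviation uses denominator k - 1.  Per-instrument means are unweighted
    means over records, and the error-vs-magnitude correlation is the Pearson
    r of the per-record average deviation against the per-record mean.
    """
    if not reps.records:
        raise ValidationError("no replicate records to summarise")
    rows = []
    for rec in reps.records:
        x = np.asarray(rec.values, dtype=float)
        m = x.mean()
        rows.append(
            {
                "specimen_id": rec.specimen_id,
                "variable_id": rec.variable_id,
                "instrument": rec.instrument,
                "k": x.size,
                "average_deviation": float(np.abs(x - m).mean()),
                "standard_deviation": float(x.std(ddof=1)),
                "magnitude": float(m),
            }
        )
    per_record = pd.DataFrame(rows)
    inst_rows = []
    for inst, grp in per_record.groupby("instrument", sort=True):
        if (
            len(grp) >= 2
            and grp["average_deviation"].nunique() > 1
            and grp["magnitude"].nunique() > 1
        ):
            r, p = stats.pearsonr(grp["average_deviation"], grp["magnitude"])
        else:
            r, p = float("nan"), float("nan")
        inst_rows.append(
            {
                "instrument": inst,
                "n_records": len(grp),
                "mean_average_deviation": float(grp["average_deviation"].mean()),
                "error_size_corr": float(r),
                "corr_p": float(p),
            }
        )
    return ErrorSummary(per_record, pd.DataFrame(inst_rows))
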