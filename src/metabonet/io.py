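"""Cohort table container, CSV I/O and validation.

A cohort is a plain pandas DataFrame wrapped with its measurement-unit
context: one row per subject, the 13 node columns in schema order, plus any
demographic columns that were supplied.  CSV is the only on-disk dialect
(UTF-8, comma separator, ``.`` decimal, header row); floats are written at
full ``repr`` precision so that read(write(t)) is numerically the identity.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError, UnitsError
from .schema import DEFAULT_SCHEMA, DEMOGRAPHIC_COLUMNS, NodeSchema, canonical_node

logger = logging.getLogger(__name__)

GLUCOSE_UNITS = ("mg/dL", "mmol/L")

_HTN_TEXT = {"yes": 1, "no": 0, "y": 1, "n": 0, "true": 1, "false": 0}


def _check_units(glucose_units: str) -> str:
    if glucose_units not in GLUCOSE_UNITS:
        raise UnitsError(
            f"unknown glucose units {glucose_units!r}; expected one of {GLUCOSE_UNITS}"
        )
    return glucose_units


@dataclass
class CohortTable:
    """Subject-level cohort with the 13 node variables.

    Parameters
    ----------
    data:
        One row per subject.  Must contain every node column (canonical
        IDs); demographic columns are optional and carried through.
    glucose_units:
        ``"mg/dL"`` (default) or ``"mmol/L"``.  Never auto-detected.
    """

    data: pd.DataFrame
    glucose_units: str = "mg/dL"
    schema: NodeSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        _check_units(self.glucose_units)
        missing = [n for n in self.schema.nodes if n not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table lacks node column(s): {missing}")
        # normalize column order: demographics first, then nodes in schema order
        demo = [c for c in self.data.columns if c not in self.schema.nodes]
        self.data = self.data[demo + list(self.schema.nodes)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def node_values(self) -> pd.DataFrame:
        """The 13 node columns, as float64, in schema order."""
        return self.data[list(self.schema.nodes)].astype(float)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(
            self.data.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True),
            glucose_units=self.glucose_units,
            schema=self.schema,
        )


@dataclass(frozen=True)
class ValidationFinding:
    rule: str
    row: int | None
    column: str | None
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __len__(self) -> int:
        return len(self.findings)

    def summary(self) -> str:
        if self.ok:
            return "clean: no findings"
        lines = [f"{len(self.findings)} finding(s):"]
        for f in self.findings:
            where = f"row {f.row}, " if f.row is not None else ""
            lines.append(f"  [{f.rule}] {where}{f.column}: {f.message}")
        return "\n".join(lines)


def read_cohort_csv(
    path,
    glucose_units: str = "mg/dL",
    schema: NodeSchema = DEFAULT_SCHEMA,
) -> CohortTable:
    """Read a subject-level cohort CSV.

    Headers are matched case-insensitively against the node alias map
    (e.g. both ``CholesT`` and ``Cholesterol-T`` are accepted) and emitted
    as canonical IDs.  ``HTN`` may be coded 0/1 or Yes/No.

    Raises
    ------
    SchemaError
        if any of the 13 node columns is absent.
    CohortValidationError
        on non-numeric cells or missing values in node columns.
    """
    _check_units(glucose_units)
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    rename: dict[str, str] = {}
    for col in raw.columns:
        node = canonical_node(col)
        if node is not None:
            if node in rename.values():
                raise SchemaError(f"duplicate column for node {node!r} in {path}")
            rename[col] = node
        elif str(col).strip().lower() in DEMOGRAPHIC_COLUMNS:
            rename[col] = str(col).strip().lower()
    df = raw.rename(columns=rename)
    missing = [n for n in schema.nodes if n not in df.columns]
    if missing:
        raise SchemaError(f"missing node column(s) {missing} in {path}")

    # map textual HTN codes before numeric coercion
    htn = df["HTN"].astype(str).str.strip().str.lower()
    df["HTN"] = htn.map(lambda v: _HTN_TEXT.get(v, v))

    for node in schema.nodes:
        # python float() is correctly rounded, so repr-serialised values
        # round-trip bit-exactly (pandas' fast csv float parser is not)
        parsed = []
        for row, value in enumerate(df[node]):
            if pd.isna(value):
                raise CohortValidationError(
                    f"missing value in node column {node!r}, row {row}; "
                    "node columns must be complete"
                )
            try:
                parsed.append(float(value))
            except (TypeError, ValueError):
                raise CohortValidationError(
                    f"non-numeric value {value!r} in column {node!r}, row {row}"
                ) from None
        df[node] = pd.array(parsed, dtype="int64" if node == "HTN" else "float64")
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return CohortTable(df, glucose_units=glucose_units, schema=schema)


def write_cohort_csv(table: CohortTable, path) -> None:
    """Write a cohort CSV that :func:`read_cohort_csv` inverts exactly.

    Floats are serialized with ``repr`` so the full binary64 value
    round-trips; writing twice yields byte-identical files.
    """
    df = table.data.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(lambda v: repr(float(v)) if pd.notna(v) else "")
    df.to_csv(path, index=False)


def cohort_to_csv_bytes(table: CohortTable) -> bytes:
    buf = _io.StringIO()
    write_cohort_csv(table, buf)
    return buf.getvalue().encode("utf-8")


def validate_cohort(table: CohortTable) -> ValidationReport:
    """Numeric sanity report: never raises, never drops rows.

    Rules checked per record: glucose > 0, insulin > 0, HTN in {0, 1},
    BMI >= 25 (study eligibility — reported, not enforced), and missing
    values in node columns (normally impossible after read).
    """
    report = ValidationReport()
    df = table.data
    for node in table.schema.nodes:
        col = df[node]
        for row in np.flatnonzero(col.isna().to_numpy()):
            report.findings.append(
                ValidationFinding("missing", int(row), node, "missing value in node column")
            )
    for node, rule in (("Glucose", "positive"), ("Insulin", "positive")):
        bad = df[node].to_numpy(dtype=float) <= 0
        for row in np.flatnonzero(bad):
            report.findings.append(
                ValidationFinding(rule, int(row), node, f"{node} must be > 0, got {df[node].iloc[row]}")
            )
    htn = df["HTN"].to_numpy(dtype=float)
    for row in np.flatnonzero(~np.isin(htn, (0.0, 1.0))):
        report.findings.append(
            ValidationFinding("domain", int(row), "HTN", f"HTN must be 0 or 1, got {htn[row]}")
        )
    bmi = df["BMI"].to_numpy(dtype=float)
    for row in np.flatnonzero(bmi < 25.0):
        report.findings.append(
            ValidationFinding(
                "bmi-eligibility", int(row), "BMI",
                f"BMI {bmi[row]:.2f} below the overweight threshold of 25",
            )
        )
    if not report.ok:
        logger.info("cohort validation: %d finding(s)", len(report.findings))
    return report
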