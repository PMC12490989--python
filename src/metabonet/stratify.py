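"""HOMA-IR computation and MHO/MUO stratification.

Insulin resistance is scored with the homeostatic model assessment,

    HOMA-IR = fasting glucose [mg/dL] x fasting insulin [mU/L] / 405
            = fasting glucose [mmol/L] x fasting insulin [mU/L] / 22.5,

and overweight/obese subjects are phenotyped as metabolically unhealthy
(MUO) when HOMA-IR >= 3 and metabolically healthy (MHO) otherwise.  The
boundary value 3.0 is MUO; there is no tolerance band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import MetabonetError, UnitsError
from .io import CohortTable

logger = logging.getLogger(__name__)

#: MUO classification cut-off on the HOMA-IR score (inclusive).
HOMA_IR_THRESHOLD = 3.0

#: Formula denominator per glucose unit.
_DENOMINATORS = {"mg/dL": 405.0, "mmol/L": 22.5}

MHO = "MHO"
MUO = "MUO"


def compute_homa_ir(glucose, insulin, glucose_units: str = "mg/dL"):
    """HOMA-IR from fasting glucose and fasting insulin (mU/L).

    Accepts scalars or arrays; strictly positive inputs required.
    """
    denom = _DENOMINATORS.get(glucose_units)
    if denom is None:
        raise UnitsError(
            f"unknown glucose units {glucose_units!r}; expected one of {tuple(_DENOMINATORS)}"
        )
    g = np.asarray(glucose, dtype=float)
    i = np.asarray(insulin, dtype=float)
    if np.any(g <= 0) or np.any(i <= 0):
        raise MetabonetError("glucose and insulin must be strictly positive")
    out = g * i / denom
    return float(out) if out.ndim == 0 else out


def classify_metabolic(homa_ir) -> str | np.ndarray:
    """MUO iff HOMA-IR >= 3 (boundary inclusive), MHO otherwise."""
    h = np.asarray(homa_ir, dtype=float)
    if np.any(h < 0):
        raise MetabonetError("HOMA-IR must be non-negative")
    labels = np.where(h >= HOMA_IR_THRESHOLD, MUO, MHO)
    return str(labels) if labels.ndim == 0 else labels


@dataclass
class StratifiedCohort:
    """Disjoint MHO/MUO strata covering the source cohort."""

    mho: CohortTable
    muo: CohortTable
    source_n: int
    n_discrepant: int = 0  # records where supplied HOMA disagrees with recomputation
    n_boundary: int = 0    # records with HOMA-IR exactly at the cut-off

    def __post_init__(self) -> None:
        if len(self.mho) + len(self.muo) != self.source_n:
            raise MetabonetError("strata do not partition the source cohort")

    def stratum(self, label: str) -> CohortTable:
        if label == MHO:
            return self.mho
        if label == MUO:
            return self.muo
        raise MetabonetError(f"unknown stratum label {label!r}")


def stratify_cohort(table: CohortTable, use_precomputed: bool = False) -> StratifiedCohort:
    """Partition a cohort into MHO and MUO strata.

    By default HOMA-IR is recomputed from glucose and insulin.  If a
    supplied HOMA column disagrees with the recomputation by more than
    0.01 the record count is logged and reported — published tables are
    not always arithmetically consistent with the printed formula — but
    the supplied value is used only when ``use_precomputed`` is set.
    """
    df = table.data
    recomputed = compute_homa_ir(
        df["Glucose"].to_numpy(float), df["Insulin"].to_numpy(float), table.glucose_units
    )
    supplied = df["HOMA"].to_numpy(float)
    n_discrepant = int(np.sum(np.abs(recomputed - supplied) > 0.01))
    if n_discrepant:
        logger.info(
            "%d/%d record(s) have supplied HOMA-IR differing from glucose*insulin "
            "recomputation by more than 0.01 (using %s values)",
            n_discrepant, len(df), "supplied" if use_precomputed else "recomputed",
        )
    homa = supplied if use_precomputed else recomputed
    labels = classify_metabolic(homa)
    is_muo = labels == MUO
    n_boundary = int(np.sum(homa == HOMA_IR_THRESHOLD))
    strat = StratifiedCohort(
        mho=table.subset(~is_muo),
        muo=table.subset(is_muo),
        source_n=len(table),
        n_discrepant=n_discrepant,
        n_boundary=n_boundary,
    )
    logger.info("stratified cohort: %d MHO, %d MUO", len(strat.mho), len(strat.muo))
    for name, stratum in (("MHO", strat.mho), ("MUO", strat.muo)):
        if len(stratum) == 0:
            logger.warning("stratum %s is empty; downstream estimation will refuse it", name)
    return strat
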