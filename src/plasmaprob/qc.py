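"""Analytical validation calculators for the plasma immunoassays.

Precision (intra-/inter-assay CV), spike recovery, dilution linearity and
parallelism, with the consortium acceptance windows used for assay
validation: %CV below 20% for precision, and %-agreement within 80%–120%
for the remaining parameters. The underlying consortium procedure does not
publish closed formulas; the conventional definitions implemented here are
documented in the methods note.

Assay lower limits of quantification (pg/mL) ship as defaults and can be
overridden per analyte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EvaluationError, MissingColumnError

__all__ = [
    "LLOQ",
    "QcOutcome",
    "SpikeExperiment",
    "DilutionSeries",
    "intra_assay_cv",
    "inter_assay_cv",
    "spike_recovery",
    "dilution_linearity",
    "parallelism",
    "read_qc_csv",
    "qc_report",
]

#: Lower limits of quantification, pg/mL.
LLOQ = {"abeta40": 1.9, "abeta42": 0.75, "ptau181": 0.47}

CV_WINDOW = (0.0, 20.0)        # %CV acceptance: below 20%
AGREEMENT_WINDOW = (80.0, 120.0)  # %-agreement acceptance


@dataclass
class QcOutcome:
    metric: str
    value: float  # percent
    window: tuple[float, float]
    passed: bool = field(init=False)

    def __post_init__(self):
        lo, hi = self.window
        self.passed = lo <= self.value < hi if self.window == CV_WINDOW \
            else lo <= self.value <= hi


@dataclass
class SpikeExperiment:
    base_concentration: float  # endogenous, pg/mL
    spike_added: float         # pg/mL
    observed: float            # pg/mL

    def __post_init__(self):
        if self.spike_added <= 0:
            raise EvaluationError("spike_added must be > 0")


@dataclass
class DilutionSeries:
    expected_neat: float
    points: list[tuple[float, float]]  # (dilution_factor >= 1, measured)

    def __post_init__(self):
        factors = [f for f, _ in self.points]
        if any(f < 1 for f in factors) or any(
                b <= a for a, b in zip(factors, factors[1:])):
            raise EvaluationError("dilution factors must be >= 1 and strictly increasing")


def _per_group_cv(values: np.ndarray) -> float:
    m = values.mean()
    if m <= 0:
        raise EvaluationError("non-positive mean: CV undefined")
    return 100.0 * values.std(ddof=1) / m


def intra_assay_cv(table: pd.DataFrame) -> QcOutcome:
    """Within-run CV% per (sample, run), averaged across samples and runs.

    ``table`` is long format with columns sample_id, run_id, value and
    >= 2 replicates per (sample, run).
    """
    cvs = []
    for (_, _), grp in table.groupby(["sample_id", "run_id"]):
        if len(grp) < 2:
            raise EvaluationError("intra-assay CV needs >= 2 replicates per run")
        cvs.append(_per_group_cv(grp["value"].to_numpy(dtype=float)))
    return QcOutcome("intra_assay_cv", float(np.mean(cvs)), CV_WINDOW)


def inter_assay_cv(table: pd.DataFrame) -> QcOutcome:
    """Between-run CV% of per-run means, averaged across samples."""
    cvs = []
    for _, grp in table.groupby("sample_id"):
        run_means = grp.groupby("run_id")["value"].mean().to_numpy(dtype=float)
        if len(run_means) < 2:
            raise EvaluationError("inter-assay CV needs >= 2 runs per sample")
        cvs.append(_per_group_cv(run_means))
    return QcOutcome("inter_assay_cv", float(np.mean(cvs)), CV_WINDOW)


def spike_recovery(exp: SpikeExperiment) -> QcOutcome:
    """Recovery% = 100 × (observed − endogenous) / spike added."""
    rec = 100.0 * (exp.observed - exp.base_concentration) / exp.spike_added
    return QcOutcome("spike_recovery", rec, AGREEMENT_WINDOW)


def dilution_linearity(series: DilutionSeries, lloq: float = 0.0) -> QcOutcome:
    """Mean %-agreement of dilution-corrected values with the neat expectation."""
    pts = [(f, m) for f, m in series.points if m >= lloq]
    if len(pts) < 2:
        raise EvaluationError("need >= 2 dilution points above the LLoQ")
    agreements = [100.0 * m * f / series.expected_neat for f, m in pts]
    return QcOutcome("dilution_linearity", float(np.mean(agreements)),
                     AGREEMENT_WINDOW)


def parallelism(series: DilutionSeries, calibration_reference: float = 1.0,
                lloq: float = 0.0) -> QcOutcome:
    """Slope of measured-vs-expected across the dilution series, as % of
    the calibration-curve reference slope."""
    pts = [(f, m) for f, m in series.points if m >= lloq]
    if len(pts) < 2:
        raise EvaluationError("need >= 2 dilution points above the LLoQ")
    expected = np.array([series.expected_neat / f for f, _ in pts])
    measured = np.array([m for _, m in pts])
    slope = np.polyfit(expected, measured, 1)[0]
    return QcOutcome("parallelism", 100.0 * slope / calibration_reference,
                     AGREEMENT_WINDOW)


# ---------------------------------------------------------------------------
# Long-format CSV interface

_QC_COLUMNS = ("sample_id", "run_id", "kind", "dilution_factor",
               "spike_added", "value")


def read_qc_csv(path) -> pd.DataFrame:
    """Read a long-format QC CSV.

    Column use by experiment kind:

    - ``precision``: sample_id, run_id, value (replicate measurement);
    - ``spike``: value = observed, spike_added = spike amount,
      dilution_factor = endogenous base concentration;
    - ``dilution``: value = measured, dilution_factor as named (a factor-1
      row, when present, supplies the expected neat concentration).
    """
    df = pd.read_csv(path, comment="#")
    for col in _QC_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(col, f"QC file {path}")
    return df


def qc_report(df: pd.DataFrame) -> list[QcOutcome]:
    """Run every applicable calculator over a long-format QC table."""
    out: list[QcOutcome] = []
    prec = df[df["kind"] == "precision"]
    if len(prec):
        out.append(intra_assay_cv(prec))
        if prec.groupby("sample_id")["run_id"].nunique().min() >= 2:
            out.append(inter_assay_cv(prec))
    for _, row in df[df["kind"] == "spike"].iterrows():
        exp = SpikeExperiment(base_concentration=row["dilution_factor"],
                              spike_added=row["spike_added"],
                              observed=row["value"])
        out.append(spike_recovery(exp))
    dil = df[df["kind"] == "dilution"]
    for sid, grp in dil.groupby("sample_id"):
        grp = grp.sort_values("dilution_factor")
        neat = grp[grp["dilution_factor"] == 1]
        expected = float(neat["value"].iloc[0]) if len(neat) else float(
            grp["value"].iloc[0] * grp["dilution_factor"].iloc[0])
        series = DilutionSeries(
            expected_neat=expected,
            points=[(float(f), float(v)) for f, v in
                    zip(grp["dilution_factor"], grp["value"]) if f > 1],
        )
        out.append(dilution_linearity(series))
        out.append(parallelism(series))
    return out
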