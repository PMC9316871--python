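"""HPLC-DPPH quantification of antioxidant activity.

A TROLOX calibration line maps the DPPH peak-area signal (sample area over
blank area: 1 means no scavenging, 0 complete decolorization) to a TEAC
concentration in mM.  Also provides the method-verification statistics:
spike recovery and relative standard deviations for accuracy/precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "PeakMeasurement",
    "VerificationReport",
    "fit_calibration",
    "signal_ratio",
    "teac_from_signal",
    "replicate_summary",
    "recovery",
    "teac_report",
]


@dataclass
class CalibrationCurve:
    """TROLOX calibration line: signal = slope * conc + intercept."""

    slope: float
    intercept: float
    pearson_r: float
    conc_range: tuple[float, float]
    n_levels: int

    def __post_init__(self) -> None:
        if self.conc_range[0] >= self.conc_range[1]:
            raise ValueError("degenerate concentration range")
        if self.n_levels < 3:
            raise ValueError("need at least 3 calibration levels")
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|r| > 1")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "slope": self.slope, "intercept": self.intercept,
                "pearson_r": self.pearson_r,
                "conc_range": list(self.conc_range),
                "n_levels": self.n_levels,
            }, fh, indent=1)


@dataclass(frozen=True)
class PeakMeasurement:
    """Chromatographic peak areas of one injection: DPPH blank vs sample."""

    blank_area: float
    sample_area: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.blank_area <= 0:
            raise ValueError("blank area must be positive")
        if self.sample_area < 0:
            raise ValueError("sample area must be non-negative")


@dataclass
class VerificationReport:
    """Method-verification summary: recoveries and RSDs."""

    recoveries: list[float]
    rsd_accuracy: float
    rsd_precision: float
    linear_range_ok: bool

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.recoveries):
            raise ValueError("recoveries must be positive")
        if self.rsd_accuracy < 0 or self.rsd_precision < 0:
            raise ValueError("RSDs must be non-negative")


def fit_calibration(concentrations, signals) -> CalibrationCurve:
    """Least-squares line through (concentration mM, signal) standards."""
    conc = np.asarray(concentrations, dtype=float).ravel()
    sig = np.asarray(signals, dtype=float).ravel()
    if len(conc) != len(sig) or len(conc) < 3:
        raise ValueError("need >= 3 matched (concentration, signal) points")
    if conc.var() == 0:
        raise ValueError("zero concentration variance")
    result = stats.linregress(conc, sig)
    return CalibrationCurve(
        slope=float(result.slope),
        intercept=float(result.intercept),
        pearson_r=float(result.rvalue),
        conc_range=(float(conc.min()), float(conc.max())),
        n_levels=len(conc),
    )


def signal_ratio(m: PeakMeasurement) -> float:
    """Remaining-DPPH signal: sample peak area over blank peak area."""
    return m.sample_area / m.blank_area


def teac_from_signal(ratio: float, curve: CalibrationCurve) -> tuple[float, dict]:
    """Invert the calibration line: TEAC = (signal - intercept)/slope, mM.

    Negative inversions clamp to 0 (flagged); values beyond the calibrated
    concentration range flag extrapolation.
    """
    if curve.slope == 0:
        raise ValueError("zero calibration slope")
    raw = (ratio - curve.intercept) / curve.slope
    flags = {"clamped": False, "extrapolated": False}
    teac = raw
    if raw < 0:
        teac, flags["clamped"] = 0.0, True
    if teac > curve.conc_range[1]:
        flags["extrapolated"] = True
    return float(teac), flags


def replicate_summary(teacs) -> tuple[float, float]:
    """Mean and percent RSD (sample SD, n-1 denominator) of replicates."""
    values = np.asarray(teacs, dtype=float).ravel()
    if len(values) < 2:
        raise ValueError("need at least 2 replicates")
    mean = float(values.mean())
    if mean == 0:
        raise ZeroDivisionError("RSD undefined for zero mean")
    return mean, float(100.0 * values.std(ddof=1) / mean)


def recovery(measured: float, nominal: float) -> float:
    """Percent recovery of a spiked standard: 100 * measured / nominal."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    return 100.0 * measured / nominal


def teac_report(standards: pd.DataFrame, measurements: pd.DataFrame) -> dict:
    """Compute per-compound TEAC (mean, RSD) from delimited-table inputs.

    ``standards`` needs columns (concentration, signal); ``measurements``
    needs (compound_id, replicate, blank_area, sample_area).
    """
    curve = fit_calibration(standards["concentration"], standards["signal"])
    out = {"calibration": {
        "slope": curve.slope, "intercept": curve.intercept,
        "pearson_r": curve.pearson_r, "conc_range": list(curve.conc_range),
        "n_levels": curve.n_levels,
    }, "compounds": {}}
    for compound, group in measurements.groupby("compound_id"):
        teacs, any_flags = [], {"clamped": False, "extrapolated": False}
        for _, row in group.iterrows():
            m = PeakMeasurement(blank_area=float(row["blank_area"]),
                                sample_area=float(row["sample_area"]),
                                replicate_id=str(row.get("replicate", "")))
            teac, flags = teac_from_signal(signal_ratio(m), curve)
            teacs.append(teac)
            any_flags = {k: any_flags[k] or flags[k] for k in any_flags}
        entry: dict = {"n_replicates": len(teacs), "flags": any_flags}
        if len(teacs) >= 2 and np.mean(teacs) != 0:
            mean, rsd = replicate_summary(teacs)
            entry.update({"teac_mm": mean, "rsd_percent": rsd})
        else:
            entry.update({"teac_mm": float(np.mean(teacs)), "rsd_percent": None})
        out["compounds"][str(compound)] = entry
    return out
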