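"""qPCR crossing-point handling: replicate averaging, the log-linear
standard curve, copy-number quantification, and detection-limit
classification.

The central QC rule: average the triplicate Cp values of every sample,
take the *minimum* average Cp across the submitted blank samples as the
detection limit, and classify a sample as above detection only when its
average Cp is strictly smaller than that limit.  Ties go below, so the
defining blank itself always classifies as below detection.  Lower Cp
means more template: with a fitted standard curve Cp = m*log10(copies) + b
(m < 0), copies/uL = 10^((Cp - b)/m) and the amplification efficiency is
E = 10^(-1/m) - 1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .io import CpTable, Metadata
from .stats import ols_r2, OlsResult

logger = logging.getLogger("blankgate")

__all__ = [
    "StandardCurve", "DetectionVerdict", "ClassificationResult",
    "average_cp", "fit_standard_curve", "copies_from_cp",
    "blank_threshold", "classify_samples", "lab_flag_verdicts",
    "volume_cp_regression", "verdicts_to_frame",
]


def average_cp(replicates: Sequence[float]) -> float:
    """Arithmetic mean of the replicate Cp values (all replicates kept;
    no outlier rejection)."""
    reps = [float(r) for r in replicates]
    if not reps:
        raise ValueError("cannot average an empty list of Cp replicates")
    if not all(math.isfinite(r) for r in reps):
        raise ValueError("non-finite Cp replicate")
    return float(np.mean(reps))


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear qPCR calibration: Cp = slope * log10(copies) + intercept.

    ``slope`` is in cycles per decade of template (negative); the
    per-cycle amplification efficiency E = 10^(-1/slope) - 1 equals 1
    for perfect doubling... slope = -1/log10(2).  ``cp_range`` records
    the calibrated Cp interval so extrapolation can be flagged.
    """

    slope: float
    intercept: float
    efficiency: float
    r2: float
    cp_range: tuple = (float("nan"), float("nan"))

    def __post_init__(self):
        if not (self.slope < 0):
            raise ValueError(f"standard-curve slope must be negative, got {self.slope}")
        expected = 10.0 ** (-1.0 / self.slope) - 1.0
        if abs(self.efficiency - expected) > 1e-9:
            raise ValueError(
                f"efficiency {self.efficiency} inconsistent with slope "
                f"{self.slope} (expected {expected})")


def fit_standard_curve(points: Sequence) -> StandardCurve:
    """Ordinary-least-squares fit of Cp on log10(copies) over calibration
    points (>= 3 distinct template levels)."""
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 calibration points, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct log10-copies levels")
    fit: OlsResult = ols_r2(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"fitted slope {fit.slope:.4g} is non-negative; Cp must decrease "
            "with template concentration")
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(slope=fit.slope, intercept=fit.intercept,
                         efficiency=efficiency, r2=fit.r2,
                         cp_range=(float(y.min()), float(y.max())))


def copies_from_cp(cp: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies/uL = 10^((cp - b) / m).

    Extrapolation beyond the calibrated Cp range is allowed but logged.
    """
    cp = float(cp)
    lo, hi = curve.cp_range
    if math.isfinite(lo) and not (lo <= cp <= hi):
        logger.info("Cp %.3f outside calibrated range [%.3f, %.3f]; extrapolating",
                    cp, lo, hi)
    return 10.0 ** ((cp - curve.intercept) / curve.slope)


def blank_threshold(cp_table: CpTable, metadata: Metadata) -> float:
    """Blank-derived detection limit: the minimum average Cp over the
    submitted blank samples present in the Cp table."""
    blank_ids = [b for b in metadata.blank_ids if b in cp_table]
    if not blank_ids:
        raise ValueError(
            "no blank samples present in both the metadata and the Cp table; "
            "the blank-derived detection limit requires submitted blanks")
    return min(average_cp(cp_table[b]) for b in blank_ids)


@dataclass(frozen=True)
class DetectionVerdict:
    sample_id: str
    avg_cp: float
    above_detection: bool
    threshold_used: float
    threshold_source: str  # "blank-derived" | "lab-flag"
    copies_per_ul: Optional[float] = None


class ClassificationResult(NamedTuple):
    verdicts: list
    skipped: list  # sample ids in metadata with no Cp data


def classify_samples(cp_table: CpTable, metadata: Metadata, threshold: float,
                     curve: Optional[StandardCurve] = None) -> ClassificationResult:
    """Classify every metadata sample against a Cp detection limit.

    ``above_detection`` is True iff avg Cp < threshold (strictly): a
    sample tied with the threshold is below detection, which guarantees
    the minimal blank defining a blank-derived threshold classifies
    below.  Samples missing from the Cp table are reported in
    ``skipped``, not fatal.  ``copies_per_ul`` is populated only when a
    standard curve is supplied.
    """
    threshold = float(threshold)
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    verdicts, skipped = [], []
    for sid in metadata.sample_ids:
        if sid not in cp_table:
            skipped.append(sid)
            continue
        avg = average_cp(cp_table[sid])
        verdicts.append(DetectionVerdict(
            sample_id=sid, avg_cp=avg, above_detection=avg < threshold,
            threshold_used=threshold, threshold_source="blank-derived",
            copies_per_ul=copies_from_cp(avg, curve) if curve is not None else None))
    if skipped:
        logger.warning("classify_samples: %d sample(s) without Cp data skipped: %s",
                       len(skipped), ", ".join(skipped))
    return ClassificationResult(verdicts=verdicts, skipped=skipped)


def lab_flag_verdicts(cp_table: CpTable, metadata: Metadata,
                      curve: Optional[StandardCurve] = None) -> ClassificationResult:
    """Verdicts from the laboratory's own amplification flag (an opaque
    input, not recomputed); the threshold field is NaN."""
    verdicts, skipped = [], []
    for sid in metadata.sample_ids:
        flag = metadata.lab_amplified(sid)
        if sid not in cp_table or flag is None or (isinstance(flag, float) and math.isnan(flag)):
            skipped.append(sid)
            continue
        avg = average_cp(cp_table[sid])
        verdicts.append(DetectionVerdict(
            sample_id=sid, avg_cp=avg, above_detection=bool(flag),
            threshold_used=float("nan"), threshold_source="lab-flag",
            copies_per_ul=copies_from_cp(avg, curve) if curve is not None else None))
    return ClassificationResult(verdicts=verdicts, skipped=skipped)


def volume_cp_regression(metadata: Metadata, cp_table: CpTable) -> OlsResult:
    """OLS of average Cp on filtered volume over non-blank samples.

    A small R^2 here is the signature of biomass being decoupled from
    filtered volume.
    """
    ids = [s for s in metadata.nonblank_ids if s in cp_table]
    if len(ids) < 3:
        raise ValueError("need at least 3 non-blank samples with Cp data")
    volumes = np.array([metadata.volume(s) for s in ids], dtype=float)
    if np.unique(volumes).size < 2:
        raise ValueError("all volumes identical; regression on volume is undefined")
    cps = np.array([average_cp(cp_table[s]) for s in ids])
    return ols_r2(volumes, cps)


def verdicts_to_frame(verdicts: Sequence[DetectionVerdict]) -> pd.DataFrame:
    """Flatten verdicts into a DataFrame indexed by sample id."""
    frame = pd.DataFrame([{
        "sample_id": v.sample_id,
        "avg_cp": v.avg_cp,
        "copies_per_uL": v.copies_per_ul,
        "above_detection": v.above_detection,
        "threshold_used": v.threshold_used,
        "threshold_source": v.threshold_source,
    } for v in verdicts])
    return frame.set_index("sample_id")
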