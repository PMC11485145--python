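"""Scan-level functional-connectivity specificity QC.

A scan is kept when the mean time series of a sensory seed correlates
strongly (r > 0.1, strict) with its homotopic contralateral counterpart
and weakly or negatively (r < 0.1, strict) with a default-mode seed.
Non-specific scans — globally coupled or pure noise — fail one of the
two criteria.  The correlations are computed on the extracted mean
series as-is; an optional band restricts them to a frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Scan4D
from .errors import ConsistencyError
from .fc import RoiTimeseries, bandpass, extract_roi_timeseries

DEFAULT_THR_POS = 0.1
DEFAULT_THR_NEG = 0.1


@dataclass
class ScanQC:
    """QC result for one scan."""

    scan_id: str
    r_homotopic: float
    r_specificity: float
    passed: bool
    reason: str = ""


@dataclass
class QCReport:
    """QC results for a cohort plus the thresholds that produced them."""

    scans: list[ScanQC]
    thr_pos: float = DEFAULT_THR_POS
    thr_neg: float = DEFAULT_THR_NEG

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.scan_id, s.r_homotopic, s.r_specificity, s.passed, s.reason)
                for s in self.scans
            ],
            columns=["scan_id", "r_homotopic", "r_specificity", "pass", "reason"],
        )


def _safe_r(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(
        np.clip(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy), -1, 1)
    )


def specificity_filter(
    scan: Scan4D,
    sensory_seed,
    homotopic_sensory_seed,
    dmn_seed,
    thr_pos: float = DEFAULT_THR_POS,
    thr_neg: float = DEFAULT_THR_NEG,
    band: tuple[float, float] | None = None,
) -> ScanQC:
    """Apply the FC-specificity criteria to one scan.

    ``r_homotopic`` is the Pearson r between the sensory seed's mean
    series and the homotopic contralateral sensory seed's;
    ``r_specificity`` between the sensory and default-mode seeds.  The
    scan passes iff ``r_homotopic > thr_pos`` and
    ``r_specificity < thr_neg`` (both strict).  A constant seed series
    marks the scan failed with reason "degenerate".  ``band`` optionally
    band-passes the three series first (default: none — QC precedes the
    analysis filtering).
    """
    ts = extract_roi_timeseries(
        scan, {"sensory": sensory_seed, "homotopic": homotopic_sensory_seed, "dmn": dmn_seed}
    )
    if band is not None:
        ts = bandpass(ts, band[0], band[1])
    sens, homo, dmn = ts.values
    r_hom = _safe_r(sens, homo)
    r_spec = _safe_r(sens, dmn)
    if not (np.isfinite(r_hom) and np.isfinite(r_spec)):
        return ScanQC(scan.subject_id, r_hom, r_spec, False, "degenerate")
    passed = (r_hom > thr_pos) and (r_spec < thr_neg)
    return ScanQC(scan.subject_id, r_hom, r_spec, passed)


def qc_cohort(
    scans,
    sensory_seed,
    homotopic_sensory_seed,
    dmn_seed,
    thr_pos: float = DEFAULT_THR_POS,
    thr_neg: float = DEFAULT_THR_NEG,
    band: tuple[float, float] | None = None,
) -> QCReport:
    """Run :func:`specificity_filter` over an iterable of scans."""
    results = [
        specificity_filter(
            scan, sensory_seed, homotopic_sensory_seed, dmn_seed, thr_pos, thr_neg, band
        )
        for scan in scans
    ]
    return QCReport(results, thr_pos, thr_neg)


def filter_manifest(manifest: pd.DataFrame, report: QCReport) -> pd.DataFrame:
    """Restrict a scan manifest to QC-passing scans, preserving order."""
    by_id = {s.scan_id: s for s in report.scans}
    ids = list(manifest["subject_id"])
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise ConsistencyError(f"no QC report for scans: {missing}")
    keep = [by_id[i].passed for i in ids]
    return manifest.loc[keep].reset_index(drop=True)
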