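"""Resting-state functional-connectivity fingerprints.

Mean ROI time series are extracted per scan, detrended and band-pass
filtered (zero-phase 4th-order Butterworth), correlated per subject
between every seed and target, and the per-subject correlation matrices
averaged into a group fingerprint with SEM error bars.  Raw correlation
coefficients are averaged by default (a Fisher-z option exists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import Fingerprint, Scan4D
from .errors import FrequencyError, InsufficientDataError, ValidationError


@dataclass
class RoiTimeseries:
    """ROIs x timepoints mean time series."""

    values: np.ndarray
    roi_ids: list
    tr_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("RoiTimeseries must be ROIs x timepoints")
        if self.values.shape[0] != len(self.roi_ids):
            raise ValidationError("one id per ROI row required")
        if self.values.shape[1] < 2:
            raise ValidationError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("ROI time series must be finite")
        if self.tr_s <= 0:
            raise ValidationError("tr_s must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


def seed_spec_from_mm(
    coords_mm,
    voxel_size_mm,
    grid_shape,
    radius: int = 0,
):
    """Build a :class:`~cingfp.tracer.SeedSpec` from point coordinates.

    ``coords_mm`` are millimetre coordinates in the canonical frame
    (axis 1 rostro-caudal, anterior at index 0, voxel centers at
    ``index * voxel_size``).  Each point is snapped to the nearest voxel
    and grown to a Chebyshev ball of ``radius`` voxels clipped to the
    grid.  Seeds are ordered anterior to posterior and carry rank
    positions u = (i + 0.5) / n.
    """
    from .tracer import SeedSpec

    coords = np.atleast_2d(np.asarray(coords_mm, dtype=float))
    if coords.shape[1] != 3:
        raise ValidationError("coords_mm must be (n, 3)")
    h = np.asarray(voxel_size_mm, dtype=float)
    shape = np.asarray(grid_shape, dtype=int)
    idx = np.rint(coords / h).astype(int)
    if np.any(idx < 0) or np.any(idx >= shape[None, :]):
        raise ValidationError("seed coordinate outside the grid")
    order = np.lexsort((idx[:, 2], idx[:, 0], idx[:, 1]))
    idx = idx[order]
    sets = []
    for center in idx:
        if radius <= 0:
            sets.append(center[None, :])
        else:
            lo = np.maximum(center - radius, 0)
            hi = np.minimum(center + radius + 1, shape)
            grid = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            sets.append(grid.reshape(3, -1).T)
    n = len(sets)
    u = (np.arange(n) + 0.5) / n
    return SeedSpec(sets, u)


def extract_roi_timeseries(scan: Scan4D, rois: dict) -> RoiTimeseries:
    """Unweighted mean time series over each ROI's voxels.

    ``rois`` maps an id to flat voxel indices (C-order into the scan's
    grid) or to (k, 3) voxel index arrays.
    """
    n_vox = scan.data.shape[0]
    ids, rows = [], []
    for roi_id, vox in rois.items():
        vox = np.asarray(vox)
        if vox.ndim == 2 and vox.shape[1] == 3:
            flat = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), scan.grid_shape)
        else:
            flat = vox.ravel()
        if flat.size == 0:
            raise ValidationError(f"ROI {roi_id!r} is empty")
        if flat.min() < 0 or flat.max() >= n_vox:
            raise ValidationError(f"ROI {roi_id!r} has voxels outside the grid")
        ids.append(roi_id)
        rows.append(scan.data[flat].mean(axis=0))
    return RoiTimeseries(np.vstack(rows), ids, scan.tr_s)


def bandpass(
    ts: RoiTimeseries, low_hz: float, high_hz: float, order: int = 4
) -> RoiTimeseries:
    """Linear detrend followed by a zero-phase Butterworth band-pass.

    The filter is applied forward-backward (``sosfiltfilt``), so the
    output has zero phase shift and unchanged length.  ``low_hz`` may be
    0, in which case only the low-pass half is applied (the detrend has
    already removed DC and linear drift).
    """
    nyq = 1.0 / (2.0 * ts.tr_s)
    if not 0 <= low_hz < high_hz:
        raise FrequencyError(f"need 0 <= low ({low_hz}) < high ({high_hz})")
    if high_hz > nyq:
        raise FrequencyError(
            f"high_hz={high_hz} exceeds the Nyquist frequency {nyq} "
            f"for tr_s={ts.tr_s}"
        )
    x = signal.detrend(ts.values, axis=1, type="linear")
    fs = 1.0 / ts.tr_s
    if low_hz > 0:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    else:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=1)
    return RoiTimeseries(y, list(ts.roi_ids), ts.tr_s)


def butterworth_gain(
    freq_hz: float, low_hz: float, high_hz: float, tr_s: float, order: int = 4
) -> float:
    """Power gain of the zero-phase filter at one frequency.

    Transfer-function oracle for the digital Butterworth band used by
    :func:`bandpass`; forward-backward application squares the
    magnitude response, so the power gain is |H|^4.
    """
    fs = 1.0 / tr_s
    if low_hz > 0:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    else:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=[2 * np.pi * freq_hz / fs])
    return float(np.abs(h[0]) ** 4)


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between every row of a and every row of b."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    sa = az.std(axis=1)
    sb = bz.std(axis=1)
    const_a, const_b = sa == 0, sb == 0
    sa = np.where(const_a, 1.0, sa)
    sb = np.where(const_b, 1.0, sb)
    r = (az @ bz.T) / a.shape[1] / np.outer(sa, sb)
    np.clip(r, -1.0, 1.0, out=r)
    r[const_a, :] = np.nan
    r[:, const_b] = np.nan
    return r


def subject_fc(
    ts: RoiTimeseries, seed_rows, target_rows
) -> np.ndarray:
    """Per-subject seeds x targets Pearson correlation matrix.

    Constant rows yield NaN entries with a warning.
    """
    if ts.n_timepoints < 8:
        raise InsufficientDataError("subject FC needs >= 8 timepoints")
    seed_rows = np.asarray(seed_rows, dtype=int)
    target_rows = np.asarray(target_rows, dtype=int)
    r = _pearson_rows(ts.values[seed_rows], ts.values[target_rows])
    if np.any(~np.isfinite(r)):
        warnings.warn("constant ROI series produced NaN correlations", stacklevel=2)
    return r


def group_fingerprint(
    per_subject: list[np.ndarray],
    seed_positions,
    target_names: list[str],
    fisher_z: bool = False,
    species: str = "",
    modality: str = "rsfmri",
) -> Fingerprint:
    """Average per-subject correlation matrices into a group fingerprint.

    The mean is the arithmetic mean of raw r values (``fisher_z``
    averages in z space and transforms back); SEM is the sample
    standard deviation over subjects divided by sqrt(n), with NaN cells
    dropped pairwise and a per-cell n recorded.  With one subject the
    SEM is NaN.
    """
    if not per_subject:
        raise ValidationError("need at least one subject")
    shapes = {m.shape for m in map(np.asarray, per_subject)}
    if len(shapes) != 1:
        raise ValidationError(f"inconsistent subject matrix shapes: {shapes}")
    stack = np.stack([np.asarray(m, dtype=float) for m in per_subject])
    if fisher_z:
        with np.errstate(divide="ignore"):
            stack = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
    n_cell = np.sum(np.isfinite(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    if fisher_z:
        mean = np.tanh(mean)
    sem = np.where(n_cell >= 2, sd / np.sqrt(np.maximum(n_cell, 1)), np.nan)
    mean = np.where(n_cell >= 1, mean, np.nan)
    return Fingerprint(
        mean,
        sem,
        np.asarray(seed_positions, dtype=float),
        list(target_names),
        n_subjects=len(per_subject),
        n_per_cell=n_cell,
        species=species,
        modality=modality,
    )
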