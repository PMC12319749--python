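"""Confound construction and time-series cleaning.

Implements framewise displacement (Power and Jenkinson flavours), the
24-parameter motion expansion, nuisance regression with spike (scrubbing)
regressors, zero-phase bandpass filtering, Gaussian spatial smoothing, and
sample-level quality-control exclusion.

Boundary conventions are strict throughout: a volume is flagged when
FD > threshold, a subject is excluded when mean FD > 0.30 mm, when any
task accuracy is not above 0.5, or when a measure lies strictly more than
3.29 SD from the pre-exclusion sample mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .bold import MOTION_COLUMNS, BoldRun

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548

FD_SCRUB_MM = 0.2
FD_EXCLUDE_MM = 0.30
OUTLIER_Z = 3.29
ACCURACY_FLOOR = 0.5


def compute_fd(
    motion: pd.DataFrame | np.ndarray,
    flavor: str = "power",
    head_radius: float = 50.0,
) -> np.ndarray:
    """Per-volume framewise displacement in mm; first volume is 0.

    ``power``: sum of absolute backward differences of the six rigid-body
    parameters, rotations converted to arc length on a ``head_radius``
    sphere.  ``jenkinson``: RMS voxel displacement over the same sphere from
    the composed differential rigid transform.
    """
    params = np.asarray(motion[MOTION_COLUMNS] if isinstance(motion, pd.DataFrame) else motion, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion must have 6 columns (3 translations mm, 3 rotations rad)")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    if not np.all(np.isfinite(params)):
        raise ValueError("motion parameters must be finite")

    if flavor == "power":
        d = np.abs(np.diff(params, axis=0))
        fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    elif flavor == "jenkinson":
        mats = np.zeros((len(params), 4, 4))
        mats[:, 3, 3] = 1.0
        mats[:, :3, :3] = Rotation.from_euler("xyz", params[:, 3:]).as_matrix()
        mats[:, :3, 3] = params[:, :3]
        fd = np.empty(len(params) - 1)
        for t in range(1, len(params)):
            m = mats[t] @ np.linalg.inv(mats[t - 1]) - np.eye(4)
            a, b = m[:3, :3], m[:3, 3]
            fd[t - 1] = np.sqrt(head_radius**2 / 5.0 * np.trace(a.T @ a) + b @ b)
    else:
        raise ValueError(f"unknown FD flavor {flavor!r}")
    return np.concatenate([[0.0], fd])


def friston24(motion: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """24-parameter motion expansion.

    Column order: the 6 parameters, their one-volume lags (first row zero),
    the squares of the parameters, the squares of the lags.
    """
    params = np.asarray(motion[MOTION_COLUMNS] if isinstance(motion, pd.DataFrame) else motion, dtype=float)
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    lagged = np.vstack([np.zeros(6), params[:-1]])
    block = np.hstack([params, lagged, params**2, lagged**2])
    names = (
        MOTION_COLUMNS
        + [f"{c}_lag" for c in MOTION_COLUMNS]
        + [f"{c}_sq" for c in MOTION_COLUMNS]
        + [f"{c}_lag_sq" for c in MOTION_COLUMNS]
    )
    return pd.DataFrame(block, columns=names)


@dataclass
class ConfoundMatrix:
    """Per-volume nuisance design: tissue signals, motion expansion, spikes."""

    frame: pd.DataFrame
    spike_volumes: list[int]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def build_confounds(
    bold: BoldRun,
    motion: pd.DataFrame,
    csf_mask: np.ndarray,
    wm_mask: np.ndarray,
    global_mask: np.ndarray | None = None,
    fd_threshold: float = FD_SCRUB_MM,
    fd_flavor: str = "power",
    scrub_mode: str = "spike",
) -> ConfoundMatrix:
    """Assemble the nuisance design for one run.

    Columns: mean CSF, mean WM, global signal (mean over ``global_mask``,
    or over the whole volume when none is given), the 24-parameter motion
    expansion, and scrubbing regressors for every volume with
    FD > ``fd_threshold``.  ``scrub_mode='spike'`` adds one one-hot column
    per flagged volume (equivalent to censoring); ``'single'`` adds a single
    shared binary column.
    """
    for name, m in [("csf", csf_mask), ("wm", wm_mask)]:
        if not np.any(m):
            raise ValueError(f"{name} mask is empty")
    if len(motion) != bold.n_volumes:
        raise ValueError("motion rows must equal run volumes")
    df = friston24(motion)
    df.insert(0, "global_signal", bold.timeseries(
        np.ones(bold.shape, dtype=bool) if global_mask is None else np.asarray(global_mask, bool)
    ).mean(axis=0))
    df.insert(0, "wm", bold.timeseries(np.asarray(wm_mask, bool)).mean(axis=0))
    df.insert(0, "csf", bold.timeseries(np.asarray(csf_mask, bool)).mean(axis=0))

    fd = compute_fd(motion, flavor=fd_flavor)
    flagged = np.flatnonzero(fd > fd_threshold)
    if scrub_mode == "spike":
        if flagged.size:
            spikes = np.zeros((bold.n_volumes, flagged.size))
            spikes[flagged, np.arange(flagged.size)] = 1.0
            df = pd.concat(
                [df, pd.DataFrame(spikes, columns=[f"spike_{v:04d}" for v in flagged])],
                axis=1,
            )
    elif scrub_mode == "single":
        col = np.zeros(bold.n_volumes)
        col[flagged] = 1.0
        if flagged.size:
            df["scrub"] = col
    else:
        raise ValueError(f"unknown scrub_mode {scrub_mode!r}")
    return ConfoundMatrix(frame=df, spike_volumes=[int(v) for v in flagged])


def _dependent_columns(x: np.ndarray, names: list[str], tol: float = 1e-8) -> list[str]:
    """Names of columns linearly dependent on the columns before them."""
    q = np.zeros((x.shape[0], 0))
    bad = []
    for j in range(x.shape[1]):
        col = x[:, j].astype(float)
        norm = np.linalg.norm(col)
        resid = col - q @ (q.T @ col)
        if np.linalg.norm(resid) <= tol * max(norm, 1.0):
            bad.append(names[j])
        else:
            q = np.column_stack([q, resid / np.linalg.norm(resid)])
    return bad


def drop_dependent_confounds(frame: pd.DataFrame) -> pd.DataFrame:
    """Drop all-zero, constant, and linearly dependent confound columns.

    The intercept added by :func:`regress_confounds` is accounted for, so
    constant columns are redundant and removed; each drop is logged.
    """
    c = frame.to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(frame)), c])
    bad = _dependent_columns(x, ["intercept"] + list(frame.columns))
    if bad:
        logger.warning("dropping redundant confound columns: %s", bad)
        return frame.drop(columns=[b for b in bad if b != "intercept"])
    return frame


def regress_confounds(bold: BoldRun, confounds: ConfoundMatrix | pd.DataFrame) -> BoldRun:
    """Voxel-wise OLS residualization against the confound design (+intercept).

    Spike columns give flagged volumes zero influence on the remaining
    estimates (spike regression is equivalent to deletion).
    """
    frame = confounds.frame if isinstance(confounds, ConfoundMatrix) else confounds
    c = frame.to_numpy(dtype=float)
    if c.shape[0] != bold.n_volumes:
        raise ValueError("confound rows must equal run volumes")
    keep = ~np.all(c == 0, axis=0)
    x = np.column_stack([np.ones(c.shape[0]), c[:, keep]])
    names = ["intercept"] + [n for n, k in zip(frame.columns, keep) if k]
    bad = _dependent_columns(x, names)
    if bad:
        raise ValueError(f"confound design is rank deficient; offending columns: {bad}")
    t = bold.n_volumes
    flat = bold.data.reshape(-1, t).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(x, flat, rcond=None)
    resid = flat - x @ beta
    return bold.with_data(resid.T.reshape(bold.data.shape))


def bandpass_series(series: np.ndarray, tr: float, low: float = 0.009, high: float = 0.09) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth bandpass along the last axis."""
    nyq = 1.0 / (2.0 * tr)
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq:.4g} Hz)"
        )
    b, a = butter(2, [low, high], btype="band", fs=1.0 / tr)
    demeaned = series - series.mean(axis=-1, keepdims=True)
    return filtfilt(b, a, demeaned, axis=-1)


def bandpass(bold: BoldRun, low: float = 0.009, high: float = 0.09) -> BoldRun:
    return bold.with_data(bandpass_series(bold.data, bold.tr, low, high))


def smooth_gaussian(bold: BoldRun, fwhm: float = 6.0) -> BoldRun:
    """Per-volume isotropic 3D Gaussian smoothing; sigma = FWHM/2.3548 per
    axis, converted from mm to voxels via the affine."""
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return bold
    sigma_vox = (fwhm * FWHM_TO_SIGMA) / bold.voxel_sizes
    out = np.empty_like(bold.data, dtype=float)
    for t in range(bold.n_volumes):
        out[..., t] = gaussian_filter(bold.data[..., t], sigma=sigma_vox, mode="nearest")
    return bold.with_data(out)


def qc_exclude(
    subjects: pd.DataFrame,
    fd_column: str = "mean_fd",
    fd_limit: float = FD_EXCLUDE_MM,
    accuracy_columns: tuple[str, ...] = (),
    accuracy_floor: float = ACCURACY_FLOOR,
    outlier_columns: tuple[str, ...] = (),
    outlier_z: float = OUTLIER_Z,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample-level exclusions with a per-subject reason log.

    Rules (all strict inequalities): mean FD > ``fd_limit`` excludes;
    any accuracy column not strictly above ``accuracy_floor`` excludes;
    values strictly beyond ``outlier_z`` SDs from the pre-exclusion mean of
    an outlier column exclude.  A value at exactly mean + 3.29 SD is kept.
    Returns (kept subjects, exclusion log with subject_id/rule/value).
    """
    for col in (fd_column, *accuracy_columns, *outlier_columns):
        if col is not None and col not in subjects.columns:
            raise KeyError(f"QC rule references missing column {col!r}")
    log_rows = []
    excluded = np.zeros(len(subjects), dtype=bool)

    if fd_column is not None:
        bad = subjects[fd_column].to_numpy() > fd_limit
        for i in np.flatnonzero(bad):
            log_rows.append(
                {"subject_id": subjects.iloc[i]["subject_id"],
                 "rule": f"{fd_column}>{fd_limit}", "value": subjects.iloc[i][fd_column]}
            )
        excluded |= bad

    for col in accuracy_columns:
        bad = ~(subjects[col].to_numpy() > accuracy_floor)
        for i in np.flatnonzero(bad):
            log_rows.append(
                {"subject_id": subjects.iloc[i]["subject_id"],
                 "rule": f"{col}<={accuracy_floor}", "value": subjects.iloc[i][col]}
            )
        excluded |= bad

    for col in outlier_columns:
        vals = subjects[col].to_numpy(dtype=float)
        mu, sd = np.nanmean(vals), np.nanstd(vals, ddof=1)
        if sd == 0:
            continue
        bad = np.abs(vals - mu) > outlier_z * sd
        for i in np.flatnonzero(bad):
            log_rows.append(
                {"subject_id": subjects.iloc[i]["subject_id"],
                 "rule": f"|{col}-mean|>{outlier_z}SD", "value": vals[i]}
            )
        excluded |= bad

    log = pd.DataFrame(log_rows, columns=["subject_id", "rule", "value"])
    return subjects.loc[~excluded].reset_index(drop=True), log


def clean_run(
    bold: BoldRun,
    motion: pd.DataFrame,
    csf_mask: np.ndarray,
    wm_mask: np.ndarray,
    fd_threshold: float = FD_SCRUB_MM,
    band: tuple[float, float] = (0.009, 0.09),
    fwhm: float = 6.0,
) -> tuple[BoldRun, ConfoundMatrix]:
    """Standard cleaning pipeline in the stated order: nuisance regression
    (with scrubbing spikes), bandpass filtering, then spatial smoothing."""
    conf = build_confounds(bold, motion, csf_mask, wm_mask, fd_threshold=fd_threshold)
    conf = ConfoundMatrix(drop_dependent_confounds(conf.frame), conf.spike_volumes)
    out = regress_confounds(bold, conf)
    out = bandpass(out, *band)
    out = smooth_gaussian(out, fwhm)
    return out, conf
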