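"""BOLD intensity-change metrics (DVARS / RDVARS) and motion-BOLD coupling.

DVARS indexes the rate of change of the BOLD signal across the brain: the
root mean square, over voxels, of the frame-to-frame intensity difference.
RDVARS is the per-ROI analogue.  Subtracting the global series from the
regional ones gives residual measures (rRD, rRDVARS) whose correlation
quantifies the *regional* component of motion-BOLD coupling, over and above
the well-known global FD-DVARS relationship.

All difference series carry a conventional zero at frame 0 (no predecessor),
mirroring the displacement-derivative convention, and frame 0 is excluded
from every correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BoldRoiSeries",
    "MotionBoldCoupling",
    "dvars",
    "rdvars",
    "residual_measures",
    "coupling_analysis",
]


@dataclass
class BoldRoiSeries:
    """Region x frame matrix of ROI-mean BOLD intensities."""

    data: np.ndarray          # (R, T)
    region_ids: np.ndarray
    tr: float                 # frame period, seconds

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.region_ids = np.asarray(self.region_ids)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("data must be (regions, frames) with >= 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite BOLD values")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionBoldCoupling:
    """Per-subject global and residual motion-BOLD coupling coefficients."""

    subject_id: str
    r_global: float      # corr(FD, DVARS), frames 1..T-1
    r_residual: float    # corr(rRD, rRDVARS) pooled over regions and frames


def _masked_voxel_series(img4d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return np.asarray(img4d, dtype=float)[mask]       # (V, T)


def dvars(img4d: np.ndarray, mask: np.ndarray, scale: str = "none") -> np.ndarray:
    """Whole-brain DVARS series.

    DVARS(t) = sqrt(mean over masked voxels of (I_t - I_{t-1})^2), with
    DVARS(0) = 0.  Computed on realigned data prior to confound regression
    and filtering.  ``scale="grand-mean-1000"`` rescales intensities so the
    spatio-temporal mean is 1000 (for cross-subject comparability).
    """
    series = _masked_voxel_series(img4d, mask)
    series = _apply_scale(series, scale)
    out = np.zeros(series.shape[1])
    diff = np.diff(series, axis=1)
    out[1:] = np.sqrt((diff ** 2).mean(axis=0))
    return out


def rdvars(img4d: np.ndarray, atlas, mask: np.ndarray | None = None,
           scale: str = "none") -> np.ndarray:
    """Region x frame RDVARS matrix (per-ROI root-mean-square intensity change)."""
    labels = np.asarray(atlas.labels)
    img4d = np.asarray(img4d, dtype=float)
    if mask is None:
        mask = labels > 0
    mask = np.asarray(mask, dtype=bool)
    series = img4d[mask]
    series = _apply_scale(series, scale)
    lab = labels[mask]
    region_ids = np.asarray(atlas.region_ids)
    T = series.shape[1]
    out = np.zeros((len(region_ids), T))
    diff2 = np.diff(series, axis=1) ** 2
    for i, rid in enumerate(region_ids):
        sel = lab == rid
        if not sel.any():
            raise ValueError(f"empty region {rid}")
        out[i, 1:] = np.sqrt(diff2[sel].mean(axis=0))
    return out


def _apply_scale(series: np.ndarray, scale: str) -> np.ndarray:
    if scale == "none":
        return series
    if scale == "grand-mean-1000":
        gm = series.mean()
        if gm == 0:
            raise ValueError("zero grand mean; cannot scale")
        return series * (1000.0 / gm)
    raise ValueError(f"unknown scale mode {scale!r}")


def residual_measures(
    rd: np.ndarray, fd: np.ndarray, rdvars_mat: np.ndarray, dvars_series: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residual regional measures: rRD = RD - FD, rRDVARS = RDVARS - DVARS."""
    rd = np.asarray(rd, dtype=float)
    fd = np.asarray(fd, dtype=float)
    rdvars_mat = np.asarray(rdvars_mat, dtype=float)
    dvars_series = np.asarray(dvars_series, dtype=float)
    if rd.shape[1] != fd.shape[0] or rdvars_mat.shape[1] != dvars_series.shape[0]:
        raise ValueError("shape mismatch")
    if rd.shape != rdvars_mat.shape:
        raise ValueError("shape mismatch between RD and RDVARS")
    return rd - fd[None, :], rdvars_mat - dvars_series[None, :]


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance input; correlation undefined", stacklevel=3)
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def coupling_analysis(
    subjects: list[tuple],
    subject_ids: list[str] | None = None,
    method: str = "pearson",
    per_region_average: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Quantify how the regional motion-BOLD relationship scales with the
    global one across subjects.

    Each element of *subjects* is ``(fd, dvars, rrd, rrdvars)``: the global
    FD and DVARS series plus the residual region x frame matrices.  For each
    subject two coefficients are computed (frame 0 excluded):

    * ``r_global``: corr(FD, DVARS);
    * ``r_residual``: corr(rRD, rRDVARS), by default over the concatenation
      of all regions and frames; with ``per_region_average=True`` the mean
      of per-region correlations instead.

    Returns the per-subject table and the across-subject correlation between
    ``r_residual`` and ``r_global`` (requires >= 3 subjects with defined
    coefficients; NaN otherwise).
    """
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(len(subjects))]
    corr = _safe_pearson if method == "pearson" else _safe_spearman
    rows = []
    for sid, (fd, dv, rrd, rrdv) in zip(subject_ids, subjects):
        fd = np.asarray(fd, float)[1:]
        dv = np.asarray(dv, float)[1:]
        r_g = corr(fd, dv)
        if per_region_average:
            vals = [corr(rrd[i, 1:], rrdv[i, 1:]) for i in range(rrd.shape[0])]
            r_r = float(np.nanmean(vals))
        else:
            r_r = corr(rrd[:, 1:].ravel(), rrdv[:, 1:].ravel())
        rows.append(MotionBoldCoupling(sid, r_g, r_r))
    table = pd.DataFrame(
        {
            "subject": [c.subject_id for c in rows],
            "r_global": [c.r_global for c in rows],
            "r_residual": [c.r_residual for c in rows],
        }
    )
    ok = table.dropna()
    if len(ok) >= 3:
        across = float(np.corrcoef(ok["r_residual"], ok["r_global"])[0, 1])
    else:
        warnings.warn("fewer than 3 subjects with defined coupling; "
                      "across-subject correlation undefined")
        across = np.nan
    return table, across


def _safe_spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance input; correlation undefined", stacklevel=3)
        return np.nan
    return float(stats.spearmanr(x, y).statistic)
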