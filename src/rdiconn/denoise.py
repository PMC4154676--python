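"""First-level nuisance regression strategies and temporal band-pass filtering.

Nine strategies are supported, differing in which confound time courses are
regressed out of the regional BOLD signal before connectivity estimation:

======  =========================================================  ====
tag     regressors (besides the intercept)                         cols
======  =========================================================  ====
NOREG        none (demeaning only)                                  0
WMCSF        eroded white-matter + CSF mean signals                 2
GSREG        whole-brain global signal                              1
COMPCOR      5 principal components of a low-tSNR noise ROI         5
NOREG+M6     6 rigid motion parameters                              6
WMCSF+M6     WMCSF + 6 motion parameters                            8
GSREG+M6     GSREG + 6 motion parameters                            7
COMPCOR+M6   COMPCOR + 6 motion parameters                          11
SAT36        9 core regressors (M6 + WM + CSF + GS), their first
             backward differences, and the squares of both          36
======  =========================================================  ====

The order of operations is regression first, then a zero-phase fourth-order
Butterworth band-pass (0.01-0.1 Hz by default); a ``filter_first`` switch is
available for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .boldmetrics import BoldRoiSeries
from .motionfield import RigidMotionSeries, matrix_to_params

__all__ = [
    "STRATEGY_COLUMNS",
    "NuisanceDesign",
    "build_wmcsf",
    "build_gsr",
    "build_compcor",
    "build_motion6",
    "build_sat36",
    "build_design",
    "regress_out",
    "bandpass",
    "denoise_bold",
]

STRATEGY_COLUMNS = {
    "NOREG": 0,
    "WMCSF": 2,
    "GSREG": 1,
    "COMPCOR": 5,
    "NOREG+M6": 6,
    "WMCSF+M6": 8,
    "GSREG+M6": 7,
    "COMPCOR+M6": 11,
    "SAT36": 36,
}


@dataclass
class NuisanceDesign:
    """Frame x k nuisance regressor matrix with column labels.

    The intercept is always added at fit time and is not a column here.
    """

    matrix: np.ndarray
    labels: list[str]
    strategy: str

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] == 0 or self.matrix.size == 0:
            self.matrix = self.matrix.reshape(self.matrix.shape[0], 0)
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("label count must match column count")
        if self.strategy not in STRATEGY_COLUMNS:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        expected = STRATEGY_COLUMNS[self.strategy]
        if self.matrix.shape[1] != expected:
            raise ValueError(
                f"{self.strategy} expects {expected} columns, got "
                f"{self.matrix.shape[1]}"
            )

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self, path) -> None:
        """Export the regressor matrix (frame x k) with labelled columns."""
        import pandas as pd

        pd.DataFrame(self.matrix, columns=self.labels).to_csv(
            path, sep="\t", index_label="frame")


def _erode(mask: np.ndarray) -> np.ndarray:
    """One 6-connectivity erosion iteration."""
    structure = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_erosion(np.asarray(mask, bool), structure=structure)


def _mean_signal(img4d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    return np.asarray(img4d, float)[mask].mean(axis=0)


def build_wmcsf(img4d: np.ndarray, wm_mask: np.ndarray, csf_mask: np.ndarray
                ) -> np.ndarray:
    """Mean BOLD of eroded white-matter and CSF masks: (T, 2)."""
    cols = []
    for name, m in (("wm", wm_mask), ("csf", csf_mask)):
        er = _erode(m)
        if not er.any():
            raise ValueError(f"erosion emptied {name} mask")
        cols.append(_mean_signal(img4d, er))
    return np.column_stack(cols)


def build_gsr(img4d: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Whole-brain global signal: (T, 1)."""
    return _mean_signal(img4d, brain_mask)[:, None]


def build_compcor(
    img4d: np.ndarray,
    brain_mask: np.ndarray,
    n_components: int = 5,
    noise_fraction: float = 0.02,
) -> np.ndarray:
    """Principal components of a low-tSNR noise ROI: (T, n_components).

    The noise ROI is the set of voxels in the lowest *noise_fraction*
    quantile of tSNR (temporal mean / temporal SD).  Voxel time courses are
    demeaned and variance-normalised before the SVD; the returned temporal
    components are unit-norm and mutually orthogonal.
    """
    mask = np.asarray(brain_mask, bool)
    series = np.asarray(img4d, float)[mask]                  # (V, T)
    sd = series.std(axis=1)
    sd_safe = np.where(sd == 0, np.inf, sd)
    tsnr = series.mean(axis=1) / sd_safe
    cutoff = np.quantile(tsnr, noise_fraction)
    noise = series[tsnr <= cutoff]
    if noise.shape[0] < n_components + 1:
        # fall back to the n+1 lowest-tSNR voxels
        order = np.argsort(tsnr)
        noise = series[order[: n_components + 1]]
    X = noise - noise.mean(axis=1, keepdims=True)
    nsd = X.std(axis=1, keepdims=True)
    nsd[nsd == 0] = 1.0
    X = X / nsd
    # temporal components: left singular vectors of (T, V)
    U, s, _ = np.linalg.svd(X.T, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if rank < n_components:
        raise ValueError(
            f"noise ROI supports only {rank} components, {n_components} requested"
        )
    return U[:, :n_components]


def build_motion6(series: RigidMotionSeries) -> np.ndarray:
    """Six rigid-body motion parameters per frame: (T, 6).

    Columns: 3 rotations (rad, extrinsic x-y-z) then 3 translations (mm).
    """
    return np.asarray([matrix_to_params(m) for m in series.transforms])


def build_sat36(core9: np.ndarray) -> np.ndarray:
    """36-parameter expansion of a 9-column core (M6 + WM + CSF + GS).

    Columns: the 9 core regressors, their first backward differences (first
    row zero), and the squares of both sets.
    """
    core9 = np.asarray(core9, float)
    if core9.ndim != 2 or core9.shape[1] != 9:
        raise ValueError("core must have 9 columns (6 motion + WM + CSF + GS)")
    deriv = np.zeros_like(core9)
    deriv[1:] = np.diff(core9, axis=0)
    return np.column_stack([core9, deriv, core9 ** 2, deriv ** 2])


def build_design(
    strategy: str,
    img4d: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    motion: RigidMotionSeries | None = None,
    n_compcor: int = 5,
    compcor_fraction: float = 0.02,
) -> NuisanceDesign:
    """Assemble the regressor matrix for any of the nine strategies."""
    if strategy not in STRATEGY_COLUMNS:
        raise ValueError(f"unknown strategy {strategy!r}")
    base = strategy.replace("+M6", "")
    with_m6 = strategy.endswith("+M6")

    cols: list[np.ndarray] = []
    labels: list[str] = []
    if strategy == "SAT36":
        m6 = build_motion6(motion)
        wmcsf = build_wmcsf(img4d, wm_mask, csf_mask)
        gs = build_gsr(img4d, brain_mask)
        core = np.column_stack([m6, wmcsf, gs])
        mat = build_sat36(core)
        base_labels = [f"rot{a}" for a in "xyz"] + [f"trans{a}" for a in "xyz"] \
            + ["wm", "csf", "gs"]
        labels = (base_labels + [f"d_{l}" for l in base_labels]
                  + [f"{l}^2" for l in base_labels]
                  + [f"d_{l}^2" for l in base_labels])
        return NuisanceDesign(mat, labels, strategy)

    if base == "WMCSF":
        cols.append(build_wmcsf(img4d, wm_mask, csf_mask))
        labels += ["wm", "csf"]
    elif base == "GSREG":
        cols.append(build_gsr(img4d, brain_mask))
        labels += ["gs"]
    elif base == "COMPCOR":
        cols.append(build_compcor(img4d, brain_mask, n_compcor, compcor_fraction))
        labels += [f"compcor{i + 1}" for i in range(n_compcor)]
    if with_m6:
        cols.append(build_motion6(motion))
        labels += [f"rot{a}" for a in "xyz"] + [f"trans{a}" for a in "xyz"]
    if cols:
        mat = np.column_stack(cols)
    else:
        mat = np.empty((0, 0))
        if img4d is not None:
            mat = np.empty((np.asarray(img4d).shape[-1], 0))
        elif motion is not None:
            mat = np.empty((motion.n_frames, 0))
    return NuisanceDesign(mat, labels, strategy)


def regress_out(bold: BoldRoiSeries, design: NuisanceDesign) -> BoldRoiSeries:
    """OLS residuals of each regional time course on [intercept | design].

    Constant-zero columns are dropped with a warning (e.g. motion parameters
    of a motionless series); collinear columns are dropped via a rank check.
    Residuals are orthogonal to every retained design column and have zero
    mean.
    """
    Y = bold.data                                        # (R, T)
    T = Y.shape[1]
    X = design.matrix
    if X.shape[0] not in (0, T) and X.size:
        raise ValueError("design frame count does not match BOLD")
    cols = [np.ones(T)]
    kept_labels = ["intercept"]
    for j in range(X.shape[1]):
        c = X[:, j]
        if np.allclose(c, 0):
            warnings.warn(f"dropping constant-zero regressor {design.labels[j]!r}")
            continue
        candidate = np.column_stack(cols + [c])
        if np.linalg.matrix_rank(candidate) < candidate.shape[1]:
            warnings.warn(f"dropping collinear regressor {design.labels[j]!r}")
            continue
        cols.append(c)
        kept_labels.append(design.labels[j])
    Xf = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(Xf, Y.T, rcond=None)
    resid = Y - (Xf @ beta).T
    return BoldRoiSeries(resid, bold.region_ids.copy(), bold.tr)


def bandpass(
    bold: BoldRoiSeries, low: float = 0.01, high: float = 0.1, order: int = 4
) -> BoldRoiSeries:
    """Zero-phase Butterworth band-pass of each regional time course.

    The filter is applied forward and backward (no phase distortion, which
    would otherwise bias correlations); the effective attenuation is that of
    the squared magnitude response.  Output length equals input length.
    """
    nyq = 0.5 / bold.tr
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist={nyq}) Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / bold.tr,
                        output="sos")
    padlen = min(bold.n_frames - 1, 3 * (2 * sos.shape[0] + 1))
    filtered = signal.sosfiltfilt(sos, bold.data, axis=1, padlen=padlen)
    return BoldRoiSeries(filtered, bold.region_ids.copy(), bold.tr)


def denoise_bold(
    bold: BoldRoiSeries,
    design: NuisanceDesign,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 4,
    filter_first: bool = False,
) -> BoldRoiSeries:
    """Apply nuisance regression and band-pass filtering (in that order by
    default) to a regional BOLD series."""
    if filter_first:
        return regress_out(bandpass(bold, low, high, order), design)
    return bandpass(regress_out(bold, design), low, high, order)
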