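"""Voxel-wise displacement fields from rigid-body realignment transforms.

In-scanner head motion is estimated during realignment as one rigid-body
transform per frame (three rotations, three translations).  Because rotation
moves voxels by an amount proportional to their distance from the rotation
axis, the displacement experienced by the head is *not* spatially constant.
This module converts a series of rigid transforms into a per-voxel, per-frame
displacement-derivative image and derives the scalar summaries used in
group-level motion correction:

* FD  -- frame-wise displacement, the brain-wide spatial mean per frame;
* RD  -- regional displacement, the per-ROI analogue of FD;
* dRD -- the temporal average of RD minus FD, a per-region scalar that
         quantifies how much more (or less) a region moves than the brain
         as a whole.

The voxel-wise displacement of a voxel with world position ``x`` at frame
``t`` is ``d_t(x) = ||T_t^{-1} x - x||`` where ``T_t`` is the rigid transform
fitting frame ``t`` to the reference frame.  What is stored and averaged is
the absolute first temporal derivative ``D_t(x) = |d_t(x) - d_{t-1}(x)|``
with ``D_0 = 0``, i.e. a per-frame rate of position change in mm/frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import nibabel as nib
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidMotionSeries",
    "DisplacementField",
    "MotionSummary",
    "load_rigid_transforms",
    "load_par_file",
    "params_to_matrix",
    "matrix_to_params",
    "reexpress_about_origin",
    "voxelwise_displacement",
    "frame_displacement",
    "regional_displacement",
    "delta_rd",
    "motion_summary",
]

RIGID_ATOL = 1e-8

# Leading frames discarded before any analysis (T1 equilibration).
DEFAULT_DROP_FRAMES = 5


def _check_rigid(mat: np.ndarray, atol: float = 1e-6) -> None:
    """Raise ValueError if *mat* is not a proper rigid-body transform."""
    if mat.shape != (4, 4):
        raise ValueError(f"invalid transform: expected 4x4, got {mat.shape}")
    if not np.allclose(mat[3], [0.0, 0.0, 0.0, 1.0], atol=atol):
        raise ValueError("invalid transform: last row must be [0, 0, 0, 1]")
    R = mat[:3, :3]
    if not np.allclose(R.T @ R, np.eye(3), atol=atol):
        raise ValueError("invalid transform: rotation block not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("invalid transform: improper rotation (det < 0)")


@dataclass
class RigidMotionSeries:
    """Per-frame rigid-body transforms of one subject.

    ``transforms[t]`` maps world coordinates of the reference frame into the
    coordinates of frame ``t``'s head position; the transform at
    ``reference_index`` is the identity.  All matrices are expressed about
    the world-coordinate origin.
    """

    transforms: np.ndarray            # (T, 4, 4)
    reference_index: int
    voxel_to_world: np.ndarray        # (4, 4) grid affine

    def __post_init__(self) -> None:
        self.transforms = np.asarray(self.transforms, dtype=float)
        self.voxel_to_world = np.asarray(self.voxel_to_world, dtype=float)
        if self.transforms.ndim != 3 or self.transforms.shape[1:] != (4, 4):
            raise ValueError("transforms must have shape (T, 4, 4)")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not 0 <= self.reference_index < self.n_frames:
            raise ValueError("reference_index out of range")
        # vectorised rigidity check over all frames
        T = self.transforms
        R = T[:, :3, :3]
        if not np.allclose(T[:, 3, :], [0.0, 0.0, 0.0, 1.0], atol=1e-6):
            raise ValueError("invalid transform: last row must be [0, 0, 0, 1]")
        if not np.allclose(R @ R.transpose(0, 2, 1), np.eye(3), atol=1e-6):
            raise ValueError("invalid transform: rotation block not orthonormal")
        if np.any(np.linalg.det(R) < 0):
            raise ValueError("invalid transform: improper rotation (det < 0)")
        ref = self.transforms[self.reference_index]
        if not np.allclose(ref, np.eye(4), atol=1e-6):
            raise ValueError("transform at reference_index must be identity")

    @property
    def n_frames(self) -> int:
        return self.transforms.shape[0]

    def to_mat_dir(self, out_dir: str | Path, prefix: str = "MAT_") -> None:
        """Write MCFLIRT-style one-matrix-per-frame text files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for t in range(self.n_frames):
            np.savetxt(out / f"{prefix}{t:04d}", self.transforms[t], fmt="%.10f")


@dataclass
class DisplacementField:
    """4-D per-voxel displacement-derivative image (mm/frame).

    ``data[i, j, k, t]`` holds ``D_t`` for the voxel at grid index
    ``(i, j, k)``; values outside ``mask`` are zero.  With the default
    absolute-derivative convention all values are >= 0 and frame 0 is zero.
    """

    data: np.ndarray                  # (X, Y, Z, T)
    affine: np.ndarray                # (4, 4)
    mask: np.ndarray                  # (X, Y, Z) bool

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D")
        if self.data.shape[:3] != self.mask.shape:
            raise ValueError("mask shape must match data grid")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def masked_series(self) -> np.ndarray:
        """Return the (n_voxels, T) series for voxels inside the mask."""
        return self.data[self.mask]

    def mean_map(self, skip_first: bool = True) -> np.ndarray:
        """Temporally averaged displacement map (3-D, mm/frame).

        Frame 0 carries the conventional zero (no predecessor) and is skipped
        by default so the average reflects actual frame-to-frame rates.
        """
        start = 1 if skip_first and self.n_frames > 1 else 0
        out = self.data[..., start:].mean(axis=3)
        out[~self.mask] = 0.0
        return out

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, mask: np.ndarray) -> "DisplacementField":
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, mask)


@dataclass
class MotionSummary:
    """Scalar/tabular motion summaries of one subject."""

    fd: np.ndarray                    # (T,) mm per frame
    rd: np.ndarray                    # (R, T) mm
    delta_rd: np.ndarray              # (R,) mm
    mean_fd: float
    mean_voxel_map: np.ndarray        # (X, Y, Z) temporally averaged map
    region_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def fd_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.fd)), "fd": self.fd})

    def rd_frame(self) -> pd.DataFrame:
        recs = []
        for i, rid in enumerate(self.region_ids):
            for t in range(self.rd.shape[1]):
                recs.append((int(rid), t, self.rd[i, t]))
        return pd.DataFrame(recs, columns=["region", "frame", "rd"])


def params_to_matrix(params: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
    """Compose a rigid 4x4 matrix from (rx, ry, rz, tx, ty, tz).

    Rotations are in radians, extrinsic x-y-z convention (FSL .par column
    order: three rotations then three translations in mm).  If *center* is
    given the rotation is performed about that world point instead of the
    origin, and the returned matrix is re-expressed about the origin.
    """
    params = np.asarray(params, dtype=float)
    rx, ry, rz, tx, ty, tz = params
    M = np.eye(4)
    M[:3, :3] = Rotation.from_euler("xyz", [rx, ry, rz]).as_matrix()
    M[:3, 3] = [tx, ty, tz]
    if center is not None:
        M = reexpress_about_origin(M, center)
    return M


def matrix_to_params(mat: np.ndarray) -> np.ndarray:
    """Decompose a rigid matrix into (rx, ry, rz, tx, ty, tz); inverse of
    :func:`params_to_matrix` with ``center=None``."""
    rot = Rotation.from_matrix(mat[:3, :3]).as_euler("xyz")
    return np.concatenate([rot, mat[:3, 3]])


def reexpress_about_origin(mat: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Re-express a transform defined about world point *center* about the
    world origin: ``W = T(+c) @ M @ T(-c)``.  Applying ``W`` to a world point
    gives the same image as applying ``M`` in center-relative coordinates."""
    c = np.asarray(center, dtype=float)
    Tc = np.eye(4)
    Tc[:3, 3] = c
    Tci = np.eye(4)
    Tci[:3, 3] = -c
    return Tc @ mat @ Tci


def load_rigid_transforms(
    paths: Sequence[str | Path],
    voxel_to_world: np.ndarray,
    reference_index: int | None = None,
    center: np.ndarray | None = None,
    n_frames_expected: int | None = None,
) -> RigidMotionSeries:
    """Read MCFLIRT-style ``.mat`` files into a :class:`RigidMotionSeries`.

    Each file holds one 4x4 row-major whitespace-separated matrix.  If
    *center* is given, matrices are re-expressed about the world origin
    (useful when the realignment tool reports them about the image center).
    The series is normalised so the transform at *reference_index* (default:
    mid-series) is exactly the identity, by composing every matrix with the
    inverse of the reference matrix.
    """
    mats = []
    for p in paths:
        arr = np.loadtxt(p)
        if arr.shape != (4, 4):
            raise ValueError(f"invalid transform in {p}: expected 4x4, got {arr.shape}")
        _check_rigid(arr)
        mats.append(arr)
    if n_frames_expected is not None and len(mats) != n_frames_expected:
        raise ValueError(
            f"length mismatch: {len(mats)} transforms but image has "
            f"{n_frames_expected} frames"
        )
    T = np.asarray(mats)
    if center is not None:
        T = np.asarray([reexpress_about_origin(m, center) for m in T])
    if reference_index is None:
        reference_index = len(T) // 2
    ref_inv = np.linalg.inv(T[reference_index])
    T = T @ ref_inv
    T[reference_index] = np.eye(4)
    return RigidMotionSeries(T, reference_index, voxel_to_world)


def load_par_file(
    path: str | Path,
    voxel_to_world: np.ndarray,
    reference_index: int | None = None,
    center: np.ndarray | None = None,
) -> RigidMotionSeries:
    """Read a 6-column ``.par`` motion-parameter file (3 rotations in rad,
    3 translations in mm, FSL column order) and convert to matrices."""
    params = np.loadtxt(path)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("invalid .par file: expected 6 columns")
    T = np.asarray([params_to_matrix(p, center=center) for p in params])
    if reference_index is None:
        reference_index = len(T) // 2
    ref_inv = np.linalg.inv(T[reference_index])
    T = T @ ref_inv
    T[reference_index] = np.eye(4)
    return RigidMotionSeries(T, reference_index, voxel_to_world)


def voxelwise_displacement(
    series: RigidMotionSeries,
    mask: np.ndarray,
    norm: str = "euclidean",
    signed_derivative: bool = False,
    frame_to_frame: bool = False,
) -> DisplacementField:
    """Compute the per-voxel displacement-derivative field.

    For each masked voxel with world position ``x`` the per-frame position
    change relative to the reference frame is ``d_t(x) = ||T_t^{-1} x - x||``;
    the stored quantity is the absolute first temporal derivative
    ``D_t = |d_t - d_{t-1}|`` with ``D_0 = 0``.

    Parameters
    ----------
    norm:
        ``"euclidean"`` (default) uses the plain 3-vector norm;
        ``"rms"`` divides by sqrt(3) (per-coordinate root mean square).
    signed_derivative:
        Keep the sign of ``d_t - d_{t-1}`` (diagnostic use).
    frame_to_frame:
        Use ``||T_t^{-1} x - T_{t-1}^{-1} x||`` directly as the per-frame
        rate instead of differencing the distance-to-reference series.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if norm not in ("euclidean", "rms"):
        raise ValueError(f"unknown norm {norm!r}")
    ijk = np.argwhere(mask).astype(float)                       # (V, 3)
    A = series.voxel_to_world
    world = ijk @ A[:3, :3].T + A[:3, 3]                        # (V, 3)
    T = series.n_frames
    V = world.shape[0]

    inv = np.linalg.inv(series.transforms)                      # (T, 4, 4)
    # displacement of every voxel under every inverse transform, relative to
    # its reference position: (T, 3, V) via batched BLAS matmul
    Rm = inv[:, :3, :3] - np.eye(3)
    diff = Rm @ world.T + inv[:, :3, 3][:, :, None]

    scale = 1.0 / np.sqrt(3.0) if norm == "rms" else 1.0

    deriv = np.zeros((T, V))
    if frame_to_frame:
        step = np.diff(diff, axis=0)
        deriv[1:] = np.sqrt((step * step).sum(axis=1)) * scale
    else:
        dist = np.sqrt((diff * diff).sum(axis=1)) * scale           # (T, V)
        deriv[1:] = np.diff(dist, axis=0)
        if not signed_derivative:
            np.abs(deriv, out=deriv)

    data = np.zeros(mask.shape + (T,))
    data[mask] = deriv.T
    return DisplacementField(data, A.copy(), mask)


def frame_displacement(fld: DisplacementField) -> np.ndarray:
    """FD(t): spatial mean of the displacement derivative over the mask."""
    return fld.masked_series().mean(axis=0)


def regional_displacement(fld: DisplacementField, atlas) -> np.ndarray:
    """RD matrix (region x frame): per-ROI mean of the displacement derivative.

    *atlas* is a :class:`rdiconn.atlas.LabelAtlas` (or any object with a
    ``labels`` integer image and ``region_ids``); every region must have at
    least one voxel inside the field's mask.
    """
    labels = np.asarray(atlas.labels)
    if labels.shape != fld.mask.shape:
        raise ValueError("atlas grid does not match field grid")
    region_ids = np.asarray(atlas.region_ids)
    lab = labels[fld.mask]                                      # (V,)
    series = fld.masked_series()                                # (V, T)
    rd = np.empty((len(region_ids), fld.n_frames))
    for i, rid in enumerate(region_ids):
        sel = lab == rid
        if not sel.any():
            raise ValueError(f"empty region {rid} within mask")
        rd[i] = series[sel].mean(axis=0)
    return rd


def delta_rd(rd: np.ndarray, fd: np.ndarray) -> np.ndarray:
    """dRD_r = mean_t (RD_r(t) - FD(t)); the RDI per-region covariate."""
    rd = np.asarray(rd, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if rd.shape[1] != fd.shape[0]:
        raise ValueError("length mismatch between RD and FD")
    return (rd - fd[None, :]).mean(axis=1)


def motion_summary(fld: DisplacementField, atlas=None) -> MotionSummary:
    """Bundle FD, RD, dRD, mean FD and the temporally averaged map."""
    fd = frame_displacement(fld)
    if atlas is not None:
        rd = regional_displacement(fld, atlas)
        drd = delta_rd(rd, fd)
        region_ids = np.asarray(atlas.region_ids)
    else:
        rd = fd[None, :].copy()
        drd = np.zeros(1)
        region_ids = np.array([0])
    return MotionSummary(
        fd=fd,
        rd=rd,
        delta_rd=drd,
        mean_fd=float(fd[1:].mean()),  # frame 0 is a conventional zero
        mean_voxel_map=fld.mean_map(),
        region_ids=region_ids,
    )
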