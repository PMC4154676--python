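"""Synthetic multi-subject fMRI cohorts with planted motion artifacts.

The generator emulates the ingredients the motion framework needs, without
any real data:

* **Rigid motion trajectories.**  Six AR(1) parameter series (three Euler
  rotations, three translations) are composed into rigid transforms about a
  subject-specific rotation centre.  Head motion is treated as a *trait*:
  each subject draws an amplitude multiplier once, and a group is defined by
  a shared motion phenotype (amplitude scale, autocorrelation, rotation
  centre).  Off-centre rotation makes the voxel-wise displacement spatially
  non-constant, the phenomenon the RDI covariates exist to model.

* **ROI phantom.**  An ellipsoidal brain mask whose outer shell is
  partitioned into contiguous parcels (Voronoi cells of k-means centroids on
  voxel coordinates) with inner white-matter and CSF stand-in compartments.

* **BOLD.**  Regional latent signals drawn from a specified inter-regional
  covariance, band-limited to the resting-state band before mixing, are
  broadcast to voxels; a motion artifact proportional to the local
  displacement derivative (intensity = gamma * D_t(x)) plus i.i.d. Gaussian
  noise is added.  This additive displacement-coupled mechanism is the
  simplest one consistent with the observed FD-DVARS and rRD-rRDVARS
  coupling.  Ground truth (latent covariance, gamma, phenotypes, seeds) is
  recorded so every pipeline stage can be checked against what was planted.

Everything is deterministic given the cohort seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import LabelAtlas
from .boldmetrics import BoldRoiSeries
from .motionfield import (
    DisplacementField,
    RigidMotionSeries,
    delta_rd,
    frame_displacement,
    params_to_matrix,
    regional_displacement,
    voxelwise_displacement,
)

__all__ = [
    "MotionPhenotype",
    "SyntheticCohortSpec",
    "SubjectRecord",
    "SyntheticCohort",
    "simulate_motion",
    "grid_affine",
    "make_phantom",
    "simulate_bold",
    "generate_cohort",
    "default_latent_correlation",
]

# Per-unit-sigma scales of the 6 rigid parameters (rot rad, trans mm).
# With sigma = 1 and phi = 0.95 these give mean FD around 0.07 mm at a
# 3 mm-voxel 24^3 grid, matching typical low-motion paediatric cohorts.
DEFAULT_PARAM_SCALES = np.array([0.0012, 0.0012, 0.0012, 0.035, 0.035, 0.035])


@dataclass
class MotionPhenotype:
    """Group-level motion trait parameters.

    ``sigma`` scales the innovation SD of all six AR(1) parameter series
    (multiplied by ``param_scales``, rad for rotations and mm for
    translations); ``phi`` is the AR(1) coefficient (motion is slow and
    autocorrelated); ``rotation_center`` is the world point (mm) about which
    rotations happen; ``center_jitter_mm`` is the SD of the per-subject
    random offset added to that centre; ``trait_cv`` is the log-scale SD of
    the per-subject amplitude multiplier.
    """

    sigma: float = 1.0
    phi: float = 0.95
    rotation_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    param_scales: np.ndarray = field(
        default_factory=lambda: DEFAULT_PARAM_SCALES.copy()
    )
    center_jitter_mm: float = 10.0
    trait_cv: float = 0.35

    def __post_init__(self) -> None:
        self.rotation_center = np.asarray(self.rotation_center, float)
        self.param_scales = np.asarray(self.param_scales, float)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError("phi must be in [0, 1)")


@dataclass
class SyntheticCohortSpec:
    """Full description of a two-group synthetic cohort."""

    n_per_group: tuple[int, int] = (30, 30)
    n_frames: int = 150
    tr: float = 2.0
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    n_regions: int = 20
    latent_correlation: np.ndarray | None = None      # (M, M) PSD
    artifact_gamma: float = 20.0       # BOLD units per mm/frame
    signal_amplitude: float = 1.0
    noise_sd: float = 1.0
    baseline: float = 1000.0
    phenotypes: tuple[MotionPhenotype, MotionPhenotype] = None
    effect_edges: list[tuple[int, int]] = field(default_factory=list)
    effect_sizes: list[float] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 20:
            raise ValueError("need at least 20 frames")
        if min(self.n_per_group) < 1:
            raise ValueError("both groups must be nonempty")
        if self.phenotypes is None:
            self.phenotypes = (MotionPhenotype(), MotionPhenotype())
        if len(self.effect_edges) != len(self.effect_sizes):
            raise ValueError("effect_edges and effect_sizes must align")
        M = self.n_regions
        for a, b in self.effect_edges:
            if not (0 <= a < M and 0 <= b < M and a != b):
                raise ValueError(f"effect edge ({a}, {b}) outside the edge set")
        if self.latent_correlation is not None:
            C = np.asarray(self.latent_correlation, float)
            if C.shape != (M, M):
                raise ValueError("latent correlation must be (M, M)")
            if np.min(np.linalg.eigvalsh((C + C.T) / 2)) < -1e-8:
                raise ValueError("latent correlation must be PSD")


@dataclass
class SubjectRecord:
    """Everything the pipeline needs about one synthetic subject."""

    subject_id: str
    group: int
    age: float
    iq: float
    gender: int
    motion: RigidMotionSeries
    bold_roi: BoldRoiSeries
    fd: np.ndarray
    rd: np.ndarray
    delta_rd: np.ndarray
    mean_fd: float
    mean_disp_map: np.ndarray          # masked-voxel vector
    dvars: np.ndarray | None = None
    rdvars: np.ndarray | None = None
    image: np.ndarray | None = None    # 4-D BOLD, kept only on request
    field: DisplacementField | None = None


@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    atlas: LabelAtlas
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    spec: SyntheticCohortSpec
    manifest: dict

    @property
    def phenotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "iq": [s.iq for s in self.subjects],
                "gender": [s.gender for s in self.subjects],
                "mean_fd": [s.mean_fd for s in self.subjects],
            }
        )

    @property
    def delta_rd_matrix(self) -> np.ndarray:
        return np.asarray([s.delta_rd for s in self.subjects])


def grid_affine(shape: tuple[int, int, int], voxel_size: float = 3.0) -> np.ndarray:
    """Affine placing the grid centre at the world origin (mm)."""
    A = np.eye(4)
    A[0, 0] = A[1, 1] = A[2, 2] = voxel_size
    A[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_size
    return A


def simulate_motion(
    phenotype: MotionPhenotype,
    n_frames: int,
    seed: int | np.random.Generator,
    voxel_to_world: np.ndarray,
    sigma_subject: float | None = None,
    rotation_center: np.ndarray | None = None,
) -> RigidMotionSeries:
    """AR(1) rigid motion trajectory for one subject.

    Each of the six parameters follows a stationary AR(1) process
    ``p_t = phi * p_{t-1} + eps_t`` with innovation SD
    ``sigma_subject * param_scale`` (stationary variance
    ``sigma^2 / (1 - phi^2)``).  Parameters are composed into rigid matrices
    about the rotation centre, re-expressed about the world origin, and the
    mid-series frame is forced to identity (the realignment reference).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    sig = phenotype.sigma if sigma_subject is None else sigma_subject
    center = phenotype.rotation_center if rotation_center is None else rotation_center
    scales = sig * phenotype.param_scales
    phi = phenotype.phi

    params = np.zeros((n_frames, 6))
    if sig > 0:
        stat_sd = scales / np.sqrt(1.0 - phi ** 2)
        params[0] = rng.normal(0.0, stat_sd)
        eps = rng.normal(0.0, scales, size=(n_frames - 1, 6))
        for t in range(1, n_frames):
            params[t] = phi * params[t - 1] + eps[t - 1]

    mats = np.asarray([params_to_matrix(p, center=center) for p in params])
    ref = n_frames // 2
    mats = mats @ np.linalg.inv(mats[ref])
    mats[ref] = np.eye(4)
    return RigidMotionSeries(mats, ref, np.asarray(voxel_to_world, float))


def make_phantom(
    shape: tuple[int, int, int] = (24, 24, 24),
    n_regions: int = 20,
    seed: int = 0,
    voxel_size: float = 3.0,
) -> tuple[LabelAtlas, np.ndarray, np.ndarray, np.ndarray]:
    """Ellipsoidal brain phantom: (atlas, brain_mask, wm_mask, csf_mask).

    The outer ("grey matter") shell of the ellipsoid is partitioned into
    *n_regions* contiguous parcels via k-means on voxel coordinates (Voronoi
    cells of the centroids, hence connected within the convex mask); the
    inner core provides white-matter and CSF stand-ins.
    """
    from sklearn.cluster import KMeans

    shape = tuple(shape)
    ii, jj, kk = np.indices(shape)
    center = (np.asarray(shape) - 1) / 2.0
    radii = np.asarray(shape) * 0.45
    rho2 = (((ii - center[0]) / radii[0]) ** 2
            + ((jj - center[1]) / radii[1]) ** 2
            + ((kk - center[2]) / radii[2]) ** 2)
    brain = rho2 <= 1.0
    if brain.sum() < max(10 * n_regions, 50):
        raise ValueError("degenerate grid: too few brain voxels for the parcels")
    # WM / CSF stand-ins: solid off-centre balls, thick enough to survive a
    # one-voxel erosion even on small grids
    rmin = min(shape)
    off = 0.20 * shape[0]
    d2_wm = ((ii - center[0] - off) ** 2 + (jj - center[1]) ** 2
             + (kk - center[2]) ** 2)
    d2_csf = ((ii - center[0] + off) ** 2 + (jj - center[1]) ** 2
              + (kk - center[2]) ** 2)
    wm = (d2_wm <= (0.22 * rmin) ** 2) & brain
    csf = (d2_csf <= (0.12 * rmin) ** 2) & brain & ~wm
    gm = brain & ~(wm | csf)

    coords = np.argwhere(gm).astype(float)
    km = KMeans(n_clusters=n_regions, n_init=4, random_state=seed)
    lab = km.fit_predict(coords)
    # assign by nearest final centroid so parcels are exact Voronoi cells
    d2 = ((coords[:, None, :] - km.cluster_centers_[None]) ** 2).sum(axis=2)
    lab = np.argmin(d2, axis=1)

    labels = np.zeros(shape, dtype=int)
    labels[tuple(coords.astype(int).T)] = lab + 1
    table = pd.DataFrame(
        {
            "region_id": np.arange(1, n_regions + 1),
            "long_name": [f"parcel-{i + 1:02d}" for i in range(n_regions)],
            "short_name": [f"p{i + 1:02d}" for i in range(n_regions)],
            "hemisphere": ["" for _ in range(n_regions)],
            "merged_from": ["" for _ in range(n_regions)],
        }
    )
    atlas = LabelAtlas(labels, table, grid_affine(shape, voxel_size))
    return atlas, brain, wm, csf


def default_latent_correlation(n_regions: int, base_r: float = 0.2) -> np.ndarray:
    """Exchangeable latent correlation: 1 on the diagonal, base_r elsewhere."""
    C = np.full((n_regions, n_regions), base_r)
    np.fill_diagonal(C, 1.0)
    return C


def _nearest_psd_correlation(C: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalise to unit diagonal."""
    w, V = np.linalg.eigh((C + C.T) / 2)
    w = np.clip(w, 1e-10, None)
    C2 = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(C2))
    return C2 / np.outer(d, d)


def _group_correlation(spec: SyntheticCohortSpec, group: int) -> np.ndarray:
    C = (
        np.asarray(spec.latent_correlation, float)
        if spec.latent_correlation is not None
        else default_latent_correlation(spec.n_regions)
    )
    if group == 1 and spec.effect_edges:
        C = C.copy()
        for (a, b), dz in zip(spec.effect_edges, spec.effect_sizes):
            r_new = np.tanh(np.arctanh(C[a, b]) + dz)
            C[a, b] = C[b, a] = r_new
        C = _nearest_psd_correlation(C)
    return C


def _band_limited_latent(
    corr: np.ndarray, n_frames: int, tr: float, rng: np.random.Generator
) -> np.ndarray:
    """Latent regional signals with the given correlation, band-limited to
    0.01-0.1 Hz and unit variance per region."""
    from scipy import signal as sps

    M = corr.shape[0]
    white = rng.standard_normal((M, n_frames))
    sos = sps.butter(4, [0.01, 0.1], btype="bandpass", fs=1.0 / tr, output="sos")
    padlen = min(n_frames - 1, 3 * (2 * sos.shape[0] + 1))
    filt = sps.sosfiltfilt(sos, white, axis=1, padlen=padlen)
    filt = filt / filt.std(axis=1, keepdims=True)
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(M))
    return L @ filt


def simulate_bold(
    spec: SyntheticCohortSpec,
    motion: RigidMotionSeries,
    atlas: LabelAtlas,
    brain_mask: np.ndarray,
    rng: np.random.Generator,
    group: int = 0,
    field: DisplacementField | None = None,
    coupling_signed: bool = False,
) -> tuple[np.ndarray, dict]:
    """4-D BOLD image with planted connectivity and motion artifact.

    Voxel intensity: baseline + amplitude * latent(region) +
    gamma * s(x) * D_t(x) + noise, where D_t is the subject's displacement
    derivative and s(x) is +1 (or a random +/-1 per voxel when
    ``coupling_signed``).  Returns the image and a ground-truth record.
    """
    if field is None:
        field = voxelwise_displacement(motion, brain_mask)
    corr = _group_correlation(spec, group)
    latent = _band_limited_latent(corr, spec.n_frames, spec.tr, rng)

    mask = np.asarray(brain_mask, bool)
    lab = atlas.labels[mask]                                 # (V,)
    V = lab.shape[0]
    vox = np.zeros((V, spec.n_frames))
    gm = lab > 0
    vox[gm] = spec.signal_amplitude * latent[lab[gm] - 1]

    disp = field.masked_series()                             # (V, T)
    if coupling_signed:
        sgn = rng.choice([-1.0, 1.0], size=V)[:, None]
    else:
        sgn = 1.0
    vox = vox + spec.artifact_gamma * sgn * disp
    vox += spec.baseline + spec.noise_sd * rng.standard_normal((V, spec.n_frames))

    img = np.zeros(mask.shape + (spec.n_frames,))
    img[mask] = vox
    truth = {
        "latent_correlation": corr,
        "gamma": spec.artifact_gamma,
        "group": group,
        "coupling_signed": coupling_signed,
    }
    return img, truth


def generate_cohort(
    spec: SyntheticCohortSpec,
    keep_images: bool = False,
    compute_dvars: bool = False,
    out_dir: str | Path | None = None,
) -> SyntheticCohort:
    """Generate a full two-group cohort and run the motion metrics.

    Each subject gets: a motion trajectory drawn from the group phenotype
    (with a per-subject amplitude trait and rotation-centre jitter), a BOLD
    image with the planted latent connectivity and displacement-coupled
    artifact, and the derived FD / RD / dRD summaries plus the ROI-mean BOLD
    series.  Ages ~ U(7, 35) years, IQ ~ N(110, 15), gender ~ Bernoulli(1/2)
    (emulating a mixed paediatric/young-adult cohort).  Deterministic from
    ``spec.seed``; all derived seeds are recorded in the manifest.  With
    *out_dir* set, NIfTI images, MCFLIRT-style .mat directories and a
    phenotype TSV are written so the cohort looks like a real one on disk.
    """
    master = np.random.default_rng(spec.seed)
    atlas_seed = int(master.integers(2 ** 31))
    atlas, brain, wm, csf = make_phantom(
        spec.grid_shape, spec.n_regions, seed=atlas_seed, voxel_size=spec.voxel_size_mm
    )
    affine = atlas.affine
    lab_mask = atlas.labels[brain]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        atlas.write(out_dir / "atlas.nii.gz", out_dir / "regions.tsv")

    subjects: list[SubjectRecord] = []
    subject_seeds: dict[str, int] = {}
    idx = 0
    for group, n_sub in enumerate(spec.n_per_group):
        phen = spec.phenotypes[group]
        for _ in range(n_sub):
            sid = f"sub-{idx:03d}"
            sseed = int(master.integers(2 ** 31))
            subject_seeds[sid] = sseed
            rng = np.random.default_rng(sseed)

            sigma_subject = phen.sigma * float(
                np.exp(rng.normal(0.0, phen.trait_cv))
            )
            center = phen.rotation_center + rng.normal(
                0.0, phen.center_jitter_mm, size=3
            )
            motion = simulate_motion(
                phen, spec.n_frames, rng, affine,
                sigma_subject=sigma_subject, rotation_center=center,
            )
            fld = voxelwise_displacement(motion, brain)
            fd = frame_displacement(fld)
            rd = regional_displacement(fld, atlas)
            drd = delta_rd(rd, fd)

            img, _truth = simulate_bold(
                spec, motion, atlas, brain, rng, group=group, field=fld
            )
            # ROI-mean BOLD over labelled voxels
            vox = img[brain]
            bold = np.empty((spec.n_regions, spec.n_frames))
            for i, rid in enumerate(atlas.region_ids):
                bold[i] = vox[lab_mask == rid].mean(axis=0)
            roi = BoldRoiSeries(bold, atlas.region_ids.copy(), spec.tr)

            dv = rdv = None
            if compute_dvars:
                from .boldmetrics import dvars as _dvars, rdvars as _rdvars

                dv = _dvars(img, brain)
                rdv = _rdvars(img, atlas, mask=brain)

            rec = SubjectRecord(
                subject_id=sid,
                group=group,
                age=float(rng.uniform(7.0, 35.0)),
                iq=float(rng.normal(110.0, 15.0)),
                gender=int(rng.integers(0, 2)),
                motion=motion,
                bold_roi=roi,
                fd=fd,
                rd=rd,
                delta_rd=drd,
                mean_fd=float(fd[1:].mean()),
                mean_disp_map=fld.masked_series()[:, 1:].mean(axis=1),
                dvars=dv,
                rdvars=rdv,
                image=img if keep_images else None,
                field=fld if keep_images else None,
            )
            subjects.append(rec)

            if out_dir is not None:
                import nibabel as nib

                nib.save(
                    nib.Nifti1Image(img.astype(np.float32), affine),
                    str(out_dir / f"{sid}_bold.nii.gz"),
                )
                motion.to_mat_dir(out_dir / f"{sid}_mats")
            idx += 1

    manifest = {
        "seed": spec.seed,
        "atlas_seed": atlas_seed,
        "subject_seeds": subject_seeds,
        "n_per_group": list(spec.n_per_group),
        "n_frames": spec.n_frames,
        "tr": spec.tr,
        "grid_shape": list(spec.grid_shape),
        "n_regions": spec.n_regions,
        "artifact_gamma": spec.artifact_gamma,
        "noise_sd": spec.noise_sd,
        "effect_edges": [list(e) for e in spec.effect_edges],
        "effect_sizes": list(spec.effect_sizes),
    }
    cohort = SyntheticCohort(subjects, atlas, brain, wm, csf, spec, manifest)
    if out_dir is not None:
        cohort.phenotype_frame.to_csv(out_dir / "phenotype.tsv", sep="\t",
                                      index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return cohort
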