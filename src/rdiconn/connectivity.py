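"""Fisher-Z functional connectivity matrices and long-format edge tables.

Connectivity strength between two denoised regional time courses is the
Fisher-Z transformed Pearson correlation, Z = atanh(r).  Matrices are
symmetric with an undefined (NaN) diagonal; the long-format edge table holds
one row per subject per unordered region pair (A < B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .boldmetrics import BoldRoiSeries

__all__ = ["ConnectivityMatrix", "fisher_z_matrix", "edge_table", "matrix_from_table"]

CLIP = 1e-7


@dataclass
class ConnectivityMatrix:
    """M x M symmetric Fisher-Z matrix for one subject and one strategy."""

    z: np.ndarray
    region_ids: np.ndarray
    subject_id: str = ""
    strategy: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.region_ids = np.asarray(self.region_ids)
        M = self.z.shape[0]
        if self.z.shape != (M, M) or M != len(self.region_ids):
            raise ValueError("z must be square and match region_ids")
        if not np.allclose(self.z, self.z.T, atol=1e-12, equal_nan=True):
            raise ValueError("z must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]

    def upper_values(self) -> np.ndarray:
        """Edge values in (A, B), A < B order."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.z[iu]

    def to_tsv(self, path: str | Path, names: list[str] | None = None) -> None:
        if names is None:
            names = [str(r) for r in self.region_ids]
        pd.DataFrame(self.z, index=names, columns=names).to_csv(path, sep="\t")


def fisher_z_matrix(
    bold: BoldRoiSeries,
    subject_id: str = "",
    strategy: str = "",
    clip: float = CLIP,
    drop_degenerate: bool = False,
) -> ConnectivityMatrix:
    """Fisher-Z matrix of a regional BOLD series.

    Correlations are clipped to +/-(1 - *clip*) before atanh so duplicated
    or perfectly anti-correlated series map to a large finite Z.  Regions
    with zero temporal variance get NaN edges with a warning (or are always
    NaN with ``drop_degenerate=True``, which is the same thing here: their
    edges cannot be defined).
    """
    Y = bold.data
    if Y.shape[1] < 3:
        raise ValueError("need at least 3 frames for a correlation")
    sd = Y.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance region(s); edges set to NaN"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(Y)
    r = np.clip(r, -(1 - clip), 1 - clip)
    z = np.arctanh(r)
    z[degenerate, :] = np.nan
    z[:, degenerate] = np.nan
    np.fill_diagonal(z, np.nan)
    z = (z + z.T) / 2.0  # enforce exact symmetry against rounding
    return ConnectivityMatrix(z, bold.region_ids.copy(), subject_id, strategy)


def edge_table(matrices: list[ConnectivityMatrix]) -> pd.DataFrame:
    """Long-format edge table: columns (subject, region_a, region_b, z).

    All matrices must share the region set; each contributes M(M-1)/2 rows.
    """
    if not matrices:
        raise ValueError("no matrices given")
    ref = matrices[0].region_ids
    rows = []
    for cm in matrices:
        if not np.array_equal(cm.region_ids, ref):
            raise ValueError("region set mismatch between matrices")
        iu = np.triu_indices(cm.n_regions, k=1)
        rows.append(
            pd.DataFrame(
                {
                    "subject": cm.subject_id,
                    "region_a": ref[iu[0]],
                    "region_b": ref[iu[1]],
                    "z": cm.z[iu],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def matrix_from_table(
    table: pd.DataFrame, subject_id: str, region_ids: np.ndarray | None = None
) -> ConnectivityMatrix:
    """Rebuild one subject's symmetric matrix from a long-format edge table."""
    sub = table[table["subject"] == subject_id]
    if sub.empty:
        raise ValueError(f"subject {subject_id!r} not in table")
    if region_ids is None:
        region_ids = np.unique(
            np.concatenate([sub["region_a"].values, sub["region_b"].values])
        )
    index = {rid: i for i, rid in enumerate(region_ids)}
    M = len(region_ids)
    z = np.full((M, M), np.nan)
    for a, b, v in zip(sub["region_a"], sub["region_b"], sub["z"]):
        z[index[a], index[b]] = v
        z[index[b], index[a]] = v
    return ConnectivityMatrix(z, np.asarray(region_ids), subject_id)
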