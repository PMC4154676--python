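"""ROI atlas construction from probabilistic maps.

Regions are delineated by retaining voxels whose probability strictly
exceeds a threshold (default 25%); voxels claimed by several regions go to
the one with the higher probability.  Regions smaller than a minimum volume
are merged into the spatially adjacent region sharing the largest boundary
surface, iterating until no undersized region remains; merge provenance is
kept in the region table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib

__all__ = [
    "LabelAtlas",
    "threshold_probabilistic",
    "merge_small_regions",
    "apply_merge_recipe",
    "load_packaged_recipe",
]

_FACE_OFFSETS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]


@dataclass
class LabelAtlas:
    """Integer label image plus a region table.

    Labels are a contiguous positive range 1..M with 0 = background.  The
    table has one row per region: ``region_id``, ``long_name``,
    ``short_name``, ``hemisphere``, ``merged_from`` (semicolon-joined source
    names, empty when unmerged) and ``n_voxels``.
    """

    labels: np.ndarray                # (X, Y, Z) int
    table: pd.DataFrame
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label image must be integer")
        present = np.unique(self.labels)
        present = present[present > 0]
        ids = np.asarray(self.table["region_id"])
        if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
            raise ValueError("region ids must be the contiguous range 1..M")
        if not set(present) <= set(ids):
            raise ValueError("label image contains ids missing from the table")
        counts = np.bincount(self.labels.ravel(), minlength=len(ids) + 1)
        if np.any(counts[1:len(ids) + 1] == 0):
            raise ValueError("every region must have at least one voxel")
        self.table = self.table.copy()
        self.table["n_voxels"] = counts[self.table["region_id"].to_numpy()]

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 from the affine."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.labels.astype(np.int16), self.affine)

    def write(self, label_path: str | Path, table_path: str | Path) -> None:
        nib.save(self.to_nifti(), str(label_path))
        self.table.to_csv(table_path, sep="\t", index=False)

    @classmethod
    def read(cls, label_path: str | Path, table_path: str | Path) -> "LabelAtlas":
        img = nib.load(str(label_path))
        table = pd.read_csv(table_path, sep="\t", keep_default_na=False)
        return cls(np.asarray(img.dataobj).astype(int), table, img.affine)


def _default_table(names: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": np.arange(1, len(names) + 1),
            "long_name": names,
            "short_name": [n[:12] for n in names],
            "hemisphere": ["" for _ in names],
            "merged_from": ["" for _ in names],
        }
    )


def threshold_probabilistic(
    prob_maps: np.ndarray,
    names: list[str] | None = None,
    threshold: float = 0.25,
    affine: np.ndarray | None = None,
) -> LabelAtlas:
    """Build a label atlas from per-region probability maps.

    *prob_maps* is an (R, X, Y, Z) stack.  A voxel is labelled with the
    argmax-probability region among regions whose probability strictly
    exceeds *threshold*; ties go to the lower region id.  Regions for which
    no voxel survives are dropped with a warning (candidates for merging at
    the source level).
    """
    prob_maps = np.asarray(prob_maps, dtype=float)
    if prob_maps.ndim != 4:
        raise ValueError("prob_maps must be (regions, X, Y, Z)")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    R = prob_maps.shape[0]
    if names is None:
        names = [f"region-{i + 1:02d}" for i in range(R)]
    if affine is None:
        affine = np.eye(4)

    best = np.argmax(prob_maps, axis=0)          # first max wins -> lower id
    best_p = np.take_along_axis(prob_maps, best[None], axis=0)[0]
    labels = np.where(best_p > threshold, best + 1, 0)

    present = np.unique(labels)
    present = present[present > 0]
    missing = sorted(set(range(1, R + 1)) - set(present.tolist()))
    if missing:
        warnings.warn(
            f"regions with no surviving voxel at threshold {threshold}: "
            f"{[names[i - 1] for i in missing]}; dropped (merge candidates)"
        )
    # relabel to a contiguous range over surviving regions
    remap = {old: new for new, old in enumerate(present, start=1)}
    out = np.zeros_like(labels)
    for old, new in remap.items():
        out[labels == old] = new
    table = _default_table([names[i - 1] for i in present])
    return LabelAtlas(out.astype(int), table, np.asarray(affine, float))


def _boundary_counts(labels: np.ndarray, region: int) -> dict[int, int]:
    """Count face-adjacent voxels of each neighbouring label around *region*."""
    sel = labels == region
    counts: dict[int, int] = {}
    for off in _FACE_OFFSETS:
        shifted = np.roll(labels, off, axis=(0, 1, 2))
        # voxels rolled across the array edge are not true neighbours
        edge = np.zeros_like(sel)
        ax = int(np.nonzero(off)[0][0])
        idx = [slice(None)] * 3
        idx[ax] = 0 if off[ax] == 1 else -1
        edge[tuple(idx)] = True
        neigh = shifted[sel & ~edge]
        for lab in np.unique(neigh):
            lab = int(lab)
            if lab not in (0, region):
                counts[lab] = counts.get(lab, 0) + int((neigh == lab).sum())
    return counts


def merge_small_regions(
    atlas: LabelAtlas,
    min_volume: float = 30.0,
    unit: str = "vox",
) -> LabelAtlas:
    """Absorb undersized regions into their largest-boundary neighbour.

    Each region whose volume is below *min_volume* (in voxels, or mm^3 with
    ``unit="mm3"``) is merged into the face-adjacent region sharing the
    largest boundary surface; ties go to the larger neighbour, then the
    lower id.  The process iterates (smallest region first) until no region
    is undersized; regions with no neighbour are left unmerged with a
    warning.  Voxel counts are conserved and merge provenance recorded.
    """
    if min_volume <= 0:
        raise ValueError("min_volume must be positive")
    if unit not in ("vox", "mm3"):
        raise ValueError("unit must be 'vox' or 'mm3'")
    vox_vol = atlas.voxel_volume() if unit == "mm3" else 1.0
    min_vox = min_volume / vox_vol

    labels = atlas.labels.copy()
    table = atlas.table.copy().set_index("region_id")
    merged_names: dict[int, list[str]] = {
        rid: ([s] if (s := table.loc[rid, "merged_from"]) else [])
        for rid in table.index
    }
    unmergeable: set[int] = set()

    while True:
        counts = np.bincount(labels.ravel(), minlength=int(table.index.max()) + 1)
        small = [
            rid for rid in table.index
            if counts[rid] < min_vox and rid not in unmergeable
        ]
        if not small:
            break
        rid = min(small, key=lambda r: (counts[r], r))
        nb = _boundary_counts(labels, rid)
        if not nb:
            warnings.warn(f"region {rid} is undersized but has no neighbour; "
                          "left unmerged")
            unmergeable.add(rid)
            continue
        target = max(nb, key=lambda lab: (nb[lab], counts[lab], -lab))
        labels[labels == rid] = target
        merged_names[target] = (
            merged_names.get(target, [])
            + [str(table.loc[rid, "long_name"])]
            + merged_names.pop(rid, [])
        )
        table = table.drop(index=rid)

    # relabel surviving regions contiguously
    survivors = sorted(table.index)
    out = np.zeros_like(labels)
    rows = []
    for new, old in enumerate(survivors, start=1):
        out[labels == old] = new
        row = table.loc[old]
        rows.append(
            {
                "region_id": new,
                "long_name": row["long_name"],
                "short_name": row["short_name"],
                "hemisphere": row["hemisphere"],
                "merged_from": "; ".join(merged_names.get(old, [])),
            }
        )
    return LabelAtlas(out, pd.DataFrame(rows), atlas.affine.copy())


def apply_merge_recipe(atlas: LabelAtlas, recipe: pd.DataFrame) -> LabelAtlas:
    """Merge explicitly named regions according to a declarative recipe.

    *recipe* has columns ``new_name``, ``short_name`` and ``sources``
    (semicolon-separated long names).  For each row, every region whose
    ``long_name`` matches one of the sources (case-insensitive) is merged
    into a single region carrying ``new_name``; provenance is recorded in
    ``merged_from``.  Rows whose sources are absent from the atlas are
    skipped — the recipe describes a specific atlas family and is a no-op on
    unrelated (e.g. synthetic) atlases.
    """
    labels = atlas.labels.copy()
    table = atlas.table.copy()
    name_to_id = {str(n).strip().lower(): i
                  for n, i in zip(table["long_name"], table["region_id"])}

    for _, row in recipe.iterrows():
        sources = [s.strip().lower() for s in str(row["sources"]).split(";")
                   if s.strip()]
        found = [name_to_id[s] for s in sources if s in name_to_id]
        if not found:
            continue
        target = found[0]
        for rid in found[1:]:
            labels[labels == rid] = target
            name_to_id = {n: i for n, i in name_to_id.items() if i != rid}
            table = table[table["region_id"] != rid]
        idx = table["region_id"] == target
        table.loc[idx, "merged_from"] = str(row["sources"])
        table.loc[idx, "long_name"] = str(row["new_name"])
        if "short_name" in recipe.columns and not pd.isna(row["short_name"]):
            table.loc[idx, "short_name"] = str(row["short_name"])

    survivors = sorted(table["region_id"])
    out = np.zeros_like(labels)
    rows = []
    for new, old in enumerate(survivors, start=1):
        out[labels == old] = new
        r = table[table["region_id"] == old].iloc[0].to_dict()
        r["region_id"] = new
        r.pop("n_voxels", None)
        rows.append(r)
    return LabelAtlas(out, pd.DataFrame(rows), atlas.affine.copy())


def load_packaged_recipe() -> pd.DataFrame:
    """The packaged Harvard-Oxford-style merge recipe (per-hemisphere region
    names; apply after prefixing names with the hemisphere if needed)."""
    from importlib import resources

    with resources.files("rdiconn.data").joinpath(
        "ho_merge_recipe.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
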