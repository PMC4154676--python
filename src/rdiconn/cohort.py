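"""Subject exclusion and motion-pattern-matched group-pair construction.

To study how between-group differences in the *spatial pattern* of head
motion bias connectivity comparisons, a cohort is repeatedly split into
random halves.  For each split the spatial Pearson correlation (rho_groups)
between the two halves' group-mean temporally-averaged voxel-wise
displacement maps is recorded; splits spanning a range of rho_groups values
can then be selected as group pairs with controlled motion-pattern
similarity.  A label-permutation test checks that the halves do not differ
in mean FD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GroupPair",
    "exclude_high_motion",
    "permute_group_pairs",
    "select_pairs_at",
    "fd_permutation_test",
]

DEFAULT_FD_EXCLUSION_MM = 0.7


@dataclass
class GroupPair:
    """Two disjoint subject groups with their motion-pattern similarity."""

    group1: list
    group2: list
    rho_groups: float
    fd_perm_p: float = np.nan

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValueError("groups must be nonempty")
        if set(self.group1) & set(self.group2):
            raise ValueError("groups must be disjoint")
        if not -1.0 <= self.rho_groups <= 1.0 + 1e-12:
            raise ValueError("rho_groups outside [-1, 1]")


def exclude_high_motion(
    mean_fd: pd.Series, threshold: float = DEFAULT_FD_EXCLUSION_MM
) -> tuple[list, pd.DataFrame]:
    """Drop subjects whose mean FD strictly exceeds *threshold* (mm).

    Returns the retained subject ids and an exclusion log (subject, mean_fd,
    excluded).
    """
    mean_fd = pd.Series(mean_fd)
    excluded = mean_fd > threshold
    log = pd.DataFrame(
        {"subject": mean_fd.index, "mean_fd": mean_fd.values,
         "excluded": excluded.values}
    )
    retained = list(mean_fd.index[~excluded])
    if not retained:
        raise ValueError("all subjects excluded")
    return retained, log


def _pearson_maps(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 1.0 if np.allclose(a, b) else np.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def permute_group_pairs(
    subject_maps: dict,
    n_perm: int,
    seed: int,
) -> list[GroupPair]:
    """Randomly halve the cohort *n_perm* times and record rho_groups.

    *subject_maps* maps subject id to that subject's temporally averaged
    voxel-wise displacement values over the brain mask (1-D array; all
    subjects must share the mask).  Each permutation splits the cohort into
    halves (odd cohorts put the extra subject in group 1) and computes the
    spatial Pearson correlation between the two group-mean maps.  Fully
    reproducible from *seed*.
    """
    ids = list(subject_maps.keys())
    if len(ids) < 4:
        raise ValueError("need at least 4 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    maps = np.asarray([np.ravel(subject_maps[i]) for i in ids])   # (S, V)
    rng = np.random.default_rng(seed)
    half = (len(ids) + 1) // 2
    pairs = []
    for _ in range(n_perm):
        order = rng.permutation(len(ids))
        g1, g2 = order[:half], order[half:]
        rho = _pearson_maps(maps[g1].mean(axis=0), maps[g2].mean(axis=0))
        pairs.append(GroupPair([ids[i] for i in g1], [ids[i] for i in g2], rho))
    return pairs


def select_pairs_at(pairs: list[GroupPair], targets: list[float]) -> list[GroupPair]:
    """Pick, for each target rho, the pair whose rho_groups is nearest.

    Ties go to the first pair encountered.  With a single available pair it
    is returned for every target with a warning.
    """
    if not pairs:
        raise ValueError("no pairs given")
    if len(pairs) == 1 and len(targets) > 1:
        warnings.warn("only one pair available; returned for every target")
    rhos = np.asarray([p.rho_groups for p in pairs])
    return [pairs[int(np.argmin(np.abs(rhos - t)))] for t in targets]


def fd_permutation_test(
    fd1: np.ndarray,
    fd2: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    exact: bool | None = None,
) -> float:
    """Two-sided permutation p-value for equal group mean FD.

    Monte-Carlo mode: p = (#{|delta_perm| >= |delta_obs|} + 1) / (n_perm + 1)
    under random relabelling of the pooled subjects into the original group
    sizes.  When the number of distinct relabellings C(n, n1) is small
    (<= 20000, or ``exact=True``) all of them are enumerated instead and the
    p-value is the exact tail fraction.
    """
    fd1 = np.asarray(fd1, float)
    fd2 = np.asarray(fd2, float)
    if fd1.size == 0 or fd2.size == 0:
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate([fd1, fd2])
    n1 = fd1.size
    n = pooled.size
    obs = abs(fd1.mean() - fd2.mean())
    total_sum = pooled.sum()
    n2 = n - n1

    from math import comb

    if exact is None:
        exact = comb(n, n1) <= 20000
    if exact:
        from itertools import combinations

        count = 0
        total = 0
        for idx in combinations(range(n), n1):
            s1 = pooled[list(idx)].sum()
            delta = abs(s1 / n1 - (total_sum - s1) / n2)
            if delta >= obs - 1e-12:
                count += 1
            total += 1
        return count / total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        delta = abs(perm[:n1].mean() - perm[n1:].mean())
        if delta >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
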