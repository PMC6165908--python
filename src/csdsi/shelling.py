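"""Post hoc nominal b-value shelling for shell-based preprocessing.

Shell-based correction tools (e.g. Gaussian-process eddy-current
modeling) require samples to lie on a small number of b-value shells.
Cartesian-grid DSI b-values can be nominally relabeled onto shells,
bounded by a maximum per-volume shift; the original b-values remain the
ones used for all subsequent model fitting — the assignment is an export
view only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ShellAssignment", "assign_shells"]


@dataclass
class ShellAssignment:
    shell_centers: np.ndarray
    original_b: np.ndarray
    assigned_b: np.ndarray

    @property
    def shift(self) -> np.ndarray:
        return self.assigned_b - self.original_b

    @property
    def max_abs_shift(self) -> float:
        return float(np.max(np.abs(self.shift))) if len(self.shift) else 0.0

    @property
    def n_shells(self) -> int:
        return len(self.shell_centers)


def assign_shells(bvals, max_shift: float = 50.0,
                  n_shells: int | None = None) -> ShellAssignment:
    """Cluster nonzero b-values onto shells by 1-D agglomerative merging.

    Starting from the distinct nonzero b-values, the closest adjacent
    pair of clusters is merged as long as no volume would shift by more
    than ``max_shift`` from its cluster's (count-weighted) mean.  If
    ``n_shells`` is given, merging continues until that many shells
    remain and fails loudly if the bound makes the target unreachable.
    b=0 volumes pass through unchanged.  Assigned values are cluster
    means rounded to the nearest integer.
    """
    bvals = np.asarray(bvals, dtype=float)
    if np.any(bvals < 0):
        raise ValueError("b-values must be >= 0")
    nz = np.unique(bvals[bvals > 0])
    counts = np.array([np.sum(bvals == b) for b in nz], dtype=float)
    # clusters as (members, counts) over sorted distinct values
    clusters: list[list[int]] = [[i] for i in range(len(nz))]

    def mean_of(c):
        w = counts[c]
        return float(np.sum(nz[c] * w) / np.sum(w))

    def spread_of(c):
        m = mean_of(c)
        return float(np.max(np.abs(nz[c] - m))) if c else 0.0

    def best_merge():
        best, best_gap = None, np.inf
        for i in range(len(clusters) - 1):
            merged = clusters[i] + clusters[i + 1]
            if spread_of(merged) <= max_shift:
                gap = mean_of(clusters[i + 1]) - mean_of(clusters[i])
                if gap < best_gap:
                    best, best_gap = i, gap
        return best

    target = n_shells if n_shells is not None else 0
    while len(clusters) > max(target, 1):
        i = best_merge()
        if i is None:
            break
        clusters[i] = clusters[i] + clusters.pop(i + 1)
    if n_shells is not None and len(clusters) > n_shells:
        gaps = [mean_of(clusters[i + 1]) - mean_of(clusters[i])
                for i in range(len(clusters) - 1)]
        j = int(np.argmin(gaps))
        raise ValueError(
            f"cannot reach {n_shells} shells under max_shift={max_shift}: "
            f"{len(clusters)} clusters remain; smallest blocking gap "
            f"{gaps[j]:.1f} s/mm^2 between shells at "
            f"{mean_of(clusters[j]):.0f} and {mean_of(clusters[j + 1]):.0f}")

    centers = np.array([round(mean_of(c)) for c in clusters], dtype=float)
    assigned = bvals.copy()
    for c, center in zip(clusters, centers):
        for i in c:
            assigned[np.isclose(bvals, nz[i])] = center
    nzmask = bvals > 0
    return ShellAssignment(shell_centers=centers,
                           original_b=bvals[nzmask],
                           assigned_b=assigned[nzmask])
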