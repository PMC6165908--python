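"""Quantitative comparison and test-retest reliability statistics.

Covers the full protocol-comparison suite: signal reconstruction error
(NMSE), per-b-value image MSE curves, angular cross-correlation of
spherical functions in the SH domain, peak-direction and crossing-angle
deviations with optimal peak matching, the minimum prevalent crossing
angle, the joint fiber-count rule, and one-way random-effects ICC with
the Bland-Altman within-subject CV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .propagator import PeakSet
from .sh import SphericalHarmonicFunction
from .sphere import angle_between_lines

__all__ = [
    "nmse",
    "mse_by_bvalue",
    "acc",
    "angular_peak_difference",
    "crossing_angle_deviation",
    "min_crossing_angle",
    "fiber_count",
    "icc",
    "wscv",
    "TRTReport",
    "trt_report",
]


def nmse(estimate, reference) -> float:
    """Normalized mean squared error ||est - ref||^2 / ||ref||^2."""
    est = np.asarray(estimate, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if est.shape != ref.shape:
        raise ValueError("estimate and reference lengths differ")
    denom = float(ref @ ref)
    if denom == 0:
        raise ValueError("reference is identically zero")
    diff = est - ref
    return float(diff @ diff) / denom


def mse_by_bvalue(set_a: np.ndarray, set_b: np.ndarray, bvals,
                  bins, mask: np.ndarray | None = None):
    """Mean squared voxel difference per b-value bin.

    ``set_a``/``set_b`` are (..., n_volumes) arrays in matching volume
    order; ``bins`` is a sequence of bin edges.  Returns (bin_centers,
    mse_per_bin); empty bins give NaN.
    """
    set_a, set_b = np.asarray(set_a, float), np.asarray(set_b, float)
    if set_a.shape != set_b.shape:
        raise ValueError("image sets have different shapes")
    bvals = np.asarray(bvals, dtype=float)
    if set_a.shape[-1] != len(bvals):
        raise ValueError("volume count does not match number of b-values")
    if mask is not None:
        set_a = set_a[mask]
        set_b = set_b[mask]
    set_a = set_a.reshape(-1, len(bvals))
    set_b = set_b.reshape(-1, len(bvals))
    edges = np.asarray(bins, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = np.full(len(centers), np.nan)
    for i in range(len(centers)):
        sel = (bvals >= edges[i]) & (bvals < edges[i + 1])
        if i == len(centers) - 1:
            sel = (bvals >= edges[i]) & (bvals <= edges[i + 1])
        if np.any(sel):
            out[i] = float(np.mean((set_a[:, sel] - set_b[:, sel]) ** 2))
    return centers, out


def acc(f: SphericalHarmonicFunction, g: SphericalHarmonicFunction) -> float | None:
    """Angular cross-correlation of two spherical functions.

    Normalized inner product of the SH coefficient vectors excluding the
    l=0 term (two isotropic functions would otherwise trivially
    correlate); by SH orthonormality this equals the functional
    correlation of the mean-removed functions on the sphere.  Returns
    None (flagged undefined) when either anisotropic part vanishes.
    """
    if f.order != g.order:
        raise ValueError("SH orders differ")
    u = f.anisotropic_part()
    v = g.anisotropic_part()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        warnings.warn("ACC undefined for an isotropic function", stacklevel=2)
        return None
    return float(u @ v / (nu * nv))


def _match_peaks(p1: PeakSet, p2: PeakSet):
    """Minimum-total-angle assignment between two peak sets (line metric)."""
    d1, d2 = p1.directions, p2.directions
    cost = np.array([[angle_between_lines(a, b) for b in d2] for a in d1])
    rows, cols = linear_sum_assignment(cost)
    return rows, cols, cost


def angular_peak_difference(p1: PeakSet, p2: PeakSet) -> float:
    """Mean angle (degrees) between optimally matched peak directions.

    Peaks are matched by minimum-total-angle assignment; on cardinality
    mismatch the smaller count is matched (flagged by a warning).
    """
    if len(p1) == 0 or len(p2) == 0:
        raise ValueError("peak sets must be non-empty")
    if len(p1) != len(p2):
        warnings.warn("peak-count mismatch; matching the smaller set",
                      stacklevel=2)
    rows, cols, cost = _match_peaks(p1, p2)
    return float(np.mean(cost[rows, cols]))


def crossing_angle_deviation(p1: PeakSet, p2: PeakSet) -> float:
    """|crossing angle of p1 - crossing angle of p2| in degrees.

    The crossing angle is taken between the two most dominant peaks of
    each set; both sets need >= 2 peaks.
    """
    a1, a2 = p1.crossing_angle(), p2.crossing_angle()
    if a1 is None or a2 is None:
        raise ValueError("both peak sets need at least two peaks")
    return abs(a1 - a2)


def min_crossing_angle(crossing_angles, prevalence: float = 0.01) -> float:
    """Smallest angle reached by at least ``prevalence`` of the voxels.

    Empirical lower quantile: the smallest a with
    fraction(angles <= a) >= prevalence.
    """
    angles = np.sort(np.asarray(crossing_angles, dtype=float))
    if len(angles) == 0:
        raise ValueError("no crossing angles given")
    if not (0.0 < prevalence <= 1.0):
        raise ValueError("prevalence must lie in (0, 1]")
    k = int(np.ceil(prevalence * len(angles)))
    return float(angles[k - 1])


def fiber_count(p1: PeakSet, p2: PeakSet, fraction_threshold: float = 0.1) -> int:
    """Fibers detected by BOTH sets with fraction above threshold, capped at 3."""
    if not (0.0 <= fraction_threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    n1 = sum(1 for p in p1 if p.relative_fraction > fraction_threshold)
    n2 = sum(1 for p in p2 if p.relative_fraction > fraction_threshold)
    return min(n1, n2, 3)


def icc(scan, rescan) -> float:
    """One-way random-effects ICC(1,1) for paired scan/rescan values.

    From the one-way ANOVA decomposition with k=2 measurements per
    subject: (MSB - MSW) / (MSB + MSW).
    """
    scan = np.asarray(scan, dtype=float)
    rescan = np.asarray(rescan, dtype=float)
    if scan.shape != rescan.shape or scan.ndim != 1:
        raise ValueError("scan and rescan must be equal-length 1-D arrays")
    n = len(scan)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    data = np.stack([scan, rescan], axis=1)  # (n, k=2)
    k = 2
    subj_means = data.mean(axis=1)
    grand = data.mean()
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((data - subj_means[:, None]) ** 2) / (n * (k - 1))
    return float((msb - msw) / (msb + (k - 1) * msw))


def wscv(scan, rescan) -> float:
    """Within-subject coefficient of variation, percent.

    Bland-Altman paired-difference form: per-subject within variance
    d^2/2, wsCV = sqrt(mean within variance) / grand mean * 100.
    """
    scan = np.asarray(scan, dtype=float)
    rescan = np.asarray(rescan, dtype=float)
    if scan.shape != rescan.shape or scan.ndim != 1:
        raise ValueError("scan and rescan must be equal-length 1-D arrays")
    grand = float(np.mean(np.stack([scan, rescan])))
    if grand == 0:
        raise ValueError("wsCV undefined: zero grand mean")
    within_var = np.mean((scan - rescan) ** 2 / 2.0)
    return float(np.sqrt(within_var) / grand * 100.0)


@dataclass
class TRTReport:
    """Test-retest reliability summary for one parameter."""

    icc: float
    wscv: float
    var_between: float
    var_within: float
    n_subjects: int


def trt_report(scan, rescan) -> TRTReport:
    """ICC, wsCV and the ANOVA variance components for paired data."""
    scan = np.asarray(scan, dtype=float)
    rescan = np.asarray(rescan, dtype=float)
    n, k = len(scan), 2
    data = np.stack([scan, rescan], axis=1)
    subj_means = data.mean(axis=1)
    grand = data.mean()
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((data - subj_means[:, None]) ** 2) / (n * (k - 1))
    return TRTReport(icc=icc(scan, rescan), wscv=wscv(scan, rescan),
                     var_between=float((msb - msw) / k),
                     var_within=float(msw), n_subjects=n)
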