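"""Measurement formulas for manually extracted imaging data.

Pure functions over intensity profiles and ROI statistics: the Golgi
position index, apical/basal membrane-signal ratios, kymograph-angle
velocity conversion (plus a line-angle estimator for raster kymographs),
EdU-positive rates, nuclear/cytoplasmic ratios, and the two-channel axial
profile normalization (baseline extraction with a running-minimum filter,
channel ratio, equal-width binning, max-rescaling).

Positions may be in pixels or microns; each function states the units it
assumes.  All inputs are already-extracted measurements — no image
segmentation or microscopy I/O happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter1d


class MeasurementError(ValueError):
    """A measurement violates its admissibility constraints."""


@dataclass(frozen=True)
class IntensityProfile:
    """1D fluorescence samples along a line: strictly increasing positions."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise MeasurementError("positions and values must be equal-length 1D arrays")
        if len(self.positions) >= 2 and not np.all(np.diff(self.positions) > 0):
            raise MeasurementError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    def reflected(self) -> "IntensityProfile":
        """The same profile traversed from the opposite end."""
        p = self.positions
        return IntensityProfile(p[0] + p[-1] - p[::-1], self.values[::-1])


@dataclass(frozen=True)
class PairedProfile:
    """Signal channel (e.g. HCR) and reference channel on a shared grid."""

    signal: IntensityProfile
    reference: IntensityProfile

    def __post_init__(self) -> None:
        if not np.array_equal(self.signal.positions, self.reference.positions):
            raise MeasurementError("signal and reference must share the position grid")


@dataclass(frozen=True)
class GolgiMeasure:
    """Apical-surface length L and the Golgi span [a, b] from the anterior end."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise MeasurementError(f"cell length must be positive, got {self.L}")
        if not 0 <= self.a <= self.b <= self.L:
            raise MeasurementError(
                f"need 0 <= a <= b <= L, got a={self.a}, b={self.b}, L={self.L}"
            )


# ----------------------------------------------------------------------


def golgi_position_index(m: GolgiMeasure) -> float:
    """Relative Golgi position along the anterior-posterior axis: (a + b)/2L.

    0 = Golgi collapsed at the anterior end, 1 = at the posterior end,
    0.5 = centered; larger means more posterior.
    """
    return (m.a + m.b) / (2.0 * m.L)


def apical_basal_signal_ratio(profile: IntensityProfile, fraction: float = 0.30) -> float:
    """Apical/basal signal ratio over the end fractions of a membrane profile.

    Sums the values in the first ``fraction`` of the profile's arc length
    (apical end) and in the last ``fraction`` (basal end) and returns their
    ratio.  Samples are assigned by arc-length position, endpoints included.
    """
    if not 0 < fraction <= 0.5:
        raise MeasurementError(f"fraction must be in (0, 0.5], got {fraction}")
    if len(profile) < 4:
        raise MeasurementError("need at least 4 samples")
    p, v = profile.positions, profile.values
    span = p[-1] - p[0]
    apical = v[p <= p[0] + fraction * span].sum()
    basal = v[p >= p[-1] - fraction * span].sum()
    if basal == 0:
        raise MeasurementError("basal sum is zero; ratio undefined")
    return float(apical / basal)


def kymograph_velocity(angle_deg: float, space_per_px: float, time_per_row: float) -> float:
    """Convert a kymograph line angle to a velocity.

    The angle is measured from the time (vertical) axis, so 0 deg is a
    stationary line; the velocity is ``tan(angle) * space_per_px /
    time_per_row``.
    """
    if not abs(angle_deg) < 90:
        raise MeasurementError("angle must satisfy |angle| < 90 degrees")
    if space_per_px <= 0 or time_per_row <= 0:
        raise MeasurementError("scales must be positive")
    return math.tan(math.radians(angle_deg)) * space_per_px / time_per_row


def estimate_kymograph_angle(image: np.ndarray, background_quantile: float = 0.5) -> float:
    """Angle (degrees from the time axis) of the dominant line in a raster.

    Rows are time, columns are position.  Each row's intensity-weighted
    centroid (after subtracting the row's ``background_quantile`` level) is
    regressed on the row index; the slope in px/row gives the angle.  Meant
    for single-front rasters such as :func:`midlinesim.synthetic.make_kymograph`
    output or mean-boundary kymographs.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2:
        raise MeasurementError("need a 2D image with at least 2 rows")
    work = img - np.quantile(img, background_quantile, axis=1, keepdims=True)
    work = np.clip(work, 0, None)
    # suppress residual background noise so the centroid tracks the line
    row_max = work.max(axis=1, keepdims=True)
    work = np.where(work >= 0.3 * row_max, work, 0.0)
    weights = work.sum(axis=1)
    ok = weights > 0
    if ok.sum() < 2:
        raise MeasurementError("image has no signal above background")
    cols = np.arange(img.shape[1])
    centroids = (work[ok] * cols).sum(axis=1) / weights[ok]
    rows = np.flatnonzero(ok)
    slope = np.polyfit(rows, centroids, 1)[0]  # px per row
    return math.degrees(math.atan(slope))


def positive_fraction(n_pos: int, n_total: int) -> float:
    """Fraction of positively scored cells (e.g. the EdU-positive rate)."""
    if n_total <= 0:
        raise MeasurementError("total count must be positive")
    if not 0 <= n_pos <= n_total:
        raise MeasurementError(f"need 0 <= n_pos <= n_total, got {n_pos}/{n_total}")
    return n_pos / n_total


def nuclear_cytoplasmic_ratio(nuc_mean: float, cyt_mean: float) -> float:
    """Nuclear-to-cytoplasmic mean-intensity ratio of one cell."""
    if cyt_mean <= 0:
        raise MeasurementError(f"cytoplasmic mean must be positive, got {cyt_mean}")
    if nuc_mean < 0:
        raise MeasurementError(f"nuclear mean must be >= 0, got {nuc_mean}")
    return nuc_mean / cyt_mean


def normalize_paired_profile(
    pp: PairedProfile, filter_window: int = 11, n_bins: int = 20
) -> np.ndarray:
    """Baseline-normalized, binned, max-rescaled axial profile.

    Steps: (1) running minimum of the reference channel over
    ``filter_window`` samples removes narrow membrane-localized peaks and
    extracts the baseline; (2) the signal is divided by the baseline
    pointwise; (3) positions are partitioned into ``n_bins`` equal-width
    bins ([left, right) with the last bin closed); (4) the normalized signal
    is averaged per bin; (5) all bins are divided by the maximum bin, so
    exactly one bin equals 1.  Returns the ``n_bins`` values.
    """
    if filter_window < 1 or filter_window % 2 == 0:
        raise MeasurementError(f"filter_window must be odd and >= 1, got {filter_window}")
    if n_bins < 2:
        raise MeasurementError(f"n_bins must be >= 2, got {n_bins}")
    baseline = minimum_filter1d(pp.reference.values, size=filter_window, mode="nearest")
    if np.any(baseline <= 0):
        raise MeasurementError("reference baseline is non-positive after filtering")
    normalized = pp.signal.values / baseline
    pos = pp.signal.positions
    edges = np.linspace(pos[0], pos[-1], n_bins + 1)
    idx = np.minimum(np.searchsorted(edges, pos, side="right") - 1, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        raise MeasurementError("empty bin: position grid does not cover every bin")
    means = np.bincount(idx, weights=normalized, minlength=n_bins) / counts
    return means / means.max()


def running_minimum(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running minimum (the baseline-extraction primitive)."""
    if window < 1 or window % 2 == 0:
        raise MeasurementError(f"window must be odd and >= 1, got {window}")
    return minimum_filter1d(np.asarray(values, dtype=float), size=window, mode="nearest")
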