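"""Synthetic inputs with known ground truth.

Every generator is deterministic under a fixed seed and returns its ground
truth alongside the data, so downstream estimators (kymograph velocity,
profile normalization, ROI statistics) can be closed-loop tested without any
external data.  Noise models are deliberately simple: Gaussian for
intensities, binomial for counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import EcmFrame, TissueMesh
from .quantify import IntensityProfile, PairedProfile


def make_initial_mesh(
    m: int,
    cell_width: float = 1.0,
    cell_height: float = 1.0,
    h: float = 0.05,
    frame: EcmFrame | None = None,
    tissue: str = "tissue",
    x0: float = 0.0,
) -> TissueMesh:
    """Fresh chain of ``m`` identical axis-aligned quads with shared vertices.

    The basal edge sits at the adhesion minimum, distance ``h`` from the
    frame's basal line; the two anterior-most vertices are x-anchored.
    Vertex count is ``2 (m + 1)``.  For a mirrored frame (``apical_sign =
    -1``) the chain extends on the apical side below the basal line and the
    cyclic storage order is flipped in x so signed areas stay positive.
    """
    if m < 1:
        raise ValueError(f"need at least one cell, got m={m}")
    if cell_width <= 0 or cell_height <= 0:
        raise ValueError("cell dimensions must be positive")
    frame = frame or EcmFrame()
    sgn = frame.apical_sign
    y_b = frame.basal_y + sgn * h
    y_a = y_b + sgn * cell_height
    xs = x0 + cell_width * np.arange(m + 1)
    verts = np.empty((2 * (m + 1), 2))
    verts[0::2] = np.column_stack([xs, np.full(m + 1, y_b)])  # basal row
    verts[1::2] = np.column_stack([xs, np.full(m + 1, y_a)])  # apical row
    b = 2 * np.arange(m + 1)  # basal vertex ids
    a = b + 1
    if sgn > 0:
        cells = np.column_stack([b[:-1], b[1:], a[1:], a[:-1]])
    else:  # mirrored: posterior-first within each pair keeps orientation positive
        cells = np.column_stack([b[1:], b[:-1], a[:-1], a[1:]])
    fixed = np.zeros(len(verts), dtype=bool)
    fixed[[0, 1]] = True  # the two anterior-most vertices
    return TissueMesh(verts, cells, fixed, [tissue] * m, {tissue: frame})


# ----------------------------------------------------------------------


@dataclass(frozen=True)
class KymographTruth:
    velocity: float
    space_per_px: float
    time_per_row: float
    x0_px: float


def make_kymograph(
    velocity: float,
    duration: float = 60.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    space_per_px: float = 0.5,
    time_per_row: float = 1.0,
    width_px: int = 256,
    line_sigma_px: float = 1.5,
) -> tuple[np.ndarray, KymographTruth]:
    """Position-time raster of one moving front plus Gaussian noise.

    The front starts near the left edge and advances at ``velocity``
    (position units per time unit); each row is a Gaussian bump of width
    ``line_sigma_px`` centered on the true position, plus iid noise.
    Returns ``(image, ground_truth)``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_rows = max(2, int(round(duration / time_per_row)))
    # widen the raster if the front would leave the frame
    travel_px = abs(velocity) * (n_rows - 1) * time_per_row / space_per_px
    width_px = max(width_px, int(np.ceil(travel_px / 0.7)) + 64)
    x0 = 0.15 * width_px if velocity >= 0 else 0.85 * width_px
    cols = np.arange(width_px)
    image = np.empty((n_rows, width_px))
    for r in range(n_rows):
        center = x0 + velocity * (r * time_per_row) / space_per_px
        image[r] = np.exp(-0.5 * ((cols - center) / line_sigma_px) ** 2)
    image += noise_sd * rng.standard_normal(image.shape)
    return image, KymographTruth(velocity, space_per_px, time_per_row, x0)


# ----------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileTruth:
    gradient_exponent: float
    baseline_decay: float
    bin_truth: np.ndarray  # analytic per-bin normalized gradient (max = 1)


def make_paired_profile(
    gradient_exponent: float = 1.0,
    baseline_decay: float = 0.5,
    peak_density: float = 0.4,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 1000,
    length: float = 500.0,
    n_bins: int = 20,
    peak_height: float = 3.0,
    peak_width: float = 0.5,
) -> tuple[PairedProfile, ProfileTruth]:
    """Two-channel axial profile emulating HCR signal + membrane reporter.

    The signal channel is a power-law anterior-posterior gradient
    ``(x/length)^gradient_exponent`` multiplied by a depth-decay baseline
    shared with the reference channel; the reference adds narrow
    membrane-like peaks (their footprint stays below the default
    running-minimum window, mirroring sub-cellular membrane crossings) and
    both channels get Gaussian noise.  The returned ground truth contains
    the analytic per-bin means of the gradient rescaled to max 1.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, length, n_samples)
    u = x / length
    baseline = 1.0 + np.exp(-baseline_decay * u) - np.exp(-baseline_decay)
    gradient = u**gradient_exponent
    signal = gradient * baseline
    reference = baseline.copy()
    n_peaks = rng.poisson(peak_density * length / 10.0)
    centers = rng.uniform(0, length, n_peaks)
    for c in centers:
        reference += peak_height * np.exp(-0.5 * ((x - c) / peak_width) ** 2)
    if noise_sd > 0:
        signal = signal + noise_sd * rng.standard_normal(n_samples)
        reference = reference + noise_sd * rng.standard_normal(n_samples)
    # analytic bin means of u^p over equal-width bins, rescaled to max 1
    edges = np.linspace(0, 1, n_bins + 1)
    p = gradient_exponent
    means = (edges[1:] ** (p + 1) - edges[:-1] ** (p + 1)) / ((p + 1) * np.diff(edges))
    truth = ProfileTruth(p, baseline_decay, means / means.max())
    pp = PairedProfile(IntensityProfile(x, signal), IntensityProfile(x, reference))
    return pp, truth


# ----------------------------------------------------------------------


@dataclass(frozen=True)
class RoiTruth:
    nc_ratio: float
    edu_rate: float


def make_roi_table(
    n_cells: int,
    true_nc_ratio: float = 1.5,
    true_edu_rate: float = 0.3,
    noise_sd: float = 0.0,
    seed: int = 0,
    cyt_mean: float = 100.0,
) -> tuple[pd.DataFrame, RoiTruth]:
    """Tidy per-cell ROI table: nuclear/cytoplasmic means and EdU calls.

    Cytoplasmic means are drawn around ``cyt_mean`` and nuclear means around
    ``true_nc_ratio * cyt_mean``, both with Gaussian noise ``noise_sd``
    (absolute intensity units); EdU positivity is Bernoulli with rate
    ``true_edu_rate``.
    """
    if not 0 <= true_edu_rate <= 1:
        raise ValueError("true_edu_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cyt = cyt_mean + noise_sd * rng.standard_normal(n_cells)
    nuc = true_nc_ratio * cyt_mean + noise_sd * rng.standard_normal(n_cells)
    edu = rng.random(n_cells) < true_edu_rate
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "nuc_mean": nuc,
            "cyt_mean": cyt,
            "edu_positive": edu.astype(int),
        }
    )
    return df, RoiTruth(true_nc_ratio, true_edu_rate)
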