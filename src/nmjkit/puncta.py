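"""Synaptic-puncta segmentation and volumetry.

The pipeline reproduces automatic 3D quantification of punctate synaptic
markers (Bruchpilot active zones, pCaMKII, Synapsin) in confocal stacks:

1. per-slice median filtering to suppress the Poisson noise of confocal
   acquisition;
2. local maximum-entropy (Kapur) thresholding: for every pixel brighter
   than a low-intensity cutoff, the threshold maximizing the sum of
   foreground and background Shannon entropies is computed on the 2D
   histogram of a square window centred on that pixel, and the pixel is
   foreground iff it is strictly brighter than that local threshold.
   Pixels at or below the cutoff (default 20 on an 8-bit scale) are
   assigned to background outright;
3. 3D connected-component labeling across slices and per-component
   volume measurement;
4. normalization of counts and volumes to axonal length or muscle
   surface area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .stack import ImageStack

__all__ = [
    "DegenerateHistogramError",
    "PunctaQuantification",
    "median_denoise",
    "max_entropy_threshold",
    "segment_local_max_entropy",
    "label_and_measure",
    "quantify",
]


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two occupied gray levels: no threshold separates it."""


def median_denoise(stack: ImageStack, kernel: int = 3) -> ImageStack:
    """Median-filter every slice of the stack with a 2D square window.

    Denoising is strictly per slice (2D); shape, spacing and bit depth
    are unchanged.  ``kernel`` is the window edge in pixels and must be
    odd; ``kernel=1`` is the identity.  Borders are handled by edge
    reflection.
    """
    kernel = int(kernel)
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return stack
    out = ndimage.median_filter(stack.voxels, size=(1, kernel, kernel))
    return stack.with_voxels(out)


def max_entropy_threshold(hist: np.ndarray) -> int:
    """Maximum-entropy (Kapur) threshold of an intensity histogram.

    Given histogram counts ``h_i`` for gray levels ``i = 0..L-1`` with
    probabilities ``p_i = h_i / N``, returns the threshold ``t*``
    maximizing ``H_b(t) + H_f(t)`` where

    ``H_b(t) = -sum_{i<=t, p_i>0} (p_i/P_t) ln(p_i/P_t)``,
    ``H_f(t) = -sum_{i>t, p_i>0} (p_i/(1-P_t)) ln(p_i/(1-P_t))``,

    with ``P_t = sum_{i<=t} p_i``.  Candidates are restricted to
    thresholds with ``0 < P_t < 1`` (both classes non-empty); ties are
    broken to the smallest ``t``.  Thresholds whose score is within a
    relative ``1e-10`` of the maximum count as tied, which makes the
    argmax invariant to the floating-point evaluation order of the
    entropy sums.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two gray levels are occupied.
    """
    counts = np.asarray(hist, dtype=np.int64)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("histogram must be a 1D array of at least two bins")
    if np.any(counts < 0):
        raise ValueError("histogram counts must be non-negative")
    n = int(counts.sum())
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("fewer than two occupied gray levels")

    p = counts / n
    # p ln p with the 0 ln 0 = 0 convention
    plogp = np.zeros_like(p)
    nz = counts > 0
    plogp[nz] = p[nz] * np.log(p[nz])

    cum_counts = np.cumsum(counts)           # integers: exact class occupancy
    head_p = np.cumsum(p)                    # P_t
    tail_p = np.cumsum(p[::-1])[::-1]        # sum_{i>=t} p_i
    tail_p = np.append(tail_p[1:], 0.0)      # sum_{i>t}  p_i = 1 - P_t
    head_s = np.cumsum(plogp)
    tail_s = np.cumsum(plogp[::-1])[::-1]
    tail_s = np.append(tail_s[1:], 0.0)

    valid = (cum_counts > 0) & (cum_counts < n)
    total = np.full(p.shape, -np.inf)
    # H_b = ln P_t - S_t / P_t  (algebraic form of the sum above);
    # same for the tail class.
    hv = head_p[valid]
    tv = tail_p[valid]
    total[valid] = (np.log(hv) - head_s[valid] / hv) + (np.log(tv) - tail_s[valid] / tv)
    best = np.max(total)
    tied = total >= best - 1e-10 * max(1.0, abs(best))
    return int(np.argmax(tied))


def segment_local_max_entropy(
    stack: ImageStack,
    window: int = 15,
    low_cut: int = 20,
) -> np.ndarray:
    """Segment puncta by per-pixel local maximum-entropy thresholding.

    For every voxel with intensity ``<= low_cut`` the voxel is assigned
    to background with no threshold computed (very low intensities are
    background by definition, which also makes the method tractable).
    For every brighter voxel, the maximum-entropy threshold of the 2D
    ``window x window`` neighbourhood *within its slice* (clipped at the
    image borders) is computed, and the voxel is foreground iff strictly
    brighter than that local threshold.  A neighbourhood with a single
    occupied gray level cannot be split and yields background.

    Returns a boolean mask of the stack's shape.
    """
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    nz, ny, nx = stack.shape
    if window > ny or window > nx:
        raise ValueError(f"window {window} exceeds slice extent {(ny, nx)}")
    half = window // 2
    n_levels = stack.n_levels
    mask = np.zeros(stack.shape, dtype=bool)
    for z in range(nz):
        sl = stack.voxels[z]
        ys, xs = np.nonzero(sl > low_cut)
        vals = sl[ys, xs]
        for y, x, v in zip(ys.tolist(), xs.tolist(), vals.tolist()):
            win = sl[max(0, y - half): y + half + 1, max(0, x - half): x + half + 1]
            hist = np.bincount(win.ravel(), minlength=n_levels)
            try:
                t = max_entropy_threshold(hist)
            except DegenerateHistogramError:
                continue  # uniform neighbourhood: background
            if v > t:
                mask[z, y, x] = True
    return mask


def label_and_measure(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    connectivity: int = 26,
) -> pd.DataFrame:
    """Label a 3D mask and measure per-component volume and centroid.

    Components are found at 6- or 26-connectivity; ids follow scan order
    (z, then y, then x) and are therefore deterministic.  Volume is
    ``voxel_count * dz*dy*dx`` and centroids are in micrometres.

    Returns a DataFrame with columns
    ``id, voxel_count, volume_um3, zc, yc, xc``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D (z, y, x)")
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    dz, dy, dx = (float(s) for s in spacing)
    voxel_volume = dz * dy * dx

    labels, n = ndimage.label(mask, structure=structure)
    cols = ["id", "voxel_count", "volume_um3", "zc", "yc", "xc"]
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols}).astype(
            {"id": int, "voxel_count": int}
        )
    ids = np.arange(1, n + 1)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    centroids = np.asarray(ndimage.center_of_mass(mask, labels, ids), dtype=float)
    centroids *= np.array([dz, dy, dx])
    return pd.DataFrame(
        {
            "id": ids,
            "voxel_count": counts,
            "volume_um3": counts * voxel_volume,
            "zc": centroids[:, 0],
            "yc": centroids[:, 1],
            "xc": centroids[:, 2],
        }
    )


@dataclass(frozen=True)
class PunctaQuantification:
    """Puncta count and total volume with normalized densities.

    ``count_density`` and ``volume_density`` are the raw values divided
    by the normalizer: puncta per um of axonal terminal length, or per
    um^2 of muscle surface area.
    """

    puncta_count: int
    total_volume_um3: float
    normalizer_kind: str
    normalizer_value: float
    count_density: float
    volume_density: float


_NORMALIZER_KINDS = ("axonal_length", "muscle_surface_area")


def quantify(
    table: pd.DataFrame,
    normalizer_value: float,
    normalizer_kind: str = "axonal_length",
) -> PunctaQuantification:
    """Summarize a component table into normalized puncta statistics."""
    if normalizer_kind not in _NORMALIZER_KINDS:
        raise ValueError(f"normalizer_kind must be one of {_NORMALIZER_KINDS}")
    normalizer_value = float(normalizer_value)
    if normalizer_value <= 0:
        raise ValueError("normalizer must be positive")
    count = int(len(table))
    total = float(table["volume_um3"].sum()) if count else 0.0
    return PunctaQuantification(
        puncta_count=count,
        total_volume_um3=total,
        normalizer_kind=normalizer_kind,
        normalizer_value=normalizer_value,
        count_density=count / normalizer_value,
        volume_density=total / normalizer_value,
    )
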