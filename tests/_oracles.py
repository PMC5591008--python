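"""Independent brute-force oracles for entropy thresholding.

These deliberately follow the literal definition — exhaustive search
over thresholds with the entropy sums computed directly from the class
probabilities — rather than the cumulative-sum algebra of the library
implementation, so the two routes are independent.
"""

import numpy as np


def brute_force_max_entropy(hist):
    """Exhaustive argmax of H_b(t) + H_f(t); None if histogram degenerate.

    For each candidate threshold the foreground/background class
    probabilities are renormalized explicitly and their Shannon
    entropies summed; ties go to the smallest threshold via strict
    improvement.
    """
    counts = np.asarray(hist, dtype=np.int64)
    n = counts.sum()
    if np.count_nonzero(counts) < 2:
        return None
    p = counts / n
    cum = np.cumsum(counts)
    occupied = np.nonzero(counts)[0]
    scores = {}
    for t in range(occupied[0], occupied[-1]):
        if not (0 < cum[t] < n):
            continue
        low = p[: t + 1]
        high = p[t + 1:]
        low = low[low > 0] / low.sum()
        high = high[high > 0] / high.sum()
        scores[t] = -(low * np.log(low)).sum() - (high * np.log(high)).sum()
    best = max(scores.values())
    # scores within a relative 1e-10 of the maximum are tied: smallest t
    tol = 1e-10 * max(1.0, abs(best))
    return min(t for t, h in scores.items() if h >= best - tol)


def naive_local_segmentation(voxels, window=15, low_cut=20, n_levels=256):
    """Literal per-pixel definition of the local max-entropy mask.

    For every voxel above the low cutoff: build the 2D window within the
    slice (clipped at borders), histogram it, exhaustively find the
    maximum-entropy threshold and mark the voxel iff strictly brighter.
    """
    voxels = np.asarray(voxels)
    half = window // 2
    nz, ny, nx = voxels.shape
    mask = np.zeros(voxels.shape, dtype=bool)
    for z in range(nz):
        sl = voxels[z]
        for y in range(ny):
            for x in range(nx):
                v = sl[y, x]
                if v <= low_cut:
                    continue
                win = sl[
                    max(0, y - half): y + half + 1,
                    max(0, x - half): x + half + 1,
                ]
                t = brute_force_max_entropy(
                    np.bincount(win.ravel(), minlength=n_levels)
                )
                if t is not None and v > t:
                    mask[z, y, x] = True
    return mask
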