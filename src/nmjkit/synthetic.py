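"""Synthetic phantom data with known ground truth.

Every downstream stage of the toolkit is validated against phantoms
generated here rather than against manual annotation:

* punctate-marker stacks: spherical-ish fluorescent spots (isotropic
  Gaussian profiles truncated at 3 sigma) over a flat background, with
  optional Poisson noise emulating confocal acquisition;
* NMJ phantoms: a tubular axon terminal with bouton swellings and side
  branches (HRP channel), bouton shells (Dlg channel) and active-zone
  puncta on bouton surfaces (Brp channel), over a rasterized muscle
  polygon;
* crawling-larva movies: one bright blob per frame following a
  prescribed speed profile with a heading random walk, 400 frames over
  40 s by default;
* long-format measurement tables with prescribed per-group
  distributions for exercising the statistical decision tree.

All generators are pure functions of (spec, seed): identical inputs
yield bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .stack import ImageStack

__all__ = [
    "PlacementError",
    "PunctaPhantomSpec",
    "PunctaGroundTruth",
    "gen_puncta_stack",
    "match_puncta",
    "NMJPhantomSpec",
    "NMJGroundTruth",
    "gen_nmj_stack",
    "random_nmj_spec",
    "LarvaPathSpec",
    "gen_larva_movie",
    "GroupDef",
    "GroupSpec",
    "gen_group_table",
]


class PlacementError(RuntimeError):
    """Objects could not be placed without overlap within the retry budget."""


# --------------------------------------------------------------------------
# puncta phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PunctaPhantomSpec:
    """Specification of a punctate-marker phantom stack.

    Defaults emulate a Bruchpilot acquisition: 0.25 um z-step,
    0.1 um in-plane pixels, 8-bit gray levels, bright puncta of
    0.3-0.6 um radius over a dim background.
    """

    shape: tuple[int, int, int] = (20, 256, 256)
    spacing: tuple[float, float, float] = (0.25, 0.1, 0.1)
    n_puncta: int = 50
    radius_range: tuple[float, float] = (0.3, 0.6)
    peak_intensity: float = 150.0
    background: float = 10.0
    noise: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.n_puncta > 0 and self.peak_intensity <= self.background:
            raise ValueError("peak_intensity must exceed background")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be positive")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError("radius_range must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class PunctaGroundTruth:
    """True puncta locations and sizes of a phantom stack."""

    centers: np.ndarray       # (n, 3) float voxel coordinates (z, y, x)
    radii: np.ndarray         # (n,) um
    true_count: int
    true_total_volume: float  # um^3, sum of 4/3 pi r^3


def gen_puncta_stack(spec: PunctaPhantomSpec) -> tuple[ImageStack, PunctaGroundTruth]:
    """Render a phantom stack of non-overlapping fluorescent puncta.

    Each punctum is an isotropic Gaussian spot with ``sigma = radius/2``
    truncated at 3 sigma, amplitude ``peak_intensity - background`` so
    the noiseless intensity at the centre equals ``peak_intensity``.
    Centers are rejection-sampled to keep pairwise (physical) distances
    above the sum of radii plus a 0.3 um margin and to keep every spot's
    3-sigma support inside the stack.  With ``noise='poisson'`` every
    voxel is drawn from a Poisson law with mean equal to its noiseless
    value.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    sp = np.array([dz, dy, dx])

    radii = rng.uniform(*spec.radius_range, size=spec.n_puncta)
    centers = np.zeros((spec.n_puncta, 3))
    placed: list[np.ndarray] = []
    max_tries = 200 * max(spec.n_puncta, 1)
    tries = 0
    for i in range(spec.n_puncta):
        margin_vox = 3 * (radii[i] / 2) / sp + 1.0  # keep 3-sigma support inside
        lo = margin_vox
        hi = np.array([nz, ny, nx]) - 1 - margin_vox
        if np.any(hi <= lo):
            raise PlacementError("puncta too large for the stack shape")
        while True:
            tries += 1
            if tries > max_tries:
                raise PlacementError(
                    f"could not place punctum {i + 1}/{spec.n_puncta} "
                    f"after {max_tries} attempts"
                )
            cand = rng.uniform(lo, hi)
            cand_um = cand * sp
            ok = True
            for j, prev in enumerate(placed):
                if np.linalg.norm(cand_um - prev) < radii[i] + radii[j] + 0.3:
                    ok = False
                    break
            if ok:
                break
        centers[i] = cand
        placed.append(cand * sp)

    field_ = np.full(spec.shape, float(spec.background))
    amp = spec.peak_intensity - spec.background
    for (cz, cy, cx), r in zip(centers, radii):
        sigma = r / 2.0
        ext = 3 * sigma / sp  # 3-sigma support in voxels per axis
        z0, z1 = int(math.floor(cz - ext[0])), int(math.ceil(cz + ext[0]))
        y0, y1 = int(math.floor(cy - ext[1])), int(math.ceil(cy + ext[1]))
        x0, x1 = int(math.floor(cx - ext[2])), int(math.ceil(cx + ext[2]))
        zz, yy, xx = np.meshgrid(
            np.arange(z0, z1 + 1), np.arange(y0, y1 + 1), np.arange(x0, x1 + 1),
            indexing="ij",
        )
        d2 = (
            ((zz - cz) * dz) ** 2 + ((yy - cy) * dy) ** 2 + ((xx - cx) * dx) ** 2
        )
        spot = amp * np.exp(-d2 / (2 * sigma**2))
        spot[d2 > (3 * sigma) ** 2] = 0.0
        field_[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1] += spot

    if spec.noise == "poisson":
        voxels = rng.poisson(field_)
    else:
        voxels = np.rint(field_)
    voxels = np.clip(voxels, 0, 255).astype(np.uint8)
    truth = PunctaGroundTruth(
        centers=centers,
        radii=radii,
        true_count=spec.n_puncta,
        true_total_volume=float(np.sum(4.0 / 3.0 * np.pi * radii**3)),
    )
    return ImageStack(voxels, spec.spacing, channel="puncta-phantom"), truth


def match_puncta(
    truth: PunctaGroundTruth,
    detections_um: np.ndarray,
    spacing: tuple[float, float, float],
    slack_um: float = 0.5,
) -> dict:
    """Greedy one-to-one matching of detected centroids to true puncta.

    A detection matches a true punctum if their physical distance is at
    most the punctum radius plus ``slack_um``; pairs are matched in
    order of increasing distance.  Returns tp/fp/fn counts plus
    precision, recall and F1.
    """
    det = np.atleast_2d(np.asarray(detections_um, dtype=float))
    if det.size == 0:
        det = det.reshape(0, 3)
    truth_um = truth.centers * np.asarray(spacing)
    pairs = []
    for i, (c, r) in enumerate(zip(truth_um, truth.radii)):
        d = np.linalg.norm(det - c, axis=1)
        for j in np.nonzero(d <= r + slack_um)[0]:
            pairs.append((d[j], i, int(j)))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    for _, i, j in pairs:
        if i not in used_t and j not in used_d:
            used_t.add(i)
            used_d.add(j)
    tp = len(used_t)
    fp = len(det) - tp
    fn = truth.true_count - tp
    precision = tp / max(tp + fp, 1)
    recall = tp / max(tp + fn, 1)
    f1 = 2 * precision * recall / max(precision + recall, 1e-12)
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "precision": precision, "recall": recall, "f1": f1,
    }


# --------------------------------------------------------------------------
# NMJ phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NMJPhantomSpec:
    """Geometry of a phantom axon terminal over a muscle.

    The terminal is a main polyline plus side branches (each branch's
    first vertex lies on the main path; the number of branches is the
    number of branch points).  Boutons are swellings centred on the main
    path at the given arc-length offsets, with radius at least 1.5x the
    tube radius so truth tables are unambiguous.  Coordinates are 2D in
    micrometres; the terminal is rendered into a thin 3D stack centred
    on the middle slice.
    """

    axon_path: np.ndarray                    # (n, 2) polyline, um
    branches: tuple[np.ndarray, ...] = ()    # side branches, each (m, 2) um
    bouton_arclengths: tuple[float, ...] = ()
    bouton_radius: float = 1.0               # um
    tube_radius: float = 0.4                 # um
    muscle_polygon: np.ndarray | None = None  # (k, 2) vertices, um
    pixel_size: float = 0.1                  # um, in-plane
    z_step: float = 0.5                      # um
    n_slices: int = 9
    channels: tuple[str, ...] = ("HRP", "Dlg", "Brp")
    brp_per_bouton: int = 3
    noise: str = "poisson"

    def __post_init__(self) -> None:
        path = np.asarray(self.axon_path, dtype=float)
        if path.ndim != 2 or path.shape[0] < 2 or path.shape[1] != 2:
            raise ValueError("axon_path must be an (n>=2, 2) polyline")
        object.__setattr__(self, "axon_path", path)
        object.__setattr__(
            self, "branches", tuple(np.asarray(b, dtype=float) for b in self.branches)
        )
        for b in self.branches:
            if b.ndim != 2 or b.shape[0] < 2:
                raise ValueError("each branch must be an (m>=2, 2) polyline")
        if self.tube_radius >= self.bouton_radius:
            raise ValueError("tube_radius must be smaller than bouton_radius")
        if self.muscle_polygon is not None:
            object.__setattr__(
                self, "muscle_polygon", np.asarray(self.muscle_polygon, dtype=float)
            )

    @property
    def branch_points(self) -> int:
        return len(self.branches)


@dataclass(frozen=True)
class NMJGroundTruth:
    axonal_length_um: float
    bouton_count: int
    branch_points: int
    muscle_area_um2: float
    bouton_centers_um: np.ndarray  # (n, 2)
    brp_count: int


def _polyline_length(path: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


def _point_at_arclength(path: np.ndarray, s: float) -> np.ndarray:
    """Point at arc length ``s`` along a polyline (clamped to its ends)."""
    seg = np.diff(path, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    s = float(np.clip(s, 0.0, cum[-1]))
    k = int(np.searchsorted(cum, s, side="right") - 1)
    k = min(k, len(lens) - 1)
    frac = (s - cum[k]) / lens[k] if lens[k] > 0 else 0.0
    return path[k] + frac * seg[k]


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _rasterize_centerline(paths, origin, pixel_size, shape):
    """Boolean 2D raster of polylines, sampled densely along each segment."""
    canvas = np.zeros(shape, dtype=bool)
    for path in paths:
        for a, b in zip(path[:-1], path[1:]):
            n = max(2, int(np.linalg.norm(b - a) / (0.25 * pixel_size)) + 1)
            pts = a + np.linspace(0, 1, n)[:, None] * (b - a)
            iy = np.round((pts[:, 1] - origin[1]) / pixel_size).astype(int)
            ix = np.round((pts[:, 0] - origin[0]) / pixel_size).astype(int)
            keep = (iy >= 0) & (iy < shape[0]) & (ix >= 0) & (ix < shape[1])
            canvas[iy[keep], ix[keep]] = True
    return canvas


def gen_nmj_stack(
    spec: NMJPhantomSpec, seed: int = 0
) -> tuple[dict[str, ImageStack], NMJGroundTruth]:
    """Render an NMJ phantom into per-channel stacks plus ground truth.

    HRP renders the tube (main path + branches) and bouton spheres; Dlg
    renders spherical bouton shells; Brp renders small active-zone
    puncta on bouton surfaces.  Ground truth holds the polyline arc
    length, bouton/branch counts and the muscle polygon area.
    """
    rng = np.random.default_rng(seed)
    paths = [spec.axon_path, *spec.branches]
    all_pts = np.vstack(paths)
    margin = 3.0 + spec.bouton_radius
    origin = all_pts.min(axis=0) - margin
    extent = all_pts.max(axis=0) + margin - origin
    ny = int(math.ceil(extent[1] / spec.pixel_size)) + 1
    nx = int(math.ceil(extent[0] / spec.pixel_size)) + 1
    nz = spec.n_slices
    zc = (nz - 1) / 2.0
    spacing = (spec.z_step, spec.pixel_size, spec.pixel_size)

    center_raster = _rasterize_centerline(paths, origin, spec.pixel_size, (ny, nx))
    d2d = ndimage.distance_transform_edt(
        ~center_raster, sampling=(spec.pixel_size, spec.pixel_size)
    )
    zoff = (np.arange(nz) - zc) * spec.z_step  # physical z offset per slice

    def tube_mask(radius: float) -> np.ndarray:
        out = np.zeros((nz, ny, nx), dtype=bool)
        for k, w in enumerate(zoff):
            if abs(w) <= radius:
                out[k] = d2d <= math.sqrt(radius**2 - w**2)
        return out

    bouton_centers = np.array(
        [_point_at_arclength(spec.axon_path, s) for s in spec.bouton_arclengths]
    ).reshape(-1, 2)

    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    py = origin[1] + yy * spec.pixel_size
    px = origin[0] + xx * spec.pixel_size

    def sphere_dist(cx: float, cy: float) -> np.ndarray:
        """(nz, ny, nx) physical distance to a sphere centre on the mid-plane."""
        d2 = (px - cx) ** 2 + (py - cy) ** 2
        return np.sqrt(d2[None] + (zoff**2)[:, None, None])

    stacks: dict[str, ImageStack] = {}

    def finish(field_: np.ndarray, channel: str) -> ImageStack:
        if spec.noise == "poisson":
            vox = rng.poisson(field_)
        else:
            vox = np.rint(field_)
        vox = np.clip(vox, 0, 255).astype(np.uint8)
        return ImageStack(vox, spacing, channel=channel)

    if "HRP" in spec.channels:
        hrp = tube_mask(spec.tube_radius)
        for cx, cy in bouton_centers:
            hrp |= sphere_dist(cx, cy) <= spec.bouton_radius
        stacks["HRP"] = finish(np.where(hrp, 180.0, 6.0), "HRP")

    if "Dlg" in spec.channels:
        shell_thickness = 0.3
        dlg = np.zeros((nz, ny, nx), dtype=bool)
        for cx, cy in bouton_centers:
            d = sphere_dist(cx, cy)
            dlg |= (d >= spec.bouton_radius) & (d <= spec.bouton_radius + shell_thickness)
        stacks["Dlg"] = finish(np.where(dlg, 170.0, 6.0), "Dlg")

    brp_count = 0
    if "Brp" in spec.channels:
        field_ = np.full((nz, ny, nx), 10.0)
        sigma = 0.15
        for cx, cy in bouton_centers:
            angles = rng.uniform(0, 2 * np.pi, size=spec.brp_per_bouton)
            for a in angles:
                sx = cx + spec.bouton_radius * math.cos(a)
                sy = cy + spec.bouton_radius * math.sin(a)
                d = sphere_dist(sx, sy)
                field_ += 140.0 * np.exp(-(d**2) / (2 * sigma**2)) * (d <= 3 * sigma)
                brp_count += 1
        stacks["Brp"] = finish(field_, "Brp")

    area = _shoelace_area(spec.muscle_polygon) if spec.muscle_polygon is not None else 0.0
    truth = NMJGroundTruth(
        axonal_length_um=float(sum(_polyline_length(p) for p in paths)),
        bouton_count=len(bouton_centers),
        branch_points=spec.branch_points,
        muscle_area_um2=area,
        bouton_centers_um=bouton_centers,
        brp_count=brp_count,
    )
    return stacks, truth


def _wiggly_path(rng, start, heading, length, step=4.0, heading_noise=0.15):
    pts = [np.asarray(start, dtype=float)]
    remaining = length
    h = heading
    while remaining > 1e-9:
        d = min(step, remaining)
        h += rng.normal(0.0, heading_noise)
        pts.append(pts[-1] + d * np.array([math.cos(h), math.sin(h)]))
        remaining -= d
    return np.array(pts)


def random_nmj_spec(
    total_length_um: float = 100.0,
    n_boutons: int = 5,
    n_branches: int = 3,
    seed: int = 0,
    bouton_radius: float = 1.0,
    tube_radius: float = 0.4,
    muscle_size_um: tuple[float, float] = (200.0, 400.0),
) -> NMJPhantomSpec:
    """Random NMJ phantom with prescribed total length and counts.

    The main trunk takes 60% of the arc length and the branches split
    the remainder equally; all polylines wiggle gently so the phantom is
    not axis-aligned.  Bouton positions are spaced along the trunk far
    enough apart that neither boutons nor their Dlg shells touch.
    """
    rng = np.random.default_rng(seed)
    main_len = total_length_um * (0.6 if n_branches else 1.0)
    branch_len = (total_length_um - main_len) / n_branches if n_branches else 0.0
    heading0 = rng.uniform(0, 2 * np.pi)
    main = _wiggly_path(rng, (0.0, 0.0), heading0, main_len)

    branches = []
    attach_fracs = np.linspace(0.25, 0.75, n_branches) if n_branches else []
    for frac in attach_fracs:
        s = frac * main_len
        p0 = _point_at_arclength(main, s)
        p1 = _point_at_arclength(main, min(s + 1.0, main_len))
        local = math.atan2(*(p1 - p0)[::-1])
        side = rng.choice([-1.0, 1.0])
        b = _wiggly_path(rng, p0, local + side * rng.uniform(0.9, 1.3), branch_len)
        branches.append(b)

    # boutons on the trunk, clear of endpoints and of each other
    min_gap = 2 * (bouton_radius + 0.3) + 1.0
    lo, hi = bouton_radius + 1.0, main_len - bouton_radius - 1.0
    if n_boutons > 1 and (hi - lo) / (n_boutons - 1) < min_gap:
        raise PlacementError("boutons cannot be spaced without touching")
    base = np.linspace(lo, hi, n_boutons) if n_boutons else np.array([])
    jitter = rng.uniform(-0.3, 0.3, size=n_boutons) * (
        min((hi - lo) / max(n_boutons - 1, 1) - min_gap, 2.0) if n_boutons > 1 else 1.0
    )
    arcs = tuple(np.clip(base + jitter, lo, hi)) if n_boutons else ()

    w, h = muscle_size_um
    muscle = np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]])
    return NMJPhantomSpec(
        axon_path=main,
        branches=tuple(branches),
        bouton_arclengths=arcs,
        bouton_radius=bouton_radius,
        tube_radius=tube_radius,
        muscle_polygon=muscle,
    )


# --------------------------------------------------------------------------
# larva movies
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LarvaPathSpec:
    """Specification of a synthetic crawling-larva film.

    Defaults follow the assay protocol of one larva filmed for 40 s at
    400 frames (0.1 s frame interval).  ``speed_profile`` may be a
    scalar (constant speed, mm/s) or a per-frame array of length
    ``n_frames - 1``.
    """

    n_frames: int = 400
    duration: float = 40.0
    frame_size: tuple[int, int] = (256, 256)
    px_size: float = 0.1          # mm per pixel
    speed_profile: float | np.ndarray = 0.6
    heading_noise: float = 0.2    # rad per frame
    blob_radius: float = 8.0      # px
    background: float = 8.0
    peak: float = 230.0
    noise: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        prof = np.broadcast_to(
            np.asarray(self.speed_profile, dtype=float), (self.n_frames - 1,)
        ).copy()
        if np.any(prof < 0):
            raise ValueError("speeds must be >= 0")
        object.__setattr__(self, "speed_profile", prof)
        if 2 * self.blob_radius + 8 >= min(self.frame_size):
            raise ValueError("blob does not fit in the frame")

    @property
    def frame_interval(self) -> float:
        return self.duration / self.n_frames


def gen_larva_movie(spec: LarvaPathSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a larva film; returns (frames, true trajectory).

    The blob follows a heading random walk at the prescribed per-frame
    speeds, reflecting its heading at the frame walls so the speed
    profile is preserved.  Frames are uint8 ``(n_frames, ny, nx)``; the
    returned trajectory has columns ``frame, t_s, x_mm, y_mm``.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.frame_size
    dt = spec.frame_interval
    wall = spec.blob_radius + 3.0
    pos = np.array(
        [rng.uniform(wall + 2, nx - wall - 2), rng.uniform(wall + 2, ny - wall - 2)]
    )
    heading = rng.uniform(0, 2 * np.pi)
    positions = [pos.copy()]
    for speed in spec.speed_profile:
        heading += rng.normal(0.0, spec.heading_noise)
        step_px = speed * dt / spec.px_size
        for _ in range(8):  # reflect until the step stays inside the walls
            delta = step_px * np.array([math.cos(heading), math.sin(heading)])
            nxt = pos + delta
            if not (wall <= nxt[0] <= nx - wall):
                heading = math.pi - heading
            elif not (wall <= nxt[1] <= ny - wall):
                heading = -heading
            else:
                break
        pos = pos + step_px * np.array([math.cos(heading), math.sin(heading)])
        pos[0] = np.clip(pos[0], wall, nx - wall)
        pos[1] = np.clip(pos[1], wall, ny - wall)
        positions.append(pos.copy())
    positions = np.array(positions)

    sigma = spec.blob_radius / 1.2  # half-maximum radius ~ blob_radius
    frames = np.empty((spec.n_frames, ny, nx), dtype=np.uint8)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    for k, (cx, cy) in enumerate(positions):
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        img = spec.background + (spec.peak - spec.background) * np.exp(
            -d2 / (2 * sigma**2)
        )
        if spec.noise == "poisson":
            img = rng.poisson(img)
        frames[k] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = pd.DataFrame(
        {
            "frame": np.arange(spec.n_frames),
            "t_s": np.arange(spec.n_frames) * dt,
            "x_mm": positions[:, 0] * spec.px_size,
            "y_mm": positions[:, 1] * spec.px_size,
        }
    )
    return frames, truth


# --------------------------------------------------------------------------
# group measurement tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDef:
    """One experimental group: label, sampling distribution and size.

    ``dist`` is one of ``normal`` (params: mean, sd), ``lognormal``
    (params: mu, sigma of the underlying normal) or ``exponential``
    (params: scale).
    """

    label: str
    dist: str
    params: tuple[float, ...]
    n: int

    def __post_init__(self) -> None:
        if self.dist not in ("normal", "lognormal", "exponential"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        if self.n < 3:
            raise ValueError("each group needs n >= 3")
        if self.dist in ("normal", "lognormal") and self.params[1] <= 0:
            raise ValueError("scale parameter must be positive")


@dataclass(frozen=True)
class GroupSpec:
    groups: tuple[GroupDef, ...]
    seed: int = 0


def gen_group_table(spec: GroupSpec) -> pd.DataFrame:
    """Draw a long-format (group, value) table from per-group distributions."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for g in spec.groups:
        if g.dist == "normal":
            vals = rng.normal(g.params[0], g.params[1], size=g.n)
        elif g.dist == "lognormal":
            vals = rng.lognormal(g.params[0], g.params[1], size=g.n)
        else:
            vals = rng.exponential(g.params[0], size=g.n)
        frames.append(pd.DataFrame({"group": g.label, "value": vals}))
    return pd.concat(frames, ignore_index=True)
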