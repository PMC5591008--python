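"""End-to-end orchestration: stacks and films in, statistics out.

Two pipelines mirror the two experimental arms:

* the NMJ pipeline quantifies each hemisegment's punctate channel
  (denoise -> local max-entropy segmentation -> 3D labeling -> volumes)
  and morphometry channels (axonal length, branch points, boutons,
  muscle area), normalizes puncta statistics, then compares genotype
  groups metric-by-metric through the statistical decision tree;
* the locomotion pipeline tracks each larva's film, derives its speed
  series and dwell statistics, and compares groups on mean speed,
  stationary fraction and maximum speed.

Both are deterministic given config + seed and write a report bundle of
CSV tables plus a JSON manifest with a config hash.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import locomotion as loco
from . import morphometry as morpho
from . import puncta
from .stack import ImageStack, read_stack
from .stats import GroupComparisonResult, select_and_run

__all__ = [
    "HemisegmentInput",
    "NMJPipelineConfig",
    "MovieInput",
    "LocomotionPipelineConfig",
    "ReportBundle",
    "run_nmj_pipeline",
    "run_locomotion_pipeline",
]

#: z-steps used at acquisition, um: Brp stacks are sampled finer
DEFAULT_Z_STEP = {"Brp": 0.25}
DEFAULT_Z_STEP_OTHER = 0.5


@dataclass(frozen=True)
class HemisegmentInput:
    """One hemisegment's channels; keyed by (larva, segment, side)."""

    larva_id: str
    segment: str          # e.g. "A3"
    side: str             # "L" / "R"
    group: str            # genotype label, plain string
    channels: dict        # channel name -> ImageStack or TIFF path
    muscle_mask: np.ndarray | str | Path | None = None
    muscle_pixel_size_um: float = 1.0

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.larva_id, self.segment, self.side)


@dataclass(frozen=True)
class NMJPipelineConfig:
    records: tuple[HemisegmentInput, ...]
    puncta_channel: str = "Brp"
    pixel_size_um: float = 0.1
    window: int = 15
    low_cut: int = 20
    median_kernel: int = 3
    connectivity: int = 26
    min_voxels: int = 0
    normalizer: str = "axonal_length"   # or "muscle_surface_area"
    min_bouton_volume_um3: float = 0.2
    control_label: str | None = None
    alpha: float = 0.05
    min_group_n: int = 4
    seed: int = 0


@dataclass(frozen=True)
class MovieInput:
    larva_id: str
    group: str
    frames: np.ndarray | str | Path


@dataclass(frozen=True)
class LocomotionPipelineConfig:
    movies: tuple[MovieInput, ...]
    px_size_mm: float = 0.1
    frame_interval_s: float = 0.1
    intensity_threshold: float = 64
    category_boundaries: tuple[float, ...] = (0.2, 0.5, 0.8)
    epsilon_mm_s: float | None = None   # default: 1 px per frame interval
    control_label: str | None = None
    alpha: float = 0.05
    seed: int = 0


@dataclass
class ReportBundle:
    """Per-record table, group summaries, comparisons and a manifest."""

    records: pd.DataFrame
    group_summary: pd.DataFrame
    comparisons: dict[str, GroupComparisonResult]
    manifest: dict

    def comparison_table(self) -> pd.DataFrame:
        rows = []
        for metric, res in self.comparisons.items():
            rows.append(
                {
                    "metric": metric,
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "significant": res.significant,
                    "posthoc": res.posthoc_method or "",
                    "routing_normal": res.routing["normal"],
                    "routing_homogeneous": res.routing["homogeneous"],
                    "k": res.routing["k"],
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.group_summary.to_csv(out / "group_summary.csv", index=False)
        self.comparison_table().to_csv(out / "comparisons.csv", index=False)
        for metric, res in self.comparisons.items():
            if res.posthoc is not None:
                res.posthoc.to_csv(out / f"posthoc_{metric}.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _config_hash(cfg) -> str:
    """Stable hash of a config, hashing array inputs by content."""

    def norm(obj):
        if isinstance(obj, np.ndarray):
            return hashlib.sha256(np.ascontiguousarray(obj).tobytes()).hexdigest()
        if isinstance(obj, ImageStack):
            return norm(obj.voxels)
        if isinstance(obj, (list, tuple)):
            return [norm(o) for o in obj]
        if isinstance(obj, dict):
            return {str(k): norm(v) for k, v in obj.items()}
        if hasattr(obj, "__dataclass_fields__"):
            return {k: norm(getattr(obj, k)) for k in obj.__dataclass_fields__}
        if isinstance(obj, Path):
            return str(obj)
        return obj

    blob = json.dumps(norm(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _as_stack(obj, spacing, channel: str) -> ImageStack:
    if isinstance(obj, ImageStack):
        return obj
    return read_stack(obj, spacing=spacing, channel=channel)


def _spacing_for(channel: str, pixel_size: float) -> tuple[float, float, float]:
    dz = DEFAULT_Z_STEP.get(channel, DEFAULT_Z_STEP_OTHER)
    return (dz, pixel_size, pixel_size)


def _compare_metrics(
    records: pd.DataFrame,
    metrics: list[str],
    control_label: str | None,
    alpha: float,
    min_group_n: int,
) -> dict[str, GroupComparisonResult]:
    comparisons: dict[str, GroupComparisonResult] = {}
    for metric in metrics:
        table = records[["group", metric]].rename(columns={metric: "value"}).dropna()
        sizes = table.groupby("group").size()
        if len(sizes) < 2 or (sizes < min_group_n).any():
            warnings.warn(f"metric {metric!r}: too few groups/observations for "
                          "a comparison", stacklevel=2)
            continue
        if table.groupby("group")["value"].nunique().eq(1).all():
            warnings.warn(f"metric {metric!r}: all groups constant, skipping",
                          stacklevel=2)
            continue
        comparisons[metric] = select_and_run(
            table, control_label=control_label, alpha=alpha
        )
    return comparisons


def run_nmj_pipeline(config: NMJPipelineConfig) -> ReportBundle:
    """Quantify every hemisegment and compare genotype groups.

    Per record: median-denoise the punctate channel, segment by local
    maximum-entropy thresholding, label in 3D and measure volumes; mask
    the HRP channel for axonal length and branch points and the Dlg
    channel for bouton counts; normalize puncta statistics by the
    configured normalizer.  Records missing a required channel are
    skipped with a warning; if all records fail the pipeline errors.
    """
    rows = []
    for rec in config.records:
        try:
            pstack = _as_stack(
                rec.channels[config.puncta_channel],
                _spacing_for(config.puncta_channel, config.pixel_size_um),
                config.puncta_channel,
            )
        except KeyError:
            warnings.warn(f"record {rec.key}: missing channel "
                          f"{config.puncta_channel!r}, skipped", stacklevel=2)
            continue

        den = puncta.median_denoise(pstack, kernel=config.median_kernel)
        mask = puncta.segment_local_max_entropy(
            den, window=config.window, low_cut=config.low_cut
        )
        table = puncta.label_and_measure(
            mask, den.spacing, connectivity=config.connectivity
        )
        if config.min_voxels > 0:
            table = table[table["voxel_count"] >= config.min_voxels]

        row = {
            "larva_id": rec.larva_id, "segment": rec.segment, "side": rec.side,
            "group": rec.group,
            "puncta_count": len(table),
            "puncta_total_volume_um3": float(table["volume_um3"].sum()),
            "axonal_length_um": np.nan, "branch_points": np.nan,
            "bouton_count": np.nan, "muscle_surface_area_um2": np.nan,
        }

        if "HRP" in rec.channels:
            hrp = _as_stack(rec.channels["HRP"],
                            _spacing_for("HRP", config.pixel_size_um), "HRP")
            hmask = morpho.mask_from_channel(hrp)
            graph = morpho.skeletonize_mask(hmask, hrp.spacing)
            row["axonal_length_um"] = morpho.measure_axonal_length(
                hmask, hrp.spacing, graph=graph
            )
            row["branch_points"] = morpho.count_branch_points(graph)
        if "Dlg" in rec.channels:
            dlg = _as_stack(rec.channels["Dlg"],
                            _spacing_for("Dlg", config.pixel_size_um), "Dlg")
            row["bouton_count"] = morpho.count_boutons(
                morpho.mask_from_channel(dlg), dlg.spacing,
                min_volume_um3=config.min_bouton_volume_um3,
            )
        if rec.muscle_mask is not None:
            mm = rec.muscle_mask
            if not isinstance(mm, np.ndarray):
                import tifffile

                mm = tifffile.imread(str(mm)) > 0
            row["muscle_surface_area_um2"] = morpho.muscle_surface_area(
                mm, rec.muscle_pixel_size_um
            )

        norm_value = (
            row["axonal_length_um"]
            if config.normalizer == "axonal_length"
            else row["muscle_surface_area_um2"]
        )
        if np.isfinite(norm_value) and norm_value > 0:
            q = puncta.quantify(table, norm_value, config.normalizer)
            row["puncta_count_density"] = q.count_density
            row["puncta_volume_density"] = q.volume_density
        else:
            warnings.warn(f"record {rec.key}: no valid normalizer, densities NaN",
                          stacklevel=2)
            row["puncta_count_density"] = np.nan
            row["puncta_volume_density"] = np.nan
        rows.append(row)

    if not rows:
        raise RuntimeError("all records failed or were skipped")
    records = pd.DataFrame(rows)

    metrics = [
        "puncta_count", "puncta_total_volume_um3", "puncta_count_density",
        "puncta_volume_density", "axonal_length_um", "branch_points",
        "bouton_count",
    ]
    comparisons = _compare_metrics(
        records, metrics, config.control_label, config.alpha, config.min_group_n
    )
    summary = (
        records.groupby("group")[metrics]
        .agg(["count", "mean", "std"])
        .reset_index()
    )
    summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]
    manifest = {
        "pipeline": "nmj",
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_records": len(records),
        "metrics": metrics,
    }
    return ReportBundle(records, summary, comparisons, manifest)


def run_locomotion_pipeline(config: LocomotionPipelineConfig) -> ReportBundle:
    """Track every film and compare groups on speed statistics.

    Per larva: threshold-track the blob, compute speeds, then summarize
    mean speed, percentage of intervals at speed = 0 (<= epsilon),
    maximum speed and distance travelled.  Films failing to track are
    excluded with a warning.  Group comparisons run on mean speed,
    stationary fraction and maximum speed.
    """
    if not config.movies:
        raise ValueError("need at least one movie")
    eps = (
        config.epsilon_mm_s
        if config.epsilon_mm_s is not None
        else loco.stationary_epsilon(config.px_size_mm, config.frame_interval_s)
    )
    rows = []
    trajectories: dict[str, pd.DataFrame] = {}
    for mov in config.movies:
        frames = mov.frames
        if not isinstance(frames, np.ndarray):
            import tifffile

            frames = tifffile.imread(str(frames))
        try:
            traj = loco.track_larva(
                frames, config.px_size_mm,
                intensity_threshold=config.intensity_threshold,
            )
            speeds = loco.compute_speeds(traj, config.frame_interval_s)
        except (loco.TrackingError, ValueError) as exc:
            warnings.warn(f"movie {mov.larva_id!r} excluded: {exc}", stacklevel=2)
            continue
        report = loco.classify_speed_categories(
            speeds, config.category_boundaries, eps, config.frame_interval_s
        )
        trajectories[mov.larva_id] = traj
        finite = speeds[np.isfinite(speeds)]
        rows.append(
            {
                "larva_id": mov.larva_id, "group": mov.group,
                "mean_speed_mm_s": float(finite.mean()),
                "percent_zero": report.percent_zero,
                "max_speed_mm_s": report.max_speed,
                "distance_mm": report.distance_mm,
            }
        )
    if not rows:
        raise RuntimeError("no movie could be tracked")
    records = pd.DataFrame(rows)
    metrics = ["mean_speed_mm_s", "percent_zero", "max_speed_mm_s"]
    comparisons = _compare_metrics(
        records, metrics, config.control_label, config.alpha, min_group_n=4
    )
    summary = (
        records.groupby("group")[metrics + ["distance_mm"]]
        .agg(["count", "mean", "std"])
        .reset_index()
    )
    summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]
    manifest = {
        "pipeline": "locomotion",
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_larvae": len(records),
        "epsilon_mm_s": eps,
        "metrics": metrics,
    }
    bundle = ReportBundle(records, summary, comparisons, manifest)
    bundle.trajectories = trajectories  # type: ignore[attr-defined]
    return bundle


def plot_trajectories(
    trajectories: dict[str, pd.DataFrame], out_path: str | Path
) -> None:
    """Write a trajectory panel (one path per larva) as PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for larva, traj in trajectories.items():
        ok = traj["valid"].to_numpy(dtype=bool)
        ax.plot(traj["x_mm"][ok], traj["y_mm"][ok], lw=1, label=larva)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_aspect("equal")
    if len(trajectories) <= 8:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
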