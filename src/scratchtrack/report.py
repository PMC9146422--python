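"""HTML report generation: metric tables, comparisons, trajectory figures.

The report collects, per experiment: the six-metric table of the sampled
leading-edge tracks, pairwise condition comparisons, wind-rose style
trajectory plots with all sampled tracks translated to a common origin,
per-frame detection counts, and an overlay of frame 1 with the two
identified leading-edge rows. Missing stages produce explicit gaps in the
report, never a crash.
"""

from __future__ import annotations

import hashlib
import html
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES, GroupComparison
from .pipeline import ExperimentResult, metrics_table

__all__ = ["build_report", "trajectory_figure", "overlay_figure", "config_hash"]


def config_hash(payload: str) -> str:
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def trajectory_figure(results: Sequence[ExperimentResult], path: Path) -> Path:
    """Sampled leading-edge trajectories translated to a common origin, one
    panel per condition; wound-ward is plotted upward."""
    n = max(len(results), 1)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for ax, res in zip(axes[0], results):
        for et in res.sampled:
            c = et.track.centers()
            c = c - c[0]
            # flip so wound-ward is +y on the plot regardless of edge side
            ax.plot(c[:, 0], et.wound_direction * c[:, 1], lw=0.8)
        ax.set_title(f"{res.condition} (n={len(res.sampled)})")
        ax.set_xlabel("x (px)")
        ax.set_ylabel("wound-ward y (px)")
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_aspect("equal", adjustable="datalim")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def overlay_figure(
    result: ExperimentResult, path: Path, frame_image: np.ndarray | None = None
) -> Path:
    """Frame-1 detections with the two leading-edge rows drawn as horizontal
    lines."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    if frame_image is not None:
        ax.imshow(frame_image, cmap="gray", vmin=0, vmax=max(1.0, float(frame_image.max())))
    for t in result.tracks:
        e = t.entries[0]
        if e.frame != 1:
            continue
        cx, cy = e.box.center
        ax.plot(cx, cy, ".", ms=2, color="tab:blue", alpha=0.6)
    if result.edges is not None:
        for y in (result.edges.y_top, result.edges.y_bottom):
            ax.axhline(y, color="red", lw=1.5)
    ax.set_xlim(0, result.meta.width)
    ax.set_ylim(result.meta.height, 0)
    ax.set_title(f"{result.condition}: frame 1 detections and leading edges")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _df_html(df: pd.DataFrame) -> str:
    return df.to_html(index=False, float_format=lambda v: f"{v:.3f}", border=0)


def build_report(
    results: Sequence[ExperimentResult],
    comparisons: Sequence[GroupComparison] | None,
    outdir,
    frame1_images: dict[str, np.ndarray] | None = None,
    run_config_echo: str = "",
) -> Path:
    """Write CSV tables, figures and ``report.html`` into ``outdir``.

    Returns the path of the HTML report. Each artifact names the config hash
    and seed that produced it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(run_config_echo or repr([r.condition for r in results]))
    seeds = sorted({r.seed for r in results})
    stamp = f"config {chash}, seed(s) {', '.join(map(str, seeds))}"

    tables = [metrics_table(r) for r in results]
    all_metrics = pd.concat([t for t in tables if not t.empty], ignore_index=True) if any(
        not t.empty for t in tables
    ) else pd.DataFrame(columns=["track_id", "condition", *METRIC_NAMES])
    all_metrics.to_csv(outdir / "migration_metrics.csv", index=False)

    comp_df = None
    if comparisons:
        comp_df = pd.DataFrame([asdict(c) for c in comparisons])
        comp_df.to_csv(outdir / "group_comparisons.csv", index=False)

    counts = pd.DataFrame(
        {r.condition: pd.Series(r.detections_per_frame) for r in results}
    ).rename_axis("frame")
    counts.to_csv(outdir / "detections_per_frame.csv")

    figures: list[tuple[str, Path]] = []
    if any(r.sampled for r in results):
        figures.append(
            ("Sampled leading-edge trajectories (common origin)",
             trajectory_figure(results, outdir / "trajectories.png"))
        )
    for r in results:
        img = (frame1_images or {}).get(r.condition)
        figures.append(
            (f"Leading edges: {r.condition}",
             overlay_figure(r, outdir / f"overlay_{r.condition}.png", img))
        )

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>Wound-repair analysis report</title>",
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
        "td,th{padding:2px 8px;border-bottom:1px solid #ddd}</style></head><body>",
        "<h1>Wound-repair analysis report</h1>",
        f"<p>Provenance: {html.escape(stamp)}</p>",
        "<h2>Cell migration metrics</h2>",
        "<p>Metrics per sampled leading-edge track: "
        + ", ".join(METRIC_NAMES)
        + ".</p>",
    ]
    if all_metrics.empty:
        parts.append("<p><em>No sampled tracks available — metrics table omitted.</em></p>")
    else:
        summary = all_metrics.groupby("condition")[list(METRIC_NAMES)].agg(["mean", "std"])
        summary.columns = [f"{m}_{s}" for m, s in summary.columns]
        parts.append("<h3>Per-condition summary</h3>")
        parts.append(_df_html(summary.reset_index()))
        parts.append("<h3>Per-track values</h3>")
        parts.append(_df_html(all_metrics))
    parts.append("<h2>Group comparisons (Wilcoxon&ndash;Mann&ndash;Whitney)</h2>")
    if comp_df is None or comp_df.empty:
        parts.append("<p><em>Fewer than two conditions — no comparisons computed.</em></p>")
    else:
        parts.append(_df_html(comp_df))
    closed = [r.condition for r in results if r.wound_closed]
    if closed:
        parts.append(
            "<p><strong>Closed-wound frames:</strong> no open wound band was "
            f"found in frame 1 of: {html.escape(', '.join(closed))}.</p>"
        )
    parts.append("<h2>Detections per frame</h2>")
    parts.append(_df_html(counts.reset_index()))
    parts.append("<h2>Figures</h2>")
    for title, fig_path in figures:
        parts.append(f"<h3>{html.escape(title)}</h3>")
        parts.append(f"<img src='{fig_path.name}' style='max-width:100%'>")
    parts.append("</body></html>")

    report_path = outdir / "report.html"
    report_path.write_text("\n".join(parts))
    return report_path
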