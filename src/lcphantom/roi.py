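"""ROI placement and CNR measurement.

CNR for a hole of given depth is

    CNR = (MPV_hole - MPV_background) / STD_background

with the averaging protocol: two mean-pixel-value samples inside the target
hole and five background regions, whose MPVs and (population) standard
deviations are each averaged before the single CNR evaluation.  Hole ROIs are
circles fully inscribed in the target; background ROIs sit on hole-free plate
regions placed from the known phantom geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Hole, PhantomModel
from .simulate import SyntheticFrame

__all__ = [
    "RoiSpec",
    "RoiStats",
    "CnrProtocol",
    "CnrMeasurement",
    "roi_stats",
    "hole_rois",
    "background_rois",
    "measure_cnr",
    "cnr_depth_profile",
    "profile_to_frame",
    "roi_layout",
    "save_roi_overlay",
]


@dataclass(frozen=True)
class RoiSpec:
    """A circular ROI targeting a pixel count, centred in plate coordinates."""

    center_xy: tuple[float, float]
    area_pixels: int = 800
    radius_mm: float | None = None  # overrides area_pixels when set

    def __post_init__(self) -> None:
        if self.radius_mm is None and self.area_pixels < 25:
            raise ValueError("ROI must target at least 25 pixels")

    def radius_for(self, pixel_pitch: float) -> float:
        if self.radius_mm is not None:
            return self.radius_mm
        return pixel_pitch * float(np.sqrt(self.area_pixels / np.pi))


@dataclass(frozen=True)
class RoiStats:
    mpv: float
    std: float
    n: int


@dataclass(frozen=True)
class CnrProtocol:
    """Sampling protocol for one CNR value."""

    hole_samples: int = 2
    background_samples: int = 5
    roi_area_pixels: int = 800
    hole_jitter_px: float = 1.0
    #: background ring radius as a fraction of the hole-ring radius (ring
    #: layouts); lateral offset in cell pitches (column layouts)
    background_radius_fraction: float = 0.5
    clearance_mm: float = 0.5


@dataclass(frozen=True)
class CnrMeasurement:
    hole_depth: float
    cnr: float
    hole_mpvs: tuple[float, ...]
    background_mpvs: tuple[float, ...]
    background_stds: tuple[float, ...]


def roi_stats(frame: SyntheticFrame, roi: RoiSpec) -> RoiStats:
    """Mean and population SD over pixels whose centres fall in the circle."""
    x, y = frame.pixel_coords()
    r = roi.radius_for(frame.pixel_pitch)
    cx, cy = roi.center_xy
    half_x = frame.shape[1] * frame.pixel_pitch / 2
    half_y = frame.shape[0] * frame.pixel_pitch / 2
    if abs(cx) + r > half_x or abs(cy) + r > half_y:
        raise ValueError("ROI extends beyond the image")
    mask = (x[np.newaxis, :] - cx) ** 2 + (y[:, np.newaxis] - cy) ** 2 <= r**2
    values = frame.pixels[mask].astype(float)
    if values.size == 0:
        raise ValueError("empty ROI")
    return RoiStats(mpv=float(values.mean()), std=float(values.std(ddof=0)), n=values.size)


def _hole_roi_radius(hole: Hole, pitch: float, protocol: CnrProtocol) -> float:
    """Largest radius honouring both the target area and full inscription."""
    r_area = pitch * float(np.sqrt(protocol.roi_area_pixels / np.pi))
    r_max = hole.radius - protocol.hole_jitter_px * pitch
    if r_max <= 0:
        raise ValueError("hole too small for the ROI protocol")
    return min(r_area, r_max)


def hole_rois(
    phantom: PhantomModel, depth: float, pitch: float, protocol: CnrProtocol
) -> list[RoiSpec]:
    """The protocol's hole-MPV placements: concentric, jittered by +-1 pixel."""
    hole = phantom.hole_at_depth(depth)
    r = _hole_roi_radius(hole, pitch, protocol)
    offsets = [(protocol.hole_jitter_px * pitch, 0.0), (-protocol.hole_jitter_px * pitch, 0.0)]
    rois = []
    for k in range(protocol.hole_samples):
        dx, dy = offsets[k % len(offsets)]
        center = (hole.center_xy[0] + dx, hole.center_xy[1] + dy)
        if np.hypot(center[0] - hole.center_xy[0], center[1] - hole.center_xy[1]) + r > hole.radius:
            raise ValueError("hole ROI crosses the hole boundary")
        rois.append(RoiSpec(center_xy=center, radius_mm=r))
    return rois


def background_rois(
    phantom: PhantomModel, pitch: float, protocol: CnrProtocol
) -> list[RoiSpec]:
    """Five hole-free placements from the known geometry, clearance-checked."""
    r_roi = pitch * float(np.sqrt(protocol.roi_area_pixels / np.pi))
    n = protocol.background_samples
    centers: list[tuple[float, float]] = []
    if phantom.layout == "ring":
        ring_r = float(np.mean([np.hypot(*h.center_xy) for h in phantom.holes]))
        bg_r = protocol.background_radius_fraction * ring_r
        for k in range(n):
            a = 2 * np.pi * k / n + np.pi / n
            centers.append((bg_r * np.cos(a), bg_r * np.sin(a)))
    else:  # column
        ys = sorted(h.center_xy[1] for h in phantom.holes)
        pitch_y = ys[1] - ys[0] if len(ys) > 1 else 15.0
        x_off = max(h.radius for h in phantom.holes) + r_roi + pitch_y / 4
        y_span = np.linspace(ys[0], ys[-1], n)
        for k, y in enumerate(y_span):
            centers.append((x_off if k % 2 == 0 else -x_off, y))
    rois = []
    for c in centers:
        for h in phantom.holes:
            d = np.hypot(c[0] - h.center_xy[0], c[1] - h.center_xy[1])
            if d < h.radius + r_roi + protocol.clearance_mm:
                raise ValueError(
                    f"background ROI at {c} too close to the {h.depth}-mm hole"
                )
        if np.hypot(*c) + r_roi > phantom.outer_diameter / 2:
            raise ValueError(f"background ROI at {c} leaves the plate")
        rois.append(RoiSpec(center_xy=c, radius_mm=r_roi))
    return rois


def measure_cnr(
    frame: SyntheticFrame,
    phantom: PhantomModel,
    depth: float,
    protocol: CnrProtocol = CnrProtocol(),
) -> CnrMeasurement:
    """CNR of the hole at ``depth`` with the 2-hole/5-background protocol."""
    h_stats = [roi_stats(frame, r) for r in hole_rois(phantom, depth, frame.pixel_pitch, protocol)]
    b_stats = [roi_stats(frame, r) for r in background_rois(phantom, frame.pixel_pitch, protocol)]
    hole_mpvs = tuple(s.mpv for s in h_stats)
    bg_mpvs = tuple(s.mpv for s in b_stats)
    bg_stds = tuple(s.std for s in b_stats)
    denom = float(np.mean(bg_stds))
    if denom == 0:
        cnr = 0.0 if np.mean(hole_mpvs) == np.mean(bg_mpvs) else float("inf")
    else:
        cnr = (float(np.mean(hole_mpvs)) - float(np.mean(bg_mpvs))) / denom
    return CnrMeasurement(
        hole_depth=depth,
        cnr=cnr,
        hole_mpvs=hole_mpvs,
        background_mpvs=bg_mpvs,
        background_stds=bg_stds,
    )


def cnr_depth_profile(
    frames,
    phantom: PhantomModel,
    protocol: CnrProtocol = CnrProtocol(),
) -> list[CnrMeasurement]:
    """One CNR measurement per hole depth, pooled over the given frames."""
    frames = [frames] if isinstance(frames, SyntheticFrame) else list(frames)
    if not frames:
        raise ValueError("no frames given")
    results = []
    for depth in sorted(phantom.depths):
        per_frame = [measure_cnr(f, phantom, depth, protocol) for f in frames]
        hole_mpvs = tuple(v for m in per_frame for v in m.hole_mpvs)
        bg_mpvs = tuple(v for m in per_frame for v in m.background_mpvs)
        bg_stds = tuple(v for m in per_frame for v in m.background_stds)
        cnr = (float(np.mean(hole_mpvs)) - float(np.mean(bg_mpvs))) / float(np.mean(bg_stds))
        results.append(
            CnrMeasurement(depth, cnr, hole_mpvs, bg_mpvs, bg_stds)
        )
    return results


def roi_layout(phantom: PhantomModel, pitch: float, protocol: CnrProtocol = CnrProtocol()) -> dict:
    """All ROI placements for a phantom as a plain dict (YAML/JSON-ready)."""
    layout = {"phantom": phantom.name, "pixel_pitch_mm": pitch, "holes": {}, "background": []}
    for depth in phantom.depths:
        layout["holes"][depth] = [
            {"center_xy_mm": list(r.center_xy), "radius_mm": r.radius_for(pitch)}
            for r in hole_rois(phantom, depth, pitch, protocol)
        ]
    layout["background"] = [
        {"center_xy_mm": list(r.center_xy), "radius_mm": r.radius_for(pitch)}
        for r in background_rois(phantom, pitch, protocol)
    ]
    return layout


def save_roi_overlay(frame: SyntheticFrame, phantom: PhantomModel, path,
                     protocol: CnrProtocol = CnrProtocol()) -> None:
    """Write a PNG of the frame with every ROI drawn, for visual audit."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    half_x = frame.shape[1] * frame.pixel_pitch / 2
    half_y = frame.shape[0] * frame.pixel_pitch / 2
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(frame.pixels, cmap="gray", extent=[-half_x, half_x, -half_y, half_y])
    layout = roi_layout(phantom, frame.pixel_pitch, protocol)
    for rois in layout["holes"].values():
        for r in rois:
            ax.add_patch(plt.Circle(r["center_xy_mm"], r["radius_mm"],
                                    fill=False, color="yellow", lw=0.8))
    for r in layout["background"]:
        ax.add_patch(plt.Circle(r["center_xy_mm"], r["radius_mm"],
                                fill=False, color="cyan", lw=0.8))
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def profile_to_frame(profile: list[CnrMeasurement]) -> pd.DataFrame:
    """Tabulate a CNR-depth profile (CSV-ready)."""
    return pd.DataFrame(
        {
            "depth_mm": [m.hole_depth for m in profile],
            "cnr": [m.cnr for m in profile],
            "hole_mpv_mean": [float(np.mean(m.hole_mpvs)) for m in profile],
            "bg_mpv_mean": [float(np.mean(m.background_mpvs)) for m in profile],
            "bg_std_mean": [float(np.mean(m.background_stds)) for m in profile],
        }
    )
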