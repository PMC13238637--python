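"""Parametric phantom geometry: plate modules, rasterization and STL export.

The printed low-contrast phantom is a set of interlocking PLA discs, one per
fluoroscopic field of view.  Each disc is a 10-mm plate carrying a ring of
10-mm-diameter flat-bottom holes whose depths step through the low-contrast
series; the contrast-detail reference is modelled as the 8-mm-diameter column
of a PMMA plate.  Plate coordinates are mm, origin at the plate centre,
x right / y up; raster row 0 is at the top and pixel centres sit at
(i + 0.5) * pitch offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .materials import Material, get_material

__all__ = [
    "Hole",
    "PhantomModel",
    "ThicknessMap",
    "build_plate_a",
    "build_plate_b",
    "build_plate_c",
    "build_cdrad_column",
    "rasterize",
    "export_stl",
]

PLATE_THICKNESS_MM = 10.0
LC_HOLE_DIAMETER_MM = 10.0
CDRAD_HOLE_DIAMETER_MM = 8.0

# Module outer diameters from the nominal fields of view (4.5"/6"/9").
PLATE_A_DIAMETER_MM = 114.3
PLATE_B_DIAMETER_MM = 152.4
PLATE_C_DIAMETER_MM = 228.6
RING_RADIUS_FRACTION = 0.35

PLATE_A_DEPTHS_MM = tuple(round(0.2 * k, 1) for k in range(1, 12))  # 0.2 .. 2.2
PLATE_B_DEPTHS_MM = tuple(round(0.3 + 0.2 * k, 1) for k in range(10))  # 0.3 .. 2.1
# 8-mm column depths, covering the comparison range 0.3-2.5 mm.
CDRAD_DEPTHS_MM = (0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.3, 1.6, 2.0, 2.5)
CDRAD_CELL_PITCH_MM = 15.0
CDRAD_COLUMN_DIAMETER_MM = 170.0


@dataclass(frozen=True)
class Hole:
    """A flat-bottom cylindrical recess milled from the top face."""

    center_xy: tuple[float, float]
    diameter: float
    depth: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("hole diameter must be positive")
        if self.depth <= 0:
            raise ValueError("hole depth must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class PhantomModel:
    """A disc plate with an ordered series of low-contrast holes."""

    name: str
    material: Material
    plate_thickness: float
    outer_diameter: float
    holes: tuple[Hole, ...]
    layout: str = "ring"  # 'ring' or 'column'; drives STL cell partitioning

    def __post_init__(self) -> None:
        if not self.holes:
            raise ValueError("phantom must have at least one hole")
        depths = [h.depth for h in self.holes]
        if any(d >= self.plate_thickness for d in depths):
            raise ValueError("hole depth must be less than the plate thickness")
        if len(set(depths)) != len(depths):
            raise ValueError("hole depths must be distinct")
        r_out = self.outer_diameter / 2.0
        for h in self.holes:
            if math.hypot(*h.center_xy) + h.radius >= r_out:
                raise ValueError("hole extends outside the plate")
        for i, a in enumerate(self.holes):
            for b in self.holes[i + 1:]:
                dist = math.hypot(
                    a.center_xy[0] - b.center_xy[0], a.center_xy[1] - b.center_xy[1]
                )
                if dist <= a.radius + b.radius:
                    raise ValueError("holes overlap")

    @property
    def depths(self) -> tuple[float, ...]:
        return tuple(h.depth for h in self.holes)

    def hole_at_depth(self, depth: float, atol: float = 1e-6) -> Hole:
        for h in self.holes:
            if abs(h.depth - depth) <= atol:
                return h
        raise KeyError(f"no hole of depth {depth} mm in {self.name!r}")


@dataclass(frozen=True)
class ThicknessMap:
    """Material path length (mm) per pixel, with the in-disc mask."""

    pixel_pitch: float
    grid: np.ndarray = field(repr=False)
    fov_mask: np.ndarray = field(repr=False)

    def to_csv(self, path) -> None:
        """Debug export of the path-length grid (mm) as plain CSV."""
        np.savetxt(path, self.grid, delimiter=",", fmt="%.3f")


def _ring_phantom(
    name: str,
    depth_series,
    hole_diameter: float,
    ring_radius: float,
    outer_diameter: float,
    material: Material,
    plate_thickness: float,
) -> PhantomModel:
    depths = [float(d) for d in depth_series]
    if not depths:
        raise ValueError("depth series must be non-empty")
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depth series must be strictly increasing")
    n = len(depths)
    holes = tuple(
        Hole(
            center_xy=(
                ring_radius * math.cos(2 * math.pi * k / n),
                ring_radius * math.sin(2 * math.pi * k / n),
            ),
            diameter=hole_diameter,
            depth=d,
        )
        for k, d in enumerate(depths)
    )
    return PhantomModel(
        name=name,
        material=material,
        plate_thickness=plate_thickness,
        outer_diameter=outer_diameter,
        holes=holes,
        layout="ring",
    )


def build_plate_a(
    depth_series=PLATE_A_DEPTHS_MM,
    hole_diameter: float = LC_HOLE_DIAMETER_MM,
    ring_radius: float | None = None,
) -> PhantomModel:
    """Central module (4.5" FOV): depths 0.2-2.2 mm in 0.2-mm steps."""
    if ring_radius is None:
        ring_radius = RING_RADIUS_FRACTION * PLATE_A_DIAMETER_MM
    return _ring_phantom(
        "plate_a", depth_series, hole_diameter, ring_radius,
        PLATE_A_DIAMETER_MM, get_material("pla"), PLATE_THICKNESS_MM,
    )


def build_plate_b(
    depth_series=PLATE_B_DEPTHS_MM,
    hole_diameter: float = LC_HOLE_DIAMETER_MM,
    ring_radius: float | None = None,
) -> PhantomModel:
    """6" FOV module: ten targets, depths 0.3-2.1 mm (0.1-mm offset from A)."""
    if ring_radius is None:
        ring_radius = RING_RADIUS_FRACTION * PLATE_B_DIAMETER_MM
    return _ring_phantom(
        "plate_b", depth_series, hole_diameter, ring_radius,
        PLATE_B_DIAMETER_MM, get_material("pla"), PLATE_THICKNESS_MM,
    )


def build_plate_c(
    depth_series=PLATE_B_DEPTHS_MM,
    hole_diameter: float = LC_HOLE_DIAMETER_MM,
    ring_radius: float | None = None,
) -> PhantomModel:
    """9" FOV module; reuses the plate-B depth series."""
    if ring_radius is None:
        ring_radius = RING_RADIUS_FRACTION * PLATE_C_DIAMETER_MM
    return _ring_phantom(
        "plate_c", depth_series, hole_diameter, ring_radius,
        PLATE_C_DIAMETER_MM, get_material("pla"), PLATE_THICKNESS_MM,
    )


def build_cdrad_column(depth_series=CDRAD_DEPTHS_MM) -> PhantomModel:
    """The 8-mm-diameter column of the contrast-detail reference phantom.

    Only the subregion around the column is modelled: a vertical run of
    8-mm holes in a 10-mm PMMA plate at the matrix cell pitch.
    """
    depths = [float(d) for d in depth_series]
    if not depths:
        raise ValueError("depth series must be non-empty")
    if any(d <= 0 for d in depths) or any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depth series must be positive and strictly increasing")
    n = len(depths)
    y0 = (n - 1) / 2.0 * CDRAD_CELL_PITCH_MM
    holes = tuple(
        Hole(center_xy=(0.0, y0 - k * CDRAD_CELL_PITCH_MM),
             diameter=CDRAD_HOLE_DIAMETER_MM, depth=d)
        for k, d in enumerate(depths)
    )
    return PhantomModel(
        name="cdrad_column",
        material=get_material("pmma"),
        plate_thickness=PLATE_THICKNESS_MM,
        outer_diameter=CDRAD_COLUMN_DIAMETER_MM,
        holes=holes,
        layout="column",
    )


def rasterize(phantom: PhantomModel, pixel_pitch: float, image_size: int) -> ThicknessMap:
    """Point-sample the phantom onto a square pixel grid.

    Each pixel centre inside a hole carries plate_thickness - depth; other
    in-disc pixels carry the full plate thickness; outside the disc the path
    length is zero and the mask is False.
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")
    half = image_size * pixel_pitch / 2.0
    if phantom.outer_diameter / 2.0 > half:
        raise ValueError(
            f"phantom ({phantom.outer_diameter} mm) exceeds the image extent "
            f"({2 * half} mm)"
        )
    coords = (np.arange(image_size) + 0.5) * pixel_pitch - half
    x = coords[np.newaxis, :]
    y = -coords[:, np.newaxis]  # row 0 at top
    r2 = x**2 + y**2
    mask = r2 <= (phantom.outer_diameter / 2.0) ** 2
    grid = np.where(mask, phantom.plate_thickness, 0.0)
    for h in phantom.holes:
        inside = (x - h.center_xy[0]) ** 2 + (y - h.center_xy[1]) ** 2 <= h.radius**2
        grid[inside] = phantom.plate_thickness - h.depth
    return ThicknessMap(pixel_pitch=pixel_pitch, grid=grid, fov_mask=mask)


# ---------------------------------------------------------------------------
# STL export.  No triangulation engine is assumed: the multiply-connected top
# face is split into convex cells (angular sectors for ring layouts,
# horizontal bands for the column), each containing one hole, and every cell
# is triangulated by zipping its boundary loop to the hole rim.
# ---------------------------------------------------------------------------


def _zip_loops(outer: np.ndarray, inner: np.ndarray, center: np.ndarray) -> list[tuple]:
    """Triangulate the annular region between two closed CCW loops.

    Both loops must be star-shaped about ``center`` (guaranteed when the
    outer loop bounds a convex cell and the inner loop is the hole rim).
    Vertices are merged by angular progress about the centre, the classic
    cylinder-zip construction.
    """
    def progress(loop):
        a = np.arctan2(loop[:, 1] - center[1], loop[:, 0] - center[0])
        a = np.unwrap(a)
        return (a - a[0]) / (2 * np.pi)

    # roll the inner loop so both loops start at about the same angle
    a_out0 = math.atan2(outer[0, 1] - center[1], outer[0, 0] - center[0])
    a_in = np.arctan2(inner[:, 1] - center[1], inner[:, 0] - center[0])
    start = int(np.argmin(np.abs(np.angle(np.exp(1j * (a_in - a_out0))))))
    inner = np.roll(inner, -start, axis=0)

    po, pi_ = progress(outer), progress(inner)
    tris = []
    i = j = 0
    no, ni = len(outer), len(inner)
    while i < no or j < ni:
        next_o = po[i + 1] if i + 1 < no else 1.0
        next_i = pi_[j + 1] if j + 1 < ni else 1.0
        if j >= ni or (i < no and next_o <= next_i):
            tris.append((outer[i % no], outer[(i + 1) % no], inner[j % ni]))
            i += 1
        else:
            tris.append((inner[(j + 1) % ni], inner[j % ni], outer[i % no]))
            j += 1
    return tris


def _circle(cx: float, cy: float, r: float, n: int, a0: float = 0.0) -> np.ndarray:
    t = a0 + 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def _wall(loop_xy: np.ndarray, z_lo: float, z_hi: float, outward: bool) -> list[tuple]:
    """Quad strip between two copies of a closed loop at different heights."""
    tris = []
    n = len(loop_xy)
    for k in range(n):
        a, b = loop_xy[k], loop_xy[(k + 1) % n]
        a0, a1 = (*a, z_lo), (*a, z_hi)
        b0, b1 = (*b, z_lo), (*b, z_hi)
        if outward:
            tris += [(a0, b0, b1), (a0, b1, a1)]
        else:
            tris += [(a0, b1, b0), (a0, a1, b1)]
    return tris


def _fan(center: tuple, loop_xy: np.ndarray, z: float, up: bool) -> list[tuple]:
    tris = []
    n = len(loop_xy)
    c = (*center, z)
    for k in range(n):
        a, b = (*loop_xy[k], z), (*loop_xy[(k + 1) % n], z)
        tris.append((c, a, b) if up else (c, b, a))
    return tris


def _with_cardinals(arc_t: np.ndarray) -> np.ndarray:
    """Insert any multiple of pi/2 covered by the arc so that rim vertices
    hit the axis extremes and the mesh bounding box equals the diameter."""
    lo, hi = arc_t[0], arc_t[-1]
    extra = [
        c
        for k in range(math.floor(lo / (math.pi / 2)), math.ceil(hi / (math.pi / 2)) + 1)
        if lo + 1e-12 < (c := k * math.pi / 2) < hi - 1e-12
    ]
    if not extra:
        return arc_t
    return np.unique(np.concatenate([arc_t, extra]))


def _cell_loops(phantom: PhantomModel, n_seg: int):
    """Convex top-face cells (CCW 2-D loops), one hole per cell.

    Returns ``(cells, outer_ring)`` where ``outer_ring`` is the global CCW
    discretization of the plate rim assembled from the cell arcs, so that the
    top face, outer wall and bottom disc share identical rim vertices.
    """
    r_out = phantom.outer_diameter / 2.0
    cells = []
    rim_angles: list[np.ndarray] = []
    if phantom.layout == "ring":
        n = len(phantom.holes)
        hole_angles = [math.atan2(h.center_xy[1], h.center_xy[0]) for h in phantom.holes]
        for k, h in enumerate(phantom.holes):
            a_lo = hole_angles[k] - math.pi / n
            a_hi = hole_angles[k] + math.pi / n
            arc_t = _with_cardinals(np.linspace(a_lo, a_hi, max(8, n_seg // n + 1)))
            arc = np.column_stack([r_out * np.cos(arc_t), r_out * np.sin(arc_t)])
            loop = arc[:-1] if n == 1 else np.vstack([[[0.0, 0.0]], arc])
            cells.append((loop, h))
            rim_angles.append(arc_t[:-1])
    elif phantom.layout == "column":
        order = np.argsort([h.center_xy[1] for h in phantom.holes])  # bottom first
        holes = [phantom.holes[i] for i in order]
        ys = [h.center_xy[1] for h in holes]
        pitch = CDRAD_CELL_PITCH_MM if len(ys) < 2 else ys[1] - ys[0]
        m = max(8, n_seg // 8)
        right_arcs, left_arcs = [], []
        for idx, h in enumerate(holes):
            y_lo = h.center_xy[1] - pitch / 2.0 if idx > 0 else -r_out
            y_hi = h.center_xy[1] + pitch / 2.0 if idx < len(holes) - 1 else r_out
            t_lo = math.asin(max(-1.0, min(1.0, y_lo / r_out)))
            t_hi = math.asin(max(-1.0, min(1.0, y_hi / r_out)))
            right = _with_cardinals(np.linspace(t_lo, t_hi, m))
            left = np.pi - right[::-1]
            pts = np.vstack([
                np.column_stack([r_out * np.cos(right), r_out * np.sin(right)]),
                np.column_stack([r_out * np.cos(left), r_out * np.sin(left)]),
            ])
            # drop coincident consecutive vertices (arc junctions at the poles)
            keep = np.linalg.norm(pts - np.roll(pts, 1, axis=0), axis=1) > 1e-9
            cells.append((pts[keep], h))
            # drop duplicate junction points: right arcs join at cell tops,
            # left arcs join at cell bottoms, the rim closes at angle 3*pi/2
            right_arcs.append(right[:-1] if idx < len(holes) - 1 else right)
            left_arcs.append(left[1:-1] if idx == 0 else left[1:])
        # rim: right side bottom->top, then left side top->bottom (CCW)
        rim_angles = right_arcs + left_arcs[::-1]
    else:  # pragma: no cover - guarded by builders
        raise ValueError(f"unknown layout {phantom.layout!r}")
    ring_t = np.concatenate(rim_angles)
    outer_ring = np.column_stack([r_out * np.cos(ring_t), r_out * np.sin(ring_t)])
    return cells, outer_ring


def phantom_mesh(phantom: PhantomModel, n_seg: int = 96):
    """Watertight triangle mesh of the plate with its cylindrical recesses."""
    import trimesh

    H = phantom.plate_thickness
    cells, outer = _cell_loops(phantom, n_seg)
    tris: list[tuple] = []
    tris += _fan((0.0, 0.0), outer, 0.0, up=False)          # bottom disc
    tris += _wall(outer, 0.0, H, outward=True)              # outer wall
    for loop, hole in cells:
        rim_n = max(24, n_seg // 2)
        rim = _circle(*hole.center_xy, hole.radius, rim_n)
        tris += [
            tuple((*p, H) for p in t)
            for t in _zip_loops(loop, rim, np.asarray(hole.center_xy))
        ]
        tris += _wall(rim, H - hole.depth, H, outward=False)   # recess wall
        tris += _fan(hole.center_xy, rim, H - hole.depth, up=True)  # recess floor
    vertices = np.array(tris, dtype=float).reshape(-1, 3)
    faces = np.arange(len(vertices)).reshape(-1, 3)
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=True)
    mesh.merge_vertices()
    mesh.fix_normals()
    return mesh


def export_stl(phantom: PhantomModel, path, n_seg: int = 96):
    """Write the phantom as a binary STL file and return the mesh."""
    mesh = phantom_mesh(phantom, n_seg=n_seg)
    mesh.export(path, file_type="stl")
    return mesh
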