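"""Printing-accuracy metrics for line, circle, and angle test structures.

Printability of an ink is scored by how faithfully simple single-layer
structures reproduce their CAD model.  Every score is normalized so that a
perfect print equals 1:

* normalized width      ``w_n = w / d_nozzle``
* normalized length     ``l_n = l / l_model``            (line only)
* normalized radii      ``r_n = (r_i + r_o) / (2 r_model)``  (circle)
* normalized angle      ``a_n = (a_i + a_o) / (2 a_model)``  (angle corners)

The radius and angle scores combine the inner and outer boundary of the
strand around the *midline* — the nozzle-center trajectory — into a single
number, so a symmetric strand of any width still scores exactly 1; only a
displaced or distorted path moves the score.

Pose is estimated from the data itself (principal axis for lines, fitted
center plus start marker for circles, skeleton vertex ordering for the angle
composite); no fiducials are required.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage import measure, morphology

from .imaging import Component, LabeledComponents

__all__ = [
    "CadTarget",
    "LineMetrics",
    "CircleMetrics",
    "VertexAngle",
    "AngleMetrics",
    "analyze_line",
    "analyze_circle",
    "analyze_angle",
    "fit_circle",
]


@dataclass(frozen=True)
class CadTarget:
    """Designed dimensions of a test structure.

    Defaults are the reference protocol: 30 mm line, 15 mm-radius circle with
    a 3 mm start-marker circle, a 30/45/60 degree angle composite, all printed
    through a 0.61 mm nozzle.
    """

    kind: str = "line"  # line | circle | angle
    line_length: float = 30.0  # mm
    circle_radius: float = 15.0  # mm
    marker_diameter: float = 3.0  # mm
    designed_angles: tuple[float, ...] = (30.0, 45.0, 60.0)  # degrees
    nozzle_diameter: float = 0.61  # mm

    def __post_init__(self) -> None:
        if self.kind not in ("line", "circle", "angle"):
            raise ValueError(f"unknown structure kind: {self.kind!r}")
        dims = (self.line_length, self.circle_radius, self.marker_diameter, self.nozzle_diameter)
        if not all(d > 0 for d in dims):
            raise ValueError("invalid CAD target: dimensions must be positive")
        if not all(0 < a < 180 for a in self.designed_angles):
            raise ValueError("invalid CAD target: angles must lie in (0, 180) degrees")


@dataclass(frozen=True)
class LineMetrics:
    width: float  # mm, mean over cross-sections in the middle third
    width_sd: float
    normalized_width: float
    length: float  # mm, material-covered path length
    normalized_length: float
    segment_count: int
    interrupted: bool


@dataclass(frozen=True)
class CircleMetrics:
    inner_radius: float  # mm
    outer_radius: float  # mm
    normalized_radii: float
    width_at_180: float  # mm
    normalized_width: float
    center: tuple[float, float]  # mm
    start_marker_angle: float  # degrees, image coords


@dataclass(frozen=True)
class VertexAngle:
    designed: float  # degrees
    inner: float
    outer: float
    normalized: float


@dataclass(frozen=True)
class AngleMetrics:
    vertices: tuple[VertexAngle, ...]
    widths: tuple[float, ...]  # mm, five probes along the strand
    width: float  # mm, mean of probes
    normalized_width: float


# --------------------------------------------------------------------------
# shared geometry helpers


def _principal_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and dominant direction (unit vector) of an (N, 2) point cloud."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    return c, vt[0]


def fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Geometric (orthogonal-distance) least-squares circle fit.

    Initialized with the algebraic Kasa fit, then refined by minimizing the
    orthogonal residuals ``|p - c| - r`` with Levenberg-Marquardt.  Stable on
    partial arcs, which matters for strands with small gaps.

    Returns ``(cx, cy, r)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("circle fit needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    (cx, cy, c0), *_ = np.linalg.lstsq(A, b, rcond=None)
    r0 = math.sqrt(max(c0 + cx**2 + cy**2, 1e-12))

    def resid(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    sol = optimize.least_squares(resid, x0=[cx, cy, r0], method="lm")
    return float(sol.x[0]), float(sol.x[1]), float(sol.x[2])


def _profile_width(
    pixel_mask: np.ndarray,
    ppm: float,
    point_mm: np.ndarray,
    normal: np.ndarray,
    half_len_mm: float,
    step_px: float = 0.25,
) -> float:
    """Foreground extent (mm) along a perpendicular cut through the strand.

    Samples the binary mask with bilinear interpolation along the normal
    direction and integrates the occupancy of the contiguous foreground run
    containing the probe point, which recovers the width with sub-pixel
    resolution.  Restricting to the central run keeps the cut from picking up
    a neighboring strand arm when the cross-section is taken inside a narrow
    wedge (e.g. near a 30 degree corner).
    """
    normal = normal / np.hypot(*normal)
    step_mm = step_px / ppm
    ts = np.arange(-half_len_mm, half_len_mm + step_mm, step_mm)
    xs = point_mm[0] + ts * normal[0]
    ys = point_mm[1] + ts * normal[1]
    samples = ndimage.map_coordinates(
        pixel_mask.astype(float), [ys * ppm, xs * ppm], order=1, mode="constant"
    )
    mid = samples.size // 2
    above = samples > 0.5
    if not above[mid]:
        return float(samples.sum() * step_mm)
    lo = mid
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = mid
    while hi < samples.size - 1 and above[hi + 1]:
        hi += 1
    # include the partial-coverage ramp just outside the run
    lo = max(0, lo - 3)
    hi = min(samples.size - 1, hi + 3)
    return float(samples[lo : hi + 1].sum() * step_mm)


# --------------------------------------------------------------------------
# line


def analyze_line(components: LabeledComponents, cad: CadTarget) -> LineMetrics:
    """Width, length, and continuity of a printed straight line.

    The principal axis of the largest component defines the line direction.
    Width is the mean foreground pixel count per cross-section perpendicular
    to that axis, averaged over the middle third of the designed length.
    Length is the material-covered path length: per segment, the extent along
    the axis minus one strand width to remove the two rounded end caps, so an
    ideal continuous print scores ``l_n = 1`` and interrupted prints score the
    fraction of the path actually covered.
    """
    if cad.kind != "line":
        raise ValueError("CAD target is not a line")
    ppm = components.px_per_mm
    main = components.largest
    rows, cols = np.nonzero(main.pixel_mask)
    pts = np.column_stack([cols, rows]) / ppm
    c0, axis = _principal_axis(pts)

    # components whose centroid lies in the corridor around the axis count as
    # line segments; anything far off-axis is ignored as unrelated material
    corridor = 3.0 * cad.nozzle_diameter
    segments: list[Component] = []
    for comp in components.components:
        d = np.array(comp.centroid_mm) - c0
        if abs(d[0] * axis[1] - d[1] * axis[0]) <= corridor:
            segments.append(comp)

    all_t = []
    seg_extents = []
    for comp in segments:
        r, c = np.nonzero(comp.pixel_mask)
        p = np.column_stack([c, r]) / ppm
        t = (p - c0) @ axis
        seg_extents.append((float(t.min()), float(t.max())))
        all_t.append(t)

    # width: bin foreground pixels of the corridor by axis coordinate in
    # 1-pixel bins; each bin's pixel count times the pixel size is the
    # cross-sectional width there
    t_main = np.concatenate(all_t)
    t_lo, t_hi = t_main.min(), t_main.max()
    t_mid = 0.5 * (t_lo + t_hi)
    win = cad.line_length / 6.0
    sel = (t_main >= t_mid - win) & (t_main <= t_mid + win)
    t_sel = t_main[sel]
    bin_w = 1.0 / ppm
    edges = np.arange(t_sel.min(), t_sel.max() + bin_w, bin_w)
    counts, _ = np.histogram(t_sel, bins=edges)
    widths_mm = counts[counts > 0] / ppm
    width = float(widths_mm.mean())
    width_sd = float(widths_mm.std(ddof=1)) if widths_mm.size > 1 else 0.0

    # material-covered length with per-segment end-cap correction
    length = float(sum(max(hi - lo - width, 0.0) for lo, hi in seg_extents))
    n_seg = len(segments)
    return LineMetrics(
        width=width,
        width_sd=width_sd,
        normalized_width=width / cad.nozzle_diameter,
        length=length,
        normalized_length=length / cad.line_length,
        segment_count=n_seg,
        interrupted=n_seg > 1,
    )


# --------------------------------------------------------------------------
# circle


def analyze_circle(components: LabeledComponents, cad: CadTarget) -> CircleMetrics:
    """Radii and width of a printed circle relative to the designed midline.

    The largest component must be annular (have an interior hole).  Geometric
    least-squares circles fitted to the hole boundary and the outer boundary
    give the inner radius ``r_i`` and outer radius ``r_o``; their mean is the
    recovered midline radius, and ``r_n = (r_i + r_o) / (2 r_model)``.  The
    strand width is evaluated over a 7.2 degree arc (2% of the circumference)
    diametrically opposite the start marker, as the mean difference between
    outer and inner boundary radius along rays from the fitted center.
    """
    if cad.kind != "circle":
        raise ValueError("CAD target is not a circle")
    annulus = components.largest
    if not annulus.holes:
        raise ValueError("no ring detected")
    hole = max(annulus.holes, key=lambda h: h.shape[0])
    cxi, cyi, r_i = fit_circle(hole)
    cxo, cyo, r_o = fit_circle(annulus.boundary)
    center = np.array([(cxi + cxo) / 2.0, (cyi + cyo) / 2.0])

    # start marker: the non-annulus component closest in size to the designed
    # marker diameter
    others = [c for c in components.components if c is not annulus]
    if others:
        def extent(c: Component) -> float:
            x0, y0, x1, y1 = c.bbox_mm
            return 0.5 * ((x1 - x0) + (y1 - y0))

        marker = min(others, key=lambda c: abs(extent(c) - cad.marker_diameter))
        dm = np.array(marker.centroid_mm) - center
        marker_angle = math.degrees(math.atan2(dm[1], dm[0]))
    else:
        warnings.warn("no start marker found; assuming angular position 0 degrees")
        marker_angle = 0.0

    # width opposite the marker: outer minus inner boundary radius over the arc
    arc_half = 3.6  # degrees; 2% of the circle
    probe = math.radians(marker_angle + 180.0)

    def radii_in_arc(boundary: np.ndarray) -> np.ndarray:
        d = boundary - center
        ang = np.arctan2(d[:, 1], d[:, 0])
        dev = np.degrees(np.angle(np.exp(1j * (ang - probe))))
        keep = np.abs(dev) <= arc_half
        return np.hypot(d[keep, 0], d[keep, 1])

    outer_r = radii_in_arc(annulus.boundary)
    inner_r = radii_in_arc(hole)
    if outer_r.size == 0 or inner_r.size == 0:
        raise ValueError("no ring detected")  # gap exactly at the probe arc
    width = float(outer_r.mean() - inner_r.mean())

    return CircleMetrics(
        inner_radius=r_i,
        outer_radius=r_o,
        normalized_radii=(r_i + r_o) / (2.0 * cad.circle_radius),
        width_at_180=width,
        normalized_width=width / cad.nozzle_diameter,
        center=(float(center[0]), float(center[1])),
        start_marker_angle=marker_angle,
    )


# --------------------------------------------------------------------------
# angle composite


def _ordered_skeleton_path(mask: np.ndarray) -> np.ndarray:
    """Skeletonize an open-strand mask and return the longest path, ordered.

    The skeleton of a stroked polyline is (up to small spurs) a tree; the
    tree diameter — the longest endpoint-to-endpoint walk — is taken as the
    centerline, which drops short corner spurs automatically.
    """
    skel = morphology.skeletonize(mask)
    rows, cols = np.nonzero(skel)
    if rows.size < 2:
        raise ValueError("no object detected")
    coords = np.column_stack([rows, cols])
    index = {tuple(p): i for i, p in enumerate(coords)}
    nbrs: list[list[int]] = [[] for _ in range(len(coords))]
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for i, (r, c) in enumerate(coords):
        for dr, dc in offs:
            j = index.get((r + dr, c + dc))
            if j is not None:
                nbrs[i].append(j)

    def farthest(start: int) -> tuple[int, dict[int, int]]:
        prev = {start: -1}
        frontier = [start]
        last = start
        while frontier:
            nxt = []
            for u in frontier:
                for v in nbrs[u]:
                    if v not in prev:
                        prev[v] = u
                        nxt.append(v)
            if nxt:
                last = nxt[-1]
            frontier = nxt
        return last, prev

    a, _ = farthest(0)
    b, prev = farthest(a)
    path = [b]
    while prev[path[-1]] != -1:
        path.append(prev[path[-1]])
    return coords[path[::-1]]


def _fit_direction(points: np.ndarray, toward: np.ndarray) -> np.ndarray:
    """Total-least-squares line direction, oriented along ``toward``."""
    _, d = _principal_axis(points)
    return d if float(d @ toward) >= 0 else -d


def _fit_direction_robust(points: np.ndarray, toward: np.ndarray) -> np.ndarray:
    """TLS line direction with iterative outlier trimming.

    Points from a rounded corner apex or a neighboring strand that slip into
    the selection lie far off the arm line; two rounds of refitting after
    dropping residuals beyond 2.5 robust standard deviations remove them.
    """
    pts = points
    d = _fit_direction(pts, toward)
    for _ in range(2):
        c = pts.mean(axis=0)
        res = (pts - c) @ np.array([-d[1], d[0]])
        mad = np.median(np.abs(res - np.median(res)))
        scale = max(1.4826 * float(mad), 1e-6)
        keep = np.abs(res - np.median(res)) <= 2.5 * scale
        if keep.sum() < 5 or keep.all():
            break
        pts = pts[keep]
        d = _fit_direction(pts, toward)
    return d


def analyze_angle(
    components: LabeledComponents,
    cad: CadTarget,
    apex_window: tuple[float, float] = (1.0, 5.0),
) -> AngleMetrics:
    """Corner angles and widths of the printed angle composite.

    The strand centerline is the skeleton's longest path; corners come from a
    polyline simplification of that path and are matched to the designed
    angles by their order along it.  Each corner angle is then measured twice
    on the traced boundary: once on the concave (inner) side and once on the
    convex (outer) side, by total-least-squares line fits to the boundary
    points of the two arms inside a window of ``apex_window`` nozzle diameters
    from the corner — the rounded apex itself is excluded.  The normalized
    angle is ``a_n = (a_i + a_o) / (2 a_model)``.

    Width is probed at five points along the centerline, away from corners
    and strand ends, by perpendicular cross-sections.
    """
    if cad.kind != "angle":
        raise ValueError("CAD target is not an angle composite")
    ppm = components.px_per_mm
    main = components.largest
    path_px = _ordered_skeleton_path(main.pixel_mask)
    path_mm = np.column_stack([path_px[:, 1], path_px[:, 0]]) / ppm

    # the skeleton forks inside wide round end caps; trim half a strand width
    # off both ends before looking for corners
    edt = ndimage.distance_transform_edt(main.pixel_mask)
    stroke_est = 4.0 * float(edt[main.pixel_mask].mean()) / ppm
    steps0 = np.hypot(*np.diff(path_mm, axis=0).T)
    arc0 = np.concatenate([[0.0], np.cumsum(steps0)])
    trim = 0.75 * stroke_est
    keep = (arc0 >= trim) & (arc0 <= arc0[-1] - trim)
    if keep.sum() >= 10:
        path_mm = path_mm[keep]

    # corner detection: simplify the centerline to a polyline
    tol_mm = max(2.0 / ppm, 0.75 * stroke_est)
    simplified = measure.approximate_polygon(path_mm, tolerance=tol_mm)
    vertices = simplified[1:-1]
    if len(vertices) != len(cad.designed_angles):
        raise ValueError(
            "structure/CAD mismatch: found "
            f"{len(vertices)} corners, expected {len(cad.designed_angles)}"
        )

    # the path may have been traversed in either direction; pick the designed
    # angle ordering (forward or reversed) that best matches the centerline
    def centerline_angle(i: int) -> float:
        e1 = simplified[i] - simplified[i + 1]
        e2 = simplified[i + 2] - simplified[i + 1]
        cosv = (e1 @ e2) / (np.hypot(*e1) * np.hypot(*e2))
        return math.degrees(math.acos(np.clip(cosv, -1.0, 1.0)))

    measured = np.array([centerline_angle(i) for i in range(len(vertices))])
    fwd = np.abs(measured - np.array(cad.designed_angles)).sum()
    rev = np.abs(measured - np.array(cad.designed_angles)[::-1]).sum()
    designed = list(cad.designed_angles) if fwd <= rev else list(cad.designed_angles)[::-1]

    # refine each corner: the polyline-simplification vertex sits on the
    # rounded skeleton apex and is pulled toward the concave side, so instead
    # fit the two centerline arm directions from skeleton points clear of the
    # apex and intersect those lines
    refined: list[np.ndarray] = []
    arm_vecs: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(len(vertices)):
        c0 = simplified[i + 1]
        fits = []
        for nb in (simplified[i], simplified[i + 2]):
            seg = nb - c0
            L = float(np.hypot(*seg))
            e = seg / L
            relp = path_mm - c0
            t = relp @ e
            perp = np.abs(relp[:, 0] * e[1] - relp[:, 1] * e[0])
            on = (t > 1.5 * stroke_est) & (t < 0.8 * L) & (perp < 0.75 * stroke_est)
            pts = path_mm[on]
            if pts.shape[0] >= 5:
                fits.append((pts.mean(axis=0), _fit_direction(pts - pts.mean(axis=0), toward=e)))
            else:
                fits.append((c0, e))
        (p1, g1), (p2, g2) = fits
        A = np.column_stack([g1, -g2])
        try:
            ts = np.linalg.solve(A, p2 - p1)
            c_ref = p1 + ts[0] * g1
        except np.linalg.LinAlgError:
            c_ref = c0
        if np.hypot(*(c_ref - c0)) > 2.0 * stroke_est:  # degenerate intersection
            c_ref = c0
        refined.append(c_ref)
        arm_vecs.append((g1, g2))

    d_n = cad.nozzle_diameter
    r_min, r_max = apex_window[0] * d_n, apex_window[1] * d_n
    boundary = main.boundary

    results = []
    for i, alpha_model in enumerate(designed):
        c = refined[i]
        e1, e2 = arm_vecs[i]
        d1, d2 = -e1, e2  # incoming / outgoing path directions
        turn = math.copysign(1.0, d1[0] * d2[1] - d1[1] * d2[0])

        rel = boundary - c
        dist = np.hypot(rel[:, 0], rel[:, 1])
        # apex exclusion per side: the inner boundary's own apex sits
        # (w/2)/sin(alpha/2) from the centerline corner, and optical blur fills
        # the narrow wedge just beyond it, so the inner fit window starts past
        # that point; the outer apex is the round join of radius w/2
        cos_a = float(np.clip(e1 @ e2, -1.0, 1.0))
        half_angle = max(math.acos(cos_a) / 2.0, math.radians(5.0))
        span = r_max - r_min
        lo_inner = (stroke_est / 2.0) / math.sin(half_angle) + 1.5 * d_n
        lo_outer = max(r_min, stroke_est / 2.0 + 0.5 * d_n)
        windows = {
            "inner": (dist >= lo_inner) & (dist <= lo_inner + span),
            "outer": (dist >= lo_outer) & (dist <= lo_outer + span),
        }
        angles = {}
        for side in ("inner", "outer"):
            window = windows[side]
            dirs = []
            for e, d in ((e1, d1), (e2, d2)):
                on_arm = window & (rel @ e > np.abs(rel @ (e2 if e is e1 else e1)))
                off = d[0] * rel[:, 1] - d[1] * rel[:, 0]  # cross(d, rel)
                want = turn if side == "inner" else -turn
                pts_sel = boundary[on_arm & (np.sign(off) == want)]
                if pts_sel.shape[0] < 5:
                    raise ValueError("structure/CAD mismatch: too few boundary points at corner")
                dirs.append(_fit_direction_robust(pts_sel, toward=e))
            cosv = float(np.clip(dirs[0] @ dirs[1], -1.0, 1.0))
            angles[side] = math.degrees(math.acos(cosv))
        results.append(
            VertexAngle(
                designed=alpha_model,
                inner=angles["inner"],
                outer=angles["outer"],
                normalized=(angles["inner"] + angles["outer"]) / (2.0 * alpha_model),
            )
        )
    if fwd > rev:
        results = results[::-1]

    # five width probes along the centerline, clear of corners and ends
    steps = np.hypot(*np.diff(path_mm, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(steps)])
    clear = np.ones(len(path_mm), dtype=bool)
    guard = 3.0 * d_n
    for v in vertices:
        clear &= np.hypot(path_mm[:, 0] - v[0], path_mm[:, 1] - v[1]) > guard
    clear &= (arclen > guard) & (arclen < arclen[-1] - guard)
    idx_clear = np.nonzero(clear)[0]
    if idx_clear.size < 5:
        raise ValueError("structure/CAD mismatch: centerline too short for width probes")
    probe_idx = idx_clear[np.linspace(0, idx_clear.size - 1, 5).astype(int)]
    widths = []
    for i in probe_idx:
        lo, hi = max(0, i - 5), min(len(path_mm) - 1, i + 5)
        tangent = path_mm[hi] - path_mm[lo]
        normal = np.array([-tangent[1], tangent[0]])
        widths.append(
            _profile_width(main.pixel_mask, ppm, path_mm[i], normal, half_len_mm=3.0 * d_n)
        )
    width = float(np.mean(widths))
    return AngleMetrics(
        vertices=tuple(results),
        widths=tuple(widths),
        width=width,
        normalized_width=width / d_n,
    )
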