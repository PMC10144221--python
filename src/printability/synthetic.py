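"""Ground-truthed synthetic inputs for every analysis stage.

Three generators emulate the laboratory's raw data with known truth:

* :func:`render_structure` draws a printed line / circle / angle-composite
  photograph: a constant-width stroke with round caps and joins, anti-aliased
  by area coverage, then Gaussian blur, a linear illumination gradient, and
  additive Gaussian noise — a bright strand on a dark background, as produced
  by a monochrome camera over a black stage (52 px/mm in the reference setup).
  Defects (gaps, bulges) and an arbitrary pose can be injected.
* :func:`simulate_viscosity` samples power-law flow sweeps with multiplicative
  lognormal noise, mimicking replicate rheometer runs.
* :func:`simulate_cytometry` draws live / dead / debris / agglomerate event
  mixtures from lognormal clusters in scatter and fluorescence channels,
  mimicking a calcein-AM / propidium-iodide stained sample.

Every artifact ships with a machine-readable :class:`GroundTruth` so recovery
tests compare against the generating parameters, never against hard-coded
numbers.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cytometry import EventTable
from .imaging import GrayImage
from .metrics import CadTarget
from .rheology import PowerLawModel, ViscosityCurve

__all__ = [
    "RenderSpec",
    "GroundTruth",
    "render_structure",
    "simulate_viscosity",
    "simulate_cytometry",
    "CYTO_CLUSTERS",
]


# --------------------------------------------------------------------------
# path primitives (physical mm coordinates, image convention: y downward)


@dataclass(frozen=True)
class _Segment:
    p0: np.ndarray
    p1: np.ndarray

    @property
    def length(self) -> float:
        return float(np.hypot(*(self.p1 - self.p0)))

    def cut(self, s0: float, s1: float) -> list["_Segment"]:
        L = self.length
        d = (self.p1 - self.p0) / L
        out = []
        if s0 > 1e-9:
            out.append(_Segment(self.p0, self.p0 + d * min(s0, L)))
        if s1 < L - 1e-9:
            out.append(_Segment(self.p0 + d * s1, self.p1))
        return out

    def distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        d = self.p1 - self.p0
        L2 = float(d @ d)
        t = ((x - self.p0[0]) * d[0] + (y - self.p0[1]) * d[1]) / L2
        t = np.clip(t, 0.0, 1.0)
        return np.hypot(x - (self.p0[0] + t * d[0]), y - (self.p0[1] + t * d[1]))

    def transform(self, rot: np.ndarray, shift: np.ndarray) -> "_Segment":
        return _Segment(rot @ self.p0 + shift, rot @ self.p1 + shift)

    def sample(self, step: float = 0.5) -> np.ndarray:
        n = max(2, int(self.length / step) + 1)
        t = np.linspace(0, 1, n)[:, None]
        return self.p0 + t * (self.p1 - self.p0)


@dataclass(frozen=True)
class _Arc:
    center: np.ndarray
    radius: float
    a0: float  # start angle, radians
    sweep: float  # positive sweep, radians

    @property
    def length(self) -> float:
        return self.radius * self.sweep

    def cut(self, s0: float, s1: float) -> list["_Arc"]:
        L = self.length
        out = []
        if s0 > 1e-9:
            out.append(_Arc(self.center, self.radius, self.a0, min(s0, L) / self.radius))
        if s1 < L - 1e-9:
            out.append(
                _Arc(self.center, self.radius, self.a0 + s1 / self.radius, (L - s1) / self.radius)
            )
        return out

    def distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx = x - self.center[0]
        dy = y - self.center[1]
        rho = np.hypot(dx, dy)
        ang = np.arctan2(dy, dx)
        rel = np.mod(ang - self.a0, 2 * math.pi)
        on_arc = rel <= self.sweep
        d_radial = np.abs(rho - self.radius)
        e0 = self.center + self.radius * np.array([math.cos(self.a0), math.sin(self.a0)])
        a1 = self.a0 + self.sweep
        e1 = self.center + self.radius * np.array([math.cos(a1), math.sin(a1)])
        d_ends = np.minimum(np.hypot(x - e0[0], y - e0[1]), np.hypot(x - e1[0], y - e1[1]))
        return np.where(on_arc, d_radial, d_ends)

    def transform(self, rot: np.ndarray, shift: np.ndarray) -> "_Arc":
        # rotation matrix rot = R(theta); rotating an arc shifts its angles
        theta = math.atan2(rot[1, 0], rot[0, 0])
        return _Arc(rot @ self.center + shift, self.radius, self.a0 + theta, self.sweep)

    def sample(self, step: float = 0.5) -> np.ndarray:
        n = max(3, int(self.length / step) + 1)
        a = self.a0 + np.linspace(0, self.sweep, n)
        return self.center + self.radius * np.column_stack([np.cos(a), np.sin(a)])


@dataclass(frozen=True)
class _Disc:
    center: np.ndarray
    radius: float

    def distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.hypot(x - self.center[0], y - self.center[1])

    def transform(self, rot: np.ndarray, shift: np.ndarray) -> "_Disc":
        return _Disc(rot @ self.center + shift, self.radius)


# --------------------------------------------------------------------------
# specs and ground truth


@dataclass(frozen=True)
class RenderSpec:
    """Parameters of one synthetic structure photograph."""

    cad: CadTarget = field(default_factory=CadTarget)
    stroke_width: float = 0.61  # mm
    px_per_mm: float = 52.0
    foreground: float = 200.0  # 8-bit level of the strand
    background: float = 20.0  # 8-bit level of the dark stage
    blur_sigma: float = 0.05  # mm, optical blur
    noise_sigma: float = 5.0  # intensity units, additive Gaussian
    illumination_gradient: float = 20.0  # intensity units across the frame
    gaps: tuple[tuple[float, float], ...] = ()  # (position mm, length mm)
    bulges: tuple[tuple[float, float], ...] = ()  # (position mm, extra width mm)
    rotation: float = 0.0  # degrees
    translation: tuple[float, float] = (0.0, 0.0)  # mm
    seed: int = 0
    margin_mm: float = 2.5
    angle_arm_length: float = 10.0  # mm, segment length of the angle composite
    marker_angle: float = 0.0  # degrees, start-marker position on the circle

    def __post_init__(self) -> None:
        if not self.stroke_width > 0:
            raise ValueError("invalid spec: stroke width must be positive")
        if not (0 <= self.background < self.foreground <= 255):
            raise ValueError("invalid spec: need 0 <= background < foreground <= 255")


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of a synthetic artifact, for recovery tests."""

    kind: str = ""
    stroke_width_mm: float = math.nan
    path_length_mm: float = math.nan  # designed path length, before defects
    covered_length_mm: float = math.nan  # path length actually covered
    centerline_radius_mm: float = math.nan
    vertex_angles_deg: tuple[float, ...] = ()
    gap_count: int = 0
    marker_angle_deg: float = math.nan
    viability: float = math.nan
    debris_fraction: float = math.nan
    agglomerate_fraction: float = math.nan
    labels: tuple[str, ...] = ()
    n: float = math.nan  # power-law truth
    K: float = math.nan
    seed: int = 0

    def to_json(self, path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


# --------------------------------------------------------------------------
# structure rendering


def _build_path(spec: RenderSpec) -> tuple[list, list, float]:
    """Main-path primitives, extra primitives (marker), designed path length."""
    cad = spec.cad
    if cad.kind == "line":
        main = [_Segment(np.array([0.0, 0.0]), np.array([cad.line_length, 0.0]))]
        extra: list = []
        length = cad.line_length
    elif cad.kind == "circle":
        r = cad.circle_radius
        main = [_Arc(np.array([0.0, 0.0]), r, 0.0, 2 * math.pi)]
        # start marker: a small stroked circle placed just outside the ring at
        # the angular start position
        rm = cad.marker_diameter / 2.0
        dist = r + spec.stroke_width + rm + 0.5
        am = math.radians(spec.marker_angle)
        mc = dist * np.array([math.cos(am), math.sin(am)])
        extra = [_Arc(mc, rm, 0.0, 2 * math.pi)]
        length = 2 * math.pi * r
    elif cad.kind == "angle":
        L = spec.angle_arm_length
        theta = 0.0
        v = np.array([0.0, 0.0])
        main = []
        sign = 1.0
        for alpha in cad.designed_angles:
            nxt = v + L * np.array([math.cos(theta), math.sin(theta)])
            main.append(_Segment(v, nxt))
            v = nxt
            theta += sign * math.radians(180.0 - alpha)
            sign = -sign
        main.append(_Segment(v, v + L * np.array([math.cos(theta), math.sin(theta)])))
        extra = []
        length = L * (len(cad.designed_angles) + 1)
    else:  # pragma: no cover - CadTarget already validates
        raise ValueError(f"unknown structure kind: {cad.kind!r}")
    return main, extra, length


def _apply_gaps(main: list, gaps) -> tuple[list, float]:
    """Cut (position, length) windows out of the main path; return covered length."""
    total = sum(p.length for p in main)
    covered = total
    for pos, glen in gaps:
        covered -= min(glen, max(total - pos, 0.0))
        new = []
        s = 0.0
        for prim in main:
            L = prim.length
            lo, hi = pos - s, pos + glen - s
            if hi <= 0 or lo >= L:
                new.append(prim)
            else:
                new.extend(prim.cut(max(lo, 0.0), min(hi, L)))
            s += L
        main = new
    return main, covered


def _point_at(main_uncut: list, s: float) -> np.ndarray:
    acc = 0.0
    for prim in main_uncut:
        if s <= acc + prim.length:
            pts = prim.sample(step=0.05)
            steps = np.hypot(*np.diff(pts, axis=0).T)
            arc = np.concatenate([[0.0], np.cumsum(steps)])
            return pts[int(np.searchsorted(arc, s - acc).clip(0, len(pts) - 1))]
        acc += prim.length
    return prim.sample(step=0.05)[-1]


def render_structure(spec: RenderSpec) -> tuple[GrayImage, GroundTruth]:
    """Rasterize a printed-structure photograph with known ground truth.

    The stroked path is rendered by an exact distance field (round caps and
    joins come for free), converted to area-coverage alpha over one pixel, and
    degraded with Gaussian blur, a linear illumination gradient, and additive
    Gaussian noise.  Deterministic for a fixed ``seed``.

    Raises
    ------
    ValueError
        ``"resolution too low"`` if the stroke spans fewer than 2 pixels.
    """
    ppm = spec.px_per_mm
    if spec.stroke_width * ppm < 2.0:
        raise ValueError("resolution too low: stroke spans fewer than 2 pixels")
    main0, extra, designed_len = _build_path(spec)
    main, covered = _apply_gaps(main0, spec.gaps)
    discs = [
        _Disc(_point_at(main0, pos), spec.stroke_width / 2.0 + ew / 2.0)
        for pos, ew in spec.bulges
    ]

    th = math.radians(spec.rotation)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    shift = np.asarray(spec.translation, dtype=float)
    prims = [p.transform(rot, shift) for p in main + extra]
    discs = [d.transform(rot, shift) for d in discs]

    samples = [p.sample() for p in prims] + [
        d.center[None, :] + d.radius * np.array([[1, 0], [-1, 0], [0, 1], [0, -1]])
        for d in discs
    ]
    pts = np.vstack(samples)
    pad = spec.stroke_width / 2.0 + spec.margin_mm
    xmin, ymin = pts.min(axis=0) - pad
    xmax, ymax = pts.max(axis=0) + pad
    origin = np.array([xmin, ymin])
    prims = [p.transform(np.eye(2), -origin) for p in prims]
    discs = [d.transform(np.eye(2), -origin) for d in discs]
    w_px = int(math.ceil((xmax - xmin) * ppm)) + 1
    h_px = int(math.ceil((ymax - ymin) * ppm)) + 1

    cols, rows = np.meshgrid(np.arange(w_px), np.arange(h_px))
    x = cols / ppm
    y = rows / ppm
    dist = np.full(x.shape, np.inf)
    for p in prims:
        np.minimum(dist, p.distance(x, y), out=dist)
    alpha = np.clip(0.5 + (spec.stroke_width / 2.0 - dist) * ppm, 0.0, 1.0)
    for d in discs:
        a = np.clip(0.5 + (d.radius - d.distance(x, y)) * ppm, 0.0, 1.0)
        np.maximum(alpha, a, out=alpha)
    if spec.blur_sigma > 0:
        alpha = ndimage.gaussian_filter(alpha, sigma=spec.blur_sigma * ppm)

    img = spec.background + (spec.foreground - spec.background) * alpha
    if spec.illumination_gradient:
        img = img + np.linspace(
            -spec.illumination_gradient / 2.0, spec.illumination_gradient / 2.0, w_px
        )[None, :]
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        kind=spec.cad.kind,
        stroke_width_mm=spec.stroke_width,
        path_length_mm=designed_len,
        covered_length_mm=covered,
        centerline_radius_mm=spec.cad.circle_radius if spec.cad.kind == "circle" else math.nan,
        vertex_angles_deg=spec.cad.designed_angles if spec.cad.kind == "angle" else (),
        gap_count=len(spec.gaps),
        marker_angle_deg=(spec.marker_angle + spec.rotation) % 360.0
        if spec.cad.kind == "circle"
        else math.nan,
        seed=spec.seed,
    )
    return GrayImage(pixels=img, px_per_mm=ppm), truth


# --------------------------------------------------------------------------
# rheometer sweeps


def simulate_viscosity(
    model: PowerLawModel,
    shear_range: tuple[float, float] = (0.1, 1000.0),
    points: int = 30,
    noise_cv: float = 0.05,
    replicates: int = 1,
    seed: int = 0,
) -> tuple[list[ViscosityCurve], GroundTruth]:
    """Log-spaced flow sweeps from a power-law model with lognormal noise.

    Each viscosity is ``K * gamma_dot**(n-1)`` times a unit-mean lognormal
    factor with coefficient of variation ``noise_cv``.
    """
    if points < 3:
        raise ValueError("insufficient data: need at least 3 points")
    if noise_cv < 0:
        raise ValueError("invalid noise: noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    gamma = np.logspace(math.log10(shear_range[0]), math.log10(shear_range[1]), points)
    clean = model.K * gamma ** (model.n - 1.0)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    curves = []
    for r in range(replicates):
        factor = (
            np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=points)) if sigma > 0 else 1.0
        )
        curves.append(
            ViscosityCurve(
                shear_rates=gamma, viscosities=clean * factor, replicate_label=f"rep{r + 1}"
            )
        )
    truth = GroundTruth(kind="viscosity", n=model.n, K=model.K, seed=seed)
    return curves, truth


# --------------------------------------------------------------------------
# flow-cytometry event mixtures

# lognormal cluster parameters (median, CV) per channel, in instrument-like
# arbitrary units; live cells are green(calcein)-dominant, dead cells
# red(PI)-dominant, debris sits at low scatter and agglomerates at very high
# scatter
CYTO_CLUSTERS: dict[str, dict[str, tuple[float, float]]] = {
    "live": {"fsc": (5e4, 0.25), "ssc": (3e4, 0.30), "green": (8e3, 0.50), "red": (60, 0.80)},
    "dead": {"fsc": (4e4, 0.30), "ssc": (3.5e4, 0.30), "green": (70, 0.80), "red": (6e3, 0.50)},
    "debris": {"fsc": (3e3, 0.60), "ssc": (2e3, 0.60), "green": (30, 1.00), "red": (40, 1.00)},
    "agglomerate": {
        "fsc": (3e5, 0.30),
        "ssc": (2.5e5, 0.30),
        "green": (1e4, 1.00),
        "red": (3e3, 1.50),
    },
}


def simulate_cytometry(
    n_events: int,
    viability: float = 0.95,
    debris_fraction: float = 0.1,
    agglomerate_fraction: float = 0.02,
    seed: int = 0,
) -> tuple[EventTable, GroundTruth]:
    """Draw a live/dead/debris/agglomerate event mixture with known labels.

    Cell events (the non-debris, non-agglomerate remainder) are live with
    probability ``viability``.  Channels are lognormal per cluster with the
    parameters in :data:`CYTO_CLUSTERS`.
    """
    if n_events <= 0:
        raise ValueError("invalid count: n_events must be positive")
    for f in (viability, debris_fraction, agglomerate_fraction):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    if debris_fraction + agglomerate_fraction >= 1.0:
        raise ValueError("debris and agglomerate fractions must sum below 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n_events)
    labels = np.where(
        u < debris_fraction,
        "debris",
        np.where(
            u < debris_fraction + agglomerate_fraction,
            "agglomerate",
            np.where(rng.random(n_events) < viability, "live", "dead"),
        ),
    )
    data = {ch: np.empty(n_events) for ch in ("fsc", "ssc", "green", "red")}
    for lab, params in CYTO_CLUSTERS.items():
        idx = labels == lab
        k = int(idx.sum())
        if k == 0:
            continue
        for ch, (median, cv) in params.items():
            s = math.sqrt(math.log(1.0 + cv**2))
            data[ch][idx] = median * np.exp(rng.normal(0.0, s, size=k))
    table = EventTable(data=pd.DataFrame(data))
    truth = GroundTruth(
        kind="cytometry",
        viability=viability,
        debris_fraction=debris_fraction,
        agglomerate_fraction=agglomerate_fraction,
        labels=tuple(labels),
        seed=seed,
    )
    return table, truth
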