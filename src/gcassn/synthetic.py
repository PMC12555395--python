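"""Procedural labeled plant point clouds for training and evaluation.

The generator emulates the structure of scanned greenhouse plants: a curved
main stem with branches (cubic-spline axes sweeping a circular, slightly
tapering cross-section), bent elliptical leaves attached along the stems,
and an optional soil plane.  It deliberately reproduces the pathologies
that make real plant scans hard to segment:

* stem-leaf junctions with smooth geometric transitions (labels inside a
  configurable blend zone follow the nearest organ surface, producing
  ambiguous boundary points);
* uneven point density (an exponential height gradient re-weights the
  surface sampling toward the canopy);
* surface jitter mimicking scanner noise.

Classes are stem=0, leaf=1, soil=2.  All geometry units are relative to the
stem height (about 1.0), matching unit-sphere-normalized clouds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .io import LabeledCloud

__all__ = [
    "StemSpec", "LeafSpec", "SoilSpec", "PlantSpec", "PlantGeometry",
    "generate_plant", "generate_plant_geometry", "generate_dataset",
]

STEM, LEAF, SOIL = 0, 1, 2


@dataclass(frozen=True)
class StemSpec:
    height: float = 1.0
    radius: float = 0.02
    curvature: float = 0.12          # lateral wander amplitude of the axis
    n_branches: int = 2
    branch_angle: tuple[float, float] = (25.0, 55.0)   # degrees from parent


@dataclass(frozen=True)
class LeafSpec:
    count: int = 6
    length: float = 0.35
    width: float = 0.18
    bend: float = 0.35               # parabolic out-of-plane bend amplitude
    attachment_jitter: float = 0.01
    petiole_frac: float = 0.25       # petiole length / blade length
    petiole_radius: float = 0.005


@dataclass(frozen=True)
class SoilSpec:
    present: bool = True
    extent: float = 1.0
    thickness: float = 0.02


@dataclass(frozen=True)
class PlantSpec:
    n_points: int = 2048
    stem: StemSpec = field(default_factory=StemSpec)
    leaves: LeafSpec = field(default_factory=LeafSpec)
    soil: SoilSpec = field(default_factory=SoilSpec)
    density_gradient: float = 0.0    # >0 samples the canopy more densely
    junction_blend: float = 0.08     # blend-zone radius / leaf length
    surface_jitter: float = 0.002    # scanner-noise std on surfaces
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 64:
            raise ValueError("n_points must be at least 64")
        if self.stem.height <= 0 or self.stem.radius <= 0:
            raise ValueError("stem dimensions must be positive")
        if self.leaves.count > 0 and (self.leaves.length <= 0 or
                                      self.leaves.width <= 0):
            raise ValueError("leaves must have positive area")
        if self.density_gradient < 0 or not 0 <= self.junction_blend <= 1:
            raise ValueError("invalid density_gradient or junction_blend")


@dataclass
class PlantGeometry:
    """Generating surfaces, kept so labels can be audited geometrically."""

    stem_axes: list[np.ndarray]        # dense (M, 3) polylines per stem piece
    stem_radii: list[float]            # max cross-section radius per piece
    leaf_attachments: np.ndarray       # (n_leaves, 3) attachment points
    reference_points: np.ndarray       # dense noise-free surface samples
    reference_class: np.ndarray        # organ class per reference point


def _orthonormal_frame(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = tangent / np.linalg.norm(tangent)
    helper = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else \
        np.array([0.0, 1.0, 0.0])
    n1 = np.cross(t, helper)
    n1 /= np.linalg.norm(n1)
    return n1, np.cross(t, n1)


class _StemPiece:
    """A spline axis swept by a tapering circular cross-section."""

    def __init__(self, control: np.ndarray, radius: float, taper: float = 0.4):
        u = np.linspace(0.0, 1.0, len(control))
        self.spline = CubicSpline(u, control, axis=0)
        self.radius = radius
        self.taper = taper
        seg = np.diff(self.spline(np.linspace(0, 1, 128)), axis=0)
        self.length = float(np.linalg.norm(seg, axis=1).sum())

    def point(self, u):
        return self.spline(u)

    def tangent(self, u):
        return self.spline(u, 1)

    def r(self, u):
        return self.radius * (1.0 - self.taper * np.asarray(u))

    @property
    def area(self) -> float:
        return 2.0 * np.pi * self.radius * (1.0 - self.taper / 2.0) * self.length

    def sample_surface(self, n: int, rng: np.random.Generator,
                       jitter: float) -> np.ndarray:
        u = rng.random(n)
        theta = rng.random(n) * 2.0 * np.pi
        pts = np.empty((n, 3))
        for i in range(n):
            c = self.point(u[i])
            n1, n2 = _orthonormal_frame(self.tangent(u[i]))
            pts[i] = c + self.r(u[i]) * (np.cos(theta[i]) * n1 +
                                         np.sin(theta[i]) * n2)
        return pts + rng.normal(0.0, jitter, pts.shape)

    def polyline(self, m: int = 96) -> np.ndarray:
        return self.spline(np.linspace(0, 1, m))


class _Leaf:
    """A petiole tube plus a parabolically bent elliptical blade.

    The blade is displaced from the stem by the petiole, as on real plants;
    the petiole itself is a thin tube carrying the leaf label, which is the
    geometrically ambiguous stem-to-leaf transition the junction blend zone
    then exercises.
    """

    def __init__(self, attach: np.ndarray, e1: np.ndarray, e2: np.ndarray,
                 e3: np.ndarray, length: float, width: float, bend: float,
                 petiole_frac: float, petiole_radius: float):
        self.attach = attach
        self.e1, self.e2, self.e3 = e1, e2, e3
        self.length, self.width, self.bend = length, width, bend
        self.petiole_len = petiole_frac * length
        self.petiole_radius = petiole_radius

    def surface(self, s: np.ndarray, w: np.ndarray) -> np.ndarray:
        # s in [0,1] along the midrib, w in [-1,1] across; (s,w) from a disk
        # so the planform is an ellipse with area-uniform sampling
        half_w = 0.5 * self.width
        return (self.attach[None, :]
                + np.outer(self.petiole_len + self.length * s, self.e1)
                + np.outer(half_w * w, self.e2)
                + np.outer(self.bend * self.length * s ** 2, self.e3))

    @property
    def blade_area(self) -> float:
        return np.pi * (self.length / 2.0) * (self.width / 2.0)

    @property
    def petiole_area(self) -> float:
        return 2.0 * np.pi * self.petiole_radius * self.petiole_len

    @property
    def area(self) -> float:
        return self.blade_area + self.petiole_area

    def sample_surface(self, n: int, rng: np.random.Generator,
                       jitter: float) -> np.ndarray:
        n_pet = int(round(n * self.petiole_area / self.area))
        pts = []
        if n_pet:
            t = rng.random(n_pet)
            theta = rng.random(n_pet) * 2.0 * np.pi
            n1, n2 = _orthonormal_frame(self.e1)
            pts.append(self.attach[None, :]
                       + np.outer(t * self.petiole_len, self.e1)
                       + self.petiole_radius * (np.outer(np.cos(theta), n1)
                                                + np.outer(np.sin(theta), n2)))
        n_blade = n - n_pet
        if n_blade:
            r = np.sqrt(rng.random(n_blade))
            phi = rng.random(n_blade) * 2.0 * np.pi
            s = (r * np.cos(phi) + 1.0) / 2.0
            w = r * np.sin(phi)
            pts.append(self.surface(s, w))
        out = np.vstack(pts)
        return out + rng.normal(0.0, jitter, out.shape)


def _build_geometry(spec: PlantSpec, rng: np.random.Generator):
    stem = spec.stem
    # main axis: vertical rise with a smooth random lateral wander
    n_ctrl = 6
    z = np.linspace(0.0, stem.height, n_ctrl)
    wander = np.cumsum(rng.normal(0.0, 1.0, (n_ctrl, 2)), axis=0)
    wander -= wander[0]
    peak = np.abs(wander).max()
    if peak > 0:
        wander *= stem.curvature * stem.height / peak
    main = _StemPiece(np.column_stack([wander, z]), stem.radius)
    pieces = [main]
    for _ in range(stem.n_branches):
        u0 = rng.uniform(0.35, 0.85)
        start = main.point(u0)
        t = main.tangent(u0)
        t = t / np.linalg.norm(t)
        n1, n2 = _orthonormal_frame(t)
        ang = np.deg2rad(rng.uniform(*stem.branch_angle))
        azim = rng.uniform(0, 2 * np.pi)
        direction = (np.cos(ang) * t +
                     np.sin(ang) * (np.cos(azim) * n1 + np.sin(azim) * n2))
        length = stem.height * rng.uniform(0.25, 0.45)
        n_ctrl_b = 4
        s = np.linspace(0, 1, n_ctrl_b)
        drift = np.cumsum(rng.normal(0.0, 1.0, (n_ctrl_b, 3)), axis=0)
        drift -= drift[0]
        peak_b = np.abs(drift).max()
        if peak_b > 0:
            drift *= 0.5 * stem.curvature * length / peak_b
        ctrl = start[None, :] + np.outer(s * length, direction) + drift
        pieces.append(_StemPiece(ctrl, stem.radius * 0.6))

    leaves = []
    lf = spec.leaves
    for _ in range(lf.count):
        piece = pieces[rng.integers(len(pieces))]
        u0 = rng.uniform(0.3, 0.95)
        t = piece.tangent(u0)
        t = t / np.linalg.norm(t)
        n1, n2 = _orthonormal_frame(t)
        azim = rng.uniform(0, 2 * np.pi)
        outward = np.cos(azim) * n1 + np.sin(azim) * n2
        elev = np.deg2rad(rng.uniform(15.0, 60.0))
        e1 = np.cos(elev) * outward + np.sin(elev) * np.array([0, 0, 1.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(e1, np.array([0, 0, 1.0]))
        if np.linalg.norm(e2) < 1e-8:
            e2 = n2
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        attach = (piece.point(u0) + piece.r(u0) * outward +
                  rng.normal(0.0, lf.attachment_jitter, 3))
        leaves.append(_Leaf(attach, e1, e2, e3, lf.length, lf.width,
                            lf.bend, lf.petiole_frac, lf.petiole_radius))
    return pieces, leaves


def _sample_soil(spec: SoilSpec, n: int, rng: np.random.Generator,
                 jitter: float) -> np.ndarray:
    xy = rng.uniform(-spec.extent / 2.0, spec.extent / 2.0, (n, 2))
    z = rng.uniform(0.0, spec.thickness, n)
    return np.column_stack([xy, z]) + rng.normal(0.0, jitter, (n, 3))


def generate_plant_geometry(spec: PlantSpec) -> tuple[LabeledCloud, PlantGeometry]:
    """Generate a plant and return it with its generating geometry."""
    rng = np.random.default_rng(spec.seed)
    pieces, leaves = _build_geometry(spec, rng)

    organs: list[tuple[int, object, float]] = \
        [(STEM, p, p.area) for p in pieces] + \
        [(LEAF, leaf, leaf.area) for leaf in leaves]
    if spec.soil.present:
        organs.append((SOIL, spec.soil, spec.soil.extent ** 2))

    # oversample area-proportionally, then thin by the density gradient
    pool_size = max(2 * spec.n_points, spec.n_points + 256)
    areas = np.array([a for _, _, a in organs])
    counts = np.maximum(
        np.round(pool_size * areas / areas.sum()).astype(int), 4)
    chunks, chunk_labels = [], []
    for (cls, organ, _), cnt in zip(organs, counts):
        if cls == SOIL:
            pts = _sample_soil(organ, cnt, rng, spec.surface_jitter)
        else:
            pts = organ.sample_surface(cnt, rng, spec.surface_jitter)
        chunks.append(pts)
        chunk_labels.append(np.full(cnt, cls, dtype=np.int64))
    pool = np.vstack(chunks)
    pool_labels = np.concatenate(chunk_labels)

    height = max(spec.stem.height, 1e-9)
    h_norm = np.clip(pool[:, 2] / height, 0.0, 1.0)
    w = np.exp(spec.density_gradient * h_norm)
    w /= w.sum()
    idx = rng.choice(len(pool), size=spec.n_points, replace=False, p=w)
    # keep every organ class represented even under aggressive thinning
    for cls in np.unique(pool_labels):
        if cls not in pool_labels[idx]:
            donor = np.flatnonzero(pool_labels == cls)[0]
            idx[rng.integers(spec.n_points)] = donor
    coords = pool[idx]
    labels = pool_labels[idx].copy()

    # reference (noise-free) surfaces for junction blending and for auditing
    ref_rng = np.random.default_rng(spec.seed + 10_007)
    ref_chunks, ref_cls = [], []
    for cls, organ, _ in organs:
        if cls == SOIL:
            pts = _sample_soil(organ, 600, ref_rng, 0.0)
        else:
            pts = organ.sample_surface(600, ref_rng, 0.0)
        ref_chunks.append(pts)
        ref_cls.append(np.full(len(pts), cls, dtype=np.int64))
    reference = np.vstack(ref_chunks)
    reference_class = np.concatenate(ref_cls)

    attachments = (np.array([leaf.attach for leaf in leaves])
                   if leaves else np.zeros((0, 3)))
    if len(attachments) and spec.junction_blend > 0:
        blend_radius = spec.junction_blend * spec.leaves.length
        near_junction = cKDTree(attachments).query(coords)[0] < blend_radius
        if near_junction.any():
            tree = cKDTree(reference)
            _, nearest = tree.query(coords[near_junction])
            labels[near_junction] = reference_class[nearest]

    geometry = PlantGeometry(
        stem_axes=[p.polyline() for p in pieces],
        stem_radii=[p.radius for p in pieces],
        leaf_attachments=attachments,
        reference_points=reference,
        reference_class=reference_class)
    cloud = LabeledCloud(coords, labels, source_id=f"synthetic:{spec.seed}")
    return cloud, geometry


def generate_plant(spec: PlantSpec) -> LabeledCloud:
    """Generate one labeled plant cloud (deterministic per spec/seed)."""
    return generate_plant_geometry(spec)[0]


def generate_dataset(spec_template: PlantSpec, n_plants: int, seed: int,
                     variation: float = 0.15) -> list[LabeledCloud]:
    """Draw ``n_plants`` plants by jittering the template's continuous
    parameters by +-``variation`` (relative) with per-plant derived seeds."""
    if n_plants < 1:
        raise ValueError("n_plants must be positive")
    if variation < 0:
        raise ValueError("variation must be non-negative")
    rng = np.random.default_rng(seed)
    clouds = []
    for i in range(n_plants):
        def jitter(v: float) -> float:
            return float(v * (1.0 + rng.uniform(-variation, variation)))

        st = spec_template.stem
        lf = spec_template.leaves
        spec = replace(
            spec_template,
            stem=replace(st, height=jitter(st.height), radius=jitter(st.radius),
                         curvature=jitter(st.curvature)),
            leaves=replace(lf, length=jitter(lf.length), width=jitter(lf.width),
                           bend=jitter(lf.bend)),
            seed=int(rng.integers(2 ** 31)))
        clouds.append(generate_plant(spec))
    return clouds
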