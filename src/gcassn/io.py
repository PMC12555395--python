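"""Reading, writing and preparing labeled plant point clouds.

Clouds arrive as whitespace-separated ``x y z label`` text (the convention
of the public plant phenotyping datasets, which code stems as 0, leaves as
1 and soil as 3) or as ASCII PLY with a per-vertex ``label`` property.
Raw file label codes are remapped to contiguous internal ids 0..P-1 so they
can serve directly as class indices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "LabeledCloud", "LabelMap", "DatasetSplit", "PLANT_LABEL_MAP",
    "read_labeled_cloud", "write_labeled_cloud", "random_sample",
    "normalize_cloud", "split_dataset",
]


@dataclass
class LabeledCloud:
    """An unordered set of 3D points with optional per-point organ labels."""

    coords: np.ndarray                    # (N, 3) float
    labels: np.ndarray | None = None      # (N,) int or None
    source_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an N x 3 matrix")
        if self.coords.shape[0] < 1:
            raise ValueError("a cloud needs at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.coords.shape[0],):
                raise ValueError("labels must be a length-N vector")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class LabelMap:
    """Injective map from raw file label codes to contiguous class ids."""

    raw_to_internal: dict[int, int]
    class_names: tuple[str, ...]

    def __post_init__(self):
        ids = sorted(self.raw_to_internal.values())
        if ids != list(range(len(ids))):
            raise ValueError("internal ids must be contiguous 0..P-1")
        if len(set(self.raw_to_internal)) != len(ids):
            raise ValueError("raw-to-internal mapping must be injective")
        if len(self.class_names) != len(ids):
            raise ValueError("one class name per internal id")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def apply(self, raw: np.ndarray) -> np.ndarray:
        out = np.empty(len(raw), dtype=np.int64)
        for i, code in enumerate(np.asarray(raw, dtype=np.int64)):
            try:
                out[i] = self.raw_to_internal[int(code)]
            except KeyError:
                raise ValueError(f"unknown label code {code} at point {i}") from None
        return out

    def invert(self, internal: np.ndarray) -> np.ndarray:
        inv = {v: k for k, v in self.raw_to_internal.items()}
        return np.array([inv[int(c)] for c in internal], dtype=np.int64)


#: Dataset convention: stem=0, leaf=1, soil=3 on disk -> 0/1/2 internally.
PLANT_LABEL_MAP = LabelMap({0: 0, 1: 1, 3: 2}, ("stem", "leaf", "soil"))


@dataclass
class DatasetSplit:
    train: list[LabeledCloud]
    test: list[LabeledCloud]
    seed: int


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _parse_xyz_label_text(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    coords, labels = [], []
    has_labels = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}: line {lineno}: expected "
                                 f"'x y z [label]', got {len(parts)} fields")
            try:
                xyz = [float(p) for p in parts[:3]]
                lab = int(parts[3]) if len(parts) == 4 else None
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: malformed record") from None
            if has_labels is None:
                has_labels = lab is not None
            elif has_labels != (lab is not None):
                raise ValueError(f"{path}: line {lineno}: inconsistent label column")
            coords.append(xyz)
            if lab is not None:
                labels.append(lab)
    if not coords:
        raise ValueError(f"{path}: empty point cloud file")
    return (np.array(coords),
            np.array(labels, dtype=np.int64) if labels else None)


def _parse_ascii_ply(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    n_vertices = None
    props: list[str] = []
    body_start = None
    in_vertex = False
    for i, line in enumerate(lines[1:], start=1):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise ValueError(f"{path}: only ASCII PLY is supported")
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertices = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            props.append(tok[-1])
        elif tok[0] == "end_header":
            body_start = i + 1
            break
    if body_start is None or n_vertices is None:
        raise ValueError(f"{path}: malformed PLY header")
    for axis in ("x", "y", "z"):
        if axis not in props:
            raise ValueError(f"{path}: PLY vertex element lacks '{axis}'")
    cols = {p: j for j, p in enumerate(props)}
    rows = []
    for lineno in range(body_start, body_start + n_vertices):
        if lineno >= len(lines):
            raise ValueError(f"{path}: PLY body ends early at line {lineno + 1}")
        parts = lines[lineno].split()
        if len(parts) != len(props):
            raise ValueError(f"{path}: line {lineno + 1}: expected "
                             f"{len(props)} fields")
        rows.append([float(p) for p in parts])
    if not rows:
        raise ValueError(f"{path}: empty point cloud file")
    arr = np.array(rows)
    coords = arr[:, [cols["x"], cols["y"], cols["z"]]]
    labels = arr[:, cols["label"]].astype(np.int64) if "label" in cols else None
    return coords, labels


def read_labeled_cloud(path, label_map: LabelMap | None = None,
                       dialect: str = "xyz_label_text") -> LabeledCloud:
    """Read a cloud and remap its raw label codes through ``label_map``.

    ``dialect`` is ``xyz_label_text`` (one ``x y z [label]`` record per line,
    ``#`` comments skipped) or ``ascii_ply``.  Point order is preserved.
    """
    path = Path(path)
    if dialect == "xyz_label_text":
        coords, raw = _parse_xyz_label_text(path)
    elif dialect == "ascii_ply":
        coords, raw = _parse_ascii_ply(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    labels = None
    if raw is not None:
        labels = label_map.apply(raw) if label_map is not None else raw
    return LabeledCloud(coords, labels, source_id=str(path))


def write_labeled_cloud(cloud: LabeledCloud, path,
                        label_map: LabelMap | None = None,
                        dialect: str = "xyz_label_text",
                        precision: int = 8) -> None:
    """Write a cloud; internal labels are mapped back to raw codes if a
    label map is given."""
    path = Path(path)
    labels = cloud.labels
    if labels is not None and label_map is not None:
        labels = label_map.invert(labels)
    fmt = f"{{:.{precision}g}}"
    if dialect == "xyz_label_text":
        with open(path, "w") as fh:
            for i, (x, y, z) in enumerate(cloud.coords):
                rec = f"{fmt.format(x)} {fmt.format(y)} {fmt.format(z)}"
                if labels is not None:
                    rec += f" {labels[i]}"
                fh.write(rec + "\n")
    elif dialect == "ascii_ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {cloud.n_points}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            if labels is not None:
                fh.write("property int label\n")
            fh.write("end_header\n")
            for i, (x, y, z) in enumerate(cloud.coords):
                rec = f"{fmt.format(x)} {fmt.format(y)} {fmt.format(z)}"
                if labels is not None:
                    rec += f" {labels[i]}"
                fh.write(rec + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def random_sample(cloud: LabeledCloud, n_points: int, seed: int) -> LabeledCloud:
    """Uniform random sample to exactly ``n_points`` points.

    When the cloud is larger, sampling is without replacement; when smaller,
    all points are kept and the deficit is drawn with replacement so small
    clouds remain usable.  Labels travel with their points.
    """
    if n_points < 1:
        raise ValueError("n_points must be positive")
    rng = np.random.default_rng(seed)
    n = cloud.n_points
    if n >= n_points:
        idx = rng.choice(n, size=n_points, replace=False)
    else:
        extra = rng.choice(n, size=n_points - n, replace=True)
        idx = np.concatenate([np.arange(n), extra])
    return LabeledCloud(cloud.coords[idx],
                        None if cloud.labels is None else cloud.labels[idx],
                        source_id=cloud.source_id)


def normalize_cloud(cloud: LabeledCloud, mode: str = "unit_sphere") -> LabeledCloud:
    """Center on the centroid and scale the farthest point to unit norm.

    ``mode``: ``none`` (identity), ``center`` (centroid only) or
    ``unit_sphere`` (center + scale; an all-coincident cloud maps to zeros).
    """
    if mode == "none":
        return replace(cloud)
    coords = cloud.coords - cloud.coords.mean(axis=0)
    if mode == "unit_sphere":
        radius = np.linalg.norm(coords, axis=1).max()
        if radius > 0:
            coords = coords / radius
    elif mode != "center":
        raise ValueError(f"unknown normalization mode {mode!r}")
    return LabeledCloud(coords, cloud.labels, source_id=cloud.source_id)


def split_dataset(clouds: list[LabeledCloud], train_fraction: float = 0.8,
                  seed: int = 0) -> DatasetSplit:
    """Random disjoint train/test partition with |train| = round(f * n)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(clouds) < 2:
        raise ValueError("need at least 2 clouds to split")
    n = len(clouds)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train = [clouds[i] for i in sorted(perm[:n_train])]
    test = [clouds[i] for i in sorted(perm[n_train:])]
    return DatasetSplit(train=train, test=test, seed=seed)
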