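"""Astrocyte morphometry on SWC skeletons.

Operators for traced cell reconstructions: Sholl intersection profiles,
branch statistics (total process length, primary/terminal branch counts,
effective soma area), and fiber-neurite colocalization split into proximal
and distal compartments at a configurable distance from the soma center
(40 µm by default, the boundary used when comparing dopaminergic /
cholinergic neurite contact between cortical and hippocampal astrocytes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class Skeleton:
    """Rooted SWC-style skeleton.

    ``parent_idx`` holds 0-based indices into the node arrays (-1 for the
    root). Exactly one root is required and it is taken as the soma; all
    coordinates are in µm.
    """

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    parent_idx: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("skeleton coordinates must be finite")
        roots = np.flatnonzero(np.asarray(self.parent_idx) == -1)
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        self._root = int(roots[0])
        # tree check: walking parents from any node must reach the root
        n = len(self.ids)
        for start in range(n):
            seen = 0
            node = start
            while node != -1:
                node = int(self.parent_idx[node])
                seen += 1
                if seen > n:
                    raise ValueError("parent references contain a cycle")

    @property
    def root(self) -> int:
        return self._root

    @property
    def soma_center(self) -> np.ndarray:
        return self.xyz[self._root]

    @property
    def soma_radius(self) -> float:
        return float(self.radius[self._root])

    def edges(self) -> list[tuple[int, int]]:
        """(child, parent) index pairs, one per segment."""
        return [
            (i, int(p)) for i, p in enumerate(self.parent_idx) if p != -1
        ]

    def n_children(self) -> np.ndarray:
        counts = np.zeros(len(self.ids), dtype=int)
        for _, p in self.edges():
            counts[p] += 1
        return counts

    # ---------------------------------------------------------------- IO

    @classmethod
    def read_swc(cls, path: str | Path) -> "Skeleton":
        """Read a 7-column SWC file (# comment lines ignored)."""
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed SWC line: {line!r}")
            rows.append(parts)
        if not rows:
            raise ValueError(f"no nodes in SWC file {path}")
        ids = np.array([int(r[0]) for r in rows])
        id_to_idx = {v: i for i, v in enumerate(ids)}
        parents = np.array(
            [-1 if int(r[6]) == -1 else id_to_idx[int(r[6])] for r in rows]
        )
        return cls(
            ids=ids,
            types=np.array([int(r[1]) for r in rows]),
            xyz=np.array([[float(r[2]), float(r[3]), float(r[4])] for r in rows]),
            radius=np.array([float(r[5]) for r in rows]),
            parent_idx=parents,
        )

    def write_swc(self, path: str | Path) -> None:
        lines = ["# id type x y z radius parent"]
        for i in range(len(self.ids)):
            p = int(self.parent_idx[i])
            pid = -1 if p == -1 else int(self.ids[p])
            x, y, z = self.xyz[i]
            lines.append(
                f"{int(self.ids[i])} {int(self.types[i])} "
                f"{x:.6f} {y:.6f} {z:.6f} {self.radius[i]:.6f} {pid}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ShollProfile:
    radii: np.ndarray
    intersections: np.ndarray


@dataclass
class BranchStats:
    total_length: float
    n_primary: int
    n_terminal: int
    soma_area: float


@dataclass
class ColocResult:
    proximal_fraction: float
    distal_fraction: float
    total_fraction: float
    proximal_length: float
    distal_length: float


def _segment_distance_extrema(
    a: np.ndarray, b: np.ndarray, center: np.ndarray
) -> tuple[float, float, float]:
    """(d_start, d_end, d_min) of distance-to-center along segment a->b.

    Distance to a fixed point along a line segment is convex, so its minimum
    is at the orthogonal projection when that falls inside the segment, else
    at an endpoint.
    """
    d0 = float(np.linalg.norm(a - center))
    d1 = float(np.linalg.norm(b - center))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return d0, d1, min(d0, d1)
    t = float((center - a) @ ab) / denom
    if 0.0 < t < 1.0:
        dmin = float(np.linalg.norm(a + t * ab - center))
    else:
        dmin = min(d0, d1)
    return d0, d1, dmin


def sholl(
    skeleton: Skeleton,
    radius_step: float = 5.0,
    max_radius: float | None = None,
    project_xy: bool = False,
) -> ShollProfile:
    """Sholl intersection profile: process crossings of concentric spheres.

    For each radius the number of points where the skeleton pierces the
    sphere centered on the soma is counted. Per segment the distance to the
    soma is convex along the segment, so a sphere is crossed 0, 1 (endpoints
    on opposite sides) or 2 times (both endpoints outside but the segment
    dips inside). Touching a sphere without crossing does not count.

    ``project_xy`` flattens the skeleton to the xy-plane first (2D Sholl on
    a projected image rather than the 3D reconstruction).
    """
    if radius_step <= 0:
        raise ValueError("radius_step must be positive")
    xyz = skeleton.xyz.copy()
    if project_xy:
        xyz[:, 2] = 0.0
    center = xyz[skeleton.root]
    edges = skeleton.edges()
    if max_radius is None:
        dmax = max(
            (float(np.linalg.norm(xyz[i] - center)) for i in range(len(xyz))),
            default=0.0,
        )
        max_radius = dmax + radius_step
    radii = np.arange(radius_step, max_radius + 1e-9, radius_step)
    counts = np.zeros(len(radii), dtype=int)
    extrema = [
        _segment_distance_extrema(xyz[p], xyz[c], center) for c, p in edges
    ]
    for k, r in enumerate(radii):
        n = 0
        for d0, d1, dmin in extrema:
            lo, hi = (d0, d1) if d0 <= d1 else (d1, d0)
            if lo < r < hi:
                n += 1
            elif lo > r > dmin:  # both endpoints outside, dip crosses twice
                n += 2
        counts[k] = n
    return ShollProfile(radii=radii, intersections=counts)


def branch_stats(skeleton: Skeleton) -> BranchStats:
    """Total length, primary/terminal branch counts and effective soma area.

    Total length sums parent-child Euclidean distances; primaries are the
    soma's direct children; terminals are non-root leaves; effective soma
    area is the disc area pi*r^2 of the soma node radius.
    """
    edges = skeleton.edges()
    total = sum(
        float(np.linalg.norm(skeleton.xyz[c] - skeleton.xyz[p])) for c, p in edges
    )
    children = skeleton.n_children()
    n_primary = int(children[skeleton.root])
    n_terminal = int(
        sum(1 for i in range(len(skeleton.ids)) if children[i] == 0 and i != skeleton.root)
    )
    return BranchStats(
        total_length=total,
        n_primary=n_primary,
        n_terminal=n_terminal,
        soma_area=math.pi * skeleton.soma_radius**2,
    )


def colocalization(
    skeleton: Skeleton,
    points: np.ndarray,
    eps: float = 1.0,
    boundary: float = 40.0,
    step: float = 0.5,
) -> ColocResult:
    """Fraction of skeleton length within ``eps`` of neurite evidence points.

    The skeleton is discretized into sub-segments of length <= ``step``; a
    sub-segment is colocalized iff its midpoint lies within ``eps`` of any
    point, and proximal iff the midpoint's Euclidean distance to the soma
    center is < ``boundary``. Fractions are colocalized length over region
    length (0 for an empty region or empty point cloud).
    """
    if eps <= 0 or boundary <= 0 or step <= 0:
        raise ValueError("eps, boundary and step must be positive")
    edges = skeleton.edges()
    if not edges:
        raise ValueError("skeleton has no segments")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    center = skeleton.soma_center

    mids, seg_len = [], []
    for c, p in edges:
        a, b = skeleton.xyz[p], skeleton.xyz[c]
        L = float(np.linalg.norm(b - a))
        if L == 0:
            continue
        n_sub = max(int(math.ceil(L / step)), 1)
        ts = (np.arange(n_sub) + 0.5) / n_sub
        mids.append(a[None, :] + ts[:, None] * (b - a)[None, :])
        seg_len.append(np.full(n_sub, L / n_sub))
    mids = np.vstack(mids)
    seg_len = np.concatenate(seg_len)

    if len(points):
        tree = cKDTree(points)
        d, _ = tree.query(mids, k=1)
        hit = d <= eps
    else:
        hit = np.zeros(len(mids), dtype=bool)
    proximal = np.linalg.norm(mids - center[None, :], axis=1) < boundary

    def frac(mask: np.ndarray) -> tuple[float, float]:
        L = float(seg_len[mask].sum())
        if L == 0:
            return 0.0, 0.0
        return float(seg_len[mask & hit].sum()) / L, L

    prox_f, prox_L = frac(proximal)
    dist_f, dist_L = frac(~proximal)
    total_f, _ = frac(np.ones(len(mids), dtype=bool))
    return ColocResult(
        proximal_fraction=prox_f,
        distal_fraction=dist_f,
        total_fraction=total_f,
        proximal_length=prox_L,
        distal_length=dist_L,
    )
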