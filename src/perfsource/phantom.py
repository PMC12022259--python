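"""Digital flow phantom.

A phantom is a forest of converging vessel trees drained by plug flow toward
an imaging slice, plus a slow "tissue" compartment feeding the branch tips
and an optional block of truly static spins.  Spins carry their tag-time
position ``r0``, a piecewise-linear trajectory, and an inflow magnetization
scale ``m0``.

The module also provides :func:`true_source_distribution`, the brute-force
ground-truth histogram of relative source offsets for spins found inside a
target voxel at a given mixing time.  It is the independent oracle against
which Fourier reconstructions are checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import GeometryError, SourceGrid, VoxelGeometry

__all__ = [
    "Segment",
    "VesselTree",
    "PhantomSpec",
    "SpinEnsemble",
    "ConfigurationError",
    "build_vessel_tree",
    "build_forest",
    "seed_spins",
    "advect",
    "true_source_distribution",
    "scale_speeds",
]

_JUNCTION_TOL = 1e-9

# compartment codes
VEIN = 0
TISSUE = 1
STATIC = 2


class ConfigurationError(ValueError):
    """Invalid phantom configuration."""


@dataclass(frozen=True)
class Segment:
    """Straight vessel segment with plug flow from ``start`` to ``end``.

    ``parent`` is the index (within the same tree) of the downstream segment
    whose ``start`` coincides with this segment's ``end``; the root segment
    (``parent is None``) is the trunk.
    """

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float
    speed: float
    parent: int | None = None

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end, self.start)))

    @property
    def direction(self) -> np.ndarray:
        d = np.subtract(self.end, self.start).astype(float)
        return d / np.linalg.norm(d)


@dataclass
class VesselTree:
    """A validated, converging drainage tree of :class:`Segment` objects."""

    segments: list[Segment]

    def __post_init__(self):
        segs = self.segments
        if not segs:
            raise ConfigurationError("tree has no segments")
        roots = [i for i, s in enumerate(segs) if s.parent is None]
        if len(roots) != 1:
            raise ConfigurationError(
                f"drainage must converge to a single trunk; found {len(roots)} roots"
            )
        for i, s in enumerate(segs):
            if not (s.speed > 0):
                raise ConfigurationError(f"segment {i}: speed must be > 0")
            if not (s.radius > 0):
                raise ConfigurationError(f"segment {i}: radius must be > 0")
            if s.length <= 0:
                raise ConfigurationError(f"segment {i}: zero length")
            if s.parent is not None:
                if not (0 <= s.parent < len(segs)) or s.parent == i:
                    raise ConfigurationError(f"segment {i}: bad parent {s.parent}")
                gap = np.linalg.norm(
                    np.subtract(s.end, segs[s.parent].start)
                )
                if gap > _JUNCTION_TOL:
                    raise ConfigurationError(
                        f"segment {i}: junction discontinuity of {gap:g} mm"
                    )
        # acyclicity: walking parents must terminate at the root
        for i in range(len(segs)):
            seen, j = set(), i
            while segs[j].parent is not None:
                if j in seen:
                    raise ConfigurationError("drainage graph has a cycle")
                seen.add(j)
                j = segs[j].parent

    @property
    def trunk_id(self) -> int:
        return next(i for i, s in enumerate(self.segments) if s.parent is None)

    def leaves(self) -> list[int]:
        parents = {s.parent for s in self.segments if s.parent is not None}
        return [i for i in range(len(self.segments)) if i not in parents]


@dataclass
class PhantomSpec:
    """Configuration of the digital phantom.

    Each entry of ``trees`` is the segment list of one vessel tree.  The
    seeding mode is either ``"uniform"`` (spin count = round(density * lumen
    volume), positions uniform in the lumen) or ``"lattice"`` (axis-only
    stations every ``lattice_spacing`` mm, used when exactly on-grid tag
    positions are needed).
    """

    trees: list[list[Segment]]
    slice_z: float = 0.0
    spin_density: float = 2.0  # spins per mm^3 (uniform seeding)
    seeding: str = "uniform"
    lattice_spacing: float = 1.0  # mm along the vessel axis
    tissue_speed: float = 0.5  # mm/s, slow feeders entering branch tips
    tissue_per_tip: int = 0
    tissue_spacing: float = 0.3  # mm between consecutive tissue spins
    static_block: dict | None = None  # {"center", "size", "spacing"}
    m0: list[float] | None = None  # per-tree inflow magnetization scale
    seed: int = 0

    def m0_for_tree(self, i: int) -> float:
        if self.m0 is None:
            return 1.0
        return float(self.m0[i])


def scale_speeds(spec: PhantomSpec, factor: float) -> PhantomSpec:
    """Return a copy of ``spec`` with every vessel speed multiplied by
    ``factor`` (tissue speed included) -- a global flow modulation."""
    if factor <= 0:
        raise ConfigurationError("speed factor must be > 0")
    trees = [
        [replace(s, speed=s.speed * factor) for s in tree] for tree in spec.trees
    ]
    return replace(spec, trees=trees, tissue_speed=spec.tissue_speed * factor)


def build_vessel_tree(spec: PhantomSpec, tree_index: int = 0) -> VesselTree:
    """Build and validate one vessel tree; the trunk must cross the imaging
    plane ``z = spec.slice_z``."""
    tree = VesselTree(list(spec.trees[tree_index]))
    trunk = tree.segments[tree.trunk_id]
    lo, hi = sorted((trunk.start[2], trunk.end[2]))
    if not (lo <= spec.slice_z <= hi):
        raise ConfigurationError(
            f"trunk spans z in [{lo}, {hi}] and does not cross the imaging "
            f"plane z={spec.slice_z}"
        )
    return tree


def build_forest(spec: PhantomSpec) -> list[VesselTree]:
    return [build_vessel_tree(spec, i) for i in range(len(spec.trees))]


# ---------------------------------------------------------------------------
# spin ensemble

@dataclass
class SpinEnsemble:
    """Tagged spins with precomputed piecewise-linear trajectories.

    ``bp_t``/``bp_p`` hold per-spin breakpoint times and positions (padded
    with +inf / replicated endpoints); ``vel`` holds the velocity on the
    interval starting at each breakpoint, with the final entry used for
    extrapolation past the trunk outlet.
    """

    r0: np.ndarray  # (n, 3) tag-time positions, mm
    compartment: np.ndarray  # (n,) int: VEIN / TISSUE / STATIC
    tree_index: np.ndarray  # (n,) int, -1 for static spins
    m0: np.ndarray  # (n,) inflow magnetization scale
    bp_t: np.ndarray  # (n, K) breakpoint times, s
    bp_p: np.ndarray  # (n, K, 3) breakpoint positions, mm
    vel: np.ndarray  # (n, K, 3) interval velocities, mm/s

    @property
    def n(self) -> int:
        return self.r0.shape[0]

    def positions_at(self, t: float) -> np.ndarray:
        """Positions (n, 3) at time ``t`` seconds after tagging."""
        if t < 0:
            raise ValueError("time since tagging must be >= 0")
        j = np.clip((self.bp_t <= t).sum(axis=1) - 1, 0, self.bp_t.shape[1] - 1)
        rows = np.arange(self.n)
        dt = t - self.bp_t[rows, j]
        return self.bp_p[rows, j] + self.vel[rows, j] * dt[:, None]


def advect(ensemble: SpinEnsemble, t: float) -> np.ndarray:
    """Positions of all spins ``t`` seconds after tagging (plug flow along
    segments, junction hand-off to the parent, straight extrapolation past
    the trunk outlet)."""
    return ensemble.positions_at(t)


def _perp_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(d, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _chain_path(
    tree: VesselTree, seg_id: int, s0: float, offset: np.ndarray
) -> tuple[list[float], list[np.ndarray], np.ndarray]:
    """Breakpoints of a spin starting at arc-length ``s0`` of ``seg_id`` with
    a fixed perpendicular ``offset``, drained through the parent chain."""
    times = [0.0]
    start = np.asarray(tree.segments[seg_id].start, dtype=float)
    d = tree.segments[seg_id].direction
    points = [start + d * s0 + offset]
    i, s = seg_id, s0
    while True:
        seg = tree.segments[i]
        rem = seg.length - s
        times.append(times[-1] + rem / seg.speed)
        points.append(np.asarray(seg.end, dtype=float) + offset)
        if seg.parent is None:
            final_v = seg.direction * seg.speed
            return times, points, final_v
        i, s = seg.parent, 0.0


def _tissue_path(
    tree: VesselTree, leaf_id: int, dist: float, speed: float
) -> tuple[list[float], list[np.ndarray], np.ndarray]:
    """Tissue spin placed ``dist`` mm upstream of a leaf tip, creeping at the
    tissue speed until it enters the vessel."""
    leaf = tree.segments[leaf_id]
    tip = np.asarray(leaf.start, dtype=float)
    p0 = tip - leaf.direction * dist
    t_enter = dist / speed
    times, points, final_v = _chain_path(tree, leaf_id, 0.0, np.zeros(3))
    times = [0.0] + [t + t_enter for t in times]
    points = [p0] + points
    return times, points, final_v


def _assemble(paths, r0s, comps, trees_idx, m0s) -> SpinEnsemble:
    n = len(paths)
    K = max(len(t) for t, _, _ in paths)
    bp_t = np.full((n, K), np.inf)
    bp_p = np.zeros((n, K, 3))
    vel = np.zeros((n, K, 3))
    for i, (times, points, final_v) in enumerate(paths):
        k = len(times)
        bp_t[i, :k] = times
        bp_p[i, :k] = points
        for j in range(k - 1):
            dt = times[j + 1] - times[j]
            vel[i, j] = (np.asarray(points[j + 1]) - np.asarray(points[j])) / dt
        vel[i, k - 1 :] = final_v
        bp_p[i, k:] = points[-1]
    return SpinEnsemble(
        r0=np.asarray(r0s, dtype=float),
        compartment=np.asarray(comps, dtype=np.int8),
        tree_index=np.asarray(trees_idx, dtype=int),
        m0=np.asarray(m0s, dtype=float),
        bp_t=bp_t,
        bp_p=bp_p,
        vel=vel,
    )


def seed_spins(
    trees: VesselTree | Sequence[VesselTree], spec: PhantomSpec
) -> SpinEnsemble:
    """Populate vessel lumens (and the tissue/static compartments) with spins.

    Uniform seeding draws round(density * lumen volume) spins per segment,
    uniformly over axial position and lumen cross-section; lattice seeding
    places axis-only stations every ``spec.lattice_spacing`` mm measured from
    the segment start.  Deterministic for a fixed ``spec.seed``.
    """
    if isinstance(trees, VesselTree):
        trees = [trees]
    rng = np.random.default_rng(spec.seed)
    paths, r0s, comps, tidx, m0s = [], [], [], [], []

    for ti, tree in enumerate(trees):
        m0 = spec.m0_for_tree(ti)
        for si, seg in enumerate(tree.segments):
            d = seg.direction
            u, v = _perp_basis(d)
            if spec.seeding == "lattice":
                stations = np.arange(0.0, seg.length, spec.lattice_spacing)
                offsets = np.zeros((stations.size, 3))
            elif spec.seeding == "uniform":
                vol = np.pi * seg.radius**2 * seg.length
                count = int(round(spec.spin_density * vol))
                stations = rng.uniform(0.0, seg.length, size=count)
                rad = seg.radius * np.sqrt(rng.uniform(0.0, 1.0, size=count))
                ang = rng.uniform(0.0, 2 * np.pi, size=count)
                offsets = (
                    rad[:, None] * np.cos(ang)[:, None] * u
                    + rad[:, None] * np.sin(ang)[:, None] * v
                )
            else:
                raise ConfigurationError(f"unknown seeding mode {spec.seeding!r}")
            for s0, off in zip(stations, offsets):
                times, points, fv = _chain_path(tree, si, float(s0), off)
                paths.append((times, points, fv))
                r0s.append(points[0])
                comps.append(VEIN)
                tidx.append(ti)
                m0s.append(m0)
        if spec.tissue_per_tip > 0:
            for leaf in tree.leaves():
                for j in range(1, spec.tissue_per_tip + 1):
                    dist = j * spec.tissue_spacing
                    times, points, fv = _tissue_path(
                        tree, leaf, dist, spec.tissue_speed
                    )
                    paths.append((times, points, fv))
                    r0s.append(points[0])
                    comps.append(TISSUE)
                    tidx.append(ti)
                    m0s.append(m0)

    if spec.static_block is not None:
        blk = spec.static_block
        c = np.asarray(blk["center"], dtype=float)
        size = np.asarray(blk["size"], dtype=float)
        h = float(blk.get("spacing", 1.0))
        axes = [np.arange(-s / 2 + h / 2, s / 2, h) for s in size]
        for x in axes[0]:
            for y in axes[1]:
                for z in axes[2]:
                    p = c + np.array([x, y, z])
                    paths.append(([0.0], [p], np.zeros(3)))
                    r0s.append(p)
                    comps.append(STATIC)
                    tidx.append(-1)
                    m0s.append(1.0)

    if not paths:
        raise ConfigurationError("phantom spec produced an empty ensemble")
    return _assemble(paths, r0s, comps, tidx, m0s)


# ---------------------------------------------------------------------------
# brute-force ground truth

def true_source_distribution(
    ensemble: SpinEnsemble,
    voxel: VoxelGeometry,
    t_mix: float,
    grid: SourceGrid,
    weights: np.ndarray | None = None,
    normalize: bool = True,
    wrap: bool = False,
) -> np.ndarray:
    """Histogram of relative source offsets for spins inside ``voxel``.

    For every (optionally weighted) spin inside the voxel at ``t_mix``, the
    offset ``dr = r0 - voxel_center`` is projected onto (x, z) and binned on
    ``grid``.  Returns an (nx, nz) array; normalized to unit sum when the
    voxel is non-empty, all zeros otherwise.  ``wrap=True`` bins offsets
    modulo the grid FOV (the aliasing behaviour of a Fourier
    reconstruction); otherwise out-of-grid offsets are dropped.
    """
    if t_mix < 0:
        raise ValueError("t_mix must be >= 0")
    pos = ensemble.positions_at(t_mix)
    inside = voxel.contains(pos)
    w = np.ones(ensemble.n) if weights is None else np.asarray(weights, dtype=float)
    sel = inside & (w != 0)
    nx, nz = grid.shape
    hist = np.zeros((nx, nz))
    if not np.any(sel):
        return hist
    c = np.asarray(voxel.center, dtype=float)
    dr = ensemble.r0[sel] - c
    ix, iz = grid.bin_index(dr[:, 0], dr[:, 2], wrap=wrap)
    ok = (ix >= 0) & (iz >= 0)
    np.add.at(hist, (ix[ok], iz[ok]), w[sel][ok])
    if normalize:
        total = hist.sum()
        if total > 0:
            hist /= total
    return hist
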