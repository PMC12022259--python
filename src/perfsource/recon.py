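"""Echo separation and Fourier inversion of the displacement encodings.

Every acquisition samples a single point in the Fourier space of the
perfusion source maps; the stimulated echo is isolated by three-point phase
cycling and the complete rectangular encoding grid is inverted by a 2-D
inverse DFT.  The inverse transform carries the 1/N normalization so that
the map total equals the DC-encoding sample (conservation of inflowing
magnetization).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .acquisition import AcquisitionProtocol, EncodedSignal, ProtocolError

__all__ = [
    "SourceMap",
    "separate_echoes",
    "reconstruct_source_maps",
    "to_absolute",
    "to_relative",
    "combine_roi",
]


@dataclass
class SourceMap:
    """Dynamic perfusion source maps.

    ``values`` is complex, indexed by (voxel/ROI, mixing time, dx bin,
    dz bin).  In the ``"relative"`` frame bin coordinates are
    ``offsets_x/offsets_z`` (centre bin = zero offset); converting to the
    ``"absolute"`` frame relabels the axes of voxel ``v`` as
    ``origins[v] + offsets`` without touching the values.
    """

    values: np.ndarray
    offsets_x: np.ndarray
    offsets_z: np.ndarray
    source_fov: tuple[float, float]
    source_res: tuple[float, float]
    mixing_times: np.ndarray
    voxel_centers: np.ndarray  # (n_vox, 3)
    t1: float
    frame: str = "relative"
    origins: np.ndarray | None = None  # (n_vox, 2): absolute (x, z) of the centre bin

    def __post_init__(self):
        nv, nt, nx, nz = self.values.shape
        if nx != self.offsets_x.size or nz != self.offsets_z.size:
            raise ValueError("map dimensions inconsistent with offset axes")
        if nt != np.asarray(self.mixing_times).size:
            raise ValueError("map dimensions inconsistent with mixing times")
        if self.frame not in ("relative", "absolute"):
            raise ValueError(f"unknown frame {self.frame!r}")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


def separate_echoes(sig: EncodedSignal) -> np.ndarray:
    """Isolate the stimulated echo from the three-point phase cycle.

    Returns the phi-Fourier coefficient of the ``e^{+i phi}`` component,
    ``(1/3) * sum_m S(phi_m) * e^{-i phi_m}``; for phases {0, 120, 240}
    degrees the conjugate-echo and FID contributions cancel exactly.
    Output shape: (encoding, mixing time, voxel).
    """
    phases = np.asarray(sig.protocol.phase_cycle, dtype=float)
    if phases.size != 3 or sig.data.shape[1] != 3:
        raise ProtocolError("expected exactly the three phase-cycle steps")
    w = np.exp(-1j * phases) / 3.0
    return np.einsum("kptv,p->ktv", sig.data, w)


def reconstruct_source_maps(
    stim: np.ndarray, protocol: AcquisitionProtocol
) -> SourceMap:
    """Inverse 2-D DFT of the stimulated echo over the encoding grid.

    ``stim`` has shape (n_encodings, n_tmix, n_voxels) and must cover the
    complete rectangular grid (partial-Fourier input is rejected by the
    protocol validation).  Per voxel and mixing time the map over (dx, dz)
    satisfies ``sum(map) == stim[DC]`` to machine precision.
    """
    p = protocol
    nx, nz = p.grid_shape
    n_t, n_vox = stim.shape[1], stim.shape[2]
    if stim.shape[0] != nx * nz:
        raise ProtocolError("stimulated-echo array does not cover the encoding grid")
    grid = p.source_grid
    kx = p.encodings[:, 0].reshape(nx, nz)[:, 0]
    kz = p.encodings[:, 1].reshape(nx, nz)[0, :]
    ex = np.exp(-1j * np.outer(kx, grid.offsets_x))  # (nx_k, nx_map)
    ez = np.exp(-1j * np.outer(kz, grid.offsets_z))
    s = stim.reshape(nx, nz, n_t, n_vox)
    maps = np.einsum("xm,zn,xztv->vtmn", ex, ez, s) / (nx * nz)
    return SourceMap(
        values=maps,
        offsets_x=grid.offsets_x,
        offsets_z=grid.offsets_z,
        source_fov=tuple(p.source_fov),
        source_res=tuple(p.source_res),
        mixing_times=np.asarray(p.mixing_times, dtype=float),
        voxel_centers=np.asarray([v.center for v in p.voxels], dtype=float),
        t1=p.t1,
    )


def to_absolute(sm: SourceMap) -> SourceMap:
    """Relabel the source axes in scanner coordinates,
    ``r_source = voxel_center + dr``; values are unchanged."""
    if sm.frame != "relative":
        raise ValueError("map is already in the absolute frame")
    origins = sm.voxel_centers[:, [0, 2]].copy()
    return replace(sm, frame="absolute", origins=origins)


def to_relative(sm: SourceMap) -> SourceMap:
    if sm.frame != "absolute":
        raise ValueError("map is already in the relative frame")
    return replace(sm, frame="relative", origins=None)


def combine_roi(sm: SourceMap, voxel_indices, mode: str = "complex") -> SourceMap:
    """Combine member-voxel maps of an ROI on a common absolute grid.

    ``mode="complex"`` sums complex maps (default, matching displayed
    magnitude-of-sum); ``mode="magnitude"`` sums magnitudes.  The map must be
    in the absolute frame and voxel centres must sit on a common
    ``source_res`` lattice (offsets are rounded to the nearest bin).
    """
    idx = list(voxel_indices)
    if not idx:
        raise ValueError("empty ROI")
    if sm.frame != "absolute":
        raise ValueError("combine_roi requires an absolute-frame map")
    if mode not in ("complex", "magnitude"):
        raise ValueError(f"unknown ROI combination mode {mode!r}")
    rx, rz = sm.source_res
    ax = [sm.origins[v][0] + sm.offsets_x for v in idx]
    az = [sm.origins[v][1] + sm.offsets_z for v in idx]
    x0, x1 = min(a.min() for a in ax), max(a.max() for a in ax)
    z0, z1 = min(a.min() for a in az), max(a.max() for a in az)
    gx = np.arange(x0, x1 + rx / 2, rx)
    gz = np.arange(z0, z1 + rz / 2, rz)
    n_t = sm.values.shape[1]
    out = np.zeros((1, n_t, gx.size, gz.size), dtype=complex)
    for v, axv, azv in zip(idx, ax, az):
        i0 = int(round((axv[0] - x0) / rx))
        j0 = int(round((azv[0] - z0) / rz))
        vals = sm.values[v]
        if mode == "magnitude":
            vals = np.abs(vals)
        out[0, :, i0 : i0 + axv.size, j0 : j0 + azv.size] += vals
    center = sm.voxel_centers[idx].mean(axis=0)
    return SourceMap(
        values=out,
        offsets_x=gx,
        offsets_z=gz,
        source_fov=(gx.size * rx, gz.size * rz),
        source_res=sm.source_res,
        mixing_times=sm.mixing_times,
        voxel_centers=center[None, :],
        t1=sm.t1,
        frame="absolute",
        origins=np.zeros((1, 2)),
    )
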