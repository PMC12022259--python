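"""File formats.

JSON for configuration (mm / ms / degrees on disk, mm / s / radians in
memory), an HDF5 container for raw encoded signals, NIfTI-1 plus a JSON
sidecar for anything image-like, and CSV for ROI mixing-time series.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import nibabel as nib

from .acquisition import AcquisitionProtocol, EncodedSignal, protocol_from_fov
from .geometry import Slab, SliceGeometry, VoxelGeometry
from .phantom import PhantomSpec, Segment
from .recon import SourceMap

__all__ = [
    "RunConfig",
    "spec_to_json",
    "spec_from_json",
    "protocol_to_json",
    "protocol_from_json",
    "save_source_map",
    "load_source_map",
    "save_signal",
    "load_signal",
    "save_series_csv",
]


# ---------------------------------------------------------------------------
# phantom spec JSON

def spec_to_json(spec: PhantomSpec) -> str:
    d = {
        "trees": [
            [
                {
                    "start": list(s.start),
                    "end": list(s.end),
                    "radius_mm": s.radius,
                    "speed_mm_s": s.speed,
                    "parent": s.parent,
                }
                for s in tree
            ]
            for tree in spec.trees
        ],
        "slice_z_mm": spec.slice_z,
        "spin_density_per_mm3": spec.spin_density,
        "seeding": spec.seeding,
        "lattice_spacing_mm": spec.lattice_spacing,
        "tissue_speed_mm_s": spec.tissue_speed,
        "tissue_per_tip": spec.tissue_per_tip,
        "tissue_spacing_mm": spec.tissue_spacing,
        "static_block": spec.static_block,
        "m0": spec.m0,
        "seed": spec.seed,
    }
    return json.dumps(d, indent=2, sort_keys=True)


def spec_from_json(text: str) -> PhantomSpec:
    d = json.loads(text)
    trees = [
        [
            Segment(
                start=tuple(s["start"]),
                end=tuple(s["end"]),
                radius=s["radius_mm"],
                speed=s["speed_mm_s"],
                parent=s["parent"],
            )
            for s in tree
        ]
        for tree in d["trees"]
    ]
    return PhantomSpec(
        trees=trees,
        slice_z=d["slice_z_mm"],
        spin_density=d["spin_density_per_mm3"],
        seeding=d["seeding"],
        lattice_spacing=d["lattice_spacing_mm"],
        tissue_speed=d["tissue_speed_mm_s"],
        tissue_per_tip=d["tissue_per_tip"],
        tissue_spacing=d["tissue_spacing_mm"],
        static_block=d["static_block"],
        m0=d["m0"],
        seed=d["seed"],
    )


# ---------------------------------------------------------------------------
# protocol JSON

def protocol_to_json(p: AcquisitionProtocol) -> str:
    d = {
        "source_fov_mm": list(p.source_fov),
        "source_res_mm": list(p.source_res),
        "mixing_times_ms": (p.mixing_times * 1000.0).tolist(),
        "phase_cycle_deg": [float(np.degrees(x)) for x in p.phase_cycle],
        "t1_ms": p.t1 * 1000.0,
        "slices": [{"z_mm": s.z, "thickness_mm": s.thickness} for s in p.slices],
        "sat_bands": [{"z_mm": s.z, "thickness_mm": s.thickness} for s in p.sat_bands],
        "voxels": [
            {
                "center_mm": list(v.center),
                "size_mm": list(v.size),
                "thickness_mm": v.thickness,
                "slice_index": v.slice_index,
            }
            for v in p.voxels
        ],
        "interslice_gap_ms": p.interslice_gap * 1000.0,
        "repetition_time_ms": None if p.repetition_time is None else p.repetition_time * 1000.0,
        "consume_on_image": p.consume_on_image,
        "noise_sigma": p.noise_sigma,
        "seed": p.seed,
    }
    return json.dumps(d, indent=2, sort_keys=True)


def protocol_from_json(text: str) -> AcquisitionProtocol:
    d = json.loads(text)
    fov = tuple(d["source_fov_mm"])
    res = tuple(d["source_res_mm"])
    enc, shape = protocol_from_fov(fov, res)
    tr = d["repetition_time_ms"]
    return AcquisitionProtocol(
        encodings=enc,
        grid_shape=shape,
        source_fov=fov,
        source_res=res,
        mixing_times=np.asarray(d["mixing_times_ms"]) / 1000.0,
        voxels=[
            VoxelGeometry(
                center=tuple(v["center_mm"]),
                size=tuple(v["size_mm"]),
                thickness=v["thickness_mm"],
                slice_index=v["slice_index"],
            )
            for v in d["voxels"]
        ],
        slices=[SliceGeometry(s["z_mm"], s["thickness_mm"]) for s in d["slices"]],
        sat_bands=[Slab(s["z_mm"], s["thickness_mm"]) for s in d["sat_bands"]],
        phase_cycle=tuple(np.radians(d["phase_cycle_deg"])),
        t1=d["t1_ms"] / 1000.0,
        interslice_gap=d["interslice_gap_ms"] / 1000.0,
        repetition_time=None if tr is None else tr / 1000.0,
        consume_on_image=d["consume_on_image"],
        noise_sigma=d["noise_sigma"],
        seed=d["seed"],
    )


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Seedable end-to-end run description; JSON round trips losslessly."""

    phantom: PhantomSpec
    protocol: AcquisitionProtocol
    analysis: dict = field(default_factory=dict)
    output_dir: str = "out"
    seed: int = 0
    verbosity: int = 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "phantom": json.loads(spec_to_json(self.phantom)),
                "protocol": json.loads(protocol_to_json(self.protocol)),
                "analysis": self.analysis,
                "output_dir": self.output_dir,
                "seed": self.seed,
                "verbosity": self.verbosity,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        return cls(
            phantom=spec_from_json(json.dumps(d["phantom"])),
            protocol=protocol_from_json(json.dumps(d["protocol"])),
            analysis=d["analysis"],
            output_dir=d["output_dir"],
            seed=d["seed"],
            verbosity=d["verbosity"],
        )


# ---------------------------------------------------------------------------
# NIfTI source maps

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json") if path.suffix == ".nii" else Path(str(path) + ".json")


def save_source_map(sm: SourceMap, path: str | Path) -> None:
    """Write a source map as NIfTI (dims: dx, dz, mixing time, voxel) plus a
    JSON sidecar with grid, frame and timing metadata."""
    path = Path(path)
    data = np.transpose(sm.values, (2, 3, 1, 0))  # (dx, dz, t, voxel)
    affine = np.diag([sm.source_res[0], sm.source_res[1], 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.complex128), affine)
    nib.save(img, str(path))
    sidecar = {
        "source_fov_mm": list(sm.source_fov),
        "source_res_mm": list(sm.source_res),
        "offsets_x_mm": sm.offsets_x.tolist(),
        "offsets_z_mm": sm.offsets_z.tolist(),
        "mixing_times_ms": (np.asarray(sm.mixing_times) * 1000.0).tolist(),
        "voxel_centers_mm": np.asarray(sm.voxel_centers).tolist(),
        "t1_ms": sm.t1 * 1000.0,
        "frame": sm.frame,
        "origins_mm": None if sm.origins is None else np.asarray(sm.origins).tolist(),
        "axes": ["dx", "dz", "t_mix", "voxel"],
        "encoding_order": "row-major over (kx, kz), DC at grid centre",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_source_map(path: str | Path) -> SourceMap:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    meta = json.loads(_sidecar_path(path).read_text())
    values = np.transpose(data, (3, 2, 0, 1))
    offsets_x = np.asarray(meta["offsets_x_mm"])
    offsets_z = np.asarray(meta["offsets_z_mm"])
    if values.shape[2] != offsets_x.size or values.shape[3] != offsets_z.size:
        raise ValueError("sidecar grid metadata does not match array dimensions")
    if values.shape[1] != len(meta["mixing_times_ms"]):
        raise ValueError("sidecar mixing times do not match array dimensions")
    origins = meta["origins_mm"]
    return SourceMap(
        values=values,
        offsets_x=offsets_x,
        offsets_z=offsets_z,
        source_fov=tuple(meta["source_fov_mm"]),
        source_res=tuple(meta["source_res_mm"]),
        mixing_times=np.asarray(meta["mixing_times_ms"]) / 1000.0,
        voxel_centers=np.asarray(meta["voxel_centers_mm"]),
        t1=meta["t1_ms"] / 1000.0,
        frame=meta["frame"],
        origins=None if origins is None else np.asarray(origins),
    )


# ---------------------------------------------------------------------------
# HDF5 encoded signals

def save_signal(sig: EncodedSignal, path: str | Path) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset("data", data=sig.data, track_times=False)
        f.create_dataset("encodings", data=sig.protocol.encodings, track_times=False)
        f.attrs["protocol_json"] = protocol_to_json(sig.protocol)


def load_signal(path: str | Path) -> EncodedSignal:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        protocol = protocol_from_json(f.attrs["protocol_json"])
    return EncodedSignal(data, protocol)


# ---------------------------------------------------------------------------
# CSV time series

def save_series_csv(path: str | Path, times: np.ndarray, values: np.ndarray, state: str) -> None:
    """ROI mixing-time series as CSV with columns mixing_time_ms, value, state."""
    df = pd.DataFrame(
        {
            "mixing_time_ms": np.asarray(times) * 1000.0,
            "value": np.asarray(values),
            "state": state,
        }
    )
    df.to_csv(path, index=False)
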