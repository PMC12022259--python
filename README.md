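# perfsource

Simulation, reconstruction and analysis of displacement-encoded **venous
perfusion source maps**.

Blood-water spins are cosine-tagged with incremented displacement-encoding
wavevectors, drain through converging vessel trees across a mixing time, and
are imaged at a slice downstream. Each acquisition samples one point in the
Fourier space of the per-voxel *source map* — the distribution of relative
positions the blood now in a voxel came from at tagging time. The package
provides:

- **`perfsource.phantom`** — digital flow phantom: converging vessel trees
  with plug flow, a slow tissue compartment, spin seeding/advection, and the
  brute-force ground-truth source histogram used as an independent oracle.
- **`perfsource.acquisition`** — pulse-sequence simulation: cosine tagging,
  three-point (120°) phase cycling, saturation bands, T1 decay (default
  1584 ms), dynamic imaging over mixing times, complex Gaussian noise, and
  multi-slice scheduling with tagged-signal suppression (33 ms inter-slice
  gap).
- **`perfsource.recon`** — stimulated-echo separation by phase cycling and
  inverse 2-D DFT over the encoding grid (map total = DC sample), relative ↔
  absolute frames, ROI combination.
- **`perfsource.analysis`** — T1 correction, voxel-energy normalization,
  vessel detection by source-map energy peaks, venous territory masks,
  15 ms-interpolated 50%-of-max arrival times, arrival-delay maps,
  percent-change maps, paired two-sided t-maps (α = 0.05),
  consecutive-mixing-time averaging, multi-slice combination.
- **`perfsource.io` / `perfsource.fixtures` / `perfsource.cli`** — JSON
  configs, HDF5 signals, NIfTI + JSON-sidecar maps, CSV series, seeded
  fixtures (`y_tree`, `two_trees`, `deep_source`, `multislice`) and a CLI.

No external data is required; everything is generated from seeded
configurations.

## CLI

```sh
perfsource demo --fixture y_tree --seed 1 --out out/          # end-to-end
perfsource simulate --fixture two_trees --seed 0 --out out/   # phantom only
perfsource acquire --config out/config.json --out out/sig.h5
perfsource reconstruct --signal out/sig.h5 --out out/maps.nii
perfsource analyze --maps out/maps.nii --mode territory --out out/terr.json
perfsource analyze --maps task.nii --baseline base.nii --mode modulation --out mod.json
```

`demo` is byte-deterministic for a fixed seed (checksums in `report.json`).

## Conventions

Coordinates are RAS millimetres; the imaging slice is axial (normal = z),
maps are over relative offsets (Δx, Δz) projected along y, and offsets are
defined as Δr = r(tagging) − r(imaging), so maps localize where blood came
*from*. Encoding grids are row-major over (kx, kz) with DC at the grid
centre; Δk = 2π/FOV and k_max → π/res. Files use mm/ms/degrees; in-memory
units are mm/s/radians.
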