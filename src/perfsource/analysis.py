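"""Downstream analyses of dynamic source maps.

T1 correction, voxel-energy normalization, vessel detection by source-map
energy peaks, venous territories, arrival-time and delay maps, percent-change
and paired-t significance maps, consecutive-mixing-time averaging and
multi-slice combination.  All operations are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .acquisition import DEFAULT_T1

__all__ = [
    "MixingTimeSeries",
    "TerritoryMask",
    "DelayMap",
    "PercentChangeMap",
    "TStatMap",
    "t1_correct",
    "voxel_energy",
    "normalize_energy",
    "detect_vessel_voxels",
    "territory_mask",
    "arrival_time",
    "arrival_time_map",
    "delay_map",
    "percent_change",
    "ttest_maps",
    "average_mixing_pairs",
    "combine_multislice",
    "ARRIVAL_GRID_DT",
]

ARRIVAL_GRID_DT = 0.015  # s; interpolation interval for arrival times


@dataclass(frozen=True)
class MixingTimeSeries:
    """Signal magnitudes of one source location / ROI over mixing times."""

    times: np.ndarray  # seconds, strictly increasing
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class TerritoryMask:
    mask: np.ndarray  # bool (nx, nz)
    threshold_frac: float


@dataclass(frozen=True)
class DelayMap:
    values: np.ndarray  # seconds, NaN where undetected
    floor_frac: float
    dt: float = ARRIVAL_GRID_DT


@dataclass(frozen=True)
class PercentChangeMap:
    values: np.ndarray  # percent, NaN where baseline below floor
    floor_frac: float


@dataclass(frozen=True)
class TStatMap:
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float


def t1_correct(series: MixingTimeSeries, t1: float = DEFAULT_T1) -> MixingTimeSeries:
    """Undo longitudinal relaxation: multiply by ``exp(t/T1)`` elementwise
    (default T1 = 1584 ms)."""
    if t1 <= 0:
        raise ValueError("T1 must be > 0")
    return MixingTimeSeries(series.times, series.values * np.exp(series.times / t1))


def voxel_energy(values: np.ndarray, mode: str = "sumsq") -> float:
    """Overall energy of a voxel's source maps over all bins and mixing
    times: sum of squared magnitudes (default) or sum of magnitudes."""
    mags = np.abs(np.asarray(values))
    if mode == "sumsq":
        return float(np.sum(mags**2))
    if mode == "sumabs":
        return float(np.sum(mags))
    raise ValueError(f"unknown energy mode {mode!r}")


def normalize_energy(
    values: np.ndarray, energy: float | None = None, mode: str = "sumsq"
) -> np.ndarray:
    """Divide map values by the voxel's overall energy.

    With ``energy=None`` the map is normalized by its own energy under the
    chosen convention.  Note that only the ``sumabs`` convention is
    invariant to rescaling the input; ``sumsq`` (the default) divides a
    ``c``-scaled map by ``c^2``-scaled energy.
    """
    if energy is None:
        energy = voxel_energy(values, mode=mode)
    if energy <= 0:
        raise ValueError("voxel energy must be > 0")
    return np.asarray(values) / energy


def detect_vessel_voxels(energy_image: np.ndarray, min_frac: float = 0.2) -> np.ndarray:
    """Vessel-containing voxels: 8-connected local maxima of the per-voxel
    source-map energy image above ``min_frac`` of its global maximum.
    Plateaus of equal neighbours are flagged in full."""
    img = np.asarray(energy_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("energy image must be 2-D")
    peak = img.max()
    if peak <= 0:
        return np.zeros_like(img, dtype=bool)
    local_max = img >= ndimage.maximum_filter(img, size=3, mode="constant", cval=-np.inf)
    return local_max & (img >= min_frac * peak)


def territory_mask(mags: np.ndarray, threshold_frac: float = 0.1) -> TerritoryMask:
    """Venous territory: maximum extent of the sources across mixing times.

    ``mags`` is (n_t, nx, nz) magnitude maps; the mask is the union over
    mixing times of bins at or above ``threshold_frac`` of that mixing
    time's maximum (all-zero frames contribute nothing)."""
    m = np.abs(np.asarray(mags))
    if m.ndim != 3:
        raise ValueError("expected (n_t, nx, nz) magnitude maps")
    mask = np.zeros(m.shape[1:], dtype=bool)
    for frame in m:
        peak = frame.max()
        if peak > 0:
            mask |= frame >= threshold_frac * peak
    return TerritoryMask(mask, threshold_frac)


def arrival_time(series: MixingTimeSeries, dt: float = ARRIVAL_GRID_DT) -> float:
    """Blood arrival time of one source location.

    The mixing-time series is linearly interpolated to a ``dt`` (15 ms) grid
    spanning [t_min, t_max]; the arrival is the earliest grid time at which
    the interpolated amplitude reaches 50% of its maximum over the
    interpolated series.  Returns NaN for an all-zero (or negative) series.
    """
    if series.times.size < 2:
        raise ValueError("need at least two samples")
    t0, t1 = series.times[0], series.times[-1]
    grid = t0 + dt * np.arange(int(np.floor((t1 - t0) / dt)) + 1)
    if grid[-1] < t1:  # span [t_min, t_max] inclusively
        grid = np.append(grid, t1)
    interp = np.interp(grid, series.times, series.values)
    peak = interp.max()
    if peak <= 0:
        return float("nan")
    return float(grid[np.argmax(interp >= 0.5 * peak)])


def arrival_time_map(
    times: np.ndarray, values: np.ndarray, dt: float = ARRIVAL_GRID_DT
) -> np.ndarray:
    """Per-bin arrival times for ``values`` of shape (n_t, ...)."""
    times = np.asarray(times, dtype=float)
    vals = np.abs(np.asarray(values))
    flat = vals.reshape(vals.shape[0], -1)
    out = np.array(
        [arrival_time(MixingTimeSeries(times, flat[:, i]), dt=dt) for i in range(flat.shape[1])]
    )
    return out.reshape(vals.shape[1:])


def _floor_mask(mags: np.ndarray, floor_frac: float) -> np.ndarray:
    """Bins whose per-bin peak over mixing times reaches ``floor_frac`` of
    the global map maximum."""
    peaks = np.abs(mags).max(axis=0)
    return peaks >= floor_frac * peaks.max() if peaks.max() > 0 else np.zeros_like(peaks, bool)


def delay_map(
    times: np.ndarray,
    baseline: np.ndarray,
    post: np.ndarray,
    floor_frac: float = 0.05,
    dt: float = ARRIVAL_GRID_DT,
) -> DelayMap:
    """Arrival-time delay, ``arrival(post) - arrival(baseline)`` per bin.

    ``baseline`` and ``post`` are (n_t, nx, nz) magnitude maps on matching
    grids and mixing times; bins below the detection floor (``floor_frac``
    of the map maximum) in either state are NaN.
    """
    baseline = np.abs(np.asarray(baseline))
    post = np.abs(np.asarray(post))
    if baseline.shape != post.shape:
        raise ValueError("baseline and post maps must share grid and mixing times")
    detected = _floor_mask(baseline, floor_frac) & _floor_mask(post, floor_frac)
    tb = arrival_time_map(times, baseline, dt=dt)
    tp = arrival_time_map(times, post, dt=dt)
    vals = tp - tb
    vals[~detected] = np.nan
    return DelayMap(vals, floor_frac, dt)


def percent_change(
    baseline: np.ndarray, task: np.ndarray, floor_frac: float = 0.05
) -> PercentChangeMap:
    """Percent signal change ``(task - baseline) / baseline * 100`` per bin,
    NaN where the baseline is below ``floor_frac`` of its maximum."""
    b = np.abs(np.asarray(baseline, dtype=float))
    t = np.abs(np.asarray(task, dtype=float))
    if b.shape != t.shape:
        raise ValueError("baseline and task maps must share the grid")
    floor = floor_frac * b.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (t - b) / b * 100.0
    vals[b < floor] = np.nan
    return PercentChangeMap(vals, floor_frac)


def ttest_maps(
    baseline: np.ndarray,
    task: np.ndarray,
    alpha: float = 0.05,
    paired: bool = True,
    correction: str | None = None,
) -> TStatMap:
    """Two-sided t-test per bin comparing the mixing-time signal series at
    baseline and during task.

    Series are matched by design, so the default is a paired test over the
    last axis (length >= 3 required); ``paired=False`` gives the
    independent-samples variant.  Bins with zero-variance nonzero paired
    differences get signed-infinity t with p = 0; identical series give
    t = 0, p = 1.  ``correction="bh"`` applies Benjamini-Hochberg to the
    significance mask (off by default, mirroring uncorrected p = 0.05 maps).
    """
    b = np.asarray(baseline, dtype=float)
    t = np.asarray(task, dtype=float)
    if b.shape != t.shape:
        raise ValueError("baseline and task series must have matching shapes")
    n = b.shape[-1]
    if n < 3:
        raise ValueError("need at least 3 paired samples per bin")
    if paired:
        d = t - b
        mean = d.mean(axis=-1)
        sd = d.std(axis=-1, ddof=1)
        df = n - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = mean / (sd / np.sqrt(n))
        zerovar = sd == 0
        tstat = np.where(zerovar & (mean > 0), np.inf, tstat)
        tstat = np.where(zerovar & (mean < 0), -np.inf, tstat)
        tstat = np.where(zerovar & (mean == 0), 0.0, tstat)
    else:
        res = stats.ttest_ind(t, b, axis=-1)
        tstat = np.nan_to_num(res.statistic, nan=0.0, posinf=np.inf, neginf=-np.inf)
        df = 2 * n - 2
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.where(np.isinf(tstat), 0.0, p)
    p = np.where(tstat == 0.0, np.minimum(p, 1.0), p)
    if correction is None:
        sig = p < alpha
    elif correction == "bh":
        flat = p.ravel()
        order = np.argsort(flat)
        m = flat.size
        thresh = alpha * (np.arange(1, m + 1)) / m
        passed = flat[order] <= thresh
        k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
        sig = np.zeros(m, dtype=bool)
        sig[order[:k]] = True
        sig = sig.reshape(p.shape)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return TStatMap(np.asarray(tstat), np.asarray(p), sig, alpha)


def average_mixing_pairs(
    times: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average maps over consecutive mixing-time pairs.

    ``values`` has the time axis first; pairs (0,1), (2,3), ... are averaged
    elementwise and labelled with the mean time of the pair (400 & 500 ms ->
    450 ms); an odd leftover frame is passed through unpaired.
    """
    times = np.asarray(times, dtype=float)
    vals = np.asarray(values)
    if times.size != vals.shape[0]:
        raise ValueError("time axis mismatch")
    out_t, out_v = [], []
    for i in range(0, times.size - 1, 2):
        out_t.append((times[i] + times[i + 1]) / 2.0)
        out_v.append((vals[i] + vals[i + 1]) / 2.0)
    if times.size % 2:
        out_t.append(times[-1])
        out_v.append(vals[-1])
    return np.asarray(out_t), np.stack(out_v)


def combine_multislice(
    entries: list[tuple[np.ndarray, tuple[float, float], np.ndarray, np.ndarray]],
    res: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum absolute-frame maps of one labelled vein across slices.

    Each entry is ``(values (n_t, nx, nz), origin (x, z), offsets_x,
    offsets_z)`` with bin coordinate ``origin + offset``; all entries share
    ``res`` and mixing times.  Returns ``(global_x, global_z, summed)`` on
    the union grid (entries are placed at their nearest global bin; slice
    offsets that are multiples of ``res`` place exactly).
    """
    if not entries:
        raise ValueError("no maps to combine")
    rx, rz = res
    axs = [np.asarray(e[1], dtype=float)[0] + np.asarray(e[2]) for e in entries]
    azs = [np.asarray(e[1], dtype=float)[1] + np.asarray(e[3]) for e in entries]
    x0 = min(a.min() for a in axs)
    z0 = min(a.min() for a in azs)
    x1 = max(a.max() for a in axs)
    z1 = max(a.max() for a in azs)
    gx = np.arange(x0, x1 + rx / 2, rx)
    gz = np.arange(z0, z1 + rz / 2, rz)
    n_t = entries[0][0].shape[0]
    out = np.zeros((n_t,) + (gx.size, gz.size), dtype=np.result_type(*[e[0].dtype for e in entries]))
    for (vals, origin, ox, oz), axv, azv in zip(entries, axs, azs):
        if vals.shape[0] != n_t:
            raise ValueError("entries must share mixing times")
        i0 = int(round((axv[0] - x0) / rx))
        j0 = int(round((azv[0] - z0) / rz))
        out[:, i0 : i0 + axv.size, j0 : j0 + azv.size] += vals
    return gx, gz, out
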