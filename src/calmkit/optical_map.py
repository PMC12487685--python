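"""Optical-mapping analysis: activation, APD and conduction-velocity maps.

Epicardial voltage-dye movies are reduced per pixel to an activation time
(maximum upstroke slope, sub-sample refined) and action-potential
durations at 30/50/80 % repolarization. Activation maps are then turned
into local conduction-velocity estimates by sliding-window plane fits;
maximal and minimal velocities across propagation directions quantify
anisotropy (fast-axis vs transverse conduction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ApMovie",
    "ActivationMap",
    "CvResult",
    "activation_time",
    "apd",
    "compute_maps",
    "conduction_velocity",
    "isochron_map",
]

APD_LEVELS = (30, 50, 80)


@dataclass
class ApMovie:
    """Fluorescence movie F(t, y, x) on a uniform grid.

    ``frames`` has shape (T, R, C); ``dt_ms`` is the frame interval and
    ``pitch_mm`` the pixel pitch. ``truth`` optionally carries generator
    ground truth (activation/APD maps, wave speeds) for recovery tests.
    """

    frames: np.ndarray
    dt_ms: float
    pitch_mm: float
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, R, C) array")
        if self.dt_ms <= 0 or self.pitch_mm <= 0:
            raise ValueError("dt_ms and pitch_mm must be strictly positive")


@dataclass
class ActivationMap:
    activation_ms: np.ndarray
    apd_ms: dict[int, np.ndarray]
    valid: np.ndarray
    pitch_mm: float


@dataclass(frozen=True)
class CvResult:
    cv_max: float
    cv_min: float
    fast_axis_deg: float


def activation_time(
    trace: np.ndarray,
    dt_ms: float,
    baseline_samples: int = 10,
    slope_threshold_factor: float = 5.0,
) -> float:
    """Activation time of one pixel: instant of maximum upstroke slope.

    The slope maximum is refined to sub-sample precision by a parabolic
    fit through the three samples around it. The upstroke must exceed
    ``slope_threshold_factor`` times the SD of the derivative over the
    first ``baseline_samples`` frames (pre-stimulus noise); otherwise
    ``nan`` is returned and the pixel should be masked.
    """
    f = np.asarray(trace, dtype=float)
    if f.size < 3:
        raise ValueError("trace too short")
    d = np.gradient(f, dt_ms)
    base_sd = float(np.std(d[:baseline_samples]))
    k = int(np.argmax(d))
    if d[k] <= max(slope_threshold_factor * base_sd, 1e-12):
        return float("nan")
    if 0 < k < f.size - 1:
        y0, y1, y2 = d[k - 1], d[k], d[k + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    return (k + shift) * dt_ms


def apd(
    trace: np.ndarray,
    dt_ms: float,
    level: int,
    act_ms: float | None = None,
    baseline_samples: int = 10,
) -> float:
    """Action-potential duration at a repolarization level (30/50/80).

    Duration from the activation time to the first interpolated crossing
    of ``level`` percent repolarization, i.e. where fluorescence has
    returned by ``level`` % of the upstroke amplitude (APD80 crosses at
    20 % of amplitude above baseline). Amplitude is peak minus baseline;
    baseline is the pre-upstroke mean. ``nan`` when the trace never
    recrosses within the record.
    """
    if level not in APD_LEVELS:
        raise ValueError(f"level must be one of {APD_LEVELS}")
    f = np.asarray(trace, dtype=float)
    if act_ms is None:
        act_ms = activation_time(f, dt_ms, baseline_samples=baseline_samples)
    if not np.isfinite(act_ms):
        return float("nan")
    act_idx = int(act_ms / dt_ms)
    n_base = max(min(act_idx - 1, baseline_samples), 1)
    baseline = float(f[:n_base].mean())
    peak_idx = act_idx + int(np.argmax(f[act_idx:]))
    peak = f[peak_idx]
    amp = peak - baseline
    if amp <= 0:
        return float("nan")
    target = peak - (level / 100.0) * amp
    seg = f[peak_idx:]
    below = np.flatnonzero(seg <= target)
    if below.size == 0:
        return float("nan")
    j = int(below[0])
    if j == 0:
        t_cross = peak_idx * dt_ms
    else:
        f1, f2 = seg[j - 1], seg[j]
        frac = (f1 - target) / (f1 - f2)
        t_cross = (peak_idx + j - 1 + frac) * dt_ms
    return t_cross - act_ms


def compute_maps(
    movie: ApMovie,
    levels: tuple[int, ...] = APD_LEVELS,
    baseline_samples: int = 10,
) -> ActivationMap:
    """Per-pixel activation time and APD maps for a whole movie."""
    _, nr, nc = movie.frames.shape
    act = np.full((nr, nc), np.nan)
    apds = {lv: np.full((nr, nc), np.nan) for lv in levels}
    for r in range(nr):
        for c in range(nc):
            tr = movie.frames[:, r, c]
            a = activation_time(tr, movie.dt_ms, baseline_samples=baseline_samples)
            act[r, c] = a
            if np.isfinite(a):
                for lv in levels:
                    apds[lv][r, c] = apd(
                        tr, movie.dt_ms, lv, act_ms=a, baseline_samples=baseline_samples
                    )
    valid = np.isfinite(act)
    for lv in levels:
        valid &= np.isfinite(apds[lv])
    return ActivationMap(activation_ms=act, apd_ms=apds, valid=valid, pitch_mm=movie.pitch_mm)


def _plane_fit_gradients(
    act: np.ndarray, valid: np.ndarray, pitch_mm: float, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window least-squares plane fits of activation time.

    Returns per-pixel gradient components (dt/dx, dt/dy) in ms/mm; nan
    where the window lacks enough valid pixels.
    """
    half = window // 2
    nr, nc = act.shape
    gx = np.full((nr, nc), np.nan)
    gy = np.full((nr, nc), np.nan)
    offs = np.arange(-half, half + 1) * pitch_mm
    xo, yo = np.meshgrid(offs, offs)
    min_pts = (window * window) // 2 + 1
    for r in range(half, nr - half):
        for c in range(half, nc - half):
            win_t = act[r - half : r + half + 1, c - half : c + half + 1]
            win_v = valid[r - half : r + half + 1, c - half : c + half + 1]
            if win_v.sum() < min_pts:
                continue
            x = xo[win_v]
            y = yo[win_v]
            t = win_t[win_v]
            a = np.column_stack([np.ones_like(x), x, y])
            coef, *_ = np.linalg.lstsq(a, t, rcond=None)
            gx[r, c] = coef[1]
            gy[r, c] = coef[2]
    return gx, gy


def conduction_velocity(
    amap: ActivationMap,
    window: int = 5,
    n_direction_bins: int = 18,
    min_bin_count: int = 10,
    min_grad_ms_per_mm: float = 1e-6,
) -> CvResult:
    """Anisotropic conduction velocities from an activation map.

    Each pixel's local wavefront velocity is 1/|grad t| from a
    ``window`` x ``window`` plane fit, directed along the gradient.
    Directions (mod 180 deg) are binned; CV_max / CV_min are the extreme
    direction-binned median speeds and the fast axis the bin direction of
    CV_max. Median binning makes the estimate robust to fit noise at
    wavefront collisions and map edges.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if amap.valid.sum() < 25:
        raise ValueError("need at least 5x5 valid pixels")
    gx, gy = _plane_fit_gradients(amap.activation_ms, amap.valid, amap.pitch_mm, window)
    gmag = np.hypot(gx, gy)
    ok = np.isfinite(gmag) & (gmag > min_grad_ms_per_mm)
    speeds = 1.0 / gmag[ok]
    angles = np.mod(np.arctan2(gy[ok], gx[ok]), np.pi)  # direction of propagation, mod pi
    bins = np.floor(angles / (np.pi / n_direction_bins)).astype(int) % n_direction_bins
    medians: dict[int, float] = {}
    for b in range(n_direction_bins):
        sel = bins == b
        if sel.sum() >= min_bin_count:
            medians[b] = float(np.median(speeds[sel]))
    if not medians:
        raise ValueError("no direction bin has enough velocity samples")
    cv_max = max(medians.values())
    cv_min = min(medians.values())
    # fast axis from the second circular harmonic of speed vs direction;
    # smoother than the argmax bin when several bins straddle the axis
    centers = np.array([(b + 0.5) * np.pi / n_direction_bins for b in medians])
    m = np.array(list(medians.values()))
    m = m - m.mean()
    axis = 0.5 * np.arctan2(np.sum(m * np.sin(2 * centers)), np.sum(m * np.cos(2 * centers)))
    axis_deg = float(np.degrees(axis % np.pi))
    return CvResult(cv_max=cv_max, cv_min=cv_min, fast_axis_deg=axis_deg)


def isochron_map(times_ms: np.ndarray, interval_ms: float) -> np.ndarray:
    """Bin a time map into isochron bands of fixed width.

    Band k covers [t_min + k*interval, t_min + (k+1)*interval); invalid
    (nan) pixels get label -1. Deterministic labeling.
    """
    if interval_ms <= 0:
        raise ValueError("interval must be strictly positive")
    t = np.asarray(times_ms, dtype=float)
    finite = np.isfinite(t)
    if not finite.any():
        raise ValueError("no valid pixels to contour")
    t0 = np.nanmin(t)
    labels = np.full(t.shape, -1, dtype=int)
    labels[finite] = np.floor((t[finite] - t0) / interval_ms).astype(int)
    return labels
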