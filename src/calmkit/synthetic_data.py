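"""Seed-controlled synthetic inputs for every analysis stage.

Each generator draws from the noise model its downstream analysis
assumes — binomial allelic read sampling, Poisson fragment counts,
multiplicative lognormal measurement noise on peak areas, densitometry
and intervals, exponential protein decay, bi-exponential current decay
and elliptical anisotropic wavefronts — and returns its own ground truth
so recovery tests need no external oracle. Identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .cellular_ep import R50_OFFSET_MS
from .optical_map import ApMovie
from .transcript_quant import AlleleCount

__all__ = [
    "SimConfig",
    "gen_allelic_reads",
    "gen_fragment_counts",
    "gen_srm_areas",
    "gen_chase",
    "gen_beats",
    "gen_current_trace",
    "expected_r50",
    "gen_ap_movie",
    "ap_template",
    "gen_histology",
]


@dataclass(frozen=True)
class SimConfig:
    """Root seed from which every generator derives an independent stream.

    ``rng(label)`` returns a reproducible, label-specific generator so
    that adding one simulated dataset never perturbs another.
    """

    seed: int

    def rng(self, label: str = "") -> np.random.Generator:
        ss = np.random.SeedSequence([self.seed, *label.encode()])
        return np.random.default_rng(ss)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit median and coefficient of variation cv."""
    if cv < 0:
        raise ValueError("coefficient of variation must be non-negative")
    if cv == 0:
        return np.ones(() if size is None else size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size))


# ---------------------------------------------------------------------------
# transcripts


def gen_allelic_reads(
    mutant_fraction: float, depth: int, seed, position: str = "chr12:100206105"
) -> AlleleCount:
    """Binomially sampled allelic read counts at a tagging variant.

    ``alt_count ~ Binomial(depth, mutant_fraction)``;
    ``ref_count = depth - alt_count``.
    """
    if not 0.0 <= mutant_fraction <= 1.0:
        raise ValueError("mutant_fraction must lie in [0, 1]")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = _rng(seed)
    alt = int(rng.binomial(depth, mutant_fraction))
    return AlleleCount(ref_count=depth - alt, alt_count=alt, position=position)


def gen_fragment_counts(
    true_fpkm: np.ndarray,
    lengths_kb: np.ndarray,
    total_mapped_millions: float,
    seed,
    poisson: bool = True,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene fragment counts whose expectation inverts the FPKM formula.

    Expected count = fpkm * length_kb * library_millions, Poisson-sampled
    unless ``poisson=False`` (then exact expectations are returned, which
    is useful for closed-form checks).
    """
    fpkm = np.asarray(true_fpkm, dtype=float)
    length = np.asarray(lengths_kb, dtype=float)
    if np.any(fpkm < 0):
        raise ValueError("true FPKM must be non-negative")
    if np.any(length <= 0) or total_mapped_millions <= 0:
        raise ValueError("lengths and library size must be strictly positive")
    lam = fpkm * length * total_mapped_millions
    counts = _rng(seed).poisson(lam).astype(float) if poisson else lam
    if genes is None:
        genes = [f"gene{i}" for i in range(len(fpkm))]
    return pd.DataFrame(
        {
            "gene": genes,
            "count": counts,
            "length_kb": length,
            "true_fpkm": fpkm,
        }
    )


# ---------------------------------------------------------------------------
# protein


def gen_srm_areas(
    true_amounts_fmol: dict[str, float],
    spike_fmol: float,
    cv: float,
    seed,
    n_samples: int = 1,
) -> pd.DataFrame:
    """Light/heavy peak areas for spiked-standard peptide quantification.

    Per sample a shared detector gain links all peptides; light and heavy
    areas each carry independent lognormal noise with the given cv. The
    light/heavy ratio is therefore gain-free with unit-median noise.
    Truth is stored in ``true_fmol``.
    """
    if spike_fmol <= 0:
        raise ValueError("spike amount must be strictly positive")
    if any(a <= 0 for a in true_amounts_fmol.values()):
        raise ValueError("true amounts must be strictly positive")
    rng = _rng(seed)
    rows = []
    for s in range(n_samples):
        gain = np.exp(rng.normal(0.0, 0.3))  # arbitrary per-sample detector scale
        for pep, amt in true_amounts_fmol.items():
            light = gain * amt * _lognormal_factor(rng, cv, None)
            heavy = gain * spike_fmol * _lognormal_factor(rng, cv, None)
            rows.append(
                {
                    "sample": f"s{s}",
                    "peptide": pep,
                    "light_area": float(light),
                    "heavy_area": float(heavy),
                    "spike_fmol": spike_fmol,
                    "true_fmol": amt,
                }
            )
    return pd.DataFrame(rows)


def gen_chase(
    half_life_h: float,
    times_h: np.ndarray,
    cv: float,
    seed,
    control_intensity: float = 1000.0,
) -> pd.DataFrame:
    """Cycloheximide-chase densitometry with exponential decay.

    Band intensity decays as 2^(-t/half_life) under multiplicative
    lognormal noise; the loading control is constant. Expected percent
    remaining is 100 * 2^(-t/half_life) (stored in ``true_percent``).
    """
    if half_life_h <= 0:
        raise ValueError("half-life must be strictly positive")
    t = np.asarray(times_h, dtype=float)
    rng = _rng(seed)
    true_pct = 100.0 * np.power(2.0, -t / half_life_h)
    band = control_intensity * (true_pct / 100.0) * _lognormal_factor(rng, cv, t.shape)
    return pd.DataFrame(
        {
            "time_h": t,
            "band": band,
            "control": np.full_like(t, control_intensity),
            "true_percent": true_pct,
        }
    )


# ---------------------------------------------------------------------------
# ECG


def gen_beats(
    alpha_ms: float,
    exponent_n: float,
    rr_range_ms: tuple[float, float],
    n_beats: int,
    cv: float,
    seed,
) -> pd.DataFrame:
    """Beat series obeying a power-law QT-RR relation.

    RR is uniform over ``rr_range_ms``; QT = alpha * (RR/RR_mean)^n under
    multiplicative lognormal noise, where RR_mean is the realized series
    mean (the same normalization the exponent fit uses).
    """
    lo, hi = rr_range_ms
    if not 0 < lo <= hi:
        raise ValueError("RR range must be positive with lo <= hi")
    if n_beats < 2:
        raise ValueError("need at least 2 beats")
    rng = _rng(seed)
    rr = rng.uniform(lo, hi, n_beats)
    qt = alpha_ms * (rr / rr.mean()) ** exponent_n * _lognormal_factor(rng, cv, n_beats)
    return pd.DataFrame({"rr_ms": rr, "qt_ms": qt})


# ---------------------------------------------------------------------------
# patch clamp


def gen_current_trace(
    peak_pa: float,
    tau_cdi_ms: float,
    tau_vdi_ms: float,
    carrier: str = "Ca",
    dt_ms: float = 0.1,
    dur_ms: float = 400.0,
    step_onset_ms: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Idealized whole-cell current during a step depolarization.

    The current jumps to its (inward-negative) peak at step onset and
    decays as the product of a CDI and a VDI exponential; with Ba2+ as
    the carrier only VDI applies. Activation and capacitive transients
    are omitted so the remaining fraction over any 50 ms window has the
    closed form :func:`expected_r50`. Use ``np.inf`` for an absent
    inactivation pathway.
    """
    if peak_pa <= 0:
        raise ValueError("peak amplitude must be positive (sign is applied internally)")
    if tau_cdi_ms <= 0 or tau_vdi_ms <= 0:
        raise ValueError("time constants must be positive (np.inf for none)")
    if carrier not in ("Ca", "Ba"):
        raise ValueError("carrier must be 'Ca' or 'Ba'")
    t = np.arange(0.0, dur_ms + dt_ms / 2, dt_ms)
    rate = 1.0 / tau_vdi_ms + (1.0 / tau_cdi_ms if carrier == "Ca" else 0.0)
    i = np.zeros_like(t)
    on = t >= step_onset_ms
    i[on] = -peak_pa * np.exp(-(t[on] - step_onset_ms) * rate)
    return t, i


def expected_r50(tau_cdi_ms: float, tau_vdi_ms: float, carrier: str = "Ca") -> float:
    """Closed-form fraction remaining 50 ms after the peak for a generated trace."""
    rate = 1.0 / tau_vdi_ms + (1.0 / tau_cdi_ms if carrier == "Ca" else 0.0)
    return float(np.exp(-R50_OFFSET_MS * rate))


# ---------------------------------------------------------------------------
# optical mapping

#: upstroke duration of the analytic AP template (ms)
UPSTROKE_MS = 2.0


def _template_tau(apd80_ms: float) -> float:
    # repolarization time constant such that the 80 % crossing measured from
    # the max-slope instant equals apd80: apd80 = t_up/2 + tau*ln 5
    tau = (apd80_ms - UPSTROKE_MS / 2.0) / np.log(5.0)
    if tau <= 0:
        raise ValueError("APD80 too short for the template upstroke")
    return tau


def ap_template(t_ms: np.ndarray, act_ms: float, apd80_ms: float) -> np.ndarray:
    """Piecewise analytic optical action potential, amplitude 1.

    Half-cosine upstroke of 2 ms (maximum slope, i.e. the detected
    activation time, at its midpoint ``act_ms``) followed by exponential
    repolarization whose rate is set so that the 80 % repolarization
    crossing falls ``apd80_ms`` after the activation time. All level
    crossings have closed forms (see :func:`template_apd`).
    """
    tau = _template_tau(apd80_ms)
    t0 = act_ms - UPSTROKE_MS / 2.0  # upstroke start
    t1 = t0 + UPSTROKE_MS
    f = np.zeros_like(t_ms, dtype=float)
    rising = (t_ms >= t0) & (t_ms < t1)
    f[rising] = 0.5 * (1.0 - np.cos(np.pi * (t_ms[rising] - t0) / UPSTROKE_MS))
    falling = t_ms >= t1
    f[falling] = np.exp(-(t_ms[falling] - t1) / tau)
    return f


def template_apd(apd80_ms: float, level: int) -> float:
    """Closed-form APD of the template at a repolarization level."""
    tau = _template_tau(apd80_ms)
    return UPSTROKE_MS / 2.0 + tau * np.log(100.0 / (100.0 - level))


def gen_ap_movie(
    grid: tuple[int, int] = (40, 40),
    cv_long_mm_per_ms: float = 0.6,
    cv_trans_mm_per_ms: float = 0.3,
    origin_px: tuple[float, float] | None = None,
    apd_field_ms: float | np.ndarray = 40.0,
    fiber_angle_deg: float = 0.0,
    dt_ms: float = 0.5,
    pitch_mm: float = 0.1,
    dur_ms: float | None = None,
    noise_sd: float = 0.0,
    seed=0,
) -> ApMovie:
    """Movie of an elliptical wavefront spreading from a point source.

    Activation time at each pixel follows the elliptical geometry
    t = sqrt((u/CV_long)^2 + (v/CV_trans)^2) with (u, v) the coordinates
    along/across the fiber axis; each pixel's trace is the analytic AP
    template stretched to the local APD80. Ground truth (activation and
    APD maps, speeds, axis) is stored in ``.truth``.
    """
    nr, nc = grid
    if cv_long_mm_per_ms <= 0 or cv_trans_mm_per_ms <= 0:
        raise ValueError("conduction velocities must be positive")
    if origin_px is None:
        # a central source keeps fast- and slow-axis pixels inside the
        # interior region where CV plane fits are defined
        origin_px = ((nr - 1) / 2.0, (nc - 1) / 2.0)
    yy, xx = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    dx = (xx - origin_px[1]) * pitch_mm
    dy = (yy - origin_px[0]) * pitch_mm
    th = np.radians(fiber_angle_deg)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    act = np.sqrt((u / cv_long_mm_per_ms) ** 2 + (v / cv_trans_mm_per_ms) ** 2)
    # leave room for the pre-upstroke baseline the analyzers expect
    act = act + 12 * dt_ms + UPSTROKE_MS
    apd80 = np.broadcast_to(np.asarray(apd_field_ms, dtype=float), (nr, nc))
    if dur_ms is None:
        dur_ms = float(act.max() + apd80.max() + 30.0)
    t = np.arange(0.0, dur_ms, dt_ms)
    frames = np.empty((t.size, nr, nc))
    for r in range(nr):
        for c in range(nc):
            frames[:, r, c] = ap_template(t, act[r, c], apd80[r, c])
    if noise_sd > 0:
        frames += _rng(seed).normal(0.0, noise_sd, frames.shape)
    truth = {
        "activation_ms": act,
        "apd_ms": {lv: np.vectorize(template_apd)(apd80, lv) for lv in (30, 50, 80)},
        "cv_long": cv_long_mm_per_ms,
        "cv_trans": cv_trans_mm_per_ms,
        "fiber_angle_deg": fiber_angle_deg,
    }
    return ApMovie(frames=frames, dt_ms=dt_ms, pitch_mm=pitch_mm, truth=truth)


# ---------------------------------------------------------------------------
# histology


def gen_histology(
    size: int = 512,
    fibrosis_fraction: float = 0.25,
    seed=0,
    field_sigma_px: float = 8.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic trichrome-like section with known fibrotic fraction.

    Tissue (a central disk) is red-dominant; a spatially correlated
    random field selects exactly the requested fraction of tissue pixels
    as blue-dominant fibrosis; background is near-black. Returns
    ``(rgb_uint8, tissue_mask, fibrosis_mask)``.
    """
    if not 0.0 <= fibrosis_fraction <= 1.0:
        raise ValueError("fibrosis_fraction must lie in [0, 1]")
    rng = _rng(seed)
    yy, xx = np.mgrid[:size, :size]
    center = (size - 1) / 2.0
    tissue = (yy - center) ** 2 + (xx - center) ** 2 <= (0.45 * size) ** 2

    field = ndimage.gaussian_filter(rng.normal(size=(size, size)), field_sigma_px)
    vals = field[tissue]
    if fibrosis_fraction <= 0:
        fibrotic = np.zeros_like(tissue)
    elif fibrosis_fraction >= 1:
        fibrotic = tissue.copy()
    else:
        thr = np.quantile(vals, 1.0 - fibrosis_fraction)
        fibrotic = tissue & (field > thr)

    img = np.zeros((size, size, 3))
    img += rng.normal(8.0, 3.0, img.shape)  # dark slide background
    muscle = tissue & ~fibrotic
    img[muscle] = [200.0, 60.0, 60.0]
    img[fibrotic] = [60.0, 60.0, 200.0]
    img[tissue] += rng.normal(0.0, 10.0, (int(tissue.sum()), 3))
    return np.clip(img, 0, 255).astype(np.uint8), tissue, fibrotic
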