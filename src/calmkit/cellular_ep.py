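"""Ca2+-dependent inactivation (CDI) statistics from whole-cell currents.

L-type Ca2+ current decays by both Ca2+/calmodulin-dependent (CDI) and
voltage-dependent (VDI) inactivation; with Ba2+ as the charge carrier
only VDI remains. The fraction of peak current remaining 50 ms after the
peak (r50), measured with each carrier in the same cell, isolates CDI via
f50 = (r50_Ca - r50_Ba) / r50_Ba, which is <= 0 when CDI is present and 0
in its absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CdiResult", "r50", "f50", "cdi_decrement"]

#: r50 measures the remaining fraction this long after the peak (ms)
R50_OFFSET_MS = 50.0


@dataclass(frozen=True)
class CdiResult:
    r50_ca: float
    r50_ba: float
    f50: float


def r50(
    time_ms: np.ndarray,
    current_pa: np.ndarray,
    step_onset_ms: float = 0.0,
    peak_window_ms: tuple[float, float] = (2.0, 100.0),
) -> float:
    """Fraction of peak current remaining 50 ms after the peak.

    The peak is the maximum |current| within ``step_onset +
    peak_window``; the window's lower edge skips the capacitive
    transient. The remaining fraction is evaluated at peak time + 50 ms
    with linear interpolation between samples. Invariant to amplitude
    scaling and sign convention (inward-negative or magnitude traces).
    """
    t = np.asarray(time_ms, dtype=float)
    i = np.abs(np.asarray(current_pa, dtype=float))
    if t.size != i.size or t.size < 2:
        raise ValueError("time and current must be equal-length with >= 2 samples")
    lo = step_onset_ms + peak_window_ms[0]
    hi = step_onset_ms + peak_window_ms[1]
    in_win = (t >= lo) & (t <= hi)
    if not in_win.any():
        raise ValueError("peak-search window contains no samples")
    idx = np.flatnonzero(in_win)
    peak_idx = idx[np.argmax(i[idx])]
    t_peak = t[peak_idx]
    i_peak = i[peak_idx]
    if i_peak <= 0:
        raise ValueError("zero-amplitude trace: r50 undefined")
    t_eval = t_peak + R50_OFFSET_MS
    if t_eval > t[-1]:
        raise ValueError(
            f"trace ends {t[-1] - t_peak:.1f} ms after the peak; "
            f"{R50_OFFSET_MS:.0f} ms required"
        )
    return float(np.interp(t_eval, t, i) / i_peak)


def f50(r50_ca: float, r50_ba: float) -> float:
    """CDI statistic: excess inactivation of Ca2+ over Ba2+ current.

    f50 = (r50_Ca - r50_Ba) / r50_Ba; 0 means no CDI, more negative means
    stronger CDI. |f50| is reported as CDI strength.
    """
    if r50_ba <= 0:
        raise ValueError("r50 with Ba2+ carrier must be positive")
    return (r50_ca - r50_ba) / r50_ba


def paired_cdi(
    time_ms: np.ndarray,
    current_ca_pa: np.ndarray,
    current_ba_pa: np.ndarray,
    step_onset_ms: float = 0.0,
) -> CdiResult:
    """r50 for both carriers of one cell and the resulting f50."""
    rca = r50(time_ms, current_ca_pa, step_onset_ms)
    rba = r50(time_ms, current_ba_pa, step_onset_ms)
    return CdiResult(r50_ca=rca, r50_ba=rba, f50=f50(rca, rba))


def cdi_decrement(
    f50_median_group: float, f50_median_ref: float, ndigits: int | None = 1
) -> float:
    """Percent reduction of CDI strength |f50| relative to a reference group.

    ``100 * (|f50_ref| - |f50_group|) / |f50_ref|``; positive values mean
    the group has weaker CDI than the reference.
    """
    ref = abs(f50_median_ref)
    if ref == 0:
        raise ValueError("reference |f50| must be non-zero")
    pct = 100.0 * (ref - abs(f50_median_group)) / ref
    return pct if ndigits is None else round(pct, ndigits)
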