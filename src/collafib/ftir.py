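"""ATR-FTIR spectral stability metrics for collagen.

Baseline correction (rubber-band convex hull by default), normalization to
unit Amide I peak height, Amide I/II peak metrics, Amide III triplet
detection, and native-vs-denatured signature classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from . import mechanics

# analysis windows (cm^-1)
AMIDE_I_WINDOW = (1600.0, 1700.0)
AMIDE_II_WINDOW = (1500.0, 1590.0)
AMIDE_III_WINDOW = (1190.0, 1295.0)
TRIPLET_CENTERS_CM1 = (1205.0, 1235.0, 1280.0)
TRIPLET_TOL_CM1 = 10.0
# denaturation shifts Amide I from ~1630 up to ~1640
DENATURED_AMIDE_I_MIN_CM1 = 1637.0

# Savitzky-Golay smoothing before peak picking (points on a ~1 cm^-1 grid)
SMOOTH_WINDOW_PTS = 11
SMOOTH_POLYORDER = 3
# minimum peak prominence for Amide III sub-peaks, in units of the
# (unit-normalized) Amide I height; set above the smoothed noise floor of
# typical traces so noise bumps never count as sub-bands
TRIPLET_MIN_PROMINENCE = 0.02


@dataclass
class Spectrum:
    wavenumbers_cm1: np.ndarray
    absorbance: np.ndarray
    id: str = ""
    preprocessing_log: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.wavenumbers_cm1 = np.asarray(self.wavenumbers_cm1, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers_cm1.shape != self.absorbance.shape:
            raise ValueError("wavenumber/absorbance length mismatch")
        if np.any(np.diff(self.wavenumbers_cm1) <= 0):
            raise ValueError("wavenumbers must be strictly ascending")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("non-finite absorbance")


@dataclass
class BandMetrics:
    amideI_peak_cm1: float
    amideII_peak_cm1: float
    amideI_II_ratio: float
    amideIII_triplet_present: bool
    amideIII_peaks_cm1: tuple[float, ...]
    denatured_signature: bool


def _lower_hull_baseline(wn: np.ndarray, ab: np.ndarray) -> np.ndarray:
    """Rubber-band baseline: lower convex hull interpolated over the grid."""
    hull: list[int] = []
    for i in range(len(wn)):
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (wn[a] - wn[o]) * (ab[i] - ab[o]) - (ab[a] - ab[o]) * (wn[i] - wn[o])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(wn, wn[hull], ab[hull])


def preprocess(spectrum: Spectrum, baseline: str = "rubberband") -> Spectrum:
    """Baseline-correct and normalize a spectrum to unit Amide I height.

    ``baseline`` is ``"rubberband"`` (lower convex hull, default) or
    ``"linear"`` (straight line through the endpoints).  Both steps are
    recorded in ``preprocessing_log``.  Idempotent within tolerance.
    """
    wn, ab = spectrum.wavenumbers_cm1, spectrum.absorbance
    if wn.min() > 810.0 or wn.max() < 1790.0:
        raise ValueError("spectrum must cover at least 800-1800 cm^-1")
    if baseline == "rubberband":
        base = _lower_hull_baseline(wn, ab)
    elif baseline == "linear":
        base = ab[0] + (ab[-1] - ab[0]) * (wn - wn[0]) / (wn[-1] - wn[0])
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    corrected = ab - base
    sel = (wn >= AMIDE_I_WINDOW[0]) & (wn <= AMIDE_I_WINDOW[1])
    peak = float(corrected[sel].max())
    if peak <= 0:
        raise ValueError("no positive Amide I signal after baseline correction")
    return Spectrum(
        wavenumbers_cm1=wn.copy(),
        absorbance=corrected / peak,
        id=spectrum.id,
        preprocessing_log=spectrum.preprocessing_log
        + (f"baseline:{baseline}", "normalize:amideI"),
    )


def _window_peak(
    wn: np.ndarray, y: np.ndarray, window: tuple[float, float]
) -> tuple[float, float] | None:
    """Highest local maximum inside a wavenumber window -> (position, height)."""
    peaks, _ = find_peaks(y)
    sel = peaks[(wn[peaks] >= window[0]) & (wn[peaks] <= window[1])]
    if sel.size == 0:
        return None
    best = sel[np.argmax(y[sel])]
    return float(wn[best]), float(y[best])


def band_metrics(spectrum: Spectrum, ratio_mode: str = "height") -> BandMetrics:
    """Amide band summary of a preprocessed spectrum.

    Peak positions come from local maxima of a Savitzky-Golay smoothed
    trace inside documented windows; the Amide I/II ratio uses smoothed
    peak heights (or integrated band areas with ``ratio_mode="area"``).
    The triplet is present iff a local maximum of sufficient prominence is
    found within +/-10 cm^-1 of each of 1205/1235/1280 cm^-1.  The
    denatured signature is (Amide I >= 1637 cm^-1) AND (triplet absent).
    """
    wn, ab = spectrum.wavenumbers_cm1, spectrum.absorbance
    y = savgol_filter(ab, SMOOTH_WINDOW_PTS, SMOOTH_POLYORDER)

    amide_i = _window_peak(wn, y, AMIDE_I_WINDOW)
    if amide_i is None:
        raise ValueError("no Amide I peak found: not a collagen-like spectrum")
    amide_ii = _window_peak(wn, y, AMIDE_II_WINDOW)
    if amide_ii is None:
        raise ValueError("no Amide II peak found: not a collagen-like spectrum")

    if ratio_mode == "height":
        ratio = amide_i[1] / amide_ii[1]
    elif ratio_mode == "area":
        def area(window: tuple[float, float]) -> float:
            sel = (wn >= window[0]) & (wn <= window[1])
            return float(np.trapezoid(np.clip(y[sel], 0.0, None), wn[sel]))
        ratio = area(AMIDE_I_WINDOW) / max(area(AMIDE_II_WINDOW), 1e-12)
    else:
        raise ValueError(f"unknown ratio mode {ratio_mode!r}")

    peaks, props = find_peaks(y, prominence=TRIPLET_MIN_PROMINENCE)
    sub = peaks[(wn[peaks] >= AMIDE_III_WINDOW[0]) & (wn[peaks] <= AMIDE_III_WINDOW[1])]
    found: list[float] = []
    triplet = True
    for center in TRIPLET_CENTERS_CM1:
        near = sub[np.abs(wn[sub] - center) <= TRIPLET_TOL_CM1]
        if near.size == 0:
            triplet = False
            continue
        found.append(float(wn[near[np.argmax(y[near])]]))

    return BandMetrics(
        amideI_peak_cm1=amide_i[0],
        amideII_peak_cm1=amide_ii[0],
        amideI_II_ratio=float(ratio),
        amideIII_triplet_present=triplet,
        amideIII_peaks_cm1=tuple(found),
        denatured_signature=(amide_i[0] >= DENATURED_AMIDE_I_MIN_CM1) and not triplet,
    )


def compare_ratios(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Difference of mean Amide I/II ratios and a two-sided rank-sum p value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 spectra per group")
    _, p = mechanics.rank_sum_test(a, b)
    return float(a.mean() - b.mean()), p
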