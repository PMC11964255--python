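"""Seeded synthetic phantoms for every pipeline stage.

Generators for AFM fibril height images (with ground-truth morphometry
labels), pyramid-indenter force curves, tri-exponential photon-count decay
histograms, and collagen-like infrared spectra.  Every generator is a pure
function of its config + seed; ROI labels are derived from the generating
geometry, never from rendered pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import mechanics
from .constants import (
    CLARITY_BLUR_MAX_NM,
    CLARITY_NOISE_MAX_NM,
    DBAND_BLUR_MAX_NM,
    DBAND_DEPTH_MIN,
    DBAND_PERIOD_NM,
    PX_PER_UM,
)
from .flim import DecayHistogram
from .ftir import Spectrum
from .mechanics import ForceCurve
from .texture import AFMImage

LABEL_COLUMNS = ("roi_row", "roi_col", "clarity", "dbanding", "random_orientation", "linearity")


# ---------------------------------------------------------------------------
# AFM fibril image phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomImageConfig:
    """Geometry and degradation parameters of one synthetic scan."""

    field_size_um: float = 10.0
    px_per_um: int = PX_PER_UM
    n_fibrils: int = 40
    fibril_width_nm: float = 150.0
    fibril_height_nm: float = 30.0
    dband_period_nm: float = DBAND_PERIOD_NM
    dband_depth: float = 0.5
    orientation_mode: str = "random"
    aligned_axis_deg: float = 0.0
    kink_prob: float = 0.0
    kink_spacing_um: float = 1.0
    blur_sigma_nm: float = 0.0
    noise_sigma_nm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_px = self.field_size_um * self.px_per_um
        if abs(n_px - round(n_px)) > 1e-9:
            raise ValueError("field_size_um x px_per_um must give an integer pixel grid")
        if not 0.0 <= self.dband_depth <= 1.0:
            raise ValueError("dband_depth must be in [0, 1]")
        if not 0.0 <= self.kink_prob <= 1.0:
            raise ValueError("kink_prob must be in [0, 1]")
        if self.kink_spacing_um <= 0:
            raise ValueError("kink_spacing_um must be positive")
        for name in ("field_size_um", "fibril_width_nm", "fibril_height_nm", "dband_period_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.px_per_um <= 0:
            raise ValueError("px_per_um must be positive")
        if self.blur_sigma_nm < 0 or self.noise_sigma_nm < 0:
            raise ValueError("blur/noise sigmas must be non-negative")
        if self.orientation_mode not in ("random", "aligned"):
            raise ValueError("orientation_mode must be 'random' or 'aligned'")

    @property
    def n_px(self) -> int:
        return int(round(self.field_size_um * self.px_per_um))

    @property
    def px_size_nm(self) -> float:
        return 1000.0 / self.px_per_um


def _rotate(d: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])


def _sample_paths(
    config: PhantomImageConfig, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Polyline vertex lists (row, col in px) and kink vertex positions."""
    n_px = config.n_px
    paths: list[np.ndarray] = []
    kinks: list[np.ndarray] = []
    for _ in range(config.n_fibrils):
        if config.orientation_mode == "aligned":
            theta = np.deg2rad(config.aligned_axis_deg) + rng.normal(0.0, np.deg2rad(2.0))
        else:
            theta = rng.uniform(0.0, np.pi)
        d = np.array([np.sin(theta), np.cos(theta)])  # (row, col); 0 deg = horizontal
        center = rng.uniform(0.0, n_px, size=2)
        length = 1.6 * n_px
        if rng.random() < config.kink_prob:
            # a damaged fibril zigzags: abrupt direction changes roughly
            # every kink_spacing_um along its length
            spacing_px = config.kink_spacing_um * config.px_per_um
            verts = [center - 0.5 * length * d]
            walked = 0.0
            cur = d.copy()
            while walked < length:
                step = spacing_px * rng.uniform(0.7, 1.3)
                verts.append(verts[-1] + step * cur)
                walked += step
                bend = rng.choice([-1.0, 1.0]) * rng.uniform(np.deg2rad(35.0), np.deg2rad(75.0))
                cur = _rotate(cur, bend)
            paths.append(np.stack(verts))
            for v in verts[1:-1]:
                if 0.0 <= v[0] < n_px and 0.0 <= v[1] < n_px:
                    kinks.append(v.copy())
        else:
            paths.append(np.stack([center - 0.5 * length * d, center + 0.5 * length * d]))
    return paths, kinks


def _render_paths(
    paths: Sequence[np.ndarray], config: PhantomImageConfig
) -> np.ndarray:
    """Max-height compositing of semicircular-profile fibrils with axial banding."""
    n_px = config.n_px
    px_nm = config.px_size_nm
    heights = np.zeros((n_px, n_px))
    half_w = (config.fibril_width_nm / 2.0) / px_nm
    margin = half_w + 2.0
    for verts in paths:
        s0 = 0.0  # arc length so banding phase is continuous across segments
        for p0, p1 in zip(verts[:-1], verts[1:]):
            seg = p1 - p0
            seg_len = float(np.hypot(*seg))
            if seg_len == 0:
                continue
            dvec = seg / seg_len
            r0 = max(0, int(np.floor(min(p0[0], p1[0]) - margin)))
            r1 = min(n_px, int(np.ceil(max(p0[0], p1[0]) + margin)) + 1)
            c0 = max(0, int(np.floor(min(p0[1], p1[1]) - margin)))
            c1 = min(n_px, int(np.ceil(max(p0[1], p1[1]) + margin)) + 1)
            if r0 >= r1 or c0 >= c1:
                s0 += seg_len
                continue
            rows = np.arange(r0, r1)[:, None]
            cols = np.arange(c0, c1)[None, :]
            vr = rows - p0[0]
            vc = cols - p0[1]
            along = np.clip(vr * dvec[0] + vc * dvec[1], 0.0, seg_len)
            dist = np.hypot(vr - along * dvec[0], vc - along * dvec[1])
            profile = config.fibril_height_nm * np.sqrt(
                np.clip(1.0 - (dist / half_w) ** 2, 0.0, None)
            )
            if config.dband_depth > 0:
                s_nm = (s0 + along) * px_nm
                band = 1.0 - config.dband_depth * (
                    0.5 - 0.5 * np.cos(2.0 * np.pi * s_nm / config.dband_period_nm)
                )
                profile = profile * band
            np.maximum(heights[r0:r1, c0:c1], profile, out=heights[r0:r1, c0:c1])
            s0 += seg_len
    return heights


def _roi_labels(
    config: PhantomImageConfig, kinks: Sequence[np.ndarray]
) -> pd.DataFrame:
    roi_px = config.px_per_um  # 1 um ROI edge in pixels
    n_roi = config.n_px // roi_px
    clarity = (
        config.blur_sigma_nm <= CLARITY_BLUR_MAX_NM
        and config.noise_sigma_nm <= CLARITY_NOISE_MAX_NM
    )
    dbanding = (
        config.dband_depth >= DBAND_DEPTH_MIN
        and config.blur_sigma_nm <= DBAND_BLUR_MAX_NM
    )
    random_orientation = config.orientation_mode == "random"
    kinked = np.zeros((n_roi, n_roi), dtype=bool)
    for k in kinks:
        i, j = int(k[0]) // roi_px, int(k[1]) // roi_px
        if 0 <= i < n_roi and 0 <= j < n_roi:
            kinked[i, j] = True
    rows = []
    for i in range(n_roi):
        for j in range(n_roi):
            rows.append({
                "roi_row": i,
                "roi_col": j,
                "clarity": int(clarity),
                "dbanding": int(dbanding),
                "random_orientation": int(random_orientation),
                "linearity": int(not kinked[i, j]),
            })
    return pd.DataFrame(rows, columns=list(LABEL_COLUMNS))


def generate_fibril_image(
    config: PhantomImageConfig,
) -> tuple[AFMImage, pd.DataFrame]:
    """Render a fibril phantom and its per-ROI ground-truth labels.

    Fibrils are thick polylines with a semicircular height cross-section,
    axial cosine banding of fractional depth ``dband_depth``, max-height
    compositing, then Gaussian blur and additive height noise.  Labels are
    a deterministic function of the generating parameters (cutoffs in
    :mod:`collafib.constants`); an ROI is non-linear iff it contains a
    kink vertex.
    """
    if config.n_fibrils <= 0:
        raise ValueError("need at least one fibril to generate labelled phantoms")
    rng = np.random.default_rng(config.seed)
    paths, kinks = _sample_paths(config, rng)
    heights = _render_paths(paths, config)
    if config.blur_sigma_nm > 0:
        heights = ndimage.gaussian_filter(heights, sigma=config.blur_sigma_nm / config.px_size_nm)
    if config.noise_sigma_nm > 0:
        heights = heights + rng.normal(0.0, config.noise_sigma_nm, heights.shape)
    image = AFMImage(
        heights=heights,
        px_size_nm=config.px_size_nm,
        id=f"phantom-seed{config.seed}",
    )
    return image, _roi_labels(config, kinks)


# ---------------------------------------------------------------------------
# force-curve phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceCurveConfig:
    """Forward model of a pyramid-indenter extend curve."""

    E_true_GPa: float = 5.0
    poisson_ratio: float = 0.5
    half_angle_deg: float = 20.8
    max_load_nN: float = 100.0
    n_points: int = 400
    force_noise_nN: float = 0.0
    contact_offset_nm: float = 30.0  # pre-contact baseline length
    prefactor: str = "sqrt2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E_true_GPa <= 0:
            raise ValueError("E_true_GPa must be positive")
        if not 0.0 < self.half_angle_deg < 90.0:
            raise ValueError("half_angle_deg must be in (0, 90)")
        if not 0.0 < self.max_load_nN <= 100.0:
            raise ValueError("max_load_nN must be in (0, 100] nN")
        if self.n_points < 20:
            raise ValueError("need at least 20 points")
        if self.force_noise_nN < 0 or self.contact_offset_nm < 0:
            raise ValueError("noise and baseline length must be non-negative")


def generate_force_curve(config: ForceCurveConfig) -> ForceCurve:
    """Piecewise extend curve: flat (noisy) baseline, then the quadratic
    pyramid Hertz law, truncated at ``max_load_nN``.

    Separation decreases from baseline toward full indentation; contact is
    at separation ``delta_max`` where ``delta_max`` solves the force cap.
    """
    C = mechanics.hertz_prefactor(
        config.half_angle_deg, config.poisson_ratio, config.prefactor
    )
    delta_max = np.sqrt(config.max_load_nN / (C * config.E_true_GPa))
    s = np.linspace(config.contact_offset_nm + delta_max, 0.0, config.n_points)
    delta = np.clip(delta_max - s, 0.0, None)
    force = C * config.E_true_GPa * delta ** 2
    if config.force_noise_nN > 0:
        rng = np.random.default_rng(config.seed)
        force = force + rng.normal(0.0, config.force_noise_nN, force.shape)
    return ForceCurve(
        distance_nm=s,
        force_nN=force,
        direction="extend",
        id=f"synthcurve-seed{config.seed}",
    )


# ---------------------------------------------------------------------------
# decay-histogram phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayConfig:
    """Tri-exponential decay sampled as Poisson counts per bin."""

    amplitudes: tuple[float, float, float] = (0.5, 0.3, 0.2)
    lifetimes_ns: tuple[float, float, float] = (0.5, 2.0, 6.0)
    n_photons: float = 1e6
    bin_width_ps: float = 50.0
    window_ns: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        t = np.asarray(self.lifetimes_ns, dtype=float)
        if a.shape != (3,) or t.shape != (3,):
            raise ValueError("need exactly 3 amplitudes and 3 lifetimes")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")
        if not np.any(a > 0):
            raise ValueError("at least one amplitude must be positive")
        if np.any(t <= 0):
            raise ValueError("lifetimes must be positive")
        n_bins = self.window_ns * 1000.0 / self.bin_width_ps
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("window_ns / bin_width_ps must give an integer bin count")
        if self.n_photons <= 0:
            raise ValueError("n_photons must be positive")

    @property
    def n_bins(self) -> int:
        return int(round(self.window_ns * 1000.0 / self.bin_width_ps))


def expected_decay_counts(config: DecayConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin expected counts: the decay integrated over each bin,
    normalized so the expected total equals ``n_photons``.

    Returns ``(bin_centers_ns, expected_counts)``.
    """
    bw_ns = config.bin_width_ps / 1000.0
    edges = np.arange(config.n_bins + 1) * bw_ns
    a = np.asarray(config.amplitudes, dtype=float)
    tau = np.asarray(config.lifetimes_ns, dtype=float)
    mass = (
        a[None, :] * tau[None, :]
        * (np.exp(-edges[:-1, None] / tau[None, :]) - np.exp(-edges[1:, None] / tau[None, :]))
    ).sum(axis=1)
    mean = config.n_photons * mass / mass.sum()
    centers = edges[:-1] + bw_ns / 2.0
    return centers, mean


def generate_decay_histogram(config: DecayConfig) -> DecayHistogram:
    """Poisson-sample a tri-exponential decay histogram."""
    centers, mean = expected_decay_counts(config)
    rng = np.random.default_rng(config.seed)
    counts = rng.poisson(mean)
    return DecayHistogram(
        bin_centers_ns=centers,
        counts=counts,
        bin_width_ps=config.bin_width_ps,
        id=f"synthdecay-seed{config.seed}",
    )


# ---------------------------------------------------------------------------
# FTIR spectrum phantom
# ---------------------------------------------------------------------------

#: default Gaussian bands (center cm^-1, sigma cm^-1, amplitude) per state
NATIVE_BANDS: Mapping[str, tuple[float, float, float]] = {
    "amideA": (3300.0, 80.0, 0.85),
    "amideI": (1630.0, 23.0, 1.0),
    "amideII": (1540.0, 22.0, 0.625),
    "amideIII_1205": (1205.0, 9.0, 0.16),
    "amideIII_1235": (1235.0, 9.0, 0.20),
    "amideIII_1280": (1280.0, 9.0, 0.16),
}

DENATURED_BANDS: Mapping[str, tuple[float, float, float]] = {
    "amideA": (3290.0, 90.0, 0.80),
    "amideI": (1640.0, 28.0, 1.0),
    "amideII": (1540.0, 26.0, 0.30),
}

_TRIPLET_CENTERS = (1205.0, 1235.0, 1280.0)


@dataclass(frozen=True)
class SpectrumConfig:
    """Sum-of-Gaussians collagen spectrum over 800-4000 cm^-1.

    ``bands`` defaults to the state's canonical band set.  A native state
    must carry the three Amide III sub-bands; a denatured state must place
    Amide I at >= 1637 cm^-1 and carry no band in the triplet region.
    """

    state: str = "native"
    bands: Mapping[str, tuple[float, float, float]] | None = None
    baseline_slope: float = 0.0
    noise_sd: float = 0.0
    wn_min_cm1: float = 800.0
    wn_max_cm1: float = 4000.0
    wn_step_cm1: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in ("native", "denatured"):
            raise ValueError("state must be 'native' or 'denatured'")
        bands = self.resolved_bands()
        for name, (center, width, amp) in bands.items():
            if not self.wn_min_cm1 <= center <= self.wn_max_cm1:
                raise ValueError(f"band {name!r} center outside wavenumber range")
            if width <= 0 or amp < 0:
                raise ValueError(f"band {name!r} needs positive width, non-negative amplitude")
        centers = [c for c, _, _ in bands.values()]
        if self.state == "native":
            for t in _TRIPLET_CENTERS:
                if not any(abs(c - t) <= 10.0 for c in centers):
                    raise ValueError(f"native state requires an Amide III sub-band near {t}")
        else:
            amide_i = [c for c in centers if 1600.0 <= c <= 1700.0]
            if not amide_i or min(amide_i) < 1637.0:
                raise ValueError("denatured state requires Amide I shifted to >= 1637 cm^-1")
            if any(1195.0 <= c <= 1290.0 for c in centers):
                raise ValueError("denatured state must not contain Amide III triplet bands")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def resolved_bands(self) -> Mapping[str, tuple[float, float, float]]:
        if self.bands is not None:
            return self.bands
        return NATIVE_BANDS if self.state == "native" else DENATURED_BANDS


def generate_ftir_spectrum(config: SpectrumConfig) -> Spectrum:
    """Render a spectrum as Gaussian bands + linear baseline + noise."""
    wn = np.arange(config.wn_min_cm1, config.wn_max_cm1 + config.wn_step_cm1 / 2.0,
                   config.wn_step_cm1)
    ab = config.baseline_slope * (wn - config.wn_min_cm1)
    for center, width, amp in config.resolved_bands().values():
        ab = ab + amp * np.exp(-0.5 * ((wn - center) / width) ** 2)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        ab = ab + rng.normal(0.0, config.noise_sd, ab.shape)
    return Spectrum(
        wavenumbers_cm1=wn,
        absorbance=ab,
        id=f"synthspectrum-{config.state}-seed{config.seed}",
    )
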