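"""Automated AFM morphometry pipeline.

Patches height images into 1 um regions of interest, extracts a fixed
spatial-spectral descriptor vector per ROI, trains one binary linear
discriminant per morphometry metric, scores leave-one-out consistency
(whose complement is the change-detection threshold), and assembles
control-vs-irradiated prevalence change tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import structure_tensor

from .constants import (
    DBAND_PERIOD_NM,
    LDA_RIDGE_DEFAULT,
    PX_SIZE_NM,
    ROI_PX,
)

log = logging.getLogger(__name__)

#: the four binary morphometry metrics, in canonical order
METRICS = ("clarity", "dbanding", "random_orientation", "linearity")

_EPS = 1e-12
FEATURE_SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AFMImage:
    """A rectangular AFM height map with physical pixel pitch in nm."""

    heights: np.ndarray
    px_size_nm: float
    id: str = ""

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D grid")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights contain missing/non-finite values")
        if self.px_size_nm <= 0:
            raise ValueError("px_size_nm must be positive")


@dataclass
class ROI:
    """A single 51x51 patch of a parent image (0-based, top-left origin)."""

    pixels: np.ndarray
    origin: tuple[int, int] = (0, 0)
    parent_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (ROI_PX, ROI_PX):
            raise ValueError(f"ROI must be {ROI_PX}x{ROI_PX}, got {self.pixels.shape}")


@dataclass(frozen=True)
class MorphLabels:
    """The four binary morphometry labels for one ROI.

    ``linearity`` is True for a linear (kink-free) ROI.
    """

    clarity: bool
    dbanding: bool
    random_orientation: bool
    linearity: bool

    def __getitem__(self, metric: str) -> bool:
        if metric not in METRICS:
            raise KeyError(metric)
        return getattr(self, metric)


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]
    schema_version: str = FEATURE_SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("feature length does not match schema")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")


@dataclass
class ConsistencyReport:
    """Consistency (percent) of a labelling route for one metric.

    ``threshold_pct`` is exactly ``100 - consistency_pct``: a prevalence
    change smaller than the labeller's own error rate is not evidence.
    """

    metric: str
    consistency_pct: float
    n_rois: int
    threshold_pct: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.consistency_pct <= 100.0:
            raise ValueError("consistency_pct outside [0, 100]")
        self.threshold_pct = 100.0 - self.consistency_pct


@dataclass
class ChangeRow:
    """One metric's control-vs-irradiated prevalence change.

    For ``linearity`` the prevalences and change are bookkept on the
    kinked fraction (100 - linear%), so a loss of linearity is positive.
    """

    metric: str
    control_prevalence_pct: float
    irradiated_prevalence_pct: float
    change_pct: float
    threshold_pct: float
    exceeds: bool


# ---------------------------------------------------------------------------
# patching
# ---------------------------------------------------------------------------

def patch_image(image: AFMImage, roi_px: int = ROI_PX) -> list[ROI]:
    """Subdivide an image into non-overlapping ``roi_px`` square patches.

    Patches are returned in row-major order.  Dimensions that are not a
    multiple of ``roi_px`` are cropped to the largest multiple from the
    top-left corner (resampling would alter pixel-exact texture) and a
    warning is logged.  A 510x510 image at 51 px/um yields exactly 100 ROIs.
    """
    h, w = image.heights.shape
    if h < roi_px or w < roi_px:
        raise ValueError(f"image {h}x{w} smaller than one {roi_px}px patch")
    nr, nc = h // roi_px, w // roi_px
    if h % roi_px or w % roi_px:
        log.warning(
            "image %s is %dx%d; cropping to top-left %dx%d",
            image.id, h, w, nr * roi_px, nc * roi_px,
        )
    rois = []
    for i in range(nr):
        for j in range(nc):
            r0, c0 = i * roi_px, j * roi_px
            rois.append(ROI(
                pixels=image.heights[r0:r0 + roi_px, c0:c0 + roi_px].copy(),
                origin=(r0, c0),
                parent_id=image.id,
            ))
    return rois


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

_N_PSD_BINS = 6
_ST_SIGMA = 2.0  # structure-tensor integration scale (px)

# --- oriented line-opening "straightness" machinery ---
# fraction of ridge pixels surviving a morphological opening with a long
# line element at any orientation: straight fibril runs survive, kinked
# zigzag segments do not.  Implemented with precomputed FFT kernels.
_LINE_LEN_PX = 31
_LINE_ANGLES_DEG = range(0, 180, 15)
_RIDGE_THRESHOLD = 0.35  # of the ROI height range


def _line_element(length: int, deg: float) -> np.ndarray:
    se = np.zeros((length, length), dtype=bool)
    c = (length - 1) / 2.0
    th = np.deg2rad(deg)
    for t in np.linspace(-c, c, 2 * length):
        r = int(round(c + t * np.sin(th)))
        col = int(round(c + t * np.cos(th)))
        se[r, col] = True
    return se | se[::-1, ::-1]  # 180-degree symmetric, so corr == conv


_SES = np.stack([_line_element(_LINE_LEN_PX, d) for d in _LINE_ANGLES_DEG])
_FFT_PAD = 96  # >= ROI_PX + _LINE_LEN_PX - 1, FFT-friendly
_SE_FFT = np.stack([np.fft.rfft2(s.astype(float), (_FFT_PAD, _FFT_PAD)) for s in _SES])
_SE_SUM = _SES.sum(axis=(1, 2)).astype(float)
_SE_OFF = (_LINE_LEN_PX - 1) // 2


def _straightness_fraction(p: np.ndarray) -> float:
    """Fraction of ridge-mask pixels on straight runs >= the line length."""
    q = p - p.min()
    peak = q.max()
    if peak <= 0:
        return 0.0
    mask = q > _RIDGE_THRESHOLD * peak
    n_on = int(mask.sum())
    if n_on == 0:
        return 0.0
    n = p.shape[0]
    mf = np.fft.rfft2(mask.astype(float), (_FFT_PAD, _FFT_PAD))
    conv = np.fft.irfft2(mf[None] * _SE_FFT, s=(_FFT_PAD, _FFT_PAD))
    ero = conv[:, _SE_OFF:_SE_OFF + n, _SE_OFF:_SE_OFF + n] >= _SE_SUM[:, None, None] - 0.5
    ef = np.fft.rfft2(ero.astype(float), (_FFT_PAD, _FFT_PAD))
    dil = np.fft.irfft2(ef * _SE_FFT, s=(_FFT_PAD, _FFT_PAD))
    opened = dil[:, _SE_OFF:_SE_OFF + n, _SE_OFF:_SE_OFF + n] > 0.5
    return float(opened.any(axis=0).sum() / n_on)


def _feature_names() -> tuple[str, ...]:
    return tuple(
        [f"psd_bin_{i}" for i in range(_N_PSD_BINS)]
        + [
            "dband_power_frac",
            "dband_peak_logscore",
            "coherence_mean",
            "coherence_p90",
            "orientation_circvar",
            "grad_pooled_mean",
            "grad_pooled_std",
            "grad_pooled_p90",
            "local_std_mean",
            "local_std_p90",
            "curvature_mean",
            "curvature_p90",
            "straightness_fraction",
            "height_std",
            "height_span",
        ]
    )


FEATURE_NAMES = _feature_names()


def extract_features(
    roi: ROI,
    neighborhood_radius_px: int = 6,
    px_size_nm: float = PX_SIZE_NM,
    dband_period_nm: float = DBAND_PERIOD_NM,
) -> FeatureVector:
    """Deterministic spatial-spectral descriptor vector for one ROI.

    The descriptor set pairs each morphometry metric with at least one
    sensitive channel:

    * radially averaged power-spectral-density bins plus an annulus score
      centred on the D-band spatial frequency (banding);
    * structure-tensor coherence and circular variance of the doubled
      orientation angle (orientation isotropy);
    * gradient magnitude and local height contrast pooled over square
      neighborhoods of the given radius (edge clarity);
    * orientation-field curvature statistics and the fraction of ridge
      pixels surviving an oriented line opening (linearity).

    A constant patch returns the all-zero vector by convention.
    """
    p = np.asarray(roi.pixels, dtype=float)
    names = FEATURE_NAMES
    if p.std() == 0:
        return FeatureVector(np.zeros(len(names)), names)

    feats: list[float] = []

    # --- radial PSD ---
    n = p.shape[0]
    win = np.hanning(n)
    q = (p - p.mean()) * np.outer(win, win)
    psd = np.abs(np.fft.fft2(q)) ** 2
    f = np.fft.fftfreq(n)
    fr = np.hypot(*np.meshgrid(f, f, indexing="ij"))
    lowcut = 0.02  # drop DC / residual mean leakage
    sel = fr > lowcut
    total = psd[sel].sum() + _EPS
    edges = np.linspace(lowcut, 0.5, _N_PSD_BINS + 1)
    for e0, e1 in zip(edges[:-1], edges[1:]):
        m = (fr >= e0) & (fr < e1)
        feats.append(float(psd[m].sum() / total))

    f0 = px_size_nm / dband_period_nm  # cycles/px at the banding period
    ann = (fr >= 0.85 * f0) & (fr <= 1.15 * f0)
    side = ((fr >= 0.55 * f0) & (fr < 0.80 * f0)) | ((fr > 1.20 * f0) & (fr <= 1.45 * f0))
    feats.append(float(psd[ann].sum() / total))
    peak = psd[ann].mean() if ann.any() else 0.0
    bg = psd[side].mean() if side.any() else 0.0
    feats.append(float(np.log1p(peak / (bg + _EPS))))

    # --- structure tensor: coherence + orientation dispersion ---
    Arr, Arc, Acc = structure_tensor(p, sigma=_ST_SIGMA, order="rc")
    tr = Arr + Acc
    disc = np.sqrt(np.maximum((Arr - Acc) ** 2 / 4.0 + Arc ** 2, 0.0))
    l1, l2 = tr / 2.0 + disc, tr / 2.0 - disc
    coh = (l1 - l2) / (l1 + l2 + _EPS)
    wgt = tr + _EPS
    feats.append(float((coh * wgt).sum() / wgt.sum()))
    feats.append(float(np.percentile(coh, 90)))
    theta2 = np.arctan2(2.0 * Arc, Acc - Arr)  # doubled orientation angle
    resultant = np.abs((wgt * np.exp(1j * theta2)).sum()) / wgt.sum()
    feats.append(float(1.0 - resultant))

    # --- pooled gradient / local contrast ---
    gy, gx = np.gradient(p)
    g = np.hypot(gx, gy)
    size = 2 * neighborhood_radius_px + 1
    gp = ndimage.uniform_filter(g, size=size, mode="reflect")
    feats.extend([float(gp.mean()), float(gp.std()), float(np.percentile(gp, 90))])
    lm = ndimage.uniform_filter(p, size=size, mode="reflect")
    lv = ndimage.uniform_filter(p * p, size=size, mode="reflect") - lm ** 2
    ls = np.sqrt(np.maximum(lv, 0.0))
    feats.extend([float(ls.mean()), float(np.percentile(ls, 90))])

    # --- orientation-field curvature ---
    c2 = np.exp(1j * theta2)
    dcr, dcc = np.gradient(c2)
    dphi_r = np.imag(np.conj(c2) * dcr)
    dphi_c = np.imag(np.conj(c2) * dcc)
    curv = 0.5 * np.hypot(dphi_r, dphi_c)  # |d(orientation)| per pixel
    wcurv = coh * wgt
    feats.append(float((curv * wcurv).sum() / (wcurv.sum() + _EPS)))
    feats.append(float(np.percentile(curv * coh, 90)))

    # --- ridge straightness ---
    feats.append(_straightness_fraction(p))

    # --- height statistics ---
    feats.append(float(p.std()))
    feats.append(float(np.percentile(p, 95) - np.percentile(p, 5)))

    return FeatureVector(np.array(feats), names)


def _as_matrix(features: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float)
    return np.stack([np.asarray(f.values, dtype=float) for f in features])


# ---------------------------------------------------------------------------
# per-metric LDA
# ---------------------------------------------------------------------------

@dataclass
class TrainedMetricClassifier:
    """Binary LDA for one morphometry metric.

    The decision rule is fully reproducible from the stored fields:
    predict positive iff ``w . x >= decision_threshold`` (ties break toward
    the positive class).
    """

    metric: str
    class_means: np.ndarray        # (2, d): [negative, positive]
    pooled_covariance: np.ndarray  # regularized, symmetric positive-definite
    priors: np.ndarray             # (2,)
    projection_weights: np.ndarray
    decision_threshold: float
    ridge: float
    feature_names: tuple[str, ...] = ()

    def scores(self, features) -> np.ndarray:
        X = _as_matrix(features)
        return X @ self.projection_weights

    def predict(self, features) -> np.ndarray:
        return self.scores(features) >= self.decision_threshold


def train_metric_classifier(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence[bool],
    metric: str,
    ridge: float = LDA_RIDGE_DEFAULT,
) -> TrainedMetricClassifier:
    """Fit a binary LDA with ridge-regularized pooled covariance.

    Requires at least two examples of each class; raises a ``ValueError``
    naming the metric otherwise.
    """
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=bool)
    if len(y) != len(X):
        raise ValueError("features/labels length mismatch")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 < 2 or n1 < 2:
        raise ValueError(
            f"metric {metric!r}: need >= 2 examples per class (got {n0} neg / {n1} pos)"
        )
    d = X.shape[1]
    mu0, mu1 = X[~y].mean(axis=0), X[y].mean(axis=0)
    X0, X1 = X[~y] - mu0, X[y] - mu1
    S = (X0.T @ X0 + X1.T @ X1) / (len(y) - 2)
    S = S + (ridge * np.trace(S) / d + _EPS) * np.eye(d)
    w = np.linalg.solve(S, mu1 - mu0)
    pi0, pi1 = n0 / len(y), n1 / len(y)
    c = float(w @ (mu0 + mu1) / 2.0 - np.log(pi1 / pi0))
    names = tuple(getattr(features[0], "names", ())) if len(X) and not isinstance(features, np.ndarray) else ()
    return TrainedMetricClassifier(
        metric=metric,
        class_means=np.stack([mu0, mu1]),
        pooled_covariance=S,
        priors=np.array([pi0, pi1]),
        projection_weights=w,
        decision_threshold=c,
        ridge=ridge,
        feature_names=names,
    )


def loo_consistency(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence[bool],
    metric: str,
    ridge: float = LDA_RIDGE_DEFAULT,
) -> ConsistencyReport:
    """Leave-one-out consistency: percent of held-out ROIs predicted correctly.

    Each ROI is predicted by a classifier trained on all remaining ROIs.
    """
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=bool)
    if len(y) < 3:
        raise ValueError("need at least 3 examples for leave-one-out")
    correct = 0
    idx = np.arange(len(y))
    for i in idx:
        keep = idx != i
        clf = train_metric_classifier(X[keep], y[keep], metric, ridge=ridge)
        pred = bool(clf.predict(X[i:i + 1])[0])
        correct += pred == bool(y[i])
    return ConsistencyReport(
        metric=metric,
        consistency_pct=100.0 * correct / len(y),
        n_rois=len(y),
    )


def label_agreement(
    labels_a: Sequence[bool], labels_b: Sequence[bool], metric: str
) -> ConsistencyReport:
    """Percent agreement between two binary labellings of the same ROIs."""
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("label lists have different lengths")
    if a.size == 0:
        raise ValueError("empty label lists")
    return ConsistencyReport(
        metric=metric,
        consistency_pct=100.0 * float((a == b).mean()),
        n_rois=a.size,
    )


def consistency_gain(automated_pct: float, manual_pct: float) -> float:
    """Percentage-point consistency improvement of automated over manual labelling."""
    return automated_pct - manual_pct


# ---------------------------------------------------------------------------
# prevalence + change tables
# ---------------------------------------------------------------------------

def prevalence_table(
    classifiers: Mapping[str, TrainedMetricClassifier],
    rois: Sequence[ROI] | None = None,
    features: Sequence[FeatureVector] | np.ndarray | None = None,
) -> dict[str, float]:
    """Percent of a sample's ROIs predicted positive, per metric.

    For ``linearity`` an additional ``linearity_kinked`` entry reports
    ``100 - linear%``.  Features may be passed directly to avoid repeated
    extraction.
    """
    if features is None:
        if not rois:
            raise ValueError("empty ROI list")
        features = [extract_features(r) for r in rois]
    X = _as_matrix(features)
    if len(X) == 0:
        raise ValueError("empty ROI list")
    out: dict[str, float] = {}
    for metric, clf in classifiers.items():
        out[metric] = 100.0 * float(clf.predict(X).mean())
    if "linearity" in out:
        out["linearity_kinked"] = 100.0 - out["linearity"]
    return out


def change_table(
    control_prev: Mapping[str, float],
    irradiated_prev: Mapping[str, float],
    thresholds: Mapping[str, float],
) -> list[ChangeRow]:
    """Per-metric prevalence change (irradiated - control) with exceedance flags.

    Prevalences are positive-class percentages (linear% for linearity); the
    linearity change is computed on the kinked fraction so that increased
    kinking is a positive change.  ``exceeds`` is True iff the absolute
    change is strictly greater than the metric's threshold.
    """
    rows = []
    for metric in METRICS:
        if metric not in thresholds:
            continue
        for prev, side in ((control_prev, "control"), (irradiated_prev, "irradiated")):
            if metric not in prev:
                raise KeyError(f"missing metric {metric!r} in {side} prevalences")
        c, i = float(control_prev[metric]), float(irradiated_prev[metric])
        if metric == "linearity":
            c, i = 100.0 - c, 100.0 - i  # bookkeep on kinked%
        change = i - c
        thr = float(thresholds[metric])
        rows.append(ChangeRow(
            metric=metric,
            control_prevalence_pct=c,
            irradiated_prevalence_pct=i,
            change_pct=change,
            threshold_pct=thr,
            exceeds=abs(change) > thr,
        ))
    if not rows:
        raise ValueError("no metrics in threshold map")
    return rows


# ---------------------------------------------------------------------------
# classifier persistence (JSON, used by the CLI)
# ---------------------------------------------------------------------------

def classifiers_to_json(classifiers: Mapping[str, TrainedMetricClassifier]) -> str:
    payload = {}
    for metric, clf in classifiers.items():
        payload[metric] = {
            "metric": clf.metric,
            "class_means": clf.class_means.tolist(),
            "pooled_covariance": clf.pooled_covariance.tolist(),
            "priors": clf.priors.tolist(),
            "projection_weights": clf.projection_weights.tolist(),
            "decision_threshold": clf.decision_threshold,
            "ridge": clf.ridge,
            "feature_names": list(clf.feature_names),
        }
    return json.dumps(payload, indent=1, sort_keys=True)


def classifiers_from_json(text: str) -> dict[str, TrainedMetricClassifier]:
    payload = json.loads(text)
    out = {}
    for metric, d in payload.items():
        out[metric] = TrainedMetricClassifier(
            metric=d["metric"],
            class_means=np.asarray(d["class_means"]),
            pooled_covariance=np.asarray(d["pooled_covariance"]),
            priors=np.asarray(d["priors"]),
            projection_weights=np.asarray(d["projection_weights"]),
            decision_threshold=float(d["decision_threshold"]),
            ridge=float(d["ridge"]),
            feature_names=tuple(d["feature_names"]),
        )
    return out
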