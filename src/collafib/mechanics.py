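"""Hertzian pyramid indentation fitting and rank-based group statistics.

The contact model is the quadratic-pyramid Hertz law

    F(delta) = k * (E / (1 - nu^2)) * delta^2

with ``k = tan(theta)/sqrt(2)`` by default (``theta`` the half angle to
face); the Bilodeau constant ``0.7453 * tan(theta)`` is available as an
alternative prefactor.  With E in GPa, delta in nm and F in nN the law
holds with no additional unit factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

log = logging.getLogger(__name__)

DEFAULT_HALF_ANGLE_DEG = 20.8
DEFAULT_POISSON_RATIO = 0.5
CONTACT_SD_MULTIPLIER = 3.0  # baseline exceedance rule: mean + k * SD


class NoContactError(ValueError):
    """Raised when a force curve shows no contact event."""


def hertz_prefactor(
    half_angle_deg: float = DEFAULT_HALF_ANGLE_DEG,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
    mode: str = "sqrt2",
) -> float:
    """Geometric prefactor k/(1-nu^2) of the pyramid Hertz law."""
    if not 0.0 < half_angle_deg < 90.0:
        raise ValueError("half angle must be in (0, 90) degrees")
    t = np.tan(np.deg2rad(half_angle_deg))
    if mode == "sqrt2":
        k = t / np.sqrt(2.0)
    elif mode == "bilodeau":
        k = 0.7453 * t
    else:
        raise ValueError(f"unknown prefactor mode {mode!r}")
    return float(k / (1.0 - poisson_ratio ** 2))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ForceCurve:
    """A tip-sample separation vs force record (extend or retract)."""

    distance_nm: np.ndarray
    force_nN: np.ndarray
    direction: str = "extend"
    spring_constant_N_per_m: float = 2.8
    id: str = ""

    def __post_init__(self) -> None:
        self.distance_nm = np.asarray(self.distance_nm, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.distance_nm.shape != self.force_nN.shape:
            raise ValueError("distance and force arrays differ in length")
        if self.distance_nm.size < 20:
            raise ValueError("need at least 20 samples")
        if np.max(np.abs(self.force_nN)) > 1000.0:
            raise ValueError("force exceeds 1000 nN sanity bound")
        d = np.diff(self.distance_nm)
        if not (np.all(d >= 0) or np.all(d <= 0)):
            raise ValueError("distance samples must be monotone")


@dataclass
class HertzFit:
    E_GPa: float
    contact_point_nm: float
    max_depth_nm: float
    poisson_ratio: float
    half_angle_deg: float
    rms_residual_nN: float
    converged: bool


@dataclass
class GroupSummary:
    """Median indentation modulus of one experimental group."""

    group_id: str
    n: int
    median_GPa: float
    median_abs_dev_GPa: float
    variation_pct: float | None = None
    p_value: float | None = None
    significant: bool | None = None
    moduli: tuple[float, ...] = field(default=(), repr=False)


# ---------------------------------------------------------------------------
# contact point + Hertz fit
# ---------------------------------------------------------------------------

def find_contact_point(
    curve: ForceCurve,
    k: float = CONTACT_SD_MULTIPLIER,
    baseline_frac: float = 0.3,
) -> float | None:
    """Separation at which force first exceeds baseline mean + k * SD.

    The baseline is the far (large-separation) ``baseline_frac`` of the
    curve.  Returns ``None`` (with a warning) when the force is already
    above threshold at the largest separation, i.e. there is no usable
    baseline and the caller must fall back to fit-only estimation.  Raises
    :class:`NoContactError` when the force never exceeds the threshold.
    The estimate is baseline-relative, so a constant force offset leaves
    it unchanged.
    """
    order = np.argsort(-curve.distance_nm, kind="stable")  # far -> near
    s = curve.distance_nm[order]
    f = curve.force_nN[order]
    nb = max(5, int(len(s) * baseline_frac))
    base = f[:nb]
    mu, sd = float(base.mean()), float(base.std())
    scale = max(1.0, float(np.max(np.abs(f))))
    # a usable baseline is flat: its near half must not sit above its far half
    far, near = base[: nb // 2], base[nb // 2:]
    if near.mean() > far.mean() + k * far.std() + 1e-6 * scale:
        log.warning("curve %s: no pre-contact baseline; falling back to fit-only", curve.id)
        return None
    thr = mu + k * sd + 1e-9 * scale  # tiny absolute floor for noiseless curves
    above = f > thr
    if not above.any():
        raise NoContactError("no contact detected")
    i = int(np.argmax(above))
    if i == 0:
        log.warning("curve %s: no pre-contact baseline; falling back to fit-only", curve.id)
        return None
    return float(s[i])


def fit_hertz_pyramid(
    curve: ForceCurve,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
    half_angle_deg: float = DEFAULT_HALF_ANGLE_DEG,
    prefactor: str = "sqrt2",
) -> HertzFit:
    """Least-squares Hertz fit with modulus and contact point free.

    Fits the extend segment over the whole curve (the pre-contact part
    constrains the baseline at zero force); requires at least 10
    post-contact samples.
    """
    if curve.direction != "extend":
        raise ValueError("Hertz fit uses the extend segment only")
    C = hertz_prefactor(half_angle_deg, poisson_ratio, prefactor)
    s = curve.distance_nm
    f = curve.force_nN

    sc0 = find_contact_point(curve)
    if sc0 is None:
        sc0 = float(s.max())
    post = s < sc0
    if int(post.sum()) < 10:
        raise ValueError("need at least 10 post-contact samples")

    delta0 = sc0 - s[post]
    deep = delta0 > 0.2 * delta0.max()
    if deep.any():
        ratio = f[post][deep] / (C * delta0[deep] ** 2)
        E0 = float(np.clip(np.median(ratio), 1e-3, 1e4))
    else:  # pragma: no cover - degenerate initialization
        E0 = 1.0

    def resid(p: np.ndarray) -> np.ndarray:
        E, sc = p
        delta = np.clip(sc - s, 0.0, None)
        return C * E * delta * delta - f

    span = float(s.max() - s.min())
    res = optimize.least_squares(
        resid,
        x0=[E0, sc0],
        bounds=([1e-9, float(s.min())], [1e6, float(s.max())]),
        x_scale=[max(E0, 1e-3), max(span * 0.05, 1e-3)],
    )
    E, sc = float(res.x[0]), float(res.x[1])
    converged = bool(res.success) and E > 1e-6 and np.isfinite(E)
    return HertzFit(
        E_GPa=E,
        contact_point_nm=sc,
        max_depth_nm=max(0.0, sc - float(s.min())),
        poisson_ratio=poisson_ratio,
        half_angle_deg=half_angle_deg,
        rms_residual_nN=float(np.sqrt(np.mean(res.fun ** 2))),
        converged=converged,
    )


def contact_depth_for_load(
    load_nN: float,
    E_GPa: float,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
    half_angle_deg: float = DEFAULT_HALF_ANGLE_DEG,
    prefactor: str = "sqrt2",
) -> float:
    """Closed-form indentation depth (nm) reaching ``load_nN`` on the model."""
    C = hertz_prefactor(half_angle_deg, poisson_ratio, prefactor)
    if load_nN < 0 or E_GPa <= 0:
        raise ValueError("load must be >= 0 and modulus positive")
    return float(np.sqrt(load_nN / (C * E_GPa)))


# ---------------------------------------------------------------------------
# group summaries + rank statistics
# ---------------------------------------------------------------------------

def _moduli(fits: Sequence[HertzFit] | Sequence[float]) -> np.ndarray:
    vals = []
    for x in fits:
        if isinstance(x, HertzFit):
            if x.converged:
                vals.append(x.E_GPa)
        else:
            vals.append(float(x))
    return np.asarray(vals, dtype=float)


def summarize_group(
    fits: Sequence[HertzFit] | Sequence[float],
    group_id: str = "",
    paired_control: GroupSummary | None = None,
    alpha: float = 0.05,
) -> GroupSummary:
    """Median (+ MAD) of converged fits, with percent variation and a
    Mann-Whitney comparison against a paired control when one is given.

    ``variation_pct`` is computed from the unrounded medians and reported
    to one decimal.
    """
    m = _moduli(fits)
    if m.size == 0:
        raise ValueError("no converged fits to summarize")
    med = float(np.median(m))
    mad = float(np.median(np.abs(m - med)))
    variation = p = sig = None
    if paired_control is not None:
        variation = round(percent_variation(paired_control.median_GPa, med), 1)
        if paired_control.moduli:
            _, p = rank_sum_test(m, np.asarray(paired_control.moduli))
            sig = bool(p < alpha)
    return GroupSummary(
        group_id=group_id,
        n=int(m.size),
        median_GPa=med,
        median_abs_dev_GPa=mad,
        variation_pct=variation,
        p_value=p,
        significant=sig,
        moduli=tuple(m.tolist()),
    )


def percent_variation(control_median: float, irradiated_median: float) -> float:
    """100 * (irradiated - control) / control."""
    if control_median == 0:
        raise ValueError("control median is zero")
    return 100.0 * (irradiated_median - control_median) / control_median


def pooled_mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (ddof=1) standard deviation of a list of summaries."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a sample SD")
    return float(v.mean()), float(v.std(ddof=1))


def rank_sum_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic for ``group_a``).

    Uses exact enumeration for small tie-free samples (n <= 20 per group)
    and the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if max(a.size, b.size) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis_dunn(
    groups: Sequence[Sequence[float]],
    adjust: str = "bonferroni",
) -> tuple[float, dict[tuple[int, int], tuple[float, float]]]:
    """Tie-corrected Kruskal-Wallis H plus Dunn's pairwise z tests.

    Pairwise p values are Bonferroni-adjusted by default (clipped at 1).
    Requires at least 3 groups; use :func:`rank_sum_test` for two.
    """
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use rank_sum_test for two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        # degenerate: all observations identical
        m = len(arrays) * (len(arrays) - 1) // 2
        pairs = {}
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                pairs[(i, j)] = (0.0, 1.0)
        return 0.0, pairs
    H = float(stats.kruskal(*arrays).statistic)

    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in arrays:
        mean_ranks.append(float(ranks[start:start + g.size].mean()))
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    if adjust == "bonferroni":
        m = len(arrays) * (len(arrays) - 1) // 2
    elif adjust == "none":
        m = 1
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    pairs = {}
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = np.sqrt(var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))) * m)
            pairs[(i, j)] = (float(z), p)
    return H, pairs
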