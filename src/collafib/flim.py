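"""Tri-exponential TCSPC decay fitting and amplitude-weighted lifetimes.

The decay model is I(t) = a1 exp(-t/tau1) + a2 exp(-t/tau2) + a3 exp(-t/tau3)
and the amplitude-weighted average lifetime is

    tau_bar = (a1 tau1 + a2 tau2 + a3 tau3) / (a1 + a2 + a3).

Fitting is a tail fit starting at the histogram peak (no instrument
response deconvolution), with Poisson weights sigma^2 = max(counts, 1) and
multi-start initialization over log-spaced lifetime triples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

DEFAULT_MIN_PHOTONS = 1e4  # total-count floor below which fits are refused
_N_COMPONENTS = 3
_N_PARAMS = 2 * _N_COMPONENTS


@dataclass
class DecayHistogram:
    """A TCSPC histogram with uniform bin width."""

    bin_centers_ns: np.ndarray
    counts: np.ndarray
    bin_width_ps: float
    id: str = ""

    def __post_init__(self) -> None:
        self.bin_centers_ns = np.asarray(self.bin_centers_ns, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_centers_ns.shape != self.counts.shape:
            raise ValueError("bin centers and counts differ in length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integers")
        self.counts = np.round(self.counts).astype(np.int64)
        if self.bin_centers_ns.size > 1:
            steps = np.diff(self.bin_centers_ns)
            if not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("bin width must be uniform")
            if not math.isclose(steps[0] * 1000.0, self.bin_width_ps, rel_tol=1e-4):
                raise ValueError("bin_width_ps inconsistent with bin centers")

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())

    @property
    def window_ns(self) -> float:
        return self.bin_centers_ns.size * self.bin_width_ps / 1000.0


@dataclass
class TriExpFit:
    """Fitted decay parameters, components sorted by ascending lifetime."""

    amplitudes: np.ndarray
    lifetimes_ns: np.ndarray
    avg_lifetime_ns: float
    chi2_reduced: float
    converged: bool

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.lifetimes_ns = np.asarray(self.lifetimes_ns, dtype=float)
        if self.amplitudes.shape != (_N_COMPONENTS,) or self.lifetimes_ns.shape != (_N_COMPONENTS,):
            raise ValueError("expected exactly 3 components")


def tau_bar(amplitudes: Sequence[float], lifetimes_ns: Sequence[float]) -> float:
    """Amplitude-weighted average lifetime sum(a*tau)/sum(a)."""
    a = np.asarray(amplitudes, dtype=float)
    t = np.asarray(lifetimes_ns, dtype=float)
    if np.any(a < 0) or np.any(t <= 0):
        raise ValueError("amplitudes must be >= 0 and lifetimes > 0")
    s = a.sum()
    if s == 0:
        raise ValueError("all amplitudes are zero")
    return float((a * t).sum() / s)


def average_lifetime(fit: TriExpFit) -> float:
    """Amplitude-weighted average lifetime of a fit (exact in stored parameters)."""
    return tau_bar(fit.amplitudes, fit.lifetimes_ns)


def fit_triexponential(
    hist: DecayHistogram,
    n_starts: int = 4,
    min_photons: float = DEFAULT_MIN_PHOTONS,
) -> TriExpFit:
    """Weighted least-squares tail fit of a tri-exponential decay.

    Starts at the peak bin; weights are 1/sqrt(max(counts, 1)).  Each start
    fixes a log-spaced lifetime triple, solves amplitudes by non-negative
    least squares, then refines all six parameters jointly; the best
    chi-square start wins.  Deterministic for a given histogram.
    """
    if hist.total_photons < min_photons:
        raise ValueError(
            f"only {hist.total_photons} photons; need >= {min_photons:g} for a stable fit"
        )
    y_all = hist.counts.astype(float)
    ip = int(np.argmax(y_all))
    bw_half = hist.bin_width_ps / 2000.0
    # time origin at the peak bin's leading edge, so fitted amplitudes carry
    # the decay-start (t = 0) convention of the relative amplitudes
    t = hist.bin_centers_ns[ip:] - hist.bin_centers_ns[ip] + bw_half
    y = y_all[ip:]
    dof = t.size - _N_PARAMS
    if dof < 6:
        raise ValueError("fewer than 6 effective degrees of freedom")
    sigma = np.sqrt(np.maximum(y, 1.0))

    bw_ns = hist.bin_width_ps / 1000.0
    window = float(t[-1]) if t[-1] > 0 else bw_ns * t.size
    lo = max(2.0 * bw_ns, 1e-3)
    hi = max(window / 2.0, lo * 10.0)
    g = np.geomspace(lo, hi, 6)
    patterns = [
        (g[0], g[2], g[4]),
        (g[1], g[3], g[5]),
        (g[0], g[1], g[3]),
        (g[2], g[3], g[4]),
        (g[1], g[2], g[5]),
    ][:max(1, n_starts)]

    def resid(p: np.ndarray) -> np.ndarray:
        a = p[:_N_COMPONENTS]
        tau = p[_N_COMPONENTS:]
        model = (a[None, :] * np.exp(-t[:, None] / tau[None, :])).sum(axis=1)
        return (model - y) / sigma

    lb = np.array([0.0] * _N_COMPONENTS + [lo / 10.0] * _N_COMPONENTS)
    ub = np.array([np.inf] * _N_COMPONENTS + [window * 10.0] * _N_COMPONENTS)

    best = None
    for taus in patterns:
        taus = np.asarray(taus, dtype=float)
        A = np.exp(-t[:, None] / taus[None, :]) / sigma[:, None]
        amps, _ = optimize.nnls(A, y / sigma)
        p0 = np.concatenate([np.maximum(amps, 0.0), taus])
        res = optimize.least_squares(resid, p0, bounds=(lb, ub), max_nfev=400)
        if best is None or res.cost < best.cost:
            best = res

    a = np.asarray(best.x[:_N_COMPONENTS])
    tau = np.asarray(best.x[_N_COMPONENTS:])
    order = np.argsort(tau)
    a, tau = a[order], tau[order]
    chi2 = 2.0 * float(best.cost)  # least_squares cost = 0.5 * sum(res^2)
    converged = bool(best.success) and a.sum() > 0
    avg = tau_bar(a, tau) if a.sum() > 0 else float("nan")
    return TriExpFit(
        amplitudes=a,
        lifetimes_ns=tau,
        avg_lifetime_ns=avg,
        chi2_reduced=chi2 / dof,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# condition summaries
# ---------------------------------------------------------------------------

@dataclass
class LifetimeGroupSummary:
    condition: str
    mean_ns: float
    sd_ns: float | None
    n: int
    percent_change: int | None = None  # vs paired control, integer percent


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent_change(control_mean_ns: float, irradiated_mean_ns: float) -> int:
    """Integer percent change 100 * (irradiated - control) / control."""
    if control_mean_ns == 0:
        raise ValueError("control mean is zero")
    return _round_half_away(100.0 * (irradiated_mean_ns - control_mean_ns) / control_mean_ns)


def summarize_lifetimes(
    fits_by_condition: Mapping[str, Sequence[TriExpFit] | Sequence[float]],
    pairing: Mapping[str, str] | None = None,
) -> dict[str, LifetimeGroupSummary]:
    """Mean +/- SD of average lifetimes per condition, with integer percent
    change vs each condition's paired control.

    ``pairing`` maps an irradiated condition id to its control id; a pair
    referencing a missing condition is an error.
    """
    values: dict[str, np.ndarray] = {}
    for cond, fits in fits_by_condition.items():
        v = np.asarray([
            f.avg_lifetime_ns if isinstance(f, TriExpFit) else float(f) for f in fits
        ])
        if v.size == 0:
            raise ValueError(f"condition {cond!r} has no measurements")
        values[cond] = v
    out: dict[str, LifetimeGroupSummary] = {}
    for cond, v in values.items():
        out[cond] = LifetimeGroupSummary(
            condition=cond,
            mean_ns=float(v.mean()),
            sd_ns=float(v.std(ddof=1)) if v.size >= 2 else None,
            n=int(v.size),
        )
    if pairing:
        for irr, ctrl in pairing.items():
            if irr not in out or ctrl not in out:
                raise ValueError(f"unpaired condition in {irr!r} -> {ctrl!r}")
            out[irr].percent_change = percent_change(out[ctrl].mean_ns, out[irr].mean_ns)
    return out
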