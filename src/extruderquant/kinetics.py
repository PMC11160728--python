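"""FRAP recovery fitting and spot-bleach bound-fraction estimation.

Half-nucleus FRAP of a chromatin-binding protein is summarised as the
normalized difference between the unbleached and bleached region,

    D(t) = (F_ub(t) - F_b(t)) / (F_ub(0) - F_b(0)),

which decays from 1 toward the immobile fraction as the dynamic pool
exchanges.  A single exponential with an immobile fraction,

    D(t) = a + (1 - a) * exp(-koff * t),

is fitted; ``a`` is the long-term (stably) bound fraction and 1/koff the
mean residence time of the dynamically exchanging pool.

The spot-bleach assay depletes the chromatin-bound pool under continuous
point illumination; the bound fraction is read from the pre/post plateau
contrast and calibrated against a ~100% bound (H2B) and a 0% bound (free
fluorophore) reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class RecoveryCurve:
    """Normalized-difference FRAP curve; t=0 is the first post-bleach frame."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class KineticFit:
    """Result of an exponential-with-immobile-fraction recovery fit."""

    a_immobile: float
    koff: float
    residence_time: float
    ci: dict = field(default_factory=dict)
    fit_ok: bool = True
    message: str = ""


@dataclass
class DepletionTrace:
    """Fluorescence depletion trace recorded during continuous spot illumination."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")


@dataclass
class BoundFraction:
    raw_pct: float
    calibrated_pct: float | None = None
    references: tuple | None = None


def recovery_model(t, a, koff):
    """D(t) = a + (1 - a) exp(-koff t)."""
    return a + (1.0 - a) * np.exp(-koff * np.asarray(t, dtype=float))


def normalized_difference(unbleached, bleached) -> RecoveryCurve:
    """Build the normalized difference curve from per-region mean intensity series.

    Both series start at the first post-bleach frame.  ``unbleached`` and
    ``bleached`` may be (times, values) tuples or plain value arrays sampled
    at frame indices.
    """
    if isinstance(unbleached, tuple):
        t_ub, f_ub = unbleached
        t_b, f_b = bleached
        t_ub, t_b = np.asarray(t_ub, float), np.asarray(t_b, float)
        if not np.array_equal(t_ub, t_b):
            raise ValueError("region series must share time points")
        times = t_ub
    else:
        f_ub = np.asarray(unbleached, dtype=float)
        f_b = np.asarray(bleached, dtype=float)
        times = np.arange(f_ub.size, dtype=float)
    f_ub = np.asarray(f_ub, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    if f_ub.size != f_b.size:
        raise ValueError("unbleached and bleached series must have equal length")
    if f_ub.size < 3:
        raise ValueError("need at least 3 frames")
    d0 = f_ub[0] - f_b[0]
    if d0 == 0:
        raise ValueError("zero initial difference: nothing was bleached")
    return RecoveryCurve(times=times, values=(f_ub - f_b) / d0)


def fit_recovery(curve: RecoveryCurve) -> KineticFit:
    """Fit D(t) = a + (1-a) exp(-koff t) by bounded least squares.

    ``a`` is constrained to [0, 1] and ``koff`` to be positive.  The fit is
    initialised at a = last observed value and koff = ln2 / (time at half
    decay), which is deterministic and robust for monotone recoveries.
    Non-convergent or nonsensical inputs yield ``fit_ok=False`` rather than
    an exception.
    """
    t, y = curve.times, curve.values
    if t.size < 5:
        raise ValueError("need at least 5 frames to fit a recovery")
    if np.all(np.diff(y) >= 0) and y[-1] > y[0]:
        return KineticFit(np.nan, np.nan, np.nan, fit_ok=False,
                          message="monotonically increasing curve; not a recovery")

    a0 = float(np.clip(y[-1], 0.0, 1.0))
    # time at which the decay above the plateau has halved
    target = a0 + 0.5 * (y[0] - a0)
    below = np.nonzero(y <= target)[0]
    t_half = t[below[0]] if below.size and t[below[0]] > 0 else (t[-1] / 2 or 1.0)
    k0 = float(np.log(2.0) / t_half)

    koff_lo = 1e-8
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                recovery_model, t, y, p0=[a0, max(k0, 1e-6)],
                bounds=([0.0, koff_lo], [1.0, np.inf]), maxfev=10000,
            )
    except (RuntimeError, ValueError) as exc:
        return KineticFit(np.nan, np.nan, np.nan, fit_ok=False, message=str(exc))

    a_hat, koff_hat = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    ci = {"a_immobile": 1.96 * float(perr[0]), "koff": 1.96 * float(perr[1])}
    pinned = koff_hat <= 10 * koff_lo or a_hat >= 1.0 - 1e-9
    fit = KineticFit(a_hat, koff_hat, 1.0 / koff_hat, ci=ci, fit_ok=not pinned)
    if pinned:
        fit.message = "parameter pinned at bound (flat or degenerate curve)"
    return fit


def spotbleach_bound_fraction(trace: DepletionTrace, window_s: float = 0.5) -> BoundFraction:
    """Raw chromatin-bound fraction from the pre/post plateau contrast.

    raw_pct = 100 * (mean first 500 ms - mean last 500 ms) / mean first 500 ms.
    """
    t, f = trace.times, trace.intensities
    if t.size < 2 or t[-1] - t[0] < 1.0:
        raise ValueError("trace must cover at least 1 s")
    pre = f[t <= t[0] + window_s]
    post = f[t >= t[-1] - window_s]
    if pre.size == 0 or post.size == 0:
        raise ValueError("each 500 ms window must contain at least one sample")
    pre_mean = float(np.mean(pre))
    if pre_mean <= 0:
        raise ValueError("non-positive prebleach mean")
    raw = 100.0 * (pre_mean - float(np.mean(post))) / pre_mean
    return BoundFraction(raw_pct=raw)


def calibrate_bound_fraction(raw_pct: float, free_reference_pct: float,
                             h2b_reference_pct: float) -> BoundFraction:
    """Affine calibration mapping the free-mEGFP reference to 0% and H2B to 100%."""
    if h2b_reference_pct <= free_reference_pct:
        raise ValueError("H2B reference must exceed the free-protein reference")
    cal = 100.0 * (raw_pct - free_reference_pct) / (h2b_reference_pct - free_reference_pct)
    return BoundFraction(raw_pct=raw_pct,
                         calibrated_pct=float(np.clip(cal, 0.0, 100.0)),
                         references=(free_reference_pct, h2b_reference_pct))


def halfbleach_bound_fraction(pre_ub: float, pre_b: float,
                              post_ub: float, post_b: float) -> float:
    """Bound fraction after half-nucleus bleaching of the soluble pool.

    Repeated half-nucleus bleaching removes the freely diffusing pool; the
    soluble fraction is read as the fractional intensity loss in the
    UNBLEACHED half (the soluble pool equilibrates across the nucleus while
    bound molecules in the unbleached half are untouched):
    s = 1 - post_ub/pre_ub, bound = 1 - s.
    """
    if pre_ub <= 0 or pre_b <= 0:
        raise ValueError("prebleach means must be positive")
    if post_ub > pre_ub:
        warnings.warn("post-bleach unbleached intensity exceeds pre-bleach; clipping")
    soluble = 1.0 - post_ub / pre_ub
    return float(np.clip(1.0 - soluble, 0.0, 1.0))
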