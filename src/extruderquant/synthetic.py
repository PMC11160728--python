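"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one input class of the quantitative-imaging
pipeline: FRAP recovery curves, spot-bleach depletion traces, FCS
autocorrelation curves, STED-like spot images, polymer-like 3D chromatin
traces with planted loops, and intensity/concentration calibration cells.
Noise is additive Gaussian throughout; every generator takes an explicit
seed and is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .fcs import AcfCurve, acf_model
from .kinetics import DepletionTrace, RecoveryCurve, recovery_model


# ---------------------------------------------------------------------------
# FRAP

@dataclass
class FrapGroundTruth:
    """Parameters of a simulated normalized-difference FRAP curve."""

    a_immobile: float
    koff: float
    noise_sd: float = 0.0
    frame_interval: float = 20.0
    n_frames: int = 30
    contrast0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a_immobile <= 1.0:
            raise ValueError("a_immobile must be in [0, 1]")
        if self.koff <= 0:
            raise ValueError("koff must be positive")
        if self.n_frames < 3:
            raise ValueError("need at least 3 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")


def gen_frap_curve(truth: FrapGroundTruth) -> RecoveryCurve:
    """Simulate D(t) = a + (1-a) exp(-koff t) with additive Gaussian noise."""
    rng = np.random.default_rng(truth.seed)
    t = np.arange(truth.n_frames, dtype=float) * truth.frame_interval
    values = truth.contrast0 * recovery_model(t, truth.a_immobile, truth.koff)
    if truth.noise_sd > 0:
        values = values + rng.normal(0.0, truth.noise_sd, size=t.size)
    return RecoveryCurve(times=t, values=values)


# ---------------------------------------------------------------------------
# Spot-bleach

def gen_spotbleach_trace(bound_fraction: float, bleach_rate: float,
                         duration: float = 30.0, dt: float = 0.05,
                         noise_sd: float = 0.0, seed: int = 0) -> DepletionTrace:
    """Depletion trace under continuous spot illumination.

    I(t) = (1 - f_bound) + f_bound * exp(-bleach_rate t) + noise; the
    plateau after bleach_rate * duration >> 1 equals the unbound fraction.
    """
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValueError("bound_fraction must be in [0, 1]")
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be positive")
    if duration / dt < 2:
        raise ValueError("need at least two 500 ms windows worth of samples")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    i = (1.0 - bound_fraction) + bound_fraction * np.exp(-bleach_rate * t)
    if noise_sd > 0:
        i = i + rng.normal(0.0, noise_sd, size=t.size)
    return DepletionTrace(times=t, intensities=i)


# ---------------------------------------------------------------------------
# FCS

def gen_fcs_acf(n_particles: float, tau_d: float, kappa: float = 5.0,
                lags: np.ndarray | None = None, noise_sd: float = 0.0,
                seed: int = 0) -> AcfCurve:
    """Autocorrelation curve for N particles diffusing through the focus.

    ``noise_sd`` is relative: each amplitude is perturbed by N(0, (noise_sd*G)^2).
    """
    if n_particles <= 0 or tau_d <= 0:
        raise ValueError("n_particles and tau_d must be positive")
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    if lags is None:
        lags = np.geomspace(tau_d / 100.0, tau_d * 1000.0, 100)
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0:
        raise ValueError("empty lag list")
    rng = np.random.default_rng(seed)
    g = acf_model(lags, n_particles, tau_d, kappa)
    if noise_sd > 0:
        g = g * (1.0 + rng.normal(0.0, noise_sd, size=lags.size))
    return AcfCurve(lags=lags, values=g)


# ---------------------------------------------------------------------------
# STED images

@dataclass
class StedSimParams:
    """Parameters for STED-like spot image simulation.

    Spots are single-pixel impulses at uniform-random positions, Gaussian
    blurred, with the blurred peak scaled ``intensity_gain``-fold over the
    mean background so they are distinguishable above a random background.
    Dimers are planted as single impulses of doubled amplitude (unresolvable
    pairs appear as one spot of doubled intensity).
    """

    n_spots: int
    field_area: float = 200.0      # um^2
    pixel_size: float = 18.88      # nm
    blur_sigma: float = 2.6        # px
    intensity_gain: float = 6.0    # peak over mean background
    dimer_fraction: float = 0.0
    coloc_fraction: float = 0.0
    background_mean: float = 10.0
    background_noise_sd: float = 2.0
    min_separation: float = 0.0    # px, 0 = unconstrained
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 0:
            raise ValueError("n_spots must be nonnegative")
        for name in ("dimer_fraction", "coloc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.field_area <= 0 or self.pixel_size <= 0 or self.blur_sigma <= 0:
            raise ValueError("field_area, pixel_size and blur_sigma must be positive")

    @property
    def side_px(self) -> int:
        return int(np.ceil(np.sqrt(self.field_area) * 1000.0 / self.pixel_size))


def _draw_positions(rng: np.random.Generator, n: int, side: int,
                    min_sep: float) -> np.ndarray:
    if min_sep <= 0:
        return rng.integers(0, side, size=(n, 2))
    pos: list[np.ndarray] = []
    tries = 0
    while len(pos) < n:
        cand = rng.integers(0, side, size=2)
        if all(np.hypot(*(cand - p)) >= min_sep for p in pos):
            pos.append(cand)
        tries += 1
        if tries > 1000 * max(n, 1):
            raise RuntimeError("cannot place spots at the requested separation")
    return np.array(pos, dtype=int)


def _render(rng: np.random.Generator, params: StedSimParams,
            positions: np.ndarray, dimer: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    side = params.side_px
    impulses = np.zeros((side, side), dtype=float)
    # pre-scale so the blurred peak sits intensity_gain-fold over background
    probe = np.zeros((4 * int(np.ceil(params.blur_sigma)) + 9,) * 2)
    probe[probe.shape[0] // 2, probe.shape[1] // 2] = 1.0
    peak_attenuation = gaussian_filter(probe, params.blur_sigma,
                                       mode="constant", cval=0.0).max()
    amp0 = params.intensity_gain * params.background_mean / peak_attenuation
    for (r, c), d in zip(positions, dimer):
        impulses[r, c] += amp0 * (2.0 if d else 1.0)
    image = gaussian_filter(impulses, params.blur_sigma, mode="constant", cval=0.0)
    image += params.background_mean
    if params.background_noise_sd > 0:
        image += rng.normal(0.0, params.background_noise_sd, size=image.shape)
    np.clip(image, 0.0, None, out=image)
    truth = pd.DataFrame({
        "row": positions[:, 0] if len(positions) else np.array([], dtype=int),
        "col": positions[:, 1] if len(positions) else np.array([], dtype=int),
        "is_dimer": dimer.astype(bool) if len(positions) else np.array([], dtype=bool),
        "peak_amplitude": (amp0 * peak_attenuation * np.where(dimer, 2.0, 1.0)
                           if len(positions) else np.array([], dtype=float)),
    })
    return image, truth


def gen_sted_image(params: StedSimParams, second_channel: bool = False):
    """Simulate a STED-like field of blurred point spots over a noisy background.

    Returns ``(image, truth)`` or, with ``second_channel=True``, a
    ``(image, truth, image2, truth2)`` tuple in which a ``coloc_fraction``
    of channel-2 spots is copied from channel-1 positions.
    """
    rng = np.random.default_rng(params.seed)
    side = params.side_px
    pos = _draw_positions(rng, params.n_spots, side, params.min_separation)
    dimer = rng.random(params.n_spots) < params.dimer_fraction
    image, truth = _render(rng, params, pos, dimer)
    if not second_channel:
        return image, truth
    n_coloc = int(round(params.coloc_fraction * params.n_spots))
    keep = rng.permutation(params.n_spots)[:n_coloc]
    pos2 = np.concatenate([
        pos[keep].reshape(-1, 2),
        _draw_positions(rng, params.n_spots - n_coloc, side, params.min_separation),
    ]) if params.n_spots else pos
    dimer2 = rng.random(params.n_spots) < params.dimer_fraction
    image2, truth2 = _render(rng, params, pos2, dimer2)
    return image, truth, image2, truth2


# ---------------------------------------------------------------------------
# Chromatin traces

@dataclass
class TraceSimParams:
    """Gaussian-chain chromatin traces with planted, compacted loop intervals.

    The backbone is a cumulative 3D Gaussian walk with per-bin step sd
    ``step_sd`` (nm); steps inside a loop interval are multiplied by that
    loop's compaction factor (nested loops multiply), bringing loop members
    closer in space.  Emulates ~1.2 Mb regions traced at 12 kb resolution.
    """

    n_traces: int = 500
    n_bins: int = 100
    bin_kb: float = 12.0
    step_sd: float = 50.0          # nm per-axis per bin
    loops: list = field(default_factory=list)  # (start_bin, end_bin, compaction)
    loc_noise_sd: float = 20.0     # nm localization error per axis
    missing_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_traces < 0 or self.n_bins < 2:
            raise ValueError("need nonnegative n_traces and >= 2 bins")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        for s, e, c in self.loops:
            if not (0 <= s < e < self.n_bins):
                raise ValueError("loop intervals must lie within [0, n_bins)")
            if not 0.0 < c <= 1.0:
                raise ValueError("compaction factor must be in (0, 1]")
        _check_nested_or_disjoint([(s, e) for s, e, _ in self.loops])


def _check_nested_or_disjoint(intervals: list[tuple[float, float]]) -> None:
    """Raise if any two intervals partially overlap (cross)."""
    for i, (a1, b1) in enumerate(intervals):
        for a2, b2 in intervals[i + 1:]:
            lo, hi = max(a1, a2), min(b1, b2)
            if lo < hi:  # overlapping: must be nested
                if not ((a1 <= a2 and b2 <= b1) or (a2 <= a1 and b1 <= b2)):
                    raise ValueError(
                        f"loop intervals ({a1},{b1}) and ({a2},{b2}) cross; "
                        "loops must be nested or disjoint")


def gen_traces(params: TraceSimParams) -> pd.DataFrame:
    """Simulate a long-format trace table (trace_id, bin_index, x/y/z nm, QC)."""
    rng = np.random.default_rng(params.seed)
    scale = np.ones(params.n_bins - 1)
    for s, e, c in params.loops:
        scale[s:e] *= c
    frames = []
    for tid in range(params.n_traces):
        steps = rng.normal(0.0, params.step_sd, size=(params.n_bins - 1, 3))
        steps *= scale[:, None]
        xyz = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        if params.loc_noise_sd > 0:
            xyz = xyz + rng.normal(0.0, params.loc_noise_sd, size=xyz.shape)
        keep = rng.random(params.n_bins) >= params.missing_fraction
        nkept = int(keep.sum())
        frames.append(pd.DataFrame({
            "trace_id": tid,
            "bin_index": np.nonzero(keep)[0],
            "x": xyz[keep, 0], "y": xyz[keep, 1], "z": xyz[keep, 2],
            "snr": np.clip(rng.normal(10.0, 2.0, nkept), 0.1, None),
            "fit_sd": np.clip(rng.normal(30.0, 5.0, nkept), 1.0, None),
            "barcode_dist": np.abs(rng.normal(0.0, 200.0, nkept)),
        }))
    if not frames:
        return pd.DataFrame(columns=["trace_id", "bin_index", "x", "y", "z",
                                     "snr", "fit_sd", "barcode_dist"])
    out = pd.concat(frames, ignore_index=True)
    out.attrs["bin_kb"] = params.bin_kb
    return out


# ---------------------------------------------------------------------------
# Calibration cells

def gen_calibration_cells(slope: float, background: float,
                          concentrations, noise_sd: float = 0.0,
                          seed: int = 0) -> pd.DataFrame:
    """Paired intensity/concentration table for calibration-line fitting.

    intensity_i = concentration_i / slope + background + noise, so the
    inverse regression of concentration on intensity recovers ``slope`` as
    the calibration factor and ``background`` as the zero-concentration
    intensity.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("empty concentration list")
    rng = np.random.default_rng(seed)
    inten = conc / slope + background
    if noise_sd > 0:
        inten = inten + rng.normal(0.0, noise_sd, size=conc.size)
    return pd.DataFrame({"concentration": conc, "intensity": inten})
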