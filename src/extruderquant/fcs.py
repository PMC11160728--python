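"""FCS-calibrated quantitative imaging: ACF fitting, confocal-volume and
intensity-to-concentration calibration, image-based copy numbers.

The autocorrelation of fluorescence fluctuations of a species diffusing in
3D through a Gaussian confocal detection volume is modelled as

    G(tau) = (1/N) * (1 + tau/tauD)^-1 * (1 + tau/(kappa^2 tauD))^-1/2 + offset

where N is the mean particle number in the effective volume, tauD the
diffusion time and kappa the axial ratio of the volume.  Measuring a dye of
known concentration gives the effective volume V_eff = N / (C * N_A), and a
regression of FCS-derived concentrations against image intensities gives
the experiment-specific calibration line used to convert masked voxel
intensities into absolute concentrations and protein copy numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import Avogadro
from scipy.optimize import curve_fit

DEFAULT_KAPPA = 5.0  # typical confocal axial ratio; overridable everywhere


@dataclass
class AcfCurve:
    """Autocorrelation amplitudes G(tau) over lag times in seconds."""

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have equal length")
        if self.lags.size >= 2 and np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.lags < 0):
            raise ValueError("lags must be nonnegative")


@dataclass
class FcsFit:
    n_particles: float
    tau_d: float
    kappa: float
    offset: float
    fit_ok: bool = True
    stderr: dict = field(default_factory=dict)
    message: str = ""


@dataclass
class CalibrationLine:
    """Concentration [nM] = factor * (intensity - background)."""

    factor: float
    background: float
    r_squared: float


@dataclass
class EffectiveVolume:
    veff: float  # liters

    def __post_init__(self) -> None:
        if self.veff < 0:
            raise ValueError("effective volume must be nonnegative")


def acf_model(tau, n, tau_d, kappa, offset=0.0):
    """3D diffusion autocorrelation for a Gaussian detection volume."""
    tau = np.asarray(tau, dtype=float)
    return (1.0 / n) / (1.0 + tau / tau_d) / np.sqrt(1.0 + tau / (kappa**2 * tau_d)) + offset


def fit_acf(curve: AcfCurve, kappa_fixed: float | None = DEFAULT_KAPPA,
            weights: np.ndarray | None = None) -> FcsFit:
    """Weighted nonlinear least-squares fit of the diffusion ACF model.

    With ``kappa_fixed`` (default 5) only N, tauD and the offset are free;
    pass ``kappa_fixed=None`` to fit kappa as well.  A failed or degenerate
    fit returns ``fit_ok=False`` instead of raising.
    """
    tau, g = curve.lags, curve.values
    if tau.size < 5:
        raise ValueError("need at least 5 lag points")
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite correlation values")
    g0 = float(np.max(g))
    if g0 <= 0:
        return FcsFit(np.nan, np.nan, np.nan, np.nan, fit_ok=False,
                      message="non-positive amplitude; nothing to fit")
    n0 = 1.0 / g0
    half = np.nonzero(g <= g0 / 2)[0]
    tau0 = float(tau[half[0]]) if half.size and tau[half[0]] > 0 else float(np.median(tau[tau > 0]))
    sigma = None if weights is None else 1.0 / np.asarray(weights, dtype=float)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if kappa_fixed is None:
                popt, pcov = curve_fit(
                    acf_model, tau, g, p0=[n0, tau0, DEFAULT_KAPPA, 0.0],
                    bounds=([1e-12, 1e-12, 1.0, -np.inf], [np.inf] * 4),
                    sigma=sigma, maxfev=20000)
                n, tau_d, kappa, offset = popt
                names = ["n_particles", "tau_d", "kappa", "offset"]
            else:
                if kappa_fixed < 1:
                    raise ValueError("kappa must be >= 1")
                popt, pcov = curve_fit(
                    lambda t, n, td, off: acf_model(t, n, td, kappa_fixed, off),
                    tau, g, p0=[n0, tau0, 0.0],
                    bounds=([1e-12, 1e-12, -np.inf], [np.inf] * 3),
                    sigma=sigma, maxfev=20000)
                n, tau_d, offset = popt
                kappa = kappa_fixed
                names = ["n_particles", "tau_d", "offset"]
    except (RuntimeError, ValueError) as exc:
        return FcsFit(np.nan, np.nan, np.nan, np.nan, fit_ok=False, message=str(exc))

    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    stderr = dict(zip(names, perr.tolist()))
    ok = np.isfinite(n) and n > 0 and np.isfinite(tau_d)
    return FcsFit(float(n), float(tau_d), float(kappa), float(offset),
                  fit_ok=bool(ok), stderr=stderr)


def effective_volume(fit: FcsFit, reference_concentration_nM: float) -> EffectiveVolume:
    """V_eff = N / (C * N_A), from a reference dye of known concentration."""
    if not fit.fit_ok:
        raise ValueError("cannot derive a volume from a failed fit")
    if reference_concentration_nM <= 0:
        raise ValueError("reference concentration must be positive")
    c_molar = reference_concentration_nM * 1e-9
    return EffectiveVolume(veff=fit.n_particles / (c_molar * Avogadro))


def concentration_from_fcs(fit: FcsFit, veff: EffectiveVolume) -> float:
    """Concentration in nM implied by N particles in the effective volume."""
    if not fit.fit_ok:
        raise ValueError("cannot derive a concentration from a failed fit")
    if veff.veff <= 0:
        raise ValueError("effective volume must be positive")
    return fit.n_particles / (veff.veff * Avogadro) * 1e9


def build_calibration_line(pairs: pd.DataFrame) -> CalibrationLine:
    """OLS line of concentration against intensity.

    ``pairs`` needs columns ``intensity`` and ``concentration`` (nM).  The
    slope is the calibration factor and the intensity-axis intercept at zero
    concentration is the background intensity.
    """
    inten = np.asarray(pairs["intensity"], dtype=float)
    conc = np.asarray(pairs["concentration"], dtype=float)
    if inten.size < 3:
        raise ValueError("need at least 3 calibration pairs")
    if np.ptp(conc) == 0 or np.ptp(inten) == 0:
        raise ValueError("calibration pairs are rank-deficient (no spread)")
    slope, intercept = np.polyfit(inten, conc, 1)
    if slope <= 0:
        raise ValueError("non-positive calibration slope")
    pred = slope * inten + intercept
    ss_res = float(np.sum((conc - pred) ** 2))
    ss_tot = float(np.sum((conc - conc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return CalibrationLine(factor=float(slope), background=float(-intercept / slope),
                           r_squared=r2)


def image_to_numbers(intensity_image: np.ndarray, mask: np.ndarray,
                     line: CalibrationLine, voxel_volume: float) -> tuple[float, float]:
    """Convert masked image intensities to (mean nM, total copy number).

    Per-voxel concentration is factor * (I - background), clipped at zero so
    copy numbers stay nonnegative; copies = sum(C * voxel_volume * N_A) over
    the mask, with voxel_volume in liters.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if voxel_volume <= 0:
        raise ValueError("voxel volume must be positive")
    img = np.asarray(intensity_image, dtype=float)
    conc = np.clip(line.factor * (img[mask] - line.background), 0.0, None)
    mean_nM = float(conc.mean())
    copies = float(np.sum(conc * 1e-9 * voxel_volume * Avogadro))
    return mean_nM, copies
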