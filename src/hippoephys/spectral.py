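"""Welch spectra, line-bin repair, aperiodic (1/f) parameterization, and
band-power / band-ratio quantification.

The aperiodic model is the fixed (knee-free) form

    log10 P(f) = offset - exponent * log10 f

fitted robustly over 1-100 Hz after line-bin repair. Narrowband peaks are
detected iteratively on the flattened (log) spectrum and modeled as
Gaussians; the periodic ("peak-only") spectrum is the linear-scale
residual ``max(P - 10**model, 0)``, which is what band powers integrate.
The slow band (0.1-1 Hz) lies below the fit range, so the aperiodic model
is extrapolated down to the spectrum's lowest positive frequency when
forming the residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import welch as _scipy_welch

from .core import TimeSeries

__all__ = [
    "Spectrum",
    "AperiodicFit",
    "BandPowerReport",
    "DEFAULT_BANDS",
    "welch",
    "repair_line_bins",
    "fit_aperiodic",
    "band_powers",
    "band_auc",
]

#: canonical band definitions (Hz)
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "slow": (0.1, 1.0),
    "delta": (1.0, 4.0),
    "theta": (4.0, 12.0),
    "beta": (15.0, 25.0),
    "gamma": (30.0, 100.0),
}


@dataclass
class Spectrum:
    """One-sided power spectral density on a regular frequency grid."""

    freqs_hz: np.ndarray
    power: np.ndarray  # signal-units^2 / Hz
    window_s: float = 0.0
    overlap_frac: float = 0.0
    step_hz: float = 0.0

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def copy(self) -> "Spectrum":
        return Spectrum(self.freqs_hz.copy(), self.power.copy(),
                        self.window_s, self.overlap_frac, self.step_hz)


@dataclass
class AperiodicFit:
    offset: float  # log10 power at 1 Hz
    exponent: float
    fit_range_hz: tuple[float, float]
    peaks: list[tuple[float, float, float]]  # (center_hz, height_log10, width_hz)
    residual: Spectrum  # linear-scale periodic ("peak-only") spectrum

    def model_linear(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Aperiodic model 10**(offset - exponent*log10 f) on a grid."""
        f = np.asarray(freqs_hz, dtype=float)
        out = np.zeros_like(f)
        pos = f > 0
        out[pos] = 10.0 ** (self.offset - self.exponent * np.log10(f[pos]))
        return out


def welch(
    ts: TimeSeries,
    window_s: float = 10.0,
    overlap_frac: float = 0.5,
    step_hz: float | None = 0.1,
) -> Spectrum:
    """Welch PSD with a Hann window and one-sided density scaling.

    ``step_hz`` finer than the window's natural resolution is realized by
    zero-padding each segment.
    """
    if window_s > ts.duration_s:
        raise ValueError(
            f"window ({window_s} s) longer than signal ({ts.duration_s:.3f} s)")
    nperseg = int(round(window_s * ts.rate_hz))
    noverlap = int(round(overlap_frac * nperseg))
    nfft = nperseg
    if step_hz is not None:
        nfft = max(nperseg, int(round(ts.rate_hz / step_hz)))
    freqs, pxx = _scipy_welch(
        ts.data, fs=ts.rate_hz, window="hann", nperseg=nperseg,
        noverlap=noverlap, nfft=nfft, detrend="constant", scaling="density",
        axis=-1,
    )
    eff_step = float(freqs[1] - freqs[0]) if freqs.size > 1 else 0.0
    return Spectrum(freqs, pxx, window_s=window_s, overlap_frac=overlap_frac,
                    step_hz=eff_step)


def repair_line_bins(
    spec: Spectrum, line_freqs_hz: list[float], half_width_hz: float = 1.0
) -> Spectrum:
    """Replace mains-contaminated bins by the mean of flanking clean bins.

    All bins within ``half_width_hz`` of any line frequency are marked
    contaminated and replaced by the mean of the nearest clean bin on
    each side (single neighbor at a grid edge).
    """
    out = spec.copy()
    f = out.freqs_hz
    contaminated = np.zeros(f.size, dtype=bool)
    for lf in line_freqs_hz:
        if lf < f[0] or lf > f[-1]:
            raise ValueError(f"line frequency {lf} Hz outside spectrum grid")
        contaminated |= np.abs(f - lf) <= half_width_hz
    idx = np.flatnonzero(contaminated)
    clean = np.flatnonzero(~contaminated)
    if idx.size == 0:
        return out
    if clean.size == 0:
        raise ValueError("no clean bins left to repair from")
    for i in idx:
        left = clean[clean < i]
        right = clean[clean > i]
        vals = []
        if left.size:
            vals.append(spec.power[left[-1]])
        if right.size:
            vals.append(spec.power[right[0]])
        out.power[i] = float(np.mean(vals))
    return out


def _linfit(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """(offset, exponent) by least squares of logp = offset - exponent*logf."""
    A = np.column_stack([np.ones_like(logf), -logf])
    coef, *_ = np.linalg.lstsq(A, logp, rcond=None)
    return float(coef[0]), float(coef[1])


def _robust_ap_fit(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """Aperiodic fit ignoring points that sit above the bulk (peaks).

    First pass is plain least squares; the refit keeps only the points
    whose positive deviation from the first fit is within the lowest
    2.5 % of deviations — the lower envelope of the spectrum.
    """
    off, exp = _linfit(logf, logp)
    flat = logp - (off - exp * logf)
    flat = np.clip(flat, 0.0, None)
    thresh = np.percentile(flat, 2.5)
    mask = flat <= thresh
    if mask.sum() >= 2:
        off, exp = _linfit(logf[mask], logp[mask])
    return off, exp


def _gaussian_sum(f_hz: np.ndarray, *params: float) -> np.ndarray:
    """Sum of Gaussians (center, height, sd) on the linear frequency axis."""
    out = np.zeros_like(f_hz)
    for i in range(0, len(params), 3):
        c, h, w = params[i : i + 3]
        out += h * np.exp(-((f_hz - c) ** 2) / (2 * w**2))
    return out


def fit_aperiodic(
    spec: Spectrum,
    fit_range_hz: tuple[float, float] = (1.0, 100.0),
    peak_threshold_sd: float = 2.0,
    max_peaks: int = 6,
    peak_width_bounds_hz: tuple[float, float] = (0.5, 12.0),
) -> AperiodicFit:
    """Parameterize a spectrum into aperiodic 1/f component + Gaussian peaks.

    Returns the fitted offset/exponent, the detected peaks, and the
    linear-scale peak-only residual over the full spectrum grid.
    """
    f = spec.freqs_hz
    in_range = (f >= fit_range_hz[0]) & (f <= fit_range_hz[1])
    if not in_range.any():
        raise ValueError("spectrum does not cover the fit range")
    ff = f[in_range]
    pp = spec.power[in_range]
    if np.any(pp <= 0):
        raise ValueError("non-positive power inside fit range; log undefined")
    logf = np.log10(ff)
    logp = np.log10(pp)

    off, exp = _robust_ap_fit(logf, logp)
    flat = logp - (off - exp * logf)

    # iterative peak extraction on the flattened spectrum
    guesses: list[tuple[float, float, float]] = []  # center, height, width (Hz)
    work = flat.copy()
    lo_w, hi_w = peak_width_bounds_hz
    for _ in range(max_peaks):
        i = int(np.argmax(work))
        height = work[i]
        sd = float(np.std(work))
        if sd == 0 or height <= peak_threshold_sd * sd or height <= 0:
            break
        center = ff[i]
        # width from half-height extent around the maximum
        half = height / 2.0
        li = i
        while li > 0 and work[li] > half:
            li -= 1
        ri = i
        while ri < work.size - 1 and work[ri] > half:
            ri += 1
        fwhm = max(ff[ri] - ff[li], 1e-6)
        width = float(np.clip(fwhm / 2.355, lo_w / 2.0, hi_w / 2.0))
        guesses.append((float(center), float(height), width))
        work = work - height * np.exp(-((ff - center) ** 2) / (2 * width**2))

    peaks = list(guesses)
    if guesses:  # joint Gaussian refinement
        p0, lob, upb = [], [], []
        for c, h, w in guesses:
            p0 += [c, h, w]
            # keep the refinement local: the half-height-extent guess already
            # fixes the scale, the fit only polishes it
            lob += [max(c - 2 * w, fit_range_hz[0]), 0.0, max(w / 2.0, lo_w / 2.0)]
            upb += [min(c + 2 * w, fit_range_hz[1]), 2 * h + 1.0, min(2.0 * w, hi_w / 2.0)]
        try:
            popt, _ = curve_fit(
                lambda x, *p: _gaussian_sum(x, *p), ff, flat, p0=p0,
                bounds=(lob, upb), maxfev=3000,
            )
            peaks = [
                (float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
                for i in range(0, len(popt), 3)
            ]
        except RuntimeError:
            pass

    # final fit: plain least squares with detected-peak regions masked out
    # (subtracting fitted Gaussians instead would propagate their fit error
    # into the aperiodic parameters)
    mask = np.ones(ff.size, dtype=bool)
    for c, h, w in peaks:
        mask &= np.abs(ff - c) > 1.5 * 2.355 * w
    if mask.sum() >= 10:
        off, exp = _linfit(logf[mask], logp[mask])
    else:
        off, exp = _linfit(logf, logp)

    fit = AperiodicFit(
        offset=off, exponent=exp, fit_range_hz=fit_range_hz,
        peaks=[(c, h, w * 2.355) for c, h, w in peaks],  # report FWHM width
        residual=spec.copy(),
    )
    resid = np.clip(spec.power - fit.model_linear(f), 0.0, None)
    resid[f <= 0] = 0.0
    fit.residual = Spectrum(f.copy(), resid, spec.window_s, spec.overlap_frac,
                            spec.step_hz)
    return fit


def band_auc(spec: Spectrum, lo_hz: float, hi_hz: float) -> float:
    """Trapezoidal area under the PSD over [lo, hi], edge-interpolated."""
    f, p = spec.freqs_hz, spec.power
    if lo_hz < f[0] or hi_hz > f[-1]:
        raise ValueError(f"band [{lo_hz}, {hi_hz}] Hz outside spectrum range")
    inside = (f > lo_hz) & (f < hi_hz)
    grid = np.concatenate([[lo_hz], f[inside], [hi_hz]])
    vals = np.interp(grid, f, p)
    return float(np.trapezoid(vals, grid))


@dataclass
class BandPowerReport:
    absolute: dict[str, float]
    normalized: dict[str, float]
    ratios: dict[str, float]
    norm_range_hz: tuple[float, float]
    norm_denominator: str = "residual"
    flags: list[str] = field(default_factory=list)


def band_powers(
    spec: Spectrum,
    bands: dict[str, tuple[float, float]] | None = None,
    norm_range_hz: tuple[float, float] = (0.1, 100.0),
) -> BandPowerReport:
    """Absolute (AUC) and normalized band powers plus the standard ratios.

    ``spec`` is typically the peak-only residual from :func:`fit_aperiodic`
    but any spectrum (e.g. a raw PSC spectrum) can be passed. Normalized
    power divides each band AUC by the AUC over ``norm_range_hz``.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    total = band_auc(spec, *norm_range_hz)
    if total <= 0:
        raise ValueError("normalization denominator is zero")
    absolute = {name: band_auc(spec, lo, hi) for name, (lo, hi) in bands.items()}
    normalized = {name: a / total for name, a in absolute.items()}
    flags: list[str] = []

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(f"{name}: zero denominator")
            return float("nan")
        return num / den

    ratios: dict[str, float] = {}
    if {"theta", "delta"} <= normalized.keys():
        ratios["theta/delta"] = _ratio(normalized["theta"], normalized["delta"],
                                       "theta/delta")
    if {"beta", "theta"} <= normalized.keys():
        ratios["beta/theta"] = _ratio(normalized["beta"], normalized["theta"],
                                      "beta/theta")
    if {"theta", "beta", "slow", "delta"} <= normalized.keys():
        ratios["(theta+beta)/(slow+delta)"] = _ratio(
            normalized["theta"] + normalized["beta"],
            normalized["slow"] + normalized["delta"],
            "(theta+beta)/(slow+delta)",
        )
    return BandPowerReport(absolute, normalized, ratios, norm_range_hz, flags=flags)
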