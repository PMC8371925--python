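"""Welch power spectra and periodic/aperiodic spectral parameterization.

The parameterization decomposes a power spectrum, in log10-power space,
into an aperiodic background with a knee,

    L(f) = b - log10(k + f**chi),

plus Gaussian peaks fitted iteratively on the flattened residual.  This is
the standard spectral-parameterization model used to separate 1/f-like
background from genuine oscillatory peaks; a trace is called "periodic" at
frequency f only if a peak survives above the aperiodic trend.

Peak heights are in log10(power) units above the aperiodic curve; peak
bandwidth is reported as 2 * the Gaussian standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from .containers import FitError, InputError, MotionTrace, ParameterError


@dataclass
class Spectrum:
    """A one-sided power spectral density with its estimation settings."""

    freqs_hz: np.ndarray
    power: np.ndarray
    seg_len_samples: int | None = None
    overlap_samples: int | None = None
    window: str = "hann"

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float).ravel()
        self.power = np.asarray(self.power, dtype=float).ravel()
        if self.freqs_hz.size != self.power.size:
            raise InputError("freqs and power must have equal length")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise InputError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise InputError("power must be non-negative")


@dataclass
class SpectralFit:
    """Aperiodic + Gaussian-peaks decomposition of a spectrum.

    aperiodic : (offset, knee, exponent) of b - log10(knee + f**exponent)
    peaks : rows of (center_hz, height_log10power, bandwidth_hz), sorted by
        descending height; bandwidth = 2 * Gaussian sd
    r_squared : variance explained by the full model in log10-power space
    """

    aperiodic: tuple[float, float, float]
    peaks: np.ndarray
    r_squared: float
    fit_range_hz: tuple[float, float] = (0.0, np.inf)
    freqs_hz: np.ndarray = field(default_factory=lambda: np.empty(0))
    model_log10: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_peaks(self) -> int:
        return int(np.asarray(self.peaks).reshape(-1, 3).shape[0])


def welch_psd(
    trace: MotionTrace | np.ndarray,
    seg_len_samples: int = 64,
    overlap_samples: int = 32,
    rate_hz: float | None = None,
    window: str = "hann",
) -> Spectrum:
    """Welch PSD with per-segment linear detrending and a Hanning window.

    Defaults (64-sample segments, 32-sample overlap) give 2.13 s segments
    with 1.07 s overlap at a 30 Hz video rate.
    """
    if isinstance(trace, MotionTrace):
        x = trace.values
        fs = trace.rate_hz
    else:
        if rate_hz is None:
            raise InputError("rate_hz required for raw arrays")
        x = np.asarray(trace, dtype=float).ravel()
        fs = rate_hz
    if not 0 <= overlap_samples < seg_len_samples:
        raise ParameterError("need 0 <= overlap < segment length")
    if x.size < seg_len_samples:
        raise InputError(
            f"trace of {x.size} samples shorter than one segment "
            f"({seg_len_samples})"
        )
    freqs, pxx = signal.welch(
        x,
        fs=fs,
        window=window,
        nperseg=seg_len_samples,
        noverlap=overlap_samples,
        detrend="linear",
    )
    return Spectrum(
        freqs_hz=freqs,
        power=pxx,
        seg_len_samples=seg_len_samples,
        overlap_samples=overlap_samples,
        window=window,
    )


def average_spectra(spectra: list[Spectrum], weights: list[float]) -> Spectrum:
    """Weighted average of spectra on a common frequency grid.

    Used to pool per-video spectra with weights proportional to video
    duration.
    """
    if not spectra:
        raise InputError("no spectra to average")
    f0 = spectra[0].freqs_hz
    for s in spectra[1:]:
        if s.freqs_hz.shape != f0.shape or not np.allclose(s.freqs_hz, f0):
            raise InputError("spectra are on different frequency grids")
    w = np.asarray(weights, dtype=float)
    if w.size != len(spectra) or np.any(w < 0) or w.sum() == 0:
        raise ParameterError("weights must be non-negative and sum > 0")
    power = sum(wi * s.power for wi, s in zip(w, spectra)) / w.sum()
    return Spectrum(freqs_hz=f0, power=power, seg_len_samples=spectra[0].seg_len_samples,
                    overlap_samples=spectra[0].overlap_samples, window=spectra[0].window)


def _aperiodic_log10(f: np.ndarray, offset: float, knee: float, exponent: float) -> np.ndarray:
    return offset - np.log10(knee + f**exponent)


def _gaussian(f: np.ndarray, center: float, height: float, sd: float) -> np.ndarray:
    return height * np.exp(-((f - center) ** 2) / (2.0 * sd**2))


def _fit_aperiodic(freqs: np.ndarray, log_power: np.ndarray) -> np.ndarray:
    """Robust fit of the knee-aperiodic curve in log10 space.

    Two-pass: an initial least-squares fit, then a refit restricted to the
    points whose positive residual is below the 2.5% percentile threshold,
    which de-weights peak regions sitting above the background.
    """
    guess = np.array([log_power[0] + np.log10(1.0 + freqs[0]), 1.0, 2.0])
    bounds = ([-np.inf, 0.0, 0.0], [np.inf, np.inf, 10.0])
    try:
        popt, _ = curve_fit(
            _aperiodic_log10, freqs, log_power, p0=guess, bounds=bounds, maxfev=5000
        )
    except RuntimeError as err:  # pragma: no cover - rare
        raise FitError(f"initial aperiodic fit failed: {err}") from err
    resid = log_power - _aperiodic_log10(freqs, *popt)
    thresh = np.percentile(resid, 2.5)
    keep = resid <= np.abs(thresh)
    if keep.sum() >= 4:
        try:
            popt, _ = curve_fit(
                _aperiodic_log10,
                freqs[keep],
                log_power[keep],
                p0=popt,
                bounds=bounds,
                maxfev=5000,
            )
        except RuntimeError as err:  # pragma: no cover
            raise FitError(f"robust aperiodic refit failed: {err}") from err
    return popt


def parameterize_spectrum(
    spectrum: Spectrum,
    fit_range_hz: tuple[float, float] = (0.0, 15.0),
    min_peak_sd: float = 2.0,
    peak_width_limits_hz: tuple[float, float] = (1.0, 8.0),
    aperiodic_mode: str = "knee",
    max_n_peaks: int | None = None,
) -> SpectralFit:
    """Fit the aperiodic-plus-peaks model to a spectrum.

    Iterative procedure in log10-power space:

    1. fit the aperiodic curve (with knee term when ``aperiodic_mode`` is
       ``"knee"``, else fixed knee = 0);
    2. flatten: residual = log-power minus aperiodic fit;
    3. while the largest residual exceeds ``min_peak_sd`` times the
       residual SD, fit a Gaussian there, subtract it, and keep it if its
       bandwidth (2 sd) falls inside ``peak_width_limits_hz``;
    4. refit all kept Gaussians jointly on the flattened spectrum, refit
       the aperiodic curve on the peak-removed spectrum, and report the
       r-squared of the combined model.
    """
    if aperiodic_mode not in ("knee", "fixed"):
        raise ParameterError(f"unknown aperiodic_mode {aperiodic_mode!r}")
    lo, hi = fit_range_hz
    sel = (spectrum.freqs_hz >= lo) & (spectrum.freqs_hz <= hi) & (spectrum.freqs_hz > 0)
    freqs = spectrum.freqs_hz[sel]
    power = spectrum.power[sel]
    if freqs.size < 5:
        raise InputError("fit range contains too few frequency bins")
    if np.any(power <= 0):
        raise InputError("power must be strictly positive inside the fit range")
    log_power = np.log10(power)

    if aperiodic_mode == "knee":
        ap = _fit_aperiodic(freqs, log_power)
    else:
        def _noknee(f, offset, exponent):
            return _aperiodic_log10(f, offset, 0.0, exponent)

        popt, _ = curve_fit(_noknee, freqs, log_power, p0=[log_power[0], 2.0], maxfev=5000)
        ap = np.array([popt[0], 0.0, popt[1]])

    flat = log_power - _aperiodic_log10(freqs, *ap)

    sd_lo, sd_hi = peak_width_limits_hz[0] / 2.0, peak_width_limits_hz[1] / 2.0
    guesses: list[tuple[float, float, float]] = []
    residual = flat.copy()
    df = freqs[1] - freqs[0]
    while max_n_peaks is None or len(guesses) < max_n_peaks:
        i = int(np.argmax(residual))
        height = residual[i]
        if height <= min_peak_sd * np.std(residual) or height <= 0:
            break
        center = freqs[i]
        # data-driven width guess: half-height extent around the maximum
        half = height / 2.0
        j_hi = i
        while j_hi + 1 < residual.size and residual[j_hi + 1] > half:
            j_hi += 1
        j_lo = i
        while j_lo - 1 >= 0 and residual[j_lo - 1] > half:
            j_lo -= 1
        fwhm = max((j_hi - j_lo) * df, df)
        sd_guess = np.clip(fwhm / 2.355, sd_lo, sd_hi)
        guesses.append((center, height, sd_guess))
        residual = residual - _gaussian(freqs, center, height, sd_guess)

    # standard pruning of the guesses: drop peaks hugging a fit-range edge
    # (< 1 sd away) and, among overlapping guesses (centers closer than
    # 0.75 of their summed sds), keep only the tallest
    guesses = [
        (c, h, s)
        for c, h, s in guesses
        if c - freqs[0] >= 1.0 * s and freqs[-1] - c >= 1.0 * s
    ]
    guesses.sort(key=lambda g: -g[1])
    pruned: list[tuple[float, float, float]] = []
    for c, h, s in guesses:
        if all(abs(c - c2) >= 0.75 * (s + s2) for c2, _, s2 in pruned):
            pruned.append((c, h, s))
    guesses = pruned

    def multi_gauss(f, *params):
        total = np.zeros_like(f)
        for c, h, s in np.reshape(params, (-1, 3)):
            total = total + _gaussian(f, c, h, s)
        return total

    def refine(current, ap, flat):
        """Alternate joint Gaussian refinement with a plain aperiodic
        refit on the peak-removed spectrum: the initial background
        estimate is biased upward under a peak and iteration undoes
        that."""
        lower, upper = [], []
        for c, h, s in current:
            lower += [max(freqs[0], c - 2 * s), 0.0, sd_lo * 0.75]
            upper += [min(freqs[-1], c + 2 * s), np.inf, sd_hi * 1.25]
        p0 = np.ravel(current)
        ap_bounds = ([-np.inf, 0.0, 0.0], [np.inf, np.inf, 10.0])
        for _ in range(6):
            try:
                popt, _ = curve_fit(
                    multi_gauss, freqs, flat, p0=p0,
                    bounds=(lower, upper), maxfev=10000,
                )
            except RuntimeError:
                popt = p0  # fall back to the current guesses
            p0 = popt
            peak_model = multi_gauss(freqs, *popt)
            if aperiodic_mode == "knee":
                try:
                    ap, _ = curve_fit(
                        _aperiodic_log10, freqs, log_power - peak_model,
                        p0=ap, bounds=ap_bounds, maxfev=10000,
                    )
                except RuntimeError:
                    pass
            flat = log_power - _aperiodic_log10(freqs, *ap)
        return np.reshape(p0, (-1, 3)), ap, flat

    current = guesses
    for _round in range(3):
        if not current:
            break
        fitted, ap, flat = refine(current, ap, flat)
        # prune: width limits, post-refinement detection threshold, and
        # overlapping peaks (keep the tallest of any overlapping pair)
        peak_model = multi_gauss(freqs, *np.ravel(fitted))
        resid_sd = np.std(flat - peak_model)
        survivors = [
            (c, h, s)
            for c, h, s in fitted
            if sd_lo <= s <= sd_hi and h > min_peak_sd * resid_sd
        ]
        survivors.sort(key=lambda g: -g[1])
        pruned = []
        for c, h, s in survivors:
            if all(abs(c - c2) >= 0.75 * (s + s2) for c2, _, s2 in pruned):
                pruned.append((c, h, s))
        if len(pruned) == len(current):
            current = pruned
            break
        current = pruned  # something was dropped; refit the survivors

    peaks = np.empty((0, 3))
    peak_model = np.zeros_like(freqs)
    if current:
        arr = np.asarray(current)
        peaks = np.column_stack([arr[:, 0], arr[:, 1], 2.0 * arr[:, 2]])
        peaks = peaks[np.argsort(-peaks[:, 1])]
        peak_model = multi_gauss(freqs, *np.ravel(arr))

    model = _aperiodic_log10(freqs, *ap) + peak_model
    ss_res = float(np.sum((log_power - model) ** 2))
    ss_tot = float(np.sum((log_power - log_power.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SpectralFit(
        aperiodic=(float(ap[0]), float(ap[1]), float(ap[2])),
        peaks=peaks,
        r_squared=max(0.0, min(1.0, r2)),
        fit_range_hz=(lo, hi),
        freqs_hz=freqs,
        model_log10=model,
    )
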