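"""Fourier Analysis SpecTroscopy (FAST) and trace denoising.

FAST measures broadband impedance between therapeutic bursts: a custom
low-voltage rectangular waveform is applied, voltage and current are
recorded, and the complex impedance Z(f) = V(f)/I(f) is read off the FFT
at the spectral peaks of the drive.  The low-frequency biphasic segment
(250 us pulses) puts its fundamental near 1.8-1.9 kHz, the characteristic
frequency used for the resistive agar phantom.

Also implements the two denoising fits applied to 1 Hz treatment traces:
a one-phase exponential decay for impedance and a quadratic for
temperature.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["Waveform", "ImpedanceSpectrum", "DecayFit", "QuadFit",
           "build_fast_waveform", "resistor_current", "parallel_rc_current",
           "impedance_spectrum", "impedance_at_characteristic",
           "fit_one_phase_decay", "fit_quadratic"]


@dataclass
class Waveform:
    """A sampled voltage or current record on a uniform time base."""

    sample_rate: float  # Hz
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class ImpedanceSpectrum:
    """Complex impedance at the spectral peaks of the drive waveform."""

    frequencies: np.ndarray     # full rFFT frequency axis (Hz)
    impedance: np.ndarray       # complex Z, NaN off the peak bins
    peak_bins: np.ndarray       # indices with usable drive energy

    @property
    def peak_frequencies(self) -> np.ndarray:
        return self.frequencies[self.peak_bins]

    @property
    def peak_impedance(self) -> np.ndarray:
        return self.impedance[self.peak_bins]


def _biphasic_segment(on: float, off: float, n_cycles: int,
                      sample_rate: float, amplitude: float) -> np.ndarray:
    n_on = int(round(on * sample_rate))
    n_off = int(round(off * sample_rate))
    cycle = np.concatenate([
        np.full(n_on, amplitude), np.zeros(n_off),
        np.full(n_on, -amplitude), np.zeros(n_off)])
    return np.tile(cycle, n_cycles)


def build_fast_waveform(amplitude: float = 1.0,
                        sample_rate: float = 10e6) -> Waveform:
    """Synthesize the FAST diagnostic voltage waveform.

    High-frequency segment: biphasic 1-50-1-50 us cycles repeated until
    the energized time totals 164 us, concatenated with a low-frequency
    biphasic 250-10-250-10 us segment with 1 ms energized time.  The
    sample rate must resolve the 1 us pulses (>= 2 MHz).
    """
    if sample_rate < 2e6:
        raise ValueError("sample_rate must be >= 2 MHz to resolve 1 us pulses")
    hf = _biphasic_segment(1e-6, 50e-6, 82, sample_rate, amplitude)
    lf = _biphasic_segment(250e-6, 10e-6, 2, sample_rate, amplitude)
    return Waveform(sample_rate, np.concatenate([hf, lf]))


def resistor_current(voltage: Waveform, resistance: float) -> Waveform:
    """Current through a pure resistor driven by ``voltage``."""
    if resistance <= 0:
        raise ValueError("resistance must be positive")
    return Waveform(voltage.sample_rate, voltage.samples / resistance)


def parallel_rc_current(voltage: Waveform, resistance: float,
                        capacitance: float) -> Waveform:
    """Current through a parallel RC load, computed spectrally.

    Admittance Y(f) = 1/R + j*2*pi*f*C applied to the FFT of the drive.
    """
    v_hat = np.fft.rfft(voltage.samples)
    f = np.fft.rfftfreq(len(voltage.samples), 1.0 / voltage.sample_rate)
    y = 1.0 / resistance + 2j * np.pi * f * capacitance
    i = np.fft.irfft(v_hat * y, n=len(voltage.samples))
    return Waveform(voltage.sample_rate, i)


def impedance_spectrum(voltage: Waveform, current: Waveform,
                       peak_threshold: float = 0.01,
                       noise_floor: float = 1e-12) -> ImpedanceSpectrum:
    """Z(f) = FFT(v)/FFT(i) at the spectral peaks of the drive.

    Peak bins are local maxima of |FFT(v)| exceeding ``peak_threshold``
    of the global maximum (rectangular window, matching finite-burst
    acquisition).  Bins where the current magnitude falls below
    ``noise_floor`` of its maximum are dropped as undefined.
    """
    if len(voltage.samples) != len(current.samples):
        raise ValueError("voltage and current must share a time base")
    if voltage.sample_rate != current.sample_rate:
        raise ValueError("voltage and current must share a sample rate")
    v_hat = np.fft.rfft(voltage.samples)
    i_hat = np.fft.rfft(current.samples)
    freqs = np.fft.rfftfreq(len(voltage.samples), 1.0 / voltage.sample_rate)
    mag = np.abs(v_hat)
    interior = np.zeros(len(mag), dtype=bool)
    interior[1:-1] = (mag[1:-1] >= mag[:-2]) & (mag[1:-1] >= mag[2:])
    peaks = np.flatnonzero(interior & (mag >= peak_threshold * mag.max()))
    usable = peaks[np.abs(i_hat[peaks]) > noise_floor * np.abs(i_hat).max()]
    z = np.full(len(freqs), np.nan + 0j, dtype=complex)
    z[usable] = v_hat[usable] / i_hat[usable]
    return ImpedanceSpectrum(freqs, z, usable)


def impedance_at_characteristic(spectrum: ImpedanceSpectrum,
                                window: tuple[float, float] = (1.5e3, 2.2e3),
                                ) -> complex:
    """Impedance at the characteristic (nominal 1.8 kHz) frequency.

    Returns Z at the drive spectral peak inside ``window``; with the
    default FAST waveform this is the low-frequency segment fundamental
    near 1.9 kHz.
    """
    f = spectrum.peak_frequencies
    in_window = (f >= window[0]) & (f <= window[1])
    if not np.any(in_window):
        nearest = f[np.argmin(np.abs(f - 1.8e3))] if len(f) else None
        raise ValueError(
            f"no spectral peak in {window[0]:.0f}-{window[1]:.0f} Hz; "
            f"nearest available peak at {nearest} Hz")
    candidates = np.flatnonzero(in_window)
    best = candidates[np.argmin(np.abs(f[candidates] - 1.8e3))]
    return complex(spectrum.peak_impedance[best])


@dataclass
class DecayFit:
    """One-phase exponential decay y(t) = plateau + (y0-plateau)*exp(-k t)."""

    y0: float
    plateau: float
    rate: float  # 1/s, >= 0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.plateau + (self.y0 - self.plateau) * np.exp(-self.rate * t)


@dataclass
class QuadFit:
    """Quadratic y(t) = a t^2 + b t + c."""

    a: float
    b: float
    c: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a * t ** 2 + self.b * t + self.c


def fit_one_phase_decay(t: np.ndarray, y: np.ndarray,
                        max_restarts: int = 4):
    """Nonlinear least-squares one-phase-decay fit (impedance denoising).

    Initial guesses: y0 = y[0], plateau = y[-1], k = 3/t_span, with k
    bounded at zero.  On non-convergence the fit is restarted from
    perturbed rates; the best attempt's residual norm is reported in the
    error if all restarts fail.

    Returns (DecayFit, fitted curve sampled at t).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ValueError("t and y must have equal length")
    if len(t) < 4:
        raise ValueError("need at least 4 points for a 3-parameter decay")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("t must be increasing")
    if np.ptp(y) == 0:  # degenerate: constant series
        fit = DecayFit(y0=float(y[0]), plateau=float(y[0]), rate=0.0)
        return fit, fit(t)

    def model(tt, y0, plateau, k):
        return plateau + (y0 - plateau) * np.exp(-k * tt)

    k0 = 3.0 / span
    best_err, best_resid = None, np.inf
    for attempt in range(max_restarts + 1):
        guess = [y[0], y[-1], k0 * (4.0 ** attempt) / 2.0 ** (attempt > 0)]
        try:
            popt, _ = curve_fit(
                model, t, y, p0=guess,
                bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000)
        except RuntimeError as exc:
            best_err = exc
            continue
        resid = float(np.linalg.norm(model(t, *popt) - y))
        if resid < best_resid:
            best_resid = resid
            fit = DecayFit(*map(float, popt))
        if resid <= 1.05 * best_resid:
            break
    if best_resid == np.inf:
        raise RuntimeError(
            f"one-phase decay fit failed after {max_restarts + 1} attempts "
            f"({best_err})")
    return fit, fit(t)


def fit_quadratic(t: np.ndarray, y: np.ndarray):
    """Ordinary least squares on the (1, t, t^2) basis (temperature
    denoising).  Returns (QuadFit, fitted curve sampled at t)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ValueError("t and y must have equal length")
    if len(t) < 3:
        raise ValueError("need at least 3 points for a quadratic")
    design = np.vander(t, 3)  # columns t^2, t, 1
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design (duplicate t values)")
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    fit = QuadFit(a=float(coefs[0]), b=float(coefs[1]), c=float(coefs[2]))
    return fit, fit(t)
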