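"""HRV feature extraction: 6 time-domain and 5 frequency-domain measures.

Time domain
    mRR    mean R-R interval (ms)
    mHR    mean instantaneous heart rate (bpm); the mean of 60000/RR_i, not
           60000/mRR — heart rate and heart period are nonlinearly related
    SDRR   sample standard deviation of R-R intervals (ms)
    CVRR   coefficient of variation, 100·SDRR/mRR
    RMSSD  root mean square of successive differences (ms)
    pNN5   percent of successive differences strictly exceeding 5 ms (the
           rodent analogue of the human pNN50)

Frequency domain (rat bands: LF 0.1–1.0 Hz, HF 1.0–3.5 Hz)
    lnLF, lnHF      natural log of band powers (ln ms²)
    lnLFHF          ln(LF/HF) = lnLF − lnHF
    nLF, nHF        each band's percentage of LF+HF power

The spectrum is Welch's periodogram (Hamming window, 512 points, 50% overlap)
of the R-R interval series cubic-spline resampled to a uniform 20-Hz grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .simulate import FEATURE_NAMES
from .tachogram import RRTachogram

LF_BAND: tuple[float, float] = (0.1, 1.0)
HF_BAND: tuple[float, float] = (1.0, 3.5)


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but the feature is undefined
    (e.g. zero band power makes the log-power features meaningless)."""


@dataclass(frozen=True)
class TimeDomainFeatures:
    mRR: float
    mHR: float
    SDRR: float
    CVRR: float
    RMSSD: float
    pNN5: float


@dataclass(frozen=True)
class PSD:
    """One-sided power spectral density of the interval series (ms²/Hz)."""

    freqs: np.ndarray
    density: np.ndarray
    lf_band: tuple[float, float] = LF_BAND
    hf_band: tuple[float, float] = HF_BAND

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        density = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "density", density)
        if freqs.size != density.size:
            raise ValueError("freqs and density must have equal length")
        if (np.diff(freqs) <= 0).any():
            raise ValueError("freqs must be strictly increasing")
        if (density < 0).any():
            raise ValueError("density must be non-negative")


@dataclass(frozen=True)
class FreqDomainFeatures:
    lnLF: float
    lnHF: float
    lnLFHF: float
    nLF: float
    nHF: float


def time_domain_features(rr: RRTachogram, ddof: int = 1) -> TimeDomainFeatures:
    """Compute the six time-domain HRV features from an R-R tachogram."""
    x = rr.intervals
    if x.size < 3:
        raise ValueError("need at least 3 intervals (2 successive differences)")
    if (x <= 0).any():
        raise ValueError("all intervals must be positive")
    diffs = np.diff(x)
    mrr = float(np.mean(x))
    sdrr = float(np.std(x, ddof=ddof))
    return TimeDomainFeatures(
        mRR=mrr,
        mHR=float(np.mean(60000.0 / x)),
        SDRR=sdrr,
        CVRR=100.0 * sdrr / mrr,
        RMSSD=float(np.sqrt(np.mean(diffs**2))),
        pNN5=100.0 * float(np.count_nonzero(np.abs(diffs) > 5.0)) / diffs.size,
    )


def welch_psd(
    rr: RRTachogram,
    resample_hz: float = 20.0,
    nperseg: int = 512,
) -> PSD:
    """Welch power spectral density of the beat-interval series.

    The irregularly sampled RR(t) series is cubic-spline interpolated onto a
    uniform ``resample_hz`` grid (Nyquist 10 Hz comfortably above the 3.5-Hz
    HF edge), mean-removed, and fed to Welch's method with Hamming segments
    of ``nperseg`` points at 50% overlap.  If the series is too short for a
    full segment the estimate falls back to a single full-length window with
    a warning.
    """
    if rr.intervals.size < 4:
        raise ValueError("too few intervals for a spectral estimate")
    t = rr.times
    x = rr.intervals
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    if grid.size < 8:
        raise ValueError("tachogram span too short for any spectral estimate")
    uniform = CubicSpline(t, x)(grid)
    if grid.size < nperseg:
        warnings.warn(
            f"series of {grid.size} points shorter than the {nperseg}-point "
            "Welch segment; using a single full-length window",
            stacklevel=2,
        )
        nperseg = grid.size
    freqs, density = sps.welch(
        uniform,
        fs=resample_hz,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return PSD(freqs=freqs, density=density)


def _band_power(psd: PSD, band: tuple[float, float], closed_right: bool) -> float:
    lo, hi = band
    if closed_right:
        mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    else:
        mask = (psd.freqs >= lo) & (psd.freqs < hi)
    if mask.sum() < 2:
        raise ValueError(f"PSD grid does not cover the band [{lo}, {hi}] Hz")
    return float(np.trapezoid(psd.density[mask], psd.freqs[mask]))


def frequency_domain_features(psd: PSD) -> FreqDomainFeatures:
    """Band powers and derived spectral HRV features from a PSD.

    LF is integrated over [0.1, 1.0) and HF over [1.0, 3.5] (trapezoidal
    rule); the 1.0-Hz edge belongs to HF only.
    """
    lf = _band_power(psd, psd.lf_band, closed_right=False)
    hf = _band_power(psd, psd.hf_band, closed_right=True)
    if lf <= 0 or hf <= 0:
        raise DegenerateInputError(
            f"zero band power (LF={lf:.3g}, HF={hf:.3g} ms²); "
            "log-power features undefined"
        )
    ln_lf = float(np.log(lf))
    ln_hf = float(np.log(hf))
    n_lf = 100.0 * lf / (lf + hf)
    return FreqDomainFeatures(
        lnLF=ln_lf,
        lnHF=ln_hf,
        lnLFHF=ln_lf - ln_hf,
        nLF=n_lf,
        nHF=100.0 - n_lf,
    )


def feature_vector(rr: RRTachogram, resample_hz: float = 20.0) -> pd.Series:
    """The full 11-feature HRV vector in canonical order.

    Returns a Series indexed mRR, mHR, SDRR, CVRR, RMSSD, pNN5, lnLF, lnHF,
    lnLFHF, nLF, nHF.  Component errors (too-short input, zero band power)
    propagate.
    """
    td = time_domain_features(rr)
    fd = frequency_domain_features(welch_psd(rr, resample_hz=resample_hz))
    values = {
        "mRR": td.mRR, "mHR": td.mHR, "SDRR": td.SDRR, "CVRR": td.CVRR,
        "RMSSD": td.RMSSD, "pNN5": td.pNN5,
        "lnLF": fd.lnLF, "lnHF": fd.lnHF, "lnLFHF": fd.lnLFHF,
        "nLF": fd.nLF, "nHF": fd.nHF,
    }
    return pd.Series([values[k] for k in FEATURE_NAMES], index=list(FEATURE_NAMES))
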