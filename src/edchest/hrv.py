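"""Short-term HRV parameters: time-domain, geometric, and spectral measures.

Sixteen parameters are computed from a labelled NN-interval series, following
the conventional short-term recording guidelines: time-domain statistics of
the NN intervals and instantaneous heart rate, the NN-histogram geometry
(triangular index and TINN), and Welch band powers of the cubic-spline
resampled tachogram in the VLF / LF / HF bands.

Only intervals labelled ``normal`` enter any metric. Powers are expressed in
s^2 (the tachogram is in seconds); normalized LF and HF are percentages of
LF + HF and always sum to 100 when that denominator is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .signal import RRSeries

__all__ = [
    "HRVParams",
    "SpectralConfig",
    "HistogramConfig",
    "ZeroPowerError",
    "time_domain",
    "geometric_metrics",
    "spectral_metrics",
    "compute_all",
]


class ZeroPowerError(ValueError):
    """Raised when LF+HF power vanishes and normalized powers are undefined."""


@dataclass(frozen=True)
class SpectralConfig:
    """Frequency analysis settings (Hz bands, resampling, Welch windowing)."""

    vlf_band: tuple[float, float] = (0.0033, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    resample_rate: float = 4.0
    window_length: float = 120.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        bands = [self.vlf_band, self.lf_band, self.hf_band]
        prev_hi = 0.0
        for lo, hi in bands:
            if not (prev_hi <= lo < hi):
                raise ValueError("bands must be increasing and disjoint")
            prev_hi = hi
        if bands[-1][1] >= self.resample_rate / 2:
            raise ValueError("HF band must lie below the Nyquist frequency")


@dataclass(frozen=True)
class HistogramConfig:
    """NN-histogram settings. Default bin width 1/128 s."""

    bin_width: float = 1.0 / 128.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


@dataclass
class HRVParams:
    """The 16 HRV parameters.

    Units: ``avrr``, ``sdrr``, ``rmssd``, ``tinn`` in seconds; ``avg_hr``,
    ``sd_hr`` in beats/min; ``nn50`` a count and ``pnn50`` a percentage;
    powers in s^2; ``nlf``/``nhf`` percentages of LF+HF; ``lf_hf`` a ratio.
    Spectral fields are NaN when the series admits no spectrum (e.g. a
    constant tachogram); ``spectral_defined`` records that.
    """

    avrr: float = np.nan
    sdrr: float = np.nan
    avg_hr: float = np.nan
    sd_hr: float = np.nan
    rmssd: float = np.nan
    nn50: int = 0
    pnn50: float = np.nan
    tri_index: float = np.nan
    tinn: float = np.nan
    total_power: float = np.nan
    vlf: float = np.nan
    lf: float = np.nan
    hf: float = np.nan
    nlf: float = np.nan
    nhf: float = np.nan
    lf_hf: float = np.nan
    spectral_defined: bool = field(default=True, repr=False)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "spectral_defined"}


# ---------------------------------------------------------------------------


def _nn(nn) -> np.ndarray:
    if isinstance(nn, RRSeries):
        return nn.normal_intervals
    return np.asarray(nn, dtype=float)


def time_domain(nn) -> HRVParams:
    """Time-domain statistics of the NN series.

    avrr/sdrr are the mean and (population) SD of the NN intervals; avg_hr /
    sd_hr the mean and SD of the per-interval instantaneous rate 60/NN;
    rmssd the RMS of successive differences; nn50 the number of successive
    differences exceeding 50 ms in magnitude; pnn50 = 100 * nn50 / (number
    of NN intervals).
    """
    x = _nn(nn)
    if x.size < 2:
        raise ValueError("need at least 2 normal intervals")
    hr = 60.0 / x
    d = np.diff(x)
    nn50 = int(np.count_nonzero(np.abs(d) > 0.050))
    return HRVParams(
        avrr=float(np.mean(x)),
        sdrr=float(np.std(x)),
        avg_hr=float(np.mean(hr)),
        sd_hr=float(np.std(hr)),
        rmssd=float(np.sqrt(np.mean(d * d))),
        nn50=nn50,
        pnn50=100.0 * nn50 / x.size,
    )


def geometric_metrics(nn, cfg: HistogramConfig = HistogramConfig()
                      ) -> tuple[float, float]:
    """Triangular index and TINN from the NN histogram.

    The triangular index is the total interval count divided by the modal bin
    height. TINN is the base width M - N of the triangle rising from (N, 0)
    to the modal bin's peak and falling to (M, 0) that minimizes the total
    squared deviation from the histogram, found by exhaustive search over
    bin edges N below and M above the mode. A single-occupied-bin histogram
    degenerates to tri_index = 1, tinn = 0.
    """
    x = _nn(nn)
    if x.size == 0:
        raise ValueError("empty histogram")
    bw = cfg.bin_width
    lo = np.floor(x.min() / bw) * bw
    nbins = int(np.ceil((x.max() - lo) / bw)) + 1
    edges = lo + bw * np.arange(nbins + 1)
    counts, _ = np.histogram(x, bins=edges)
    k = int(np.argmax(counts))
    peak = counts[k]
    tri_index = x.size / float(peak)
    if np.count_nonzero(counts) == 1:
        return tri_index, 0.0

    centers = (edges[:-1] + edges[1:]) / 2.0
    ck = centers[k]
    best = (np.inf, 0.0)
    for iN in range(0, k + 1):          # N = edges[iN] < ck
        N = edges[iN]
        for iM in range(k + 1, nbins + 1):  # M = edges[iM] > ck
            M = edges[iM]
            tri = np.zeros_like(counts, dtype=float)
            left = (centers >= N) & (centers < ck)
            tri[left] = peak * (centers[left] - N) / (ck - N)
            right = (centers > ck) & (centers <= M)
            tri[right] = peak * (M - centers[right]) / (M - ck)
            tri[k] = peak
            err = float(np.sum((counts - tri) ** 2))
            if err < best[0]:
                best = (err, M - N)
    return tri_index, float(best[1])


def resample_tachogram(nn: RRSeries, rate: float = 4.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline interpolation of the normal-interval tachogram.

    Returns ``(t, y)``: a uniform time grid at ``rate`` Hz spanning the
    labelled series, and the interpolated NN value (seconds) at each point.
    Each interval is anchored at its later beat's time.
    """
    t_nn = nn.normal_times
    y_nn = nn.normal_intervals
    if t_nn.size < 4:
        raise ValueError("too few normal intervals for spline resampling")
    spline = CubicSpline(t_nn, y_nn)
    n = int(np.floor((t_nn[-1] - t_nn[0]) * rate)) + 1
    t = t_nn[0] + np.arange(n) / rate
    return t, spline(t)


def _band_power(f: np.ndarray, psd: np.ndarray, band: tuple[float, float]
                ) -> float:
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], f[mask]))


def spectral_metrics(nn: RRSeries, cfg: SpectralConfig = SpectralConfig()
                     ) -> dict[str, float]:
    """Welch band powers of the resampled tachogram.

    Returns total_power (over the full VLF-to-HF range), vlf, lf, hf in s^2,
    the normalized powers nlf/nhf (percent of LF+HF), and the LF/HF ratio.

    Raises
    ------
    ValueError
        If less than 60 s of normal intervals is available.
    ZeroPowerError
        If LF+HF (or HF alone, for the ratio) is zero, leaving the
        normalized powers undefined.
    """
    t_nn = nn.normal_times
    if t_nn.size < 4 or (t_nn[-1] - t_nn[0]) < 60.0:
        raise ValueError("need at least 60 s of normal intervals")
    t, y = resample_tachogram(nn, cfg.resample_rate)
    nperseg = min(y.size, int(round(cfg.window_length * cfg.resample_rate)))
    noverlap = int(round(cfg.overlap * nperseg))
    f, psd = sps.welch(y, fs=cfg.resample_rate, window="hann",
                       nperseg=nperseg, noverlap=noverlap, detrend="constant")
    vlf = _band_power(f, psd, cfg.vlf_band)
    lf = _band_power(f, psd, cfg.lf_band)
    hf = _band_power(f, psd, cfg.hf_band)
    total = _band_power(f, psd, (cfg.vlf_band[0], cfg.hf_band[1]))
    # powers below this are numerical residue of a constant tachogram (s^2)
    zero_tol = 1e-20
    if lf + hf <= zero_tol or hf <= zero_tol:
        raise ZeroPowerError("LF+HF power is zero; normalized powers undefined")
    nlf = 100.0 * lf / (lf + hf)
    return {
        "total_power": total,
        "vlf": vlf,
        "lf": lf,
        "hf": hf,
        "nlf": nlf,
        "nhf": 100.0 - nlf,
        "lf_hf": lf / hf,
    }


def compute_all(nn: RRSeries,
                spectral_cfg: SpectralConfig = SpectralConfig(),
                histogram_cfg: HistogramConfig = HistogramConfig()
                ) -> HRVParams:
    """All 16 parameters from a labelled series (normal intervals only).

    If the spectrum is undefined (constant tachogram, zero band power) the
    spectral fields are NaN and ``spectral_defined`` is False rather than
    failing the whole computation.
    """
    params = time_domain(nn)
    params.tri_index, params.tinn = geometric_metrics(nn, histogram_cfg)
    try:
        spec = spectral_metrics(nn, spectral_cfg)
    except ZeroPowerError:
        params.spectral_defined = False
        return params
    for name, value in spec.items():
        setattr(params, name, value)
    return params
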