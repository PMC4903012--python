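"""Single-lead ECG signal chain: I/O, filtering, QRS detection, NN labelling.

The chain mirrors how short-term HRV is obtained from routine monitoring ECG:
a 6-minute lead-II segment is band-pass filtered (5-28 Hz) to suppress baseline
wander and T waves, QRS complexes are found with an amplitude-adaptive
squared-derivative detector, R-to-R intervals are labelled normal / ectopic by
a local-median ratio rule, and a recording is eligible for HRV analysis only
when at most 30 % of its intervals are abnormal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "ECGRecord",
    "BeatSequence",
    "RRSeries",
    "EligibilityReport",
    "NoQRSError",
    "read_ecg",
    "write_ecg_csv",
    "select_segment",
    "bandpass",
    "detect_qrs",
    "to_rr",
    "label_beats",
    "eligibility",
]

NORMAL = "normal"
ECTOPIC = "ectopic"
ARTIFACT = "artifact"

#: fraction of abnormal intervals above which a recording is excluded
MAX_ABNORMAL_FRACTION = 0.30


class NoQRSError(ValueError):
    """Raised when no QRS complex can be found (flat or pure-noise input)."""


@dataclass
class ECGRecord:
    """A uniformly sampled single-lead voltage trace.

    Parameters
    ----------
    sampling_rate : float
        Sampling frequency in Hz (> 0).
    samples : ndarray
        Voltages in millivolt.
    lead_label : str
        Lead name, e.g. ``"II"``.
    t0 : float
        Time offset of the first sample, seconds.
    true_beat_times : ndarray, optional
        Ground-truth R-peak times carried along by the simulator; ``None``
        for real recordings.
    """

    sampling_rate: float
    samples: np.ndarray
    lead_label: str = "II"
    t0: float = 0.0
    true_beat_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (n / fs)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class BeatSequence:
    """Detected R-peak sample indices (strictly increasing)."""

    beat_indices: np.ndarray
    sampling_rate: float
    n_samples: int | None = None

    def __post_init__(self) -> None:
        self.beat_indices = np.asarray(self.beat_indices, dtype=int)
        if np.any(np.diff(self.beat_indices) <= 0):
            raise ValueError("beat indices must be strictly increasing")
        if self.beat_indices.size and self.beat_indices[0] < 0:
            raise ValueError("beat indices must be non-negative")
        if self.n_samples is not None and self.beat_indices.size and (
            self.beat_indices[-1] >= self.n_samples
        ):
            raise ValueError("beat index beyond record length")

    @property
    def beat_times(self) -> np.ndarray:
        return self.beat_indices / self.sampling_rate


@dataclass
class RRSeries:
    """Beat times with derived inter-beat intervals and per-interval labels.

    ``intervals[i] = beat_times[i+1] - beat_times[i]``; each interval is
    attributed to its later beat. Labels are one of ``normal`` / ``ectopic``
    / ``artifact``.
    """

    beat_times: np.ndarray
    intervals: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size < 2:
            raise ValueError("an RR series needs at least 2 beats")
        if self.intervals is None:
            self.intervals = np.diff(self.beat_times)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.labels is None:
            self.labels = np.full(self.intervals.size, NORMAL, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive (beat times increasing)")
        if self.labels.size != self.intervals.size:
            raise ValueError("labels length must equal intervals length")

    @classmethod
    def from_beat_times(cls, beat_times) -> "RRSeries":
        return cls(beat_times=np.asarray(beat_times, dtype=float))

    @property
    def n_intervals(self) -> int:
        return self.intervals.size

    @property
    def normal_mask(self) -> np.ndarray:
        return self.labels == NORMAL

    @property
    def normal_intervals(self) -> np.ndarray:
        """NN intervals: intervals labelled normal, in seconds."""
        return self.intervals[self.normal_mask]

    @property
    def normal_times(self) -> np.ndarray:
        """Times (of the later beat) of normal intervals."""
        return self.beat_times[1:][self.normal_mask]

    def copy(self) -> "RRSeries":
        return RRSeries(
            beat_times=self.beat_times.copy(),
            intervals=self.intervals.copy(),
            labels=self.labels.copy(),
        )


@dataclass(frozen=True)
class EligibilityReport:
    """Outcome of the >30 %-abnormal exclusion rule."""

    fraction_abnormal: float
    eligible: bool
    n_beats: int


# ---------------------------------------------------------------------------
# I/O


def read_ecg(path, format: str = "csv", sampling_rate: float | None = None,
             lead_label: str = "II") -> ECGRecord:
    """Read a single-lead ECG from a two-column CSV or a WFDB record.

    CSV layout is ``time_s,mv`` (an optional single header line is skipped);
    a one-column CSV of voltages requires an explicit ``sampling_rate``.
    The time column must be a uniform grid within 1 % relative tolerance.

    For ``format="wfdb"`` pass the path of the ``.hea`` header (or the record
    name without extension); only single-segment format-16 records are
    supported, and the first signal channel is returned.
    """
    if format == "csv":
        return _read_csv(path, sampling_rate, lead_label)
    if format == "wfdb":
        return _read_wfdb(path, lead_label)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path, sampling_rate, lead_label) -> ECGRecord:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        data = np.genfromtxt(path, delimiter=",", skip_header=0)
    except Exception as exc:  # pragma: no cover - unreadable file
        raise ValueError(f"unreadable CSV file {path}: {exc}") from exc
    if data.ndim == 1:
        data = data[:, None]
    if np.isnan(data[0]).any():  # header line
        data = data[1:]
    if data.shape[0] < 2:
        raise ValueError("CSV must contain at least 2 samples")
    if data.shape[1] == 1:
        if sampling_rate is None:
            raise ValueError("single-column CSV requires an explicit sampling_rate")
        return ECGRecord(sampling_rate, data[:, 0], lead_label)
    t, mv = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("non-uniform sampling: time column not increasing")
    dt0 = np.median(dt)
    if np.any(np.abs(dt - dt0) > 0.01 * dt0):
        raise ValueError("non-uniform sampling: time grid deviates by more than 1 %")
    fs = 1.0 / dt0
    if sampling_rate is not None and abs(fs - sampling_rate) > 0.01 * sampling_rate:
        raise ValueError(
            f"time column implies fs={fs:.3f} Hz, conflicting with "
            f"sampling_rate={sampling_rate}"
        )
    return ECGRecord(fs, mv, lead_label, t0=float(t[0]))


def _read_wfdb(path, lead_label) -> ECGRecord:
    """Minimal WFDB reader: single-segment header + format-16 .dat."""
    path = str(path)
    hea = path if path.endswith(".hea") else path + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(hea)
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    nsig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    sig_line = lines[1].split()
    dat_file, fmt = sig_line[0], sig_line[1].split("x")[0].split(":")[0]
    if fmt != "16":
        raise ValueError(f"unsupported WFDB signal format {fmt!r} (only 16)")
    gain = 200.0
    if len(sig_line) > 2:
        g = sig_line[2].split("(")[0].split("/")[0]
        gain = float(g) if float(g) != 0 else 200.0
    baseline = 0.0
    if len(sig_line) > 2 and "(" in sig_line[2]:
        baseline = float(sig_line[2].split("(")[1].split(")")[0])
    raw = np.fromfile(os.path.join(os.path.dirname(hea), dat_file), dtype="<i2")
    sig = raw.reshape(-1, nsig)[:, 0].astype(float)
    return ECGRecord(fs, (sig - baseline) / gain, lead_label)


def write_ecg_csv(ecg: ECGRecord, path) -> None:
    """Write a record as ``time_s,mv`` CSV (header included)."""
    arr = np.column_stack([ecg.times, ecg.samples])
    np.savetxt(path, arr, delimiter=",", header="time_s,mv", comments="",
               fmt="%.9g")


# ---------------------------------------------------------------------------
# Segmenting & filtering


def select_segment(ecg: ECGRecord, start: float, duration: float = 360.0) -> ECGRecord:
    """Extract ``round(duration * fs)`` samples beginning at ``start`` seconds."""
    if duration <= 0:
        raise ValueError("empty segment: duration must be positive")
    if start < 0:
        raise ValueError("start must be non-negative")
    fs = ecg.sampling_rate
    i0 = int(round(start * fs))
    n = int(round(duration * fs))
    if i0 >= ecg.n_samples:
        raise ValueError("segment start beyond end of record")
    if i0 + n > ecg.n_samples:
        raise ValueError("segment exceeds record length")
    return ECGRecord(fs, ecg.samples[i0:i0 + n].copy(), ecg.lead_label,
                     t0=ecg.t0 + i0 / fs)


def bandpass(ecg: ECGRecord, low: float = 5.0, high: float = 28.0,
             order: int = 4) -> ECGRecord:
    """Zero-phase Butterworth band-pass (default 5-28 Hz).

    Applied forward-backward so R-peak timing is not shifted; the stop band
    removes baseline wander (< ~0.5 Hz) and mains/muscle noise above the QRS
    band, and the output has (numerically) zero mean.
    """
    fs = ecg.sampling_rate
    if not 0 < low < high < fs / 2:
        raise ValueError(
            f"band edges ({low}, {high}) invalid for sampling rate {fs} Hz"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, ecg.samples)
    return ECGRecord(fs, out, ecg.lead_label, t0=ecg.t0,
                     true_beat_times=ecg.true_beat_times)


# ---------------------------------------------------------------------------
# QRS detection


def detect_qrs(filtered: ECGRecord, *, smooth_window: float = 0.12,
               threshold_frac: float = 0.4, percentile: float = 95.0,
               block_duration: float = 10.0, refractory: float = 0.25,
               refine_window: float = 0.1) -> BeatSequence:
    """Find R peaks in a band-pass-filtered trace.

    The detection function is the squared first derivative smoothed by a
    ``smooth_window``-second moving average. The threshold adapts to the
    signal: within consecutive ``block_duration``-second blocks it is
    ``threshold_frac`` times the block's ``percentile``-th percentile of the
    detection function, which makes detection invariant to any positive
    rescaling of the waveform. Peaks closer than ``refractory`` seconds are
    merged (larger peak wins), and each peak is refined to the local maximum
    of the filtered waveform within ``±refine_window`` seconds.
    """
    fs = filtered.sampling_rate
    x = filtered.samples
    if filtered.duration < 10.0:
        raise ValueError("detect_qrs requires at least 10 s of signal")

    deriv = np.gradient(x) * fs
    energy = deriv * deriv
    win = max(1, int(round(smooth_window * fs)))
    det = np.convolve(energy, np.ones(win) / win, mode="same")

    if det.max() <= 0:
        raise NoQRSError("no QRS found")

    # blockwise adaptive threshold
    blk = max(1, int(round(block_duration * fs)))
    thr = np.empty_like(det)
    for i0 in range(0, det.size, blk):
        seg = det[i0:i0 + blk]
        thr[i0:i0 + blk] = threshold_frac * np.percentile(seg, percentile)

    dist = max(1, int(round(refractory * fs)))
    peaks, _ = sps.find_peaks(det, distance=dist)
    peaks = peaks[det[peaks] > thr[peaks]]
    if peaks.size == 0:
        raise NoQRSError("no QRS found")

    # refine to the local maximum of the filtered waveform
    half = max(1, int(round(refine_window * fs)))
    refined = np.empty(peaks.size, dtype=int)
    for j, p in enumerate(peaks):
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined[j] = lo + int(np.argmax(x[lo:hi]))

    # dedupe after refinement, enforcing the refractory period
    order = np.argsort(refined, kind="stable")
    refined = refined[order]
    kept: list[int] = []
    for p in refined:
        if kept and p - kept[-1] < dist:
            if x[p] > x[kept[-1]]:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    return BeatSequence(np.array(kept, dtype=int), fs, n_samples=x.size)


# ---------------------------------------------------------------------------
# RR series


def to_rr(beats: BeatSequence) -> RRSeries:
    """Convert detected beats to an R-to-R interval series (labels ``normal``)."""
    if beats.beat_indices.size < 2:
        raise ValueError("need at least 2 beats to form RR intervals")
    return RRSeries.from_beat_times(beats.beat_times)


def label_beats(rr: RRSeries, ratio_low: float = 0.75,
                ratio_high: float = 1.25, n_neighbors: int = 5) -> RRSeries:
    """Label ectopic/artifact intervals by a local-median ratio rule.

    An interval is abnormal when it falls outside
    ``[ratio_low, ratio_high] x median`` of its ``n_neighbors`` nearest
    intervals (the interval itself excluded). Degenerate series with fewer
    than 3 intervals are returned unchanged. This replaces the manual noise
    editing a human operator would perform on real recordings.
    """
    out = rr.copy()
    n = out.n_intervals
    if n < 3:
        return out
    iv = out.intervals
    for i in range(n):
        # nearest neighbours by index distance, symmetric around i
        lo, hi = i - 1, i + 1
        neigh: list[float] = []
        while len(neigh) < n_neighbors and (lo >= 0 or hi < n):
            if lo >= 0:
                neigh.append(iv[lo])
                lo -= 1
            if len(neigh) < n_neighbors and hi < n:
                neigh.append(iv[hi])
                hi += 1
        med = float(np.median(neigh))
        if not (ratio_low * med <= iv[i] <= ratio_high * med):
            out.labels[i] = ECTOPIC
    return out


def eligibility(rr: RRSeries) -> EligibilityReport:
    """Apply the >30 %-abnormal exclusion rule (exactly 30 % stays eligible)."""
    n = rr.n_intervals
    if n == 0:
        raise ValueError("empty RR series")
    frac = float(np.count_nonzero(~rr.normal_mask)) / n
    return EligibilityReport(
        fraction_abnormal=frac,
        eligible=bool(frac <= MAX_ABNORMAL_FRACTION + 1e-12),
        n_beats=n + 1,
    )
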