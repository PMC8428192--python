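"""Traditional time- and frequency-domain HRV over non-overlapping 5-min windows.

The NN series is partitioned into tumbling 300-s wall-clock windows anchored
at sleep onset.  Windows that are too sparse (fewer than 150 NN intervals)
or too gappy (NN intervals covering less than 75% of the window) are
excluded.  Within each qualified window we compute:

* AVNN  — mean NN interval (ms)
* SDNN  — sample standard deviation of NN intervals (ms)
* rMSSD — root mean square of successive NN differences, within runs only (ms)
* HF    — spectral power of the NN series in 0.15–0.4 Hz (ms²), from the
  Lomb periodogram of the unevenly sampled beat-time-indexed series,
  normalized so the full-spectrum integral equals the series variance.

Per subject, window values are averaged (each index separately, in its
linear units) and natural-log transforms of the aggregated rMSSD, SDNN and
HF are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from .nn_io import NNSeries

__all__ = [
    "HRVWindow",
    "HRVResult",
    "WINDOW_SECONDS",
    "HF_BAND",
    "partition_windows",
    "qualify_window",
    "window_time_domain",
    "window_hf_power",
    "compute_hrv",
]

WINDOW_SECONDS = 300.0
HF_BAND = (0.15, 0.40)
MIN_BEATS_PER_WINDOW = 150
MIN_NN_FRACTION = 0.75
MIN_POINTS_FOR_SPECTRUM = 16
LOMB_OVERSAMPLE = 4


@dataclass
class HRVWindow:
    """One 5-min analysis window of the NN series."""

    start_s: float
    end_s: float
    intervals: np.ndarray  # ms
    end_times: np.ndarray  # s
    run_id: np.ndarray
    qualified: bool = False

    @property
    def n_beats(self) -> int:
        """Number of NN intervals whose terminating beat falls in the window."""
        return int(self.intervals.size)

    @property
    def fraction_nn(self) -> float:
        """Fraction of window time covered by NN intervals."""
        return float(np.sum(self.intervals) / 1000.0 / (self.end_s - self.start_s))

    def run_slices(self) -> list[slice]:
        if self.intervals.size == 0:
            return []
        bounds = np.flatnonzero(np.diff(self.run_id)) + 1
        edges = [0, *bounds.tolist(), self.intervals.size]
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class HRVResult:
    """Subject-level HRV indices averaged over qualified windows."""

    avnn_ms: float
    sdnn_ms: float
    rmssd_ms: float
    hf_ms2: float
    ln_rmssd: float
    ln_sdnn: float
    ln_hf: float
    n_windows_qualified: int

    def to_dict(self) -> dict:
        return {
            "avnn_ms": self.avnn_ms,
            "sdnn_ms": self.sdnn_ms,
            "rmssd_ms": self.rmssd_ms,
            "hf_ms2": self.hf_ms2,
            "ln_rmssd": self.ln_rmssd,
            "ln_sdnn": self.ln_sdnn,
            "ln_hf": self.ln_hf,
            "n_windows_qualified": self.n_windows_qualified,
        }


def partition_windows(nn: NNSeries) -> list[HRVWindow]:
    """Partition the series into tumbling 300-s windows from sleep onset.

    An interval belongs to the window containing its terminating beat time
    (half-open [start, start+300)); a trailing partial window is discarded.
    """
    t0 = nn.start_s
    t_last = nn.termination_s if nn.termination_s is not None else float(nn.end_times[-1])
    n_win = int(np.floor((t_last - t0) / WINDOW_SECONDS))
    windows: list[HRVWindow] = []
    for k in range(n_win):
        lo = t0 + k * WINDOW_SECONDS
        hi = lo + WINDOW_SECONDS
        mask = (nn.end_times >= lo) & (nn.end_times < hi)
        w = HRVWindow(
            start_s=lo,
            end_s=hi,
            intervals=nn.intervals[mask],
            end_times=nn.end_times[mask],
            run_id=nn.run_id[mask],
        )
        w.qualified = qualify_window(w)
        windows.append(w)
    return windows


def qualify_window(w: HRVWindow) -> bool:
    """Exclude windows with < 150 NN intervals or < 75% NN coverage."""
    return w.n_beats >= MIN_BEATS_PER_WINDOW and w.fraction_nn >= MIN_NN_FRACTION


def window_time_domain(w: HRVWindow) -> tuple[float, float, float]:
    """(mean NN, sample SD, rMSSD) of a window, in ms.

    rMSSD uses successive differences within contiguous runs only.  With
    fewer than 2 intervals (or no within-run pair) the affected statistics
    are NaN.
    """
    x = w.intervals
    if x.size < 2:
        return (float(np.mean(x)) if x.size else float("nan"), float("nan"), float("nan"))
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    sq = [np.diff(x[sl]) ** 2 for sl in w.run_slices() if sl.stop - sl.start >= 2]
    if sq:
        d2 = np.concatenate(sq)
        rmssd = float(np.sqrt(np.mean(d2)))
    else:
        rmssd = float("nan")
    return mean, sd, rmssd


def window_hf_power(
    w: HRVWindow, band: tuple[float, float] = HF_BAND
) -> float:
    """High-frequency spectral power (ms²) of a window's NN series.

    The Lomb periodogram of the mean-subtracted NN values at their
    (unevenly spaced) terminating beat times is evaluated on a grid from
    1/300 Hz to half the mean beat rate with 4x oversampling, converted to
    a power spectral density with the 2T/N factor (calibrated so the
    full-spectrum integral equals the series variance for evenly sampled
    data), and integrated over ``band`` by the trapezoidal rule.
    """
    x = w.intervals
    t = w.end_times
    if x.size < MIN_POINTS_FOR_SPECTRUM:
        return float("nan")
    xc = x - np.mean(x)
    var = float(np.var(xc))
    if var == 0.0:
        return 0.0
    span = t[-1] - t[0]
    df = 1.0 / (LOMB_OVERSAMPLE * max(span, 1.0))
    f_lo = 1.0 / WINDOW_SECONDS
    f_hi = 0.5 * x.size / max(span, 1e-9)  # half the mean beat rate
    if f_hi <= f_lo:
        return float("nan")
    freqs = np.arange(f_lo, f_hi, df)
    pgram = lombscargle(t, xc, 2.0 * np.pi * freqs)
    psd = pgram * 2.0 * span / x.size
    lo, hi = band
    in_band = (freqs >= lo) & (freqs <= hi)
    if not np.any(in_band):
        return 0.0
    return float(np.trapezoid(psd[in_band], freqs[in_band]))


def compute_hrv(nn: NNSeries, band: tuple[float, float] = HF_BAND) -> HRVResult:
    """Subject-level HRV: average each index over qualified 5-min windows.

    All four indices (AVNN, SDNN, rMSSD, HF) are averaged in their linear
    units across qualified windows, then rMSSD, SDNN and HF are
    log-transformed once.  With zero qualified windows every field is NaN.
    """
    windows = [w for w in partition_windows(nn) if w.qualified]
    nan = float("nan")
    if not windows:
        return HRVResult(nan, nan, nan, nan, nan, nan, nan, 0)
    means, sds, rmssds, hfs = [], [], [], []
    for w in windows:
        m, s, r = window_time_domain(w)
        means.append(m)
        sds.append(s)
        rmssds.append(r)
        hfs.append(window_hf_power(w, band))
    avnn = float(np.nanmean(means))
    sdnn = float(np.nanmean(sds))
    rmssd = float(np.nanmean(rmssds))
    hf = float(np.nanmean(hfs))

    def _ln(v: float) -> float:
        return float(np.log(v)) if v > 0 else nan

    return HRVResult(
        avnn_ms=avnn,
        sdnn_ms=sdnn,
        rmssd_ms=rmssd,
        hf_ms2=hf,
        ln_rmssd=_ln(rmssd),
        ln_sdnn=_ln(sdnn),
        ln_hf=_ln(hf),
        n_windows_qualified=len(windows),
    )
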