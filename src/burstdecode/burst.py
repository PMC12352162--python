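"""Detection and representation of high-gamma and beta oscillatory bursts.

A Morlet-wavelet time-frequency transform is computed on detection grids
that deliberately over-cover the bands of interest ([50, 250] Hz for high
gamma, [5, 50] Hz for beta).  Bursts are found by a topographical analysis
of the wavelet power: after per-frequency z-scoring across time, local
maxima above a z threshold seed events, each seed is expanded to its
half-maximum contour in the time-frequency plane, and only events whose
peak frequency falls strictly inside the high-gamma (80-200 Hz) or beta
(15-40 Hz) band are kept.  Each burst is then rendered as a Gaussian kernel

    f(t) = A * exp(-(t - p)**2 / (2 * w**2))

with amplitude ``A`` scaled by the burst's power, center ``p`` at the
midpoint of onset and offset, and width ``w`` equal to the burst duration.
Summing kernels yields one non-negative convolved-burst time series per
channel and band - the rows of the decoder input tensors.

The band-limited burst signal-to-noise estimator used by the explanatory
model lives here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import signal as sps

__all__ = [
    "BurstEvent",
    "HG_DETECT_FREQS",
    "BETA_DETECT_FREQS",
    "STRICT_BANDS",
    "N_CYCLES",
    "wavelet_tfr",
    "detect_bursts",
    "detect_channel",
    "detect_session",
    "convolve_bursts",
    "session_convolved_rows",
    "burst_snr",
    "mean_experiment_snr",
    "bursts_to_frame",
    "frame_to_bursts",
]

# Detection grids over-cover the strict bands so that contour expansion is
# not clipped at the band edge.
HG_DETECT_FREQS = np.arange(50.0, 251.0, 4.0)
BETA_DETECT_FREQS = np.arange(5.0, 51.0, 1.0)
STRICT_BANDS = {"hg": (80.0, 200.0), "beta": (15.0, 40.0)}
#: Morlet cycles per band: more cycles sharpen frequency resolution for the
#: wide high-gamma band, fewer preserve time resolution for beta.
N_CYCLES = {"hg": 7.0, "beta": 5.0}
DETECT_FREQS = {"hg": HG_DETECT_FREQS, "beta": BETA_DETECT_FREQS}
#: time decimation of the power map before detection (block means); the
#: effective resolution (10 ms HG, 20 ms beta) stays well under the wavelet
#: temporal smearing.
DETECT_DECIM = {"hg": 5, "beta": 10}

# FIR orders of the band-limited SNR estimator.
SNR_FIR_ORDER = {"hg": 500, "beta": 100}


@dataclass(frozen=True)
class BurstEvent:
    """One detected oscillatory burst."""

    channel: int
    band: str
    onset_s: float
    offset_s: float
    peak_freq_hz: float
    power: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def __post_init__(self):
        if self.offset_s <= self.onset_s:
            raise ValueError("burst offset must exceed onset")
        if self.power <= 0:
            raise ValueError("burst power must be positive")


def wavelet_tfr(signal: np.ndarray, fs_hz: float, freqs_hz: np.ndarray,
                n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet transform magnitude**2, shape (n_freqs, n_times).

    The convolution with each unit-energy Morlet wavelet (temporal width
    ``sigma_t = n_cycles / (2 pi f)``) is evaluated in the frequency domain:
    one FFT of the signal, then a Gaussian spectral window per analysis
    frequency.  This is algebraically the standard wavelet convolution and
    keeps long recordings cheap.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if n_cycles < 3:
        raise ValueError("n_cycles must be >= 3")
    if freqs_hz.max() >= fs_hz / 2:
        raise ValueError("frequencies must lie below Nyquist")
    x = np.asarray(signal, dtype=np.float64)
    n = x.shape[-1]
    from scipy.fft import next_fast_len

    nfft = next_fast_len(n)
    X = np.fft.fft(x, nfft)
    nu = np.fft.fftfreq(nfft, d=1.0 / fs_hz)
    power = np.empty((len(freqs_hz), n), dtype=np.float64)
    for i, f in enumerate(freqs_hz):
        sigma_t = n_cycles / (2.0 * np.pi * f)
        sigma_f = 1.0 / (2.0 * np.pi * sigma_t)
        H = np.exp(-0.5 * ((nu - f) / sigma_f) ** 2)
        energy = np.sum(H * H) / nfft  # wavelet L2 energy (Parseval)
        H /= np.sqrt(energy)
        y = np.fft.ifft(X * H)[:n]
        power[i] = y.real ** 2 + y.imag ** 2
    return power


def _decimate_time(power: np.ndarray, decim: int) -> np.ndarray:
    if decim <= 1:
        return power
    n = power.shape[1] // decim * decim
    return power[:, :n].reshape(power.shape[0], -1, decim).mean(axis=2)


def detect_bursts(tfr: np.ndarray, freqs_hz: np.ndarray, fs_hz: float,
                  band: str, z_thresh: float = 2.0, channel: int = 0,
                  merge: bool = True) -> list[BurstEvent]:
    """Topographical burst detection on a wavelet power map.

    Per-frequency rows are z-scored across time; connected supra-threshold
    regions seed events at their power maximum, each expanded to the
    half-maximum contour of its seed by flood fill; events whose peak
    frequency leaves the strict band are discarded; overlapping same-band
    events are merged (union of extents, frequency of the strongest seed).
    """
    lo, hi = STRICT_BANDS[band]
    tfr = np.asarray(tfr, dtype=np.float64)
    if tfr.size == 0:
        return []
    mu = tfr.mean(axis=1, keepdims=True)
    sd = tfr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (tfr - mu) / sd

    mask = z >= z_thresh
    if not mask.any():
        return []
    labels, n_comp = ndimage.label(mask)
    objects = ndimage.find_objects(labels)
    n_f, n_t = z.shape
    pad_t = max(int(round(0.25 * fs_hz)), 2)  # room for half-max expansion
    pad_f = 6

    events: list[tuple[float, float, float, float, float]] = []
    for comp_idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = z[sl]
        inside = labels[sl] == comp_idx
        flat = np.where(inside, sub, -np.inf).argmax()
        fi_loc, ti_loc = np.unravel_index(flat, sub.shape)
        fi = sl[0].start + fi_loc
        ti = sl[1].start + ti_loc
        z_seed = z[fi, ti]
        # spectral content: the raw-power peak of the component (the z map
        # over-weights high rows, whose 1/f background variance is tiny)
        flat_p = np.where(inside, tfr[sl], -np.inf).argmax()
        fi_pow = sl[0].start + np.unravel_index(flat_p, sub.shape)[0]
        # expand to the half-maximum contour within a local crop
        f0 = max(sl[0].start - pad_f, 0)
        f1 = min(sl[0].stop + pad_f, n_f)
        t0 = max(sl[1].start - pad_t, 0)
        t1 = min(sl[1].stop + pad_t, n_t)
        crop = z[f0:f1, t0:t1] >= z_seed / 2.0
        lab_crop, _ = ndimage.label(crop)
        comp = lab_crop == lab_crop[fi - f0, ti - t0]
        t_any = comp.any(axis=0)
        tmin = t0 + int(np.argmax(t_any))
        tmax = t0 + len(t_any) - int(np.argmax(t_any[::-1]))  # exclusive
        peak_freq = float(freqs_hz[fi_pow])
        if not (lo <= peak_freq <= hi):
            continue
        power = float(tfr[f0:f1, t0:t1][comp].sum())
        events.append((tmin / fs_hz, tmax / fs_hz, peak_freq, power, float(z_seed)))

    if not events:
        return []
    events.sort(key=lambda e: e[0])
    if merge:
        merged = [list(events[0])]
        for ev in events[1:]:
            cur = merged[-1]
            if ev[0] < cur[1]:  # temporal overlap -> union
                cur[1] = max(cur[1], ev[1])
                cur[3] += ev[3]
                if ev[4] > cur[4]:
                    cur[2], cur[4] = ev[2], ev[4]
            else:
                merged.append(list(ev))
        events = [tuple(e) for e in merged]
    return [BurstEvent(channel=channel, band=band, onset_s=on, offset_s=off,
                       peak_freq_hz=f, power=p)
            for on, off, f, p, _ in events if off > on and p > 0]


def detect_channel(signal: np.ndarray, fs_hz: float, band: str,
                   z_thresh: float = 2.0, channel: int = 0,
                   decim: int | None = None) -> list[BurstEvent]:
    """Detect one band's bursts in a single-channel recording."""
    freqs = DETECT_FREQS[band]
    freqs = freqs[freqs < fs_hz / 2]  # grid may touch Nyquist at 500 Hz
    power = wavelet_tfr(signal, fs_hz, freqs, N_CYCLES[band])
    d = DETECT_DECIM[band] if decim is None else decim
    power = _decimate_time(power, d)
    return detect_bursts(power, freqs, fs_hz / d, band, z_thresh=z_thresh,
                         channel=channel)


def detect_session(signal: np.ndarray, fs_hz: float,
                   bands: tuple[str, ...] = ("hg", "beta"),
                   z_thresh: float = 2.0) -> pd.DataFrame:
    """Detect bursts on every channel of a (channels x samples) recording."""
    events: list[BurstEvent] = []
    for ch in range(signal.shape[0]):
        for band in bands:
            events.extend(detect_channel(signal[ch], fs_hz, band,
                                         z_thresh=z_thresh, channel=ch))
    return bursts_to_frame(events)


def bursts_to_frame(bursts: list[BurstEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.channel, b.band, b.onset_s, b.offset_s, b.peak_freq_hz, b.power)
         for b in bursts],
        columns=["channel", "band", "onset_s", "offset_s", "peak_freq_hz", "power"])


def frame_to_bursts(frame: pd.DataFrame) -> list[BurstEvent]:
    return [BurstEvent(int(r.channel), str(r.band), float(r.onset_s),
                       float(r.offset_s), float(r.peak_freq_hz), float(r.power))
            for r in frame.itertuples(index=False)]


def convolve_bursts(bursts, n_samples: int, fs_hz: float,
                    power_norm: str | float = "median",
                    width_scale: float = 1.0) -> np.ndarray:
    """Sum of Gaussian kernels, one per burst, sampled at ``fs_hz``.

    Amplitude A = burst power / median power of the burst set (default), the
    center p is the onset/offset midpoint and the width w the burst duration
    (times ``width_scale``).  Overlapping kernels add.  Kernels are evaluated
    out to where their tail drops below 1e-13 * A, so the result matches the
    full analytic sum to well under 1e-9.
    """
    out = np.zeros(n_samples, dtype=np.float64)
    if isinstance(bursts, pd.DataFrame):
        bursts = frame_to_bursts(bursts)
    if not bursts:
        return out
    powers = np.array([b.power for b in bursts])
    if power_norm == "median":
        norm = float(np.median(powers)) or 1.0
    elif power_norm in (None, "none"):
        norm = 1.0
    else:
        norm = float(power_norm)
    t_axis = np.arange(n_samples) / fs_hz
    for b, pw in zip(bursts, powers):
        A = pw / norm
        p = 0.5 * (b.onset_s + b.offset_s)
        w = b.duration_s * width_scale
        radius = w * np.sqrt(2.0 * np.log(max(A, 1e-300) / 1e-13))
        i0 = max(int(np.floor((p - radius) * fs_hz)), 0)
        i1 = min(int(np.ceil((p + radius) * fs_hz)) + 1, n_samples)
        if i1 <= i0:
            continue
        t = t_axis[i0:i1]
        out[i0:i1] += A * np.exp(-((t - p) ** 2) / (2.0 * w * w))
    return out


def session_convolved_rows(bursts: pd.DataFrame, n_channels: int,
                           n_samples: int, fs_hz: float,
                           width_scale: float = 1.0) -> np.ndarray:
    """Stack per-contact convolved series into the 2-D row layout used by the
    decoders: for contact c, row 2c is its high-gamma series and row 2c+1 its
    beta series (contact-major, HG before beta)."""
    rows = np.zeros((2 * n_channels, n_samples), dtype=np.float64)
    for ch in range(n_channels):
        for bi, band in enumerate(("hg", "beta")):
            sel = bursts[(bursts.channel == ch) & (bursts.band == band)]
            rows[2 * ch + bi] = convolve_bursts(sel, n_samples, fs_hz,
                                                width_scale=width_scale)
    return rows


def burst_snr(signal_uv: np.ndarray, fs_hz: float, band: str,
              z_thresh: float = 2.0) -> float:
    """Band-limited burst signal-to-noise ratio of one contact.

    The signal is band-passed with a symmetric FIR filter (order 500 for
    high gamma, 100 for beta), zero-phase.  Noise is estimated as the RMS of
    the filtered trace.  Candidate burst peaks are local maxima of the
    absolute filtered trace whose amplitude exceeds ``z_thresh`` times the
    RMS; the signal estimate is the 95th percentile of those peak
    amplitudes, and the SNR their ratio.  When no peak clears the threshold
    (e.g. a burst-free narrowband signal) all local maxima are used.
    """
    x = np.asarray(signal_uv, dtype=np.float64)
    if not np.any(x):
        raise ValueError("signal is identically zero; SNR undefined")
    band_edges = STRICT_BANDS[band]
    numtaps = SNR_FIR_ORDER[band] + 1
    taps = sps.firwin(numtaps, band_edges, pass_zero=False, fs=fs_hz)
    filt = sps.filtfilt(taps, [1.0], x)
    noise = float(np.sqrt(np.mean(filt ** 2)))
    if noise == 0:
        raise ValueError("filtered signal has zero RMS; SNR undefined")
    absx = np.abs(filt)
    peaks, _ = sps.find_peaks(absx)
    if peaks.size == 0:
        raise ValueError("no peaks in the filtered signal")
    heights = absx[peaks]
    strong = heights[heights >= z_thresh * noise]
    if strong.size == 0:
        strong = heights
    sig = float(np.percentile(strong, 95))
    return sig / noise


def mean_experiment_snr(hg_snrs, beta_snrs) -> tuple[float, float]:
    """Average per-contact burst SNRs across all contacts of an experiment."""
    hg = np.asarray(list(hg_snrs), dtype=float)
    beta = np.asarray(list(beta_snrs), dtype=float)
    if hg.size == 0 or beta.size == 0:
        raise ValueError("need at least one channel per band")
    return float(hg.mean()), float(beta.mean())
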