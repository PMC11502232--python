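"""LFP band-limited event detection, nonrhythmic epochs, and multitaper PSD.

Oscillation events are detected on the band-pass filtered, rectified and
smoothed signal: candidate events exceed the noise mean by ``detect_sd``
standard deviations for at least ``min_event_ms``; their boundaries are then
extended outward to where the envelope falls below ``edge_sd`` SD, and
overlapping extended events are merged. Nonrhythmic epochs are times when no
band's envelope exceeds 0.5 SD above its noise mean.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .datatypes import EpochSet, LfpSignal, ValidationError

#: Default bands (Hz) whose quiescence defines a nonrhythmic epoch: delta,
#: theta, beta, the two gamma event bands, upper gamma, and fast oscillations.
NONRHYTHMIC_BANDS_HZ = (
    (2.0, 4.0),
    (5.0, 10.0),
    (15.0, 30.0),
    (30.0, 60.0),
    (61.0, 90.0),
    (90.0, 120.0),
    (120.0, 200.0),
)


def downsample_wideband(samples: np.ndarray, fs_in: float, fs_out: float = 1250.0,
                        session_id: str = "") -> LfpSignal:
    """Anti-alias low-pass at 0.4*fs_out, then resample to fs_out."""
    if fs_in < fs_out:
        raise ValidationError(f"fs_in {fs_in} < fs_out {fs_out}")
    x = np.asarray(samples, dtype=float)
    if fs_in == fs_out:
        return LfpSignal(samples=x.copy(), fs_hz=fs_out, session_id=session_id)
    sos = sps.butter(8, 0.4 * fs_out, btype="low", fs=fs_in, output="sos")
    y = sps.sosfiltfilt(sos, x)
    t_out = np.arange(int(np.floor(x.size * fs_out / fs_in))) / fs_out
    t_in = np.arange(x.size) / fs_in
    out = np.interp(t_out, t_in, y)
    return LfpSignal(samples=out, fs_hz=fs_out, session_id=session_id)


def band_envelope(lfp: LfpSignal, band_hz: tuple, smooth_sd_ms: float = 10.0) -> tuple:
    """Band-pass (zero-phase), rectify, Gaussian-smooth; return envelope + stats.

    The noise statistics are the whole-session mean and SD of the rectified
    band-passed signal (single pass, before smoothing); the smoothed trace is
    what detection thresholds are compared against. Taking the amplitude
    scale from the unsmoothed rectified signal keeps the threshold's meaning
    independent of the smoothing width: the smoothing only stabilizes the
    run structure of threshold crossings.
    """
    lo, hi = band_hz
    nyq = lfp.fs_hz / 2
    if not 0 < lo < hi < nyq:
        raise ValidationError(f"band {band_hz} invalid for fs {lfp.fs_hz}")
    if np.ptp(lfp.samples) == 0:
        raise ValidationError("zero-variance signal: envelope statistics degenerate")
    sos = sps.butter(4, [lo, hi], btype="band", fs=lfp.fs_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, lfp.samples)
    rect = np.abs(filtered)
    stats = {"mean": float(rect.mean()), "sd": float(rect.std())}
    sd_samples = smooth_sd_ms / 1000.0 * lfp.fs_hz
    env = gaussian_filter1d(rect, sd_samples) if sd_samples > 0 else rect
    return env, stats


def _runs(mask: np.ndarray) -> np.ndarray:
    """Start/stop sample indices (half-open) of True runs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.empty((0, 2), dtype=int)
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate([[0], starts])
    if m[-1]:
        stops = np.concatenate([stops, [m.size]])
    return np.column_stack([starts, stops])


def _merge(intervals: np.ndarray) -> np.ndarray:
    if len(intervals) == 0:
        return intervals
    iv = intervals[np.argsort(intervals[:, 0])]
    out = [iv[0].astype(float).copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e], dtype=float))
    return np.array(out)


def detect_events(
    envelope: np.ndarray,
    noise_stats: dict,
    fs_hz: float,
    detect_sd: float = 2.0,
    edge_sd: float = 1.0,
    min_event_ms: float = 25.0,
    label: str = "event",
    session_id: str = "",
) -> EpochSet:
    """Envelope-threshold event detection.

    Candidates are maximal runs above mean + detect_sd*SD lasting at least
    min_event_ms; each is extended outward to the mean + edge_sd*SD crossings,
    and overlapping extended events are merged.
    """
    env = np.asarray(envelope, dtype=float)
    mu, sd = noise_stats["mean"], noise_stats["sd"]
    hi_thr = mu + detect_sd * sd
    lo_thr = mu + edge_sd * sd
    min_samples = int(np.ceil(min_event_ms / 1000.0 * fs_hz))
    above_lo = env >= lo_thr
    candidates = _runs(env > hi_thr)
    keep = candidates[(candidates[:, 1] - candidates[:, 0]) >= min_samples]
    extended = []
    lo_runs = _runs(above_lo)
    if len(keep) and len(lo_runs):
        # each candidate lies inside exactly one above-lo run; extend to it
        idx = np.searchsorted(lo_runs[:, 0], keep[:, 0], side="right") - 1
        for (s, e), j in zip(keep, idx):
            extended.append([lo_runs[j, 0], max(e, lo_runs[j, 1])])
    intervals = _merge(np.array(extended, dtype=float)) if extended else np.empty((0, 2))
    return EpochSet(
        label=label,
        intervals=intervals / fs_hz,
        session_id=session_id,
        params={
            "detect_sd": detect_sd,
            "edge_sd": edge_sd,
            "min_event_ms": min_event_ms,
            "noise_mean": mu,
            "noise_sd": sd,
        },
    )


def detect_band_events(
    lfp: LfpSignal,
    band_hz: tuple,
    detect_sd: float = 2.0,
    edge_sd: float = 1.0,
    min_event_ms: float = 25.0,
    smooth_sd_ms: float = 10.0,
    label: str | None = None,
) -> EpochSet:
    """Convenience: envelope + detection for one band of an LfpSignal."""
    env, stats = band_envelope(lfp, band_hz, smooth_sd_ms)
    if label is None:
        label = f"band_{band_hz[0]:g}_{band_hz[1]:g}"
    es = detect_events(env, stats, lfp.fs_hz, detect_sd, edge_sd, min_event_ms,
                       label=label, session_id=lfp.session_id)
    es.params["band_hz"] = tuple(band_hz)
    return es


def detect_nonrhythmic(
    lfp: LfpSignal,
    band_list: tuple = NONRHYTHMIC_BANDS_HZ,
    thresh_sd: float = 0.5,
    min_epoch_ms: float = 100.0,
    smooth_sd_ms: float = 10.0,
) -> EpochSet:
    """Epochs during which every band's envelope stays below mean + 0.5 SD."""
    nyq = lfp.fs_hz / 2
    quiet = np.ones(lfp.samples.size, dtype=bool)
    for band in band_list:
        if band[1] >= nyq:
            raise ValidationError(f"band {band} above Nyquist ({nyq} Hz)")
        env, stats = band_envelope(lfp, band, smooth_sd_ms)
        quiet &= env < stats["mean"] + thresh_sd * stats["sd"]
    min_samples = int(np.ceil(min_epoch_ms / 1000.0 * lfp.fs_hz))
    runs = _runs(quiet)
    runs = runs[(runs[:, 1] - runs[:, 0]) >= min_samples]
    return EpochSet(
        label="nonrhythmic",
        intervals=runs.astype(float) / lfp.fs_hz,
        session_id=lfp.session_id,
        params={"thresh_sd": thresh_sd, "min_epoch_ms": min_epoch_ms,
                "bands_hz": tuple(tuple(b) for b in band_list)},
    )


def multitaper_psd(samples: np.ndarray, fs_hz: float, nw: float = 3.0,
                   window: int = 1024) -> dict:
    """Multitaper power spectral density (Slepian tapers, averaged windows).

    Uses 2*NW - 1 DPSS tapers on sliding half-overlapping windows; tapered
    periodograms are averaged across tapers and windows. Power is a density
    per Hz (one-sided).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < window:
        raise ValidationError(f"signal length {x.size} < window {window}")
    n_tapers = int(2 * nw - 1)
    tapers = sps.windows.dpss(window, nw, Kmax=n_tapers)  # rows unit-norm
    step = window // 2
    n_win = 1 + (x.size - window) // step
    freqs = np.fft.rfftfreq(window, d=1.0 / fs_hz)
    acc = np.zeros(freqs.size)
    for w in range(n_win):
        seg = x[w * step: w * step + window]
        seg = seg - seg.mean()
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        p = (np.abs(spec) ** 2).mean(axis=0)
        acc += p
    psd = acc / n_win / fs_hz
    # one-sided: double interior bins
    psd[1:-1 if window % 2 == 0 else None] *= 2
    return {"freqs": freqs, "power": psd}
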