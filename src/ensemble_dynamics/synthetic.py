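"""Synthetic multi-session recordings with known ground truth.

Emulates the study conditions every analysis stage assumes: scored behavioral
episodes with lognormal durations (feeding bouts much longer than social or
object episodes), spike trains from seven planted population templates (four
feeding-phase bumps at ordered phase centers plus feeding-, social- and
object-homogeneous elevations), pink-noise LFP with planted band-limited
oscillation bursts, and cell pairs whose cofiring is selectively elevated
inside chosen epochs. All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .datatypes import (
    BEHAVIORS,
    MIN_FEEDING_S,
    Cell,
    EpochSet,
    Episode,
    Ethogram,
    LfpSignal,
    SpikeDataset,
    ValidationError,
)
from .io import derive_rng

#: Median episode durations (s). Feeding bouts in the emulated recordings are
#: roughly six times longer than social or object episodes.
FEEDING_MEDIAN_S = 22.0
OTHER_MEDIAN_S = 4.0
#: Lognormal shape (SD of log-duration); moderate spread around the median.
DURATION_SIGMA = 0.5
#: Unscored gap between consecutive episodes (uniform range, s).
GAP_RANGE_S = (8.0, 20.0)

#: Default rate multiplier at the peak of a template's tuning (the within-
#: population modulation depth; a free simulation choice).
PEAK_MULTIPLIER = 3.0
#: Phase-bump centers for the four feeding-phase populations, and their width.
BUMP_CENTERS = {"FOn": 0.05, "EF": 0.30, "LF": 0.70, "FOff": 0.95}
BUMP_WIDTH = 0.1

#: Baseline rates (Hz) guided by the reported per-population averages.
DEFAULT_BASELINES = {
    "FOn": 3.2, "EF": 2.6, "LF": 1.7, "FOff": 1.9,
    "Fd": 2.7, "Sol": 2.6, "Exp": 3.5,
}


@dataclass
class PopulationTemplate:
    """Rate model of one planted population.

    ``tuning(behavior, phase)`` returns a rate multiplier (>= 1 at baseline);
    bump templates modulate within feeding episodes as a Gaussian of episode
    phase, homogeneous templates elevate uniformly during their behavior.
    """

    name: str
    baseline_hz: float
    behavior: str  # behavior during which the template is active
    phase_center: float | None = None
    phase_width: float = BUMP_WIDTH
    peak_multiplier: float = PEAK_MULTIPLIER

    def __post_init__(self) -> None:
        if self.baseline_hz < 0:
            raise ValidationError("baseline rate must be non-negative")

    def tuning(self, behavior: str, phase: np.ndarray) -> np.ndarray:
        phase = np.asarray(phase, dtype=float)
        if behavior != self.behavior:
            return np.ones_like(phase)
        if self.phase_center is None:
            return np.full_like(phase, self.peak_multiplier)
        gain = self.peak_multiplier - 1.0
        return 1.0 + gain * np.exp(-0.5 * ((phase - self.phase_center) / self.phase_width) ** 2)

    @property
    def max_multiplier(self) -> float:
        return self.peak_multiplier


def default_templates() -> list[PopulationTemplate]:
    """The seven planted populations: FOn/EF/LF/FOff bumps, Fd/Sol/Exp."""
    out = []
    for name, center in BUMP_CENTERS.items():
        out.append(PopulationTemplate(name, DEFAULT_BASELINES[name], "feeding",
                                      phase_center=center))
    out.append(PopulationTemplate("Fd", DEFAULT_BASELINES["Fd"], "feeding"))
    out.append(PopulationTemplate("Sol", DEFAULT_BASELINES["Sol"], "social"))
    out.append(PopulationTemplate("Exp", DEFAULT_BASELINES["Exp"], "object"))
    return out


@dataclass
class SyntheticGroundTruth:
    populations: dict = field(default_factory=dict)  # cell key -> population name
    lfp_events: dict = field(default_factory=dict)  # band label -> EpochSet
    coupled_pairs: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# ethogram

def _lognormal_duration(rng, median_s, sigma, minimum=0.0):
    while True:
        d = float(rng.lognormal(mean=math.log(median_s), sigma=sigma))
        if d >= minimum:
            return d


def generate_ethogram(n_sessions: int, session_len_s: float, seed: int = 0) -> Ethogram:
    """Non-overlapping feeding/social/object episodes with unscored gaps.

    Feeding durations are lognormal with median ~22 s, truncated at the 4.8 s
    scoring minimum; social and object durations are lognormal with median
    ~4 s. Behaviors are interleaved in shuffled triplets separated by
    unscored time.
    """
    if session_len_s < 300:
        raise ValidationError("session_len_s must be >= 300")
    rng = derive_rng(seed, "ethogram")
    episodes = []
    for s in range(n_sessions):
        sess = f"S{s:02d}"
        t = float(rng.uniform(*GAP_RANGE_S))
        placed = {b: 0 for b in BEHAVIORS}
        while True:
            order = list(BEHAVIORS)
            rng.shuffle(order)
            stop = False
            for b in order:
                if b == "feeding":
                    dur = _lognormal_duration(rng, FEEDING_MEDIAN_S, DURATION_SIGMA,
                                              minimum=MIN_FEEDING_S)
                else:
                    dur = _lognormal_duration(rng, OTHER_MEDIAN_S, DURATION_SIGMA)
                if t + dur > session_len_s:
                    stop = True
                    break
                episodes.append(Episode(sess, b, t, t + dur))
                placed[b] += 1
                t += dur + float(rng.uniform(*GAP_RANGE_S))
            if stop:
                break
        if min(placed.values()) < 1:
            raise ValidationError(
                f"session of {session_len_s:.0f} s too short to place every behavior"
            )
    return Ethogram(episodes=episodes)


# ---------------------------------------------------------------------------
# spike trains

def _cell_rate_on_grid(template, etho, session_id, grid):
    mult = np.ones(grid.size)
    for ep in etho.of(session_id, template.behavior):
        sel = (grid >= ep.start_s) & (grid < ep.end_s)
        phase = (grid[sel] - ep.start_s) / ep.duration_s
        mult[sel] = template.tuning(template.behavior, phase)
    return template.baseline_hz * mult


def _thin_poisson(rng, rate_fn, t0, t1, rate_max):
    """Inhomogeneous Poisson process on [t0, t1) by thinning."""
    n = rng.poisson(rate_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n))
    if not cand.size:
        return cand
    accept = rng.uniform(0, 1, size=cand.size) < rate_fn(cand) / rate_max
    return cand[accept]


def generate_population_spikes(
    etho: Ethogram,
    templates: list[PopulationTemplate] | None = None,
    n_cells_per_pop: int = 50,
    seed: int = 0,
    n_shanks: int = 4,
) -> tuple[SpikeDataset, SyntheticGroundTruth]:
    """Inhomogeneous-Poisson (thinning) spike trains for planted populations.

    Each cell fires at its template baseline everywhere, multiplied by the
    template tuning inside episodes of the template's behavior (phase =
    elapsed fraction of the episode). Cells are distributed round-robin over
    sessions and over >= 2 shanks.
    """
    if templates is None:
        templates = default_templates()
    if not templates:
        raise ValidationError("templates must be non-empty")
    for tpl in templates:
        if tpl.baseline_hz == 0 and tpl.peak_multiplier <= 1:
            raise ValidationError(f"template {tpl.name}: degenerate (always silent)")
    n_shanks = max(2, n_shanks)
    sessions = sorted({e.session_id for e in etho.episodes})
    span_by_sess = {}
    for sess in sessions:
        eps = etho.of(sess)
        span_by_sess[sess] = (0.0, float(max(e.end_s for e in eps)) + 10.0)
    rng = derive_rng(seed, "spikes")
    cells = []
    truth = SyntheticGroundTruth()
    idx = 0
    for tpl in templates:
        for j in range(n_cells_per_pop):
            sess = sessions[idx % len(sessions)]
            shank = idx % n_shanks
            t0, t1 = span_by_sess[sess]
            rate_max = tpl.baseline_hz * tpl.max_multiplier
            grid = np.arange(t0, t1, 0.005)
            rate = _cell_rate_on_grid(tpl, etho, sess, grid)
            spikes = _thin_poisson(
                rng, lambda t, g=grid, r=rate: np.interp(t, g, r), t0, t1, rate_max
            )
            cid = f"{tpl.name}_{j:03d}"
            cells.append(Cell(cell_id=cid, session_id=sess, shank_id=shank,
                              spike_times_s=spikes))
            truth.populations[(sess, cid)] = tpl.name
            idx += 1
    ds = SpikeDataset(cells=cells, session_spans=span_by_sess)
    return ds, truth


# ---------------------------------------------------------------------------
# LFP

def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def _background_envelope_stats(noise, fs_hz, band_hz):
    # amplitude scale of the detector: mean/SD of the rectified band signal
    sos = sps.butter(4, list(band_hz), btype="band", fs=fs_hz, output="sos")
    rect = np.abs(sps.sosfiltfilt(sos, noise))
    return float(rect.mean()), float(rect.std())


def generate_lfp_with_events(
    session_len_s: float,
    fs_hz: float = 1250.0,
    event_spec: list | None = None,
    seed: int = 0,
    session_id: str = "",
) -> tuple[LfpSignal, dict]:
    """Pink-noise LFP with planted band-limited oscillation bursts.

    ``event_spec`` entries: {band_hz: (lo, hi), amplitude_sd, duration_ms,
    count}. Each burst is a Tukey-windowed sinusoid at the band center whose
    rectified-smoothed envelope sits ``amplitude_sd`` background-envelope SDs
    above the background-envelope mean — the same scale on which the event
    detector thresholds ("k SD above the noise mean"). Returns the signal
    and the exact truth intervals per band label.
    """
    event_spec = event_spec or []
    rng = derive_rng(seed, "lfp")
    n = int(round(session_len_s * fs_hz))
    x = pink_noise(n, rng)
    truth: dict[str, EpochSet] = {}
    for spec in event_spec:
        lo, hi = spec["band_hz"]
        if hi >= fs_hz / 2:
            raise ValidationError(f"band {spec['band_hz']} above Nyquist")
        count = int(spec.get("count", 0))
        label = spec.get("label", f"band_{lo:g}_{hi:g}")
        if count == 0:
            truth[label] = EpochSet(label=label, intervals=np.empty((0, 2)),
                                    session_id=session_id)
            continue
        dur_s = spec["duration_ms"] / 1000.0
        bg_mean, bg_sd = _background_envelope_stats(x, fs_hz, (lo, hi))
        # rectified-sine mean is (2/pi) * amplitude
        amp = (bg_mean + spec["amplitude_sd"] * bg_sd) * math.pi / 2.0
        f0 = (lo + hi) / 2.0
        n_burst = int(round(dur_s * fs_hz))
        margin = 1.0
        starts = []
        attempts = 0
        while len(starts) < count:
            attempts += 1
            if attempts > 10000:
                raise ValidationError("could not place non-overlapping events")
            s = float(rng.uniform(margin, session_len_s - margin - dur_s))
            if all(abs(s - s2) >= dur_s + 0.2 for s2 in starts):
                starts.append(s)
        starts.sort()
        intervals = []
        for s in starts:
            i0 = int(round(s * fs_hz))
            tt = np.arange(n_burst) / fs_hz
            burst = amp * np.sin(2 * math.pi * f0 * tt + rng.uniform(0, 2 * math.pi))
            burst *= sps.windows.tukey(n_burst, alpha=0.25)
            x[i0:i0 + n_burst] += burst
            intervals.append([s, s + dur_s])
        truth[label] = EpochSet(label=label, intervals=np.array(intervals),
                                session_id=session_id)
    return LfpSignal(samples=x, fs_hz=fs_hz, session_id=session_id), truth


# ---------------------------------------------------------------------------
# coupled pairs

def couple_pairs_to_events(
    dataset: SpikeDataset,
    epochs: EpochSet,
    pairs: list,
    excess_sync_rate_hz: float = 1.0,
    jitter_ms: float = 5.0,
    seed: int = 0,
) -> tuple[SpikeDataset, SyntheticGroundTruth]:
    """Insert synchronous spike pairs inside the given epochs only.

    ``pairs`` are ((session_id, cell_id), (session_id, cell_id)) tuples on
    different shanks. At ``excess_sync_rate_hz`` (Poisson within the epochs),
    a spike is added to the first cell and a second spike, offset by
    U(+/-jitter_ms), to the second. Original spikes are preserved.
    """
    import logging

    truth = SyntheticGroundTruth()
    if not len(epochs):
        logging.getLogger("ensemble_dynamics").warning("empty epochs: coupling is a no-op")
        return dataset, truth
    rng = derive_rng(seed, "coupling")
    extra: dict = {}
    for (key_a, key_b) in pairs:
        cell_a = dataset.get(*key_a)
        cell_b = dataset.get(*key_b)
        if cell_a.session_id != cell_b.session_id:
            raise ValidationError(f"pair {key_a}/{key_b} spans sessions")
        if cell_a.shank_id == cell_b.shank_id:
            raise ValidationError(f"pair {key_a}/{key_b} on the same shank")
        if excess_sync_rate_hz <= 0:
            continue
        t0, t1 = dataset.session_spans[cell_a.session_id]
        events = []
        for (s, e) in epochs.intervals:
            n = rng.poisson(excess_sync_rate_hz * (e - s))
            events.extend(rng.uniform(s, e, size=n))
        events = np.array(sorted(events))
        events = events[(events >= t0) & (events < t1)]  # epochs may outrun the span
        partner = events + rng.uniform(-jitter_ms, jitter_ms, size=events.size) / 1000.0
        partner = partner[(partner >= t0) & (partner < t1)]
        extra.setdefault(key_a, []).append(events)
        extra.setdefault(key_b, []).append(partner)
        truth.coupled_pairs.append({
            "cell_a": key_a, "cell_b": key_b, "epoch_label": epochs.label,
            "excess_sync_rate_hz": excess_sync_rate_hz, "jitter_ms": jitter_ms,
            "n_injected": int(events.size),
        })
    new_cells = []
    for c in dataset.cells:
        if c.key in extra:
            merged = np.sort(np.concatenate([c.spike_times_s] + extra[c.key]))
            new_cells.append(Cell(c.cell_id, c.session_id, c.shank_id, merged))
        else:
            new_cells.append(c)
    return SpikeDataset(cells=new_cells, session_spans=dict(dataset.session_spans)), truth


# ---------------------------------------------------------------------------
# triangular waveform (for the spike-width measure)

def triangular_waveform(half_width_ms: float, amplitude: float = 1.0,
                        fs_hz: float = 20000.0, pad_ms: float = 0.5) -> np.ndarray:
    """Toy symmetric triangular spike: rises over half_width, falls over half_width."""
    n_half = int(round(half_width_ms / 1000.0 * fs_hz))
    n_pad = int(round(pad_ms / 1000.0 * fs_hz))
    up = np.linspace(0, amplitude, n_half + 1)
    down = np.linspace(amplitude, 0, n_half + 1)[1:]
    return np.concatenate([np.zeros(n_pad), up, down, np.zeros(n_pad)])
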