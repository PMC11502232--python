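"""Time-warped firing-rate feature construction.

Per cell: Gaussian-kernel instantaneous rate -> episodes of each behavior
rescaled ("warped") to a common number of 10 ms phase bins -> the three
behavior vectors concatenated (feeding | social | object), z-scored, and
reduced by PCA to the leading components capturing the variance target.

The kernel "size" of 500 ms is read as the standard deviation of the Gaussian
(the most common convention); it is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from sklearn.decomposition import PCA

from .datatypes import BEHAVIORS, Ethogram, SpikeDataset, ValidationError

log = logging.getLogger("ensemble_dynamics")

#: Rate-series grid step (s); matches the warp resolution so that phase-bin
#: means are well defined.
RATE_GRID_DT_S = 0.01


def make_grid(t0_s: float, t1_s: float, dt_s: float = RATE_GRID_DT_S) -> np.ndarray:
    """Regular time grid covering [t0, t1]."""
    n = int(np.floor((t1_s - t0_s) / dt_s)) + 1
    return t0_s + np.arange(n) * dt_s


def estimate_rate(
    spike_times_s: np.ndarray,
    kernel_sd_ms: float = 500.0,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Instantaneous firing rate (Hz) by Gaussian-kernel smoothing.

    The rate is the sum over spikes of a unit-mass Gaussian of SD
    ``kernel_sd_ms`` centered at each spike, evaluated on the regular grid.
    The kernel integrates to one, so the rate integrates to the spike count
    (up to tail mass beyond the grid).
    """
    t = np.asarray(spike_times_s, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValidationError("spike times must be sorted ascending")
    if grid is None:
        raise ValueError("grid is required")
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("grid must have at least 2 points")
    dt = grid[1] - grid[0]
    if not np.allclose(np.diff(grid), dt, rtol=1e-6):
        raise ValueError("grid must be regular")
    if t.size == 0:
        return np.zeros(grid.size)
    sd_s = kernel_sd_ms / 1000.0
    # Bin spikes onto the grid, then convolve with a sampled unit-mass kernel.
    edges = np.concatenate([grid - dt / 2, [grid[-1] + dt / 2]])
    counts, _ = np.histogram(t, bins=edges)
    half = int(np.ceil(5 * sd_s / dt))
    x = np.arange(-half, half + 1) * dt
    kern = np.exp(-0.5 * (x / sd_s) ** 2)
    kern /= kern.sum()
    rate = np.convolve(counts, kern, mode="same") / dt
    return rate


@dataclass
class BehaviorRateVector:
    """Per-cell average warped rate over episodes of one behavior."""

    behavior: str
    values: np.ndarray  # length n_bins, Hz (or z-units downstream)
    n_bins: int
    n_episodes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("rate vector contains non-finite values")

    @property
    def empty(self) -> bool:
        return self.n_episodes == 0


def n_warp_bins(mean_duration_s: float, warp_bin_ms: float = 10.0) -> int:
    """Number of phase bins at the warp resolution in the average episode."""
    return max(1, int(round(mean_duration_s / (warp_bin_ms / 1000.0))))


def warp_episodes(
    grid: np.ndarray,
    rate: np.ndarray,
    episodes: list,
    warp_bin_ms: float = 10.0,
    n_bins: int | None = None,
) -> BehaviorRateVector:
    """Rescale episodes of one behavior to a common phase axis and average.

    Each episode [start, end) is split into ``n_bins`` equal sub-intervals;
    the bin value is the mean of the rate over the sub-interval (computed
    exactly for the piecewise-linear interpolant via the cumulative
    integral), then averaged across episodes.
    """
    behaviors = {e.behavior for e in episodes}
    if len(behaviors) > 1:
        raise ValidationError(f"episodes mix behaviors {behaviors}")
    behavior = behaviors.pop() if behaviors else ""
    if not episodes:
        return BehaviorRateVector(behavior=behavior, values=np.array([]), n_bins=0, n_episodes=0)
    if n_bins is None:
        mean_dur = float(np.mean([e.duration_s for e in episodes]))
        n_bins = n_warp_bins(mean_dur, warp_bin_ms)
    cum = cumulative_trapezoid(rate, grid, initial=0.0)
    acc = np.zeros(n_bins)
    for ep in episodes:
        edges = np.linspace(ep.start_s, ep.end_s, n_bins + 1)
        f_edges = np.interp(edges, grid, cum)
        widths = np.diff(edges)
        acc += np.diff(f_edges) / widths
    return BehaviorRateVector(
        behavior=behavior,
        values=acc / len(episodes),
        n_bins=n_bins,
        n_episodes=len(episodes),
    )


@dataclass
class FeatureMatrix:
    """Concatenated z-scored behavior rate vectors and PCA reduction."""

    cells: list  # ordered (session_id, cell_id) keys of retained cells
    concatenated: np.ndarray  # cells x (nF + nS + nE), z-scored rows
    reduced: np.ndarray  # cells x m PCA scores
    explained_variance: np.ndarray  # per-component fractions (all computed)
    m: int
    n_bins: dict  # behavior -> bin count
    excluded: list  # (session_id, cell_id, reason)
    raw_vectors: dict  # (session_id, cell_id) -> {behavior: BehaviorRateVector}

    def first_pcs(self, n: int = 5) -> np.ndarray:
        full = self.reduced if self.reduced.shape[1] >= n else self._scores
        return full[:, :n]


def behavior_rate_vectors(
    dataset: SpikeDataset,
    etho: Ethogram,
    kernel_sd_ms: float = 500.0,
    warp_bin_ms: float = 10.0,
    grid_dt_s: float = RATE_GRID_DT_S,
) -> tuple[dict, dict]:
    """Warped behavior rate vectors for every cell.

    Episode durations are pooled across sessions so that every cell's vector
    for a behavior has the same length (one shared bin count per behavior),
    which joint clustering of cells from many sessions requires.

    Returns ``(vectors, n_bins)`` where ``vectors`` maps cell key ->
    {behavior: BehaviorRateVector} and ``n_bins`` maps behavior -> bins.
    """
    n_bins = {}
    for b in BEHAVIORS:
        durs = etho.durations(b)
        n_bins[b] = n_warp_bins(float(np.mean(durs)), warp_bin_ms) if durs.size else 0
    vectors: dict = {}
    for sess in dataset.session_ids:
        t0, t1 = dataset.session_spans[sess]
        grid = make_grid(t0, t1, grid_dt_s)
        eps_by_b = {b: etho.of(sess, b) for b in BEHAVIORS}
        for cell in dataset.cells_of(sess):
            rate = estimate_rate(cell.spike_times_s, kernel_sd_ms, grid)
            vectors[cell.key] = {
                b: warp_episodes(grid, rate, eps_by_b[b], warp_bin_ms, n_bins[b] or None)
                for b in BEHAVIORS
            }
    return vectors, n_bins


def build_feature_matrix(
    dataset: SpikeDataset,
    etho: Ethogram,
    kernel_sd_ms: float = 500.0,
    warp_bin_ms: float = 10.0,
    variance_target: float = 0.90,
) -> FeatureMatrix:
    """Concatenate per-behavior warped vectors, z-score rows, reduce by PCA.

    Cells lacking episodes of any behavior in their session, or with a
    zero-variance concatenated vector, are excluded with a logged warning.
    """
    vectors, n_bins = behavior_rate_vectors(dataset, etho, kernel_sd_ms, warp_bin_ms)
    keys, rows, excluded = [], [], []
    for key in sorted(vectors):
        per_b = vectors[key]
        if any(per_b[b].empty for b in BEHAVIORS):
            excluded.append((*key, "missing behavior episodes"))
            continue
        row = np.concatenate([per_b[b].values for b in BEHAVIORS])
        sd = row.std()
        if sd == 0 or not np.isfinite(sd):
            excluded.append((*key, "zero-variance rate vector"))
            continue
        keys.append(key)
        rows.append((row - row.mean()) / sd)
    for key in excluded:
        log.warning("excluding cell %s: %s", key[:2], key[2])
    if len(rows) < 2:
        raise ValidationError("need at least 2 cells with all three behavior vectors")
    X = np.vstack(rows)
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    m = int(np.searchsorted(np.cumsum(evr), variance_target) + 1)
    m = min(m, n_comp)
    fm = FeatureMatrix(
        cells=keys,
        concatenated=X,
        reduced=scores[:, :m],
        explained_variance=evr,
        m=m,
        n_bins=n_bins,
        excluded=excluded,
        raw_vectors=vectors,
    )
    fm._scores = scores
    return fm
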