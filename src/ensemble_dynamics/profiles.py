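"""Behavioral naming of clusters, peak-time uniformity, per-behavior rate
summaries, anatomical enrichment maps, and spike width.

Clusters are named by the behavior with the highest mean peak rate across
their cells. Among feeding-preferring clusters, the four phase-localized
ones are ordered by the median feeding peak phase and named FOn/EF/LF/FOff;
a feeding cluster whose peak-time distribution is closest to uniform (small
KS D against Uniform(0,1)) is the homogeneous feeding population Fd.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as st

from .datatypes import BEHAVIORS, ValidationError

log = logging.getLogger("ensemble_dynamics")

PHASE_NAMES = ("FOn", "EF", "LF", "FOff")


def peak_time_uniformity(
    peak_phases: np.ndarray,
    alpha_family: float = 0.05,
    n_tests: int = 1,
) -> dict:
    """One-sample KS test of peak phases against Uniform(0, 1) with a
    Bonferroni-adjusted alpha (alpha_family / n_tests)."""
    x = np.asarray(peak_phases, dtype=float)
    if x.size < 5:
        raise ValidationError("need at least 5 phases")
    if np.any((x < 0) | (x > 1)):
        raise ValidationError("phases must lie in [0, 1]")
    res = st.kstest(x, "uniform")
    alpha_adj = alpha_family / n_tests
    return {
        "D": float(res.statistic),
        "p": float(res.pvalue),
        "alpha_adj": float(alpha_adj),
        "reject": bool(res.pvalue < alpha_adj),
        "n": int(x.size),
    }


def peak_phase(values: np.ndarray) -> float:
    """Phase in [0, 1] of the maximum of a warped rate vector (bin center)."""
    v = np.asarray(values, dtype=float)
    return float((np.argmax(v) + 0.5) / v.size)


@dataclass
class PopulationProfile:
    names: dict  # cluster id -> population name
    preferred_behavior: dict  # cluster id -> behavior
    mean_rates: dict  # cluster id -> {behavior: mean across cells of mean rate}
    peak_rates: dict  # cluster id -> {behavior: mean across cells of peak rate}
    peak_phases: dict  # cluster id -> array of per-cell phases (preferred behavior)
    ks: dict  # cluster id -> uniformity test result
    alpha_adj: float = field(default=np.nan)


def label_populations(
    raw_vectors: dict,
    cell_keys: list,
    labels: np.ndarray,
    alpha_family: float = 0.05,
) -> PopulationProfile:
    """Name clusters from raw (Hz) behavior rate vectors and cluster labels.

    ``raw_vectors`` maps cell key -> {behavior: BehaviorRateVector}, aligned
    with ``cell_keys``/``labels`` over the retained cells.
    """
    labels = np.asarray(labels)
    if len(cell_keys) != labels.size:
        raise ValidationError("vectors and labels must cover the same cells")
    clusters = np.unique(labels)
    n_tests = len(clusters) * len(BEHAVIORS)
    alpha_adj = alpha_family / n_tests
    mean_rates, peak_rates, preferred = {}, {}, {}
    phases_by_cluster, ks_by_cluster = {}, {}
    for cl in clusters:
        keys = [k for k, l in zip(cell_keys, labels) if l == cl]
        mr, pr = {}, {}
        for b in BEHAVIORS:
            vals = [raw_vectors[k][b].values for k in keys]
            mr[b] = float(np.mean([v.mean() for v in vals]))
            pr[b] = float(np.mean([v.max() for v in vals]))
        pref = max(BEHAVIORS, key=lambda b: pr[b])
        mean_rates[int(cl)] = mr
        peak_rates[int(cl)] = pr
        preferred[int(cl)] = pref
        ph = np.array([peak_phase(raw_vectors[k][pref].values) for k in keys])
        phases_by_cluster[int(cl)] = ph
        if ph.size >= 5:
            ks_by_cluster[int(cl)] = peak_time_uniformity(ph, alpha_family, n_tests)
        else:
            ks_by_cluster[int(cl)] = {"D": np.nan, "p": np.nan,
                                      "alpha_adj": alpha_adj, "reject": False,
                                      "n": int(ph.size)}
    names = _assign_names(preferred, phases_by_cluster, ks_by_cluster)
    return PopulationProfile(
        names=names,
        preferred_behavior=preferred,
        mean_rates=mean_rates,
        peak_rates=peak_rates,
        peak_phases=phases_by_cluster,
        ks=ks_by_cluster,
        alpha_adj=alpha_adj,
    )


def _assign_names(preferred: dict, phases: dict, ks: dict) -> dict:
    """Naming rule.

    Non-feeding clusters: Sol/Exp by preferred behavior (suffixed if several).
    Feeding clusters: with five or more, the smallest-KS-D cluster (closest
    to uniform peak times) is Fd and the rest take FOn/EF/LF/FOff in median-
    phase order; with four or fewer, clusters that fail to reject uniformity
    are Fd and the rejecting ones take phase names in order.
    """
    names: dict = {}
    by_behavior: dict = {"feeding": [], "social": [], "object": []}
    for cl, b in preferred.items():
        by_behavior[b].append(cl)

    for b, base in (("social", "Sol"), ("object", "Exp")):
        ordered = sorted(by_behavior[b])
        for i, cl in enumerate(ordered):
            names[cl] = base if len(ordered) == 1 else f"{base}{i + 1}"

    feed = by_behavior["feeding"]
    if not feed:
        return names
    d_of = {cl: ks[cl]["D"] for cl in feed}

    def med_phase(cl):
        return float(np.median(phases[cl]))

    def mean_phase(cl):
        return float(np.mean(phases[cl]))

    if len(feed) >= 5:
        fd = min(feed, key=lambda cl: (d_of[cl] if np.isfinite(d_of[cl]) else np.inf))
        names[fd] = "Fd"
        rest = [cl for cl in feed if cl != fd]
    else:
        homogeneous = [cl for cl in feed if not ks[cl]["reject"]]
        homogeneous.sort(key=lambda cl: d_of[cl])
        for i, cl in enumerate(homogeneous):
            names[cl] = "Fd" if i == 0 else f"Fd{i + 1}"
        rest = [cl for cl in feed if cl not in homogeneous]
    rest.sort(key=lambda cl: (med_phase(cl), mean_phase(cl)))
    for a, b_ in zip(rest, rest[1:]):
        if med_phase(a) == med_phase(b_):
            log.warning("clusters %s and %s tie on median phase; ordered by mean phase", a, b_)
    for i, cl in enumerate(rest):
        names[cl] = PHASE_NAMES[i] if i < len(PHASE_NAMES) else f"F{i + 1}"
    return names


def behavior_rate_correlations(mean_z_rates: np.ndarray, groups: np.ndarray) -> dict:
    """Per-population 3x3 Pearson matrix of per-cell mean z-rates.

    ``mean_z_rates`` is cells x 3 (feeding, social, object order);
    ``groups`` assigns a population label per cell.
    """
    X = np.asarray(mean_z_rates, dtype=float)
    groups = np.asarray(groups)
    out = {}
    for g in np.unique(groups):
        sub = X[groups == g]
        if sub.shape[0] < 3:
            out[g] = None
            continue
        r = np.full((3, 3), np.nan)
        p = np.full((3, 3), np.nan)
        for i in range(3):
            for j in range(3):
                if i == j:
                    r[i, j], p[i, j] = 1.0, 0.0
                    continue
                if np.std(sub[:, i]) == 0 or np.std(sub[:, j]) == 0:
                    continue  # r undefined for a constant vector
                rr = st.pearsonr(sub[:, i], sub[:, j])
                r[i, j], p[i, j] = rr.statistic, rr.pvalue
        out[g] = {"r": r, "p": p, "behaviors": BEHAVIORS, "n": int(sub.shape[0])}
    return out


def anatomical_enrichment(
    locations_um: np.ndarray,
    labels: np.ndarray,
    grid: tuple = (10, 10),
    ml_bin_um: float = 70.0,
    dv_bin_um: float = 38.8,
    origin_um: tuple | None = None,
    min_cells: int = 3,
) -> dict:
    """Per-population density-difference maps on a fixed ML x DV grid.

    Each map is the population's unit-mass 2D histogram minus the all-cell
    unit-mass histogram (so each map sums to ~0). Also returns pairwise
    Pearson correlations between flattened maps.
    """
    X = np.asarray(locations_um, dtype=float)
    labels = np.asarray(labels)
    n_ml, n_dv = grid
    if origin_um is None:
        origin_um = (X[:, 0].min(), X[:, 1].min())
    ml_edges = origin_um[0] + np.arange(n_ml + 1) * ml_bin_um
    dv_edges = origin_um[1] + np.arange(n_dv + 1) * dv_bin_um
    if X[:, 0].max() > ml_edges[-1] or X[:, 1].max() > dv_edges[-1]:
        raise ValidationError("locations outside the grid extent")
    overall, _, _ = np.histogram2d(X[:, 0], X[:, 1], bins=[ml_edges, dv_edges])
    overall /= overall.sum()
    maps = {}
    for g in np.unique(labels):
        sub = X[labels == g]
        if sub.shape[0] < min_cells:
            log.warning("population %s has %d located cells; map omitted", g, sub.shape[0])
            continue
        h, _, _ = np.histogram2d(sub[:, 0], sub[:, 1], bins=[ml_edges, dv_edges])
        maps[g] = h / h.sum() - overall
    names = sorted(maps)
    corr = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rr = st.pearsonr(maps[a].ravel(), maps[b].ravel())
            corr[(a, b)] = {"r": float(rr.statistic), "p": float(rr.pvalue)}
    return {"maps": maps, "correlations": corr,
            "grid": {"ml_edges_um": ml_edges, "dv_edges_um": dv_edges}}


def spike_width(mean_waveform: np.ndarray, fs_hz: float, level: float = 0.25) -> float:
    """Spike width (ms) at a fraction of the peak-to-baseline amplitude.

    Width is the time between the two crossings of level*amplitude flanking
    the extremum, linearly interpolated; NaN when a flank never crosses.
    """
    w = np.asarray(mean_waveform, dtype=float)
    if w.size < 3:
        return float("nan")
    baseline = (w[0] + w[-1]) / 2.0
    dev = w - baseline
    i_pk = int(np.argmax(np.abs(dev)))
    amp = dev[i_pk]
    if amp == 0:
        return float("nan")
    sig = dev / amp  # peak-normalized, peak = +1
    thr = level

    left = None
    for i in range(i_pk - 1, -1, -1):  # walk left from the peak
        if sig[i] < thr:
            frac = (sig[i + 1] - thr) / (sig[i + 1] - sig[i])
            left = (i + 1) - frac
            break
    right = None
    for i in range(i_pk + 1, w.size):  # walk right from the peak
        if sig[i] < thr:
            frac = (sig[i - 1] - thr) / (sig[i - 1] - sig[i])
            right = (i - 1) + frac
            break
    if left is None or right is None:
        return float("nan")
    return float((right - left) / fs_hz * 1000.0)


def population_rate_tests(values_by_group: dict, alpha: float = 0.05) -> dict:
    """Pairwise Mann-Whitney tests across populations (e.g. average rates or
    spike widths); standard library calls, reported per ordered pair."""
    names = sorted(values_by_group)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x, y = np.asarray(values_by_group[a]), np.asarray(values_by_group[b])
            if x.size < 2 or y.size < 2:
                out[(a, b)] = None
                continue
            res = st.mannwhitneyu(x, y, alternative="two-sided")
            out[(a, b)] = {"U": float(res.statistic), "p": float(res.pvalue),
                           "significant": bool(res.pvalue < alpha)}
    return out
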