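"""Epoch-conditioned cross-correlograms and the cofiring ratio (CFR).

A CCG is triggered on one cell's spikes inside a given epoch set (gamma
events or nonrhythmic epochs); response spikes are counted at 1 ms lags in a
+/-50 ms window and the histogram normalized to unit mass. The cofiring
probability is the mean normalized bin value within +/-15 ms of the trigger.
CFR = cofiring during nonrhythmic epochs / cofiring during gamma; CFR < 1
means stronger coordination during gamma. The significance null shifts each
trigger spike independently by Uniform(-25, 25) s (wrapped within the
session) and recomputes the CFR, 1,000 times by default.

Only the trigger train is epoch-restricted (response spikes may fall at any
time), and pairs are formed across different probe shanks within a session.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as st

from .datatypes import EpochSet, SpikeDataset, ValidationError
from .io import derive_rng

log = logging.getLogger("ensemble_dynamics")


@dataclass
class CcgResult:
    trigger: tuple
    response: tuple
    lags_ms: np.ndarray  # bin centers
    probs: np.ndarray  # normalized counts, sum 1 when defined
    n_trigger: int
    n_coincidences: int
    epoch_label: str

    @property
    def defined(self) -> bool:
        return self.n_trigger > 0 and self.n_coincidences > 0


@dataclass
class CfrResult:
    pair: tuple  # (trigger key, response key)
    band: str
    p_nonrhythmic: float
    p_gamma: float
    cfr: float
    shuffle: dict | None = None  # {n, mean, p2_5, p50, p97_5, values}


def _lag_edges_s(bin_ms: float, half_window_ms: float) -> np.ndarray:
    n_half = int(round(half_window_ms / bin_ms))
    centers = np.arange(-n_half, n_half + 1) * bin_ms
    edges = np.concatenate([centers - bin_ms / 2, [centers[-1] + bin_ms / 2]])
    return edges / 1000.0


def ccg(
    trigger_spikes_s: np.ndarray,
    response_spikes_s: np.ndarray,
    trigger_epochs: EpochSet | None = None,
    bin_ms: float = 1.0,
    half_window_ms: float = 50.0,
    trigger_key: tuple = (), response_key: tuple = (),
) -> CcgResult:
    """Epoch-conditioned cross-correlogram, normalized to unit mass."""
    trig = np.asarray(trigger_spikes_s, dtype=float)
    resp = np.asarray(response_spikes_s, dtype=float)
    if trigger_epochs is not None:
        trig = trig[trigger_epochs.contains(trig)]
    edges = _lag_edges_s(bin_ms, half_window_ms)
    centers = (edges[:-1] + edges[1:]) / 2 * 1000.0
    counts = np.zeros(centers.size)
    if trig.size and resp.size:
        lo = np.searchsorted(resp, trig + edges[0], side="left")
        hi = np.searchsorted(resp, trig + edges[-1], side="left")
        has = hi > lo
        if has.any():
            lags = np.concatenate(
                [resp[a:b] - t for t, a, b in zip(trig[has], lo[has], hi[has])]
            )
            # half-open lag bins [edge_i, edge_{i+1})
            idx = np.floor((lags - edges[0]) / (bin_ms / 1000.0)).astype(int)
            idx = idx[(idx >= 0) & (idx < centers.size)]
            counts = np.bincount(idx, minlength=centers.size).astype(float)
    total = counts.sum()
    probs = counts / total if total > 0 else counts
    return CcgResult(
        trigger=trigger_key,
        response=response_key,
        lags_ms=centers,
        probs=probs,
        n_trigger=int(trig.size),
        n_coincidences=int(total),
        epoch_label=trigger_epochs.label if trigger_epochs is not None else "",
    )


def cofiring_probability(result: CcgResult, half_window_ms: float = 15.0) -> float:
    """Mean normalized CCG value over bins with centers within +/-half_window."""
    if half_window_ms > result.lags_ms.max():
        raise ValidationError("cofiring window exceeds CCG extent")
    inner = np.abs(result.lags_ms) <= half_window_ms + 1e-9
    return float(result.probs[inner].mean())


def _cofire_fast(
    trig: np.ndarray,
    resp: np.ndarray,
    bin_ms: float,
    ccg_half_ms: float,
    cofire_half_ms: float,
) -> float:
    """Cofiring probability without building the histogram.

    Equals cofiring_probability(ccg(...)) exactly: the inner count over the
    bins with |center| <= cofire_half is a contiguous half-open lag range.
    """
    if trig.size == 0 or resp.size == 0:
        return np.nan
    outer = (ccg_half_ms + bin_ms / 2) / 1000.0
    inner = (cofire_half_ms + bin_ms / 2) / 1000.0
    n_inner_bins = 2 * int(round(cofire_half_ms / bin_ms)) + 1
    tot = float(np.sum(np.searchsorted(resp, trig + outer, side="left")
                       - np.searchsorted(resp, trig - outer, side="left")))
    if tot == 0:
        return np.nan
    cin = float(np.sum(np.searchsorted(resp, trig + inner, side="left")
                       - np.searchsorted(resp, trig - inner, side="left")))
    return cin / tot / n_inner_bins


def cofiring_ratio(
    trigger_spikes_s: np.ndarray,
    response_spikes_s: np.ndarray,
    nonrhythmic: EpochSet,
    gamma: EpochSet,
    bin_ms: float = 1.0,
    ccg_half_window_ms: float = 50.0,
    cofire_half_window_ms: float = 15.0,
    band: str = "",
    pair: tuple = ((), ()),
) -> CfrResult | None:
    """CFR = cofiring(nonrhythmic-triggered) / cofiring(gamma-triggered).

    Returns None (pair excluded) when either CCG is undefined or the gamma
    cofiring probability is zero.
    """
    if not len(nonrhythmic) or not len(gamma):
        raise ValidationError("both epoch sets must be non-empty")
    kw = dict(bin_ms=bin_ms, half_window_ms=ccg_half_window_ms)
    c_nr = ccg(trigger_spikes_s, response_spikes_s, nonrhythmic, **kw)
    c_g = ccg(trigger_spikes_s, response_spikes_s, gamma, **kw)
    if not (c_nr.defined and c_g.defined):
        log.info("pair %s: undefined CCG, excluded", pair)
        return None
    p_nr = cofiring_probability(c_nr, cofire_half_window_ms)
    p_g = cofiring_probability(c_g, cofire_half_window_ms)
    if p_g == 0:
        log.info("pair %s: zero gamma cofiring, excluded", pair)
        return None
    return CfrResult(pair=pair, band=band, p_nonrhythmic=p_nr, p_gamma=p_g, cfr=p_nr / p_g)


def shuffle_null(
    trigger_spikes_s: np.ndarray,
    response_spikes_s: np.ndarray,
    nonrhythmic: EpochSet,
    gamma: EpochSet,
    session_span: tuple,
    n: int = 1000,
    range_s: tuple = (-25.0, 25.0),
    seed: int = 0,
    bin_ms: float = 1.0,
    ccg_half_window_ms: float = 50.0,
    cofire_half_window_ms: float = 15.0,
) -> np.ndarray:
    """Control CFR distribution by uniform trigger-spike time shifts.

    Each trigger spike already selected by its epoch set is shifted
    independently by U(range_s), wrapped modulo the session span, and the
    cofiring probabilities and CFR recomputed against the intact response
    train. Returns the n control CFRs (NaN where a shuffle is undefined).
    """
    t0, t1 = session_span
    span = t1 - t0
    if span < 2 * abs(range_s[1]):
        raise ValidationError(
            f"session of {span:.0f} s too short for +/-{abs(range_s[1]):.0f} s shifts"
        )
    trig = np.asarray(trigger_spikes_s, dtype=float)
    resp = np.asarray(response_spikes_s, dtype=float)
    trig_nr = trig[nonrhythmic.contains(trig)]
    trig_g = trig[gamma.contains(trig)]
    rng = derive_rng(seed, "shuffle")
    out = np.empty(n)
    for i in range(n):
        s_nr = t0 + np.mod(trig_nr + rng.uniform(*range_s, size=trig_nr.size) - t0, span)
        s_g = t0 + np.mod(trig_g + rng.uniform(*range_s, size=trig_g.size) - t0, span)
        s_nr.sort()
        s_g.sort()
        p_nr = _cofire_fast(s_nr, resp, bin_ms, ccg_half_window_ms, cofire_half_window_ms)
        p_g = _cofire_fast(s_g, resp, bin_ms, ccg_half_window_ms, cofire_half_window_ms)
        out[i] = p_nr / p_g if (np.isfinite(p_nr) and np.isfinite(p_g) and p_g > 0) else np.nan
    return out


def summarize_shuffles(controls: np.ndarray) -> dict:
    ok = controls[np.isfinite(controls)]
    return {
        "n": int(controls.size),
        "n_defined": int(ok.size),
        "mean": float(ok.mean()) if ok.size else np.nan,
        "p2_5": float(np.percentile(ok, 2.5)) if ok.size else np.nan,
        "p50": float(np.percentile(ok, 50)) if ok.size else np.nan,
        "p97_5": float(np.percentile(ok, 97.5)) if ok.size else np.nan,
    }


def cfr_distribution_summary(cfrs: np.ndarray, controls: np.ndarray) -> dict:
    """Distribution-level comparison of original and control CFRs.

    ``controls`` holds one control CFR per pair (e.g. the per-pair shuffle
    mean). Reports ECDFs, the fraction of pairs with CFR < 1, paired t tests
    in the lower/upper 2.5% tails and middle 20% (ranked by original CFR),
    and a two-sample KS test between the distributions.
    """
    x = np.asarray(cfrs, dtype=float)
    y = np.asarray(controls, dtype=float)
    if x.size != y.size:
        raise ValidationError("need one control per pair")
    if x.size < 40:
        raise ValidationError("need at least 40 pairs for tail comparisons")
    order = np.argsort(x)
    n = x.size
    n_tail = max(1, int(round(0.025 * n)))
    n_mid = max(1, int(round(0.20 * n)))
    mid_lo = (n - n_mid) // 2
    groups = {
        "lower_tail": order[:n_tail],
        "middle": order[mid_lo: mid_lo + n_mid],
        "upper_tail": order[-n_tail:],
    }
    tests = {}
    for name, idx in groups.items():
        if idx.size < 2:
            tests[name] = None
            continue
        t, p = st.ttest_rel(x[idx], y[idx])
        tests[name] = {"t": float(t), "p": float(p), "n": int(idx.size)}
    ks = st.ks_2samp(x, y)
    xs = np.sort(x)
    ys = np.sort(y)
    ecdf = np.arange(1, n + 1) / n
    return {
        "ecdf_original": {"x": xs, "p": ecdf},
        "ecdf_control": {"x": ys, "p": ecdf},
        "frac_below_1": float(np.mean(x < 1)),
        "frac_below_1_control": float(np.mean(y < 1)),
        "tail_tests": tests,
        "ks": {"D": float(ks.statistic), "p": float(ks.pvalue)},
    }


def session_pairs(dataset: SpikeDataset, session_id: str) -> list:
    """All ordered (trigger, response) cell pairs across different shanks."""
    cells = dataset.cells_of(session_id)
    out = []
    for a in cells:
        for b in cells:
            if a.cell_id != b.cell_id and a.shank_id != b.shank_id:
                out.append((a, b))
    return out


def population_pair_assembly(
    cfr_rows: list,
    alpha: float = 0.05,
    min_pairs: int = 2,
) -> dict:
    """Group per-pair CFRs by ordered (trigger, response) population and test
    original vs control per group.

    ``cfr_rows`` are dicts with keys pop_a, pop_b, band, cfr, ctrl_mean.
    Uses a paired t test when the paired differences pass a Shapiro normality
    check at alpha, otherwise the Wilcoxon signed-rank test. Groups below
    ``min_pairs`` are reported as missing.
    """
    groups: dict = {}
    for row in cfr_rows:
        groups.setdefault((row["band"], row["pop_a"], row["pop_b"]), []).append(
            (row["cfr"], row["ctrl_mean"])
        )
    out = {}
    for key, vals in sorted(groups.items()):
        x = np.array([v[0] for v in vals])
        y = np.array([v[1] for v in vals])
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < min_pairs:
            out[key] = None
            continue
        diff = x - y
        if np.allclose(diff, 0):
            out[key] = {"test": "degenerate", "p": 1.0, "stat": 0.0,
                        "n": int(x.size), "median_cfr": float(np.median(x)),
                        "significant": False}
            continue
        use_t = x.size >= 3 and st.shapiro(diff).pvalue >= alpha
        if use_t:
            stat, p = st.ttest_rel(x, y)
            test = "paired_t"
        else:
            stat, p = st.wilcoxon(x, y)
            test = "wilcoxon"
        out[key] = {
            "test": test,
            "stat": float(stat),
            "p": float(p),
            "n": int(x.size),
            "median_cfr": float(np.median(x)),
            "significant": bool(p < alpha),
        }
    return out
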