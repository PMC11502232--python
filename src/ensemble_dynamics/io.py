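"""Readers/writers for the canonical file dialects, pipeline configuration,
seed derivation and logging.

Canonical formats are plain CSV (spikes, ethogram, epochs, results) plus flat
interleaved little-endian int16 binary for LFP, matching the field's .lfp/.dat
convention.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    MIN_FEEDING_S,
    Cell,
    Episode,
    Ethogram,
    FormatError,
    LfpSignal,
    SpikeDataset,
    ValidationError,
)

log = logging.getLogger("ensemble_dynamics")

SPIKE_COLUMNS = ["session_id", "cell_id", "shank_id", "time_s"]
ETHOGRAM_COLUMNS = ["session_id", "behavior", "start_s", "end_s"]
EPOCH_COLUMNS = ["session_id", "label", "start_s", "end_s"]


# ---------------------------------------------------------------------------
# seeding

def derive_seed(master_seed: int, *tags) -> int:
    """Derive a stable stage seed (< 2**31) from a master seed and tags.

    Tags are hashed with CRC32 so that textual stage names give reproducible
    integer entropy; the same (master_seed, tags) always yields the same seed.
    """
    ent = [int(master_seed) & 0xFFFFFFFF]
    ent += [zlib.crc32(str(t).encode()) for t in tags]
    ss = np.random.SeedSequence(ent)
    return int(ss.generate_state(1)[0] % (2**31))


def derive_rng(master_seed: int, *tags) -> np.random.Generator:
    ent = [int(master_seed) & 0xFFFFFFFF]
    ent += [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(ent))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with the study defaults."""

    # firing-rate features
    kernel_sd_ms: float = 500.0
    warp_bin_ms: float = 10.0
    variance_target: float = 0.90
    # clustering / stability
    cluster_range: tuple = tuple(range(2, 11))
    knn_range: tuple = (10, 20, 30)
    n_bootstrap: int = 100
    subsample_fraction: float = 0.9
    silhouette_iters: int = 100
    silhouette_min_pass: int = 95
    # LFP bands (Hz)
    slow_gamma_hz: tuple = (30.0, 60.0)
    fast_gamma_hz: tuple = (61.0, 90.0)
    nonrhythmic_bands_hz: tuple = (
        (2.0, 4.0),
        (5.0, 10.0),
        (15.0, 30.0),
        (30.0, 60.0),
        (61.0, 90.0),
        (90.0, 120.0),
        (120.0, 200.0),
    )
    detect_sd: float = 2.0
    edge_sd: float = 1.0
    min_event_ms: float = 25.0
    nonrhythmic_sd: float = 0.5
    nonrhythmic_min_ms: float = 100.0
    lfp_fs_hz: float = 1250.0
    # cross-correlation / cofiring
    ccg_bin_ms: float = 1.0
    ccg_half_window_ms: float = 50.0
    cofire_half_window_ms: float = 15.0
    shuffle_n: int = 1000
    shuffle_range_s: tuple = (-25.0, 25.0)
    # reproducibility
    master_seed: int = 0

    def __post_init__(self) -> None:
        positive = dict(
            kernel_sd_ms=self.kernel_sd_ms,
            warp_bin_ms=self.warp_bin_ms,
            min_event_ms=self.min_event_ms,
            nonrhythmic_min_ms=self.nonrhythmic_min_ms,
            ccg_bin_ms=self.ccg_bin_ms,
            ccg_half_window_ms=self.ccg_half_window_ms,
            cofire_half_window_ms=self.cofire_half_window_ms,
            lfp_fs_hz=self.lfp_fs_hz,
        )
        for name, v in positive.items():
            if v <= 0:
                raise ValidationError(f"{name} must be positive (got {v})")
        if not 0 < self.variance_target <= 1:
            raise ValidationError("variance_target must be in (0, 1]")
        if not 0 < self.subsample_fraction <= 1:
            raise ValidationError("subsample_fraction must be in (0, 1]")
        if len(self.cluster_range) == 0:
            raise ValidationError("cluster_range is empty")
        if len(self.knn_range) == 0:
            raise ValidationError("knn_range is empty")
        lo, hi = self.shuffle_range_s
        if not np.isclose(lo, -hi):
            raise ValidationError("shuffle_range_s must be symmetric about 0")
        if self.silhouette_min_pass > self.silhouette_iters:
            raise ValidationError("silhouette_min_pass exceeds silhouette_iters")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from YAML or JSON mirroring the field names."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = data or {}
    known = PipelineConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    for key, val in data.items():
        if isinstance(val, list):
            data[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val)
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# spike CSV

def read_spike_csv(path: str | Path, session_spans: dict | None = None) -> SpikeDataset:
    """Read the canonical spike dialect: header session_id,cell_id,shank_id,time_s.

    Session spans default to (0, max spike time + 1 s) per session unless
    given explicitly (e.g. from a sidecar span file).
    """
    df = pd.read_csv(path, dtype={"session_id": str, "cell_id": str},
                     float_precision="round_trip")
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    neg = df.index[df["time_s"] < 0]
    if len(neg):
        raise ValidationError(f"{path}: negative spike time at row {neg[0]}")
    cells = []
    for (sess, cid), grp in df.groupby(["session_id", "cell_id"], sort=True):
        shanks = grp["shank_id"].unique()
        if len(shanks) > 1:
            raise ValidationError(f"cell ({sess}, {cid}) listed on several shanks")
        cells.append(
            Cell(
                cell_id=str(cid),
                session_id=str(sess),
                shank_id=int(shanks[0]),
                spike_times_s=np.sort(grp["time_s"].to_numpy(dtype=float)),
            )
        )
    if session_spans is None:
        session_spans = {}
        for sess, grp in df.groupby("session_id", sort=True):
            session_spans[str(sess)] = (0.0, float(grp["time_s"].max()) + 1.0)
    return SpikeDataset(cells=cells, session_spans=dict(session_spans))


def write_spike_csv(dataset: SpikeDataset, path: str | Path) -> None:
    rows = []
    for c in sorted(dataset.cells, key=lambda c: c.key):
        for t in c.spike_times_s:
            rows.append((c.session_id, c.cell_id, c.shank_id, t))
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(path, index=False)


def write_session_spans(dataset: SpikeDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: list(v) for k, v in sorted(dataset.session_spans.items())}, fh, indent=1)


def read_session_spans(path: str | Path) -> dict:
    with open(path) as fh:
        return {k: tuple(v) for k, v in json.load(fh).items()}


# ---------------------------------------------------------------------------
# ethogram CSV

def read_ethogram_csv(path: str | Path) -> Ethogram:
    """Read scored episodes; feeding bouts below the scoring minimum are
    dropped with a warning (they would not have been scored)."""
    df = pd.read_csv(path, dtype={"session_id": str, "behavior": str},
                     float_precision="round_trip")
    missing = [c for c in ETHOGRAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    episodes = []
    for row in df.itertuples(index=False):
        dur = float(row.end_s) - float(row.start_s)
        if row.behavior == "feeding" and dur < MIN_FEEDING_S:
            log.warning(
                "dropping feeding episode of %.2f s (< %.1f s scoring minimum) "
                "in session %s", dur, MIN_FEEDING_S, row.session_id,
            )
            continue
        episodes.append(
            Episode(
                session_id=str(row.session_id),
                behavior=str(row.behavior),
                start_s=float(row.start_s),
                end_s=float(row.end_s),
            )
        )
    return Ethogram(episodes=episodes)


def write_ethogram_csv(etho: Ethogram, path: str | Path) -> None:
    rows = [
        (e.session_id, e.behavior, e.start_s, e.end_s)
        for e in sorted(etho.episodes, key=lambda e: (e.session_id, e.start_s))
    ]
    pd.DataFrame(rows, columns=ETHOGRAM_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# flat binary LFP

def read_lfp_flat(
    path: str | Path,
    fs_hz: float = 1250.0,
    n_channels: int = 1,
    channel: int = 0,
    scale_uv_per_bit: float = 1.0,
    session_id: str = "",
) -> LfpSignal:
    """Read one channel from flat interleaved little-endian int16 binary."""
    path = Path(path)
    if channel >= n_channels:
        raise IndexError(f"channel {channel} >= n_channels {n_channels}")
    nbytes = path.stat().st_size
    frame = 2 * n_channels
    if nbytes % frame:
        raise FormatError(
            f"{path}: size {nbytes} not divisible by {frame} "
            f"(2 bytes x {n_channels} channels); truncated file?"
        )
    raw = np.fromfile(path, dtype="<i2").reshape(-1, n_channels)
    return LfpSignal(
        samples=raw[:, channel].astype(float) * scale_uv_per_bit,
        fs_hz=fs_hz,
        session_id=session_id,
    )


def write_lfp_flat(signal: LfpSignal, path: str | Path, scale_uv_per_bit: float = 1.0) -> None:
    scaled = np.round(signal.samples / scale_uv_per_bit)
    scaled = np.clip(scaled, -32768, 32767).astype("<i2")
    scaled.tofile(path)


# ---------------------------------------------------------------------------
# epochs CSV

def write_epochs_csv(epoch_sets: list, path: str | Path) -> None:
    rows = []
    for es in epoch_sets:
        for s, e in es.intervals:
            rows.append((es.session_id, es.label, s, e))
    pd.DataFrame(rows, columns=EPOCH_COLUMNS).to_csv(path, index=False)


def read_epochs_csv(path: str | Path):
    from .datatypes import EpochSet

    df = pd.read_csv(path, dtype={"session_id": str, "label": str},
                     float_precision="round_trip")
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = []
    for (sess, label), grp in df.groupby(["session_id", "label"], sort=True):
        out.append(
            EpochSet(
                label=str(label),
                session_id=str(sess),
                intervals=grp[["start_s", "end_s"]].to_numpy(dtype=float),
            )
        )
    return out
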