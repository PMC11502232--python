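"""End-to-end pipeline: features -> stability-selected clustering ->
silhouette filtering -> population naming -> LFP epoch detection -> CFR.

Every stochastic stage is seeded deterministically from the master seed, and
a log records every parameter actually used; re-running with the same config
and inputs reproduces every output file exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, cofiring, oscillations, profiles, rates
from .datatypes import Ethogram, SpikeDataset, ValidationError
from .io import (
    PipelineConfig,
    derive_seed,
    read_ethogram_csv,
    read_lfp_flat,
    read_session_spans,
    read_spike_csv,
    write_epochs_csv,
)

log = logging.getLogger("ensemble_dynamics")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def cluster_stage(dataset: SpikeDataset, etho: Ethogram, config: PipelineConfig) -> dict:
    """Features, stability scan, final clustering, silhouette filter, naming."""
    fm = rates.build_feature_matrix(
        dataset, etho,
        kernel_sd_ms=config.kernel_sd_ms,
        warp_bin_ms=config.warp_bin_ms,
        variance_target=config.variance_target,
    )
    report = clustering.stability_scan(
        fm.reduced,
        config.cluster_range,
        config.knn_range,
        n_boot=config.n_bootstrap,
        frac=config.subsample_fraction,
        seed=derive_seed(config.master_seed, "stability"),
    )
    sel = report.selected["by_mean_over_sd"] or report.selected["by_mean"]
    k, knn = sel
    log.info("selected k=%d, knn=%d (variance-adjusted criterion)", k, knn)
    solution = clustering.cluster_features(
        fm.reduced, k, knn, derive_seed(config.master_seed, "final-cluster")
    )
    sil = clustering.silhouette_filter(
        fm.reduced, k, knn,
        n_iter=config.silhouette_iters,
        min_pass=config.silhouette_min_pass,
        seed=derive_seed(config.master_seed, "silhouette"),
    )
    retained = sil["retained"]
    retained_keys = [key for key, r in zip(fm.cells, retained) if r]
    retained_labels = solution.labels[retained]
    profile = profiles.label_populations(fm.raw_vectors, retained_keys, retained_labels)
    quality = None
    if len(np.unique(solution.labels)) >= 2:
        quality = clustering.cluster_quality(fm.first_pcs(5), solution.labels)
    return {
        "features": fm,
        "stability": report,
        "selected": {"k": k, "knn": knn},
        "solution": solution,
        "silhouette": sil,
        "retained_keys": retained_keys,
        "retained_labels": retained_labels,
        "profile": profile,
        "quality": quality,
    }


def epochs_stage(lfp_by_session: dict, config: PipelineConfig) -> dict:
    """Detect slow/fast gamma events and nonrhythmic epochs per session."""
    out: dict = {}
    for sess, lfp in sorted(lfp_by_session.items()):
        slow = oscillations.detect_band_events(
            lfp, config.slow_gamma_hz, config.detect_sd, config.edge_sd,
            config.min_event_ms, label="slow_gamma")
        fast = oscillations.detect_band_events(
            lfp, config.fast_gamma_hz, config.detect_sd, config.edge_sd,
            config.min_event_ms, label="fast_gamma")
        nonr = oscillations.detect_nonrhythmic(
            lfp, config.nonrhythmic_bands_hz, config.nonrhythmic_sd,
            config.nonrhythmic_min_ms)
        out[sess] = {"slow_gamma": slow, "fast_gamma": fast, "nonrhythmic": nonr}
    return out


def cofire_stage(
    dataset: SpikeDataset,
    epochs_by_session: dict,
    config: PipelineConfig,
    populations: dict | None = None,
) -> list:
    """Per cross-shank pair: CFR and shuffle null for both gamma bands."""
    populations = populations or {}
    rows = []
    for sess in dataset.session_ids:
        if sess not in epochs_by_session:
            continue
        eps = epochs_by_session[sess]
        nonr = eps["nonrhythmic"]
        span = dataset.session_spans[sess]
        for band in ("slow_gamma", "fast_gamma"):
            gamma = eps[band]
            if not len(gamma) or not len(nonr):
                continue
            for trig_cell, resp_cell in cofiring.session_pairs(dataset, sess):
                res = cofiring.cofiring_ratio(
                    trig_cell.spike_times_s, resp_cell.spike_times_s, nonr, gamma,
                    bin_ms=config.ccg_bin_ms,
                    ccg_half_window_ms=config.ccg_half_window_ms,
                    cofire_half_window_ms=config.cofire_half_window_ms,
                    band=band, pair=(trig_cell.key, resp_cell.key),
                )
                if res is None:
                    continue
                controls = cofiring.shuffle_null(
                    trig_cell.spike_times_s, resp_cell.spike_times_s, nonr, gamma,
                    span, n=config.shuffle_n, range_s=config.shuffle_range_s,
                    seed=derive_seed(config.master_seed, "shuffle", sess, band,
                                     trig_cell.cell_id, resp_cell.cell_id),
                    bin_ms=config.ccg_bin_ms,
                    ccg_half_window_ms=config.ccg_half_window_ms,
                    cofire_half_window_ms=config.cofire_half_window_ms,
                )
                summ = cofiring.summarize_shuffles(controls)
                rows.append({
                    "session": sess,
                    "cell_a": trig_cell.cell_id,
                    "cell_b": resp_cell.cell_id,
                    "pop_a": populations.get(trig_cell.key, ""),
                    "pop_b": populations.get(resp_cell.key, ""),
                    "band": band,
                    "cfr": res.cfr,
                    "ctrl_mean": summ["mean"],
                    "ctrl_p2_5": summ["p2_5"],
                    "ctrl_p97_5": summ["p97_5"],
                })
    return rows


def run_pipeline(
    config: PipelineConfig,
    spikes_path,
    ethogram_path,
    lfp_manifest: dict | None = None,
    out_dir=".",
    session_spans_path=None,
) -> dict:
    """Full pipeline over canonical input files; writes the results bundle.

    ``lfp_manifest`` maps session_id -> flat int16 LFP path (fs from config).
    On any stage failure, partially written outputs are removed and a
    StageError names the stage and cause.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "load"
    try:
        log.info("config: %s", json.dumps(config.to_dict(), default=str))
        spans = read_session_spans(session_spans_path) if session_spans_path else None
        dataset = read_spike_csv(spikes_path, session_spans=spans)
        etho = read_ethogram_csv(ethogram_path)
        shared = set(dataset.session_spans) & {e.session_id for e in etho.episodes}
        if not shared:
            raise ValidationError("spike and ethogram files share no session ids")

        stage = "clustering"
        cl = cluster_stage(dataset, etho, config)
        labels_csv = out_dir / "labels.csv"
        retained_set = set(cl["retained_keys"])
        name_of = cl["profile"].names
        rows = []
        for key, lab in zip(cl["features"].cells, cl["solution"].labels):
            rows.append({
                "session_id": key[0], "cell_id": key[1], "cluster": int(lab),
                "population": name_of.get(int(lab), ""),
                "retained": key in retained_set,
            })
        pd.DataFrame(rows).to_csv(labels_csv, index=False)
        written.append(labels_csv)
        stab_json = out_dir / "stability.json"
        with open(stab_json, "w") as fh:
            json.dump(cl["stability"].to_jsonable(), fh, indent=1, default=str)
        written.append(stab_json)

        epochs_by_session: dict = {}
        if lfp_manifest:
            stage = "epochs"
            lfps = {
                sess: read_lfp_flat(path, fs_hz=config.lfp_fs_hz, session_id=sess)
                for sess, path in lfp_manifest.items()
            }
            epochs_by_session = epochs_stage(lfps, config)
            all_sets = [es for per in epochs_by_session.values() for es in per.values()]
            epochs_csv = out_dir / "epochs.csv"
            write_epochs_csv(all_sets, epochs_csv)
            written.append(epochs_csv)

        cfr_rows: list = []
        group_tests: dict = {}
        if epochs_by_session:
            stage = "cofiring"
            populations = {
                key: name_of.get(int(lab), "")
                for key, lab in zip(cl["retained_keys"], cl["retained_labels"])
            }
            cfr_rows = cofire_stage(dataset, epochs_by_session, config, populations)
            cfr_csv = out_dir / "cfr.csv"
            pd.DataFrame(
                cfr_rows,
                columns=["session", "cell_a", "cell_b", "pop_a", "pop_b", "band",
                         "cfr", "ctrl_mean", "ctrl_p2_5", "ctrl_p97_5"],
            ).to_csv(cfr_csv, index=False)
            written.append(cfr_csv)
            labeled = [r for r in cfr_rows if r["pop_a"] and r["pop_b"]]
            if labeled:
                group_tests = cofiring.population_pair_assembly(labeled)

        stage = "summary"
        summary = {
            "n_cells": len(dataset),
            "n_cells_clustered": len(cl["features"].cells),
            "n_cells_retained": len(cl["retained_keys"]),
            "selected": cl["selected"],
            "m_components": cl["features"].m,
            "n_bins": cl["features"].n_bins,
            "population_names": {str(k): v for k, v in name_of.items()},
            "quality": cl["quality"],
            "n_cfr_pairs": len(cfr_rows),
            "group_tests": {"|".join(k): v for k, v in group_tests.items()},
            "master_seed": config.master_seed,
        }
        summary_json = out_dir / "summary.json"
        with open(summary_json, "w") as fh:
            json.dump(summary, fh, indent=1, default=str)
        written.append(summary_json)
        return {"clustering": cl, "epochs": epochs_by_session,
                "cfr_rows": cfr_rows, "group_tests": group_tests,
                "summary": summary}
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
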