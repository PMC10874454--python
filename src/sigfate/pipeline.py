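"""End-to-end orchestration of the synthetic study.

``run_pipeline`` executes the full chain — generate histories and
markers, track a division fixture, extract sigmoid features, denoise,
call fates, quantify predictability, analyze a micropattern colony, run
the integrator ODE model and the RNA screen — writing each stage's
artifacts and a manifest (with checksums and seeds) into a run
directory. A rerun with the same configuration is bit-identical for
every deterministic stage.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffuse, fatecall, fatepredict, histfeat, integrator, io, pattern, rnascreen, synthgen, tracklink

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline"]

_KNOWN_KEYS = {
    "seed", "outdir", "n_cells", "n_track_cells", "n_track_frames",
    "n_genes", "knn", "t_diffusion", "max_disp", "division_radius",
    "colony", "history", "fate",
}


def default_config(seed: int = 0, outdir: str = "sigfate_run") -> dict:
    return {
        "seed": seed,
        "outdir": outdir,
        "n_cells": 400,
        "n_track_cells": 120,
        "n_track_frames": 40,
        "n_genes": 1200,
        "knn": 3,
        "t_diffusion": 3,
        "max_disp": 10.0,
        "division_radius": 10.0,
    }


def _validate(config: dict):
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")


def run_pipeline(config: dict | None = None) -> dict:
    """Run every stage; returns the manifest (also written to the run dir)."""
    cfg = default_config()
    cfg.update(config or {})
    _validate(cfg)
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {k: v for k, v in cfg.items()}, "stages": {}, "files": {}}

    def record(stage, **info):
        manifest["stages"][stage] = {"status": "ok", **info}

    def save(name, writer, *args):
        path = outdir / name
        writer(*args, path)
        manifest["files"][name] = io.file_checksum(path)
        return path

    try:
        # ---- generate -------------------------------------------------
        hp = dataclasses.replace(synthgen.HistoryGenParams(n_cells=int(cfg["n_cells"])), seed=seed)
        histories, truth = synthgen.gen_histories(hp, rng=synthgen.substream(seed, "histories"))
        fates = synthgen.gen_fates(truth, synthgen.FateGenParams(),
                                   rng=synthgen.substream(seed, "fates"))
        save("histories.csv", io.write_histories, histories)
        fates.to_csv(outdir / "markers.csv")
        manifest["files"]["markers.csv"] = io.file_checksum(outdir / "markers.csv")
        record("generate", n_cells=len(histories), seed=seed)

        # ---- track ----------------------------------------------------
        dets, track_truth = synthgen.gen_tracking_fixture(
            n_cells=int(cfg["n_track_cells"]), n_frames=int(cfg["n_track_frames"]),
            rng=synthgen.substream(seed, "tracking"))
        ts = tracklink.link_frames(dets, max_disp=float(cfg["max_disp"]))
        ts = tracklink.resolve_divisions(ts, division_radius=float(cfg["division_radius"]))
        metrics = tracklink.track_metrics(ts, track_truth)
        save("detections.tsv", io.write_detections, dets)
        io.write_json(ts.lineage().reset_index().to_dict(orient="records"),
                      outdir / "lineage.json")
        manifest["files"]["lineage.json"] = io.file_checksum(outdir / "lineage.json")
        record("track", **metrics)

        # ---- features -------------------------------------------------
        feats = histfeat.feature_table(histories)
        scores, comps, var = histfeat.pca_histories(histories)
        feat_out = pd.concat([feats, scores], axis=1)
        feat_out.to_csv(outdir / "features.csv")
        manifest["files"]["features.csv"] = io.file_checksum(outdir / "features.csv")
        record("features", variance_explained=[float(v) for v in var])

        # ---- denoise & fate ------------------------------------------
        denoised = diffuse.fate_based_denoise(histories, fates,
                                              knn=int(cfg["knn"]), t=int(cfg["t_diffusion"]))
        save("histories_denoised.csv", io.write_histories, denoised)
        control = diffuse.randomized_control(histories, fates, seed=seed)
        labels = fatecall.cluster_fates(fates, seed=seed)
        score = fatecall.fate_score(fates)
        record("fate", control_corr=control["corr_integral_fate"],
               amnion_fraction=float((labels == "amnion").mean()))

        # ---- predict --------------------------------------------------
        clf = fatepredict.bayes_threshold(feats["integral"], score["fate_label"],
                                          feature="integral")
        mi = fatepredict.decoder_mutual_information(clf.confusion)
        cv = fatepredict.history_classifier(histories, score["fate_label"],
                                            model="linear_sigmoid", seed=seed)
        io.write_json({"feature": clf.feature, "threshold": clf.threshold,
                       "accuracy": clf.accuracy, "confusion": clf.confusion,
                       "mi_bits": mi, "cv_accuracy": cv["cv_accuracy"]},
                      outdir / "predict.json")
        manifest["files"]["predict.json"] = io.file_checksum(outdir / "predict.json")
        record("predict", bayes_accuracy=clf.accuracy, cv_accuracy=cv["cv_accuracy"])

        # ---- pattern --------------------------------------------------
        cp = synthgen.ColonyGenParams(seed=seed)
        positions, chist, cfates, _ = synthgen.gen_colony(
            cp, rng=synthgen.substream(seed, "colony"))
        binning = pattern.radial_bin(positions, cp.radius)
        kymo = pattern.kymograph(chist, binning)
        kymo.to_csv(outdir / "kymograph.csv")
        manifest["files"]["kymograph.csv"] = io.file_checksum(outdir / "kymograph.csv")
        _, dominant = pattern.cluster_radial_histories(kymo, seed=seed)
        fmap = pattern.fate_map(fatecall.fate_score(cfates)["fate_label"], binning)
        io.write_json({"cluster_map": dominant.tolist(), "fate_map": fmap.tolist()},
                      outdir / "maps.json")
        manifest["files"]["maps.json"] = io.file_checksum(outdir / "maps.json")
        record("pattern", n_bins=binning.n_bins)

        # ---- model ----------------------------------------------------
        model = integrator.IntegratorModel(tier="full")
        sim = model.simulate(integrator.Smad4Input.step(1.0, 32.0), (0.0, 42.0))
        sim.to_csv(outdir / "integrator_sim.csv")
        manifest["files"]["integrator_sim.csv"] = io.file_checksum(outdir / "integrator_sim.csv")
        record("model", final_sox2=float(sim["SOX2"].iloc[-1]),
               final_isl1=float(sim["ISL1"].iloc[-1]))

        # ---- rnascreen ------------------------------------------------
        tc, dose, gene_truth = synthgen.gen_counts(
            n_genes=int(cfg["n_genes"]), rng=synthgen.substream(seed, "counts"))
        tc_cpm = rnascreen.cpm(tc)
        expressed = rnascreen.filter_expressed(tc_cpm)
        dynamic, thr = rnascreen.filter_dynamic(tc_cpm.loc[expressed])
        classes = rnascreen.cluster_timecourses(tc_cpm.loc[dynamic])
        screen = rnascreen.dose_response_screen(
            rnascreen.cpm(dose).loc[dynamic],
            timeseries_max=tc_cpm.loc[dynamic].max(axis=1))
        cands = rnascreen.integrator_candidates(classes, screen, gene_truth["is_tf"])
        io.write_json({"threshold": thr,
                       "class_sizes": classes.value_counts().to_dict(),
                       "candidates": cands}, outdir / "rnascreen.json")
        manifest["files"]["rnascreen.json"] = io.file_checksum(outdir / "rnascreen.json")
        record("rnascreen", n_dynamic=len(dynamic),
               n_candidates=sum(len(v) for v in cands.values()))
    except Exception as err:  # partial manifest with the failure recorded
        manifest["stages"]["error"] = {"status": "failed", "error": repr(err)}
        io.write_json(manifest, outdir / "manifest.json")
        raise

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
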