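"""End-to-end seeded pipeline: generate -> featurize -> simulate -> encode
-> map -> FBS -> decode, with a JSON report.

The default configuration is a reduced-scale session (10 modulation
archetypes, a few clips per genre, 6-s clips, ~100 simulated voxels) whose
structure mirrors the full experimental design; every stage is driven by a
single seed and is bit-reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth, design, features, encoding, maps, fbs, decoding


@dataclass
class PipelineConfig:
    seed: int = 0
    n_genres: int = 10
    train_clips_per_genre: int = 3
    test_clips_per_genre: int = 1
    clip_duration: float = 6.0
    sample_rate: int = 22050
    tr: float = 1.5
    n_train_runs: int = 2
    n_test_runs: int = 1
    test_repetitions: int = 4
    dummy_duration: float = 15.0
    n_voxels: int = 100
    tuned_fraction: float = 0.7
    snr: float = 3.0
    models: tuple = ("cochlear", "mtf", "mfcc")
    lambda_grid: tuple = (1e-1, 1e1, 1e3, 1e5)
    n_lambda_resamples: int = 5
    fdr_q: float = 0.05
    roi_resamples: int = 20
    roi_freq_threshold: float = 0.8
    # map statistics over fewer voxels than this are degenerate; fall back
    # to all voxels (reduced-session robustness; real ROIs are hundreds)
    min_roi_voxels: int = 10
    voice_nuisance: bool = True
    mtf_variance_threshold: float = 0.99

    def validate(self):
        known = {"cochlear", "mtf", "mfcc", "mirt"}
        unknown = set(self.models) - known
        if unknown:
            raise ValueError(f"unimplemented feature models: {sorted(unknown)}")
        if self.n_genres < 2 or self.snr < 0:
            raise ValueError("invalid config")
        return self


def _zscore_train_test(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def _clip_features(clip, model: str, tr: float):
    if model == "cochlear":
        return features.cochlear_features(features.cochleogram(clip), tr).values
    if model == "mtf":
        return features.mtf_energy(features.cochleogram(clip), tr).values
    if model == "mfcc":
        return features.mfcc_features(clip, tr).values
    if model == "mirt":
        return features.mirt_features(clip, tr).values
    raise ValueError(f"unknown feature model {model!r}")


def generate_stimuli(cfg: PipelineConfig):
    """Archetypes, clip inventory (manifest + waveforms), run schedule."""
    rng = np.random.default_rng(cfg.seed)
    archetypes = synth.make_archetypes(cfg.n_genres, int(rng.integers(2**31)))
    per_genre = cfg.train_clips_per_genre + cfg.test_clips_per_genre
    rows, clips = [], {}
    for a in archetypes:
        for j in range(per_genre):
            cid = f"g{a.genre_id:02d}c{j:02d}"
            cseed = int(rng.integers(2**31))
            clip = synth.synthesize_clip(
                a, cfg.clip_duration, cfg.sample_rate, cseed
            )
            clips[cid] = clip
            rows.append(
                {"clip_id": cid, "genre": a.genre_id,
                 "voice_flag": bool(clip.voice_flag), "seed": cseed}
            )
    inventory = pd.DataFrame(rows)
    n_train = cfg.n_genres * cfg.train_clips_per_genre
    schedule = design.build_schedule(
        inventory,
        n_train_runs=cfg.n_train_runs,
        n_test_runs=cfg.n_test_runs,
        clips_per_run=n_train // cfg.n_train_runs,
        test_clips_per_run=(cfg.n_genres * cfg.test_clips_per_genre
                            * cfg.test_repetitions) // cfg.n_test_runs,
        test_repetitions=cfg.test_repetitions,
        tr=cfg.tr,
        clip_duration=cfg.clip_duration,
        dummy_duration=cfg.dummy_duration,
        seed=int(rng.integers(2**31)),
    )
    return archetypes, inventory, clips, schedule


def extract_session_features(cfg: PipelineConfig, clips: dict, schedule):
    """Per-model train/test feature matrices (z-scored by training stats).

    The raw (pre-PCA) MTF matrices and the fitted reducer are kept for
    reference profiles and weight back-projection.
    """
    out = {}
    for model in cfg.models:
        per_clip = {cid: _clip_features(clip, model, cfg.tr)
                    for cid, clip in clips.items()}
        tr_raw = design.stack_clip_features(schedule, "train", per_clip)
        te_raw = design.stack_clip_features(schedule, "test", per_clip)
        tr_z, te_z = _zscore_train_test(tr_raw, te_raw)
        # train_std: standardized features in the interpretable space —
        # the units the fitted weights (after back-projection) live in,
        # hence the units reference genre profiles must use
        entry = {"train_raw": tr_raw, "test_raw": te_raw,
                 "train_std": tr_z, "train": tr_z, "test": te_z}
        if model == "mtf":
            reducer, reduced = features.mtf_reduce(tr_z, cfg.mtf_variance_threshold)
            entry["reducer"] = reducer
            entry["train"] = reduced
            entry["test"] = reducer.transform(te_z)
        out[model] = entry
    return out


def simulate_brain_responses(cfg: PipelineConfig, archetypes, schedule, feats):
    """Ground-truth brain tuned in the raw MTF space; simulated train/test
    responses (test includes the repetition structure), preprocessed."""
    rng = np.random.default_rng(cfg.seed + 1)
    sim_space = "mtf" if "mtf" in feats else cfg.models[0]
    F_sim_train = feats[sim_space]["train_raw"]
    F_sim_test = feats[sim_space]["test_raw"]
    F_sim_train, F_sim_test = _zscore_train_test(F_sim_train, F_sim_test)
    D = F_sim_train.shape[1]
    n_tuned = int(round(cfg.tuned_fraction * cfg.n_voxels))
    brain = synth.make_ground_truth_brain(
        D, cfg.n_voxels, n_tuned, archetypes, cfg.snr, int(rng.integers(2**31))
    )
    tb = design.run_boundaries(schedule, "train")
    eb = design.run_boundaries(schedule, "test")
    Fd_train = encoding.delay_embed(F_sim_train, tb)
    Fd_test = encoding.delay_embed(F_sim_test, eb)
    R_train = synth.simulate_responses(Fd_train.values, brain, int(rng.integers(2**31)))
    R_test = synth.simulate_responses(Fd_test.values, brain, int(rng.integers(2**31)))
    R_train, _ = encoding.preprocess_bold(R_train, cfg.tr, run_boundaries=tb)
    R_test, _ = encoding.preprocess_bold(R_test, cfg.tr, run_boundaries=eb)
    R_test_avg = design.average_test_repetitions(R_test, schedule)
    return brain, R_train, R_test_avg


def analyze_session(cfg: PipelineConfig, archetypes, schedule, feats, brain,
                    R_train, R_test_avg):
    """Encoding, ROI, genre maps, FBS comparison, decoding; returns report."""
    rng = np.random.default_rng(cfg.seed + 2)
    tb = design.run_boundaries(schedule, "train")
    tpc = schedule.trs_per_clip
    # averaged-test row blocks, one per test run
    avg_b, start = [], 0
    for r in schedule.test_runs():
        rows = len(set(r.clip_ids)) * tpc
        avg_b.append((start, start + rows))
        start += rows

    G_train = design.genre_label_features(schedule, "train", cfg.n_genres)
    G_test = design.genre_label_features(schedule, "test", cfg.n_genres)
    # averaged test rows follow the unique-clip order
    uniq_rows = []
    for r in schedule.test_runs():
        uniq = len(set(r.clip_ids))
        start = len(uniq_rows)
        uniq_rows.extend(r.clip_ids[:uniq])
    test_genres = np.array([schedule.genre_of[c] for c in uniq_rows])
    G_test_avg = np.repeat(np.eye(cfg.n_genres)[test_genres], tpc, axis=0)

    report = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in asdict(cfg).items()},
              "models": {}}

    # genre-label encoding model, lambda selection, ROI
    Fg_train = encoding.delay_embed(G_train.values, tb)
    Fg_test = encoding.delay_embed(G_test_avg, avg_b)
    lam_g, _ = encoding.select_lambda(
        Fg_train, R_train, cfg.lambda_grid, cfg.n_lambda_resamples,
        seed=int(rng.integers(2**31)), chunk_size=tpc,
    )
    label_model = encoding.fit_ridge(Fg_train, R_train, lam_g, "genre_label")
    label_map = encoding.evaluate(label_model, Fg_test, R_test_avg, cfg.fdr_q)
    roi = encoding.roi_from_resampling(
        Fg_train, R_train, lam_g, cfg.roi_resamples,
        freq_threshold=cfg.roi_freq_threshold, fdr_q=cfg.fdr_q,
        seed=int(rng.integers(2**31)), chunk_size=tpc,
    )
    fallback = roi.mask.sum() < cfg.min_roi_voxels
    roi_mask = np.ones(brain.n_voxels, bool) if fallback else roi.mask
    report["roi"] = {"n_voxels": int(roi.mask.sum()),
                     "fallback_all_voxels": bool(fallback)}
    report["models"]["genre_label"] = {
        "mean_roi_accuracy": float(label_map.r[roi_mask].mean()),
        "n_significant": int(label_map.q_significant.sum()),
    }

    # voice-nuisance variant of the genre-label model
    if cfg.voice_nuisance:
        V_train = design.voice_label_features(schedule, "train")
        Fv_train = encoding.delay_embed(V_train.values, tb)
        nuis_model = encoding.fit_with_nuisance(Fg_train, Fv_train, R_train, lam_g)
        pred = encoding.predict_excluding_nuisance(nuis_model, Fg_test)
        r_nuis = encoding.pearson_by_column(pred, R_test_avg)
        report["models"]["genre_label_voice_regressed"] = {
            "mean_roi_accuracy": float(r_nuis[roi_mask].mean()),
        }

    gmap = maps.average_delays(label_model, "sim")
    embedding = maps.pca_embed([gmap])
    report["genre_pca"] = {
        "explained_variance": embedding.explained_variance.tolist(),
        "top3_variance": float(embedding.explained_variance[:3].sum()),
    }

    # acoustic encoding models + FBS
    train_genre_of_row = np.array(
        [schedule.genre_of[c] for c in G_train.clip_of_row]
    )
    per_genre_r = {}
    for model in cfg.models:
        entry = feats[model]
        Fm_train = encoding.delay_embed(entry["train"], tb)
        test_avg = design.average_test_repetitions(entry["test"], schedule)
        Fm_test = encoding.delay_embed(test_avg, avg_b)
        lam_m, _ = encoding.select_lambda(
            Fm_train, R_train, cfg.lambda_grid, cfg.n_lambda_resamples,
            seed=int(rng.integers(2**31)), chunk_size=tpc,
        )
        emodel = encoding.fit_ridge(Fm_train, R_train, lam_m, model)
        amap = encoding.evaluate(emodel, Fm_test, R_test_avg, cfg.fdr_q)

        refs = fbs.genre_reference_profiles(
            entry["train_std"], train_genre_of_row, cfg.n_genres, tpc, model
        )
        basis = entry["reducer"].basis_ if "reducer" in entry else None
        tuning = fbs.voxel_tuning(emodel, basis)
        fmap = fbs.fbs_map(tuning, refs)
        r_g, r_mean = fbs.map_correspondence(fmap, gmap, roi_mask)
        per_genre_r[model] = r_g
        report["models"][model] = {
            "mean_roi_accuracy": float(amap.r[roi_mask].mean()),
            "fbs_correspondence_per_genre": r_g.tolist(),
            "fbs_correspondence_mean": r_mean,
        }

    if "mtf" in per_genre_r and len(per_genre_r) >= 2:
        comp = fbs.model_comparison(per_genre_r, reference="mtf")
        report["model_comparison"] = {
            m: {"statistic": v["statistic"], "p": v["p"]} for m, v in comp.items()
        }

    # decoding from ROI responses (future lags: hemodynamic mirror image)
    Rd_train = decoding.delay_embed_responses(R_train[:, roi_mask], tb)
    Rd_test = decoding.delay_embed_responses(R_test_avg[:, roi_mask], avg_b)
    dec = decoding.fit_decoder(
        Rd_train, G_train.values, cfg.lambda_grid, cfg.n_lambda_resamples,
        seed=int(rng.integers(2**31)), chunk_size=tpc,
    )
    tr_labels = decoding.decode_timepoints(dec, Rd_test)
    clip_pred = decoding.majority_vote(tr_labels, tpc)
    cm = decoding.confusion(test_genres, clip_pred, cfg.n_genres)
    report["decoding"] = {
        "clip_accuracy_pct": cm.accuracy,
        "confusion_matrix": cm.values.tolist(),
        "n_test_clips": int(len(test_genres)),
    }
    return report


REPORT_REQUIRED_KEYS = ("config", "roi", "models", "genre_pca", "decoding")


def validate_report(report: dict) -> bool:
    """Minimal schema check of a pipeline report."""
    return all(k in report for k in REPORT_REQUIRED_KEYS) and all(
        "mean_roi_accuracy" in m for m in report["models"].values()
    )


def run_pipeline(cfg: PipelineConfig, outdir=None) -> dict:
    """Run every stage under one seed; optionally write stage outputs and
    the JSON report under ``outdir``."""
    cfg.validate()
    t0 = time.time()
    archetypes, inventory, clips, schedule = generate_stimuli(cfg)
    feats = extract_session_features(cfg, clips, schedule)
    brain, R_train, R_test_avg = simulate_brain_responses(cfg, archetypes, schedule, feats)
    report = analyze_session(cfg, archetypes, schedule, feats, brain, R_train, R_test_avg)
    report["elapsed_s"] = round(time.time() - t0, 2)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        inventory.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        design.schedule_to_frame(schedule).to_csv(
            outdir / "schedule.tsv", sep="\t", index=False
        )
        synth.write_brain(outdir / "brain", brain)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
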