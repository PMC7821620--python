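"""Seeded validation studies: structural checks and recovery simulations.

Each function runs the package end to end at a stated problem size and
returns measured quantities — dimension counts, oracle deviations,
parameter-recovery correlations, empirical false-discovery proportions,
model-recovery win rates, decoding accuracies.  The problem sizes are
reduced relative to the full experimental design (stated per function);
every study derives all randomness from its ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synth, design, features, encoding, fbs, decoding
from .pipeline import PipelineConfig, generate_stimuli, \
    extract_session_features, simulate_brain_responses, analyze_session


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31, size=n)


def full_scale_inventory(n_genres: int = 10, clips_per_genre: int = 54) -> pd.DataFrame:
    """Manifest of the full stimulus inventory (no audio is synthesized)."""
    rows = [
        {"clip_id": f"g{g:02d}c{j:02d}", "genre": g,
         "voice_flag": bool(g % 2 == 0), "seed": 0}
        for g in range(n_genres) for j in range(clips_per_genre)
    ]
    return pd.DataFrame(rows)


def structural_counts(seed: int = 0) -> dict:
    """Exact structural counts of the full design and feature spaces.

    The schedule counts use the full 540-clip inventory (18 runs, TR 1.5 s,
    15-s clips); the feature dimensionalities are measured on one short
    synthetic clip per extractor.
    """
    inv = full_scale_inventory()
    schedule = design.build_schedule(inv, seed=seed)
    G_train = design.genre_label_features(schedule, "train")
    train_clips = schedule.unique_clips("train")
    test_clips = schedule.unique_clips("test")
    genre_of = dict(zip(inv["clip_id"], inv["genre"]))
    per_genre_train = pd.Series([genre_of[c] for c in train_clips]).value_counts()

    # averaged test rows, measured through the averaging operation itself
    n_test_rows = sum(
        len(r.clip_ids) * schedule.trs_per_clip for r in schedule.test_runs()
    )
    R_fake = np.zeros((n_test_rows, 1))
    n_avg_rows = design.average_test_repetitions(R_fake, schedule).shape[0]

    arch = synth.make_archetypes(2, seed)[0]
    clip = synth.synthesize_clip(arch, duration=6.0, seed=seed)
    coch = features.cochleogram(clip)
    counts = {
        "n_clips_total": len(inv),
        "n_train_clips": len(train_clips),
        "n_test_clips": len(test_clips),
        "train_clips_per_genre": int(per_genre_train.iloc[0]),
        "train_samples": G_train.values.shape[0],
        "test_samples_averaged": n_avg_rows,
        "volumes_per_run": design.scheduled_volumes_per_run(schedule),
        "cochlear_dim": features.cochlear_features(coch).values.shape[1],
        "mtf_raw_dim": features.mtf_energy(coch).values.shape[1],
        "mfcc_dim": features.mfcc_features(clip).values.shape[1],
        "mirt_dim": features.mirt_features(clip).values.shape[1],
    }
    return counts


def ridge_oracle_deviation(seed: int = 0, n_systems: int = 50,
                           n_rows: int = 60, n_cols: int = 8) -> float:
    """Max |W_svd - W_normal_equations| over random small ridge systems."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_systems):
        F = rng.normal(size=(n_rows, n_cols))
        R = rng.normal(size=(n_rows, 3))
        lam = 10.0 ** rng.uniform(-2, 3)
        W = encoding.RidgeEncoder(alpha=lam).fit(F, R).W_
        W_ref = np.linalg.solve(F.T @ F + lam * np.eye(n_cols), F.T @ R)
        worst = max(worst, float(np.abs(W - W_ref).max()))
    return worst


def _random_session(rng, T, D, V, n_tuned, snr):
    """Random standardized features + simulated responses for recovery."""
    archetypes = synth.make_archetypes(min(10, max(2, n_tuned or 2)),
                                       int(rng.integers(2**31)))
    F = rng.normal(size=(T, D))
    F = (F - F.mean(axis=0)) / F.std(axis=0)
    Fd = encoding.delay_embed(F)
    brain = synth.make_ground_truth_brain(
        D, V, n_tuned, archetypes, snr, int(rng.integers(2**31)), mtf_layout=False
    )
    return Fd, brain


def weight_recovery(seed: int = 0, T: int = 1200, D: int = 40, V: int = 200,
                    snr: float = 1.0, n_seeds: int = 10) -> dict:
    """Encoding-weight recovery from simulated responses.

    Noiseless check: with λ=1e-6 every tuned voxel's estimated weight
    vector must correlate > 0.999 with the truth.  Noisy check: at the
    stated SNR, the median per-voxel weight correlation over ``n_seeds``
    simulated sessions.
    """
    rng = np.random.default_rng(seed)
    Fd, brain = _random_session(rng, T, D, V, n_tuned=V, snr=1e12)
    R = Fd.values @ synth.true_weights(brain)  # exactly noiseless
    W = encoding.RidgeEncoder(alpha=1e-6).fit(Fd.values, R).W_
    W_true = synth.true_weights(brain)
    noiseless_min = float(
        min(np.corrcoef(W[:, v], W_true[:, v])[0, 1] for v in range(V))
    )

    medians = []
    for s in _child_seeds(seed + 1, n_seeds):
        rr = np.random.default_rng(int(s))
        Fd, brain = _random_session(rr, T, D, V, n_tuned=V, snr=snr)
        R = synth.simulate_responses(Fd.values, brain, int(rr.integers(2**31)))
        lam, _ = encoding.select_lambda(
            Fd, R, grid=(1e0, 1e2, 1e4), n_resamples=3,
            seed=int(rr.integers(2**31)), chunk_size=10,
        )
        W = encoding.RidgeEncoder(alpha=lam).fit(Fd.values, R).W_
        W_true = synth.true_weights(brain)
        cors = [np.corrcoef(W[:, v], W_true[:, v])[0, 1] for v in range(V)]
        medians.append(float(np.median(cors)))
    return {"noiseless_min_corr": noiseless_min,
            "noisy_median_corr": float(np.median(medians)),
            "noisy_per_seed_medians": medians}


def fdr_null_fdp(seed: int = 0, n_sims: int = 500, V: int = 500,
                 T_test: int = 100, q: float = 0.05) -> float:
    """Empirical false-discovery proportion under the global null.

    Each simulation evaluates a random prediction against independent
    noise responses; any BH discovery is false, so the mean FDP over
    simulations estimates the achieved FDR.
    """
    rng = np.random.default_rng(seed)
    fdp = []
    model = encoding.EncodingModel(np.zeros((5, 1)), 1.0, 1)
    for _ in range(n_sims):
        pred = rng.normal(size=(T_test, V))
        R = rng.normal(size=(T_test, V))
        r = encoding.pearson_by_column(pred, R)
        p = encoding.accuracy_pvalues(r, T_test)
        from statsmodels.stats.multitest import multipletests

        sig = multipletests(p, alpha=q, method="fdr_bh")[0]
        n_disc = int(sig.sum())
        fdp.append(1.0 if n_disc > 0 else 0.0)
    return float(np.mean(fdp))


def fbs_model_recovery(seed: int = 0, n_reps: int = 20) -> dict:
    """Model-comparison recovery at reduced scale.

    Responses are generated from ground-truth tuning in the raw MTF space;
    per repetition the full pipeline (2 train + 1 test clip per genre,
    6-s clips, 80 voxels, SNR 3) is run with the cochlear, MTF and MFCC
    models, and the MTF model 'wins' when its mean FBS-map/genre-weight-map
    correspondence is the largest of the three.
    """
    wins = 0
    means = []
    for s in _child_seeds(seed, n_reps):
        cfg = PipelineConfig(
            seed=int(s), n_genres=10, train_clips_per_genre=2,
            test_clips_per_genre=1, clip_duration=6.0, n_voxels=80,
            tuned_fraction=0.7, snr=3.0, models=("cochlear", "mtf", "mfcc"),
            n_lambda_resamples=3, roi_resamples=10, voice_nuisance=False,
        )
        archetypes, _, clips, schedule = generate_stimuli(cfg)
        feats = extract_session_features(cfg, clips, schedule)
        brain, R_train, R_test = simulate_brain_responses(
            cfg, archetypes, schedule, feats
        )
        report = analyze_session(cfg, archetypes, schedule, feats, brain,
                                 R_train, R_test)
        m = {name: report["models"][name]["fbs_correspondence_mean"]
             for name in ("cochlear", "mtf", "mfcc")}
        means.append(m)
        if m["mtf"] >= max(m.values()):
            wins += 1
    return {"n_reps": n_reps, "mtf_wins": wins,
            "win_fraction": wins / n_reps, "per_rep_means": means}


def _label_space_session(seed: int, V: int, snr: float, n_tuned: int,
                         n_genres: int = 10):
    """Full-size schedule with responses driven by genre-label tuning
    (no audio): the decoding test bed."""
    rng = np.random.default_rng(seed)
    inv = full_scale_inventory(n_genres)
    schedule = design.build_schedule(inv, seed=int(rng.integers(2**31)))
    G_train = design.genre_label_features(schedule, "train", n_genres)
    G_test = design.genre_label_features(schedule, "test", n_genres)
    tb = design.run_boundaries(schedule, "train")
    eb = design.run_boundaries(schedule, "test")
    archetypes = synth.make_archetypes(n_genres, int(rng.integers(2**31)))
    brain = synth.make_ground_truth_brain(
        n_genres, V, n_tuned, archetypes, max(snr, 1e-12),
        int(rng.integers(2**31)), mtf_layout=False,
    )
    if snr == 0:
        brain.tuning[:] = 0.0
        brain.roi_flags[:] = False
        brain = synth.GroundTruthBrain(
            brain.tuning, brain.delay_kernel, np.ones(V), brain.roi_flags,
            brain.archetype_of_voxel,
        )
    Fd_train = encoding.delay_embed(G_train.values, tb)
    Fd_test = encoding.delay_embed(G_test.values, eb)
    R_train = synth.simulate_responses(Fd_train.values, brain, int(rng.integers(2**31)))
    R_test = synth.simulate_responses(Fd_test.values, brain, int(rng.integers(2**31)))
    R_train, _ = encoding.preprocess_bold(R_train, run_boundaries=tb)
    R_test, _ = encoding.preprocess_bold(R_test, run_boundaries=eb)
    R_test_avg = design.average_test_repetitions(R_test, schedule)
    uniq = [c for r in schedule.test_runs()
            for c in r.clip_ids[: len(set(r.clip_ids))]]
    test_genres = np.array([schedule.genre_of[c] for c in uniq])
    return schedule, G_train, R_train, R_test_avg, test_genres, tb


def decoding_accuracy(seed: int = 0, V: int = 60, snr: float = 10.0,
                      lam: float = 100.0) -> float:
    """Clip-level decoding accuracy (%) on one label-tuned session."""
    schedule, G_train, R_train, R_test_avg, test_genres, tb = \
        _label_space_session(seed, V, snr, n_tuned=V)
    tpc = schedule.trs_per_clip
    avg_b = []
    start = 0
    for r in schedule.test_runs():
        rows = len(set(r.clip_ids)) * tpc
        avg_b.append((start, start + rows))
        start += rows
    Rd_train = decoding.delay_embed_responses(R_train, tb)
    Rd_test = decoding.delay_embed_responses(R_test_avg, avg_b)
    dec = decoding.GenreDecoder(alpha=lam).fit(Rd_train, G_train.values)
    labels = decoding.decode_timepoints(dec, Rd_test)
    clip_pred = decoding.majority_vote(labels, tpc)
    cm = decoding.confusion(test_genres, clip_pred)
    return cm.accuracy


def decoding_null(seed: int = 0, n_reps: int = 50, V: int = 40,
                  lam: float = 100.0) -> dict:
    """Mean clip accuracy (%) decoding pure-noise sessions (chance = 10%)."""
    accs = [decoding_accuracy(int(s), V=V, snr=0.0, lam=lam)
            for s in _child_seeds(seed, n_reps)]
    return {"mean_accuracy_pct": float(np.mean(accs)), "per_rep": accs}


def mtf_sanity(seed: int = 0) -> dict:
    """Physical sanity of the modulation filterbank.

    A 4-Hz amplitude-modulated 1-kHz tone must peak at the 4.0-Hz rate
    filter; a static 1-cyc/oct spectral ripple (built directly in the
    cochleogram domain) must peak at the 1.0-cyc/oct scale filter.
    """
    sr = 22050
    t = np.arange(int(6.0 * sr)) / sr
    am = (1.0 + np.sin(2 * np.pi * 4.0 * t)) * np.sin(2 * np.pi * 1000.0 * t)
    m = features.mtf_energy(features.cochleogram(synth.AudioClip(am, sr)))
    _, ri = features.modulation_peak(m)

    cfs = features.cochlear_center_freqs()
    x_oct = np.log2(cfs / cfs[0])
    prof = 1.0 + np.sin(2 * np.pi * 1.0 * x_oct)
    coch = features.Cochleogram(np.tile(prof, (300, 1)), 0.010, 0.025, cfs)
    si, _ = features.modulation_peak(features.mtf_energy(coch))
    return {"am4hz_peak_rate_hz": float(features.RATES[ri]),
            "ripple_peak_scale_cyc_oct": float(features.SCALES[si])}
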