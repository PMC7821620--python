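"""Run schedule, train/test split, label features, repetition averaging.

The default session mirrors the full experiment: 540 clips (54 per genre),
18 runs of 40 clips each (12 training, 6 test), TR 1.5 s, 15-s clips
(10 TRs each), a 15-s dummy period per run that never enters the analysis,
and each test run presenting 10 unique clips four times in the same order.
All sizes are configurable so that reduced sessions can be scheduled for
simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Run:
    role: str  # 'train' | 'test'
    clip_ids: list  # ordered clip tokens (length clips_per_run)


@dataclass
class RunSchedule:
    runs: list
    tr: float = 1.5
    clip_duration: float = 15.0
    dummy_duration: float = 15.0
    test_repetitions: int = 4
    genre_of: dict = field(default_factory=dict)  # clip_id -> genre
    voice_of: dict = field(default_factory=dict)  # clip_id -> bool

    @property
    def trs_per_clip(self) -> int:
        n = self.clip_duration / self.tr
        if abs(n - round(n)) > 1e-9:
            raise ValueError("clip duration must be a multiple of TR")
        return int(round(n))

    def train_runs(self):
        return [r for r in self.runs if r.role == "train"]

    def test_runs(self):
        return [r for r in self.runs if r.role == "test"]

    def clip_sequence(self, subset: str):
        """Ordered clip tokens over all runs of a subset (dummy excluded)."""
        runs = self.train_runs() if subset == "train" else self.test_runs()
        return [cid for r in runs for cid in r.clip_ids]

    def unique_clips(self, subset: str):
        seen, out = set(), []
        for cid in self.clip_sequence(subset):
            if cid not in seen:
                seen.add(cid)
                out.append(cid)
        return out


def build_schedule(
    inventory: pd.DataFrame,
    n_train_runs: int = 12,
    n_test_runs: int = 6,
    clips_per_run: int = 40,
    test_clips_per_run: int | None = None,
    test_repetitions: int = 4,
    tr: float = 1.5,
    clip_duration: float = 15.0,
    dummy_duration: float = 15.0,
    seed: int = 0,
    balanced: bool = True,
) -> RunSchedule:
    """Assign inventory clips to training and test runs.

    ``inventory`` needs columns ``clip_id``, ``genre`` and (optionally)
    ``voice_flag``.  Training runs each hold ``clips_per_run`` distinct
    clips with no repetition anywhere; each test run holds
    ``clips_per_run / test_repetitions`` unique clips presented
    ``test_repetitions`` times in the same order.  With ``balanced=True``
    (default) the test clips are drawn evenly across genres.
    """
    if test_clips_per_run is None:
        test_clips_per_run = clips_per_run
    if test_clips_per_run % test_repetitions != 0:
        raise ValueError("test_clips_per_run must be divisible by test_repetitions")
    test_unique_per_run = test_clips_per_run // test_repetitions
    n_train = n_train_runs * clips_per_run
    n_test = n_test_runs * test_unique_per_run
    if len(inventory) < n_train + n_test:
        raise ValueError(
            f"inventory has {len(inventory)} clips; "
            f"{n_train + n_test} required"
        )
    rng = np.random.default_rng(seed)
    inv = inventory.reset_index(drop=True)
    genres = sorted(inv["genre"].unique())

    if balanced:
        if n_test % len(genres) != 0:
            raise ValueError("balanced split needs n_test divisible by n_genres")
        per_genre_test = n_test // len(genres)
        test_ids = []
        for g in genres:
            ids = inv.loc[inv["genre"] == g, "clip_id"].to_numpy()
            test_ids.extend(rng.choice(ids, per_genre_test, replace=False))
        test_ids = list(test_ids)
    else:
        test_ids = list(rng.choice(inv["clip_id"].to_numpy(), n_test, replace=False))
    test_set = set(test_ids)
    train_pool = [c for c in inv["clip_id"] if c not in test_set]
    train_ids = list(rng.permutation(train_pool)[:n_train])

    runs = []
    for i in range(n_train_runs):
        runs.append(Run("train", train_ids[i * clips_per_run : (i + 1) * clips_per_run]))
    test_order = list(rng.permutation(test_ids))
    for i in range(n_test_runs):
        uniq = test_order[i * test_unique_per_run : (i + 1) * test_unique_per_run]
        runs.append(Run("test", uniq * test_repetitions))

    genre_of = dict(zip(inv["clip_id"], inv["genre"]))
    voice_of = (
        dict(zip(inv["clip_id"], inv["voice_flag"].astype(bool)))
        if "voice_flag" in inv
        else {c: False for c in inv["clip_id"]}
    )
    return RunSchedule(runs, tr, clip_duration, dummy_duration, test_repetitions,
                       genre_of, voice_of)


@dataclass
class LabelFeatureMatrix:
    values: np.ndarray  # (T, N) binary
    feature_names: list
    clip_of_row: np.ndarray  # (T,) clip_id per TR row

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        rows = self.values.sum(axis=1)
        if not np.allclose(rows, 1.0):
            raise ValueError("label rows must be one-hot")


def _label_matrix(schedule: RunSchedule, subset: str, value_of, names):
    tpc = schedule.trs_per_clip
    seq = schedule.clip_sequence(subset)
    n = len(names)
    values = np.zeros((len(seq) * tpc, n))
    clip_of_row = np.empty(len(seq) * tpc, dtype=object)
    for i, cid in enumerate(seq):
        col = value_of(cid)
        if not 0 <= col < n:
            raise KeyError(f"unknown label for clip {cid!r}")
        values[i * tpc : (i + 1) * tpc, col] = 1.0
        clip_of_row[i * tpc : (i + 1) * tpc] = cid
    return LabelFeatureMatrix(values, list(names), clip_of_row)


def genre_label_features(schedule: RunSchedule, subset: str, n_genres: int = 10) -> LabelFeatureMatrix:
    """One-hot genre indicators per TR (T x n_genres); dummy rows are never
    generated."""
    names = [f"genre_{g}" for g in range(n_genres)]
    return _label_matrix(schedule, subset, lambda c: int(schedule.genre_of[c]), names)


def voice_label_features(schedule: RunSchedule, subset: str) -> LabelFeatureMatrix:
    """One-hot voice indicators per TR; column order [voice, no-voice]."""
    return _label_matrix(
        schedule, subset, lambda c: 0 if schedule.voice_of[c] else 1, ["voice", "no_voice"]
    )


def stack_clip_features(schedule: RunSchedule, subset: str, features_of: dict) -> np.ndarray:
    """Stack per-clip feature matrices (each trs_per_clip x N) in schedule
    order, giving the session-level T x N feature matrix."""
    seq = schedule.clip_sequence(subset)
    return np.vstack([features_of[cid] for cid in seq])


def run_boundaries(schedule: RunSchedule, subset: str) -> list:
    """Row index ranges [(start, stop), ...] per run of a subset."""
    tpc = schedule.trs_per_clip
    runs = schedule.train_runs() if subset == "train" else schedule.test_runs()
    out, start = [], 0
    for r in runs:
        stop = start + len(r.clip_ids) * tpc
        out.append((start, stop))
        start = stop
    return out


def average_test_repetitions(R_test: np.ndarray, schedule: RunSchedule) -> np.ndarray:
    """Average the four test repetitions; one output row per unique
    (clip, TR-within-clip), in presentation order of the unique clips."""
    R_test = np.asarray(R_test, dtype=float)
    tpc = schedule.trs_per_clip
    reps = schedule.test_repetitions
    out_blocks = []
    start = 0
    for r in schedule.test_runs():
        n_tokens = len(r.clip_ids)
        if n_tokens % reps != 0:
            raise ValueError("test run length not divisible by repetitions")
        uniq = n_tokens // reps
        if r.clip_ids[:uniq] * reps != r.clip_ids:
            raise ValueError("test repetition structure violated")
        block_rows = uniq * tpc
        run_rows = n_tokens * tpc
        chunk = R_test[start : start + run_rows]
        if chunk.shape[0] != run_rows:
            raise ValueError("response rows do not match schedule")
        out_blocks.append(chunk.reshape(reps, block_rows, -1).mean(axis=0))
        start += run_rows
    if start != R_test.shape[0]:
        raise ValueError("response rows do not match schedule")
    return np.vstack(out_blocks)


def scheduled_volumes_per_run(schedule: RunSchedule) -> int:
    """Scanner volumes per (train) run: dummy volumes + clip volumes."""
    dummy = schedule.dummy_duration / schedule.tr
    if abs(dummy - round(dummy)) > 1e-9:
        raise ValueError("dummy duration must be a multiple of TR")
    clips = len(schedule.runs[0].clip_ids) if schedule.runs else 0
    return int(round(dummy)) + clips * schedule.trs_per_clip


def schedule_to_frame(schedule: RunSchedule) -> pd.DataFrame:
    """Serialize as a tidy table (run, role, position, clip_id, repetition)."""
    rows = []
    for ri, r in enumerate(schedule.runs):
        uniq = len(set(r.clip_ids))
        for pos, cid in enumerate(r.clip_ids):
            rows.append(
                {"run": ri, "role": r.role, "position": pos, "clip_id": cid,
                 "repetition": pos // uniq if r.role == "test" else 0}
            )
    return pd.DataFrame(rows)
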