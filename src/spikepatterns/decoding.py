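"""Stimulus decoding from spike patterns, and time-resolved effect sizes.

Three classifiers probe which feature of the population response carries
stimulus information:

* **mean rate** — each stimulus is summarised by its model rate vector
  ``MR_j(i) = r_j(i) / (TD * T_j/2)`` (Hz, from training trials); a test
  trial's rate vector is assigned to the nearest model in Euclidean
  distance.  Blind to everything but spike counts.
* **specificity** — a test trial scores each stimulus by
  ``SCORE_l(j) = sum_p r_l(p) * SP_p(j)`` with specificities fitted on the
  training trials; highest score wins.  Uses pattern identity but ignores
  where in the trial patterns occur.
* **trajectory** — trials are segmented into windows of ``tau`` bins, each
  window averaged into a mean model vector; per-stimulus model trajectories
  are window-wise means over training trials, and a test trial is assigned
  to the model trajectory with the smallest summed window-wise Euclidean
  distance.  Sensitive to the stimulus-locked position of patterns.

Performance is estimated by repeated random half-splits of the trials of
every stimulus into train/test halves (1,000 repeats in the full protocol);
chance level is ``1/s``.  Ties everywhere resolve to the lowest stimulus
index, deterministically.

Time-resolved analysis slides the trajectory window (step <= 5 ms) and
compares, at each time, a test trial's distance to its own stimulus's model
trajectory (``d_T``) versus the models of the other stimuli (``d_O``),
standardised as Cohen's d with the pooled SD over test trials:

    d(t) = (d_O(t) - d_T(t)) / sqrt((sd_T(t)^2 + sd_O(t)^2) / 2)

Positive d means the trial is reliably closer to its true stimulus's model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .activation import build_activity_vectors
from .datasets import SpikeDataset
from .som import ModelTrialSet, SomConfig, SomMap, assign_patterns, train_som
from .specificity import pattern_specificity

__all__ = [
    "SplitPlan",
    "RateModel",
    "TrajectoryModel",
    "EffectSizeTimecourse",
    "split_half",
    "mean_rate_classify",
    "specificity_classify",
    "build_trajectory",
    "sliding_trajectory",
    "model_trajectories",
    "trajectory_classify",
    "Prepared",
    "prepare",
    "classify_split",
    "run_performance",
    "jitter_performance",
    "time_resolved_distances",
    "cohens_d_timecourse",
    "one_sample_z",
]


@dataclass
class SplitPlan:
    """Disjoint train/test trial-id sets per stimulus."""

    stimulus_set: list
    train: dict
    test: dict
    seed: int = 0

    def __post_init__(self) -> None:
        for j in self.stimulus_set:
            if set(self.train[j]) & set(self.test[j]):
                raise ValueError(f"stimulus {j!r}: train/test overlap")

    @property
    def train_ids(self) -> set:
        return {t for ids in self.train.values() for t in ids}

    @property
    def test_ids(self) -> set:
        return {t for ids in self.test.values() for t in ids}


def split_half(ds: SpikeDataset, seed: int) -> SplitPlan:
    """Random half-split of each stimulus's trials; with an odd trial count
    the extra trial goes to the training half."""
    rng = np.random.default_rng(seed)
    train, test = {}, {}
    for j in ds.stimulus_set:
        ids = [t.trial_id for t in ds.trials_of(j)]
        if len(ids) < 2:
            raise ValueError(f"stimulus {j!r} has fewer than 2 trials")
        perm = rng.permutation(len(ids))
        n_train = int(np.ceil(len(ids) / 2))
        train[j] = [ids[i] for i in perm[:n_train]]
        test[j] = [ids[i] for i in perm[n_train:]]
    return SplitPlan(list(ds.stimulus_set), train, test, seed)


# ---------------------------------------------------------------- mean rate


@dataclass
class RateModel:
    """Per-stimulus mean-rate vectors ``MR_j(i)`` in Hz."""

    stimulus_set: list
    mr: np.ndarray  # (s, n)


def _trial_counts(ds: SpikeDataset) -> dict[int, np.ndarray]:
    return {t.trial_id: np.array([len(s) for s in t.spikes], dtype=float)
            for t in ds.trials}


def mean_rate_classify(ds: SpikeDataset, plan: SplitPlan) -> dict[int, object]:
    """Nearest-model-rate-vector classification of the test trials.

    Returns ``{test trial_id: predicted stimulus}``.
    """
    TD_s = ds.trial_duration_ms / 1000.0
    counts = _trial_counts(ds)
    mr = []
    for j in plan.stimulus_set:
        ids = plan.train[j]
        if not ids:
            raise ValueError(f"stimulus {j!r}: empty training set")
        total = np.sum([counts[t] for t in ids], axis=0)
        mr.append(total / (TD_s * len(ids)))
    mr = np.asarray(mr)
    pred = {}
    for j in plan.stimulus_set:
        for tid in plan.test[j]:
            rv = counts[tid] / TD_s
            d2 = ((mr - rv) ** 2).sum(axis=1)
            pred[tid] = plan.stimulus_set[int(np.argmin(d2))]
    return pred


# -------------------------------------------------------------- specificity


def specificity_classify(mts: ModelTrialSet, plan: SplitPlan) -> dict[int, object]:
    """Specificity-score classification of the test trials.

    Specificities are fitted on the training trials only; patterns unseen
    in training contribute zero score.
    """
    table = pattern_specificity(mts, plan.stimulus_set, trial_subset=plan.train_ids)
    sp = table.sp_lookup(mts.som.n_patterns)  # (patterns, s)
    pred = {}
    test_ids = plan.test_ids
    for tid, pids in zip(mts.trial_ids, mts.pattern_ids):
        if tid not in test_ids:
            continue
        r = np.bincount(pids, minlength=mts.som.n_patterns)
        scores = r @ sp
        pred[tid] = plan.stimulus_set[int(np.argmax(scores))]
    return pred


# --------------------------------------------------------------- trajectory


@dataclass
class TrajectoryModel:
    """Per-stimulus model trajectories of window-averaged model vectors."""

    stimulus_set: list
    mt: dict  # stimulus -> (Nw, n)
    tau_bins: int

    @property
    def n_windows(self) -> int:
        return next(iter(self.mt.values())).shape[0]


def build_trajectory(pattern_ids: np.ndarray, som: SomMap, tau_bins: int) -> np.ndarray:
    """Window-average the model vectors of a pattern sequence.

    Non-overlapping windows of ``tau_bins`` samples; a trailing partial
    window is dropped.  Returns ``(Nw, n)`` with ``Nw = samples // tau_bins``.
    """
    if tau_bins < 1:
        raise ValueError("tau_bins must be >= 1")
    if tau_bins > len(pattern_ids):
        raise ValueError("tau_bins exceeds number of samples")
    nw = len(pattern_ids) // tau_bins
    mv = som.model_vectors[pattern_ids[: nw * tau_bins]]
    return mv.reshape(nw, tau_bins, -1).mean(axis=1)


def sliding_trajectory(
    pattern_ids: np.ndarray, som: SomMap, win_bins: int, step_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping-window version: returns ``(centers_bins, (Nw, n))`` where
    windows of ``win_bins`` start every ``step_bins`` samples."""
    if win_bins < 1 or step_bins < 1:
        raise ValueError("win_bins and step_bins must be >= 1")
    mv = som.model_vectors[pattern_ids]
    csum = np.vstack([np.zeros((1, mv.shape[1])), np.cumsum(mv, axis=0)])
    starts = np.arange(0, len(pattern_ids) - win_bins + 1, step_bins)
    out = (csum[starts + win_bins] - csum[starts]) / win_bins
    centers = starts + win_bins / 2.0
    return centers, out


def model_trajectories(
    trajectories: dict[int, np.ndarray], labels: dict[int, object], stimulus_set
) -> TrajectoryModel:
    """Average trajectories of same-stimulus (training) trials window-wise."""
    nw = {t.shape[0] for t in trajectories.values()}
    if len(nw) > 1:
        raise ValueError(f"trajectories have mismatched window counts: {sorted(nw)}")
    mt = {}
    for j in stimulus_set:
        ids = [tid for tid in trajectories if labels[tid] == j]
        if not ids:
            raise ValueError(f"stimulus {j!r}: no trajectories")
        mt[j] = np.mean([trajectories[tid] for tid in ids], axis=0)
    tau_bins = 0  # filled by callers that know it; not needed for classification
    return TrajectoryModel(list(stimulus_set), mt, tau_bins)


def trajectory_classify(
    test_trajectories: dict[int, np.ndarray], model: TrajectoryModel
) -> dict[int, object]:
    """Assign each test trajectory to the model with the smallest summed
    window-wise Euclidean distance."""
    mt = np.stack([model.mt[j] for j in model.stimulus_set])  # (s, Nw, n)
    pred = {}
    for tid, traj in test_trajectories.items():
        if traj.shape != mt.shape[1:]:
            raise ValueError(
                f"trial {tid}: trajectory shape {traj.shape} != model {mt.shape[1:]}"
            )
        dt = np.linalg.norm(traj[None] - mt, axis=2).sum(axis=1)  # (s,)
        pred[tid] = model.stimulus_set[int(np.argmin(dt))]
    return pred


# ------------------------------------------------------- performance harness


@dataclass
class Prepared:
    """Per-(dataset, tau) artifacts shared by all splits: the trained map,
    the model trials, and the per-trial trajectories."""

    ds: SpikeDataset
    som: SomMap
    mts: ModelTrialSet
    tau_bins: int
    trajectories: dict[int, np.ndarray] = field(default_factory=dict)
    labels: dict[int, object] = field(default_factory=dict)


def prepare(
    ds: SpikeDataset,
    tau_ms: float,
    som_config: SomConfig | None = None,
    dt_ms: float = 1.0,
) -> Prepared:
    """Run the pattern chain once for a given timescale: filter, train the
    map, assign patterns, and precompute per-trial trajectories (window size
    equal to the integration constant, in bins)."""
    series = build_activity_vectors(ds, tau_ms, dt_ms)
    cfg = som_config or SomConfig()
    X = np.concatenate([s.vectors for s in series], axis=0)
    som = train_som(X, cfg)
    mts = assign_patterns(som, series)
    tau_bins = max(1, int(round(tau_ms / dt_ms)))
    trajs = {
        tid: build_trajectory(pids, som, tau_bins)
        for tid, pids in zip(mts.trial_ids, mts.pattern_ids)
    }
    labels = dict(zip(mts.trial_ids, mts.stimuli))
    return Prepared(ds, som, mts, tau_bins, trajs, labels)


CLASSIFIERS = ("rate", "specificity", "trajectory")


def classify_split(prep: Prepared, plan: SplitPlan, classifier) -> float:
    """Fraction of test trials classified correctly under one split.

    ``classifier`` is one of :data:`CLASSIFIERS` or a callable
    ``(prep, plan) -> {trial_id: predicted stimulus}``.
    """
    if callable(classifier):
        pred = classifier(prep, plan)
    elif classifier == "rate":
        pred = mean_rate_classify(prep.ds, plan)
    elif classifier == "specificity":
        pred = specificity_classify(prep.mts, plan)
    elif classifier == "trajectory":
        train = {tid: prep.trajectories[tid] for tid in plan.train_ids}
        model = model_trajectories(train, prep.labels, plan.stimulus_set)
        test = {tid: prep.trajectories[tid] for tid in plan.test_ids}
        pred = trajectory_classify(test, model)
    else:
        raise ValueError(f"unknown classifier {classifier!r}; use one of {CLASSIFIERS}")
    correct = sum(pred[tid] == prep.labels[tid] for tid in pred)
    return correct / len(pred)


@dataclass
class PerformanceResult:
    classifier: str
    tau_ms: float
    mean: float
    sd: float
    per_split: np.ndarray
    chance: float


def run_performance(
    ds: SpikeDataset,
    classifier: str,
    tau_ms: float,
    n_splits: int = 1000,
    seed: int = 0,
    som_config: SomConfig | None = None,
    dt_ms: float = 1.0,
    prep: Prepared | None = None,
) -> PerformanceResult:
    """Mean +/- SD fraction correct over repeated random half-splits.

    The pattern chain (map training, assignment, trajectories) runs once per
    dataset-condition and is reused across splits; pass ``prep`` to share it
    across classifiers.  Chance level is ``1/s``.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if prep is None:
        prep = prepare(ds, tau_ms, som_config, dt_ms)
    split_seeds = np.random.default_rng(seed).integers(0, 2**31, size=n_splits)
    perf = np.array(
        [classify_split(prep, split_half(ds, int(s)), classifier) for s in split_seeds]
    )
    return PerformanceResult(
        classifier, tau_ms, float(perf.mean()),
        float(perf.std(ddof=1)) if n_splits > 1 else 0.0,
        perf, 1.0 / ds.s,
    )


def jitter_performance(
    ds: SpikeDataset,
    classifier: str,
    tau_ms: float,
    jitter_sd_ms: float,
    n_jitters: int = 20,
    n_splits: int = 20,
    seed: int = 0,
    som_config: SomConfig | None = None,
    dt_ms: float = 1.0,
) -> np.ndarray:
    """Average performance per independent jitter realisation.

    For each of ``n_jitters`` independent jitters the whole chain is rebuilt
    (map included) on the jittered data and performance is averaged over
    ``n_splits`` half-splits; the returned array (one mean per jitter)
    carries the variability attributable to the jittering itself.
    """
    from .datasets import jitter_spikes

    rng = np.random.default_rng(seed)
    means = []
    for _ in range(n_jitters):
        jseed = int(rng.integers(0, 2**31))
        jds = jitter_spikes(ds, jitter_sd_ms, jseed)
        cfg = som_config or SomConfig()
        res = run_performance(
            jds, classifier, tau_ms, n_splits,
            seed=int(rng.integers(0, 2**31)), som_config=cfg, dt_ms=dt_ms,
        )
        means.append(res.mean)
    return np.asarray(means)


# -------------------------------------------------- time-resolved distances


@dataclass
class EffectSizeTimecourse:
    times_ms: np.ndarray
    d_true: np.ndarray
    d_other: np.ndarray
    sd_true: np.ndarray
    sd_other: np.ndarray
    cohens_d: np.ndarray


def time_resolved_distances(
    prep: Prepared,
    plan: SplitPlan,
    stimulus,
    win_bins: int | None = None,
    step_ms: float = 5.0,
):
    """Sliding-window distances of test trials to the true vs. other models.

    At each window centre ``t``: ``d_T(t)`` is the mean over test trials of
    stimulus ``stimulus`` of the distance to that stimulus's model
    trajectory; ``d_O(t)`` averages, per trial, the distances to the models
    of the other ``s - 1`` stimuli and then over test trials.  SDs are over
    test trials (for ``d_O``, of the per-trial means).  Windows slide with
    step <= 5 ms by default.
    """
    if prep.ds.s < 2:
        raise ValueError("need at least 2 stimuli")
    win = win_bins if win_bins is not None else prep.tau_bins
    dt = prep.mts.dt_ms
    step_bins = max(1, int(round(step_ms / dt)))
    slid = {
        tid: sliding_trajectory(pids, prep.som, win, step_bins)
        for tid, pids in zip(prep.mts.trial_ids, prep.mts.pattern_ids)
    }
    centers = next(iter(slid.values()))[0] * dt
    # model trajectories from training trials, at the same sliding windows
    mt = {}
    for j in plan.stimulus_set:
        ids = plan.train[j]
        mt[j] = np.mean([slid[tid][1] for tid in ids], axis=0)
    test_ids = plan.test[stimulus]
    d_true = np.array([
        np.linalg.norm(slid[tid][1] - mt[stimulus], axis=1) for tid in test_ids
    ])  # (trials, Nw)
    others = [j for j in plan.stimulus_set if j != stimulus]
    d_other = np.array([
        np.mean([np.linalg.norm(slid[tid][1] - mt[j], axis=1) for j in others], axis=0)
        for tid in test_ids
    ])
    return (
        centers,
        d_true.mean(axis=0),
        d_other.mean(axis=0),
        d_true.std(axis=0, ddof=1),
        d_other.std(axis=0, ddof=1),
    )


def cohens_d_timecourse(
    d_true: np.ndarray, d_other: np.ndarray, sd_true: np.ndarray, sd_other: np.ndarray
) -> np.ndarray:
    """Standardised margin ``(d_O - d_T) / s_pooled`` per time point, with
    ``s_pooled = sqrt((sd_T^2 + sd_O^2) / 2)``; defined as 0 where both SDs
    vanish and the means agree."""
    d_true, d_other = np.asarray(d_true, float), np.asarray(d_other, float)
    sd_true, sd_other = np.asarray(sd_true, float), np.asarray(sd_other, float)
    if np.any(sd_true < 0) or np.any(sd_other < 0):
        raise ValueError("SDs must be non-negative")
    pooled = np.sqrt((sd_true**2 + sd_other**2) / 2.0)
    diff = d_other - d_true
    d = np.where(pooled > 0, diff / np.where(pooled > 0, pooled, 1.0), 0.0)
    degenerate = (pooled == 0) & (diff != 0)
    if np.any(degenerate):
        d = np.where(degenerate, np.where(diff > 0, np.inf, -np.inf), d)
    return d


def effect_size_timecourse(prep: Prepared, plan: SplitPlan, stimulus,
                           win_bins: int | None = None,
                           step_ms: float = 5.0) -> EffectSizeTimecourse:
    """Convenience wrapper: distances plus their Cohen's d in one object."""
    t, dT, dO, sT, sO = time_resolved_distances(prep, plan, stimulus, win_bins, step_ms)
    return EffectSizeTimecourse(t, dT, dO, sT, sO, cohens_d_timecourse(dT, dO, sT, sO))


# ------------------------------------------------------------------ Z-test


def one_sample_z(values, mu0: float) -> tuple[float, float]:
    """One-sample location Z-test of ``mean(values) == mu0``.

    ``z = (mean - mu0) / (SD / sqrt(n))`` with the sample SD (ddof=1);
    two-sided p from the standard normal.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    z = (values.mean() - mu0) / (sd / np.sqrt(values.size))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
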