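"""Pattern specificity, thresholded sequences, and pattern-triggered rasters.

The specificity of pattern *p* for stimulus *j* is the fraction of its
occurrences that fall in trials of *j*:

    SP_p(j) = r_p(j) / sum_c r_p(c)

where ``r_p(j)`` counts occurrences of *p* over all trials of stimulus *j*,
one occurrence per sample of the model trial.  SP ranges from 0 (never
occurs for that stimulus) to 1 (occurs only for it) and sums to 1 across
the stimulus set; with ``s`` equally likely stimuli the chance level is
``1/s``.  Patterns that never occur carry no specificity row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import SpikeDataset
from .som import ModelTrialSet

__all__ = [
    "SpecificityTable",
    "pattern_specificity",
    "threshold_sequences",
    "ptsr_histogram",
    "first_occurrence_jitter",
]

MASKED = -1


@dataclass
class SpecificityTable:
    """Occurrence counts and specificities of the observed patterns.

    ``counts`` and ``sp`` are ``(n_observed_patterns, s)`` arrays aligned
    with ``pattern_index`` (the observed pattern ids, ascending) and
    ``stimulus_set``.
    """

    pattern_index: np.ndarray
    stimulus_set: list
    counts: np.ndarray
    sp: np.ndarray

    @classmethod
    def from_counts(cls, counts: np.ndarray, stimulus_set=None,
                    pattern_index=None) -> "SpecificityTable":
        """Build a table directly from a (patterns x stimuli) count matrix;
        all-zero rows are dropped (no occurrences, no specificity)."""
        counts = np.atleast_2d(np.asarray(counts, dtype=float))
        if np.any(counts < 0):
            raise ValueError("occurrence counts must be non-negative")
        if stimulus_set is None:
            stimulus_set = list(range(counts.shape[1]))
        if pattern_index is None:
            pattern_index = np.arange(counts.shape[0])
        totals = counts.sum(axis=1)
        observed = totals > 0
        counts = counts[observed]
        sp = counts / counts.sum(axis=1, keepdims=True)
        return cls(np.asarray(pattern_index)[observed], list(stimulus_set), counts, sp)

    @property
    def s(self) -> int:
        return len(self.stimulus_set)

    def specificity_of(self, pattern_id: int, stimulus) -> float:
        row = np.flatnonzero(self.pattern_index == pattern_id)
        if row.size == 0:
            raise KeyError(f"pattern {pattern_id} never observed")
        return float(self.sp[row[0], self.stimulus_set.index(stimulus)])

    def sp_lookup(self, n_patterns: int) -> np.ndarray:
        """Dense ``(n_patterns, s)`` SP matrix; unobserved patterns get 0."""
        out = np.zeros((n_patterns, self.s))
        out[self.pattern_index] = self.sp
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.pattern_index):
            for j, stim in enumerate(self.stimulus_set):
                rows.append((int(p), stim, self.counts[i, j], self.sp[i, j]))
        return pd.DataFrame(rows, columns=["pattern_id", "stimulus", "count", "specificity"])


def _occurrence_counts(mts: ModelTrialSet, stimulus_set, trial_subset=None) -> np.ndarray:
    n_patterns = mts.som.n_patterns
    counts = np.zeros((n_patterns, len(stimulus_set)))
    stim_idx = {stim: j for j, stim in enumerate(stimulus_set)}
    for tid, stim, pids in zip(mts.trial_ids, mts.stimuli, mts.pattern_ids):
        if trial_subset is not None and tid not in trial_subset:
            continue
        if stim not in stim_idx:
            raise ValueError(f"trial {tid}: stimulus {stim!r} not in stimulus set")
        counts[:, stim_idx[stim]] += np.bincount(pids, minlength=n_patterns)
    return counts


def pattern_specificity(
    mts: ModelTrialSet, stimulus_set=None, trial_subset=None
) -> SpecificityTable:
    """Compute SP_p(j) from model trials; each sample is one occurrence.

    ``trial_subset`` restricts the counting to a set of trial ids (used to
    fit specificities on training trials only).
    """
    if stimulus_set is None:
        stimulus_set = sorted(set(mts.stimuli), key=str)
    counts = _occurrence_counts(mts, stimulus_set, trial_subset)
    if counts.sum() == 0:
        raise ValueError("no pattern occurrences to compute specificity from")
    return SpecificityTable.from_counts(counts, stimulus_set)


def threshold_sequences(
    mts: ModelTrialSet, table: SpecificityTable, stimulus, threshold: float
) -> dict[int, np.ndarray]:
    """Mask the model trials of one stimulus by pattern specificity.

    Samples whose pattern has ``SP_p(stimulus) > threshold`` keep their id;
    all others become :data:`MASKED`.  Lowering the threshold only ever
    unmasks more samples.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    if stimulus not in table.stimulus_set:
        raise ValueError(f"unknown stimulus {stimulus!r}")
    sp = table.sp_lookup(mts.som.n_patterns)[:, table.stimulus_set.index(stimulus)]
    out = {}
    for tid, stim, pids in zip(mts.trial_ids, mts.stimuli, mts.pattern_ids):
        if stim != stimulus:
            continue
        out[tid] = np.where(sp[pids] > threshold, pids, MASKED)
    return out


def ptsr_histogram(
    ds: SpikeDataset, occurrences: list[tuple[int, float]], window_ms: float = 30.0
) -> np.ndarray:
    """Pattern-triggered spike-raster histogram.

    For each occurrence time ``t_i`` (per trial), binarize each unit's spikes
    in the ``window_ms`` window before ``t_i`` — 1 ms bins covering
    ``(t_i - window, t_i]`` — and sum across occurrences.  Returns a
    ``(n_units, window_ms)`` integer matrix; every entry is at most the
    number of occurrences.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    n_bins = int(np.ceil(window_ms))
    hist = np.zeros((ds.n, n_bins), dtype=int)
    by_id = {t.trial_id: t for t in ds.trials}
    for tid, t_i in occurrences:
        if tid not in by_id:
            raise ValueError(f"unknown trial id {tid}")
        if not 0 <= t_i < ds.trial_duration_ms:
            raise ValueError(f"occurrence time {t_i} outside trial bounds")
        tr = by_id[tid]
        for u, st in enumerate(tr.spikes):
            rel = t_i - st  # lag before the occurrence
            sel = (rel >= 0) & (rel < window_ms)
            if not sel.any():
                continue
            # bin b covers lags [b, b+1); binarize per bin before summing
            bins = np.unique(np.floor(rel[sel]).astype(int))
            hist[u, bins] += 1
    return hist


def first_occurrence_jitter(
    mts: ModelTrialSet, pattern_id: int, stimulus
) -> tuple[dict[int, float], float, int]:
    """First-occurrence times of a pattern across the trials of a stimulus.

    Returns ``(first_times, range_ms, n_trials_containing)`` where
    ``first_times`` maps trial id to the earliest sample time (ms) at which
    the pattern appears and ``range_ms`` is their max - min: the
    stimulus-locking jitter of the pattern.
    """
    first = {}
    for tid, stim, pids in zip(mts.trial_ids, mts.stimuli, mts.pattern_ids):
        if stim != stimulus:
            continue
        hit = np.flatnonzero(pids == pattern_id)
        if hit.size:
            first[tid] = float(hit[0] * mts.dt_ms)
    if not first:
        raise ValueError(
            f"pattern {pattern_id} absent from all trials of stimulus {stimulus!r}"
        )
    times = np.array(list(first.values()))
    return first, float(times.max() - times.min()), len(first)
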