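"""Spike-train data model, file I/O, and surrogate-data controls.

A :class:`SpikeDataset` holds simultaneously recorded spike trains organised
as trials, each labelled with the stimulus that evoked it.  Spike times are
milliseconds from trial onset, stored as floats, strictly inside
``[0, trial_duration_ms)``.

Three control manipulations used to probe what carries stimulus information
are implemented here:

* :func:`jitter_spikes` — displace every spike independently by Gaussian
  noise, destroying temporal structure finer than the jitter SD;
* :func:`shuffle_windows` — permute fixed-length windows of the trial,
  destroying the position of activity within the trial while preserving its
  local structure;
* :func:`remove_bursts` — keep only the first spike of each burst
  (consecutive inter-spike intervals below a threshold, 8 ms by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Trial",
    "SpikeDataset",
    "read_spikes",
    "write_spikes",
    "jitter_spikes",
    "shuffle_windows",
    "remove_bursts",
]


@dataclass
class Trial:
    """One trial: a stimulus label and per-unit sorted spike-time arrays (ms)."""

    trial_id: int
    stimulus: object
    spikes: list[np.ndarray]

    def spike_count(self) -> int:
        return int(sum(len(s) for s in self.spikes))


@dataclass
class SpikeDataset:
    """Trials of per-unit spike times with stimulus labels.

    Attributes
    ----------
    units:
        Unit identifiers ``0..n-1``.
    trials:
        List of :class:`Trial`; each ``trial.spikes`` has one array per unit.
    stimulus_set:
        Ordered list of the ``s`` distinct stimulus labels.
    trial_duration_ms:
        Common trial duration ``TD`` (ms); every spike time lies in
        ``[0, TD)``.
    """

    units: list[int]
    trials: list[Trial]
    stimulus_set: list
    trial_duration_ms: float
    epochs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n(self) -> int:
        return len(self.units)

    @property
    def s(self) -> int:
        return len(self.stimulus_set)

    def trials_of(self, stimulus) -> list[Trial]:
        return [t for t in self.trials if t.stimulus == stimulus]

    def trial_counts(self) -> dict:
        """Number of trials per stimulus (``T_j``)."""
        return {j: len(self.trials_of(j)) for j in self.stimulus_set}

    def validate(self) -> None:
        if self.trial_duration_ms <= 0:
            raise ValueError("trial_duration_ms must be positive")
        if self.units != list(range(len(self.units))):
            raise ValueError("units must be consecutive integers 0..n-1")
        seen = set()
        for tr in self.trials:
            if tr.trial_id in seen:
                raise ValueError(f"duplicate trial_id {tr.trial_id}")
            seen.add(tr.trial_id)
            if tr.stimulus not in self.stimulus_set:
                raise ValueError(
                    f"trial {tr.trial_id}: stimulus {tr.stimulus!r} not in stimulus_set"
                )
            if len(tr.spikes) != self.n:
                raise ValueError(
                    f"trial {tr.trial_id}: expected {self.n} spike trains, "
                    f"got {len(tr.spikes)}"
                )
            for u, st in enumerate(tr.spikes):
                st = np.asarray(st, dtype=float)
                tr.spikes[u] = st
                if st.size == 0:
                    continue
                if np.any(np.diff(st) < 0):
                    raise ValueError(f"trial {tr.trial_id}, unit {u}: spikes not sorted")
                if st[0] < 0 or st[-1] >= self.trial_duration_ms:
                    raise ValueError(
                        f"trial {tr.trial_id}, unit {u}: spike outside "
                        f"[0, {self.trial_duration_ms})"
                    )

    def copy(self) -> "SpikeDataset":
        trials = [
            Trial(t.trial_id, t.stimulus, [s.copy() for s in t.spikes])
            for t in self.trials
        ]
        return replace(self, trials=trials, epochs=dict(self.epochs))


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_spikes(ds: SpikeDataset, path: str | Path) -> None:
    """Write a dataset as a spike CSV plus a YAML metadata sidecar."""
    path = Path(path)
    rows = []
    for tr in ds.trials:
        for u, st in enumerate(tr.spikes):
            for t in st:
                rows.append((tr.trial_id, tr.stimulus, u, t))
    df = pd.DataFrame(rows, columns=["trial_id", "stimulus", "unit", "time_ms"])
    df.to_csv(path, index=False)
    meta = {
        "n": ds.n,
        "TD": float(ds.trial_duration_ms),
        "stimulus_set": list(ds.stimulus_set),
        "trials": [
            {"trial_id": int(t.trial_id), "stimulus": t.stimulus} for t in ds.trials
        ],
        "epochs": ds.epochs,
    }
    with open(_meta_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_spikes(path: str | Path, meta_path: str | Path | None = None) -> SpikeDataset:
    """Read a spike CSV (columns ``trial_id,stimulus,unit,time_ms``) plus its
    YAML sidecar (``n``, ``TD``, ``stimulus_set``, trial list, epochs).

    Rows out of time order are sorted; a spike time at or beyond ``TD`` is a
    validation error naming the offending row.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _meta_path(path)
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    n = int(meta["n"])
    TD = float(meta["TD"])
    stimulus_set = list(meta["stimulus_set"])

    df = pd.read_csv(path)
    required = {"trial_id", "stimulus", "unit", "time_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spike file missing columns: {sorted(missing)}")
    bad = df.index[(df["time_ms"] < 0) | (df["time_ms"] >= TD)]
    if len(bad):
        raise ValueError(f"row {bad[0]}: time_ms outside [0, {TD})")

    trial_meta = meta.get("trials")
    if trial_meta is None:
        trial_meta = [
            {"trial_id": int(tid), "stimulus": grp["stimulus"].iloc[0]}
            for tid, grp in df.groupby("trial_id")
        ]

    grouped = {
        (tid, u): np.sort(grp["time_ms"].to_numpy(dtype=float))
        for (tid, u), grp in df.groupby(["trial_id", "unit"])
    }
    trials = []
    for tm in trial_meta:
        tid = int(tm["trial_id"])
        spikes = [grouped.get((tid, u), np.empty(0)) for u in range(n)]
        trials.append(Trial(tid, tm["stimulus"], spikes))
    return SpikeDataset(
        units=list(range(n)),
        trials=trials,
        stimulus_set=stimulus_set,
        trial_duration_ms=TD,
        epochs=meta.get("epochs") or {},
    )


def jitter_spikes(ds: SpikeDataset, sd_ms: float, seed: int) -> SpikeDataset:
    """Displace each spike by an independent Gaussian draw of SD ``sd_ms``.

    Spikes pushed outside ``[0, TD)`` are reflected back into range so that
    per-(trial, unit) counts and local densities are preserved.  ``sd_ms=0``
    returns a bit-exact copy.
    """
    if sd_ms < 0:
        raise ValueError("sd_ms must be non-negative")
    out = ds.copy()
    if sd_ms == 0:
        return out
    rng = np.random.default_rng(seed)
    TD = ds.trial_duration_ms
    for tr in out.trials:
        for u, st in enumerate(tr.spikes):
            if st.size == 0:
                continue
            t = st + rng.normal(0.0, sd_ms, size=st.size)
            # reflect into [0, TD): fold over period 2*TD
            t = np.abs(t) % (2 * TD)
            t = np.where(t >= TD, 2 * TD - t, t)
            t = np.minimum(t, np.nextafter(TD, 0.0))
            tr.spikes[u] = np.sort(t, kind="stable")
    return out


def shuffle_windows(ds: SpikeDataset, window_ms: float, seed: int) -> SpikeDataset:
    """Permute consecutive ``window_ms`` windows of each trial independently.

    Spikes move rigidly with their window; a trailing partial window (when
    ``window_ms`` does not divide TD) stays in place.  Uses one RNG stream
    per trial so the permutations are independent and reproducible.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    TD = ds.trial_duration_ms
    n_win = int(TD // window_ms)
    out = ds.copy()
    streams = np.random.SeedSequence(seed).spawn(len(out.trials))
    for tr, ss in zip(out.trials, streams):
        perm = np.random.default_rng(ss).permutation(n_win)
        # new start of original window w is window_ms * position of w in perm
        dest = np.empty(n_win)
        dest[perm] = np.arange(n_win) * window_ms
        for u, st in enumerate(tr.spikes):
            if st.size == 0:
                continue
            w = np.minimum((st // window_ms).astype(int), n_win)  # tail kept
            offs = st - w * window_ms
            new = np.where(w < n_win, dest[np.minimum(w, n_win - 1)] + offs, st)
            tr.spikes[u] = np.sort(new, kind="stable")
    return out


def remove_bursts(ds: SpikeDataset, isi_threshold_ms: float = 8.0) -> SpikeDataset:
    """Keep only the first spike of each burst.

    A burst is a maximal run of spikes in the *original* train whose
    consecutive inter-spike intervals are all below ``isi_threshold_ms``.
    Idempotent; never increases spike counts.
    """
    if isi_threshold_ms <= 0:
        raise ValueError("isi_threshold_ms must be positive")
    out = ds.copy()
    for tr in out.trials:
        for u, st in enumerate(tr.spikes):
            if st.size <= 1:
                continue
            keep = np.ones(st.size, dtype=bool)
            keep[1:] = np.diff(st) >= isi_threshold_ms
            tr.spikes[u] = st[keep]
    return out
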