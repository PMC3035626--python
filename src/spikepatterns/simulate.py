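"""Seeded synthetic multineuron spike datasets for the three stimulus regimes.

The generators emulate the statistical structure the pattern analysis
assumes, with ground truth available for parameter-recovery tests:

* :func:`gen_grating_like` — slow stimuli: trials of 4,800 ms (1,000 ms
  spontaneous, 3,500 ms stimulus, 300 ms OFF), 12 direction conditions at
  20 trials each; during the stimulus epoch each unit's rate is a slow
  sinusoid (temporal frequency ~0.83 Hz, from 2 deg/s drift over 2.4
  deg/cycle) scaled by a von-Mises direction-tuning gain.
* :func:`gen_flash_sequence_like` — fast stimuli: trials of 1,200 ms with
  three 100 ms flashes at 500/700/900 ms; each flashed item drives a
  stimulus-specific unit subset with a transient onset response (latency
  30-40 ms, ~10 ms wide) and a sustained offset response (latency 70 ms).
* :func:`gen_movie_like` — mixed dynamics: labelled slow epochs (smooth
  low-frequency rate modulation) and fast epochs (trains of sharp transient
  bumps), per-stimulus profiles fixed across trials.

Spikes are drawn by thinning a bounded-rate inhomogeneous Poisson process.
Burstiness is controllable: each accepted spike spawns, with probability
``burst_prob``, a doublet or triplet at intra-burst intervals of 3-6 ms
(below the 8 ms burst criterion).  Stimulus locking is controlled by a
per-trial latency jitter on the transient responses.  All randomness flows
from one master seed through named substreams.
"""

from __future__ import annotations

import numpy as np

from .datasets import SpikeDataset, Trial

__all__ = [
    "gen_grating_like",
    "gen_flash_sequence_like",
    "gen_movie_like",
    "inject_pattern",
    "thinned_poisson",
]


def thinned_poisson(rate_hz: np.ndarray, TD: float, rng: np.random.Generator) -> np.ndarray:
    """Sample one spike train on [0, TD) ms from a rate profile (Hz) given
    at 1 ms resolution, by thinning a homogeneous process at the peak rate."""
    rmax = float(rate_hz.max(initial=0.0))
    if rmax <= 0:
        return np.empty(0)
    n = rng.poisson(rmax * TD / 1000.0)
    if n == 0:
        return np.empty(0)
    t = rng.uniform(0.0, TD, size=n)
    r = np.interp(t, np.arange(len(rate_hz)), rate_hz)
    keep = rng.uniform(0.0, rmax, size=n) < r
    return np.sort(t[keep])


def _add_bursts(spikes: np.ndarray, burst_prob: float, TD: float,
                rng: np.random.Generator) -> np.ndarray:
    """Replace single spikes by doublets/triplets (ISI 3-6 ms) with
    probability ``burst_prob``."""
    if burst_prob <= 0 or spikes.size == 0:
        return spikes
    extra = []
    bursty = rng.uniform(size=spikes.size) < burst_prob
    for t in spikes[bursty]:
        n_extra = rng.integers(1, 3)  # doublet or triplet
        isis = rng.uniform(3.0, 6.0, size=n_extra)
        extra.extend(t + np.cumsum(isis))
    if not extra:
        return spikes
    out = np.concatenate([spikes, np.asarray(extra)])
    out = out[(out >= 0) & (out < TD)]
    return np.sort(out)


def _dataset(trials, n_units, stimulus_set, TD, epochs) -> SpikeDataset:
    return SpikeDataset(
        units=list(range(n_units)),
        trials=trials,
        stimulus_set=list(stimulus_set),
        trial_duration_ms=float(TD),
        epochs=epochs,
    )


# ------------------------------------------------------------- grating-like


def gen_grating_like(
    n_units: int = 12,
    n_stimuli: int = 12,
    n_trials: int = 20,
    TD: float = 4800.0,
    seed: int = 0,
    baseline_hz: float = 3.0,
    peak_gain_hz: float = 15.0,
    tuning_kappa: float = 2.0,
    temporal_freq_hz: float = 2.0 / 2.4,
    spont_ms: float = 1000.0,
    stim_ms: float = 3500.0,
    burst_prob: float = 0.1,
) -> SpikeDataset:
    """Drifting-grating-like trials: slow sinusoidal rate modulation with
    von-Mises direction tuning during the stimulus epoch, baseline activity
    in the spontaneous and OFF epochs.

    Directions are ``j * 360 / n_stimuli`` degrees.  Setting
    ``peak_gain_hz=0`` makes all stimuli statistically identical.
    """
    if n_units < 2 or n_stimuli < 1 or n_trials < 1:
        raise ValueError("invalid n_units / n_stimuli / n_trials")
    root = np.random.SeedSequence(seed)
    ss_units, ss_trials = root.spawn(2)
    urng = np.random.default_rng(ss_units)

    directions = np.arange(n_stimuli) * 2 * np.pi / n_stimuli
    pref = urng.uniform(0, 2 * np.pi, size=n_units)
    phase = urng.uniform(0, 2 * np.pi, size=n_units)
    t = np.arange(int(np.ceil(TD)))
    stim_on, stim_off = spont_ms, spont_ms + stim_ms

    rates = np.empty((n_stimuli, n_units, t.size))
    for j, theta in enumerate(directions):
        gain = peak_gain_hz * np.exp(tuning_kappa * (np.cos(theta - pref) - 1.0))
        for i in range(n_units):
            r = np.full(t.size, baseline_hz)
            in_stim = (t >= stim_on) & (t < stim_off)
            mod = 1.0 + np.sin(
                2 * np.pi * temporal_freq_hz * (t[in_stim] - stim_on) / 1000.0
                + phase[i]
            )
            r[in_stim] += gain[i] * mod
            rates[j, i] = r

    trials = []
    tid = 0
    trial_streams = ss_trials.spawn(n_stimuli * n_trials)
    for j in range(n_stimuli):
        for _ in range(n_trials):
            rng = np.random.default_rng(trial_streams[tid])
            spikes = []
            for i in range(n_units):
                st = thinned_poisson(rates[j, i], TD, rng)
                spikes.append(_add_bursts(st, burst_prob, TD, rng))
            trials.append(Trial(tid, j, spikes))
            tid += 1
    epochs = {"spontaneous": [0.0, stim_on], "stimulus": [stim_on, stim_off],
              "off": [stim_off, TD]}
    return _dataset(trials, n_units, range(n_stimuli), TD, epochs)


# ------------------------------------------------------- flash-sequence-like


DEFAULT_SEQUENCES = (("A", "B", "C"), ("A", "D", "C"), ("D", "B", "C"))


def gen_flash_sequence_like(
    n_units: int = 12,
    sequences=DEFAULT_SEQUENCES,
    n_trials: int = 50,
    TD: float = 1200.0,
    seed: int = 0,
    onsets=(500.0, 700.0, 900.0),
    flash_ms: float = 100.0,
    locking_jitter_sd: float = 3.0,
    background_hz: float = 2.0,
    onset_peak_hz: float = 150.0,
    onset_width_ms: float = 5.0,
    offset_rate_hz: float = 30.0,
    offset_dur_ms: float = 80.0,
    burst_prob: float = 0.1,
) -> SpikeDataset:
    """Flashed-letter-sequence trials.

    Each stimulus is a sequence of items flashed for ``flash_ms`` at the
    given onsets.  Every distinct item drives its own unit subset: a
    transient onset bump (Gaussian rate profile, per-unit latency fixed in
    30-40 ms, SD ``onset_width_ms``) and a sustained offset response
    starting 70 ms after flash offset.  ``locking_jitter_sd`` shifts each
    item's response latency per trial, degrading stimulus locking.
    """
    sequences = [tuple(s) for s in sequences]
    n_items = len(onsets)
    for s in sequences:
        if len(s) != n_items:
            raise ValueError(f"sequence {s} length != number of onsets ({n_items})")
    for a, b in zip(onsets[:-1], onsets[1:]):
        if a + flash_ms > b:
            raise ValueError("overlapping flash items")
    letters = sorted({item for s in sequences for item in s})
    root = np.random.SeedSequence(seed)
    ss_units, ss_trials = root.spawn(2)
    urng = np.random.default_rng(ss_units)

    # each letter drives a unit subset (round-robin partition)
    subsets = {L: [u for u in range(n_units) if u % len(letters) == k]
               for k, L in enumerate(letters)}
    onset_latency = {  # per (letter, unit): fixed latency in 30-40 ms
        (L, u): urng.uniform(30.0, 40.0) for L in letters for u in subsets[L]
    }

    t = np.arange(int(np.ceil(TD)))
    trials = []
    tid = 0
    trial_streams = ss_trials.spawn(len(sequences) * n_trials)
    for j, seq in enumerate(sequences):
        for _ in range(n_trials):
            rng = np.random.default_rng(trial_streams[tid])
            rate = np.full((n_units, t.size), background_hz)
            for onset, L in zip(onsets, seq):
                shift = rng.normal(0.0, locking_jitter_sd) if locking_jitter_sd else 0.0
                for u in subsets[L]:
                    peak_t = onset + onset_latency[(L, u)] + shift
                    rate[u] += onset_peak_hz * np.exp(
                        -0.5 * ((t - peak_t) / onset_width_ms) ** 2
                    )
                    off_t = onset + flash_ms + 70.0 + shift
                    rate[u] += offset_rate_hz * ((t >= off_t) & (t < off_t + offset_dur_ms))
            spikes = []
            for u in range(n_units):
                st = thinned_poisson(rate[u], TD, rng)
                spikes.append(_add_bursts(st, burst_prob, TD, rng))
            trials.append(Trial(tid, j, spikes))
            tid += 1
    epochs = {"flashes": [[float(o), float(o + flash_ms)] for o in onsets]}
    return _dataset(trials, n_units, range(len(sequences)), TD, epochs)


# --------------------------------------------------------------- movie-like


def gen_movie_like(
    n_units: int = 12,
    n_stimuli: int = 3,
    n_trials: int = 20,
    TD: float = 2400.0,
    seed: int = 0,
    slow_epochs=((0.0, 1200.0),),
    fast_epochs=((1200.0, 2400.0),),
    baseline_hz: float = 3.0,
    slow_gain_hz: float = 12.0,
    fast_peak_hz: float = 120.0,
    fast_width_ms: float = 5.0,
    fast_event_rate_hz: float = 8.0,
    locking_jitter_sd: float = 2.0,
    burst_prob: float = 0.1,
    share_slow: bool = False,
) -> SpikeDataset:
    """Movie-like trials mixing slow and fast rate dynamics.

    ``slow_epochs`` carry smooth low-frequency (0.3-1 Hz) sinusoidal
    modulation; ``fast_epochs`` carry trains of sharp transient bumps at
    per-stimulus fixed random times, hitting per-event random unit subsets.
    The two epoch lists must partition [0, TD) without overlap.  Epoch
    labels are stored for slow/fast-segment analyses.  With
    ``share_slow=True`` all stimuli share one slow profile, so they differ
    only in their fast epochs — discrimination then has to come from there.
    """
    eps = [(float(a), float(b), "slow") for a, b in slow_epochs]
    eps += [(float(a), float(b), "fast") for a, b in fast_epochs]
    eps.sort()
    cursor = 0.0
    for a, b, _ in eps:
        if a < cursor:
            raise ValueError("epochs overlap")
        if a > cursor:
            raise ValueError(f"epochs leave a gap at {cursor} ms")
        if b <= a:
            raise ValueError("empty epoch")
        cursor = b
    if cursor != float(TD):
        raise ValueError("epochs must partition [0, TD)")

    root = np.random.SeedSequence(seed)
    ss_profile, ss_trials = root.spawn(2)
    prng = np.random.default_rng(ss_profile)
    t = np.arange(int(np.ceil(TD)))

    rates = np.full((n_stimuli, n_units, t.size), baseline_hz)
    event_times = {j: [] for j in range(n_stimuli)}
    shared = {}
    for j in range(n_stimuli):
        for a, b, kind in eps:
            span = (t >= a) & (t < b)
            if kind == "slow":
                if share_slow and (a, b) in shared:
                    f, ph = shared[(a, b)]
                else:
                    f = prng.uniform(0.3, 1.0, size=n_units)
                    ph = prng.uniform(0, 2 * np.pi, size=n_units)
                    shared[(a, b)] = (f, ph)
                for i in range(n_units):
                    rates[j, i, span] += 0.5 * slow_gain_hz * (
                        1.0 + np.sin(2 * np.pi * f[i] * (t[span] - a) / 1000.0 + ph[i])
                    )
            else:
                n_events = prng.poisson(fast_event_rate_hz * (b - a) / 1000.0)
                times = np.sort(prng.uniform(a, b, size=n_events))
                for et in times:
                    sub = prng.choice(n_units, size=max(1, n_units // 3), replace=False)
                    for i in sub:
                        rates[j, i] += fast_peak_hz * np.exp(
                            -0.5 * ((t - et) / fast_width_ms) ** 2
                        )
                    event_times[j].append(float(et))

    trials = []
    tid = 0
    trial_streams = ss_trials.spawn(n_stimuli * n_trials)
    for j in range(n_stimuli):
        for _ in range(n_trials):
            rng = np.random.default_rng(trial_streams[tid])
            shift = rng.normal(0.0, locking_jitter_sd) if locking_jitter_sd else 0.0
            spikes = []
            for i in range(n_units):
                r = rates[j, i]
                if shift:
                    r = np.interp(t - shift, t, r)
                st = thinned_poisson(r, TD, rng)
                spikes.append(_add_bursts(st, burst_prob, TD, rng))
            trials.append(Trial(tid, j, spikes))
            tid += 1
    epochs = {"slow": [[a, b] for a, b, k in eps if k == "slow"],
              "fast": [[a, b] for a, b, k in eps if k == "fast"],
              "events": event_times}
    return _dataset(trials, n_units, range(n_stimuli), TD, epochs)


# ----------------------------------------------------------- ground truth


def inject_pattern(
    ds: SpikeDataset,
    unit_subset,
    trial_ids,
    time_ms: float,
    latency_sd_ms: float,
    seed: int = 0,
    n_spikes: int = 3,
    intra_isi_ms: float = 2.0,
) -> tuple[SpikeDataset, dict]:
    """Inject a synchronized multi-unit volley into selected trials.

    Each selected trial receives, at ``time_ms`` plus a per-trial Gaussian
    latency of SD ``latency_sd_ms``, a volley of ``n_spikes`` spikes at
    ``intra_isi_ms`` spacing on every unit of ``unit_subset``.  Returns the
    modified dataset and a ground-truth dict with the realised injection
    time per trial, for recovery tests.
    """
    rng = np.random.default_rng(seed)
    out = ds.copy()
    truth = {"units": list(unit_subset), "times": {}}
    by_id = {t.trial_id: t for t in out.trials}
    for tid in trial_ids:
        if tid not in by_id:
            raise ValueError(f"unknown trial id {tid}")
        t0 = time_ms + rng.normal(0.0, latency_sd_ms)
        t0 = float(np.clip(t0, 0.0, ds.trial_duration_ms - n_spikes * intra_isi_ms - 1))
        tr = by_id[tid]
        volley = t0 + np.arange(n_spikes) * intra_isi_ms
        for u in unit_subset:
            tr.spikes[u] = np.sort(np.concatenate([tr.spikes[u], volley]))
        truth["times"][tid] = t0
    return out, truth
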