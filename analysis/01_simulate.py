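"""Generate the three synthetic stimulus-regime datasets.

Writes spike CSVs + YAML metadata under results/data/ for:
  * grating-like trials  (slow sinusoidal rate modulation, 12 directions),
  * flash-sequence-like trials (three 100 ms flashes at 500/700/900 ms),
  * movie-like trials (slow first half, fast second half, shared slow
    profile so the stimuli differ only in their fast epochs).

Scaled to desk size (12 units) so every downstream script runs in minutes.
"""

from pathlib import Path

import spikepatterns as sp

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

FLASH_SEQS = [("A", "B", "C"), ("B", "C", "A"), ("C", "A", "B"), ("A", "C", "B")]

datasets = {
    "grating": sp.gen_grating_like(n_units=12, n_stimuli=4, n_trials=20, seed=SEED),
    "flash": sp.gen_flash_sequence_like(n_units=12, sequences=FLASH_SEQS,
                                        n_trials=20, seed=SEED),
    "movie": sp.gen_movie_like(n_units=12, n_stimuli=3, n_trials=20, TD=2400.0,
                               share_slow=True, seed=SEED),
}

for name, ds in datasets.items():
    path = OUT / f"{name}_spikes.csv"
    sp.write_spikes(ds, path)
    total = sum(t.spike_count() for t in ds.trials)
    print(f"{name:8s} {ds.n} units, {len(ds.trials)} trials of "
          f"{ds.trial_duration_ms:.0f} ms, {total} spikes -> {path}")
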