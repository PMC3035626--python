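"""Filter the flash-like dataset and cluster activity vectors with the 3D map.

At an integration constant of 10 ms, spike trains are convolved with the
exponential kernel, sampled at 1 kHz, and quantized by a 10x10x10 Kohonen
map.  Writes the trained map (HDF5), the model trials (CSV of pattern ids
per sample), and a color-sequence figure where each pattern is painted with
the RGB color of its lattice position — repeatable colored stripes across
trials of one stimulus are stereotypical, stimulus-locked patterns.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import spikepatterns as sp
from spikepatterns.pipeline import color_sequence_image

ROOT = Path(__file__).resolve().parent.parent / "results"
TAU_MS = 10.0

ds = sp.read_spikes(ROOT / "data" / "flash_spikes.csv")
prep = sp.prepare(ds, TAU_MS, sp.SomConfig(n_side=10, m_steps=8000, seed=0))
prep.som.save(ROOT / "som_flash_tau10.h5")

rows = []
for tid, pids in zip(prep.mts.trial_ids, prep.mts.pattern_ids):
    for k, p in enumerate(pids):
        rows.append((tid, k, int(p)))
pd.DataFrame(rows, columns=["trial_id", "sample_ms", "pattern_id"]).to_csv(
    ROOT / "model_trials_flash_tau10.csv", index=False
)

n_used = len({int(p) for pids in prep.mts.pattern_ids for p in np.unique(pids)})
print(f"tau={TAU_MS} ms: {n_used} of {prep.som.n_patterns} patterns in use")

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

fig, axes = plt.subplots(len(ds.stimulus_set), 1, figsize=(8, 6), sharex=True)
for ax, stim in zip(axes, ds.stimulus_set):
    img = color_sequence_image(prep.mts, stim)
    ax.imshow(img, aspect="auto", interpolation="nearest")
    ax.set_ylabel(f"stim {stim}\ntrials")
axes[-1].set_xlabel("time (ms)")
fig.suptitle(f"color sequences, tau = {TAU_MS:.0f} ms")
fig.tight_layout()
fig.savefig(ROOT / "color_sequences_flash.png", dpi=150)
print(f"wrote {ROOT / 'color_sequences_flash.png'}")
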