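# spikepatterns

Multi-timescale analysis of multineuronal spike patterns.

## The problem

Population recordings raise a question that single-neuron firing rates
cannot answer: on **which timescale** does the joint activity of many
neurons carry stimulus information — millisecond spike synchrony, slow rate
modulation, or something in between? Most analyses commit to one timescale
in advance. This package implements a chain that treats timescale as a
single explicit parameter and applies one identical method across the whole
range, for anyone analysing simultaneous spike trains (or building
simulations of them).

## The method

For `n` simultaneously recorded neurons:

1. **Filter.** Convolve each spike train with a causal exponential kernel,
   `a_i(t) = Σ_{t_s ≤ t} e^{−(t−t_s)/τ}`. The integration constant τ sets
   the timescale: τ = 1–5 ms sees near-coincident spikes, τ > 100 ms sees
   rate modulation. Sample at 1 kHz to get *activity vectors* `AV(t) ∈ ℝⁿ`.
2. **Quantize.** Cluster the activity vectors with an N×N×N Kohonen map
   (N = 10 → 1,000 *model vectors*, a.k.a. *patterns*); replace each sample
   by its best-matching pattern id to obtain *model trials*. The 3D lattice
   gives every pattern an RGB color, so trials can be read as color
   sequences.
3. **Quantify.** Pattern specificity `SP_p(j) = r_p(j)/Σ_c r_p(c)`
   measures how exclusively pattern p occurs for stimulus j (rows sum to 1;
   chance = 1/s). Three classifiers under repeated random half-split
   cross-validation decode the stimulus from: mean firing rates, pattern
   specificities (position-blind), or pattern *trajectories* — sequences of
   window-averaged model vectors (position-sensitive). A sliding-window
   Cohen's d, `d(t) = (d_O(t) − d_T(t))/s_pooled`, localises discriminative
   information in time.
4. **Control.** Spike-time jitter (SD 10–100 ms), 20 ms window shuffling,
   and burst removal (ISI < 8 ms) establish what the decoders actually use.

Since the multielectrode recordings this kind of analysis targets are not
publicly deposited, the package includes seeded generators for three
stimulus regimes — slow grating-like, fast flashed-sequence-like, and
mixed movie-like trials — with ground truth for recovery tests. See
`docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
import spikepatterns as sp

seqs = [("A","B","C"), ("B","C","A"), ("C","A","B"), ("A","C","B")]
ds = sp.gen_flash_sequence_like(n_units=12, sequences=seqs, n_trials=20, seed=1)
cfg = sp.SomConfig(n_side=10, m_steps=8000, seed=0)
for tau in (5, 20, 100):
    prep = sp.prepare(ds, tau, cfg)        # filter -> map -> model trials
    for clf in ("rate", "specificity", "trajectory"):
        r = sp.run_performance(ds, clf, tau, n_splits=100, seed=7, prep=prep)
        print(f"tau={tau:>3} ms  {clf:12s} {r.mean:.2f} (chance {r.chance:.2f})")
```

prints

```
tau=  5 ms  rate         0.25 (chance 0.25)
tau=  5 ms  specificity  0.28 (chance 0.25)
tau=  5 ms  trajectory   1.00 (chance 0.25)
tau= 20 ms  rate         0.25 (chance 0.25)
tau= 20 ms  specificity  0.38 (chance 0.25)
tau= 20 ms  trajectory   1.00 (chance 0.25)
tau=100 ms  rate         0.25 (chance 0.25)
tau=100 ms  specificity  0.52 (chance 0.25)
tau=100 ms  trajectory   1.00 (chance 0.25)
```

The four stimuli here are the *same* three letters flashed in different
orders, so mean rate is at chance by construction and the specificity
classifier (which ignores *when* patterns occur) barely beats it; only the
trajectory classifier, which uses the stimulus-locked position of fast
patterns, decodes the sequences — the signature of information carried by
pattern timing rather than pattern identity. Shuffling 20 ms windows
(`sp.shuffle_windows`) collapses trajectory performance to ~0.23 while
leaving the other two unchanged, and 100 ms spike jitter degrades it
significantly (one-sample Z across 10 independent jitters: z = −9.3,
p ≈ 9e−21) while moving specificity by < 5 points.

## Analysis scripts

`analysis/` contains numbered drivers that reproduce the full study flow on
synthetic data, writing tables and figures under `results/`:

```
python analysis/01_simulate.py          # three regime datasets (CSV + YAML)
python analysis/02_cluster_patterns.py  # 3D map, model trials, color sequences
python analysis/03_specificity.py       # specificity tables, locking, PTSRH
python analysis/04_decode_timescales.py # performance vs tau, both regimes
python analysis/05_controls.py          # shuffle / jitter / burst controls
python analysis/06_effect_size.py       # time-resolved Cohen's d (movie-like)
```

The whole sequence takes a few minutes on one core. A `spikepatterns`
console script (`simulate` / `run` / `report`) exposes the same pipeline
under a YAML config.

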