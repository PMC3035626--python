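"""Classifier performance as a function of the integration time constant.

For the grating-like (slow) and flash-like (fast) datasets, runs the three
classifiers — mean rate, specificity, trajectory — over tau in
{2, 5, 10, 20, 50, 100} ms with 100 random half-splits each, and writes the
performance table plus a performance-vs-tau figure per dataset.

Expected structure: for slow stimuli all three classifiers do well across
timescales; for fast flashed sequences only the trajectory classifier
(which uses where in the trial patterns occur) decodes well, peaking at
intermediate time constants.
"""

from pathlib import Path

import pandas as pd

import spikepatterns as sp

ROOT = Path(__file__).resolve().parent.parent / "results"
TAUS = [2, 5, 10, 20, 50, 100]
N_SPLITS = 100
CFG = sp.SomConfig(n_side=10, m_steps=8000, seed=0)

rows = []
for name in ("grating", "flash"):
    ds = sp.read_spikes(ROOT / "data" / f"{name}_spikes.csv")
    for tau in TAUS:
        prep = sp.prepare(ds, float(tau), CFG)
        for clf in ("rate", "specificity", "trajectory"):
            res = sp.run_performance(ds, clf, float(tau), N_SPLITS, seed=7, prep=prep)
            rows.append((name, clf, tau, res.mean, res.sd, res.chance))
        line = " ".join(f"{c}={r[3]:.2f}" for c, r in
                        zip(("rate", "spec", "traj"), rows[-3:]))
        print(f"{name:8s} tau={tau:>3} ms  {line}")

perf = pd.DataFrame(rows, columns=["dataset", "classifier", "tau_ms",
                                   "mean", "sd", "chance"])
perf.to_csv(ROOT / "performance_vs_tau.csv", index=False)

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
colors = {"rate": "tab:blue", "specificity": "tab:green", "trajectory": "tab:red"}
for ax, name in zip(axes, ("grating", "flash")):
    sub = perf[perf.dataset == name]
    for clf, grp in sub.groupby("classifier"):
        grp = grp.sort_values("tau_ms")
        ax.errorbar(grp.tau_ms, grp["mean"], yerr=grp.sd, marker="o",
                    color=colors[clf], label=clf)
    ax.axhline(sub.chance.iloc[0], ls="--", c="gray")
    ax.set_xscale("log")
    ax.set_title(name)
    ax.set_xlabel("integration time constant (ms)")
axes[0].set_ylabel("fraction correct")
axes[0].legend()
fig.tight_layout()
fig.savefig(ROOT / "performance_vs_tau.png", dpi=150)
print(f"wrote {ROOT / 'performance_vs_tau.png'}")
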