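"""End-to-end orchestration: simulate, run, report.

The pipeline ties the modules together under a single YAML-configurable
entry point: generate a synthetic dataset, run the pattern chain across a
list of integration time constants (with optional jitter / window-shuffle /
burst-removal controls), and render summary figures.  All outputs are CSV
(tables), HDF5 (maps, activations) and PNG (figures); identical config and
seeds give byte-identical CSV output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .datasets import SpikeDataset, jitter_spikes, read_spikes, remove_bursts, shuffle_windows, write_spikes
from .decoding import CLASSIFIERS, effect_size_timecourse, prepare, run_performance, split_half
from .som import SomConfig, pattern_color
from .specificity import pattern_specificity

log = logging.getLogger("spikepatterns")

__all__ = ["AnalysisConfig", "cmd_simulate", "cmd_run", "cmd_report"]


@dataclass
class AnalysisConfig:
    """Pipeline settings; mirrors the YAML config file."""

    taus_ms: list = field(default_factory=lambda: [1, 5, 10, 20, 50, 100, 500])
    dt_ms: float = 1.0
    som: SomConfig = field(default_factory=SomConfig)
    classifiers: tuple = CLASSIFIERS
    n_splits: int = 1000
    jitter_sds_ms: list = field(default_factory=lambda: [10, 20, 50, 100])
    shuffle_window_ms: float = 20.0
    burst_threshold_ms: float = 8.0
    effect_size_taus_ms: list = field(default_factory=lambda: [10, 20, 50, 100])
    controls: list = field(default_factory=list)  # subset of jitter/shuffle/deburst
    generator: str = "flash"  # flash | grating | movie
    generator_kwargs: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.taus_ms):
            raise ValueError("all taus must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        som = SomConfig(**raw.pop("som", {}))
        return cls(som=som, **raw)


_GENERATORS = {
    "flash": sim.gen_flash_sequence_like,
    "grating": sim.gen_grating_like,
    "movie": sim.gen_movie_like,
}


def cmd_simulate(cfg: AnalysisConfig) -> Path:
    """Generate the configured synthetic dataset and write it (CSV + YAML),
    plus a ground-truth sidecar recording generator and seed."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = _GENERATORS[cfg.generator]
    ds = gen(seed=cfg.seed, **cfg.generator_kwargs)
    path = out / f"{cfg.generator}_spikes.csv"
    write_spikes(ds, path)
    truth = {"generator": cfg.generator, "seed": cfg.seed,
             "kwargs": cfg.generator_kwargs, "epochs": ds.epochs}
    (out / f"{cfg.generator}_truth.json").write_text(json.dumps(truth, indent=2))
    log.info("simulated %s dataset (seed=%d) -> %s", cfg.generator, cfg.seed, path)
    return path


def _condition_dataset(ds: SpikeDataset, control: str, cfg: AnalysisConfig,
                       seed: int) -> SpikeDataset:
    if control == "original":
        return ds
    if control == "shuffle":
        return shuffle_windows(ds, cfg.shuffle_window_ms, seed)
    if control == "deburst":
        return remove_bursts(ds, cfg.burst_threshold_ms)
    if control.startswith("jitter"):
        sd = float(control.split(":")[1])
        return jitter_spikes(ds, sd, seed)
    raise ValueError(f"unknown control {control!r}")


def cmd_run(cfg: AnalysisConfig, dataset: str | Path | SpikeDataset) -> pd.DataFrame:
    """Run the full chain for every (tau, condition): activations -> map ->
    model trials -> specificity -> classifiers; write the performance table
    and per-tau specificity tables under ``cfg.out_dir``."""
    ds = dataset if isinstance(dataset, SpikeDataset) else read_spikes(dataset)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conditions = ["original"] + list(cfg.controls)
    rows = []
    for cond in conditions:
        cds = _condition_dataset(ds, cond, cfg, cfg.seed)
        for tau in cfg.taus_ms:
            t0 = time.perf_counter()
            prep = prepare(cds, tau, cfg.som, cfg.dt_ms)
            table = pattern_specificity(prep.mts, cds.stimulus_set)
            if cond == "original":
                table.to_frame().to_csv(out / f"specificity_tau{tau}.csv", index=False)
            for clf in cfg.classifiers:
                res = run_performance(cds, clf, tau, cfg.n_splits, cfg.seed, prep=prep)
                rows.append((clf, tau, cond, res.mean, res.sd, res.chance))
            log.info("tau=%s cond=%s done in %.1fs (%d training vectors)",
                     tau, cond, time.perf_counter() - t0,
                     sum(len(p) for p in prep.mts.pattern_ids))
    perf = pd.DataFrame(rows, columns=["classifier", "tau_ms", "condition",
                                       "mean", "sd", "chance"])
    perf.to_csv(out / "performance.csv", index=False)

    es_rows = []
    for tau in cfg.effect_size_taus_ms:
        if tau not in cfg.taus_ms:
            continue
        prep = prepare(ds, tau, cfg.som, cfg.dt_ms)
        plan = split_half(ds, cfg.seed)
        for stim in ds.stimulus_set:
            es = effect_size_timecourse(prep, plan, stim)
            for t, dT, dO, d in zip(es.times_ms, es.d_true, es.d_other, es.cohens_d):
                es_rows.append((tau, stim, t, dT, dO, d))
    if es_rows:
        pd.DataFrame(es_rows, columns=["tau_ms", "stimulus", "time_ms",
                                       "d_true", "d_other", "cohens_d"]
                     ).to_csv(out / "effect_size.csv", index=False)
    return perf


def cmd_report(results_dir: str | Path) -> list[Path]:
    """Render summary figures from a results directory produced by
    :func:`cmd_run`: performance vs tau (with chance line), and Cohen's d
    timecourses when present."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results_dir = Path(results_dir)
    perf_path = results_dir / "performance.csv"
    if not perf_path.exists():
        raise FileNotFoundError(f"missing {perf_path}; run the pipeline first")
    perf = pd.read_csv(perf_path)
    figs = []

    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"rate": "tab:blue", "specificity": "tab:green", "trajectory": "tab:red"}
    for clf, grp in perf[perf.condition == "original"].groupby("classifier"):
        grp = grp.sort_values("tau_ms")
        ax.errorbar(grp.tau_ms, grp["mean"], yerr=grp.sd, label=clf,
                    color=colors.get(clf), marker="o")
    ax.axhline(perf.chance.iloc[0], ls="--", c="gray", label="chance")
    ax.set_xscale("log")
    ax.set_xlabel("integration time constant (ms)")
    ax.set_ylabel("fraction correct")
    ax.legend()
    fig.tight_layout()
    p = results_dir / "performance_vs_tau.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    figs.append(p)

    es_path = results_dir / "effect_size.csv"
    if es_path.exists():
        es = pd.read_csv(es_path)
        fig, ax = plt.subplots(figsize=(6, 4))
        for tau, grp in es.groupby("tau_ms"):
            m = grp.groupby("time_ms")["cohens_d"].mean()
            ax.plot(m.index, m.values, label=f"tau={tau} ms")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("Cohen's d")
        ax.legend()
        fig.tight_layout()
        p = results_dir / "cohens_d_timecourse.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        figs.append(p)
    return figs


def color_sequence_image(mts, stimulus) -> np.ndarray:
    """RGB image (trials x samples x 3) of the pattern sequences of one
    stimulus, colored by lattice position."""
    rows = [pids for stim, pids in zip(mts.stimuli, mts.pattern_ids) if stim == stimulus]
    N = mts.som.n_side
    lut = np.array([pattern_color(mts.som.position(p), N) for p in range(mts.som.n_patterns)])
    return np.stack([lut[r] for r in rows])
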