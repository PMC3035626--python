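"""3D Kohonen self-organizing map over activity vectors.

Activity vectors are quantized by an N x N x N lattice of *model vectors*.
Each lattice element doubles as a *pattern*: replacing every activity vector
of a trial by the id of its best-matching unit (BMU) produces a *model
trial*, the discrete pattern sequence all downstream analyses run on.  The
3D lattice orders the patterns so that each can be painted with the RGB
color of its lattice position, giving similar patterns similar colors.

Training schedule
-----------------
At step ``k`` of ``M`` a random training vector is learned by moving the
BMU and its lattice neighborhood toward it:

* learning rate  ``L(k) = L0 * (LM / L0) ** (k / M)``  (geometric decay
  from ``L0 = 1`` to ``LM = 0.01``);
* neighborhood radius  ``R(k) = round(R0 * max(0, 1 - k / (g * M / 100)))``
  — linear decay from ``R0 = N/2`` reaching 0 after ``g = 66`` percent of
  the steps, so the first two thirds of training establish the map topology
  and the remainder fine-tunes individual model vectors (only the BMU moves
  once ``R = 0``);
* within the radius (Chebyshev lattice distance), updates are weighted by a
  3D Gaussian envelope of SD ``R(k)/3`` centred on the BMU:
  ``MV += L(k) * G * (AV - MV)``.

A flat K-Means backend is provided as an alternative clustering that lacks
the lattice ordering (and hence the color mapping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from sklearn.cluster import KMeans

from .activation import ActivityVectorSeries

__all__ = [
    "SomConfig",
    "SomMap",
    "ModelTrialSet",
    "learning_rate",
    "neighborhood_radius",
    "find_bmu",
    "train_som",
    "assign_patterns",
    "pattern_color",
    "kmeans_backend",
    "quantization_error",
]

#: training vectors beyond which a seeded uniform subsample is used
TRAIN_SUBSAMPLE_CAP = 200_000
#: hard cap on the default number of training steps
DEFAULT_STEP_CAP = 30_000


@dataclass
class SomConfig:
    """Training schedule for a 3D Kohonen map.

    ``m_steps=None`` resolves at training time to ``20x`` the number of
    training vectors, capped at :data:`DEFAULT_STEP_CAP`.
    """

    n_side: int = 10
    m_steps: int | None = None
    learning_rate_initial: float = 1.0
    learning_rate_final: float = 0.01
    radius_initial: float | None = None  # None -> n_side / 2
    radius_zero_pct: float = 66.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_side < 2:
            raise ValueError("n_side must be >= 2")
        if not (0 < self.learning_rate_final <= self.learning_rate_initial):
            raise ValueError("need 0 < LM <= L0")
        if not (0 < self.radius_zero_pct <= 100):
            raise ValueError("radius_zero_pct must be in (0, 100]")
        if self.m_steps is not None and self.m_steps < 1:
            raise ValueError("m_steps must be >= 1")

    @property
    def r0(self) -> float:
        return self.n_side / 2 if self.radius_initial is None else self.radius_initial


@dataclass
class SomMap:
    """Trained map: ``model_vectors`` is ``(N^3, n)``; pattern id ``p`` sits
    at lattice position ``(x, y, z) = (p // N^2, (p // N) % N, p % N)``."""

    model_vectors: np.ndarray
    config: SomConfig

    @property
    def n_side(self) -> int:
        return self.config.n_side

    @property
    def n_patterns(self) -> int:
        return self.model_vectors.shape[0]

    @property
    def n_units(self) -> int:
        return self.model_vectors.shape[1]

    def position(self, pattern_id: int) -> tuple[int, int, int]:
        N = self.n_side
        return (pattern_id // (N * N), (pattern_id // N) % N, pattern_id % N)

    def linear_index(self, x: int, y: int, z: int) -> int:
        N = self.n_side
        return x * N * N + y * N + z

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("model_vectors", data=self.model_vectors)
            cfg = self.config
            d.attrs.update(
                n_side=cfg.n_side,
                m_steps=-1 if cfg.m_steps is None else cfg.m_steps,
                learning_rate_initial=cfg.learning_rate_initial,
                learning_rate_final=cfg.learning_rate_final,
                radius_initial=-1.0 if cfg.radius_initial is None else cfg.radius_initial,
                radius_zero_pct=cfg.radius_zero_pct,
                seed=cfg.seed,
            )

    @classmethod
    def load(cls, path: str | Path) -> "SomMap":
        with h5py.File(path, "r") as f:
            mv = f["model_vectors"][...]
            a = f["model_vectors"].attrs
            cfg = SomConfig(
                n_side=int(a["n_side"]),
                m_steps=None if a["m_steps"] < 0 else int(a["m_steps"]),
                learning_rate_initial=float(a["learning_rate_initial"]),
                learning_rate_final=float(a["learning_rate_final"]),
                radius_initial=None if a["radius_initial"] < 0 else float(a["radius_initial"]),
                radius_zero_pct=float(a["radius_zero_pct"]),
                seed=int(a["seed"]),
            )
        return cls(mv, cfg)


@dataclass
class ModelTrialSet:
    """Per-trial pattern-id sequences aligned to sample times."""

    trial_ids: list[int]
    stimuli: list
    pattern_ids: list[np.ndarray]
    som: SomMap
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        if not (len(self.trial_ids) == len(self.stimuli) == len(self.pattern_ids)):
            raise ValueError("trial_ids, stimuli, pattern_ids lengths differ")

    def __len__(self) -> int:
        return len(self.trial_ids)


def _resolve_m(cfg: SomConfig, n_vectors: int) -> int:
    if cfg.m_steps is not None:
        return cfg.m_steps
    return min(20 * n_vectors, DEFAULT_STEP_CAP)


def learning_rate(k: int, cfg: SomConfig, m_steps: int | None = None) -> float:
    """L(k): geometric interpolation from L0 (k=0) to LM (k=M)."""
    M = m_steps if m_steps is not None else cfg.m_steps
    if M is None:
        raise ValueError("m_steps unresolved; pass m_steps explicitly")
    if not 0 <= k <= M:
        raise ValueError(f"step k={k} outside [0, {M}]")
    L0, LM = cfg.learning_rate_initial, cfg.learning_rate_final
    return float(L0 * (LM / L0) ** (k / M))


def neighborhood_radius(k: int, cfg: SomConfig, m_steps: int | None = None) -> int:
    """R(k): linear decay from round(R0), hitting 0 at g percent of M."""
    M = m_steps if m_steps is not None else cfg.m_steps
    if M is None:
        raise ValueError("m_steps unresolved; pass m_steps explicitly")
    if not 0 <= k <= M:
        raise ValueError(f"step k={k} outside [0, {M}]")
    zero_at = cfg.radius_zero_pct * M / 100.0
    r = cfg.r0 * max(0.0, 1.0 - k / zero_at)
    return int(np.floor(r + 0.5))  # round half away from zero


def _lattice_coords(N: int) -> np.ndarray:
    g = np.arange(N)
    return np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)


def find_bmu(som: SomMap, v: np.ndarray) -> tuple[int, int, int]:
    """Lattice position of the model vector closest (Euclidean) to ``v``;
    ties resolve to the lowest linear index."""
    v = np.asarray(v, dtype=float)
    if v.shape != (som.n_units,):
        raise ValueError(f"expected vector of dim {som.n_units}, got {v.shape}")
    d2 = ((som.model_vectors - v) ** 2).sum(axis=1)
    return som.position(int(np.argmin(d2)))


def train_som(vectors: np.ndarray, cfg: SomConfig) -> SomMap:
    """Train a 3D Kohonen map on a set of n-dimensional vectors.

    Deterministic under ``cfg.seed``: initialization, training-vector draws
    and subsampling all derive from it.  Model vectors are initialized
    uniformly within the per-dimension min-max of the training set.  When
    more than :data:`TRAIN_SUBSAMPLE_CAP` vectors are supplied, training
    draws from a seeded uniform subsample (assignment elsewhere always uses
    all samples).
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] == 0:
        raise ValueError("need a non-empty (m, n) array of training vectors")
    rng = np.random.default_rng(cfg.seed)
    if vectors.shape[0] > TRAIN_SUBSAMPLE_CAP:
        idx = rng.choice(vectors.shape[0], TRAIN_SUBSAMPLE_CAP, replace=False)
        vectors = vectors[idx]
    m, n = vectors.shape
    M = _resolve_m(cfg, m)
    N = cfg.n_side

    lo, hi = vectors.min(axis=0), vectors.max(axis=0)
    MV = rng.uniform(lo, hi, size=(N**3, n))
    coords = _lattice_coords(N)

    draws = rng.integers(0, m, size=M)
    for k in range(M):
        v = vectors[draws[k]]
        L = learning_rate(k, cfg, M)
        R = neighborhood_radius(k, cfg, M)
        d2 = ((MV - v) ** 2).sum(axis=1)
        bmu = int(np.argmin(d2))
        if R == 0:
            MV[bmu] += L * (v - MV[bmu])
            continue
        delta = coords - coords[bmu]
        cheb = np.abs(delta).max(axis=1)
        mask = cheb <= R
        lat2 = (delta[mask] ** 2).sum(axis=1)
        G = np.exp(-lat2 / (2.0 * (R / 3.0) ** 2))
        MV[mask] += (L * G)[:, None] * (v - MV[mask])
    return SomMap(MV, cfg)


def _assign_chunked(MV: np.ndarray, X: np.ndarray, chunk: int = 65536) -> np.ndarray:
    """argmin over model vectors for each row of X, in memory-bounded chunks."""
    mv2 = (MV**2).sum(axis=1)
    out = np.empty(X.shape[0], dtype=np.int64)
    for i in range(0, X.shape[0], chunk):
        xb = X[i : i + chunk]
        # squared distance up to a per-row constant
        d = mv2[None, :] - 2.0 * (xb @ MV.T)
        out[i : i + chunk] = np.argmin(d, axis=1)
    return out


def assign_patterns(som: SomMap, series: list[ActivityVectorSeries]) -> ModelTrialSet:
    """Replace each activity vector by the linear index of its BMU."""
    if series and series[0].vectors.shape[1] != som.n_units:
        raise ValueError(
            f"map dimension {som.n_units} != data dimension "
            f"{series[0].vectors.shape[1]}"
        )
    pattern_ids = [_assign_chunked(som.model_vectors, s.vectors) for s in series]
    return ModelTrialSet(
        trial_ids=[s.trial_id for s in series],
        stimuli=[s.stimulus for s in series],
        pattern_ids=pattern_ids,
        som=som,
        dt_ms=series[0].dt_ms if series else 1.0,
    )


def pattern_color(position: tuple[int, int, int], n_side: int) -> tuple[float, float, float]:
    """RGB in [0,1]^3 for a lattice position: ``(x, y, z) / (N - 1)``.

    Nearby lattice points — hence similar patterns — get similar colors.
    """
    x, y, z = position
    if not all(0 <= c < n_side for c in (x, y, z)):
        raise ValueError(f"position {position} outside lattice of side {n_side}")
    return (x / (n_side - 1), y / (n_side - 1), z / (n_side - 1))


def kmeans_backend(vectors: np.ndarray, K: int, seed: int) -> np.ndarray:
    """Flat K-Means alternative to the SOM: returns ``(K, n)`` centroids
    usable wherever model vectors are (no lattice ordering, no colors)."""
    vectors = np.asarray(vectors, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    n_distinct = np.unique(vectors, axis=0).shape[0]
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds number of distinct vectors ({n_distinct})")
    km = KMeans(n_clusters=K, random_state=seed, n_init=10).fit(vectors)
    return km.cluster_centers_


def quantization_error(MV: np.ndarray, X: np.ndarray) -> float:
    """Mean Euclidean distance from each vector to its nearest model vector."""
    idx = _assign_chunked(np.asarray(MV, float), np.asarray(X, float))
    return float(np.linalg.norm(X - MV[idx], axis=1).mean())
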