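"""Reliability Maps and per-probe unreliability scores.

Background noise recorded by the negative-control probes is resampled
onto a fixed grid of (M_k, U_l) intensity pairs.  For each grid cell the
simulated beta distribution

    beta_m = (M_k + Merr_m) / ((M_k + Merr_m) + (U_l + Uerr_m)),  m = 1..n_draws

is summarised by its mean absolute deviation about the mean (the Q
score): the expected perturbation of a beta value measured at those
intensities.  Note the simulated beta carries no alpha constant; alpha
only enters reported beta values.

The channel chemistry decides which noise pool feeds which side:
type II draws M noise from the Green pool and U noise from the Red pool;
type I probes draw both sides independently from their single channel's
pool.

A probe's unreliability score is the average of Q values looked up at
its background-subtracted observed intensities across all samples.
Coordinates above the grid maximum are deemed fully reliable (Q* = 0);
coordinates below the grid minimum clamp to the minimum, the least
reliable regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Channel, IntensityDataset, ProbeType, ValidationError

__all__ = [
    "GridSpec",
    "NoisePool",
    "ReliabilityMap",
    "build_noise_pool",
    "simulate_beta_distribution",
    "q_score",
    "build_reliability_map",
    "lookup_q",
    "unreliability_scores",
    "save_reliability_map",
    "load_reliability_map",
]

#: noise-pool channel chemistry per probe type: (M side, U side)
TYPE_CHANNELS: dict[ProbeType, tuple[Channel, Channel]] = {
    ProbeType.II: (Channel.GRN, Channel.RED),
    ProbeType.I_GRN: (Channel.GRN, Channel.GRN),
    ProbeType.I_RED: (Channel.RED, Channel.RED),
}


@dataclass(frozen=True)
class GridSpec:
    """Uniform intensity grid; defaults (0, 5000, 100) give 51 axis points."""

    min: float = 0.0
    max: float = 5000.0
    step: float = 100.0

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise ValidationError("grid min must be below max")
        if self.step <= 0:
            raise ValidationError("grid step must be positive")
        n = (self.max - self.min) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("(max - min) must be divisible by step")

    @property
    def n_points(self) -> int:
        return int(round((self.max - self.min) / self.step)) + 1

    def axis(self) -> np.ndarray:
        return self.min + self.step * np.arange(self.n_points)


@dataclass
class NoisePool:
    """Pooled negative-control noise feeding the M and U sides of one map."""

    type_channel: ProbeType
    m_noise: np.ndarray
    u_noise: np.ndarray

    def __post_init__(self) -> None:
        self.m_noise = np.asarray(self.m_noise, dtype=float)
        self.u_noise = np.asarray(self.u_noise, dtype=float)
        if self.m_noise.size == 0 or self.u_noise.size == 0:
            raise ValidationError("noise pools must be non-empty")

    @property
    def m_noise_mean(self) -> float:
        return float(self.m_noise.mean())

    @property
    def u_noise_mean(self) -> float:
        return float(self.u_noise.mean())


@dataclass
class ReliabilityMap:
    grid: GridSpec
    q: np.ndarray  # [k, l] indexed by (M axis, U axis)
    type_channel: ProbeType
    n_draws: int
    seed: int
    m_noise_mean: float
    u_noise_mean: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (self.grid.n_points, self.grid.n_points):
            raise ValidationError("Q matrix dimensions must match the grid")
        if not np.isfinite(self.q).all() or (self.q < 0).any():
            raise ValidationError("Q values must be finite and non-negative")


def build_noise_pool(dataset: IntensityDataset, ptype: ProbeType) -> NoisePool:
    """Pool all samples' negative-control intensities per the type's chemistry."""
    m_chan, u_chan = TYPE_CHANNELS[ptype]
    m_noise = dataset.noise_channel(m_chan)
    u_noise = dataset.noise_channel(u_chan)
    if m_noise.size == 0 or u_noise.size == 0:
        raise ValidationError(f"empty negative-control channel for type {ptype.value}")
    return NoisePool(type_channel=ptype, m_noise=m_noise, u_noise=u_noise)


def simulate_beta_distribution(
    m_k: float,
    u_l: float,
    pool: NoisePool,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulated beta values at fixed (M_k, U_l) under resampled noise.

    M and U noise are drawn independently with replacement from the
    pool's two vectors.  When noise and signal are all exactly zero the
    ratio is undefined and beta is set to 0.5, the symmetric value.
    """
    if n_draws < 2:
        raise ValidationError("n_draws must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m_err = pool.m_noise[rng.integers(0, pool.m_noise.size, n_draws)]
    u_err = pool.u_noise[rng.integers(0, pool.u_noise.size, n_draws)]
    num = m_k + m_err
    den = num + u_l + u_err
    with np.errstate(invalid="ignore"):
        beta = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
    return beta


def q_score(betas: np.ndarray) -> float:
    """Mean absolute deviation about the sample mean."""
    betas = np.asarray(betas, dtype=float)
    if betas.size < 2:
        raise ValidationError("q_score needs at least 2 values")
    if betas.max() == betas.min():  # constant: exactly zero, no round-off
        return 0.0
    return float(np.abs(betas - betas.mean()).mean())


def build_reliability_map(
    pool: NoisePool,
    grid: GridSpec | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> ReliabilityMap:
    """Q score at every grid cell, with per-cell RNG streams.

    Each cell (k, l) uses ``default_rng([seed, k, l])`` so the map is
    reproducible and independent of evaluation order.
    """
    grid = grid or GridSpec()
    axis = grid.axis()
    n = grid.n_points
    q = np.empty((n, n), dtype=float)
    for k in range(n):
        for l in range(n):
            rng = np.random.default_rng([seed, k, l])
            betas = simulate_beta_distribution(axis[k], axis[l], pool, n_draws, rng)
            q[k, l] = q_score(betas)
    return ReliabilityMap(
        grid=grid,
        q=q,
        type_channel=pool.type_channel,
        n_draws=n_draws,
        seed=seed,
        m_noise_mean=pool.m_noise_mean,
        u_noise_mean=pool.u_noise_mean,
    )


def lookup_q(rmap: ReliabilityMap, m, u):
    """Q* at the nearest grid node after background subtraction.

    Accepts scalars or arrays.  Corrected coordinates above the grid
    maximum in either axis return 0 (very reliable); coordinates below
    the grid minimum clamp to the minimum.  Nearest node by Euclidean
    distance, ties broken toward the lower-index cell.  Missing inputs
    yield NaN.
    """
    grid = rmap.grid
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    cm = m - rmap.m_noise_mean
    cu = u - rmap.u_noise_mean
    missing = np.isnan(cm) | np.isnan(cu)
    above = (cm > grid.max) | (cu > grid.max)
    cm = np.clip(cm, grid.min, grid.max)
    cu = np.clip(cu, grid.min, grid.max)
    # On a uniform grid the Euclidean-nearest node factorises per axis;
    # ceil(frac - 0.5) rounds half-way points down (lower index).
    ki = np.ceil((np.nan_to_num(cm) - grid.min) / grid.step - 0.5).astype(int)
    li = np.ceil((np.nan_to_num(cu) - grid.min) / grid.step - 0.5).astype(int)
    ki = np.clip(ki, 0, grid.n_points - 1)
    li = np.clip(li, 0, grid.n_points - 1)
    out = rmap.q[ki, li]
    out = np.where(above, 0.0, out)
    out = np.where(missing, np.nan, out)
    return float(out) if out.ndim == 0 else out


def unreliability_scores(
    dataset: IntensityDataset,
    rmap: ReliabilityMap,
    ptype: ProbeType,
) -> pd.DataFrame:
    """Per-probe mean Q* across samples with non-missing intensities.

    Returns columns ``probe_id, infinium_type, unreliability,
    n_samples_used``; probes without any usable sample get NaN.
    """
    if rmap.type_channel != ptype:
        raise ValidationError(
            f"map was built for {rmap.type_channel.value}, not {ptype.value}"
        )
    m, u = dataset.partition(ptype)
    if m.shape[1] == 0:
        raise ValidationError(f"no probes of type {ptype.value} in dataset")
    qstar = lookup_q(rmap, m.to_numpy(dtype=float), u.to_numpy(dtype=float))
    n_used = (~np.isnan(qstar)).sum(axis=0)
    sums = np.nansum(qstar, axis=0)
    score = np.divide(sums, n_used, out=np.full(m.shape[1], np.nan), where=n_used > 0)
    return pd.DataFrame(
        {
            "probe_id": m.columns,
            "infinium_type": ptype.value,
            "unreliability": score,
            "n_samples_used": n_used.astype(int),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_reliability_map(rmap: ReliabilityMap, json_path: str | Path, tsv_path: str | Path) -> None:
    meta = {
        "type_channel": rmap.type_channel.value,
        "grid": {"min": rmap.grid.min, "max": rmap.grid.max, "step": rmap.grid.step},
        "n_draws": rmap.n_draws,
        "seed": rmap.seed,
        "m_noise_mean": rmap.m_noise_mean,
        "u_noise_mean": rmap.u_noise_mean,
        "q_matrix": str(Path(tsv_path).name),
    }
    Path(json_path).write_text(json.dumps(meta, indent=2))
    axis = rmap.grid.axis()
    df = pd.DataFrame(rmap.q, index=axis, columns=axis)
    df.index.name = "M"
    df.to_csv(tsv_path, sep="\t")


def load_reliability_map(json_path: str | Path) -> ReliabilityMap:
    meta = json.loads(Path(json_path).read_text())
    tsv_path = Path(json_path).parent / meta["q_matrix"]
    q = pd.read_csv(tsv_path, sep="\t", index_col=0).to_numpy(dtype=float)
    return ReliabilityMap(
        grid=GridSpec(**meta["grid"]),
        q=q,
        type_channel=ProbeType(meta["type_channel"]),
        n_draws=int(meta["n_draws"]),
        seed=int(meta["seed"]),
        m_noise_mean=float(meta["m_noise_mean"]),
        u_noise_mean=float(meta["u_noise_mean"]),
    )
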