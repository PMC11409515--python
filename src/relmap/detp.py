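"""Detection p-value (detP) baseline.

The conventional outlier filter compares a probe's total intensity
(M + U) against a Gaussian background whose mean is the sum of the two
relevant channels' negative-control means and whose standard deviation
is the sum of their standard deviations.  The detection p-value is the
upper-tail probability of the observed total under that background; a
probe "fails" a sample when p exceeds the chosen threshold, and is
flagged at probe level when it fails in more than ``sample_fraction``
of samples.  Channels follow the probe type's chemistry, as in the
reliability module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import IntensityDataset, ProbeType, ValidationError
from .reliability import build_noise_pool

__all__ = ["DEFAULT_DETP_THRESHOLDS", "compute_detp", "detp_flagged", "detp_summary"]

#: the three stringencies conventionally used with detP filtering
DEFAULT_DETP_THRESHOLDS = (0.01, 1e-16, 1e-40)


def compute_detp(dataset: IntensityDataset, ptype: ProbeType) -> pd.DataFrame:
    """Per-sample detection p-values for probes of one type.

    Returns a sample x probe DataFrame of p-values in [0, 1]; missing
    intensities give missing p-values.
    """
    pool = build_noise_pool(dataset, ptype)
    mu = pool.m_noise.mean() + pool.u_noise.mean()
    sd = pool.m_noise.std(ddof=1) + pool.u_noise.std(ddof=1)
    if sd <= 0:
        raise ValidationError("background standard deviation is zero")
    m, u = dataset.partition(ptype)
    if m.shape[1] == 0:
        raise ValidationError(f"no probes of type {ptype.value} in dataset")
    total = m + u
    p = pd.DataFrame(
        stats.norm.sf(total.to_numpy(dtype=float), loc=mu, scale=sd),
        index=total.index,
        columns=total.columns,
    )
    return p


def detp_flagged(
    p: pd.DataFrame,
    p_threshold: float,
    sample_fraction: float = 0.5,
) -> set[str]:
    """Probes whose p exceeds ``p_threshold`` in more than
    ``sample_fraction`` of their non-missing samples."""
    if not 0 < p_threshold <= 1:
        raise ValidationError("p_threshold must lie in (0, 1]")
    failed = p > p_threshold
    n_obs = p.notna().sum(axis=0)
    frac = failed.sum(axis=0) / n_obs.replace(0, np.nan)
    return set(p.columns[(frac > sample_fraction).fillna(False)])


def detp_summary(
    p: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_DETP_THRESHOLDS,
) -> pd.DataFrame:
    """Per-probe fraction of failing samples at each threshold."""
    n_obs = p.notna().sum(axis=0)
    out = {"probe_id": p.columns}
    for thr in thresholds:
        frac = (p > thr).sum(axis=0) / n_obs.replace(0, np.nan)
        out[f"fraction_failed_at_{thr:g}"] = frac.to_numpy(dtype=float)
    return pd.DataFrame(out).reset_index(drop=True)
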