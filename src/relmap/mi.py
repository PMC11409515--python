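"""Mean normalized Intensity (MI) score.

Within each probe type/channel partition (II, I-Grn, I-Red) and for each
sample i the Average Intensity of the Sample is

    AIS_i = mean_j(M_ij) + mean_j(U_ij)

each probe's normalized intensity on that sample is

    N_ij = (M_ij + U_ij) / AIS_i

and the MI score of probe j is the mean of N_ij over samples.  By
construction the probe-mean of N_ij is 1 for every complete sample, so
MI averages to 1 per type/channel; a low MI marks a probe whose total
signal is weak relative to the array average.  Missing intensities are
excluded from every mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import IntensityDataset, ProbeType, ValidationError

__all__ = ["average_sample_intensity", "normalized_intensity", "compute_mi"]


def average_sample_intensity(m_row, u_row) -> float:
    """AIS for one sample: mean non-missing M plus mean non-missing U."""
    m = np.asarray(m_row, dtype=float)
    u = np.asarray(u_row, dtype=float)
    if np.isnan(m).all() or np.isnan(u).all():
        raise ValidationError("sample has no non-missing intensities")
    return float(np.nanmean(m) + np.nanmean(u))


def normalized_intensity(m_ij: float, u_ij: float, ais_i: float) -> float:
    """N_ij = (M_ij + U_ij) / AIS_i."""
    if ais_i <= 0:
        raise ZeroDivisionError("average sample intensity must be positive")
    return (m_ij + u_ij) / ais_i


def compute_mi(dataset: IntensityDataset, ptype: ProbeType) -> pd.DataFrame:
    """Per-probe MI table for one probe type/channel.

    Returns columns ``probe_id, infinium_type, mi, n_samples_used``.
    """
    m, u = dataset.partition(ptype)
    if m.shape[1] == 0:
        raise ValidationError(f"no probes of type {ptype.value} in dataset")
    if m.shape[0] == 0:
        raise ValidationError("dataset has no samples")
    ais = m.mean(axis=1, skipna=True) + u.mean(axis=1, skipna=True)
    bad = ais.index[~(ais > 0)]
    if len(bad):
        raise ZeroDivisionError(
            f"non-positive average intensity for sample(s): {list(bad[:5])}"
        )
    total = m + u  # NaN wherever either channel is missing
    n_ij = total.div(ais, axis=0)
    mi = n_ij.mean(axis=0, skipna=True)
    n_used = n_ij.notna().sum(axis=0)
    return pd.DataFrame(
        {
            "probe_id": mi.index,
            "infinium_type": ptype.value,
            "mi": mi.to_numpy(dtype=float),
            "n_samples_used": n_used.to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
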