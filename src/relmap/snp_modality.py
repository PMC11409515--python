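"""Modality-based flagging of SNP-affected probes.

A genetic variant at the target CpG's cytosine (position 0) turns the
probe's beta values tri-modal across a cohort — each mode holds the
carriers of one genotype ("SNP-II-0 effect").  A variant at the guanine
(position 1) degrades hybridisation and yields a tri-modal distribution
of *total intensity* (tiers roughly 1 : 0.5 : 0.05 for the two-, one-
and zero-copy genotypes) while beta becomes bi- or tri-modal
("SNP-II-1 effect").  Type I probes admit more variant configurations
but produce the same two fingerprints.

Modes are counted by fitting 1..max_modes-component Gaussian mixtures,
choosing the component count by BIC, and discarding components whose
mixture weight falls below ``min_weight``.  Total intensities are
log-transformed before fitting because the tiers are multiplicative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .data_model import ValidationError

__all__ = ["ModalityCall", "count_modes", "classify_snp_effect"]

MIN_VALUES = 30


@dataclass
class ModalityCall:
    probe_id: str
    beta_modes: int
    intensity_modes: int
    snp_effect: str  # none | snp0_like | snp1_like
    fit_diagnostics: dict = field(default_factory=dict)


def _fit_bic(values: np.ndarray, max_modes: int, seed: int) -> tuple[GaussianMixture, dict]:
    x = values.reshape(-1, 1)
    best = None
    scores = {}
    for k in range(1, max_modes + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=1e-6,
            random_state=seed,
            n_init=3,
        ).fit(x)
        bic = gm.bic(x)
        scores[k] = float(bic)
        if best is None or bic < best[0]:
            best = (bic, gm)
    return best[1], scores


def count_modes(
    values: np.ndarray,
    max_modes: int = 3,
    min_weight: float = 0.05,
    seed: int = 0,
) -> int:
    """Number of well-supported mixture components in a 1-D sample."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < MIN_VALUES:
        raise ValidationError(f"need at least {MIN_VALUES} values to count modes")
    if max_modes < 1:
        raise ValidationError("max_modes must be at least 1")
    gm, _ = _fit_bic(values, max_modes, seed)
    return int((gm.weights_ >= min_weight).sum())


def classify_snp_effect(
    betas: np.ndarray,
    total_intensities: np.ndarray,
    seed: int = 0,
    probe_id: str = "",
    max_modes: int = 3,
    min_weight: float = 0.05,
) -> ModalityCall:
    """Call a probe's SNP fingerprint from per-sample beta and intensity.

    ``snp0_like`` requires tri-modal beta; otherwise ``snp1_like``
    requires tri-modal (log) total intensity together with bi- or
    tri-modal beta; anything else is ``none``.
    """
    betas = np.asarray(betas, dtype=float)
    totals = np.asarray(total_intensities, dtype=float)
    if betas.shape != totals.shape:
        raise ValidationError("betas and total_intensities must be aligned")
    if betas.size < MIN_VALUES:
        raise ValidationError(f"need at least {MIN_VALUES} samples")
    gm_b, scores_b = _fit_bic(betas[np.isfinite(betas)], max_modes, seed)
    beta_modes = int((gm_b.weights_ >= min_weight).sum())
    log_tot = np.log(np.clip(totals[np.isfinite(totals)], 1e-9, None))
    gm_i, scores_i = _fit_bic(log_tot, max_modes, seed)
    intensity_modes = int((gm_i.weights_ >= min_weight).sum())

    if beta_modes == 3:
        effect = "snp0_like"
    elif intensity_modes == 3 and beta_modes >= 2:
        effect = "snp1_like"
    else:
        effect = "none"
    return ModalityCall(
        probe_id=probe_id,
        beta_modes=beta_modes,
        intensity_modes=intensity_modes,
        snp_effect=effect,
        fit_diagnostics={"beta_bic": scores_b, "intensity_bic": scores_i},
    )
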