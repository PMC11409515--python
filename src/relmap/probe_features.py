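"""Sequence-derived probe features and CpG-context enrichment.

Probe hybridisation strength depends on base composition: probes with a
low C content (equivalently, targets with a low G content) bind more
weakly and yield lower intensities.  The melting temperature is
estimated from GC content with the empirical formula

    Tm(1 M Na+) = 81.5 + 0.41 * GC% - 600 / length   [degC]

followed by the Owczarzy GC-dependent monovalent-salt correction on the
reciprocal Kelvin scale,

    1/Tm(mon) = 1/Tm(1M) + (4.29 * f_GC - 3.95) * 1e-5 * ln(mon)
                + 9.40e-6 * ln(mon)^2

where ``mon = Na + Tris/2`` (in molar) is the effective monovalent
cation concentration; defaults Na = 50 mM, Tris = 10 mM match the EPIC
v1.0 hybridisation buffer.  Ambiguity codes are excluded from base
counts; the 600/length term uses the full sequence length.

Context enrichment builds, per stratum, the 2x2 table of flagged vs
unflagged probes inside vs outside the stratum, tests it with a
two-sided Fisher exact test and adjusts across strata with
Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ProbeType, ValidationError

__all__ = [
    "base_content",
    "gc_fraction",
    "melting_temperature",
    "probe_feature_table",
    "context_enrichment",
    "EnrichmentResult",
]

_COMPLEMENT = str.maketrans("ACGTNRY", "TGCANYR")

# empirical GC-count Tm constants (Primer3-style variant)
_TM_A = 81.5
_TM_B = 0.41
_TM_C = 600.0


def base_content(seq: str, base: str) -> float:
    """Fraction of ``base`` among unambiguous bases of ``seq``."""
    if not seq:
        raise ValidationError("empty sequence")
    seq = seq.upper()
    unambiguous = [c for c in seq if c in "ACGT"]
    if not unambiguous:
        raise ValidationError("sequence has no unambiguous bases")
    return unambiguous.count(base.upper()) / len(unambiguous)


def gc_fraction(seq: str) -> float:
    """G+C fraction among unambiguous bases."""
    return base_content(seq, "G") + base_content(seq, "C")


def melting_temperature(
    seq: str,
    na_mM: float = 50.0,
    tris_mM: float = 10.0,
) -> float:
    """GC-content melting temperature with Owczarzy salt correction, in degC."""
    if len(seq) < 10:
        raise ValidationError("sequence must be at least 10 bases for Tm estimation")
    mon = (na_mM + tris_mM / 2.0) / 1000.0
    if mon <= 0:
        raise ValidationError("effective monovalent cation concentration must be positive")
    fgc = gc_fraction(seq)
    tm_1m = _TM_A + _TM_B * (100.0 * fgc) - _TM_C / len(seq)
    tm_k = tm_1m + 273.15
    inv = 1.0 / tm_k + (4.29 * fgc - 3.95) * 1e-5 * math.log(mon) + 9.40e-6 * math.log(mon) ** 2
    return 1.0 / inv - 273.15


def probe_feature_table(manifest: pd.DataFrame, na_mM: float = 50.0, tris_mM: float = 10.0) -> pd.DataFrame:
    """Per-probe sequence features from a validated manifest.

    Type I probes get two melting temperatures (unmethylated seq_A and
    methylated seq_B); type II probes have no methylated sequence and
    get a missing ``tm_meth``.  ``g_content_target`` is the G fraction
    of the reverse-complement target of seq_A.
    """
    rows = []
    for probe_id, rec in manifest.iterrows():
        seq_a = rec["seq_A"]
        seq_b = rec["seq_B"]
        target = seq_a.translate(_COMPLEMENT)[::-1]
        rows.append(
            {
                "probe_id": probe_id,
                "c_content": base_content(seq_a, "C"),
                "g_content_target": base_content(target, "G"),
                "length": len(seq_a),
                "tm_unmeth": melting_temperature(seq_a, na_mM, tris_mM),
                "tm_meth": melting_temperature(seq_b, na_mM, tris_mM) if seq_b else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    stratum: str
    odds_ratio: float
    p_value: float
    fdr_adjusted_p: float
    table: tuple[int, int, int, int]  # (flag&in, flag&out, noflag&in, noflag&out)


def context_enrichment(flags, strata) -> list[EnrichmentResult]:
    """Fisher-exact enrichment of a probe flag within each stratum.

    ``flags`` is a per-probe boolean (e.g. low-MI); ``strata`` the
    per-probe category (e.g. CpG context).  Empty strata are skipped
    with a warning.  P-values are BH-adjusted across the tested strata.
    """
    flags = np.asarray(flags, dtype=bool)
    strata = np.asarray(strata)
    if flags.shape != strata.shape:
        raise ValidationError("flags and strata must be aligned")
    levels = pd.unique(strata)
    if len(levels) < 2:
        raise ValidationError("need at least 2 strata")
    if not flags.any():
        raise ValidationError("need at least 1 flagged probe")
    results = []
    for level in levels:
        inside = strata == level
        if inside.sum() == 0:
            warnings.warn(f"empty stratum {level!r} skipped", stacklevel=2)
            continue
        a = int((flags & inside).sum())
        b = int((flags & ~inside).sum())
        c = int((~flags & inside).sum())
        d = int((~flags & ~inside).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        results.append(EnrichmentResult(str(level), float(odds), float(p), np.nan, (a, b, c, d)))
    adj = stats.false_discovery_control([r.p_value for r in results], method="bh")
    for r, q in zip(results, adj):
        r.fdr_adjusted_p = float(q)
    return results
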