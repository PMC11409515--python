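"""Domain types and I/O for Infinium-style methylation intensity data.

An Infinium array records, for every CpG probe, a methylated (M) and an
unmethylated (U) fluorescence intensity.  Type II probes read M in the
Green channel and U in the Red channel from a single bead; type I probes
carry two bead sequences (one per allele) read in a single channel,
either Green (I-Grn) or Red (I-Red).  Negative-control probes have no
genomic target; their intensities characterise per-channel background
noise and drive the reliability simulation downstream.

The methylation level is summarised as the beta value

    beta = M / (M + U + alpha)

with ``alpha`` a small positive constant (typically 100) guarding
against division by zero when both signals vanish.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ProbeType",
    "Channel",
    "SchemaError",
    "ValidationError",
    "AlignmentError",
    "IntensityDataset",
    "BetaMatrix",
    "read_manifest",
    "validate_manifest",
    "read_negative_controls",
    "read_intensity_tables",
    "write_dataset",
    "compute_beta",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 100.0

#: characters permitted in probe sequences (incl. common ambiguity codes)
SEQUENCE_ALPHABET = frozenset("ACGTNRY")

MANIFEST_COLUMNS = [
    "probe_id",
    "infinium_type",
    "chr",
    "cpg_context",
    "seq_A",
    "seq_B",
    "snp_flag",
]

CPG_CONTEXTS = {"island", "shore", "shelf", "open_sea", "unknown"}
SNP_FLAGS = {"none", "snp_pos0", "snp_pos1", "other"}


class ProbeType(str, enum.Enum):
    """Infinium probe design / read-out channel."""

    II = "II"
    I_GRN = "I-Grn"
    I_RED = "I-Red"

    @classmethod
    def parse(cls, label: str) -> "ProbeType":
        norm = str(label).strip()
        aliases = {
            "II": cls.II,
            "2": cls.II,
            "I-Grn": cls.I_GRN,
            "I-Green": cls.I_GRN,
            "I-Red": cls.I_RED,
        }
        if norm in aliases:
            return aliases[norm]
        raise SchemaError(f"unknown infinium_type {label!r}")


class Channel(str, enum.Enum):
    GRN = "Grn"
    RED = "Red"


class SchemaError(ValueError):
    """A file does not follow the documented column schema."""


class ValidationError(ValueError):
    """Values violate a dataset invariant (e.g. negative intensity)."""


class AlignmentError(ValueError):
    """Two matrices that must share indexing do not."""


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a probe annotation table.

    Returns a copy indexed by ``probe_id`` with ``infinium_type`` mapped
    onto :class:`ProbeType` values.  Raises :class:`SchemaError` or
    :class:`ValidationError` on malformed input.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise SchemaError(f"manifest is missing columns: {missing}")
    df = manifest.copy()
    if df["probe_id"].duplicated().any():
        dupes = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValidationError(f"duplicate probe ids in manifest: {dupes[:5]}")
    df["infinium_type"] = df["infinium_type"].map(lambda x: ProbeType.parse(x).value)
    df["cpg_context"] = df["cpg_context"].fillna("unknown")
    bad_ctx = set(df["cpg_context"]) - CPG_CONTEXTS
    if bad_ctx:
        raise ValidationError(f"unknown cpg_context values: {sorted(bad_ctx)}")
    df["snp_flag"] = df["snp_flag"].fillna("none")
    bad_snp = set(df["snp_flag"]) - SNP_FLAGS
    if bad_snp:
        raise ValidationError(f"unknown snp_flag values: {sorted(bad_snp)}")
    for col in ("seq_A", "seq_B"):
        df[col] = df[col].fillna("").astype(str).str.upper()
        bad = df.loc[~df[col].map(lambda s: set(s) <= SEQUENCE_ALPHABET), "probe_id"]
        if len(bad):
            raise ValidationError(
                f"probe sequences with characters outside {sorted(SEQUENCE_ALPHABET)}: "
                f"{bad.tolist()[:5]}"
            )
    type2 = df["infinium_type"] == ProbeType.II.value
    if (df.loc[type2, "seq_B"] != "").any():
        offenders = df.loc[type2 & (df["seq_B"] != ""), "probe_id"].tolist()
        raise ValidationError(f"type II probes must have empty seq_B: {offenders[:5]}")
    return df.set_index("probe_id", drop=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read ``manifest.csv`` (comma- or tab-separated, header required)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    return validate_manifest(df)


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class IntensityDataset:
    """Per-sample, per-probe raw intensities plus negative-control noise.

    ``m`` and ``u`` are sample x probe matrices covering *all* probes in
    the manifest; :meth:`partition` exposes the per-type views used by
    the scoring modules.  ``noise`` maps sample id -> channel ->
    vector of negative-control intensities.  Missing intensities are
    ``NaN`` and are excluded from all downstream means.
    """

    m: pd.DataFrame
    u: pd.DataFrame
    noise: dict[str, dict[Channel, np.ndarray]]
    manifest: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.m.index.equals(self.u.index) or not self.m.columns.equals(self.u.columns):
            raise AlignmentError("M and U matrices must share identical sample and probe indexing")
        for name, mat in (("M", self.m), ("U", self.u)):
            vals = mat.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError(f"negative intensity in {name} matrix")
        for sample in self.samples:
            per_chan = self.noise.get(sample, {})
            for chan in (Channel.GRN, Channel.RED):
                arr = np.asarray(per_chan.get(chan, ()), dtype=float)
                if arr.size == 0:
                    raise ValidationError(
                        f"sample {sample!r} has no negative-control intensities in channel {chan.value}"
                    )
                if (arr < 0).any():
                    raise ValidationError(
                        f"negative negative-control intensity for sample {sample!r}"
                    )

    @property
    def samples(self) -> list[str]:
        return list(self.m.index)

    def probes_of(self, ptype: ProbeType) -> pd.Index:
        mask = self.manifest["infinium_type"] == ptype.value
        probes = self.manifest.index[mask]
        return probes.intersection(self.m.columns)

    def partition(self, ptype: ProbeType) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (M, U) restricted to probes of the requested type."""
        probes = self.probes_of(ptype)
        return self.m.loc[:, probes], self.u.loc[:, probes]

    def noise_channel(self, channel: Channel) -> np.ndarray:
        """Pool a channel's negative-control intensities across all samples."""
        return np.concatenate([np.asarray(self.noise[s][channel], dtype=float) for s in self.samples])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_negative_controls(path: str | Path) -> dict[str, dict[Channel, np.ndarray]]:
    """Read ``negctrl.tsv`` (columns sample_id, channel, intensity)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "channel", "intensity"}
    if not required <= set(df.columns):
        raise SchemaError(f"negative-control file must have columns {sorted(required)}")
    if (df["intensity"].astype(float) < 0).any():
        row = int(df.index[df["intensity"].astype(float) < 0][0])
        raise ValidationError(f"negative intensity in negative-control file at row {row}")
    noise: dict[str, dict[Channel, np.ndarray]] = {}
    for (sample, chan), grp in df.groupby(["sample_id", "channel"], sort=False):
        noise.setdefault(str(sample), {})[Channel(chan)] = grp["intensity"].to_numpy(dtype=float)
    return noise


def _read_long_intensities(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"probe_id", "sample_id", "M", "U"}
    if not required <= set(df.columns):
        raise SchemaError(f"intensity file must have columns {sorted(required)}")
    for col in ("M", "U"):
        vals = df[col].astype(float)
        neg = vals < 0
        if neg.any():
            row = int(df.index[neg][0])
            raise ValidationError(f"negative intensity in column {col!r} at row {row}")
    m = df.pivot(index="sample_id", columns="probe_id", values="M").astype(float)
    u = df.pivot(index="sample_id", columns="probe_id", values="U").astype(float)
    for mat in (m, u):
        mat.index.name = None
        mat.columns.name = None
    return m, u


def _read_wide_matrix(path: str | Path) -> pd.DataFrame:
    """Wide matrices have probe rows and sample columns; transpose to sample x probe."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0).astype(float)
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"negative intensity in {path}")
    return df.T


def read_intensity_tables(
    paths: Mapping[str, str | Path],
    manifest: pd.DataFrame,
) -> IntensityDataset:
    """Assemble an :class:`IntensityDataset` from delimited text files.

    ``paths`` maps logical names to files: either ``{"intensities": ...}``
    (long format: probe_id, sample_id, M, U) or ``{"m": ..., "u": ...}``
    (wide matrices with probe rows and sample columns), plus a required
    ``"negctrl"`` entry.  Probes absent from the manifest are dropped
    with a warning; a probe in the manifest missing from the files is
    kept as all-missing only if present in neither matrix column set.
    """
    if "negctrl" not in paths:
        raise SchemaError("paths must include a 'negctrl' entry")
    if "intensities" in paths:
        m, u = _read_long_intensities(paths["intensities"])
    elif "m" in paths and "u" in paths:
        m, u = _read_wide_matrix(paths["m"]), _read_wide_matrix(paths["u"])
    else:
        raise SchemaError("paths must contain 'intensities' or both 'm' and 'u'")
    if not m.columns.equals(u.columns) or not m.index.equals(u.index):
        u = u.reindex(index=m.index, columns=m.columns)

    known = m.columns.isin(manifest.index)
    n_unknown = int((~known).sum())
    if n_unknown:
        warnings.warn(
            f"dropping {n_unknown} probe(s) absent from the manifest",
            stacklevel=2,
        )
        m, u = m.loc[:, known], u.loc[:, known]
    noise = read_negative_controls(paths["negctrl"])
    missing_noise = [s for s in m.index if s not in noise]
    if missing_noise:
        raise ValidationError(f"samples without negative controls: {missing_noise[:5]}")
    return IntensityDataset(m=m, u=u, noise=noise, manifest=manifest)


def write_dataset(dataset: IntensityDataset, outdir: str | Path) -> dict[str, Path]:
    """Write intensities.tsv, negctrl.tsv and manifest.csv; returns the paths.

    Floats are written with ``repr`` round-trip precision so a write/read
    cycle reproduces the dataset bit-exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": outdir / "intensities.tsv",
        "negctrl": outdir / "negctrl.tsv",
        "manifest": outdir / "manifest.csv",
    }
    long = (
        dataset.m.stack(future_stack=True)
        .rename("M")
        .to_frame()
        .join(dataset.u.stack(future_stack=True).rename("U"))
        .reset_index()
    )
    long.columns = ["sample_id", "probe_id", "M", "U"]
    long = long[["probe_id", "sample_id", "M", "U"]]
    long.to_csv(paths["intensities"], sep="\t", index=False, na_rep="NA")
    rows = []
    for sample in dataset.samples:
        for chan in (Channel.GRN, Channel.RED):
            for v in dataset.noise[sample][chan]:
                rows.append((sample, chan.value, v))
    pd.DataFrame(rows, columns=["sample_id", "channel", "intensity"]).to_csv(
        paths["negctrl"], sep="\t", index=False
    )
    dataset.manifest.to_csv(paths["manifest"], index=False)
    return paths


# ---------------------------------------------------------------------------
# beta values
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Beta values in [0, 1] with the alpha constant that produced them."""

    values: pd.DataFrame
    alpha: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("beta values must lie in [0, 1]")


def compute_beta(
    m: pd.DataFrame | np.ndarray,
    u: pd.DataFrame | np.ndarray,
    alpha: float = DEFAULT_ALPHA,
) -> BetaMatrix:
    """Elementwise beta = M / (M + U + alpha); missing in, missing out."""
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    m_df = pd.DataFrame(m) if not isinstance(m, pd.DataFrame) else m
    u_df = pd.DataFrame(u) if not isinstance(u, pd.DataFrame) else u
    if m_df.shape != u_df.shape or not m_df.index.equals(u_df.index) or not m_df.columns.equals(u_df.columns):
        raise AlignmentError("M and U must be aligned (same shape, samples and probes)")
    values = m_df / (m_df + u_df + alpha)
    return BetaMatrix(values=values, alpha=float(alpha))
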