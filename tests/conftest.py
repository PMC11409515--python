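"""Shared fixtures: tiny handcrafted datasets and small synthetic draws."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from relmap import (
    Channel,
    IntensityDataset,
    IntensityTier,
    NoiseModel,
    ProbeType,
    SyntheticConfig,
    generate_dataset,
    validate_manifest,
)


def make_manifest(n2=3, n1g=0, n1r=0) -> pd.DataFrame:
    rows = []
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    i = 0
    for ptype, n in ((ProbeType.II, n2), (ProbeType.I_GRN, n1g), (ProbeType.I_RED, n1r)):
        for _ in range(n):
            seq_a = "".join(rng.choice(bases, 50))
            seq_b = "" if ptype == ProbeType.II else "".join(rng.choice(bases, 50))
            rows.append(
                {
                    "probe_id": f"cg{i:07d}",
                    "infinium_type": ptype.value,
                    "chr": "chr1",
                    "cpg_context": "island",
                    "seq_A": seq_a,
                    "seq_B": seq_b,
                    "snp_flag": "none",
                }
            )
            i += 1
    return validate_manifest(pd.DataFrame(rows))


def make_dataset(m, u, manifest=None, noise_g=(10.0, 20.0), noise_r=(30.0, 50.0)):
    """Small dataset from explicit sample x probe arrays."""
    m = np.atleast_2d(np.asarray(m, dtype=float))
    manifest = manifest if manifest is not None else make_manifest(n2=m.shape[1])
    samples = [f"s{i}" for i in range(m.shape[0])]
    probes = list(manifest["probe_id"])[: m.shape[1]]
    m_df = pd.DataFrame(m, index=samples, columns=probes)
    u_df = pd.DataFrame(np.atleast_2d(np.asarray(u, dtype=float)), index=samples, columns=probes)
    noise = {
        s: {
            Channel.GRN: np.asarray(noise_g, dtype=float),
            Channel.RED: np.asarray(noise_r, dtype=float),
        }
        for s in samples
    }
    return IntensityDataset(m=m_df, u=u_df, noise=noise, manifest=manifest)


@pytest.fixture
def tiny_dataset():
    """2 samples x 3 type II probes, complete data."""
    return make_dataset(
        m=[[100.0, 200.0, 300.0], [110.0, 190.0, 310.0]],
        u=[[300.0, 400.0, 100.0], [280.0, 420.0, 90.0]],
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """Small but realistic complete synthetic dataset (seconds to build)."""
    config = SyntheticConfig(
        seed=11,
        n_samples=20,
        replicates=2,
        n_probes={ProbeType.II: 1500},
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def mixed_type_synthetic():
    """Synthetic dataset containing all three probe types."""
    config = SyntheticConfig(
        seed=5,
        n_samples=8,
        replicates=2,
        n_probes={ProbeType.II: 300, ProbeType.I_GRN: 120, ProbeType.I_RED: 120},
    )
    return generate_dataset(config)


def noiseless_config(seed=3, n_samples=10, n_probes=400):
    """Zero noise, unit gain, no biological spread: exact recovery regime."""
    return SyntheticConfig(
        seed=seed,
        n_samples=n_samples,
        replicates=2,
        n_probes={ProbeType.II: n_probes},
        noise={
            Channel.GRN: NoiseModel(median=0.0, sigma=0.0),
            Channel.RED: NoiseModel(median=0.0, sigma=0.0),
        },
        gain_sigma=0.0,
        beta_individual_sd=0.0,
        tiers=(
            IntensityTier(fraction=0.5, target=1000.0, sigma=0.0),
            IntensityTier(fraction=0.5, target=8000.0, sigma=0.0),
        ),
    )
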