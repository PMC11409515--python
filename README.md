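# relmap

Data-driven reliability scoring and dynamic probe filtering for Illumina
Infinium methylation arrays.

## The problem

Infinium arrays (450K, EPIC) report DNA methylation at each CpG as a
beta value

```
β = M / (M + U + α),      α ≈ 100
```

from the methylated (M) and unmethylated (U) fluorescence intensities.
At low total intensity, background noise dominates the ratio and β
becomes irreproducible: the same sample measured twice can give wildly
different values at weak probes, while strong probes replicate almost
perfectly. Fixed blocklists cannot capture this because signal strength
and noise levels differ between datasets. `relmap` quantifies, for a
*specific* dataset, how much that dataset's own background noise
perturbs each probe's β value, and derives a data-driven exclusion
threshold. It is aimed at epigenomics analysts doing array QC before
differential-methylation or clock analyses.

## The method

Probes are handled per type/channel (type II; type I-Green; type I-Red)
throughout.

1. **MI score.** For sample *i*, AIS_i = mean_j(M_ij) + mean_j(U_ij) is
   the sample's average intensity; N_ij = (M_ij + U_ij) / AIS_i the
   probe's normalized intensity; and MI_j = mean_i(N_ij) the probe's
   mean normalized intensity. MI averages to 1 per type/channel; low MI
   marks weak probes.
2. **Reliability Map.** Negative-control probes (no genomic target)
   give per-channel background noise pools. On a fixed grid of
   intensity pairs (M_k, U_l) — default 0..5000 step 100 — noise values
   are resampled 1000× and β_m = (M_k + M_err) / (M_k + M_err + U_l +
   U_err) simulated; the cell's Q score is the mean absolute deviation
   of these β values. Q is the expected β perturbation at those
   intensities.
3. **Unreliability score.** Each observed (M_ij, U_ij) is
   background-subtracted and looked up at the nearest grid node; a
   probe's unreliability is its average Q* across samples. Coordinates
   beyond the grid maximum score 0 (fully reliable).
4. **Dynamic threshold.** Unreliability falls steeply with MI, then
   stabilizes. A penalized-spline GAM is fitted to the (MI,
   unreliability) scatter and the *critical point* — the maximum of the
   curve's second derivative on the declining limb — marks where the
   decline flattens. Probes with MI below the critical MI are flagged
   unreliable.

Also included: a detection p-value (detP) baseline that compares total
intensity against the Gaussian background summary; SNP-effect flagging
from modality fingerprints (a variant at the target CpG's C gives
tri-modal β; at the G, tri-modal total intensity); probe sequence
features (C content, GC-based melting temperature with Owczarzy salt
correction, CpG-context enrichment via Fisher tests); and a synthetic
array generator with full ground truth, so the whole framework is
testable without controlled-access data.

## Worked example

```python
from relmap import (
    ProbeType, SyntheticConfig, generate_dataset, compute_mi,
    build_noise_pool, build_reliability_map, unreliability_scores,
    dynamic_threshold, compute_detp, detp_flagged,
)

config = SyntheticConfig(seed=7, n_samples=40, replicates=2,
                         n_probes={ProbeType.II: 4000})
dataset, truth = generate_dataset(config)

mi = compute_mi(dataset, ProbeType.II)
pool = build_noise_pool(dataset, ProbeType.II)
rmap = build_reliability_map(pool, n_draws=1000, seed=7)
unrel = unreliability_scores(dataset, rmap, ProbeType.II)
result = dynamic_threshold(mi, unrel, ProbeType.II)

print(f"background means (M, U): ({pool.m_noise_mean:.1f}, {pool.u_noise_mean:.1f})")
print(f"mean MI: {mi['mi'].mean():.6f}")
print(f"Q at (100, 100): {rmap.q[1, 1]:.4f}   Q at (4000, 4000): {rmap.q[40, 40]:.4f}")
print(f"critical MI: {result.critical_mi:.3f}")
print(f"probes flagged unreliable: {len(result.flagged_probes)} / {dataset.m.shape[1]}")

detp = compute_detp(dataset, ProbeType.II)
print(f"probes flagged by detP at p > 0.01: {len(detp_flagged(detp, 0.01))}")
```

prints

```
background means (M, U): (100.7, 125.8)
mean MI: 1.000000
Q at (100, 100): 0.0173   Q at (4000, 4000): 0.0009
critical MI: 0.197
probes flagged unreliable: 1558 / 4000
probes flagged by detP at p > 0.01: 37
```

Reading this: channel backgrounds average ~100 (M/Green) and ~126
(U/Red) intensity units; MI is normalized so its mean is exactly 1; a
probe measured at raw intensities (100, 100) has an expected β
perturbation of ±0.017 under this dataset's noise, versus ±0.0009 at
(4000, 4000); the fitted curve flattens at MI ≈ 0.20, flagging the
1558 probes below it — far more than the 37 statistical outliers the
conventional detP filter catches, because β instability sets in well
above the detection limit.

The same pipeline runs from the shell on exported intensity tables:

```
relmap simulate --outdir sim --seed 7 --n-samples 40 --n-probes 4000
relmap run --intensities sim/intensities.tsv --negctrl sim/negctrl.tsv \
           --manifest sim/manifest.csv --outdir out --seed 7
```

which writes `mi_scores.tsv`, `unreliability.tsv`, `scores.tsv` (with a
boolean `unreliable` column), `threshold.json`, the reliability maps,
detP tables and a `run_manifest.json` recording every seed and
parameter.

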