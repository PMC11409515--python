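# Methods

## Signal model and scores

An Infinium probe reports a methylated intensity M and an unmethylated
intensity U; methylation is summarised as β = M/(M+U+α) with α = 100 by
default (configurable; it only guards the denominator and caps β below
1). Probes are always processed within their type/channel partition —
type II (M read in Green, U in Red), type I-Green and type I-Red (both
alleles in one channel) — because the chemistries have different
background and intensity characteristics.

**MI.** The mean normalized intensity of probe j is
MI_j = mean_i[(M_ij + U_ij)/AIS_i] with AIS_i the sample's average M
plus average U over the partition's probes. With complete data the
probe-mean of normalized intensities is exactly 1 for every sample, so
MI averages to 1 per partition; MI is invariant to per-sample scaling
(array brightness) by construction. Missing intensities are excluded
from both the AIS and the probe means, and `n_samples_used` records the
coverage; this is the natural extension of the complete-data formulas.

**Reliability Map.** Background noise is taken from the
negative-control probes, pooled across all samples per channel (the map
is a dataset-level object; per-array maps would be an option for very
heterogeneous batches but are not built here). The M-side and U-side
pools follow the chemistry: type II draws M noise from Green and U
noise from Red; type I probes draw both sides from their single
channel's pool, independently — the M and U noise of a type I probe are
conceptually distinct draws but no disjoint negative-control subsets
are defined, so independent resampling from one pool is used. On a grid
of fixed intensities (default min 0, max 5000, step 100, i.e. 51 × 51
cells), β values are simulated by adding resampled noise:
β_m = (M_k + M_err,m)/((M_k + M_err,m) + (U_l + U_err,m)), m = 1..1000.
Note there is no α in this formula: the simulation characterises the
noise-induced spread of the intensity ratio itself; α only enters
reported β values. The cell's Q score is the mean absolute deviation
about the mean (not the median) of the simulated β values; it is
bounded by 0.5 for values in [0, 1]. If signal and noise are all
exactly zero the ratio is undefined and β is set to 0.5; a constant β
vector yields Q = 0 exactly.

Each cell uses an independent RNG stream seeded by (map seed, k, l), so
the map is bit-reproducible and independent of evaluation order.

**Unreliability.** For each observed (M_ij, U_ij) the pooled channel
noise means are subtracted and the Q value at the Euclidean-nearest
grid node is retrieved (ties break toward the lower-index node; on the
uniform grid the search factorises per axis and is verified against an
exhaustive scan in the tests). Corrected coordinates above the grid
maximum in either axis return Q* = 0 — beyond the modelled range noise
is immaterial. Coordinates below the grid minimum clamp to the minimum
rather than returning 0: near-zero corrected signal is the *least*
reliable regime, and "outside the grid means reliable" is only sensible
above the maximum. The probe's unreliability score is the mean Q* over
its non-missing samples.

**Dynamic threshold.** Unreliability falls steeply with MI and then
stabilises. The curve is estimated by a Gaussian GAM with a single
penalized smooth: a cubic B-spline basis (default 35 basis functions on
equally spaced knots), an Eilers–Marx second-order difference penalty,
and natural boundary conditions (second derivative zero at both ends,
as in cubic smoothing splines and mgcv's cubic regression splines). The
penalty weight is selected by generalized cross-validation over a
49-point log-spaced grid unless fixed. The natural boundary condition
is load-bearing: with a clamped basis the steep low-MI limb concentrates
spurious curvature at the boundary and the second-derivative maximum
degenerates to the first grid point; with natural boundaries it lands
at the foot of the decline, which is the intended critical point. The
default basis dimension sits on a stable plateau (25–50 basis functions
give essentially the same flagged set on the validation designs).

The fitted curve is evaluated on a uniform 512-point grid from the
minimum MI to the 99th percentile of MI; probes beyond that quantile
are excluded from the fit as well as the grid, which makes the
threshold insensitive to a small fraction of extreme-MI probes.
Duplicated input rows are aggregated into weights normalized to mean 1,
so replicating the whole input leaves the fit unchanged. The second
derivative is taken by central finite differences on the grid, and the
critical point is its maximum restricted to strictly right of the
curve's global maximum (the declining limb and its flattening); a flat
curve raises a "no critical point" error. Probes with MI *strictly*
below the critical MI are flagged; a probe exactly at the threshold is
kept (an arbitrary but fixed boundary rule). Flagging by
unreliability > critical unreliability is exposed as an option
(`flag_by="unreliability"`); the two coincide on a monotone curve but
can differ for noisy scores, and MI-based flagging is the default
because MI is the smoother, better-estimated quantity.

## detP baseline

The conventional detection p-value treats a probe's total intensity
M+U as a draw from a Gaussian background with mean equal to the sum of
the two relevant channels' negative-control means and standard
deviation equal to the sum of their standard deviations; p is the
upper-tail probability of the observed total. A probe fails a sample
when p exceeds the threshold, and is flagged when it fails in more than
half of its samples (the aggregation rule is configurable via
`sample_fraction`). Exposed stringencies are 0.01, 1e-16 and 1e-40;
note that the *smaller* numeric threshold is the more aggressive
filter — every probe failing at 0.01 also fails at 1e-40 — so the
flagged sets nest as flags(0.01) ⊆ flags(1e-16) ⊆ flags(1e-40). The
detP variant here summarises both channels into one Gaussian; it is a
faithful but independent re-implementation of the conventional filter,
not a port of any particular package. Out-of-band detection p-values
are out of scope.

## SNP modality flagging

A genetic variant at the target CpG's cytosine (position 0) splits β
across a cohort into three genotype modes; a variant at the guanine
(position 1) degrades hybridisation, producing total-intensity tiers of
roughly 1 : 0.5 : 0.05 for the two/one/zero intact-allele genotypes and
a bi- (sometimes tri-) modal β distribution. The detector fits 1..3
component Gaussian mixtures (scikit-learn, fixed random state, 3
initialisations), picks the component count by BIC, and discards
components with weight < 0.05; total intensities are log-transformed
first because the tiers are multiplicative. A probe is `snp0_like` if β
is tri-modal, else `snp1_like` if log-intensity is tri-modal and β has
at least two modes, else `none`. The mixture-BIC detector is a design
choice — the fingerprints, not the detector, are the domain knowledge —
and it needs at least 30 samples; that floor is a practical choice, not
a derived bound. Genotype calling and identifying which mode is the
true C/C variant are out of scope.

## Probe sequence features

C content (and the target's G content, its reverse-complement mirror)
is computed over unambiguous bases. Melting temperature uses the
GC-count empirical family, Tm(1 M Na+) = 81.5 + 0.41·GC% − 600/length
(°C), followed by the Owczarzy GC-dependent monovalent correction on
the reciprocal Kelvin scale with effective monovalent concentration
Na + Tris/2 (defaults Na = 50 mM, Tris = 10 mM, the EPIC v1.0
hybridisation buffer). At 1 M monovalent the correction vanishes and
the base formula is returned exactly, which the tests pin
(50-mer, GC 50% → 90.0 °C). Tm is monotone in GC at fixed length and
salt; lower salt lowers Tm. Type I probes get separate Tm values for
the unmethylated and methylated bead sequences; type II has one
sequence. Nearest-neighbour thermodynamics and genome alignment of
probes are out of scope.

Context enrichment builds a 2×2 table per stratum (flagged × in-stratum)
and tests it with the two-sided Fisher exact test (scipy), reporting
the sample odds ratio ad/bc and Benjamini–Hochberg adjusted p values
across strata. The implementation is cross-checked against brute-force
hypergeometric enumeration over every table with all margins ≤ 30.

## Synthetic data generator

The generator emulates the structures the framework exploits:
log-normal per-channel background noise (defaults: Green median 100,
Red median 125, log-sd 0.12) recorded both inside every measurement and
as dedicated negative-control draws; probe total-signal "tiers"
spanning a wide range (log-normal around a target or log-uniform over a
range); per-sample multiplicative gain (log-sd 0.15) for array
brightness differences; true β from a mixture concentrated near 0 and
1 with a uniform component; per-individual biological β variation
(sd 0.02) shared across technical replicates — without it, the small
α/noise offsets between intensity tiers register as artificial β
modes; genotype-driven SNP artifacts under Hardy–Weinberg sampling
(position-0: β modes 0.1/0.5/0.9; position-1: tier multipliers
1/0.5/0.05); and Y-chromosome probes retaining 2% signal in
female-labelled samples. The signal model is additive with
multiplicative gain: M = s·β·g + noise, U = s·(1−β)·g + noise.

Fixed study designs (all type II):

* **reference**: 100 samples as 50 technical-replicate pairs, 10,000
  probes over five tiers (targets 100/400/1500/5000/12000, spread
  log-sd 0.25). The lowest tier sits below the summed background mean
  (~227), populating the Q-saturation regime as real arrays do
  (near-zero-intensity probes).
* **threshold recovery**: 40 samples, 8,000 probes; 2,000 draw their
  total signal log-uniformly in (20, 450) — below the designed
  noise-dominance boundary T = 500 — and the rest span 450..20,000.
* **SNP cohort**: 200 independent samples, 520 probes at one tier with
  60 position-0, 60 position-1 and 400 ordinary probes.

What the generator does **not** emulate: bisulfite-conversion
chemistry, cross-hybridisation, cell-type composition, dye bias,
batch/position effects, and empirically fitted noise shapes (the
log-normal defaults are stylised, not fitted to any instrument).
Passing tests therefore demonstrate that the method recovers designed
noise structure, intensity dependence and modality fingerprints — not
that it is robust to every artifact of real arrays.

Replicate statistics: Δβ is the per-probe mean |β difference| over
sample pairs; SDβ the per-probe standard deviation (n−1 denominator)
over a sample subset.

## Numerical and interface choices

* Missing intensities are an explicit "NA" sentinel in files, NaN in
  memory, and excluded from every mean; writers emit round-trip
  (shortest-repr) floats so write→read is bit-exact.
* Probes in files but absent from the manifest are dropped with a
  warning; negative intensities and malformed schemas raise typed
  errors naming the offending row/column.
* All probes are scored; filtering is left to the user, and AIS uses
  all probes of the partition (no circular exclusion of unreliable
  probes).
* Every stochastic step takes an explicit seed; the pipeline writes a
  run manifest (seeds, grid, smoothing parameters, versions, stage
  timings) and reruns are bit-identical.
* Validation designs were sized (10,000 probes × 100 samples at the
  largest) so the full suite and the acceptance script each run in a
  few minutes on one CPU; the framework itself is vectorised and
  handles EPIC-scale arrays (~850k probes) in memory.

## Known limitations

* The critical point's exact location depends on the smoother's basis
  dimension within a factor of ~2 on smooth hyperbola-like curves; the
  flagged set is stable because the curve is flat there, but reporting
  `critical_mi` to more than ~1 significant figure overstates its
  precision.
* Type I M/U noise independence is an assumption (see above); if the
  true within-array noise of the two bead types is correlated, Q is
  slightly overestimated for type I probes.
* detP here summarises two channels into a single Gaussian; packages
  differ in the exact variant, so absolute flagged counts are
  comparable only qualitatively.
* The SNP detector reports fingerprints, not genotypes, and loses power
  below ~100 samples or for allele frequencies far from 0.5 (few
  carriers in the minor mode).
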