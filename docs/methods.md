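# Methods

This note documents the models, defaults and numerical conventions behind
each stage of the pipeline, the design choices made where the methodology
was genuinely open, and what the synthetic benchmarks do and do not
establish about real data.

## Miniature synaptic event detection

**Signal model.** Recordings are uniformly sampled current traces (pA) at
10 kHz. Miniature events are transient deflections (inward/negative for
EPSCs at −65 mV, outward/positive for IPSCs at 0 mV) riding on Gaussian
baseline noise.

**Filtering.** A zero-phase 2nd-order Butterworth band-pass (4–1000 Hz by
default), applied forward–backward (`scipy.signal.sosfiltfilt`). Zero
phase preserves event timing, which matters because detected events are
scored against planted times with a ±5 ms tolerance. The forward–backward
pass squares the magnitude response, so the effective roll-off is 4th
order.

**Baseline SD.** The detection thresholds are expressed in multiples of
the baseline noise SD, measured in a 50 ms event-free segment. Segment
selection is automated: a 50 ms window slides in 10 ms steps over the
filtered trace and the SD of the *median-SD* window is used. Windows
containing events populate the upper tail of the window-SD distribution,
so the median window is event-free whenever events occupy less than half
the trace (at the event rates and kinetics relevant here they occupy a few
percent). The minimum-SD window was rejected: band-passed noise has few
effective degrees of freedom per 50 ms, so the minimum runs 20–30% below
the true SD, which at fixed thresholds inflates the false-event rate by an
order of magnitude.

**Dual-threshold detection.** A candidate event is a contiguous excursion
of the rectified filtered trace above `amp_thresh_sd × SD`. Its extent
runs between crossings of one quarter of the amplitude threshold; the wide
extent exists solely to keep noise-interrupted decay tails of a single
event inside one candidate (an 8×SD event remains above a 2-SD threshold
for ~10 ms, and noise readily carves spurious local maxima into that
tail). The candidate is accepted when the trapezoidal area of its largest
supra-threshold excursion, in SD·ms, reaches `area_thresh_sd_ms`. Peak
amplitude is read off the rectified filtered trace. Accepted peaks closer
than 2 ms are resolved keeping the larger. Candidates within 100 ms of
either trace end are discarded (zero-phase filter edge transients live
there, and boundary events are incompletely sampled). Both acceptance
counts are monotone in the thresholds: raising either threshold never
increases the number of accepted events on a fixed trace.

Default thresholds follow the age/condition table (amplitude SD, area
SD·ms): (3, 4.5) 0M mEPSC, (3, 9) 0M mIPSC, (2, 3) 3M/6M mEPSC,
(2, 6) 3M/6M mIPSC. At the permissive (2, 3) setting a residual
false-alarm rate of ~0.05–0.1 events/s on pure noise is intrinsic — a
2-SD amplitude bar admits frequent noise excursions and the area test
removes most but not all. Consequently the relative error of frequency
estimates grows as the true event rate approaches the false-alarm rate;
recovery is excellent at ≥1 Hz (median error ≤8%) and degrades at
0.2 Hz.

**Summaries.** Frequency = accepted events / trace duration; amplitude =
mean accepted peak (flagged missing when no events). E/I ratio = mEPSC
over mIPSC frequency per cell (miniature mode) or evoked EPSC over IPSC
peak amplitude (evoked mode; amplitude rather than charge, matching the
miniature analysis). Zero denominators yield NaN and are excluded listwise
from group statistics. LTD magnitude renormalizes the field-EPSP series to
unit mean over (−10, 0] min and returns the mean over [30, 40] min —
idempotent and invariant to uniform rescaling. Group phenotype effects are
logFC = log₂(mean VPA / mean UE), so the logFC of an E/I ratio computed
from group means decomposes exactly as logFC(E) − logFC(I). Per-age group
comparisons use Welch's t-test with step-down Sidak (Holm–Sidak)
correction across the age family.

## Spine morphometry

Diameters come from least-squares fits of
`a·exp(−(x−µ)²/2σ²) + c` to transverse and axial intensity profiles; the
diameter is 2σ. The constant offset `c` absorbs background staining (real
profiles do not decay to zero). Volume is the spheroid form
V = π·d_t²·d_a/6. Because direct diameter measurement is unreliable for
small spines, a proportional model V = c·OD is calibrated by
through-origin least squares on reference spines — both diameters
> 0.4 µm and volume < 0.4 µm³ (the published criterion names a single
"diameter"; requiring both axes is the conservative reading) — and applied
to the remaining spines' optical densities. Through-origin fitting has no
intercept by construction, matching the proportionality assumption; it is
not robust to gross OD outliers (a single 1.5× corrupted reference among
ten shifts the coefficient by ~7%). Spine density is count per µm of
dendritic segment (25–50 µm from the soma at 0M, 50–75 µm at 3M/6M, the
segments of highest density at those ages). Volume and PSD-length
distributions are compared with the two-sample two-sided KS test, exact
when min(n) ≤ 10, asymptotic otherwise.

## Vocal repertoire

Calls carry one of seven labels (ekk/cough, phee, trill, tsik, twitter,
phee-trill/trill-phee, other). Consecutive calls separated by ≤ 50 ms are
merged into one bout (the merge threshold tolerates annotation jitter
around "no silent gap"); a bout mixing phee and trill takes the compound
label, otherwise the modal type with ties going to the first occurrence.
Ratios rᵢ are per-type bout fractions; entropy is −Σ rᵢ log₂ rᵢ bits with
0·log 0 := 0, maximal (log₂ 7 ≈ 2.81) for a uniform repertoire and 0 when
a single call type dominates. Entropy is computed per session on bouts
(a flag switches to raw calls) and averaged per animal over postnatal
weeks 11–13.

## Differential expression and trajectory clustering

The pipeline starts from a normalized log2 matrix (probes or genes ×
samples) with (age, group, area) metadata; cortical areas are treated as
exchangeable replicates within each age × group cell (an assumption, not a
validated equivalence — per-area stratification is possible by subsetting
the metadata).

1. *Expressed filter*: mean log2 value across all samples > 5 (strict).
   The mean aggregation is a stable choice where any-sample or per-region
   rules would also be defensible.
2. *Per-age tests*: logFC = mean(VPA) − mean(UE) on the log2 scale;
   two-sided Welch t; Benjamini–Hochberg within the family of expressed,
   testable genes of that age (each age is its own family, since adjusted
   p-values are reported per age). Zero-variance genes: equal means → p=1;
   unequal means → flagged and excluded from the family with a logged
   count.
3. *Probe collapse*: per gene keep the probe with the smallest adjusted p
   (minimum across ages; ties by smallest raw p, then lexicographic probe
   id).
4. *DEG rule*: |logFC| > 0.4 and p_adj < 0.05 at either age, both strict.
5. *Clustering*: k-means (k-means++, 50 restarts, seeded) on DEG logFC
   triples over (0M, 3M, 6M), for k = 1..8. The cluster number minimizes
   AIC(k) = RSS(k) + 2·k·d with d = 3 — the Gaussian information criterion
   with the per-coordinate variance treated as known, so the penalty is
   2 parameters per centroid coordinate. The popular log-likelihood
   variant with an *estimated* shared variance,
   n·d·ln(RSS/(n·d)) + 2·k·d, is unusable for this selection task: on any
   Gaussian-ish cloud the log term falls faster than the penalty grows
   (splitting one spherical cluster cuts RSS by ~7%, i.e. hundreds of AIC
   units against a penalty of 6), so it always elects the largest k, and
   it is undefined (ln 0) on noise-free data. The penalized-RSS form
   selects the planted number on synthetic data, rises strictly past it in
   the noiseless limit, and degrades to k = 1 when all trajectories
   coincide. Ties elect the smaller k. Labels are renumbered 1..k by
   ascending centroid value at 0M, making "cluster 1" the most
   birth-downregulated — deterministic across seeds once the solution has
   converged.

Fisher's exact test (one-sided, enrichment) serves both between-age DEG
overlap and gene-set enrichment (e.g. ASD-associated and critical-period
gene sets) against the expressed-gene universe; enrichment reports the
in-cluster and universe ratios alongside p. No multiplicity correction is
applied across enrichment tests (raw one-sided p-values are reported).

## Integration

The linkage metric between a phenotype trajectory and a cluster centroid
is the mean absolute difference over the three ages — a proper metric on
ℝ³ (scaled L1). The distance matrix includes a "3r" column against the
negated cluster-3 centroid to expose inverse correlation. Cross-species
agreement: Spearman correlation (average ranks on ties) of model vs
external logFC over genes with p_adj < 0.1 in *both* datasets (a flag
relaxes to either); with ≤ 8 qualifying genes the two-sided p is exact by
full permutation enumeration, otherwise asymptotic; fewer than 3 genes is
flagged insufficient rather than tested. Module concordance: within each
co-expression module, genes with nonzero logFC in both datasets are
scored for sign agreement and tested one-sided against binomial(n, 0.5);
the module direction is the majority model-logFC sign. Homolog maps
resolve one-to-many mappings to the lexicographically first target and
drop unmapped or duplicate-target rows with logged counts — a
deterministic convention, not a biological claim.

## Synthetic data

All generators are pure functions of their configuration; the single seed
is split per named sub-stream (CRC32-keyed `SeedSequence` spawn), so
adding a generator never perturbs existing draws. Every generator returns
its ground truth as a serializable table.

- *Traces*: homogeneous Poisson event times; gamma-distributed peak
  amplitudes with configured mean and CV (exactly mean `amp_mean_pa`, CV
  `amp_cv`, always positive); a difference-of-exponentials kernel
  (0.5 ms rise, 5 ms decay) normalized to unit peak so thresholds act on
  the drawn amplitude; linear superposition of overlaps; additive white
  Gaussian noise. Defaults (10 pA mean peak, CV 0.3, 1.25 pA noise — an
  8× peak-to-noise ratio) are placeholders in the plausible range for
  cortical miniature currents; no distributional parameters are
  established for marmoset cortex. Real recordings additionally contain
  correlated noise, baseline drift and amplitude-kinetics correlations
  that this generator does not emulate, so detector benchmarks here bound
  performance under ideal noise, not recording artifacts.
- *Spine profiles*: per-axis Gaussians with σ = diameter/2 on a fixed
  61-point grid, random amplitude over a constant background,
  multiplicative noise; OD = coefficient × true volume × (1 + noise).
- *Call sessions*: i.i.d. categorical draws with exponential inter-call
  gaps (mean 2 s); bout structure itself is not simulated.
- *Expression*: per-gene baseline ~ N(7, 1.5²) log2 units; 10% of genes
  are DEGs split 40/30/30 across three clusters with planted logFC
  trajectories (−0.8, −0.2, −0.1), (−0.1, −0.7, −0.3), (0.1, 0.7, 0.3);
  VPA samples of a DEG gene receive the cluster effect at each age;
  residual noise SD 0.3; 8 samples per age × group. DEG effects are
  planted only on genes whose baseline clears the expression floor
  (baseline > 5.5), so planted truth is recoverable in principle — at
  zero noise no planted DEG can be lost to the expressed filter.
  Microarray realities (probe-level artifacts, intensity-dependent
  variance, batch structure) are not emulated; recovery rates measured
  here are upper bounds under the homoscedastic model.
- *Cross-species tables*: logFC_A ~ N(0, 0.5²) per gene; the external
  sign agrees with the module's concordance probability, magnitudes drawn
  independently; adjusted p-values uniform on (0, 0.09) so the standard
  modulation cut keeps all genes.
- *LTD series*: piecewise-constant (baseline 1, planted post-LFS level)
  plus jitter; induction dynamics are deliberately not modeled.

## Pipeline

`run_pipeline` executes simulate → ephys/spines/vocal/degs → integrate,
exchanging only declared TSV files between stages, and writes a manifest
with the SHA-256 of every output; identical config + seed reruns are
byte-identical (floats are serialized with fixed formatting; no
timestamps enter outputs). Default planted group effects give the two
phenotype time courses the integration stage is meant to expose:
synaptogenesis-like parameters (spine density, mEPSC/mIPSC frequency)
maximally reduced at birth, plasticity-like parameters (E/I ratio,
post-LFS field EPSP, spine volume) dipping at 3 months. Default problem
sizes (20 s traces, 3 cells per group, 40 spines, 5000 genes × 48
samples, six 200-gene modules) run the full pipeline in well under a
minute while leaving the group comparisons adequately powered.

## Known limitations

- The detector is threshold-based by design; template-matching or
  deconvolution approaches would outperform it at low SNR and high event
  rates, and no kinetic (rise/decay) fitting is performed.
- Holm–Sidak and Welch assume independent cells/animals; the pipeline has
  no hierarchical (animal-level) model.
- The AIC selection assumes spherical clusters of comparable variance in
  logFC space; elongated or nested expression programs would require a
  mixture model.
- KS exact p-values assume continuous data (no ties); volume data passed
  through the OD calibration satisfy this in practice.
- The 2σ-diameter convention is taken as given (validated in the source
  literature against electron microscopy); it is not re-derivable from
  intensity profiles alone.
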