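# Methods

`denoisebench` compares resting-state fMRI confound-regression strategies on
a common footing: every strategy is applied in parallel to the same
minimally preprocessed data, scored with metrics that are deliberately in
tension with each other (removing more variance always looks better to a
noise metric and worse to a signal-preservation metric), and the tension is
resolved by a composite index.  Because real rs-fMRI has no noise-free
ground truth, the package ships a synthetic cohort generator whose
structure the metrics can be validated against.

## The processing conditions

Ten conditions are compared: the minimally preprocessed **baseline** and
nine denoising pipelines built from four confound families —

- **MP expansions**: the six rigid-body realignment parameters, optionally
  with squares, backward-difference derivatives and squared derivatives
  (6 / 12 / 24 columns);
- **tissue mean signals**: global signal (GS, whole-brain mean), mean white
  matter (WM) and mean cerebrospinal fluid (CSF) series;
- **aCompCor**: the first five principal components of the variance-
  normalized WM∪CSF voxel series (a `csf_only` flag reproduces the known
  upstream behavior of drawing components from CSF alone);
- **ICA-based motion removal**: a spatial ICA (FastICA on voxels-as-samples)
  whose components are classified as noise by fixed rules — CSF fraction
  > 10%, high-frequency content > 35% (median frequency of the mixing
  series over Nyquist), or a linear decision boundary in (max realignment-
  parameter correlation, edge fraction) space with the coefficients of the
  original automated classifier — and removed *nonaggressively*: each voxel
  is regressed on all mixing series jointly and only the noise components'
  fitted contribution is subtracted.

Simple-regressor pipelines are executed as one joint OLS regression of the
union of their columns (joint OLS is order-invariant; sequential partial
regression is not).  Pipelines that start with ICA removal are sequential:
downstream confounds are recomputed from the already-cleaned data.  Every
regression includes an intercept and restores the series mean, so the
grand-mean level survives every pipeline.

**Temporal degrees of freedom.** T volumes provide T tDOF; every removed
regressor costs one.  ICA removal costs one per noise-classified component
even under nonaggressive removal, so its cost varies across subjects.

## Minimal preprocessing and the filter-parity contract

Three steps: spatial Gaussian smoothing (FWHM 6 mm, mask-renormalized so
the brain rim is not darkened), grand-mean scaling of the within-scan
spatiotemporal mean to 10 000, and a Gaussian-weighted running-line
temporal high-pass (FWHM 125 s): a local line is fitted under Gaussian
weights (SD = FWHM/2.355 s) at every time point, subtracted, and the series
mean restored exactly.  The kernel is truncated and renormalized at the
boundaries, so a pure linear trend is removed everywhere; a 0.15 Hz tone
passes with gain > 0.95 while a 500 s-period oscillation is attenuated
below 0.3.

Any filter applied to the voxel series must also be applied to every
nuisance series, otherwise regression re-introduces removed variance.
Motion-parameter confounds therefore pass through the identical filter
operator before regression.  Data-derived confounds (GS/WM/CSF means,
aCompCor components) are extracted from a *confound-source* volume — scaled
and filtered but **unsmoothed**, cleaned in parallel with the analysis
volume.  Extracting nuisance signals upstream of smoothing mirrors how
production pipelines generate confounds and is essential on small phantoms,
where a 6 mm kernel would smear gray-matter signal into the thin WM/CSF
compartments and tissue regression would then delete the very signal being
benchmarked.

## Connectivity representations

ROI series are unweighted voxel means over an integer-label parcellation.
For real atlases the shipped AAL-116 table is used with cerebellar and
vermis labels excluded (90 ROIs remain) and an editable ROI→network mapping
covering seven canonical networks (basal ganglia, CEN, DMN, motor,
salience, visual, auditory); unmapped ROIs contribute only between-network
edges.

*Time domain*: the Pearson correlation matrix.  *Time-frequency domain*:
wavelet coherence with the analytic Morlet wavelet (center frequency 6), 12
voices per octave from 2/(T·TR) to Nyquist.  Coherence is
|smoothed cross-spectrum|² over the product of smoothed auto-spectra, with
boxcar smoothing over 0.6·scale in time and one octave in scale; values are
clipped to [0, 1].  Cells inside the cone of influence (e-folding width
√2·s with the standard Morlet scale-frequency relation) are excluded from
every band average.  Series are demeaned before the transform because the
sampled wavelet is only approximately zero-mean and a DC offset would
otherwise leak into the coarsest scales.  Band averages use LF = 0.01–0.1 Hz
(closed) and HF = (0.1 Hz, Nyquist]; all ROI pairs are evaluated in one
vectorized pass and each pair's coherence field feeds both bands.

Note the estimator floor: with these smoothing windows, independent white
noise shows band-mean coherence near 0.4–0.5.  Differences of coherence
(pre minus post) subtract this floor out, which is one reason the metrics
are built on difference matrices rather than absolute coherence.

## The eight quality metrics

Noise-sensitive — higher is better after inversion/normalization:

- **FD-DVARS**: Pearson correlation between framewise displacement
  (Σ|Δtranslations| + 50 mm·Σ|Δrotations|, frames 2..T) and DVARS (spatial
  RMS of the temporally differentiated in-mask series).  Low |r| means
  little residual motion; the raw score is inverted as 1−|x|.
- **HF-FC content**: mean upper triangle of the pre-minus-post HF coherence
  difference matrix — high values mean the pipeline destroyed
  high-frequency (presumed noise) coupling.

Network-sensitive:

- **Modularity Q**: signed-network Louvain on the Pearson connectome.  The
  modularity matrix treats positive and negative weights asymmetrically
  (positive part normalized by total positive weight, negative part by the
  total weight of both signs).  The optimizer runs randomized node sweeps
  with incremental community sums plus community merges; the best Q over
  `n_restarts` (default 100) restarts is returned and is never below the
  single-community Q.  On 8-node two-clique graphs it provably attains the
  exhaustive-search maximum over all 4140 partitions (tested).
- **Time-based FCC**: the tie-corrected normal-approximation Wilcoxon
  rank-sum Z contrasting within-network edges (WNE) against between-network
  edges (BNE) of the Pearson matrix, positive when WNEs are stochastically
  larger.  Per-network variants restrict the WNE group to one network.
- **Frequency-based FCC**: the same rank-sum machinery on the pre-minus-post
  LF coherence difference matrix, computed on *negated* differences so that
  preserved within-network LF links (small differences) and removed
  between-network coherence both increase the score.  The direction of this
  convention is genuinely ambiguous in the literature this metric descends
  from; the negation is the reading under which "preserving network links
  scores higher", and it is a deliberate, documented choice.

Signal-sensitive:

- **LF BOLD content**: per ROI, raw-periodogram power in 0.01–0.1 Hz after
  denoising divided by the same before (bin edges inclusive, no window, no
  detrend beyond the mean); averaged over ROIs.  ROIs with essentially zero
  pre-denoising LF power (below 1e-12 of their total) are skipped with a
  warning.
- **tDOF loss**: regressors removed / T, reported as a percentage.

Motion-bias diagnostics correlate each subject's mean FD with FD-DVARS and
with Q, per pipeline (Pearson r with two-sided p; needs ≥ 3 subjects).

## Scoring and statistics

FD-DVARS and tDOF loss (both bounded by magnitude in [0, 1]) are inverted
to 1−|x|.  Each metric column is then z-scored over **all** rows — subjects
and pipelines pooled — using the sample SD (n−1); pooling is what lets
pipeline contrasts survive normalization.  The summary performance index is
the mean of the three category means (noise: FD-DVARS†, HF-FC; network: Q,
time-FCC, freq-FCC; signal: LF content, tDOF†; † inverted).  Two variants:
a geometric mean over the seven metrics after min-max rescaling each column
into (0, 1] + 1e-6 (z-scores can be negative, so a shift is unavoidable; the
rescaling is this package's construction), and a *balanced* index,
mean{noise mean, mean(network mean, signal mean)}.

Pipelines are compared per metric family with the tie-corrected
Kruskal-Wallis test (chi-square reference, 9 df for ten pipelines),
followed by Dunn-type pairwise comparisons reusing the pooled KW ranks.
With seven metrics plus the summary index there are eight parallel
families; the family threshold is the Bonferroni-corrected alpha rounded
down to the conventional 1-2-5 grid — 0.05/8 tightened to 0.005 — so it is
never looser than the exact correction.  All-identical groups are flagged
degenerate rather than tested.

## The synthetic cohort

The generator emulates a 200-volume acquisition at TR 2.5 s with 2 mm
voxels on a 16³ grid (toy scale; the geometry, not the field of view, is
what the metrics need).  One phantom per cohort keeps parcel identity fixed
across subjects: an ellipsoidal brain whose one-voxel rim is the brain-edge
class, a central CSF block inside a WM core, and a GM shell cut into blocky
parcels assigned round-robin to the seven networks (14 parcels → two per
network by default).

**Motion** is a Gaussian random walk per parameter, bounded by reflection at the limits (clamping would leave degenerate constant stretches) (low severity:
0.02 mm / 2e-4 rad steps; high severity: doubled steps plus sparse
repositioning jumps at 4% per frame, ~0.7 mm scale), giving mean FD ≈ 0.07
mm (low) and ≈ 0.2 mm with spikes (high).

**Noise** is additive over a 1000-unit baseline, each component drawn from
its own child random stream so amplitudes can be changed independently:

| component | default | shape |
|---|---|---|
| drift | 1% of baseline | band-limited < 0.005 Hz, smooth spatial gain |
| physiological | 0.5% | 0.3 Hz respiratory + 1.23 Hz cardiac sinusoids at true rates, sampled at TR (aliasing to 0.1 / 0.03 Hz falls out of the sampling); 3× amplitude in CSF |
| global LF | 1% | band-limited 0.01–0.1 Hz, shared across the brain, GM-dominant (0.25 weight in WM/CSF) — the arousal/vascular confound GSR targets |
| system | 1% SD | white Gaussian |
| motion-coupled | gain 0.5 | (global FD term + zero-mean spatial maps × MP increments) / 0.1 mm, i.e. 1% intensity change per 0.1 mm displacement at unit gain |

The motion component's two terms are what make the noise metrics
discriminative: the global term is removable by GS regression, the
MP-linear spatial term only by motion-parameter regression (its quadratic
terms also absorb most of the FD-proportional part, since |Δ| and Δ² are
strongly correlated for Gaussian steps).  The GM-dominant global
fluctuation is reachable by GS regression but not by aCompCor, which sees
only WM/CSF — without it those two families would be indistinguishable on
network metrics.

**Signal**: each of the seven networks receives its own latent band-limited
(0.01–0.1 Hz) source; an ROI in a target network gets
√ρ·latent + √(1−ρ)·private (ρ = 0.8 by default), other ROIs independent
series, non-GM voxels zero.  Planting all seven networks (rather than a
single network) is the default because the edge-contrast metrics need more
than one within-network edge to be meaningful on a 14-parcel phantom;
single-network planting remains available.  Signal is added at SNR 1,
defined as the ratio of pooled GM temporal SDs (signal vs noise).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: EPI physics (k-space, distortion, slice timing),
anatomical realism, hemodynamic response convolution, spatially
heterogeneous vasculature, non-stationary motion artifacts (spin-history
effects), and realistic ICA dimensionality (real data yields far more than
20 meaningful components).  Rankings on the synthetic cohort demonstrate
that the metrics detect the structure they claim to detect, not that any
pipeline is optimal for a given real dataset.

## Numerical choices and degenerate inputs

- Seeds: every generator and optimizer takes an explicit seed; per-subject
  and per-component streams are derived with `SeedSequence` spawn keys and
  kept below 2³¹.  Identical configuration ⇒ byte-identical outputs.
- The baseline condition *is* the pre state: its difference matrices are
  exactly zero, its LF ratio exactly one, its tDOF loss zero; the
  all-tied rank-sum statistic is defined as 0.
- Constant series: FD-DVARS returns a flagged NaN; Pearson FC and coherence
  raise; zero-variance motion regressors are dropped with a warning.
- Rank-deficient confound designs raise and name the collinear columns.
- FastICA occasionally stalls; the ICA stage retries up to three
  deterministically derived seeds before raising.
- Coherence smoothing runs in float32 (the estimator's own bias dwarfs
  single-precision error); everything else is float64.

## Problem sizes used in the shipped checks

Cohort-scale checks run at the 16³-voxel toy grid with T = 200: a
53-subject × 10-pipeline run verifies the full 530-value panel, and five
20-subject cohorts at fixed seeds verify the ranking structure (MP
pipelines best on inverted FD-DVARS; the four GSR pipelines occupying the
top four ranks on modularity and time-FCC; WM+CSF+GS in the summary top
three on at least 80% of cohort seeds).  These sizes were chosen so the
whole suite runs on a laptop-class single core in minutes; the statistics
at this scale are property checks, not effect-size estimates.

## Known limitations

- The wavelet and smoothing parameters are a standard but particular
  choice; absolute coherence values (and thus HF-content magnitudes) are
  estimator-dependent and only differences/rankings should be interpreted.
- On the synthetic cohort the frequency-FCC tends to *penalize* GSR
  pipelines: removing the global LF confound lowers within-network LF
  coherence toward the estimator floor faster than between-network
  coherence.  The metric's sign convention is kept as documented; its
  behavior under strong global confounds is a property of
  coherence-difference contrasts worth knowing about.
- Dunn's pairwise p-values are reported unadjusted and compared to the
  0.005 family threshold; no within-family multiplicity correction beyond
  the family threshold is applied.
- aCompCor extracts one joint five-component set from WM∪CSF; a
  per-tissue alternative exists in the literature and can be emulated by
  calling the builder twice with custom masks.
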