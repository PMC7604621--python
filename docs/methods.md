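# Methods

This note documents the models behind each analysis stage, the parameters
that matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Enrichment filtering and status clustering

Input is a per-gene table of log₂ fold changes (protrusion over cell body),
one column per dataset, with p-values for the reference dataset and BH
FDR q-values. The filter keeps genes with FC > 1.6 and q < 0.05 on the
reference dataset (depletion: FC < 0.625, the reciprocal threshold on the
other side of 1). Both inequalities are strict; genes exactly on a
threshold are excluded. BH q-values are the step-up quantities
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j capped at 1 (computed via
`statsmodels.stats.multitest`; the test suite checks them against a literal
transcription of the definition).

Clustering operates on the log₂ FC columns of the comparison cell types
only, after scaling and centring each column to mean 0 and SD 1 with the
n−1 denominator. Genes missing a value in any comparison dataset are
dropped first: a gene not expressed in a cell type is uninformative about
universal targeting. The cluster count is not tuned; it is the number of
possible enrichment/depletion status combinations, k = 2^D (8 for D = 3).
k-means uses k-means++ seeding, 20 restarts, at most 300 Lloyd iterations,
and a fixed seed (`sklearn.cluster.KMeans` underneath, which also
guarantees nonempty clusters by relocating empty ones).

The universal cluster is the one whose centroid is strictly positive in
*every* comparison column, evaluated on centroids back-transformed to raw
log₂ FC units — standardisation can flip the sign of a column whose values
are mostly negative, so the standardized centroid is not a safe basis for a
sign test. If several clusters qualify, the one with the largest minimum
coordinate (the most uniformly enriched) wins.

## PWM scanning with exact p-values

A motif is a 4 × w column-stochastic matrix over ACGT (U read as T).
Windows are scored s(W) = Σⱼ log₂(pⱼ(wⱼ)/b(wⱼ)) against a 0-order
background b. Match p-values are exact tail probabilities
P(s(W′) ≥ s) for a random background word W′, computed by dynamic
programming over scores discretised to ε = 1/1000 bit; the DP result equals
exhaustive enumeration over all 4^w words (tested to w = 8). Scanning
reports every window with p below the threshold (default 10⁻⁵), sense
strand only — the substrates are single-stranded mRNA 3′UTRs, so no
reverse-complement pass. Overlapping occurrences are all reported; a
`no_overlap` option keeps a greedy left-to-right disjoint subset. Log-odds
of near-zero probabilities are floored at −64 bits before discretisation;
`N` contributes its column's background-expected score, which can only
lower a match. The per-cluster statistic is the fraction of a cluster's
genes with ≥ 2 occurrences in their 3′UTR.

Two consequences of discreteness are worth knowing. First, attainable
p-values form a finite set, so the effective scan threshold is the largest
attainable tail probability below `p_max`; the background false-positive
rate is binomial at that attainable value, not at `p_max` itself. Second, a
width-8 motif on uniform background has a best possible match p-value of
4⁻⁸ ≈ 1.5 × 10⁻⁵ — *no* width-8 window can pass the 10⁻⁵ threshold — so
planted synthetic motifs default to width 10. De-novo motif discovery is
out of scope; the PWM is an input (MEME minimal format) or estimated from
aligned instances with an additive pseudocount (0.1 by default).

## Polarisation Index

For a spot set S in a cell with binary mask M at pixel size δ (µm/px):
centroid c and radius of gyration R_g = √(mean‖x−c‖²) are computed over
mask pixel centers, and

PI = ‖ mean(S) − c ‖ / R_g.

The metric is a centroid offset over cell size; R_g is the size normaliser
(an equivalent-radius normaliser is available as an option and logged). PI = 0 when spots centre on the cell centroid; for a disk,
spots at one rim point give R/(R/√2) = √2; a uniform pattern of n spots has
E[PI] ≈ (R/2√n)·√(π/2)/R_g → 0. PI is invariant under translations,
rotations and isotropic rescalings applied jointly to mask and spots (the
suite verifies exact raster-preserving transforms to 10⁻⁶). Analysis is 2D
on maximum-intensity projections; spots are equally weighted (intensity
weighting would couple PI to illumination). Degenerate inputs — zero spots,
or a single-pixel mask with R_g = 0 — are errors, not silent zeros.
Per-cell target/control PI ratios (e.g. candidate mRNA over a uniformly
distributed housekeeping transcript) are averaged over a cohort; cells with
control PI exactly 0 are excluded and counted.

Spot detection: scale-normalised Laplacian of Gaussian at the PSF scale,
median-subtracted (the discrete LoG kernel does not sum exactly to zero, so
a flat background otherwise leaves a constant offset), thresholded at
`snr_min` (default 5) times the robust (MAD) noise SD of the response with
a small relative floor for the noiseless limit; local maxima closer than
`min_separation` (default 2σ_PSF) merge to the brightest; positions refine
by a 3×3 response centroid. Masks are inputs — no cell segmentation.

## Filopodia–particle proximity statistics

Only filopodia that emerged *and* retracted strictly inside the movie are
analysed (events touching the first or last frame are censored). For each
event, the observed distance is from its base to the nearest particle
sampled at the emergence frame; the control distance replaces the base by a
position drawn uniformly within the ROI at that frame (random pixel plus
in-pixel jitter; one draw per event by default, `n_control_draws` averages
several). Events with no particle at their frame are excluded and counted.
Distances are binned in half-open 5-µm intervals covering the larger of
the two maxima, so observed and control profiles share bin edges and each
sums to 1; frequencies are raw fractions, not annulus-area-normalised, so
an area-decay trend is expected even under no coupling.

Reported statistics:

- Pearson r with two-sided t-based p (df = n_bins − 2) of frequency against
  bin midpoint, separately for observed and control profiles — the trend
  statistic as usually plotted.
- the observed-vs-control profile test: Pearson r of (observed − control)
  frequency against midpoint, with a **permutation** p-value (499 shuffles
  of the observed/control labels on the pooled distances). Under no
  coupling the two samples are exchangeable, so this p is uniform by
  construction; the t-based p on the same statistic is conservative
  (distant bins contribute exact-zero differences) and is reported
  alongside for reference.
- Spearman ρ (average ranks) with p, between per-event distance and
  filopodium duration, for observed and control distances.
- one-sided Mann–Whitney p for observed < control — the direction check
  that control distances stochastically dominate observed ones under
  positive coupling.

A practical note on power: when the spatial coupling scale (λ ≈ 2 µm) is
smaller than the bin width, nearly all coupled events fall in the first
bin, and a *linear* trend test across ≤ 8 bins saturates around r ≈ −0.7
with p ≈ 0.1 no matter how many events are observed. The distributional
tests (Mann–Whitney, permutation profile test) carry the power in that
regime; the calibration and power checks in the acceptance suite are built
on them, with the binned Pearson reported as the descriptive trend.

Distal-axis binning projects filopodia base positions onto the unit vector
from the cell's distal tip and counts per half-open 12-µm interval;
positions projecting behind the tip are ignored.

## Synthetic data: what is and is not emulated

All generators are pure functions of their spec (including the seed), with
ground truth returned alongside the data.

- **Fold-change tables.** One block of genes per planted status vector
  (±effect per comparison dataset, default effect 1 log₂ unit) plus
  Gaussian noise (default SD 0.2 log₂ units); an optional reference column
  in which all signal genes are enriched, with p ~ Beta(0.1, 1) for signal
  and p ~ U(0, 1) for an admixture of null genes. This gives controllable
  FDR behaviour but is *not* a count-level model: no dispersion, no
  mean–variance trend, no correlated genes. Passing the recovery tests
  shows the clustering machinery is correct, not that real RNA-seq noise is
  benign.
- **Cells and spots.** Elliptical masks (default semi-axes 20 × 10 µm at
  0.2 µm/px); spots placed by rejection sampling, uniform over mask pixels,
  with von Mises angular acceptance exp(κ(cos(θ−θ₀)−1)) about the long
  axis. κ = 0 is uniform; κ ≈ 1–5 spans PI ≈ 0.1–1 (the range seen in
  polarised cells); κ ≈ 50 pins spots to a rim sector (PI → √2 on a disk).
  Real cell outlines, nuclear exclusion and 3D structure are not modelled.
- **Images.** Flat background plus isotropic Gaussian spots (default
  σ = 0.2 µm, amplitude 200, background 100 photons), Poisson or additive
  Gaussian noise. No 3D PSF, drift, photobleaching or autofluorescence.
- **Time-lapses.** Default: a 30-µm-radius disk ROI (a cell footprint),
  5 particles doing ROI-confined random walks (step SD 0.3 µm/frame;
  out-of-ROI proposals are redrawn), 300 frames at 5 s. Filopodium birth
  positions are uniform in the ROI, or, with probability
  `coupling_strength`, at an Exp(λ) radial offset from a random particle.
  Durations are `duration_base + gain/(1 + d) + noise` frames — a
  saturating proximity gain that yields a negative distance–duration trend
  without unbounded lifetimes; events outliving the movie are truncated and
  flagged incomplete. Particle intermittency, merging/splitting and ROI
  deformation over time are not modelled.
- **Sequences.** I.i.d. background letters (default uniform) with
  consensus (or PWM-sampled) motif copies planted at non-overlapping
  uniform offsets; lengths uniform in 200–400 nt.

The generator defaults were fixed once, from the experimental geometry they
emulate (cell sizes, a handful of visible reporter particles, ~25-minute
movies, 99 analysed filopodia), and the acceptance checks run at exactly
those conditions.

## Numerical choices and degenerate inputs

- Score discretisation ε = 1/1000 bit; DP and scanner share the integer
  grid, so hit p-values are exactly the DP tails.
- Coordinates: image origin top-left, x rightward, y downward, pixel
  centers at half-integers, all distances in µm via the pixel size. All
  sequence intervals are 0-based half-open, in memory and on disk; a
  figure-style region "90–282" names the half-open interval [90, 282),
  length 192 nt.
- Binning conventions are half-open everywhere: a distance exactly on an
  edge belongs to the upper bin.
- A distance-exactly-tied k-means assignment follows sklearn's tie rule;
  clustering determinism comes from the fixed seed and restart count.
- MEME files with column sums within 10⁻³ of 1 are renormalised (with a
  warning above 10⁻⁴, silently below — writers that round to 6 decimals
  produce ~10⁻⁶ deviations); larger deviations are parse errors naming the
  line.
- Zero-variance columns, empty masks, empty ROIs, empty distance lists,
  zero-spot PI and zero control PI are all explicit errors.

## Pipeline and reproducibility

The pipeline derives every stage's RNG stream from the global seed and the
stage name (BLAKE2 hash), so stages are independent and reordering or
adding stages does not perturb the others. The run manifest records the
configuration and the SHA-256 of every output file and contains no
timestamps; two runs with the same configuration are byte-identical. The
acceptance script reruns the analyses at full scale: 8 × 50-gene
status blocks for clustering recovery, 20 sequences × 3 planted motifs and
a 1-Mb background scan, 10⁴-spot PI patterns, 200 uncoupled replicates for
null calibration and 100 coupled replicates at 99 events for power, and a
double pipeline run for determinism — about one minute on one CPU.

## Known limitations

- The motif stage cannot reproduce published per-cluster motif frequencies
  for real data, because the discovered motif matrix is not machine-readable
  from the source figures; planted-motif recovery is the verifiable
  substitute.
- PI assumes single-molecule spots; transcription sites containing many
  RNAs would need intensity weighting (available behind a flag) and are not
  simulated.
- The proximity analysis treats the ROI as the particles' and filopodia's
  common support; if the real ROI under-segments the cell, control
  positions are biased toward the segmented region.
- Wilcoxon/Mann–Whitney/ANOVA-style group comparisons beyond the statistics
  above are deliberately left to general statistics libraries.
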