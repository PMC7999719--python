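# Methods

## Event trains and activity

A unitary calcium event is a (time, amplitude) pair produced upstream
by deconvolution of a raw trace; one polyphasic transient contributes
several unitary events. "Activity" is amplitude-weighted throughout
(sum of unitary-event amplitudes per minute); event-count rates are
available behind a `weighted=False` flag. Binning is half-open
`[t, t+Δ)` with the origin at session start; an event landing exactly
on the session end is assigned to the final bin. Default session
durations follow the recording protocol: preC 600 s, preS 600 s, postS
300 s, consolidation recording 9000 s, test 600 s.

## Autocorrelation and block length

The circular autocorrelation of a binned series is the Pearson
correlation between the series and its circular rotation by k bins,
computed at 1 s resolution by default (the 10 s bins used for display
heatmaps are a separate setting). A constant series has no defined
correlation; it is returned as an all-zero acf with a degenerate flag
rather than 0/0.

The block length for the moving block bootstrap comes from fitting
`a + b·exp(−lag/τ)` to the positive lags by least squares (lag 0 is
excluded — it is 1 by construction and would dominate the fit). The
block is the smallest whole second at which the decay term has fallen
to 5% of its initial amplitude, `ceil(τ·ln 20) ≈ 3τ`. With the
generator's ~3 s within-burst spread this lands at 9–12 s, matching the
~10 s aggregation window the analysis assumes. A non-decaying fit
(b ≤ 0 or τ ≤ 0) falls back to a configurable default of 10 s with a
warning.

## Bootstraps

Two-group contrasts use the percentile bootstrap of the mean
difference: both groups resampled independently with replacement at
original size, 10,000 replicates by default, CI at the
Bonferroni-adjusted level α/m where m is the number of contrasts in the
figure-level analysis (2 for the session-transition contrasts, 3 for
the period-wise group contrasts). Percentile (not BCa) intervals are
used; significance is CI excluding zero.

Temporally correlated series use the moving block bootstrap (Künsch
construction): overlapping blocks of L bins with uniform start
positions are concatenated until the original length is reached and
the overhang truncated; the statistic is the difference of means, and
the two series use independent RNG streams derived from one seed.
Because the statistic is the mean, the resampled-series mean is
computed exactly from precomputed block sums and a partial sum for the
truncated final block; a unit test pins this to the literal
rebuild-the-series construction. With L = 1 the scheme reduces to the
ordinary bootstrap.

Known property: percentile intervals are mildly anticonservative for
small samples (groups of ~10) and for block bootstraps whose blocks
are comparable to the dependence length; measured inflation on the
null generator is ≈2–2.5× at the adjusted level. The responsiveness
classifier therefore operates, as the analysis defines it, with its
Bonferroni-corrected level (α = 0.05 over two session contrasts),
under which its realized per-transition error stays below 1.5·α.

Multiple testing across neurons uses Benjamini–Hochberg step-up
adjustment (via statsmodels).

## Responsiveness and active sets

Each neuron's change across a session transition is the block
bootstrap applied to its two 1 s-binned traces, with one block length
shared across neurons (estimated from the population
autocorrelation). Labels are increase / decrease / no_change by CI
sign; a neuron missing from a session is no_change with a missing-data
flag. The bootstrap always runs on the protocol-ordered session pair
and flips sign for reversed transitions, making label antisymmetry
under transition swap exact rather than approximate.

The active/inactive criterion resamples a period's bins with
replacement (ordinary bootstrap — the criterion "≥1 event anywhere" is
insensitive to temporal order, so block resampling adds nothing) and
declares a neuron active when ≥95% of replicates contain at least one
event-bearing bin. For state-restricted periods (e.g. REM during
consolidation) events are mapped onto cumulative state dwell time
first. Active sets are compared by Jaccard index, both conditional
fractions, and a hypergeometric enrichment p-value (the sources being
compared do not state which was used; all are reported).

## Activity vectors, similarity, clustering

Per window, per neuron, mean activity is computed, then values above
the neuron's mouse's 95th percentile (linear interpolation between
order statistics) are truncated to that percentile, and mice are
concatenated in fixed id order. Two rescalings are used downstream:
min-max of the whole vector to [0, 1] (session-similarity analysis)
and per-neuron division by the maximum across windows (consolidation
matrix and group profiles). Note that re-computing the percentile on
already-truncated data yields a lower threshold, so truncation is
idempotent only for a fixed threshold — the implementation exposes the
threshold for exactly that reason.

Similarity is cosine; clustering is agglomerative with Ward's linkage
on the angular distance `1 − cos`. Ward's criterion presumes squared
Euclidean distances and the angular distance is not one; the
combination is used deliberately because it is the procedure under
study, and the caveat is that merge heights are Lance–Williams
recursions, not interpretable as variance increments.

Cluster significance: per replicate each vector's entries are
independently permuted across neuron positions (destroying inter-vector
alignment, preserving marginals) and the linkage recomputed; the
threshold is the α-quantile of the null distribution of *minimum* merge
heights, so under the null the probability that any observed merge
beats it is α (family-wise control; per-merge thresholds would reject
in ~1−(1−α)^(n−1) of null experiments). The null scheme is pluggable
(`bootstrap_within` resamples entries with replacement instead); the
resampling scheme behind the original procedure is not specified
precisely, and the default choice is recorded here, not asserted as
the original intent.

## Remapping

The consolidation recording is cut into 15-min bins (incomplete
trailing bins dropped; 150 min → 10 bins). The remapping index uses
the sign convention of the statistic's verbal definition — +1 at the
first bin, −1 at the last — because the printed formula's numerator
order contradicts that definition and the downward trend it describes;
`convention="printed"` exposes the literal printed sign. A zero
denominator (first and last bins collinear) is defined as 0 with a
degenerate flag, equidistance being the only consistent reading.

State-filtered traces (sleep = NREM ∪ REM; wake) restrict each bin's
activity to hypnogram dwell time of the matching states, drop bins
with under 60 s of dwell, and are scaled by the *all-state* per-neuron
maxima with the all-state first/last bins as anchors, so all traces
live on one scale. REM-only traces are refused by default: REM
occupies well under 10% of the recording and carries too little ABN
activity for a stable vector. Trends are Pearson r with two-sided p
against bin-center minutes (bin centers, not indices, define the slope
units), plus the least-squares slope.

Per-neuron classification correlates raw (untruncated) per-bin mean
activity with time; decreasing/increasing require p < 0.05 and
BH-FDR q < 0.05 with matching sign; constant neurons get p = 1.
Group profiles scale each neuron by its maximum across the preS,
postS, consolidation and test windows, average preS and postS into a
learning period, and contrast decreasing vs increasing groups per
period with the percentile bootstrap, Bonferroni over three periods.
Subgroup similarity reruns the session-vector clustering restricted to
the remapping (decreasing + increasing) and non-remapping subsets;
subsets under 3 neurons are skipped with a warning.

## Synthetic generator

Each neuron is a compound-Poisson cluster process: transient onsets
are Poisson (baseline 1/min), each onset spawns `1 + Poisson(2)`
unitary events (mean 3 per transient) whose offsets are exponential
with mean 3 s — so pairwise within-burst lags are Laplace(3 s) and the
population autocorrelation decays within ~10 s. Amplitudes are
lognormal (σ = 0.5, median 1). A Hawkes process would also reproduce
the decay but adds nothing the analysis is sensitive to.

Planted structure, with defaults matching the study conditions:
28% context-responsive neurons get a 4× preS rate; a 10% shock-
suppressed subset (drawn from the non-remapping part of the context
population) returns to baseline at postS; 16% decreasing neurons
(all context-responsive — they are the learning population) crossfade
linearly from 2× to 0.5× baseline across consolidation (4× start/end
ratio) and stay at 0.5× in the test; 10% increasing neurons mirror
them and are driven 4× in the test session.

Two features beyond the planted fractions are needed for the data to
behave like recordings. First, neurons carry a persistent lognormal
rate profile (σ = 0.5, unit mean) shared by preC, preS, postS and
consolidation — real populations have stable rate identities, and
without one the preC vector is informationless (its permutation-null
similarity equals its observed similarity) and can never join the
learning cluster significantly. Second, the test session draws an
independent profile (`retrieval_remap`): retrieval recruits a
different population, which is what separates the test vector. The
free parameters (burst size and spread, amplitude σ, heterogeneity σ)
were set once so the generator reproduces the reported summary
features of the original recordings — overall remapping trend r near
−0.95, slope ≈ −0.01/min, aggregation decay within 10 s, ~1
transient/min — and are not tuned per analysis.

The hypnogram is a semi-Markov chain (wake → NREM; NREM → REM with
probability 0.3, else wake; REM → wake) with exponential dwells (wake
200 s, NREM 400 s, REM 50 s, 10 s minimum), giving ~2–4% REM — sparse
by design so the REM-refusal path is exercised.

`generate_null_experiment` removes *all* structure: fractions zero,
unit effect sizes, no rate heterogeneity, no retrieval remap. The
persistent profile must be off in the null because population identity
is itself a (correct) detection for the clustering stage; the null's
purpose is exchangeability, so that every detection is a false
positive.

What the generator does not emulate: state-dependent firing (rates do
not differ between wake and sleep beyond dwell time), bursting
non-stationarity within sessions, amplitude drift, cross-neuron
correlations beyond the shared profile, and mouse-level effects beyond
grouping. Passing recovery tests therefore demonstrates sensitivity to
rate-remapping structure under realistic sparseness, not robustness to
those further features of real recordings.

## Numerical and interface choices

Percentiles interpolate linearly between order statistics. Cosine
values are clipped to [−1, 1]; zero vectors raise rather than return
NaN. All stochastic routines take explicit seeds and spawn independent
child streams (`numpy` SeedSequence) per neuron / series / stage, so
runs are bit-reproducible and label antisymmetries hold exactly. CSV
readers parse floats in round-trip mode so write→read is byte-exact.
The pipeline report echoes the full configuration, the estimated and
used block length, and the RI sign convention.

Default problem sizes (100 neurons over 4 mice; 10,000 bootstrap and
permutation replicates, reduced to 1,000 in the Monte-Carlo
calibration suites, which repeat the full pipeline across hundreds of
generated experiments) keep every analysis deterministic and fast
while matching the scale of the original cohort (94 neurons, 4 mice).

## Known limitations

Ward-on-angular-distance is improper (above). Percentile bootstrap
inflation at small n is documented rather than corrected (no BCa).
Cluster significance tests only the minimum-height family; nested
sub-cluster significance inherits the single threshold. The remapping
index anchors A and C are single noisy bins, which compresses interior
RI values toward 0 and bounds attainable |r| below 1 even for a
perfect linear crossfade. Hypnograms must fully cover the
consolidation recording for state-filtered analyses.
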