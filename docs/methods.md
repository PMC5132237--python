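# Methods

`cellspan` analyses single-cell replicative-aging life histories of
budding yeast: longitudinal records of a mother cell's cross-sectional
area (μm²), the clock time of each division (hours), and optionally the
average intensity of a fluorescent reporter (AU), indexed by replicative
age k = 1..K.  The replicative lifespan (RLS) is K, the number of budding
events observed before death; sizes are measured at the unbudded G1
directly preceding each budding event, and the death frame itself is
never recorded.

## Data model and validation

Wide tables (one row per cell, one column per age, trailing blanks after
death) are the interchange format, as CSV or as a multi-sheet XLSX
workbook.  Validation is strict and names the offending cell: series must
be positive, times strictly increasing and re-zeroed to the first G1, the
size and time rows of a cell must have the same number of entries, and
only *trailing* missingness is legal — an interior gap means a corrupted
record, not a skipped frame.  Times may be declared in hours, minutes or
20-minute imaging frames; everything is converted to hours on ingestion.
Censoring (a cell washed out before death) is carried as a per-cell flag
and honoured by the survival estimator; curated microfluidic cohorts are
typically fully death-observed.

## Trajectory smoothing

Longitudinal profiles are smoothed with a penalized natural cubic
smoothing spline, minimising Σ(y − f)² + λ∫f″(u)²du with knots at the
observed ages, solved by the Reinsch banded system and evaluated at the
original integer ages.  The smoothing level uses R-style `spar`
semantics: with the age axis rescaled to [0, 1], λ = r·256^(3·spar − 1),
where r = n/tr(K) is the trace ratio of the fidelity and roughness
matrices in the fitted-value basis.  The default spar = 0.5 suppresses
segmentation noise while leaving the post-senescence size acceleration
intact.  The trace ratio is basis-dependent, so other spline
implementations with nominally the same spar can differ at the few-percent
level; spline-dependent statistics should be read with that tolerance.
Series shorter than four points are passed through unfitted.  Two
conventions follow the standard analysis: starting- and ending-size
correlations use *raw* sizes (they are assessed before fitting), and every
other per-age feature (fold-increase, reporter concentration) uses fitted
values.

Fold-increase normalises the fitted size trajectory to the first-G1 value,
so every cell starts at exactly 1 and the value at age k is the relative
enlargement since trapping.  It is scale-invariant by construction.

## Senescence Entry Point (SEP)

Cell-cycle durations (first differences of the G1 times) typically run
flat for most of life and lengthen sharply a few divisions before death.
The SEP detector makes the visual "elbow" call algorithmic: both axes of
the duration-vs-age profile are rescaled to the unit square (hours and
divisions are incommensurable), and the SEP is the interior point with
the maximum perpendicular distance from the chord joining the first and
last points, on the convex (sagging) side — a rising profile bends
upward at the end, so the early flat cycles sit below the chord and the
deepest point marks where lengthening begins.  Ties break to the earliest
age; profiles within ε = 0.02 (scaled units) of their chord are straight
lines and get no SEP, as do cells with fewer than four entries (their
duration profile has no interior).  Raw durations are used by default
(configurable); the detector is exactly equivalent to exhaustive
distance search, which the test suite asserts on random profiles.

## Population statistics

*Per-age correlation screen.*  At each age a, the feature value of every
cell still alive (K ≥ a) is Pearson-correlated with that cell's final
RLS.  Ages with fewer than `min_n = 10` cells are dropped (the cutoff is
a reporting choice, not a test).  With post-SEP exclusion a cell
contributes only while its SEP lies ahead, which isolates the early-life
signal from the terminal enlargement.  No multiple-testing adjustment is
applied across ages: the screen is descriptive, mirroring how such
per-age profiles are usually read, and p-values are not attached to the
per-age correlations at all.

*Median split and survival.*  The cohort alive at the split age (default
5, chosen young enough that no mortality has occurred) is split at the
population median of the feature; ties side with the "more" group, so an
odd cohort of 119 yields the 59/60 partition.  The groups are compared
with the Kaplan-Meier estimator (lifelines) and the two-group log-rank
test (1-df chi-square, no continuity correction).  The KM median is the
smallest age with survival ≤ 0.5, which equals the lower sample median
when nothing is censored.  Group medians are also summarised as a percent
difference, rounded to integer percent.

*Rank-sum.*  Distribution shifts (e.g. hours to reach age 5 in the two
split groups) use the two-sided Wilcoxon/Mann-Whitney test: exact
enumeration of the permutation distribution for untied samples with
n+m ≤ 10, otherwise the normal approximation with tie and continuity
correction.

*Reporter accounting.*  Average intensity is read as concentration;
intensity × area as total amount.  Cross-sectional concentration-size
relations at a given age report the Pearson r and OLS slope over the
cells alive at that age, on fitted values of both channels.

## Synthetic life-history generator

The generator is the package's ground-truth instrument: it emulates the
statistical structure the analysis assumes, with every latent parameter
recorded per cell for recovery tests.  Per cell i it draws log-normal
starting area s_i (median 17.65 μm², sdlog 0.18), growth rate g_i
(median 0.55 μm²/h, sdlog 0.5 — enlargement rate varies widely between
cells), and base cycle duration τ_i (median 1.5 h, sdlog 0.2).

*Lifespan.*  RLS is a discretized log-normal (median 16 divisions, sdlog
0.3, floor 3) whose log-median decreases with κ·log(g_i·τ_i/median): the
coupling acts on the per-division size gain, not on size itself, so
starting size stays uncorrelated with lifespan while fold-increase at
age 5 correlates at about −0.2 with the default κ = 0.16.  A cohort of
119 cells spans roughly 6–35 divisions with a sigmoidal survival curve.

*Division timing.*  Pre-SEP cycles are τ_i with multiplicative log-normal
jitter, snapped to the 20-minute frame grid; the SEP sits at 75% of the
lifespan (interior to the duration profile), after which durations
compound by 1.4× per division.  The slowdown factor is a calibration
choice — it makes the elbow detectable (≥ 80% of detected SEPs within ±1
division of truth) without collapsing lifespans into the imaging limit.

*Growth.*  Size at age k is s_i + g_i·t_k plus Gaussian measurement noise
(sd 0.5 μm²): growth is linear in clock time, so the post-SEP size jumps
per division come entirely from the longer cycles, not from a changed
rate.  An exponential-growth mode is deliberately absent: the analysis
never fits a growth law, and the linear mode is what the division-time
analyses assume.

*Reporter.*  Concentration is
p_i·(1 + ρ·t)·σ^(post-SEP divisions) / (1 + δ·min(fold − 1, cap)) plus
noise, with per-cell production p_i (sdlog 0.10), dilution δ = 4
saturating at cap = 0.7, time slope ρ = 0.02/h, and post-SEP surge
σ = 1.7.  Dilution makes rapidly enlarging cells reporter-poor (negative
concentration-size relation at mid ages, positive concentration-lifespan
correlation at young ages); the surge makes senescent cells reporter-rich
(sign reversal of the concentration-size relation late in life, strongly
negative concentration-lifespan correlation at old ages); the time slope
keeps the population-median total amount rising with age.  A one-sided
reporter-load penalty on lifespan — active only above half the median
baseline lifespan, growing with it, and never extending life — makes the
negative concentration-lifespan association emerge progressively as the
analysis is conditioned on longer-lived subsets, without fattening the
lifespan upper tail.

What the generator does *not* emulate: daughter lineages, mechanistic
cell-cycle structure (G1/S), heterogeneous modes of death beyond the
single SEP slowdown, strain-to-strain differences, and segmentation
artefacts beyond i.i.d. Gaussian noise.  Passing tests on synthetic
cohorts therefore demonstrate that the pipeline recovers the structure it
was built for — not that real microfluidic data satisfies that structure.

## Numerical and reporting choices

- Spline systems are solved with a symmetric banded Cholesky
  (`scipy.linalg.solveh_banded`); the test oracle solves the dense
  system assembled from natural-spline interpolants of unit vectors and
  agrees to 1e-6.
- SEP epsilon 0.02 (scaled units) separates genuine elbows from noise on
  a straight trend; the split of ages is pre = ages strictly before the
  SEP, post = SEP onward, a partition even when no SEP exists.
- Degenerate inputs are explicit: constant series make Pearson
  correlations an error, an all-equal feature makes a median split
  "degenerate" (flagged, not raised), a group with no death events makes
  the log-rank test an error.
- Problem sizes in the acceptance script: the primary cohort is 119
  cells (the cohort size the analysis conventions assume); reporter
  relations use 500 cells and the conditional trend 1500 cells, sizes at
  which the designed sign structure is resolvable against sampling noise;
  ground-truth recovery uses 1000 cells.
- At 119 cells the median-split log-rank test is genuinely marginal at
  the calibrated effect size (about half of seeded cohorts cross
  p < 0.05); the reported p-value is the honest draw for the requested
  seed, not a summary over seeds.

## Known limitations

- The spar→λ trace-ratio is computed in the fitted-value basis; other
  bases (e.g. B-spline) give slightly different λ at the same spar.
- The SEP detector assumes a single late slowdown; cells with multi-phase
  or non-monotone duration profiles get the single deepest elbow.
- Per-age correlations treat each age independently; no longitudinal
  model links them, by design.
- The reporter model is phenomenological: its couplings reproduce the
  observed sign structure but are not a mechanistic model of ribosome
  biogenesis.
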