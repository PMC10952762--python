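# Methods

## Biotic indices

All seven score-based indices are table-driven: a `ScoreTable` holds the
per-taxon parameters (WHPT abundance-class scores s1–s4; LIFE flow groups
I–VI with a group × class flow-score matrix; PSI sensitivity groups A–D
with a score matrix, groups A and B counted sensitive; ePSI per-taxon
weights and a sensitive flag; CoFSI oFSI/ToFSI sub-scores with
combination weights; TRPI scores; SPEAR at-risk flags). The package ships
a *synthetic* fixture set over 60 invented taxa
(`src/bioassess/data/synthetic_score_tables/`, regenerable with
`generate_score_table_fixtures`); published tables can replace it file
for file, because none of the score values are hard-coded.

Abundance weighting uses the conventional four log-abundance classes
(1–9, 10–99, 100–999, ≥1000). Indices are computed per replicate; samples
are never pooled. A taxon present in a sample but absent from an index's
table is ignored for that index and flagged. A sample with no scoring
taxa yields a missing value with a flag, never an exception. TRPI is
undefined for summer samples by construction and returns missing with an
explanatory flag. log10 abundance uses a +1 offset so the empty sample is
defined (0.0); the offset is monotone and affects no ordering. The CoFSI
combination weights default to (0.5, 0.5) and are a table attribute — the
exact published combination rule lives with the table, not in code.
Percentage indices are clamped to [0, 100] to absorb one-ulp float
overshoot in the ratio.

## Antecedent-window summaries

Windows are half-open, `[00:00 of (sample day − w), 00:00 of sample
day)`, for w ∈ {1, 5, 10, 20, 30, 60, 90}: the sampling day itself is
excluded so that disturbance from sampling cannot contaminate the
summary. A complete 15-min day therefore contributes exactly 96
observations, a 30-min day 48. Coverage is the fraction of the nominal
grid present; below 0.5 every statistic in the window is reported missing
(quantiles of sparse windows are unstable). Windows reaching past the
previous sampling occasion are computed but flagged `overlapping`.

Quantiles use linear interpolation between order statistics (the
Hyndman–Fan type-7 rule, the numpy default); Qp denotes the p-th
percentile, so Q95 is a peak and Q5 a trough. CV is sample SD over mean
and is reported missing when the window mean is ≤ 0 (it is computed, and
meaningless, for interval-scale determinands like pH — consumers should
drop it there; we compute rather than special-case). `days exceeding
3×Q50` counts distinct calendar days whose *daily mean* strictly exceeds
three times the within-window median; both the day aggregation and the
reference period are package choices, made once and pinned.

Free ammonia uses the freshwater pKa form pKa(T) = 0.09018 + 2729.92/T_K
with the logistic fraction 1/(1 + 10^(pKa−pH)); temperatures outside
(−5, 45) °C give missing with a warning. Nutrient fractions are simple
differences; small negative values (analytical noise near detection
limits) are clamped to zero and flagged.

The design matrix has one row per replicate sample and one column per
`{determinand}__{statistic}__{window}d` candidate; candidates missing in
more than half the rows are dropped and logged; the full default grid is
13 statistics × 7 windows = 91 candidates per determinand.

## Driver selection

Model search uses the Gaussian Schwarz criterion, BIC = n·ln(SSE/n) +
k·ln(n), with k the number of estimated coefficients including the
intercept. Search is forward selection with backward elimination: add the
term whose inclusion most decreases BIC, then test single-term removals;
stop when no move decreases BIC. Candidates are z-standardised first so
every summary statistic enters on an equal footing; ties break
lexicographically by term name, so the search is deterministic under any
candidate ordering. All candidate fits use a common complete-case row
set, keeping BIC values comparable across fits.

Replicate structure is approximated with fixed effects: `site` and
`occasion` dummy blocks offered to the search like candidates, with
replicates kept as separate rows. This is an approximation to a nested
random-effects covariance structure (two replicates nested in site ×
occasion), not an equivalent; with only two replicates per cell and the
focus on term *selection* rather than interval estimation, the fixed-
effects surrogate is adequate and far simpler. REML mixed models are
deliberately out of scope.

On orthogonal candidate sets the forward-with-backward search provably
coincides with the all-subsets BIC minimum, and the test suite checks
this equivalence on 50 random orthogonalised designs.

A known property of this selection rule: with m candidates the entry
threshold corresponds to |r| ≈ √(ln n / n), so under a pure-noise
response the probability that *some* candidate crosses it grows quickly
with m. With hundreds of correlated candidates the search accepts a small
spurious model (R² ≈ 0.2 at n = 210) in most null replicates rather than
keeping the intercept alone. BIC penalisation controls overfitting
*within* a path but is not a familywise error control across a large
candidate screen; the type-I experiment quantifies this honestly instead
of hiding it.

The variance partition is a hierarchical nested ANOVA with sequential
(type-I) sums of squares, entered covariate → site → occasion-within-site
→ residual. Crediting the covariate first is intentional: variance shared
between the covariate and space is attributed to the hydrochemical
driver, matching how the partition is used (how much could this driver
explain at most?). Shares are non-negative by nesting and sum to one.

## Synthetic data generator

The generator emulates the study design the analysis assumes: `n_sites`
small headwater catchments (default 7) monitored for `n_years` (default
3) at 15-min (sonde: discharge, velocity, turbidity, pH, DO, temperature)
and 30-min (bankside nutrients: TP, SRP, NO3-N, NH4-N, TN, TDN, TDP, DOC)
resolution, with two replicate kick samples per site in spring, summer
and autumn of each year (7 × 3 × 3 × 2 = 126 samples at the defaults).

Storms arrive as a Poisson process (0.12/day) with lognormal magnitudes
(σ = 0.6). Each determinand responds with a rise-then-exponential-decay
kernel scaled by a determinand-specific flush coefficient (negative for
NO3-N dilution) and an independent lognormal per-event multiplier
(σ = 1.0) — storm timing is shared across determinands but event-level
chemistry is not, as in real systems.

Dissolved oxygen has its own model. Daylight — a seasonally varying
window (8.5–15.5 h, centred 14:00) — carries a photosynthetic plateau
whose height is modulated day to day by a lognormal "bloom" state
(σ = 0.8); night sits one diel amplitude (10 % sat) below the 95 % sat
baseline. Storms produce oxygen sags with probability 0.6 (oxygen
depletion needs an organic load the storm may or may not carry), with
depth saturating in event magnitude, depth = 40·(1 − e^(−0.8·m·ε)) % sat
(a sag cannot drive DO below zero), and decay constant 1.5 days. The
consequence, and the reason for each choice, is that DO *troughs* track
the organic-storm process while DO peaks, means and medians also move
with the independent bloom/photoperiod processes — the statistic families
decorrelate the way they do in real streams.

Communities respond through a threshold hinge on the trough exposure E
(the Q5 of DO over the true window D* = 10 days before sampling):

    E[count_i] = b_i · exp(−β · s_i · max(0, 92 − E))

with per-taxon sensitivities s_i ∈ (0, 1) shared across indices through a
Gaussian copula (ρ = 0.7) — this "common sensitivity" is what makes the
stressor-specific indices co-vary. Baselines b_i come from a shared
regional pool (lognormal, ln-mean 3.0, ln-sd 0.5) filtered per site
(lognormal σ = 0.3); counts are negative-binomial (dispersion 20 —
overdispersed relative to Poisson by ×2 at typical abundances); replicate
pairs share the expectation and differ only in sampling noise. Effect
presets: none (β = 0), weak (0.02), strong (0.06); the strong preset was
designed to put single-candidate R² in the 0.4–0.8 range typical of
strong field relationships while keeping the index response quasi-linear
in the exposure (larger β saturates the community response, and curved
responses reward variance statistics over the true trough covariate).
The WHPT fixture's class scores run *with* sensitivity (sensitive taxa
score higher at higher abundance, tolerant taxa lower), so abundance
weighting reinforces rather than cancels the dropout signal.

What the generator does **not** emulate: rainfall–runoff hydrology,
sensor drift and gap structure, taxonomic realism, seasonal community
phenology, dispersal or between-site community correlation. Passing
recovery tests therefore show the *inference chain* recovers a known
driver under the stated statistical structure — not that field data meet
that structure.

## Experiment scales

The replicate experiments (type-I and recovery) use a scaled study: 7
sites × 5 years (15 occasions per site, n = 210 replicate rows), 30-min
resolution throughout, and a four-determinand candidate set (DO,
discharge, turbidity, TP → 364 candidates), chosen so a 100-replicate
experiment completes in minutes while preserving the full 13 × 7
candidate grid per determinand. The five-year span gives each site enough
exposure contrast for stable power; the full 15-determinand, 15-min
design remains the default for single runs and the file-based pipeline.

## Numerical choices

- SSE floored at 1e−12 inside the BIC so perfect fits stay finite; R² of
  a constant response is defined as 0.
- Rank-deficient designs are fitted by pseudo-inverse with k counted as
  the estimated rank, and a warning outside the search loop.
- Duplicate timestamps on read: keep-first with a warning. Non-ISO
  timestamps are a hard error naming the line.
- All randomness descends from one integer seed through
  `numpy.random.SeedSequence` spawns keyed by (seed, site, stream), so
  datasets are bit-reproducible and adding a determinand does not
  perturb the others' draws.

## Known limitations

- The fixed-effects site/occasion surrogate understates uncertainty
  relative to a true nested mixed model; selection frequencies, not
  p-values, are the supported inference.
- The null-preset experiment shows the stepwise-BIC screen admits small
  spurious models in most replicates at this candidate:sample ratio;
  treat any single selected term as a candidate for corroboration, not a
  finding (the selection-frequency experiments are the package's answer
  to this).
- Synthetic score tables share only the *structure* of the published
  index tables; absolute index values are not comparable to field
  studies.
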