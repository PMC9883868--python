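# Methods

## Community model and the diversity indices

The unit of analysis is the genus of each isolate's closest ITS match — the
first whitespace token of the binomial, so `Fusarium sp.` and
`Fusarium oxysporum` both tally to *Fusarium*. Richness `S` therefore counts
genera, not species epithets. This choice is validated by the packaged
survey: the published per-stratum Shannon, Simpson, PIE and Pielou values are
reproduced to 4 decimals at genus rank for all eight (plant, tissue) strata,
and are not reproduced at species rank.

All six indices use natural logarithms; base-2 or base-10 variants do not
reproduce the published grid. Reports round half-even to 4 decimals (the
published presentation); full precision is retained internally.

Degenerate strata yield flagged NaN values rather than exceptions so the full
grid always renders: Pielou's `J = H'/ln S` is undefined at `S = 1`
(`undefined_J`), and Margalef's `D'` and `PIE` are undefined at `Nt = 1`
(`undefined_D`, `undefined_PIE`). Flagged values are never reported as 0.

One cell of the original survey's published grid is not reproduced by its
stated formula: the *P. ternata* root stratum has `S = 5` genera over
`Nt = 6` isolates, giving `D' = 4/ln 6 = 2.2324`, while the published value
is 2.7906 = 5/ln 6 — consistent with a richness of 6, i.e. species rather
than genus rank for that one cell. Whether that is what happened is not
decidable from the published text. The package always reports the formula
value; the cell is recorded in
`endodiv.diversity.KNOWN_PRINTED_DISCREPANCIES` and annotated in the combined
report. Similarly, the transcription yields 10 distinct pooled-stem genera
where the survey's prose says 9; the computed value is reported.

## Phylogeny

Distances: p-distance (default), JC69 `d = −(3/4)ln(1 − 4p/3)`, and K2P
`d = −½ln((1 − 2P − Q)√(1 − 2Q))` with transition proportion `P` and
transversion proportion `Q`. Gaps and IUPAC ambiguity codes are handled by
pairwise deletion: a site counts for a pair only when both sequences carry an
unambiguous A/C/G/T there. A pair with zero comparable sites, or a divergence
beyond a correction's domain (`p ≥ 3/4` for JC69; non-positive log arguments
for K2P), raises a specific error. p-distance is the default because the
survey names only "neighbor-joining" without a model; the model is a flag and
nothing downstream depends on one particular choice.

Neighbor joining follows the Saitou–Nei Q-criterion. Ties in Q are broken by
the smallest (row, column) pair in the current matrix order, making runs
bit-reproducible (exercised by the all-equal-distances test). Negative
branch-length estimates are clamped to zero with the deficit moved to the
sister branch, preserving the joined pair's path length. The output is
unrooted, represented as a trifurcating root node; on additive matrices the
builder recovers the generating topology exactly (verified for 4–12 taxa
against path-sum distance matrices, and cross-checked against an independent
NJ implementation on noisy matrices).

Bootstrap: alignment columns are resampled with replacement; each replicate
`r` consumes its own substream (`SeedSequence(seed).spawn`) of one seeded
generator, so a fixed seed gives identical supports and extending the
replicate count never perturbs earlier replicates. Supports are the percent
of non-skipped replicate trees containing each internal bipartition of the
reference (full-data) tree, matched as leaf-set splits, never by node order.
Replicates whose distances are undefined are skipped and counted, with a
warning past 10%. Newick output writes supports as internal-node labels and
quotes labels containing metacharacters; parsing is delegated to dendropy and
round-trips topology, branch lengths and supports.

The real survey tree is not reproduced here: that would require fetching the
deposited ITS sequences (GenBank ON677855–ON677931) and an external alignment
step, both out of scope. The phylogeny stage is instead verified by
consistency and simulation properties on synthetic alignments.

## Bioassays

The radicle inhibition rate is `(mean(control) − mean(treated))/mean(control)
× 100`, the standard germination-bioassay definition. The standard deviation
is propagated replicate-wise: each treated replicate is scored against the
control mean, so the mean of per-replicate rates equals the mean-length
formula exactly while their spread gives the sd (raw treated/control pairing
is not recorded in this assay design). Rates ≤ 0 (no inhibition, or growth
promotion) are NI and excluded from numeric aggregation.

Band edges are half-open: complete = exactly 100, strong = [80, 100), potent
= [60, 80), weak = [10, 60), NI below 10. The "weak" band deliberately
overlaps threshold queries such as "more than 50%"; `count_over(50,
strict=True)` serves those, and strict inequality is used because the
packaged screen contains entries at exactly 52.0% and the survey's published
count (52) is reproduced only under strict ">".

ANOVA is the classical between/within sums-of-squares decomposition with
Fisher's (unprotected) LSD pairwise t comparisons on the pooled within-group
mean square, two-sided at α (default 0.05). Zero within- and between-group
variance together is indeterminate and raises; zero within-group variance
with separated means yields `F = ∞, p = 0`. The t test offers pooled
(default) and Welch variants; zero-variance equal-mean input returns
`t = 0, p = 1`. Only the F/t distribution tails come from scipy; the
statistics are computed in-package and tested against textbook-formula
evaluation to 1e-9 and against scipy's independent implementations.

MIC values are stored and validated only — the twofold ladder
100…1.56 µg/mL plus the censored ">100" ceiling, which sorts last in
rankings; no growth-curve modeling is attempted. Active disc-diffusion zones
must be at least the 6 mm disc diameter.

## Synthetic data

`simulate_catalog` draws genus counts from a multinomial per stratum —
isolate counts in a culturable survey are a fixed-size sample from an
(unknown) genus-frequency simplex, which multinomial sampling emulates
directly. It does not emulate isolation-medium bias, co-isolation, or
tissue-to-tissue correlation, so passing recovery tests say nothing about
those real-data effects. `simulate_radicle_assay` draws replicate lengths
from a Normal truncated at zero by clipping (defaults: control mean 20 mm,
sd 1 mm, 3 replicates — a realistic barnyard-grass radicle scale and the
screen's replicate count); clipping biases means slightly when sd/mean is
large, so tests use small ratios. A full effect of 1 emits exactly-zero
treated lengths (complete inhibition leaves no radicle to measure) rather
than a truncated normal around zero. `evolve_sequences` runs site-independent
JC69 along a branch-length tree from a uniform i.i.d. root sequence; there is
no indel or rate-heterogeneity process, so simulated "ITS" data are easier
than real ITS.

All generators derive from one root seed with a named substream per call
(`blake2s(name)` → `SeedSequence(seed, spawn_key)`), so outputs are
bit-reproducible and adding a generator never shifts existing streams.

Known estimator limitation: the plug-in Shannon `H'` is biased low by
approximately `(S − 1)/(2Nt)` in small samples — about 0.2 nats at the
packaged survey's tuber depth (`Nt = 28`, `S = 12`). Simulated-catalog means
therefore sit below the generating community's `H'` at that depth and
converge to it as `n` grows (the convergence is tested); no bias correction
is applied because the survey's own indices are plug-in values.

## Problem sizes and numerical choices

The test suite and acceptance script use: 100 random additive-matrix trials
at 4–12 taxa; a six-taxon simulated alignment of 2000 sites with 100
bootstrap replicates; 1000 random inputs for the statistics oracles; and
1000 seeded community draws at `n = 28` for the recovery study. Distance-tie
rounding in the NJ Q-matrix uses 12 decimals to merge floating-point ties
before index-order tie-breaking. Report rounding is half-even. The CLI exits
0 on success, 2 on validation errors, 3 on computation errors; the combined
report isolates timestamps in a metadata sidecar so payload outputs are
byte-comparable across reruns.
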