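# Methods

## The QC procedure

`blankgate` targets the situation where filters from a low-biomass
environment (produced water from an oil/gas well is the motivating
case) are sequenced alongside negative-control blanks, and the analyst
must decide (a) which samples carried enough template to trust and (b)
which OTUs are reagent or handling contaminants.

**Detection limit.** Triplicate qPCR crossing points are averaged per
sample with no outlier rejection — rejecting replicates would silently
change the reported Cp of exactly the marginal samples the rule is
meant to judge. The detection limit is the *minimum* average Cp over
all submitted blanks: the most contaminated blank defines what "no
environmental signal" can look like, so any sample that does not beat
it cannot be distinguished from a blank. Classification is
`above ⇔ avg Cp < T` with ties going below, which guarantees the
defining blank classifies below its own threshold. The procedure runs
entirely on Cp; a standard curve is optional and only adds absolute
copies/µL to the verdicts.

**Standard curve.** Fitted by ordinary least squares of Cp on
log10(copies) — the universal qPCR convention — giving slope m
(cycles/decade, negative), intercept b (cycles at 1 copy/µL),
efficiency `E = 10^(−1/m) − 1`, and R². Inversion
`copies = 10^((Cp−b)/m)` extrapolates outside the calibrated range but
logs when it does.

**Decontamination.** Every OTU with at least `min_count` reads
(default 1) in at least one blank is removed from every sample. The
rule operates on raw counts; percent normalisation happens afterwards,
so removal never changes surviving cell values. OTU columns that end
up all-zero are retained (ids stay stable) but logged; dropping them
is an option. The before/after report counts sequences and OTUs per
sample plus dataset-level distinct-OTU totals and per-sample sequence
extremes. We deliberately do not implement frequency- or
prevalence-model decontamination; the point of this package is the
blunt, auditable blank rule.

**Validation statistics.** Richness is a positive-count; Shannon H is
`−Σ p ln p` in nats (scale-invariant, so counts and percent rows give
identical H; natural log matches the vegan default this kind of
analysis is usually compared against). Bray-Curtis is computed on
percent rows (a counts input is normalised with a warning); on rows
with equal sums it coincides with half the total-variation distance.
PERMANOVA is the one-factor distance-based decomposition
`SS_total = (1/n)Σ_{i<j} d²`, `SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²`,
`pseudo-F = (SS_B/(a−1))/(SS_W/(n−a))`, with p-values from label
permutations using the `(1 + exceedances)/(1 + n_perm)` convention
(p is never exactly 0; the floor is 1/(1+n_perm)). An exhaustive mode
enumerates all distinct label assignments for small n and reports the
plain exceedance fraction. Kruskal-Wallis uses average ranks and the
`1 − Σ(t³−t)/(N³−N)` tie correction, with H defined as 0 (p = 1) when
all observations are identical.

**NMDS.** Each random start alternates monotone regression
(pool-adjacent-violators; the `sklearn.isotonic` implementation) of the
configuration distances on the dissimilarity order with a Guttman
transform of the configuration, stopping when Kruskal stress-1
(`sqrt(Σ(d̂−e)²/Σe²)`) improves by less than `tol`. Ties in the
dissimilarities are handled in the primary fashion by ordering tied
entries by their current configuration distances. Defaults: k = 2,
20 random starts, 300 iterations/start, tol 1e-7. The reported stress
is always recomputable from the returned (centred) coordinates; it is
invariant to rotation, reflection and translation. When all
dissimilarities are equal the configuration is arbitrary and a warning
is raised.

## The model interface

`LowBiomassQC(otu, cp, metadata).fit(seed=...)` runs: threshold →
verdicts (both the blank-derived rule and, when supplied, the lab's
own amplification flag) → volume statistics (OLS R², Kruskal-Wallis of
Cp by volume bin) → alpha diversity and Bray-Curtis/NMDS on the full
percent table (blanks included) → blank-OTU removal and accounting →
Bray-Curtis/NMDS/PERMANOVA again on the cleaned table. Both threshold
definitions are reported side by side at both stages; the blank-derived
one is marked recommended. Samples missing from any table are skipped
and listed, never silently dropped; samples left with zero reads after
removal are excluded from the post-removal ordination and reported.
The single `seed` drives every stochastic step through one generator,
so a fit (and its saved report bundle) is reproducible byte for byte.

## The synthetic-study generator

The generator emulates the statistical structure the QC procedure
assumes, with ground truth for recovery tests:

* one "formation water" composition `π_true ~ Dirichlet(α_true)` and
  one contaminant-pool composition `π_cont ~ Dirichlet(α_cont)`;
  a configurable number of shared OTUs (default 1) receives a fixed
  slice of both, reproducing the ubiquitous contaminant observed in
  every sample;
* per-filter formation biomass
  `B = Z · exp(N(μ_B, σ_B)) · (v/500)^γ` copies/µL, where
  `Z ~ Bernoulli(1 − p_fail)` models filters that capture essentially
  no formation biomass. γ = 0 (the default) decouples biomass from
  filtered volume; γ = 1 makes it proportional;
* per-extraction contaminant load `C = exp(N(μ_C, σ_C))`, with blanks
  scaled by `blank_contaminant_scale` (default 2): a blank pushes 2 L
  of lab water through its filter, or ships the bare filter, and so
  integrates more kit/water contaminant than a 1-µL-template sample
  extraction. A batch map can instead share one draw per extraction
  batch (kit-lot behaviour);
* contaminant read fraction `f = C/(B+C)` — rising as biomass falls,
  exactly 1 for blanks (B = 0);
* reads `~ Multinomial(N, (1−f)π_true + f π_cont)` at lognormal depth
  N, with an optional Dirichlet-multinomial overdispersion knob;
* Cp replicates `= b + m·log10(B+C) + N(0, σ_cp)`, default curve
  m = −3.42, b = 40 (efficiency ≈ 96%).

Key defaults and why (all on the natural-log scale unless noted):
57 samples = 49 filters over ten volumes (100–1000 mL, 4–5 each) + 8
blanks; μ_B = 9.1, σ_B = 1.4 → captured samples at Cp ≈ 26.5 ± 2;
p_fail = 0.45 → roughly half the filters sit at blank level regardless
of volume; μ_C = 4.7, σ_C = 1.0 and blank scale 2 → blanks at
Cp ≈ 32 ± 2 with the hottest of eight near Cp 30; depth ≈ 8 100 reads
lognormal; σ_cp = 0.3 cycles; α_true = 0.15 over 719 true OTUs
(Shannon ≈ 4–5, per-sample richness up to ≈ 150), α_cont = 0.3 over
156 contaminant-pool OTUs. These are the conditions of a repetitive
volume-series study of a single source water; the bimodal biomass
(capture success/failure) is what the observed spread of same-volume
Cp values in such studies looks like, and it is what makes the
blank-minimum rule informative at all — with unimodal biomass the rule
has an irreducible error band where `B` is comparable to `C`.

The simulated laboratory amplification flag is a noisy Cp cut
(default 31 ± 1.5 cycles), so samples with near-identical Cp can be
flagged differently — the behaviour that motivates preferring the
blank-derived limit.

`study_like_config()` switches on coverage enforcement: after
sampling, any configured OTU never observed receives one top-up read
in an appropriate sample (contaminant-pool OTUs in a blank,
true-community OTUs in a non-blank), so the dataset-level accounting
is exact by construction — 875 distinct OTUs observed, 156 in blanks,
719 retained after removal — at any seed.

**What the generator does not emulate:** taxonomic realism (OTU ids
are abstract); PCR chimeras and sequencing error; cross-talk between
samples; PCR inhibitors (a biomass-independent reason for high Cp);
compositional correlation between contaminant load and sample type
beyond the blank scale factor; read-length/quality artefacts. Passing
recovery tests therefore show that the *statistical* chain behaves
correctly under the stated generative assumptions, not that any given
real dataset satisfies those assumptions.

## Problem sizes and numerical tolerances in the test suite

Oracle-equivalence checks run 100+ random fixtures (n ≤ 14) against
loop-and-formula reference implementations at 1e-9 relative
tolerance. Permutation-test calibration uses 2 000 Kruskal-Wallis
replicates (3 × 8 samples) and 500 PERMANOVA replicates (20 samples,
999 permutations each; the permutation scan is vectorised across
permutations). Parameter recovery averages 10 default-config studies
(57 samples each). NMDS exactness is asserted at stress < 1e-3 on
configurations that are Euclidean by construction. The acceptance
script generates one 57 × 875 study and reports the retained-OTU
count.

## Known limitations

* The blank-minimum rule is only as good as the blanks: with few
  blanks the minimum is noisy, and a single contaminated blank can
  push the threshold low enough to discard genuine samples. The
  package intentionally refuses to run without blanks rather than
  falling back to a fixed Cp.
* Blank-OTU subtraction removes genuinely shared taxa (an OTU present
  in both the environment and the kit is deleted everywhere); the
  per-sample accounting makes the cost visible but cannot recover the
  reads.
* PERMANOVA is one-factor only, matching the above/below use case;
  dispersion differences between groups can masquerade as location
  effects (no PERMDISP companion test).
* NMDS with few points and many starts can still land in local minima
  for pathological dissimilarities; the stress trajectory is exposed
  for diagnosis.
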