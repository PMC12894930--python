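# Methods notes

## Scope and model

The package implements the statistics of a proximity-labeling interactome
study: label-free protein-group preprocessing, bait-vs-control differential
enrichment, consensus/overlap set analytics, position-specific weight
matrices (PSWMs) from X5-Y-X5 peptide-display sequencing, and phosphosite
scoring. Everything runs on synthetic data whose generative parameters are
known, so each analysis stage can be scored against ground truth
(sensitivity, observed FDR, matrix recovery correlation). It deliberately
does not model spectral identification, peptide-to-protein roll-up, biotin
labeling kinetics, organelle geometry, read merging/trimming, or GO
enrichment.

## Preprocessing

Stages are ordered raw → noised → filtered → normalized → log2, enforced by
a stage tag; out-of-order calls raise.

* **LOD noise.** Reports encode missing values as 0. Per sample the limit
  of detection is taken as the 1st percentile of nonzero raw intensities,
  and every entry receives an independent additive draw from
  `U(0.1·LOD, LOD)`. The draw is added to *all* entries, not only missing
  ones, so observed and imputed cells are perturbed identically. The exact
  distribution and range of "the lower range of the limit of detection" is
  a design choice here (percentile and lower fraction are parameters); only
  the qualitative contract — small, positive, sub-LOD — should be relied
  on. After this stage all intensities are strictly positive, which is what
  licenses the later log2 transform.
* **MS/MS evidence filter.** A protein group is retained iff its mean MS/MS
  count is ≥ 4.99. The mean is taken across all samples jointly (the
  per-condition alternative is a parameter away, `filter_low_evidence`'s
  input is the full matrix). The comparison is deliberately strict-at-4.98 /
  keep-at-4.99 and tested at the boundary.
* **Total-intensity normalization.** Columns are scaled to equal sums; the
  common rescale by the mean column sum keeps values on the original
  intensity scale. Note a composition effect this creates: when true
  interactors are enriched in the bait channel, every other protein's
  normalized bait intensity decreases slightly, giving null proteins a
  small negative expected log2 fold-change (visible in the README example).

## Differential enrichment

The Welch (heteroscedastic, two-tailed) t-test is computed from the usual
statistic with unbiased sample variances and Welch–Satterthwaite degrees of
freedom, with two conventions for degenerate inputs that arise in
simulation: both variances zero and equal means gives p = 1; both variances
zero and different means gives p = 0. Group size below 2 is an error, not a
p-value. The implementation is cross-checked in the tests against an
independently coded oracle (statistic and df from first principles, tail
probability by numerical integration of the t density) to 1e-10, and
against `scipy.stats.ttest_ind(equal_var=False)`.

Fold-changes are differences of mean log2 intensities (volcano axis);
linear-scale summaries are ratios of means with first-order error
propagation `sd(r) = |r|·sqrt((s_a/m_a)² + (s_b/m_b)²)`. Both exist because
downstream figures use both conventions.

The hit rule is `p < 0.05 AND log2FC > 1`, both strict, with **no
multiple-testing correction by default** — the joint gate, not FDR control,
is the operative filter. A Benjamini–Hochberg adjustment can be switched on
(`fit(bh=True)`) but is off to match the analysis this package reimplements.
Whether the t-test runs on log2 or linear intensities is ambiguous in that
style of analysis; log2 is used here, consistent with "log2-transformed and
averaged" preceding the fold-change computation.

## Set analytics

* `core_interactome(hits, k)`: row-sum threshold; monotone decreasing in k.
* `relaxed_overlap(a, b)`: both cut-offs on the first table, *at least one*
  of the two on the second. "Only one of these cut-offs" is read as the
  union, not exclusive-or: the purpose of the rule is to relax, and the
  union is the choice that always contains the strict overlap (a property
  the tests assert universally).
* Fraction curves emit NaN, not 0, where no protein exceeds the threshold.
* Proteins missing from the annotation table are treated as unannotated
  (all flags false, compartment unknown).

## PSWM construction

Reads may be amino-acid 11-mers or 33-nt coding sequences (translated with
the standard genetic code); rejections are tallied by reason (wrong length,
stop codon, non-Y center, invalid character) and rejected + retained always
equals total. Non-Y-center reads are rejected by default because the
library fixes the central tyrosine, so such reads are sequencing errors;
this is configurable. Counting produces a 20-residue × 11-position matrix
whose columns each sum to the peptide count; rows follow a fixed
biochemical grouping (G A S T C | P V I L M | F W Y | H K R | D E N Q) —
cosmetic, since files name rows explicitly.

A pseudocount of 1 is added to every cell of both counts matrices before
frequency conversion (cell → (count+1)/(n+20)), guaranteeing finite log2
enrichments; zero-count handling is not specified by the analysis style
this follows, so the pseudocount is a parameter. Replicate screens are
averaged entrywise after the log2 transform.

## Phosphosite scoring

Raw score = mean matrix value of the ≤ 10 non-gap flanking residues;
central Y excluded. Theoretical bounds are the means of per-column maxima
(minima) over the ten flanking columns; normalization maps them to exactly
1 and 0 — the per-position argmax window attains 1 and the argmin window 0
by construction, which the acceptance script recomputes. Windows at protein
termini are padded with `_`; gap positions contribute nothing and shrink
the denominator, the minimal generalization of the full-window rule (how
the original analysis handled termini is unstated). With replicates, each
matrix is normalized with its own bounds before averaging, preserving the
stated order of operations.

## Synthetic-data generator

The generator defines the study conditions; defaults were fixed once as
realistic values for this experiment type:

| parameter | default | rationale |
| --- | --- | --- |
| n_proteins | 2000 | order of quantified protein groups in a TurboID IP |
| n_interactors / effect | 50 at δ = 2 log2 | spike-in benchmark: 4-fold true enrichment |
| n_replicates | 3 | standard biological replication |
| replicate_sd | 0.5 log2 | typical LFQ replicate scatter |
| baseline log2 abundance | Normal(20, 2) | wide log-normal dynamic range |
| detection_limit | 1e5 intensity | ~2.5th percentile of the baseline distribution |
| dropout_below_lod | 0.5 | sub-LOD signals missing about half the time |
| msms_rate_per_intensity | 20 | tens of MS/MS scans for a median protein |
| n_reads (input/selected) | 1e5 each | desk-scale deep-sequencing depth |
| selection_sharpness β | 0.5 | see calibration note below |

Intensities are generated on the log2 scale as
`Normal(baseline + bait·δ, replicate_sd)` and exponentiated, matching the
log2-space testing downstream; noise is drawn before the effect is added so
that, at fixed seed, increasing a protein's δ can only increase its
realized bait/control ratio (a tested invariant). Entries below the
detection limit are set to 0 with the dropout probability — the missingness
mechanism of real reports is unknown, and this
censor-below-threshold-at-random model is an assumption. MS/MS counts are
`Poisson(rate · intensity / median intensity)`, so evidence scales with
abundance and the 4.99 filter has realistic prey. Selected display reads
are drawn with replacement from the input pool (PCR/sequencing resampling)
with probability ∝ `exp(β · s_true)`.

**Calibration of β.** The recovered matrix is
`log2(exp(β·e) / column-mean of exp(β·e))`, which is only quasi-linear in
the true energy e when `β·|e| ≲ 1`. An infinite-read analytic check showed
that at β = 1 with ±2 effects the column-renormalization distortion alone
caps the truth–recovery Pearson r below 0.9 for a quarter of random effect
layouts; β = 0.5 stays in the quasi-linear regime (analytic r ≥ 0.907
across 300 layouts) while producing realized enrichments of about ±1.3
log2, comparable to real SH2 screens.

**Energy matrices.** The default ground truth is dense —
`Normal(0, 0.75)` on all flanking cells — mirroring real specificity
profiles where every residue carries some preference. A sparse variant
(±2 on 6 random flanking cells, everything else 0) is kept as a hard,
exactly identifiable target for the matrix-recovery benchmark.

**Planted phosphosites.** A planted site of tier t ∈ (0, 1] carries the
per-column argmax residue at `round(10·t)` randomly chosen flanking
positions and random residues elsewhere. The planted-position count is
deterministic in t (not Bernoulli per position) so the tier is a faithful
ordinal of window quality; with Bernoulli planting, Binomial(10, t) noise
dominates the tier signal and tier–score rank correlations are
structurally depressed.

**What the simulation does not emulate**: correlated protein abundances
(complexes), intensity-dependent variance beyond the LOD noise, ratio
compression, shared peptides between protein groups, position-dependent
sequencing error, and non-random missingness. Passing recovery tests
therefore show the *statistical pipeline* is correct and well calibrated
under its stated model, not that the model captures every pathology of
real data.

## Numerical choices and degenerate inputs

* p-values at variance-zero inputs: see above; keeps simulated constant
  rows total.
* Normalization with a zero column sum, log2 of nonpositive values,
  empty peptide sets, all-gap windows, degenerate score bounds
  (constant matrix) and mismatched truth/config sizes are all errors, not
  silent results.
* Argmax/argmin window ties are broken by residue row order; this only
  matters for exactly tied matrix cells.
* Problem sizes in the test suite are desk scale (hundreds to thousands of
  proteins, 1e5–2e5 reads, 10 simulation seeds for the spike-in benchmark),
  chosen so the full suite runs in seconds while keeping binomial/sampling
  error well inside the asserted tolerances.

## Known limitations

* The LOD-noise distribution is a documented guess at an under-specified
  step; absolute p-values near the detection limit depend on it.
* Welch p-values at n = 3 are approximate (Satterthwaite df); the null
  calibration test bounds the practical effect (p < 0.05 rate within
  [0.03, 0.07] at 2000 proteins).
* The PSWM is a linear (independent-positions) model by construction; the
  simulator's selection model is also position-independent, so recovery
  tests cannot detect epistasis between peptide positions.
* Reference-interactor analytics take the reference list as given; no
  attempt is made to model literature bias.
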