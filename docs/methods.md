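# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter.

## Study design and contrasts

The design crosses cytokine stimulation (TNFα) with heat-shock pre-treatment:
four conditions Ctr, TNF, HS and HS_TNF (heat shock immediately followed by
TNFα), each with replicate log2 expression measurements.  Four contrasts are
examined:

* **TNF vs Ctr** — the cytokine response ("TNF-modulated" genes);
* **HS vs Ctr** — the heat-shock response;
* **HS_TNF vs TNF** — the effect of heat-shock pre-treatment on the cytokine
  response, the contrast that defines the combined-effect modes;
* **HS_TNF vs HS** — the reverse analysis (effect of the cytokine on the
  heat-shock response), provided by the same machinery with the contrast
  swapped.

FDR estimation is applied per contrast, not globally, since the contrasts ask
separate questions.

## Moderated differential expression

A gene's variance estimate from 3 replicates per condition is unstable, so
the two-sample *t* uses an empirical-Bayes posterior variance: per-gene
pooled variances s²_g (d_g = n₁+n₂−2 df) are assumed drawn from a scaled
inverse-χ² prior with parameters (d₀, s₀²); the posterior variance is
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g) and the statistic t_g = Δx̄_g /(s̃_g·
√(1/n₁+1/n₂)) is referred to a Student t with d₀+d_g df.

(d₀, s₀²) are fitted by moment matching on e_g = log s²_g:
Var(e) = ψ′(d_g/2) + ψ′(d₀/2) identifies d₀ through an inverse-trigamma
Newton solve, and the mean of e identifies s₀² after the log-scale bias
correction.  Two documented reductions keep the statistic auditable:

* **d₀ = 0** is exactly the textbook pooled two-sample t (verified against
  an independent implementation to 1e-10);
* **d₀ = ∞** (chosen automatically when the log-variance dispersion does not
  exceed the pure sampling term) treats all genes as sharing one variance,
  estimated unbiasedly by the plain mean of s²_g, and uses a normal
  reference distribution.

Zero-noise input (all s²_g = 0) is a degenerate case: the prior fit refuses
it, and the call path falls back to d₀ = 0 with p ∈ {0, 1} decided by the
mean difference, so noise-free simulations classify exactly.

### Calls and q-values

A contrast call is `up` when the linear ratio 2^Δx̄ is strictly > 1.2 and
q < 0.05, `down` when the ratio is strictly < 0.8 and q < 0.05, otherwise
`none`.  The thresholds are strict inequalities (a ratio of exactly 1.2 is
not a call).  q-values use the step-up rule q_(i) = min_{j≥i} π̂₀·m·p_(j)/j
with π̂₀ from Storey's λ-grid (λ = 0.05…0.95, cubic-spline smoother
evaluated at λ = 0.95, clipped to (0,1], falling back to π̂₀ = 1 — i.e.
Benjamini–Hochberg — for small inputs or unstable estimates).

## Motif models and scanning

The proximal promoter is the 1000 bp upstream of the TSS, strand-aware,
half-open and 0-based internally.  Scanning scores every window on both
strands by Σ log2(p_base/bg_base) (bits) and reports windows with score ≥
`rel_threshold` × the maximum attainable score; the default 0.8 is the
common relative-score convention for TRANSFAC-style matrices.  Windows
containing N are skipped.  A pseudocount of 0.01 per cell is added before
column normalisation of count matrices; probability matrices read from
JASPAR-style files are used as-is.

Because the original matrices behind published genome-wide motif counts are
not available, the package ships its own defaults and treats genome-wide
counts only as percentage arithmetic, never as reproducible gene lists:

* **κB**: the canonical RelA/p50 decamer GGGRNNYYCC as a probability matrix
  (invariant positions at 0.97, R/Y at 0.485/0.485, N at background);
* **HSE**: built by `build_hse_pwm(n_units≥3)` as alternating-orientation
  nGAAn pentamer units (three-unit consensus nGAAnnTTCnnGAAn), invariant
  positions at 0.94.

Both are overridable via JASPAR-style files.

## Regulatory windows and induced binding

The regulatory window spans 7500 bp upstream to 2500 bp downstream of the
TSS (oriented by strand, clipped at the chromosome start).  An alternative
narrower window (−2500..+500) reported in some summaries is available
through the window-extent options; the wide definition is the default.
Genes with several annotated TSS keep the single 5′-most one.

A peak is assigned to every gene whose window it overlaps by ≥1 bp
(half-open interval semantics; one peak may serve several genes).  The
bundled peak caller is deliberately simple — per fixed-width bin, a Poisson
upper tail at a depth-scaled reference λ floored at the global reference
rate, BH across bins, adjacent significant bins merged, peak score =
−log10(best adjusted p) — and is a stand-in, not a re-implementation of a
full caller (no fragment-shift model, no local-λ hierarchy).

"HS-induced binding" is the union over the 10- and 20-min heat-shock
timepoints.  With only BED peak sets, a gene is induced at a timepoint when
its window holds an HS peak whose score exceeds 2× the best control score in
the window (trivially satisfied when control has none); with binned tag
tracks, window counts are compared by a depth-scaled Poisson test with BH
across genes at FDR 0.05.

## Combined-effect classification

Each TNF-modulated gene receives exactly one mode from the HS_TNF-vs-TNF
contrast using the same ratio+FDR rule as primary calling: significant
increase on a TNF-up gene → enhanced activation; significant decrease on
TNF-up → suppressed activation; significant decrease on TNF-down → enhanced
repression; significant increase on TNF-down → relieved repression;
otherwise unaffected.  Co-activation (label **A**) additionally requires the
gene to be HS-upregulated on its own; the two antagonistic modes carry label
**O**.  The significance requirement (not the ratio alone) is part of the
rule: a printed-style report can show a ratio well below 0.8 yet stay
unlabelled when the contrast is not significant.

Report ordering is O block, then A block, then unlabelled, with HS-down
before HS-up before unchanged inside a block and alphabetical gene order as
the final tie-break.

### Percentage reporting rule

Summary percentages are rendered half-up to the nearest integer when ≥ 2 %,
and truncated at one decimal below 2 %, so marginal classes are never
inflated past their printed precision (3/193 renders as 1.5, not 1.6).

## Term overrepresentation

The hypergeometric upper tail P[X ≥ k] is computed in log space from log
binomial coefficients (log-sum-exp over the tail).  Terms are flat labels —
no ontology ancestry propagation — and the background universe is always
supplied explicitly, typically "all genes with detected transcripts".
Comparative enrichment (a subset against the TNF-modulated set, and against
the universe) is done by running the test twice with the two backgrounds.
Unadjusted p < 0.05 is the default significance rule; BH adjustment is
available but off by default.

## Synthetic-data generator

The generator plants a known truth at every layer: one synthetic chromosome
(TSS on a 25-kb grid with ≤2-kb jitter, so 10-kb regulatory windows never
overlap), ~50/50 strands, per-gene regulation modes drawn from configurable
fractions, additive log2 effects (tabulated in the `simulate` module
docstring), i.i.d. N(0, noise_sd) replicate noise, i.i.d. background
promoter sequence with consensus motif instances inserted at recorded
offsets and strands, uniformly placed basal peaks present in all conditions,
and strong extra peaks (5× the basal score) in the HS timepoints for
induced genes, with a weak control counterpart in 30 % of cases.
Optional binned tag tracks are Poisson draws around ``tag_depth`` per 100-bp
bin plus an excess rate of score/2 over each peak footprint (induced peaks
~7.5× the input background, basal peaks ~2.5×), with an input track at pure
background.

Defaults are the study conditions and were fixed once: effect_log2fc = 2,
noise_sd = 0.25, 3 replicates/condition; mode fractions with 70 % null and
the antagonized class the largest TNF-involved class; motif plant
backgrounds 0.24 (κB) and 0.06 (HSE) and binding background 0.11, matching
the genome-wide frequencies the analysis reports; peak widths uniform on
200–800 bp, matching chromatin fragment sizes.  Recovery experiments use
5000 genes and ≥10 seeds; calibration checks use 2000 null genes (type-I
error of the moderated test) and 50 seeds of 400-bin null Poisson tracks
(peak-caller false positives).

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: technical-vs-biological replicate
variance structure (replicates are i.i.d.; pooled-RNA designs have smaller,
purely technical variance), probe-level microarray artefacts and
normalisation, read-level ChIP-seq noise (no FASTQ, no alignment, no
duplicate structure), promoter GC/CpG composition and repeats, correlated
gene programs, and ontology DAG structure in the term tables.

## Known limitations

* The moderated-variance fit assumes a common residual df across genes and
  no mean–variance trend.
* Storey's π̂₀ is unstable for very small gene sets; the BH fallback is
  then conservative.
* The BED-only induction rule depends on comparable peak scores across
  conditions; use tag tracks when depths differ strongly.
* Published genome-wide motif/binding gene counts depend on unavailable
  matrices and thresholds; only their percentage arithmetic and the 27-gene
  worked example are treated as reproducible.
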