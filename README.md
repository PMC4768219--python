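# tfcrosstalk

Integrative analysis of cross talk between two stress–response transcription
programs: the cytokine-driven NF-κB pathway (TNFα stimulation) and the
heat-shock response driven by HSF1.  The package is aimed at transcriptomics
analysts who want to ask, for a factorial design over the conditions
{Ctr, TNF, HS, HS_TNF} (heat shock followed by cytokine), *which
cytokine-responsive genes does heat-shock pre-treatment co-activate,
co-repress, antagonize, or leave alone — and which of those carry κB / HSE
promoter motifs and gain HSF1 binding after heat shock?*

## What it computes

1. **Differential expression** per contrast (TNF vs Ctr, HS vs Ctr,
   HS_TNF vs TNF, HS_TNF vs HS) with an empirical-Bayes moderated *t*:
   per-gene variances are shrunk towards a scaled inverse-χ² prior
   (s₀², d₀) fitted by moment matching on the log variances,
   t_g = Δx̄_g / (s̃_g √(1/n₁+1/n₂)),  s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g),
   with q-values by Storey's π̂₀ λ-grid estimator (BH available).  A gene is
   called changed when its linear signal ratio is > 1.2 or < 0.8 **and**
   q < 0.05.
2. **Promoter motif prediction**: log-odds PWM scanning of both strands of
   the proximal promoter (−1000 bp to the TSS) for the κB decamer
   (GGGRNNYYCC) and a heat-shock element of ≥3 alternating nGAAn units,
   with a relative-score threshold (default 0.8 of the maximum).
3. **HSF1 binding windows**: strand-aware regulatory windows (−7500..+2500 bp
   of the TSS), ≥1-bp-overlap peak assignment, a simple Poisson+BH peak
   caller for binned tag tracks, and a per-gene "HS-induced binding" verdict
   as the union over the 10- and 20-min heat-shock timepoints.
4. **Combined-effect classification** of every TNF-modulated gene into
   enhanced activation / enhanced repression / suppressed activation /
   relieved repression / unaffected, using the same ratio+FDR rule on the
   HS_TNF-vs-TNF contrast, plus co-activation/co-repression flags and
   published-style report tables.
5. **Term overrepresentation** by the hypergeometric upper tail against an
   explicit background universe.
6. A **synthetic study generator** that plants all of the above (modes,
   motif instances, induced peaks) with a ground-truth ledger, so every
   stage's recovery can be scored exactly.

## Worked example

```python
from tfcrosstalk import CrosstalkModel, SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(n_genes=400, rng_seed=21))
model = CrosstalkModel(
    study.expression, annotation=study.annotation,
    promoters=study.promoters, pwms=study.pwms,
    peaks=study.peaks, terms=study.terms,
)
results = model.fit()
print(results.summary())
```

prints (for this seed):

```
Cross-talk analysis summary
===========================
genes analysed:            400
TNF-modulated:             67 (up 42 / down 25)
HS-modulated:              75 (up 34 / down 41)
modulated by both:         26 (up both 10 / down both 8)
affected by HS pre-treat.: 42 of 67 TNF-modulated
combined-effect modes (of TNF-modulated):
  enhanced_activation      10
  enhanced_repression      8
  suppressed_activation    17
  relieved_repression      7
  unaffected               25
co-activated (also HS-up): 10
co-repressed (also HS-dn): 8
TNF-modulated with kB motif:   50
TNF-modulated with HSE motif:  10
TNF-modulated with HSF1 induction: 9
TNF-up with kB motif and HSF1:     7
```

i.e. of the 67 genes this simulated cytokine response contains, 42 respond
differently when heat shock precedes the cytokine; 10 are co-activated
(further increased, and HS-up on their own), 17 are antagonized, and 7
TNF-upregulated genes combine a promoter κB motif with heat-shock-induced
HSF1 binding — the subset the published-style report
(`results.table1_report()`) lists gene by gene with its O/A labels.

The same pipeline runs from the shell:

```bash
tfcrosstalk run-all --seed 7 --n-genes 2000 --outdir crosstalk_out
tfcrosstalk simulate --n-genes 500 --seed 1 --outdir sim    # per-stage
tfcrosstalk de --expression sim/expression.tsv --sample-map sim/sample_map.tsv --outdir de_out
```

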