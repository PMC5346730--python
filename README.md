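# resistnet

Co-expression-network prioritization of drug-resistance targets, with
survival validation.

## The problem

When a cancer cell line acquires resistance to a targeted drug (the
motivating case: a HER2-positive breast-cancer line grown into trastuzumab
resistance), a two-condition expression profile of resistant vs. parental
cells yields hundreds of differentially expressed (DE) genes — far too many
to validate, and most unrelated to the resistance phenotype. `resistnet`
implements a network strategy for narrowing that list: project the DE
signal onto co-expression modules learned from a large patient cohort, and
keep the genes whose modules soak up far more of the top DE genes than
chance allows. Candidates are then validated as prognostic biomarkers on
the cohort's survival data.

## The method

1. **Differential expression.** Transcript abundances (FPKM,
   `10^9·count/(length·library size)`) are reduced to one representative
   transcript per protein-coding gene (highest mean abundance across the
   two conditions). Genes are ranked by pseudocounted
   `log2FC = log2((b+c)/(a+c))` after dropping unexpressed and
   abnormal-signal outliers; the top fraction *q* (default 10%) by |log2FC|
   is the DE set.
2. **Co-expression modules.** On the cohort matrix (genes × samples,
   restricted to the genes shared with the DE profile), a weighted network
   `a_ij = |cor(x_i, x_j)|^β` is built at the smallest soft-threshold power
   β giving an approximately scale-free connectivity distribution. Modules
   are average-linkage clusters of the topological-overlap dissimilarity
   `1 − TOM`; each module is summarized by its eigengene (first principal
   component of the standardized member genes) and correlated with binary
   clinical traits (tumor/normal, ER, PR, HER2).
3. **Enrichment score.** If resistance genes were unrelated to cohort
   co-expression, top-DE genes would hit each module at the background rate
   *q*. Each module is tested with the exact upper-tail binomial
   probability `P(X ≥ k), X ~ Binomial(n, q)` and scored by `−ln p`; a
   module is *enriched* when `p < α` and `k/n > q`. Candidates are the
   top-DE genes inside enriched modules, ordered by module score, then
   |log2FC|.
4. **Survival validation.** For each candidate, cohort patients are split
   at the median of its expression; the high/low groups are compared with
   Kaplan–Meier curves and the log-rank test, and the hazard ratio
   `HR = exp(β̂)` is estimated by a Cox proportional-hazards fit (Breslow
   ties, Newton–Raphson), reported with a 95% Wald CI and the percent
   change in hazard `100·(HR−1)`.

A latent-factor simulator (`resistnet.synthetic_data`) generates all three
inputs with planted structure — modules, trait associations, a DE set
concentrated in one tumor-associated module, one designated target gene
with a true proportional-hazards effect — so the whole pipeline is testable
end to end without any external data.

## Worked example

```bash
cat > demo.yaml <<'YAML'
simulation:
  seed: 3
outdir: demo_out
YAML
resistnet run-all --config demo.yaml
```

This simulates the default demo study (600 genes, six planted modules of
60 genes, 120 samples, 40 planted DE genes concentrated in the
tumor-associated module, a planted target with HR = 2) and runs every
stage. The run reports, via `demo_out/*.tsv` and `report.json`:

```
power 6  n_modules 6  enriched [1]  n_universe 600  n_top 60  n_candidates 33

module   n   k    q  p_binom    score  tumor_r  enriched
     1  61  33  0.1    0.000  39.0452   0.4825      True
     3  60   5  0.1    0.729   0.3160  -0.0300     False

gene_id  rank      hr  ci_low  ci_high  percent_risk  wald_p  logrank_p
 G00026     1  1.7026  1.0819   2.6794       70.2586  0.0214     0.0201
 G00031     2  1.0895  0.7032   1.6879        8.9475  0.7012     0.7011
```

Reading this: the network stage recovered all six planted modules at
soft-threshold power 6; module 1 holds 33 of the 60 top-DE genes
(k/n = 0.54 ≫ q = 0.1, binomial `−ln p` ≈ 39) and is the only enriched
module, and it is the tumor-correlated one (r = 0.48). The top-ranked
candidate `G00026` is the planted target: its high-expression group shows a
70% hazard elevation (HR 1.70, 95% CI 1.08–2.68, log-rank p = 0.020),
while the next candidate shows no survival effect — exactly the
candidate-then-validate behavior the method is designed for.

Each stage is also available separately (`resistnet simulate | de |
network | enrich | survive`) and as library functions.

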