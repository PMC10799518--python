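# immunocycle

Tools for cancer-immunity-cycle phenotyping of tumor cohorts. The package
scores each tumor on an eight-axis **immunogram** (sample-level gene-set
enrichment for seven axes plus a neoantigen-burden axis), discovers
immunogram **subtypes** by consensus non-negative matrix factorization with
cophenetic rank selection, quantifies **clonal selection** per subtype with a
context-corrected dN/dS estimator and a random-gene resampling null, computes
per-sample tumor statistics (MATH heterogeneity, TMB/TNB, Ti/Tv spectrum,
immunoediting score, TCR Shannon entropy), and relates subtypes to overall
survival (Kaplan–Meier, log-rank, Cox). A first-class synthetic cohort
generator plants known archetypes, selection intensities and hazards so the
whole pipeline is testable end to end without patient data.

It is aimed at computational immuno-oncology analysts who want the pieces of
this workflow as tested, composable library functions (plus a thin CLI)
rather than a monolithic script.

## The core quantities

* **Enrichment score** — per gene, expression is transformed to a
  kernel-smoothed cross-sample CDF; per sample, genes are ranked and a
  weighted Kolmogorov–Smirnov-like random walk over each gene set yields the
  max-deviation-difference score in [−1, 1].
* **Subtypes** — the sample × 8 matrix, split losslessly into nonnegative
  posneg features, is factorized X ≈ WH by multiplicative updates minimizing
  generalized KL divergence; co-clustering over random restarts gives a
  consensus matrix whose cophenetic correlation selects k over 2..7.
* **dN/dS (ω)** — with synonymous mutations as neutral background, the
  per-context rate r_c = s_c / L[c,syn] gives the neutral expectation
  E = Σ_c r_c·L[c,class] and ω̂ = n_class / E, with an exact
  conditional-binomial confidence interval; ω > 1 indicates positive
  selection, ω < 1 negative selection.
* **MATH** — 100 · MAD / median of variant allele fractions.

See `docs/methods.md` for the full model descriptions, defaults and
limitations.

## Worked example

```python
import immunocycle as ic

cfg = ic.SyntheticConfig(n_samples=120, seed=7)     # 4 planted archetypes
cohort = ic.simulate_cohort(cfg)

enrich = ic.enrichment_scores(cohort.expression, cohort.gene_sets.axis_sets())
ig = ic.assemble_immunogram(enrich, ic.tnb_axis(cohort.mutations.neoantigens))

X = ic.nonnegativize(ig)
res = ic.select_rank(X.to_numpy(), range(2, 8), n_restarts=30, seed=7,
                     sample_ids=ig.index)
print(res.k, res.per_k_cophenetic)

for cluster in sorted(res.labels.unique()):
    sids = list(res.labels.index[res.labels == cluster])
    est = ic.dnds_ratio(cohort.mutations.catalog, cohort.opportunities.genes,
                        cohort.opportunities, samples=sids)
    print(cluster, round(est.ratio, 2), (round(est.ci_low, 2), round(est.ci_high, 2)))

chi2, p = ic.logrank_test(cohort.clinical.os_time, cohort.clinical.os_event,
                          res.labels.loc[cohort.clinical.index])
print(chi2, p)
```

Output (abridged):

```
selected k: 4
per-k cophenetic: {2: 0.9893, 3: 0.9956, 4: 1.0, 5: 0.9998, 6: 0.9995, 7: 0.9992}
cluster 1: dN/dS = 1.71 [1.57, 1.85]
cluster 2: dN/dS = 1.22 [1.12, 1.33]
cluster 3: dN/dS = 2.08 [1.89, 2.30]
cluster 4: dN/dS = 3.00 [2.66, 3.40]
log-rank chi2 = 19.10, p = 2.61e-04
```

The rank search picks k = 4, matching the four planted archetypes. The
per-cluster dN/dS recovers the planted selection intensities (the
"cold/radical" archetype simulated at ω = 3 comes back at 3.00, the
"cold/inert" one at ω = 1.2 comes back at 1.22), and the log-rank test
detects the planted subtype-dependent hazards.

The same workflow is scriptable from the shell:

```bash
immunocycle simulate --out cohort/ --seed 7
immunocycle score --expr cohort/expression.tsv --gmt cohort/gene_sets.gmt \
                  --tnb cohort/neoantigens.tsv --out ig.tsv
immunocycle cluster --ig ig.tsv --kmin 2 --kmax 7 --restarts 200 --seed 7 --out clust/
immunocycle dnds --maf cohort/mutations.tsv --genes targets.txt \
                 --cds cohort/cds.fasta --labels clust/labels.tsv --out dnds.tsv
immunocycle survive --clinical cohort/clinical.tsv --group subtype --out surv.json
immunocycle run --out run/ --seed 7        # the whole thing, one report.json
```

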