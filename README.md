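# pleioscan

Bayesian phenome-wide scan that tests whether a *query variant* — a variant
already known to be causal for some primary trait — is also causal for each
of many *query traits*, using only regional GWAS summary statistics and LD
information. For every (query variant, query trait) region the scan
compares three hypotheses:

* **Hn** — no causal variant in the region,
* **Ha** — a causal variant other than the query variant (LD confounding),
* **Hc** — the query variant itself is causal (true pleiotropy).

Evidence is combined from per-SNP Wakefield approximate Bayes factors
(single-causal-variant mode) or from a built-in sum-of-single-effects
(SuSiE-RSS) fine-mapper (multiple-causal-variant mode). Priors can be fixed
or learned across all regions by a hierarchical random-walk Metropolis
model, optionally modulated by a per-trait covariate such as the genetic
correlation with the primary trait. A simulator with known truth labels and
a conventional p-value-threshold PheWAS comparator (BH / Bonferroni) make
the whole benchmark reproducible offline.

## Layout

| module | contents |
| --- | --- |
| `pleioscan.io` | summary-table / LD-matrix / covariate I/O, allele harmonization, QC filters |
| `pleioscan.bayes_factors` | Wakefield log-ABFs, per-region single-signal decomposition |
| `pleioscan.susie` | minimal SuSiE-RSS on (z, LD): per-signal lbf rows, credible sets, purity filter |
| `pleioscan.posteriors` | (ppHn, ppHa, ppHc) per signal, trait-level calls, internal FDR estimator |
| `pleioscan.hierarchical` | hierarchical prior model, MCMC, averaged priors/posteriors |
| `pleioscan.simulate` | LD models, five-class trait simulator, covariate simulator |
| `pleioscan.benchmark` + `pleioscan.cli` | conventional PheWAS comparator, evaluation metrics, CLI |

## CLI

Each verb reads/writes plain tab-delimited tables and drops a JSON summary
next to every output. A full simulated run:

```sh
pleioscan simulate --out run/ds --counts Hn=2000,Ha=100,Ha2=100,Hc=150,Hc2=150 \
    --q 100 --seed 1
pleioscan bf --dataset run/ds --method abf --out run/bf.tsv
pleioscan fit-priors --bf run/bf.tsv --out-chain run/chain.tsv \
    --out-posteriors run/post.tsv --n-iter 30000 --thin 30 --seed 2
pleioscan call --posteriors run/post.tsv --out run/calls.tsv
pleioscan evaluate --calls run/calls.tsv --truth run/ds/truth.tsv \
    --out run/report.json
pleioscan phewas-classic --dataset run/ds --method BH --out run/classic.tsv
```

`pleioscan score` applies fixed priors (`--fixed-priors pa,pc`) or reuses a
previous fit (`--priors-from chain.tsv.json`); `pleioscan bf --method susie`
switches to the multi-signal mode; `fit-priors --covariate run/ds/rg.tsv`
enables the covariate-modulated prior. `pleioscan report --config run.yaml`
chains all stages from one YAML file.

## Notes

* All Bayes-factor arithmetic is on the natural-log scale with log-sum-exp
  accumulation; LD matrices are shrunk toward the identity
  (`(1-1e-4) r + 1e-4 I`) before factorization.
* Default calling thresholds: trait is Hc when ppHc > 0.6, Hn when
  ppHn > 0.2, otherwise Ha; the internal FDR estimate is
  `1 - mean(ppHc | ppHc > t)`.
* Effect-size priors default to sd 0.2 (log-OR, case-control) and 0.15
  (standardized, quantitative) and are configurable.
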