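# gpsig — gene-pair signatures for treatment-response prediction

`gpsig` builds and applies rank-based gene-pair signatures for predicting
the pathological response of locally advanced rectal cancer (LARC) to
neoadjuvant chemoradiation (nCRT), and for stratifying disease-free
survival. It is aimed at transcriptomics analysts who need classifiers
that transfer across microarray/RNA platforms without between-sample
normalization.

The core idea is the **within-sample relative expression ordering (REO)**:
for a gene pair (a, b), only the comparison G_a > G_b inside each sample
is used. REOs are invariant to any strictly increasing per-sample
transform, hence robust to batch effects. The pipeline:

1. **Reversal screen** — keep pairs whose majority orientation flips
   between responders and non-responders, stable in both classes by an
   exact binomial test against ½ (P(X ≥ max(k, n−k)), X ~ Bin(n, ½);
   p < α = 0.05 in each class).
2. **Random-forest ranking** — encode each pair as a binary
   responder-orientation indicator and rank by mean decrease Gini
   (defaults in the analysis: ntree = 2500, mtry = 88).
3. **Best top-N selection** — the smallest ranking prefix that maximizes
   majority-vote training accuracy becomes the signature.
4. **Application** — a sample's *response ratio* is the fraction of
   evaluable signature pairs with G_a > G_b; a strict majority votes
   "responder". Evaluation includes exact Clopper–Pearson CIs, ROC/AUC
   with DeLong CI, Kaplan–Meier/log-rank and covariate-adjusted Cox.

The published 41-gene-pair nCRT-response signature (41-GPS; 41 ordered
pairs over 76 genes) ships as a checksummed fixture:
`gpsig.load_published_signature()` or `--signature builtin:41gps`.

## Layout

- `src/gpsig/` — the library: `io`, `reo` (screen), `ranking`,
  `selection`, `classify`, `evaluate`, `survival`, `simulate`,
  `pipeline`, and the `gps` CLI (`simulate`, `screen`, `rank`, `select`,
  `predict`, `evaluate`, `survival`, `discover`, `validate`).
- `analysis/01…06_*.py` — numbered drivers that run the full story on a
  simulated world and the published signature, writing under `results/`.
- `docs/methods.md` — model, assumptions, numerical choices, limitations.

## Worked example

Running the analysis chain (`python analysis/01_simulate_cohorts.py` …
`06_published_signature_checks.py`) prints:

```
train: 500 genes x 80 samples, 50 planted pairs
1399 reversal pairs at alpha=0.05 (124750 tested)
planted recall: 50/50
ranked 1399 pairs (ntree=2500, mtry=88); 48/50 of the top 50 are planted
selected N=3 (training accuracy 1.0000); 3/3 signature pairs are planted truth
held-out confusion: tp=40 fn=0 tn=40 fp=0
accuracy 100.00% (95% CI 95.49%-100.00%)
[label] non-responder: RMST 84.6 mo vs responder: RMST 269.3 mo
[label] log-rank p = 0.000197; adjusted HR 0.241 (95% CI 0.120-0.482, p = 5.82e-05)
```

Reading this: the screen recovers all 50 planted reversal pairs (among
~1,350 permissive extras — the forest, not the screen, is the filter);
the forest puts 48 planted pairs in its top 50; a 3-pair majority-vote
signature classifies a held-out, per-sample batch-distorted cohort
perfectly; and predicted responders show the longer restricted-mean DFS
and a protective adjusted hazard ratio close to the simulated truth
(HR 0.25). The desk-scale checks in `06_…` reproduce, from published
per-cohort confusion counts, sensitivity 82.86% / specificity 87.80% /
accuracy 84.68% (58/70 and 36/41), accuracy 73.81% (17/19, 14/23) and
69.70% (10/12, 13/21), and sensitivity 95.83% (23/24).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch: it simulates the
reference world from the given seed, discovers a signature (screen → RF
ranking → top-N selection), validates it on a held-out batch-distorted
cohort including survival stratification, checks the packaged published
signature, and writes the results JSON to `--out`.
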