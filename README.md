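# tadbound

Analysis toolkit for studying how TAD (topologically associating domain)
boundaries are established and what happens when individual insulator
proteins — CTCF, BEAF-32, Su(Hw), CP190 — are removed from early embryos.
It is aimed at chromatin/regulatory-genomics researchers who want a fully
testable, dependency-light reimplementation of the standard quantitative
steps of such a study:

* **Insulation & boundary calling** — diamond insulation score
  `IS(i) = log2 d(i) − ⟨log2 d⟩`, where `d(i)` is the mean contact count in
  the window of pairs straddling bin `i`; boundaries are prominence-filtered
  local minima of the multi-window separation score with a rank-sum test and
  BH correction (q < 0.1). Lower score = stronger insulation.
* **Differential boundaries** — per-condition Pearson correlation of the
  detrended contact window against an idealized boundary kernel;
  `diff_score = score(depletion) − score(WT)` (negative = weakened), with a
  contrast-to-noise filter (snr ≥ 5) and top-k vs stable-set stratification.
* **Insulator occupancy** — summit colocalization within 200 bp (UpSet
  tables), boundary occupancy classes within the 10-kb boundary region, and
  insulation stratified by factor combination.
* **Expression topology** — zygotic DEG calling (|log2FC| > 0.7,
  FDR < 0.05), promoter/peak overlap (TSS ± 500 bp, Fisher's exact test),
  and enhancer-hijacking candidates: up-regulated zygotic genes in a TAD
  flanking a disrupted boundary.
* **3-D DNA-FISH** — spot detection in anisotropic stacks, per-allele
  centre-of-mass distances, strict <250 nm / >600 nm fractions, KS tests.
* **Spike-in C&T normalization** — coverage rescaling by
  reference/sample spike-in read ratio and per-peak binding-loss ratios.

Everything runs on synthetic data with planted ground truth (distance-decay
Poisson Hi-C with tunable boundary strengths, peak sets, expression tables,
FISH mixtures, spike-in pairs), so every stage is verifiable without any
download. See `docs/methods.md` for the models and their assumptions.

## Worked example

Run a small scenario end to end (a 4-Mb chromosome, 9 boundaries of strength
0.7, one weakened to 80 % loss in the depletion condition):

```bash
tadbound init-config --out cfg.yaml     # edit chromosome/boundaries as needed
tadbound run --config cfg.yaml --outdir out/
```

`out/report.json` then contains the planted-truth recovery summary; for the
run above it reads (abridged):

```json
{
  "boundaries": {"n_called": 9, "n_false_calls": 0, "n_planted": 9,
                 "recovery_rate": 1.0},
  "diff":       {"n_affected_lenient": 1, "n_weakened_planted": 1,
                 "topk_weakened_fraction": 1.0},
  "insulation": {"mean_loss_stable": -0.0219, "mean_loss_weakened": 1.5207},
  "occupancy":  {"class_recovery_rate": 1.0},
  "expression": {"hijack_precision": 1.0, "hijack_recall": 1.0, "n_degs": 1},
  "fish": {"wt":       {"n_alleles": 100, "pct_near": 21.0, "pct_far": 48.0},
           "depleted": {"n_alleles": 100, "pct_near": 33.0, "pct_far": 40.0},
           "ks": {"statistic": 0.18, "pvalue": 0.0783231}},
  "spikein": {"median_peak_ratio": 0.1007}
}
```

Reading this: all 9 planted boundaries were called within one 10-kb bin with
no spurious calls; the one weakened boundary has the most negative
differential score and crosses the −0.1 cutoff, and its insulation score
rose by 1.52 log2 units while unweakened boundaries moved by −0.02; every
boundary's insulator-combination label was read back exactly; the planted
hijack gene is the one DEG and the one hijacking candidate; the FISH
"contact" fraction (< 250 nm) rose from 21 % to 33 % of alleles in the
depletion; and spike-in-scaled C&T signal at reference peaks collapsed to a
median 0.10 of WT under full depletion.

The same machinery is importable as a library:

```python
from tadbound import insulation, synthetic

layout = synthetic.evenly_spaced_layout(n_boundaries=10, strength=0.7)
matrix = synthetic.gen_contact_matrix(layout, synthetic.DecayModel(), seed=7)
calls = insulation.call_boundaries(matrix)          # windows 50 kb + 100 kb
print([c.bin for c in calls])                        # -> the 10 planted bins
```

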