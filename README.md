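# sigrev

Classifier-gene discovery and drug-induced signature reversal analysis for
two-arm expression-microarray studies.

## The problem

A recurring chemoprevention question in colorectal transcriptomics: given
(a) biopsy expression profiles of normal mucosa, adenoma and carcinoma, and
(b) expression profiles of a colon cancer cell line with and without drug
treatment (e.g. a COX2 inhibitor), which disease-discriminating genes does
the drug push back toward the normal state? `sigrev` implements the full
analysis chain as a tested, reusable library plus CLI:

1. **QC and normalization** — a present-call proxy (>25% of probes above
   background), within-group Euclidean-distance replicate checks, quantile
   normalization, and Tukey median-polish probe-set summarization.
2. **Classifier discovery** — nearest-shrunken-centroid classification
   (PAM). Per probe *i* and class *k*,
   `d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0))` is soft-thresholded,
   `d'_ik = sign(d_ik)·max(|d_ik| − Δ, 0)`; probes with any surviving
   deviation are the classifier genes. Δ is chosen by stratified
   cross-validation, and sensitivity/specificity are reported with the
   disease class positive.
3. **Differential expression** — a SAM-style moderated t-statistic
   `d_i = r_i/(s_i + s0)` with the fudge factor chosen by the
   coefficient-of-variation criterion and a permutation null pooled across
   probes (exhaustive enumeration for small designs: a 3-vs-3 contrast has
   exactly 20 relabelings). Selection uses p < 0.05 with two-fold gates
   logFC > 1 / logFC < −1.
4. **Reversal scoring** — a classifier gene is *reversed* when its
   treatment logFC has the sign opposite to its disease-vs-normal
   direction; reversals with permutation p < α are *significant*. The
   summary is the (classifiers, reversed, reversed-significant) triple.
5. **qPCR validation** — ΔΔCT relative quantification with the half-cycle
   technical-replicate gate, a k·SD ΔRn assay filter, fold change
   `2^(−ΔΔCT)`, pooled-variance t-tests on ΔCT, and direction concordance
   against microarray fold changes.
6. **Synthetic data** — a seeded generator emulating the study design
   (11/20/22 biopsies, 3+3 cell-line profiles, planted signatures with a
   configurable reversed subset, triplicate CT tables with an 18S-style
   reference), so every stage is testable against known ground truth.

## Worked example

```python
from sigrev import SimulationConfig
from sigrev.pipeline import run_synthetic

cfg = SimulationConfig(n_probes=2000, n_signature=20, n_reversed=17,
                       effect_size=2.0, noise_sd=0.2, seed=1)
report = run_synthetic(cfg, "runs/demo")
cls = report.stages["classify"]["adenoma_vs_normal"]
rev = report.stages["reversal"]["adenoma_vs_normal"]
de = report.stages["de"]
print(f"classifiers: {cls['n_classifiers']} at Delta={cls['chosen_delta']:.2f} "
      f"(sens {cls['sensitivity_pct']:.2f}%, spec {cls['specificity_pct']:.2f}%)")
print(f"treatment DE: {de['n_de']} significant, {de['n_up_twofold']} up two-fold, "
      f"{de['n_down_twofold']} down two-fold (s0={de['s0']:.3f}, "
      f"{de['n_permutations']} exhaustive relabelings)")
print(f"reversal: {rev['n_reversed']}/{rev['n_classifiers']} reversed, "
      f"{rev['n_reversed_significant']} at p<0.05")
```

prints

```
classifiers: 20 at Delta=9.52 (sens 100.00%, spec 100.00%)
treatment DE: 348 significant, 111 up two-fold, 121 down two-fold (s0=0.236, 20 exhaustive relabelings)
reversal: 17/20 reversed, 17 at p<0.05
```

The simulation planted a 20-probe adenoma signature of which 17 probes were
shifted in the opposite direction in the treated cell-line group; the
pipeline recovers exactly those counts: all 20 planted probes survive the
cross-validated shrinkage threshold, 17 of them show an opposite-sign
treatment change, and all 17 reversals are significant under the exhaustive
permutation null. The remaining DE genes are the planted unrelated drug
response background.

Every stage is also available from the shell:

```sh
sigrev simulate --seed 1 --outdir data/
sigrev qc --matrix data/biopsy_matrix.tsv --annot data/biopsy_annotation.tsv --out qc.json
sigrev normalize --matrix data/biopsy_matrix.tsv --out normalized.tsv
sigrev classify-pam --matrix normalized.tsv --annot data/biopsy_annotation.tsv --out-prefix pam
sigrev de-sam --matrix data/treatment_matrix.tsv --annot data/treatment_annotation.tsv \
       --group-a control --group-b treated --out-prefix de
sigrev reversal --classifiers pam_classifiers.csv --de de.csv --out reversal.json
sigrev ddct --ct data/ct_table.csv --groups data/ct_groups.tsv --reference RNA18S \
       --case adenoma --control normal --out-prefix ddct
sigrev run --config pipeline.yaml
```

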