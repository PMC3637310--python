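# estrofinger

Signature-based detection of estrogen-mimicking (phytoestrogenic)
transcriptional activity in perturbation expression experiments.

Plant extracts and other candidate endocrine modulators can be screened for
estrogen-like action by comparing their whole-genome expression response to
that of a reference estrogen (17β-estradiol, E2) in an ER-positive cell
line such as MCF-7. `estrofinger` implements that comparison as a reusable
pipeline over replicated log2 expression matrices:

1. **Differential expression** — per-probe pooled-variance two-sample
   *t*-test and fold change FC = 2^(mean log2 treatment − mean log2 control)
   for every treatment-vs-control contrast, with Benjamini–Hochberg FDR.
2. **Signature derivation** — a two-tier filter on the reference contrast:
   an initial screen (*p* < 0.05, fold > 1.5 either direction), then a
   stringent filter (FC > 4 up, FC < 0.4 down, BH FDR < 0.01 within the
   screened candidates) giving an ordered, direction-labelled
   "estrogen-responsive" probe signature. An optional cross-study
   concordance filter drops probes whose direction is not reproduced at
   ≥ 2-fold in external fold-change profiles.
3. **Connectivity-style scoring** — Spearman rank correlation ρ between
   log2 fold-change profiles of the reference and each query dose, both
   genome-wide and restricted to the signature.
4. **Clustering** — average-linkage (UPGMA) trees on the correlation
   distance 1 − *r* (centred Pearson) for treatments and probes, with
   median-centred heatmap ordering and Newick export.
5. **Response classification** — each probe's pattern across the dose
   series: `mimicked_full`, `mimicked_attenuated`, `not_mimicked`,
   `discordant`, `query_specific`, or `unaffected`, plus a monotone
   dose-trend call.

A synthetic-data module reproduces the underlying study design (3
replicates × {vehicle control C, reference EM, query doses SL/SM/SH at
0.0256/0.256/2.56 mg/ml}) with planted signature, mimicked and
query-specific probe blocks and full ground truth, so the entire pipeline
runs and is testable without any download. The published 44-row
fold-change table for the strongly E2-responsive probes ships as a worked
example fixture.

## Worked example

```python
import estrofinger as ef

e2, sh, sm = ef.table1_fixture()          # published fold changes, 44 probes
sig = ef.stringent_filter(e2, ef.table1_annotation())
print(len(sig), len(sig.up_probes))       # 44 36

r_sh = ef.spearman_similarity(e2.log2_fc_map(), sh.log2_fc_map(), name_a="E2", name_b="SH")
r_sm = ef.spearman_similarity(e2.log2_fc_map(), sm.log2_fc_map(), name_a="E2", name_b="SM")
print(round(r_sh.rho, 4), round(r_sm.rho, 4))   # 0.7727 0.6678

print(ef.classify_probe(10.69, [1.65, 10.70]))  # mimicked_full   (EGR3)
print(ef.classify_probe(6.78,  [1.29, 1.26]))   # not_mimicked    (MYBL1)
print(ef.classify_probe(0.38,  [0.97, 1.76]))   # discordant      (CYP1A1)
```

All 44 fixture probes survive the stringent filter with their printed
directions (36 up, 8 down). The signature-restricted correlations 0.77
(E2 vs the top dose) and 0.67 (E2 vs the middle dose) recover the published
coefficients 0.79 and 0.69 to within the rounding of the printed two-decimal
fold changes. The three classifications formalize the study's narrative
examples: EGR3 is up-regulated to the same extent by reference and query,
MYBL1 is induced only by the reference, and CYP1A1 responds in opposite
directions.

On a simulated experiment the full pipeline runs end to end:

```python
matrix, truth = ef.generate_experiment(ef.SimulationConfig(seed=1))
contrasts = ef.compute_contrasts(matrix)          # EM, SL, SM, SH vs C
sig = ef.derive_signature(contrasts)              # two-tier filter
print(ef.score_recovery(sig, truth).sensitivity)  # 0.9333 (seed 1)
```

## Command line

```sh
estrofinger simulate --config sim.yaml --seed 1 --out-dir data/
estrofinger de --matrix data/matrix.tsv --samples data/samples.csv \
               --treatment EM --control C --out em.tsv
estrofinger signature --contrast em.tsv --annotation data/annotation.tsv --out sig.tsv
estrofinger score --contrast-a em.tsv --contrast-b sh.tsv --signature sig.tsv --out rho.json
estrofinger cluster --contrast em.tsv --contrast sl.tsv --contrast sm.tsv \
               --contrast sh.tsv --out tree.nwk
estrofinger classify --reference em.tsv --dose 0.256=sm.tsv --dose 2.56=sh.tsv \
               --probes sig.tsv --out classes.tsv
estrofinger report --matrix data/matrix.tsv --samples data/samples.csv --out-dir report/
```

All formats are plain text: TSV matrices and tables, a CSV sample sheet,
JSON similarity results, Newick dendrograms.

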