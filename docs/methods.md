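# Methods

## Problem and model

`estrofinger` detects estrogen-mimicking transcriptional activity by
comparing a query perturbation's expression response to that of a reference
estrogen in the same cell system. The input is a probes × samples matrix of
log2 intensities with a sample sheet assigning each array to a treatment
group: vehicle control (C), reference (EM), and a query dose series
(SL/SM/SH). All inference is built from treatment-vs-control contrasts.

### Differential expression

For each probe, fold change is FC = 2^(x̄_t − x̄_c) where x̄ are group
means of log2 intensity, and significance comes from a pooled-variance
two-sample Student's *t* with n₁+n₂−2 degrees of freedom (a Welch option
exists but is off by default; with triplicate groups the pooled test is the
classical microarray choice and keeps the df interpretable). Degenerate
zero-variance probes are resolved deterministically: equal means give
(t, p) = (0, 1); unequal means give p = 0 with a warning. Multiple testing
uses Benjamini–Hochberg step-up q-values (the default meaning of "FDR" in
this literature), delegated to `statsmodels` and checked in the test suite
against a brute-force implementation of the step-up definition.

### Two-tier signature derivation

The reference signature is derived in two stages:

1. *initial screen*: p < 0.05 and fold > 1.5, applied symmetrically
   (FC > 1.5 or FC < 1/1.5);
2. *stringent filter*: FC > 4 (up) or FC < 0.4 (down) and BH FDR < 0.01,
   with q-values computed **within the screened candidate set**.

The staged FDR universe is a deliberate design choice. With triplicate
groups the pooled *t* has 4 degrees of freedom, so per-probe p-values have
a resolution floor near 4×10⁻⁵; a BH correction across a whole-genome array
(tens of thousands of probes) can then never reach q < 0.01 no matter how
large the effect, and a flat genome-wide FDR clause would return an empty
signature under exactly the replication level the pipeline targets.
Restricting the correction to the candidates that survive the initial
screen reflects the staged character of the derivation (the stringent
filter refines an already-selected responsive list) and makes the FDR
clause operate at a meaningful scale. The realized false-discovery rate of
the full procedure is measured directly on simulations with ground truth
(below) rather than assumed from the nominal level. `stringent_filter`
itself is universe-agnostic: it filters whatever contrast table (and
q-values) it is given, so a genome-wide usage remains available.

Signature probes are ordered by descending FC within the up block, then
ascending within the down block, and each probe's direction is fixed by the
reference contrast — it is never relabelled by a query contrast.

The optional concordance filter keeps a signature probe only if every
external fold-change profile containing it moves at least 2-fold in the
signature's direction; probes absent from all external profiles are kept
with a warning, since absence is no evidence of discordance.

The strongly query-responsive set uses the same fold thresholds on the
top-dose contrast with the FDR clause off by default (the selection is
fold-driven there; an `fdr_max` argument re-enables it, and the difference
in counts is logged).

### Similarity scoring

Similarity between two contrasts is the Spearman rank correlation of their
per-probe log2 fold changes, with average ranks for ties and a two-sided
p-value from the *t* approximation (adequate at the ≥ 40-probe universes
the score is used with; an exact permutation p would only matter below
~10 probes). The probe universe is either all shared probes (genome-wide)
or the signature (signature-restricted, the connectivity-style score).
Note that contrasts sharing a control group are positively correlated even
under the null — the control's noise enters both profiles — so genome-wide
ρ of ~0.5 between same-experiment contrasts is expected, and the
informative quantity is the *gain* from restricting to the signature.

### Clustering and heatmap ordering

Treatments and probes are clustered by average linkage (UPGMA) on the
correlation distance 1 − *r*, with *r* the centred Pearson correlation
(the CLUSTER/TREEVIEW convention; Spearman is reserved for similarity
scoring, where it is the named statistic). The UPGMA implementation is
written in-package so tie-breaking can be fixed: at every step the closest
pair is merged and ties are resolved by the lexicographically smallest
label pair, so dendrograms are bit-reproducible. Heights are checked in the
tests against both a brute-force O(n³) oracle that re-averages raw leaf
distances and `scipy.cluster.hierarchy` average linkage. Zero-variance
profiles have no defined correlation and are assigned distance 1 to every
other item with a warning. Trees export to Newick with ultrametric branch
lengths (a node at merge height h sits h/2 above its leaves). Heatmap
preparation median-centres each probe row (the above/below-median red-green
convention) and orders rows and columns by two-way UPGMA.

### Response classification

Per probe, with R = log2(reference FC) and Q = log2(top-dose query FC):

* reference-responsive ⇔ |R| ≥ log2(`reference_respond_min`), default 2.5;
* query-responsive ⇔ |Q| ≥ log2(`respond_min`), default 1.5;
* both, same sign: `mimicked_full` if |Q| ≥ `full_ratio`·|R| (default 0.8),
  else `mimicked_attenuated`;
* both, opposite sign: `discordant`;
* reference only: `not_mimicked`; query only: `query_specific`;
  neither: `unaffected`.

The reference threshold is symmetric at 2.5-fold, matching the scale of
the stringent filter's down cutoff (FC < 0.4 ⇔ 2.5-fold down): a probe
strong enough to enter the signature in the down direction must count as
reference-responsive, otherwise the canonical discordant case (repressed
by the reference ~2.6-fold, induced by the query) would be mis-filed. A
symmetric threshold also makes the classifier exactly mirror-symmetric:
inverting every fold change (swapping up and down) leaves categories
unchanged, which the suite verifies by property test. The top dose defines
the query response; lower doses feed only the monotone trend call
(`monotone_up` iff log2 FC strictly increases across doses and the top
dose reaches 1.5-fold; `monotone_down` symmetric). All thresholds are
keyword-configurable.

## Synthetic data

The generator emulates the target study design: 3 replicates ×
{C, EM, SL, SM, SH}, with doses 0.0256/0.256/2.56 mg/ml. Per probe,
baseline log2 intensity is N(8, 1.5²); effects are additive on the log2
scale; replicate noise is i.i.d. N(0, 0.25²). Planted blocks:

| block | count (default) | reference effect | dose-d query effect |
|---|---|---|---|
| signature up | 36 | log2 U(2, 4) (4–16-fold) | m_d × effect |
| signature down | 9 | log2 U(−2.5, −1.3) | m_d × effect |
| query-specific | 60 | 0 | 0.5 / 1.2 / 2.5 (log2) |
| null | rest of 20,000 | 0 | 0 |

Mimicry coefficients m_d default to 0.2/0.4/0.7 (partial, dose-increasing
imitation of the reference; a multiplicative attenuation of the log2
effect reproduces "same direction, lower degree" profiles). The signature
block counts mirror the 36-up/9-down published estrogen-responsive probe
set; the query-specific count is on the order of the dose-dependent
query-only cluster reported for the top dose. 5% of simulated probes get
empty gene symbols to exercise the gene-collapse rules. Ground truth
(category and per-group planted effect for every probe) is returned with
the matrix.

What the generator does **not** emulate: intensity-dependent
(mean–variance) noise trends, probe cross-hybridization, array batch
effects, and correlation between probes of the same gene. Passing recovery
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not robustness to those real-data artifacts.

## Verification strategy and problem sizes

* Hand-checkable oracles: fold-change arithmetic, the {1,2,3} vs {4,5,6}
  *t* example, the 4-point BH step-up example, the 3-item UPGMA merge are
  frozen as unit tests; BH and UPGMA are additionally compared to
  brute-force reimplementations on random instances (n ≤ 1000 and n ≤ 12).
* The packaged 44-row fold-change fixture reproduces the published
  signature-restricted correlations (0.77 vs printed 0.79; 0.67 vs 0.69 —
  the deviation budget covers two-decimal rounding and the one probe
  described but not printed), the 36-up count, and the three narrative
  classifications.
* The simulation study runs 20 seeded default-size experiments
  (20,000 probes × 15 samples each; ~2 s total): mean planted-signature
  sensitivity ≥ 0.9 with realized FDR ≤ 0.05, median signature-restricted
  ρ above median genome-wide ρ, and dose-wise median ρ strictly increasing
  in the planted mimicry coefficient. Null calibration pools three
  no-effect simulations and checks the p < 0.05 fraction against 0.05
  within 3 binomial standard errors.

`scripts/acceptance.py` recomputes all of the above from scratch with a
user-supplied seed.

## Known limitations

* The fixture's fold changes are printed to two decimals and one described
  probe is absent from the printed table, so fixture-derived statistics
  carry a small irreducible deviation from the original full-precision
  values.
* With triplicate groups the pooled *t* cannot produce genome-wide
  FDR-significant calls at stringent levels (see the staged-FDR rationale
  above); analyses with many replicates may prefer the genome-wide
  `stringent_filter` route directly.
* BH within a screened subset does not control the family-wise FDR of the
  combined two-stage selection; the pipeline's operating characteristics
  are therefore reported empirically from simulations with ground truth.
* Spearman p-values use the *t* approximation; they are indicative, not
  exact, below ~10 probes.
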