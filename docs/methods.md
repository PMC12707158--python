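# Methods

## Rank-annotation scoring

**Model.** Gene prioritization is framed as similarity-to-training-set in
annotation space. For each knowledge source — a gene × feature matrix of
quantitative annotations — features are z-scored across the genome
(population SD; zero-variance features are dropped with a logged warning,
since they carry no ranking information and would divide by zero). A gene's
raw score is the cosine similarity between its standardized feature vector
and the centroid of the standardized training-gene vectors. Cosine was
chosen over Euclidean or correlation distance because it is scale-free in
gene magnitude, deterministic, and matches the "similarity to a set of
training genes" semantics; with z-scored features it is equivalent to
Pearson correlation against the centroid up to each vector's own centering.

**Percentiles.** Raw scores are mapped to midrank percentiles,
`100·(rank_avg − 0.5)/N`, so ties share a value, scores lie strictly inside
(0, 100), and the genome median is exactly 50 whenever N is even or values
are distinct. Midranks rather than floor/ceil ranks are what make the
median-50 property hold under ties.

**Omnibus combination.** Per-source percentiles are averaged gene-wise and
re-percentiled. Rank aggregation is robust to incommensurate raw-score
scales across sources, and the final re-percentiling restores the
median-50-by-definition property that averaging would otherwise blur.
Training genes are *not* removed from the ranked universe — their headline
scores are reported like any other gene's — they are only removed from the
centroid during leave-one-out validation.

**Leave-one-out validation.** For each training gene *t*, per-source
centroids are re-fit without *t* (a rank-one update of the precomputed
training-row sum, so the full LOOCV over 20–53 genes costs milliseconds at
N = 1000) and *t*'s omnibus percentile under exclusion is recorded. The
ROC-style curve is built over one genome-wide score list in which each
training gene carries its leave-one-out percentile and every other gene its
full-fit percentile: sweeping the percentile threshold from 100 to 0, x is
the fraction of the genome at or above threshold ("genome fraction called
positive", positives included) and y the fraction of held-out training genes
recovered. The threshold grid is the distinct LOO percentiles plus {0, 100},
with (0, 0) prepended; integration is trapezoidal, and
`auc_above_diagonal = AUC − 0.5` (0 = chance, 0.5 − T/2N = perfect
separation for T training genes among N). Substituting LOO percentiles into
the genome list is what gives the perfect-separation limit its exact
0.5 − T/2N value; using full-fit scores for x instead would let training
genes inflate x without being genuinely recoverable.

## Score-set summaries

Gene-subset summaries use linear interpolation between order statistics
(quantile positions `(n−1)·p` — numpy's default) for the median and
quartiles. No quartile convention is canonical for small samples; this one
is declared so results are reproducible, and Tukey hinges would flag at most
marginally different outliers. The outlier rule is one-sided: a gene is
reported only when its score falls below Q1 − 1.5·IQR, because the
scientific question is which established disease genes score *unexpectedly
low*. Percentages are rounded half-up to one decimal at the presentation
layer only; all internal comparisons use full precision.

## Diagnostic-certainty rules

Findings are grouped per (individual, gene); likely-benign and benign
variants are ignored. For autosomal-dominant and X-linked disorders the best
single finding decides: P → definitive, LP → probable, VUS → provisional,
each conditional on the individual's phenotype being suggestive of the
disorder; non-suggestive findings yield no diagnosis. For
autosomal-recessive disorders every pair of qualifying variants is
evaluated and the highest-certainty outcome kept: in trans,
{P,P}/{P,LP}/{LP,LP} → definitive, P+VUS → probable, LP+VUS → provisional.
The last two rules are fixed and cannot be overridden by the YAML rule file;
the rest of the table is configurable. Design choices where the framework
is genuinely open:

* **Phase unknown** demotes a qualifying pair one bin relative to its
  in-trans bin, floored at provisional — unphased compound hets are weaker
  evidence but not dismissible. In-cis pairs never qualify (one allele), and
  a single AR variant is carrier status, not a diagnosis.
* **Monotonicity** is a designed invariant: upgrading any finding one ACMG
  tier (VUS→LP→P) can never lower the resulting certainty. The property
  suite enforces this and order-independence of the row order.
* De novo status, mosaicism and imprinting are not modeled.

Efficacy counts each individual once at their highest certainty; diagnosis
counts are gene-level (an AR diagnosis with two variants in one gene is one
diagnosis), so one individual can contribute several diagnoses in distinct
genes. Panel coverage is set membership of the diagnostic gene in the panel,
reported per panel at diagnosis level and unique-gene level with the
cross-panel min–max range.

## Phenotypic-expansion rule

Candidates are genes with ≥1 definitive/probable diagnosis not present in
the known-gene registry (the 53-gene training list plus 16 established TOF
genes). The narrative "sufficient evidence" judgment is formalized as:
*supported* iff rank score > 50% AND published cases link the gene (or its
syndrome) to the phenotype; mouse-CHD evidence is recorded as supportive
annotation but not required, because supported genes exist both with and
without it. Score bands are >50% (positive) and ≥85% (high). Thresholds and
the literature requirement are configurable (`ExpansionRule`).

## Synthetic data

`simulate_sources` draws each source's matrix iid Normal(0, `noise_sd`) and
adds `enrichment` to the first 20% of features for training genes —
independent Gaussian noise with an additive mean shift is the simplest model
with a single separability dial. Defaults (N = 1000 genes, K = 3 sources, 50
features/source, 20 training genes, enrichment 3, noise SD 1) give clear but
imperfect separation: training genes reach the high 90s in percentile while
the genome median stays at 50. `enrichment = 0` makes genes exchangeable,
which is the null used for calibration. Each source draws from its own
substream (`SeedSequence.spawn`) of one global seed, so components are
independently regenerable yet jointly reproducible; identical configs yield
byte-identical TSVs.

`simulate_cohort` works *backwards* from the rule table: each requested
definitive/probable/provisional individual receives findings from a template
that classifies into exactly that bin (≈60% monoallelic, 40% AR compound-het
in trans), so classification reproduces the requested composition exactly —
constructive generation rather than rejection sampling. Multi-diagnosis
individuals receive extra distinct-gene diagnoses of their own bin (hosts
must be in the definitive/probable stratum) so per-individual counts stay
exact while diagnosis-level counts grow. `n_unique_dx_genes` controls how
many distinct genes the definitive/probable diagnoses span, by cycling a
shuffled gene pool, so diagnosis-level vs unique-gene-level coverage
arithmetic (e.g. 33 diagnoses over 30 genes) is reproducible from the cohort
itself. Undiagnosed individuals may carry non-qualifying findings
(non-suggestive VUS, likely-benign variants).

**What the generator does not emulate:** real annotation semantics (GO
terms, expression profiles), correlated features, variant-level sequence
context, CNVs, and inter-source dependence. Passing tests therefore
demonstrate that the *procedure* is implemented correctly and is calibrated
under a controlled signal model — not that any particular real gene would
receive any particular score. The published TOF scores (e.g. DVL3 96.8%)
depend on proprietary knowledge sources and are used here only as inputs to
downstream stages.

## Numerical choices and problem sizes

* Percentile ties: midrank everywhere; quantiles: linear interpolation.
* Cosine with a zero-norm vector (all-constant gene after standardization)
  is defined as 0.
* Rounding half-up (`decimal.ROUND_HALF_UP`) at presentation; exact
  `Fraction`s are the ground truth for efficacy (31/131 prints as 23.7%).
* Validation simulations use N = 1000 genes, K = 3 sources, 20 training
  genes; the null calibration averages 20 seeds. At these sizes the whole
  suite runs in a few seconds. The null acceptance check is aggregate —
  mean AUC over seeds within ±0.1 and pooled LOO-percentile median in
  [35, 65] — because a single-seed AUC with 20 training genes has a null SD
  of ≈ 1/√(12·20) ≈ 0.064, so per-seed bounds at 0.1 would fail by chance.

## Known limitations

* The similarity metric, source list and combination scheme of the original
  scorer are unpublished; this is a faithful implementation of the described
  procedure, not a re-implementation of the original code.
* The certainty base table beyond the two fixed AR rules is a declared
  default, overridable by YAML, not a transcription of the full published
  criteria framework.
* The expansion rule treats "literature cases" and "mouse CHD" as boolean
  inputs; no literature or database mining is performed.
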