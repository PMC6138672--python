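# Methods

`trapclient` re-implements, as a tested pipeline, the computational route from
label-free quantification (LFQ) protein-intensity matrices to calls of
TRAP/Sec61 client proteins, and the downstream physicochemical analysis of
signal peptides (SPs) that characterizes TRAP clients as carrying high
glycine+proline (GP), low-hydrophobicity SPs. This note records the model, the
defaults and why, the numerical choices, and what the synthetic benchmarks do
and do not show.

## The experimental design being modelled

A depletion screen measures one control group (non-targeting siRNA) and two
targeting groups (two independent siRNAs against the same gene), each in
triplicate, as LFQ intensities for several thousand proteins. LFQ intensities
are comparable within a protein across samples, not across proteins. Proteins
whose abundance drops concordantly and significantly under both targeting
siRNAs are candidate clients of the depleted transport component; concordant
increases mark candidate compensatory proteins.

## Imputation

Missing LFQ values are missing-not-at-random: low-abundance proteins drop
below the detection limit preferentially. Two cases are distinguished:

* **Bottom tail** — proteins with *no* valid value in any sample. Each missing
  cell in sample *j* is drawn from
  N(mean_j − downshift·sd_j, (width·sd_j)²), where mean_j and sd_j describe
  sample *j*'s observed log2 distribution. Defaults `downshift = 1.8`,
  `width = 0.3` (in sd units) are the canonical defaults of the Perseus-style
  strategy this emulates. Tails are per-sample by default; a pooled
  (matrix-wide) tail is available via `pooled_tail`.
* **Local least squares (LLS)** — proteins with at least one valid value.
  Candidate neighbours (proteins fully observed in every column the fit or
  prediction needs) are ranked by absolute Pearson correlation with the
  target over the target's observed columns, ties broken by protein id. The
  top `k = 10` enter a least-squares fit *with intercept* (log2 abundances
  carry arbitrary per-protein offsets); missing cells are predicted from the
  fit. When k exceeds the number of observed columns the system is solved in
  the minimum-norm sense, which spreads weight over the correlated
  neighbours; this is deliberately preferred over capping k at the
  interpolation threshold, where prediction variance is maximal.
* **Final fallback** — cells LLS cannot serve (fewer observed columns than
  `min_overlap = 3`, a flat observed profile, or no eligible neighbour)
  receive bottom-tail draws inside the combined `impute()`: under MNAR an
  uninformative missing cell is most plausibly below detection. The
  standalone `impute_lls()` falls back to the observed row mean instead, so
  it remains usable outside the MNAR context.

Observed cells are never modified; a report partitions imputed cells by
mechanism. All draws come from one seeded generator, so identical
(matrix, config, seed) triples give bit-identical output.

Known limitation: with only nine samples, neighbour selection and regression
are estimated from very few points. On masked low-rank benchmarks the median
imputation error sits at roughly the replicate noise sd, not below it; no LLS
variant can do much better at this matrix width. For heavily censored rows
(knocked-down proteins whose targeting-group cells all dropped out) the
observed columns carry no effect information and LLS necessarily attenuates
the effect — this is the dominant cost of missingness in the recovery
benchmark below.

## Normalization

Intensities are log2-transformed (missing cells preserved), imputed, then
quantile-normalized. `sample_quantile` mode is the classical procedure: the
i-th smallest value in each sample is replaced by the across-sample mean of
i-th smallest values; ties receive the mean reference value of their tied
ranks. After normalization every sample has an identical sorted value vector
(checked to 1e-12) and the procedure is idempotent. A `gene_quantile` mode
applies the same procedure along rows; it exists because screen workflows are
sometimes described as normalizing "per protein", but cross-sample
comparability — what the volcano analysis needs — requires the sample-wise
default. Note that the reference vector depends on the data, so transforming
one column changes all output values while leaving every rank pattern intact.

## Differential testing and permutation FDR

For each targeting group versus control, the per-protein effect is the mean
log2 difference (targeting − control), identical to the log2 intensity ratio.
Two statistics share the permutation machinery:

* `student_t`: pooled-variance two-sample t; its two-sided p-value (df
  n_a+n_b−2) is reported per protein.
* `moderated_d` (default): the significance-analysis-of-microarrays
  statistic d = Δ/(s + s₀), where s is the pooled standard error and the
  exchangeability constant s₀ damps the heavy small-denominator tail a
  triplicate design produces. s₀ is auto-selected by the standard criterion:
  candidates are percentiles of s, and the one minimizing the coefficient of
  variation of the per-s-bin median absolute deviation of d is chosen.
  `moderated_d` is the default because the screen's statistics were computed
  with the SAM package, whose test *is* this statistic, and because a plain t
  with 2+2 degrees of freedom has essentially no usable permutation power.

Multiple testing: all C(6,3) = 20 exhaustive relabelings of the contrast's
six samples (a seeded subsample of distinct relabelings for larger designs)
give a pooled null of m × B statistics. For each protein's threshold
c = |d_i|, the estimated false-call count is the median over permutations of
the pooled null exceedances of c, scaled by π₀ (the fraction of observed
statistics inside the central 50% of the null, capped at 1), and divided by
the observed exceedance count. q-values are monotonized (a running minimum in
significance order) and calls are made at q < α = 0.05 with the sign of the
mean difference. A protein enters the intersected *negatively affected* set
only if it is significant with a negative difference in **every** targeting
contrast (likewise positively affected); discordant or single-contrast hits
are dropped. Volcano tables floor q at 1/(B·m) before taking −log10.

Degenerate cases: zero-variance identical groups score 0 with p = 1; a
zero-variance mean gap scores ±∞ (p = 0) for the t statistic and a finite
value when s₀ > 0.

## Signal-peptide features

GP content is 100·(#G+#P)/length; hydrophobicity is the arithmetic mean of
Kyte-Doolittle hydropathies over the full sequence; both reject empty or
non-standard sequences. SPs with GP content strictly above 15% are classified
`high_gp` — the threshold used to delimit putative TRAP clients. Feature
distributions between a client set and a background set are compared by the
two-sided Wilcoxon rank-sum test: exact by enumeration for pooled n ≤ 12
without ties, otherwise the normal approximation with tie and continuity
correction; the report carries group means/medians and the client/background
mean ratio.

The bundled reference table transcribes two published SP tables (38 client
SPs; 8 validation SPs including two mutants). Recomputing GP from the printed
sequences reproduces the printed GP values for 28/38 client rows and 8/8
validation rows at printed precision; the ten exceptions are internally
inconsistent in the source text (visibly truncated or corrupted sequences,
one double-rounded value) and are surfaced by `datasets.gp_consistency`
rather than silently reconciled. The printed hydrophobicity column is *not*
reproduced by the literal full-length Kyte-Doolittle mean (e.g. CALR prints
2.307 where the hand-verified mean is 41.1/17 = 2.418); the computation
behind the printed column is unspecified, so hydrophobicity is excluded from
exact anchors and the discrepancy is asserted in tests. Table-style rounding
is half-up at one decimal; full precision is kept internally.

## Enrichment

For binary categories (signal peptide, membrane, N-glycosylated, secretory
pathway, user-defined) the enrichment factor of an affected set against the
quantified background is (k/n)/(K/N). The background is the set of proteins
quantified in all samples — the statistically analyzed universe — not the
whole proteome. Significance is the upper-tail hypergeometric probability
with Benjamini-Hochberg correction across the report; the test is an addition
of this implementation (screens of this kind report only fold factors) and is
labelled as such. K = 0 yields an undefined factor (NaN) with p = 1.

## Synthetic data

`generate_lfq_dataset` draws, per protein, a log2 baseline from N(25, 2²)
(typical LFQ magnitudes), adds group effects in log2 space (multiplicative in
intensity) and N(0, 0.25²) replicate noise, and censors cells with logistic
MNAR dropout P(missing|x) = expit(−slope·(x − midpoint)), midpoint =
baseline mean − 2·sd, slope 1 per log2 unit (≈7% of cells missing, biased
low). Defaults: 2000 proteins; 100 clients at −1 log2FC in both targeting
groups; 50 compensatory positives at +0.5 (emulating SRP-receptor-style
up-regulation); 25 off-target decoys per targeting group at −1 in that group
only. Scenario presets: `null` (no effects), `default_knockdown` (defaults),
`offtarget_stress` (150 decoys per group). `generate_sp_cohort` draws SP
sequences with per-position G/P probability equal to the target GP fraction
and hydrophobic-rich background residues elsewhere. `end_to_end_fixture`
writes a byte-reproducible bundle (matrix, design, annotations, SP table,
truth, YAML config with paths relative to the bundle).

What the generator does *not* emulate: peptide-level quantification,
ionization efficiency, correlated protein modules, contaminants, or
between-replicate batch structure. Passing the benchmarks below therefore
shows the statistical machinery behaves as designed under the assumed model,
not that the biological counts of any particular screen are reproduced (those
require the deposited raw data).

## Measured operating characteristics

On seeded synthetic screens (problem size: 2000 proteins × 9 samples, 20
seeds in the test suite, 10 in the acceptance script — sizes chosen to make
Monte-Carlo error small relative to the quantities measured):

* **Null calibration**: fraction of proteins with q < 0.05 in any contrast is
  ≈ 0.001, well within 3 Monte-Carlo standard errors of the nominal level.
* **Recovery**: the intersected negative set recovers ≈ 70% of planted
  clients with an empirical FDR below 1%. The procedure is strongly
  conservative: requiring q < 0.05 per contrast *and* intersecting two
  contrasts compounds two type-II error sources. With missingness disabled
  entirely the same pipeline reaches ≈ 85–90%, which bounds what any
  imputation could achieve; the remaining loss under MNAR comes from clients
  whose knocked-down cells are censored and hence statistically
  unrecoverable. This conservatism mirrors the method's design goal —
  high-confidence client lists rather than exhaustive ones.
* **Off-target rejection**: hundreds of per-contrast decoy calls are reduced
  by the intersection to ≈1 in 1000 decoy trials (leakage requires a decoy
  to fluke past q < 0.05 in the contrast where it has no effect).

## Reproducibility

Every stochastic step takes an explicit seed. The pipeline derives per-stage
seeds from one global seed by hashing the stage name (CRC32, reduced mod
2³¹), so stages can be re-run in isolation; identical (config, seed) pairs
yield identical outputs, byte-identical result files and an identical run
manifest hash.
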