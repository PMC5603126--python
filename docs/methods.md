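# Methods

## Data model and scope

The pipeline operates on a probes × samples matrix of methylation beta
values (β ∈ [0, 1], the methylated fraction of signal at a CpG probe) and a
phenotype table assigning each sample to one of `normal`, `LN_negative`,
`LN_positive`, `unclassified`. Two binary contrasts are derived: normal vs
all tumours (unclassified tumours included by default — they are cancers of
unknown node status; a flag excludes them) and LN− vs LN+ (unclassified
always excluded). "DMR analysis" here means per-probe testing; no
region-level merging or genomic-coordinate handling is done, and no
normalisation of raw intensities — input is assumed to be level-3-style
processed beta values.

Missing values: probes with more than 20 % missing in either group of a
comparison, or fewer than 5 usable values in a group, are skipped for that
comparison (logged); otherwise missing entries are dropped pairwise before
ranking and mean computation.

## Stage 1 — quintile-restricted Mann–Whitney screen

Restricting the rank test to the extreme quintiles of the β distribution
concentrates the test on the samples where a methylation difference
manifests. Three readings of the restriction are implemented
(`quintile_mode`), because the choice is consequential:

- `pooled` (default): rank all N samples of the comparison together and
  keep the union of the bottom and top ⌈N/5⌉ samples; the test then
  compares the two phenotypes' values within this extreme subset. The
  restriction never looks at labels, so label exchangeability — and hence
  exact type-I control — is preserved. Measured null rate at α = 0.05 is
  0.046–0.048, and power on planted effects is close to that of the
  unrestricted test.
- `within_group_union`: each group contributes its own bottom and top
  ⌈n/5⌉ samples. Also null-valid (both subsets are identically
  constructed), but the comparison of within-group extremes bounds
  attainable significance far above the pooled variant — with a 27-sample
  group the smallest reachable p is ~10⁻⁸, which after multiplicity
  adjustment cannot clear stringent genome-scale cutoffs.
- `directional`: the lower-mean group contributes its bottom quintile, the
  higher-mean group its top quintile (ties toward group A). This is the most
  literal reading of "compare the lower quintile to the upper quintile",
  but it compares bottom-ranked to top-ranked values and is therefore
  degenerate under the null (essentially every probe significant at any
  cutoff). It is retained for illustration and must not be used for
  screening.

The U statistic counts pairs with x < y plus half the tied pairs. For
pooled subset sizes ≤ 12 the two-sided p value is computed by exact
enumeration of all C(n+m, n) assignments of the observed (multiset of)
values, counting arrangements whose U deviates from nm/2 at least as much
as observed — ties in the data are thereby handled exactly. Above 12, a
normal approximation with tie-corrected variance and 0.5 continuity
correction is used; at the 6+6 boundary the two branches agree within
|Δp| ≤ 0.02 on tie-free data.

Benjamini–Hochberg adjustment is applied per comparison across all testable
probes (not pooled across comparisons, since the two contrasts use
different cutoffs). Significance uses strict inequalities, `p_adj < α` and
`|Δβ| > δ`, with the mean difference computed on the *full* groups, not the
quintile subsets — the restriction sharpens the test, not the effect-size
estimate. Defaults (α, δ) = (10⁻⁵, 0.2) for normal vs cancer and
(0.01, 0.02) for LN− vs LN+: the LN contrast is biologically far weaker and
identical cutoffs would leave it empty.

## Stage 2 — mRMR

Beta values of surviving probes are discretised per probe by the μ ± σ rule
(level 0 below μ−σ, level 2 above μ+σ, else 1; a constant probe maps to all
1s), the convention of the original mRMR formulation; a pooled-median
binary mode is available. Mutual information is the plug-in estimate in
bits over observed cells. Selection is greedy forward with the MID
(difference) criterion — relevance minus mean redundancy against the
already-selected set — rather than the MIQ quotient, avoiding
division-by-zero handling; MIQ is config-switchable, as is a
relevance-only diagnostic ranking. The full greedy order is computed and
the leading ⌈0.10 · n⌉ probes are kept. Ties in the argmax (within 10⁻¹²)
resolve to the lexicographically smallest probe ID, making the ranking
deterministic and independent of input row order.

## Stage 3 — GA wrapper

Chromosomes are inclusion bit-vectors over the mRMR survivors. The
evolutionary parameters follow the study configuration: population 100,
tournament selection of size 2 (ties to the first-drawn), 10 elites copied
unchanged and exempt from mutation (strict elitism, so best fitness is
non-decreasing — asserted on every run), two-point crossover with
probability 0.6 and internal cut points 1 ≤ i < j ≤ L−1 (a proper segment
is always exchanged), per-bit mutation with probability 0.05, initial
chromosomes with exactly round(0.30 · L) bits set. A chromosome mutated to
all-zero is repaired by setting one uniform bit.

Fitness is the pooled out-of-fold AUROC of a random forest trained on the
selected probes under stratified k-fold cross-validation. Fold assignment
and the forest seed are fixed per run, so fitness is a deterministic
function of the bit pattern and is cached; resubstitution AUROC would be
degenerate (≈1 for any random forest) and carry no gradient. Defaults are
2 folds and 10 trees — deliberately small so that a full wrapper run
(≈3 000 distinct evaluations) stays in the minutes range on one core; the
fields `fitness_cv_folds` and `rf_n_trees` raise the fidelity when compute
allows. AUROC is computed by the rank formulation (concordant pairs plus
half the ties over n₊ · n₋).

Consensus panel: after a burn-in (12 generations for the cancer contrast,
20 for LN), each generation's best solutions are collected and each probe's
appearances are counted; the panel is the top `panel_size` probes by count,
ties by probe ID. "Best solutions" means the generation's `elitism_count`
best *distinct* chromosomes, not only the single best: with deterministic
cached fitness, the single best individual turns over only on strict
improvement and freezes once the search plateaus, which would collapse the
consensus onto one chromosome's bit pattern; the elite set keeps churning
at its lower ranks and so resolves which probes are common to all top
solutions rather than private to one lineage. The single best chromosome
per generation is still recorded in the trace.

### Known limitation: consensus resolution

The consensus ranking cannot resolve probes whose marginal fitness
contribution is below the evaluation noise of the forest. At typical
desk-scale settings (100 samples, 2-fold CV, 10 trees) the per-chromosome
evaluation spread is σ ≈ 0.015–0.06 (worst for dense chromosomes, whose
√p-feature-sampling luck varies most), while the marginal AUROC of an
8th–10th informative probe is ~0.005–0.02. Selection therefore fixes some
lucky null "hitchhikers" alongside the planted probes, and per-bit mutation
drifts chromosome density toward 50 %, amplifying the effect. In planted
recovery experiments (10 informative probes, Δβ = 0.3, heterogeneous noise,
200 candidates, 30 generations) the size-10 consensus panel typically
recovers 5–7 of 10 planted probes; recovering essentially all of them would
require an order of magnitude more trees per evaluation. Panels should be
read as "probes consistently useful to strong solutions", not an exhaustive
list of informative probes.

## Evaluation

`compare_strategies` draws `n_repeats` (default 100) stratified random
splits (default 70/30) and, per split, trains a random forest (100 trees)
per feature strategy on the training portion, scoring test AUROC. Splits
and per-repeat forest seeds are shared across strategies, making the
comparison paired. Following the original protocol, the panels are selected
once on all data and the splits evaluate classification only; the test
samples therefore participated in selection and absolute AUROCs are
optimistic. A fully nested re-selection per split would remove this bias
but multiplies the wrapper cost by the repeat count and is not implemented;
conclusions should rest on the paired ordering between strategies, which
shares the bias.

## Synthetic data

The generator emulates the study's structure, not its marginal
distributions. Per probe, values are Beta(μc, (1−μ)c) with baseline mean
μ ~ U(0.05, 0.95) and concentration c (default 20, within-group SD ≈ 0.11
at mid-methylation — a realistic per-probe spread; lower c models the
pole-mixture heterogeneity of impure tumour samples). Cancer-informative
probes shift μ between normal and tumour samples by `delta_cancer`
(default 0.3, sign random, baselines drawn so the shifted mean stays in
[0.05, 0.95] and is never clipped); LN-informative probes shift μ between
LN− and LN+ by `delta_ln` (default 0.08 — weak, per the near-indistinct LN
contrast; normals sit at the midpoint). Redundant probes are a parent's
values plus N(0, 0.02) jitter, clipped to [0, 1], giving mRMR true
redundancy to remove. Unclassified samples carry cancer-level methylation
but no node label. One global seed drives per-probe substreams
(`SeedSequence.spawn`), so enlarging the probe count never changes earlier
probes' values.

Default sizes are desk-scale: 2 000 probes with 100 cancer-informative and
90 LN-informative parents (plus 2 near-copies each). Relative to a real
array the null background is compressed ~200-fold, so absolute survivor
counts are not comparable to genome-scale runs, but the stage *proportions*
(survivors → 10 % candidates → panel of 20/12) match the study's shape.
What passing tests on this generator do **not** show: robustness to batch
effects, cell-type composition, probe cross-reactivity, missingness
patterns of real arrays, or bimodal/U-shaped marginals — none of which are
modelled. The generator's LN contrast, though per-probe weak, is jointly
much cleaner than a real one; synthetic AUROCs saturate and should be read
as orderings only.

## Reproducibility

Every stochastic component takes a seed. The pipeline expands one global
seed into fixed named substreams (synthetic data, GA per comparison,
evaluation per comparison), so changing, say, the number of evaluation
repeats never perturbs the wrapper search. Re-running a configuration
reproduces every output byte-for-byte; the manifest records the config
echo, all derived seeds, package versions and per-stage row counts.
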