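# Methods

## The inference problem

miRNAs and transcription factors (TFs) often act without changing their own
mRNA level: a transfected miRNA is not measured on an mRNA array at all, and
TFs are frequently switched on or off post-translationally (e.g. by
phosphorylation). Their activity is therefore inferred indirectly: if a
regulator is active in a transfection-vs-control comparison, the log2 fold
changes (l2fc) of its annotated target genes should not look like a random
sample from the background of the remaining measured genes.

For each regulator *R* with target set *T(R)* and an expression profile
mapping genes to l2fc values, the package restricts *T(R)* to the measured
genes, takes every other measured gene as background, and computes:

- **Wilcoxon rank-sum (WR)** — two-sided test that target ranks differ from
  background ranks, on the configured ranking scale;
- **Kolmogorov–Smirnov (KS)** — two-sided two-sample test on the ECDFs,
  statistic D = sup |F̂_T − F̂_B|;
- **Hypergeometric (HG)** — upper-tail over-representation of targets among
  differentially expressed (DE) genes, where DE means fold change ≥ 2 or
  ≤ 0.5 (|l2fc| ≥ 1 at the default threshold).

P-values per test are Benjamini–Hochberg adjusted — by default separately
within the miRNA family and the TF family of each experiment, mirroring the
separate miRNA and TF analyses; a pooled scope is available
(`RunConfig.bh_scope`). A regulator is called **active** when both WR and KS
are significant at the adjusted α (default 0.05), or — for TFs only, since
miRNAs are not on the array — when the TF's own gene shows a fold change
≥ 2 or ≤ 0.5. The HG q-value is reported alongside for comparison but never
gates the verdict: the simulations below quantify its lower sensitivity at
the small shifts miRNA activity induces.

## Ranking scale

The default ranking mode is `absolute`: genes are compared on |l2fc|, so a
regulator whose targets move strongly in *either* direction is detected.
This is the appropriate scale for TFs, which activate some targets and
repress others, and it makes target-set enrichment visible as an inflation
of fold-change magnitudes. The alternative `signed` mode ranks on raw l2fc
and is more powerful when all targets move the same way (e.g. pure miRNA
repression); it is a one-line config switch. Direction is annotated on every
call (sign of the signed median difference) regardless of mode.

## Numerical choices in the tests

- **Small samples.** When the number of target/background label assignments
  C(n_t+n_b, n_t) is ≤ 25,000 (covers group sizes up to 8+8), both rank
  tests use their exact permutation distribution, enumerating all
  assignments with mid-rank tie handling. This makes tiny target sets exact
  rather than relying on an asymptotic formula far outside its regime.
- **Large samples.** WR uses the tie-corrected normal approximation with
  continuity correction; KS uses the asymptotic Kolmogorov distribution
  (scipy implementations).
- **Ties.** Mid-ranks for WR; ECDF step heights for KS (D is evaluated at
  the right edge of tied blocks).
- **Degenerate input.** If every value in both groups is identical, p = 1
  and the result is flagged `degenerate`.
- **BH.** Standard step-up; adjusted values are order-preserving and never
  below the raw p. Note that step-up adjustment is not idempotent in
  general — re-adjusting an adjusted vector inflates it further — so
  pipelines must adjust raw p-values exactly once.
- p-values are clamped into (0, 1] (the smallest positive float replaces an
  underflowed 0) so that downstream log-scale handling stays finite.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | BH-adjusted significance threshold |
| `fc_threshold` | 2.0 | fold-change cutoff (symmetric, ≥2 or ≤0.5) for the TF own-expression criterion and the DE set |
| `min_targets` | 5 | measured targets required to test a regulator; below it the regulator is reported *untested* (rank tests on fewer values are close to meaningless) |
| `ranking_mode` | absolute | ranking scale, see above |
| `max_cascade_steps` | 3 | edge layers beyond the root in model building; the admissible path types (miRNA→TF, miRNA→kinase→TF, …→TF→TF) all fit in three layers |
| `bh_scope` | per-kind | BH family: miRNAs and TFs separately, per test, per experiment |

## Regulatory model construction

Given the active TF set of one experiment, the model is grown
breadth-first from the transfecting miRNA. Layer 1 admits the root's
direct targets that are kinases (from the kinase–TF interaction table) or
active TFs. Each further layer (up to `max_cascade_steps`) adds an active
TF if an edge reaches it from a node already in the model — a kinase→TF
protein interaction, or a TF→TF edge (a TF's target-set annotation whose
target is itself an active TF; the upstream TF must itself be active,
since only active TFs enter the model). Kinase activity is never tested —
kinases are connectors only — and kinases that reach no active TF are
pruned. Active TFs that no path reaches are kept in
`unconnected_active_tfs`. Kinase–TF edges from protein-interaction data
are undirected in origin but traversed miRNA-side → TF only.

A DE gene is **explained** by the model when it is a direct target of the
root miRNA or a target of a connected active TF; `explained_fraction` is
the explained share of all DE genes (0 when there are none, DE defined by
`fc_threshold`). Models from several experiments are intersected by
element support: `intersect_models(models, k)` keeps nodes/edges present
in ≥ k models, with support counts.

## Synthetic data: what it emulates and what it does not

The generator builds a catalog of regulators with target sets drawn
uniformly at random from a gene universe (TF and kinase symbols are part
of the universe, so the fold-change criterion and kinase cascades are
exercisable), kinase–TF edges sampled at a configurable density, and an
expression profile of i.i.d. Normal(0, `background_sd`) l2fc noise — with
an optional heavy-tailed Student-t alternative — into which planted
regulators' targets receive a shift of size δ. Three shift signs exist:
`down` (miRNA-like repression), `up`, and `absolute` (the shift carries the
sign of the gene's base value, inflating |l2fc| symmetrically — the generic
signature of an active regulator with mixed-direction targets, and the
default for planted benchmarks since the default ranking scale is
absolute). Overlapping planted sets add their shifts.

The standard study condition, used by the acceptance checks, is 5,000
measured genes, 200 regulators (100 miRNA + 100 TF) with target sets of
20–200 genes, and unit background SD; planted benchmarks use δ = 1.0 on 50
targets (recovery), δ = 0.3 (sensitivity comparison), and a cascade of
1 miRNA → 2 kinases → 3 TFs with δ_TF = 0.8 (model construction, with a
reduced 60-regulator catalog so that a hundred end-to-end repetitions stay
cheap). These sizes are the package's chosen benchmark conditions, fixed
once.

What the generator does **not** emulate: probe-level microarray artifacts,
normalization residue, correlated noise across co-regulated genes,
sequence-based miRNA targeting biology, or realistic target-set overlap
structure (real databases share targets much more than uniform sampling
does). Passing the synthetic benchmarks therefore demonstrates the
statistical machinery — calibration under the null, power under planted
shifts, correct graph assembly — not performance on any real transfection
dataset, where annotation quality dominates.

## Evaluation protocols

- **Primary recall** — the transfecting miRNA of each experiment must be
  re-detected; an untested primary counts as a miss.
- **AUROC** — primary miRNAs are positives, all other tested miRNAs
  negatives; scores are adjusted p-values (lower = better), ties count ½
  (Mann–Whitney pair counting). The two-test consensus is turned into a
  ranking by scoring each regulator with max(q_WR, q_KS), the worst of the
  two — a regulator ranks highly only when both tests support it.
- **Randomization null** — the gene-label ↔ value assignment is permuted
  (within the experiment), the full pipeline re-run, and consensus-active
  calls counted; per-shuffle RNG substreams spawn from one master seed.
  Note what this can and cannot certify: BH at level α controls the
  family-wise error *under the global null* at exactly ≈ α, so across many
  shuffles a small fraction ≈ α per BH family (miRNA and TF separately by
  default) is *expected* to produce a stray consensus call even in a
  perfectly calibrated pipeline. The meaningful check is that the rate of
  shuffles with any call stays at or below that bound, not that the count
  is literally zero in every finite run.
- **Power table** — per (test, δ, n_targets): the fraction of replicates
  in which a planted regulator, tested among 19 null regulators of the
  same kind, is BH-significant.

## Known limitations

- Target-set annotations are taken as given; no weighting by annotation
  confidence or binding-site score.
- The consensus rule is binary; no combined p-value or effect-size estimate
  is produced beyond the direction annotation.
- Edge signs (activation vs repression) are not inferred; models are
  connectivity hypotheses, not signed causal graphs.
- Under strongly dependent target sets (heavily overlapping regulons) BH's
  nominal FDR control is the positive-dependence variant; the randomization
  null is the empirical check that calls stay calibrated.
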