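# Methods

## The model

`netmark` screens candidate diagnostic miRNA biomarkers for a disease
condition (the worked examples are NSCLC adenocarcinoma) by integrating
two-group expression data with a reference miRNA→mRNA interactome:

1. **Differential expression.** Each assay (miRNA and mRNA) is tested with an
   empirical-Bayes moderated two-sample t statistic. The pooled per-feature
   variance s²_g (residual df d_g = n₁+n₂−2) is shrunk toward a prior s₀²,

       s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),
       t_g  = (x̄_case − x̄_control) / √(s̃²_g (1/n₁ + 1/n₂)),

   referred to a t distribution on d₀+d_g df (normal when d₀ = ∞).
   Hyperparameters (d₀, s₀²) come from method-of-moments on z_g = log s²_g
   under the scaled-F sampling model s²_g ~ s₀²·F(d_g, d₀):
   d₀ solves trigamma(d₀/2) = Var(z) − trigamma(d_g/2) (Newton inversion,
   relative tolerance 1e-10, ≤50 iterations; d₀ treated as ∞ above 1e6),
   and s₀² follows from E(z) after removing the digamma/log sampling bias.
   Two deliberate corner-case choices: variances are floored at 1e-12 before
   taking logs, and when every sample variance is *literally* identical the
   fit returns (∞, that variance) — there is no sampling spread to
   deconvolve, so the bias correction is not applied in that degenerate case.
   Significance is BH-adjusted p strictly below α (default 0.05). A paired
   mode (within-pair differences, one-sample moderated t, pairing by column
   order) exists for paired designs; the default contrast is unpaired.

2. **Condition network.** Differentially expressed miRNAs are mapped onto the
   reference interactome; by default edges are additionally restricted to
   differentially expressed genes (`restrict_genes`), since both endpoints of
   a dysregulated interaction should be condition-specific. DE miRNAs whose
   edges all drop are retained with empty target sets.

3. **Structural indices.** For every miRNA of the condition network:
   **NOG** = number of its targets with in-degree exactly 1 in that network
   (regulations no other retained miRNA can compensate), and
   **TFP** = fraction of its targets annotated as transcription factors.
   Both are defined *within* the condition network. Empty target sets score
   0/0. TFP is reported to 2 decimals, rounded half away from zero (1/8 →
   0.13). The conservation identity Σ_m NOG(m) = #{genes with in-degree 1}
   holds exactly and is tested exhaustively.

4. **Signed-rank screen.** Each index value is compared against the same
   index over all *other* miRNAs (leave-one-out background; a flag includes
   the candidate) with a one-sample Wilcoxon signed-rank test on the
   differences candidate − background_i, alternative "greater". Ranks of |d|
   use average ranks for ties; zero differences are dropped (classic
   convention; Pratt available via `zero_policy`). The p-value is exact —
   full 2ⁿ sign enumeration via the rank generating polynomial — for
   tie-free n ≤ 12, else a normal approximation with tie and continuity
   corrections. Candidates must have **both** p_NOG and p_TFP below α (raw,
   no cross-miRNA correction). Because the test depends only on (background
   multiset, candidate value), miRNAs with equal index values receive equal
   p-values — the property that pins this formulation.

   *Calibration caveat:* the test's null hypothesis is "the candidate value
   is the center of symmetry of the background distribution". For a candidate
   that is merely a typical draw from the background, the differences all
   share the single candidate draw and the test is anticonservative by
   construction (per-index call rate ≈ 0.38 at n = 30 under a continuous
   exchangeable null). The screen is therefore a *ranking* device with a
   conventional threshold, not a calibrated hypothesis test of
   exchangeability; requiring both indices to pass tempers, but does not
   remove, this. The suite asserts calibration at the test's actual null and
   the end-to-end recovery behaviour, not exchangeable-null calibration.

5. **Known-biomarker annotation.** Candidates are matched against a curated
   literature list; matching is arm-insensitive by default (-3p/-5p stripped
   on both sides), since literature entries often cite the stem or the other
   arm's official id.

6. **Enrichment.** Targets of all candidate miRNAs are pooled into one query
   (per the pooled-validation convention) and tested per gene set with the
   hypergeometric upper tail P(X ≥ k), X ~ HG(N, K, n); the universe defaults
   to all genes of the reference network; BH across the collection;
   significant means adjusted p < α.

## Synthetic study conditions

The generator emulates the real study's shapes: miRNA assay 47 case / 47
control, mRNA assay 33 / 32; log2 expression around baseline 8.0 with
residual SD 0.5; differential features shifted ±2.0 log2 units in cases
(sign per feature, recorded); 100 miRNAs × 400 genes with Poisson(8)
out-degree; 40 TF genes; DE fractions 0.25/0.25; 3 planted biomarkers with 5
exclusive targets each and target sets forced to ≥ 60% TF content; 50 gene
sets of 20 genes, one loaded with planted-biomarker targets at fraction 0.4.
Effect size and noise are calibration choices — the original study reports
neither — set to a regime where a moderated t at BH 0.05 has near-complete
power at these sample sizes, so recovery failures indicate pipeline defects
rather than underpowered conditions.

Internal coupling that makes end-to-end recovery well-posed: planted
biomarkers are always differential, and every target of a planted biomarker
is always a differential gene (the DE gene set is filled to its fraction with
random genes on top). Each artifact (network+truth, miRNA matrix, mRNA
matrix, gene sets) draws from its own child stream of the master seed, so
outputs are byte-reproducible and independent per artifact.

What the generator does **not** emulate: probe-level microarray structure,
normalization artifacts, batch effects, correlated (paired) samples,
heavy-tailed variance distributions, and a scale-free interactome degree
distribution. Passing tests therefore demonstrate correctness of the
computations and recoverability under idealized two-group log-normal data,
not performance on raw GEO arrays.

## Worked-example fixtures

The package ships the nine-miRNA candidate subnetwork of the NSCLC
adenocarcinoma study (56 miRNA→target pairs over 47 genes, as printed) with
a pinned 8-gene TF annotation (FOS, FOSB, KLF4, KLF9, ZFP36, SPDEF, HOXA5,
ETS2) that reproduces six of the published TF percentages exactly; the TF
members behind two rows (miR-567, miR-590-3p) are not inferable from the
published numbers and those two values are not reproduced. Published NOG
values other than miR-139-5p's were computed on the full (unreleased)
93-miRNA condition network and differ from the 9-row subnetwork tally by
construction; the same applies to the published screening p-values, which
would require the original background of 93 miRNAs. Re-screening the nine
pre-screened miRNAs against one another is statistically meaningless, so the
scoring-only workflow accepts `alpha_screen ≥ 1` to bypass the screen and
carry every scored miRNA forward — that is how the fixture's 9-candidate /
5-novel bookkeeping is reproduced.

## Numerical and design choices

- Quantile normalization (column-sorted values mapped to the across-sample
  mean profile; ties get the mean over their rank span) is the default; it is
  the microarray convention and downstream statistics are shift-invariant.
  `normalization="none"` switches it off.
- BH adjustment is shared by the DE and enrichment stages (one
  implementation, statsmodels step-up behind it). BH is deliberately *not*
  asserted to be idempotent — step-up adjusted values are not a fixed point
  of the procedure in general.
- Thresholds are strict (`<`) everywhere a published cut is quoted as
  "less than".
- Score tables order miRNAs by descending NOG, then descending TFP, then id;
  floats serialize at 6 significant digits except TFP (2 decimals).
- Problem sizes in the test suite (e.g. 2000-feature null matrices × 20
  seeds; 50 end-to-end recovery runs at the default 100×400 study shape) are
  chosen to put Monte-Carlo error well inside the asserted bands while the
  whole suite stays interactive.

## Known limitations

- The screen's p-values are exact only for the stated null (see the
  calibration caveat); magnitudes from differently sized backgrounds are not
  comparable across networks.
- The reference interactome is always a user input; the package bundles no
  target database and makes no claim about target-prediction quality.
- Identifier handling normalizes case and species prefixes only; mapping
  array accessions to gene symbols is the caller's responsibility.
- GEO series-matrix ingestion is a thin loader hook (metadata lines skipped,
  caller supplies the case/control split); results on real GEO data are not
  part of the tested surface.
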