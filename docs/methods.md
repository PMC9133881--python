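# Methods

This note documents the statistical model behind each stage of
`cernapipe`, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical and design choices made where
the procedure was genuinely open.

## Differential expression (`cernapipe.diffexpr`)

Counts are modelled as NB(μ<sub>gj</sub> = s<sub>j</sub>q<sub>g(j)</sub>,
α<sub>g</sub>) with per-sample size factors s<sub>j</sub> and gene-wise
dispersion α<sub>g</sub> (variance μ + αμ²).

* **Size factors** are median-of-ratios against the per-gene geometric-mean
  pseudo-reference, computed over genes expressed in every sample. If no
  such gene exists the function raises rather than silently switching to a
  pseudo-count reference — the caller should decide how to handle such
  degenerate data.
* **Dispersion** is estimated per gene by a pooled within-group method of
  moments on normalized counts, then stabilized in two steps: (i) a
  log-linear mean–dispersion trend is fit through *binned means* of the raw
  estimates. Raw estimates at 2–3 replicates per group are extremely
  skewed; fitting the trend through the log of per-gene estimates (or only
  the positive ones) biases it low, whereas bin averages that keep negative
  estimates are unbiased for the trend level. (ii) The per-gene value is
  the additive blend 0.5·max(α̂, 0) + 0.5·α_trend, clamped from below at
  the trend: with a handful of replicates there is no evidence to support
  below-trend dispersion, and letting noisy estimates dip below it inflates
  the Wald statistic (measured type-I error ≈ 0.06–0.07 without the clamp,
  ≈ 0.04 with it, at a nominal 0.05). Constant (zero-variance) genes and
  datasets whose bin averages collapse (Poisson-like data) resolve to the
  floor of 1e-8.
* **The Wald test** uses log₂FC = log₂((m̄_t + pc)/(m̄_r + pc)) with
  pseudocount pc = 0.5 (stabilizes all-zero groups), a delta-method
  standard error from the NB variance (using m̄ + pc as the mean plug-in so
  an all-zero group still contributes variance), and a two-sided normal
  p-value. All-zero genes are flagged and given p = 1, log₂FC = 0.
* **Calls** are strict: `up` iff FDR < 0.05 *and* log₂FC > 1; `down`
  symmetric. The reference level is the normal condition, so positive
  log₂FC means higher in the hairless condition.

This is deliberately not a full GLM engine: no IRLS fit, no posterior
fold-change shrinkage, no independent filtering, no outlier refitting.
The downstream ceRNA logic consumes only (log₂FC, FDR) direction calls,
and the simplified pipeline is calibrated under its own generative model
(type-I error within [0.03, 0.07] at α = 0.05; sensitivity ≥ 0.9 for
four-fold effects at dispersion 0.05 with 3 replicates). Counts on real
data will differ from a full GLM implementation's.

## lncRNA candidate filter (`cernapipe.lncfilter`)

Five rules, applied in a fixed printed order for reason reporting but
order-independent in outcome: length ≥ 200 nt; exons ≥ 2; FPKM > 0.5 in at
least one sample; read coverage ≥ 3 in at least one sample; no
protein-coding annotation; and a consensus non-coding vote. Notes:

* FPKM = count / (length/10³) / (library/10⁶). The "in at least one
  sample" scope for the FPKM rule parallels the coverage clause; applying
  it across all samples would conflate low expression in one tissue with
  non-candidacy.
* Coverage is proxied by count·read_length/length with read_length
  configurable (default 150 bp, paired-end short-read sequencing).
* Coding potential is a pluggable scorer contract; the built-in scorer is
  the logistic of the longest ATG→stop ORF fraction over the three forward
  frames (midpoint 0.5, steepness 10). A transcript is non-coding only if
  *all* registered scorers vote non-coding, mirroring multi-tool consensus
  filtering; with the single built-in scorer this degenerates cleanly.

## Target assignment (`cernapipe.targets`)

* **cis**: same chromosome and a transcript-boundary gap ≤ 100 kb
  (overlap counts as gap 0; strand ignored). The gap is measured between
  closest boundaries rather than TSS-to-TSS, since "adjacent genes" does
  not specify anchors.
* **trans**: |Pearson r| ≥ 0.95 on VST-scale profiles, sign reported;
  zero-variance profiles are skipped with a warning (r undefined).
* **seed**: exact reverse complement of miRNA positions 2–8 (the canonical
  7-mer core shared by TargetScan-class predictors) occurring ≥ 1 time in
  the target, U/T-normalized, overlapping sites counted, positions 0-based
  half-open. Thermodynamic (minimum-free-energy) site filtering is not
  implemented — free-energy models are predictor-specific — but the edge
  evidence field and the `intersect_predictors` operator (edges present in
  every predictor's set, any arity) preserve multi-tool-overlap semantics
  for plugging in external predictors.
* In the assembled pipeline, mRNA seed sites are restricted to the UTRs
  (both 5' and 3'; the annotation records the transcript-relative CDS span)
  because functional sponge sites are described in UTRs in this literature
  — reports disagree on which UTR, so both are scanned. The lncRNA sponge
  is scanned over its full length.

## Triple assembly and prioritization (`cernapipe.cerna`)

A triple (L, M, G) is emitted iff a seed edge M→L and a seed edge M→G
exist and the DE directions match one of the two sponge-consistent trend
models: model1 = (L down, M up, G down), model2 = (L up, M down, G up).
Output is deduplicated and sorted. A direct L→G cis/trans edge is recorded
when present and required only in strict mode (`require_lnc_mrna_edge`),
since co-location/co-expression support for the lncRNA–mRNA leg is
desirable but not logically necessary for sponging.

Tissue specificity is direction-agnostic: a feature DE up in the focal
tissue and down elsewhere is not specific. `prioritize` retains triples
whose mRNA is a hub (|kME| ≥ 0.8) of a module with p < 0.05 (strict) at
the focal stage. An optional curated gene allowlist can further restrict
the mRNA universe; no curation is shipped.

## Co-expression core (`cernapipe.coexpr`)

* Genes with total count ≤ 10 are dropped (strict `> 10`).
* The VST is approximated by log₂(count/size_factor + 1) — monotone,
  asymptotically log-scale — rather than a parametric variance-stabilizing
  fit; a documented simplification.
* Soft power β: for each candidate power the unsigned adjacency
  |cor|^β is formed, connectivity k<sub>i</sub> = Σ<sub>j≠i</sub>
  a<sub>ij</sub> is binned (10 bins on log₁₀ k) and log₁₀ frequency is
  regressed on log₁₀ mean k; the chosen β is the smallest with R² ≥ 0.8,
  else the argmax. Planted-block data is not genuinely scale-free, so on
  the synthetic fixture the argmax branch usually governs (β ≈ 4).
* TOM as defined above; the implementation is a single matrix product and
  is oracle-tested against a triple loop.
* **Module detection** is average-linkage clustering of 1 − TOM with a
  *static* height cut; the full dynamic hybrid tree-cut algorithm is not
  reimplemented, so module counts on real data will differ from the
  reference R implementation's. By default the cut height is chosen
  automatically at the midpoint of the largest gap in the sorted merge
  heights: within-module merges happen at low dissimilarity, unrelated
  genes agglomerate near 1, and the widest dendrogram gap separates the
  two regimes without an instance-specific constant (a fixed height that
  works at one soft power fails at another). An explicit `cut_height`
  overrides this. Clusters below `min_module_size` (30) become label 0
  (grey); modules are renumbered by decreasing size.
* Eigengenes are the first right singular vector of the module's
  gene-standardized expression, unit norm, sign-oriented to correlate
  positively with the module's mean profile; variance explained is
  reported. Module–trait association uses Pearson r against binary stage
  indicators with the exact Student-t p-value (n − 2 df). Hubs are genes
  with |kME| ≥ 0.8; grey genes are never hubs.
* The network is unsigned; signed variants are a straightforward extension
  but were not needed for sponge-direction logic, which operates on DE
  calls rather than correlation signs.

In the end-to-end pipeline the network is built on the focal tissue's
stage series restricted to the reference (normal) condition: the
condition-response DE effect would otherwise manufacture correlation
structure among DE genes in the case arm and contaminate stage-driven
modules.

## Phenotype and qPCR utilities (`cernapipe.assays`)

Embryos below 1 follicle/cm² are hairless, above 4 are normal; the
interval [1, 4] is deliberately left indeterminate since only the two
tails are defined phenotypes. Relative qPCR expression is 2^−ΔΔCt; it is
invariant to adding a constant to all four Ct values, and no efficiency
correction is applied.

## The synthetic-data generator (`cernapipe.simulate`)

The generator emulates exactly the statistical structures the pipeline
assumes, as a pure function of (parameters, seed):

* **Design**: 2 conditions × 5 tissues × 3 replicates at the focal stage
  for all three assays, plus the focal tissue's full 5-stage series for
  the mRNA assay (one embryo = one sample; no litter random effect).
* **Counts**: NB with gene-wise dispersion (default 0.05) and log₂-uniform
  base means on (3.3, 10) (≈10–1000). Planted members (triple RNAs, module
  genes) draw base means from the upper half of that range — validated
  ceRNA members in this literature are well-expressed genes, and
  co-expression analysis operates on expressed genes. Library offsets are
  a shuffled log₂-linspace over ±0.5, guaranteeing ≥ 2-fold spread to
  exercise normalization.
* **DE**: per tissue, a de_fraction (5%) of mRNAs get a ±2 log₂ shift in
  the hairless condition at the focal stage. Triple members anchor the
  focal tissue with trend-consistent signs and are excluded from all other
  tissues so they remain tissue-specific; other tissues get their own DE
  sets (lncRNA and miRNA included), which exercises the Venn logic.
* **Modules**: each module has a latent per-sample factor, mean-shifted by
  +2 log₂ units at the module's associated stage (the first module is tied
  to the focal stage; the others to distinct stages so unsigned
  correlations cannot merge them). Gene loadings are U(0.8, 1.2); per-
  sample factor noise is kept small (sd 0.3) relative to the DE effect so
  the module structure cannot mask planted DE on shared genes, and triple
  mRNAs — planted as hub members — get loadings U(1.2, 1.5) so their kME
  stays above the hub threshold despite estimation noise at 15 samples.
  Module filler genes are never planted DE in the focal tissue: the
  modules model stage-driven co-expression, not condition response, and
  this keeps the two planted structures individually identifiable.
* **Sequences**: background is uniform over {A,C,G,T} with no deliberate
  sites. For each triple the reverse complement of the miRNA seed is
  embedded in the sponge lncRNA and in one UTR of the target mRNA.
  Planted-member sequences are rejection-sampled so they contain no *other*
  planted miRNA's seed site — a chance occurrence would be a real,
  undeclared interaction and would make the planted truth ambiguous — and
  true lncRNAs are resampled until their longest-ORF fraction is below 0.4
  so they survive the coding filter by construction. mRNAs are
  150 nt UTR + 300 nt ORF + 150 nt UTR; lncRNAs 300 nt over two exons;
  miRNAs 22 nt. These compact lengths match the scaled-down gene counts.
* **Decoys**: four classes at 6% of lncRNAs each — short (150 nt),
  mono-exonic, coding-ORF-bearing, and silent (zero counts, failing the
  FPKM/coverage rules) — for negative testing of the candidate filter.
* **Placement**: features are laid out sequentially over 10 chromosomes
  with 150–250 kb gaps; designated cis pairs (half the triples) place the
  sponge 20–80 kb from its target so only designed pairs fall inside the
  100 kb window. Placement failures raise naming the violated constraint.

What the generator does **not** emulate: read-level artifacts (FASTQ,
alignment, assembly), batch effects, litter structure, GC/length biases,
isoform complexity, signed regulatory cascades, or any thermodynamics of
miRNA binding. Passing the planted-truth recovery tests therefore shows
the *integration logic* is correct under its stated model, not that the
pipeline is robust to upstream artifacts of real sequencing data.

## Problem sizes used in tests and the acceptance script

The default fixture is 2000 mRNAs, 100 lncRNAs, 50 miRNAs, 10 triples and
3 modules of 60/50/40 genes, a deliberately compact instance on which the
full pipeline runs in a few seconds; calibration studies use 5000 null
genes and 200 planted genes at 3 replicates per group. These sizes give
binomial standard errors of well under a percentage point on the reported
rates while keeping the whole suite fast.

## Known limitations

* The DE engine's p-values are asymptotic (normal Wald with plug-in
  dispersion); at very low means they are conservative rather than exact.
* Static-cut module detection has no per-gene reassignment stage; genes
  with borderline module membership can land in grey.
* The seed predictor models only canonical 7-mer site recognition; no
  conservation, context, or energy scoring.
* FPKM/coverage rules inherit whatever library-size definition the caller
  supplies (the pipeline uses combined mRNA+lncRNA totals per sample).
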