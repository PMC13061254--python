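# Methods

This note documents the models, parameters, and numerical conventions
behind `e3ome`, and what the synthetic-data tests do and do not establish
about behaviour on real inputs.

## Evidence model and scoring

The unit of curation is a gene with an HGNC-style symbol, an alias set, and
two kinds of attached records: curator votes (yes / no / inconclusive /
unassessed, at most one per curator per family context) and evidence items
— distinct (source, claim) pairs from a closed source vocabulary
(InterPro-style domain annotations, BioGRID-style interaction partners,
literature-annotated motifs). Symbols are canonicalised to uppercase;
alias collisions surface as ambiguity errors at resolution time rather
than at load time, because real alias maps do contain shared historical
symbols and the right behaviour is to refuse the ambiguous token, not the
whole ledger. Duplicate evidence rows are collapsed, not summed: the
scoring model rewards the presence of a line of evidence, and fifty
redundant reports of the same interaction carry no more weight than one.

The confidence score is a weighted sum: +5 per curator inclusion, −5 per
exclusion, +2 per distinct evidence line; inconclusive and unassessed
votes are neutral. Multiple curators stack — the categories are defined by
"at least one curator", which presumes independent votes. Category
assignment is score-free: 1 iff any yes vote, 2 iff no yes vote but at
least one evidence item of any source (the weakest defensible reading of
"some evidence"; the threshold is an argument), 3 otherwise. Ranking is by
score descending with ties broken by category ascending then symbol, so
output order is a pure function of the ledger.

Family classification is driven by a YAML rule file shipped as package
data (domains, motifs, interaction partners per family); curator-only
families (APC/C substrate receptors, atypical, pseudo) are entered through
family-context votes. A gene may satisfy several rules and receives one
assignment per satisfied family; the high/low confidence tier is category
1 vs not, evaluated within the family's vote context. Because CRL2 and
CRL5 substrate receptors share the elongin adaptors ELOB/ELOC, an
elongin-only evidence pattern legitimately matches both families — the
resolution between them is a curator call, not a rule.

## Association stages

PheWAS records are filtered at p ≤ 1e-8 (inclusive), deduplicated per
(variant, phenotype) across the four genetic models keeping the smallest
p (exact ties go to a fixed model priority, genotypic/additive first, so
results are order-independent), and summarised per (gene, phenotype
category) as the arithmetic mean of odds ratios (binary traits, OR scale —
not log-OR) or of absolute effect sizes (continuous traits). Binary and
continuous groups are never pooled. Protective odds ratios are averaged
directly by default; folding (1/OR) is an option.

The GWAS cascade applies, in order: p ≤ 5e-8; per (mapped gene set,
variant, trait) minimum-p across studies; unique single-gene mapping;
high/moderate functional impact; exclusion of non-specific parent
categories ("Other trait", "Other disease", "NR", "Other measurement"),
of rows with no parent category, and of "Body measurement" (height, weight
and BMI are so polygenic that they drown specific signals). Each stage
logs its survivor count; the log is non-increasing by construction.

## Term enrichment

For each family, every ontology term annotating ≥ 3 family genes (the
threshold applies to the intersection, not the term's total size) is
tested one-sided for enrichment with an exact Fisher test: the
hypergeometric upper tail is accumulated in log space from log-factorials
(`gammaln`), which is exact to floating precision for the small
intersection counts involved — no normal approximation. BH adjustment is
computed separately within each family across exactly its tested terms;
there is no global adjustment. Odds ratios use the Haldane-Anscombe
correction (+0.5 per cell). Annotations are propagated to ancestor terms
before testing (standard true-path practice; a flag disables it), with
cycle detection on the is_a graph. The default universe is the 19,294
protein-coding genes of the HGNC-style reference; it is a parameter.

## Expression procedures

Donor sampling retains one sample per donor and exactly 9 donors per
tissue, donors exclusive to a single tissue, under a fixed seed (42).
Reproducibility requires pinning what the underlying RNG library leaves
open, so tissues are processed in sorted order, donor lists are sorted
before selection, a donor seen in several tissues is assigned to its
sorted-first tissue, and the retained sample is the donor's sorted-first
sample. Capacity violations name the offending tissue.

Bulk counts are AUC-scaled to a common 4×10⁷ library size (unrounded) and
restricted to a predefined gene panel supplied as a file — the panel is an
input, not derived from the census, because panel membership on a given
expression reference reflects annotation versions the package cannot
reconstruct. The bulk differential-expression engine itself
(moderated-t / empirical-Bayes pipelines) is out of scope: `de_call`
thresholds any engine's (FDR, log2FC) table at FDR < 0.05 (strict) and
|log2FC| ≥ 1 (inclusive), and the in-package Wilcoxon harness serves as
the testable stand-in engine. Row-wise Z-scores use the sample (n−1)
standard deviation, matching heat-mapping defaults; constant rows map to
zeros.

Single-cell counts are normalised per cell to CP10K with library sizes
clipped at 1e-12 (so all-zero cells pass through as zeros rather than
dividing by zero) and non-finite entries zeroed; log1p is natural-log.
Classes with < 20 cells are dropped. Marker detection is a two-sided
Wilcoxon rank-sum of each class against the pooled rest, using the normal
approximation with tie correction and no continuity correction — the
convention of mainstream single-cell toolkits — switching to exhaustive
enumeration when the total cell count is at most 16 so small cases are
exact. Zero-variance genes return p = 1 (no evidence of difference).
Fold changes are log2((mean_in + ε)/(mean_out + ε)) with ε = 1e-9. BH runs
across genes within each class; significance is p_adj < 0.05. Matrices
carry a layer tag (raw → auc_scaled or cp10k → log1p) and operations
refuse wrong-layer inputs, preventing silent double normalisation.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of a config whose single seed feeds named
sub-streams (one per output kind), so adding a generator never shifts
existing fixtures. Defaults encode the study conditions: 31 tissues × 12
donors with 1–3 samples each; a 19,294-gene universe with 100 terms at 2%
background annotation; negative-binomial counts parameterised by (mean,
dispersion) with variance mean + dispersion·mean² (dispersion 0.5, base
mean 2 with log-normal gene-to-gene spread), 3 classes × 100–200 cells,
10 planted markers per class at 8-fold; curator accuracy 0.9 and evidence
sensitivity 0.8 where noise is wanted, 1.0 for recovery checks. The
ontology generator bounds depth at 5 and fan-in at 3 to keep exhaustive
propagation oracles feasible.

Passing tests on these fixtures establish that the procedures implement
their definitions and control false positives under their own null
models. They do not establish robustness to features of real data the
generators omit: correlated phenotypes and linkage between variants,
scale-free interaction evidence, ontology annotation bias toward
well-studied genes, batch effects and donor covariance in expression, or
gene-gene correlation in counts.

## Numerical and testing conventions

Exact statistics (Fisher, BH, rank-sum, Haldane-Anscombe) are verified
against independent brute-force oracles: rational hypergeometric
enumeration for margins ≤ 30 at 1e-12, the direct step-up formula and an
external multiple-testing implementation for BH, exhaustive permutation at
1e-10 for rank-sum groups ≤ 8. Simulation guarantees are checked at fixed
seeds: null term enrichment flags ≤ 7% of 1,000 uniformly drawn families
(the 95% binomial envelope around a nominal 0.05, which the discrete
Fisher test undershoots), null marker detection over 50 replicates of
500 genes × 3 classes × 100 cells keeps the mean significant fraction
within the same envelope, and planted 8-fold markers are recovered with
recall ≥ 0.9, ranking in the top decile by p within their class. These
problem sizes were chosen as the smallest at which the binomial envelopes
are meaningful.

Known limitations: no live database access (all evidence arrives as
files); no sequence- or structure-based domain detection; no EFO reasoning
beyond a supplied trait→parent table; the workbook reader's tolerant
header matching is written against a compendium-style layout and exercised
on a synthetic stand-in, so a deposited workbook with unanticipated
headers may need a mapping entry.
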