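# e3ome

Curation and integration toolkit for a human E3 ubiquitin-ligase gene
census. E3 ligases — the terminal enzymes of the ubiquitination cascade —
are scattered across heterogeneous published lists, domain databases, and
interaction resources; assembling a trustworthy census requires combining
curator judgement with typed evidence in a reproducible, auditable way.
This package implements that workflow as a tested library plus a small CLI,
for computational biologists who maintain or consume gene-family
compendia.

## What it computes

**Evidence-based confidence scoring.** Each candidate gene accumulates an
integer score

```
score = 5·(# curator "yes" votes) − 5·(# curator "no" votes) + 2·(# distinct evidence lines)
```

where an evidence line is a distinct (source, claim) pair: an
InterPro-style domain annotation, a BioGRID-style interaction partner, or a
literature-annotated motif. Genes fall into category 1 (at least one
curator included them), category 2 (no curator inclusion, but some
evidence), or category 3 (neither), and are ranked by score with a
deterministic tie-break.

**Rule-based family classification.** Families are data, not code: a YAML
rule file maps each family to admitting claims (e.g. CRL1 substrate
receptors via an F-box domain and/or CUL1/SKP1 interactions; CRL3 via
BTB/3-box and/or CUL3; degenerate RINGs via U-box, SP-RING, hemiRING or
RING-like folds). A gene may enter several families (a dual F-box +
helix-loop-helix receptor joins both CRL1 and CRL4), and per-family Sankey
tallies (input → per-claim evidence → high/low confidence) conserve the
input count.

**Association summarisation.** PheWAS summary statistics are filtered at
p ≤ 1e-8, collapsed across genetic models (genotypic/additive, allelic,
dominant, recessive) to the smallest p per variant-phenotype pair, and
averaged per gene within each phenotype category — odds ratios for binary
traits, absolute effect sizes for continuous ones, never mixed. GWAS
catalog rows pass a five-stage cascade: p ≤ 5e-8, min-p dedup across
studies, unique gene mapping, high/moderate impact, and removal of
non-specific or body-measurement trait categories.

**Phenotype-term enrichment.** For each family, ontology terms annotating
at least 3 family genes are tested with a one-sided Fisher exact test
against a 19,294-gene protein-coding universe, BH-adjusted within the
family, with Haldane-Anscombe odds ratios
(a+½)(d+½)/((b+½)(c+½)) that stay finite with zero cells.

**Expression profiling.** Seeded donor sampling (one sample per donor,
9 donors per tissue, donors exclusive to one tissue), AUC scaling to a
4×10⁷ common library size, gene-panel restriction, per-cell CP10K
normalisation with library clipping, one-vs-rest Wilcoxon rank-sum marker
detection (tie-corrected, BH within class, p_adj < 0.05), DE thresholding
(FDR < 0.05 and |log2FC| ≥ 1), and row-wise Z-scores.

**Synthetic data.** Every input has a seeded generator with a ground-truth
table: curator votes with configurable accuracy, per-family evidence
patterns, variant associations with mixed null/signal p-values, ontology
annotations with planted family enrichment, and negative-binomial count
matrices with planted fold-change markers.

## Worked example

```
$ e3ome simulate --seed 3 --out demo
synthetic inputs written to demo
$ e3ome curate --genes demo/evidence/genes.tsv --votes demo/evidence/votes.tsv \
    --evidence demo/evidence/evidence.tsv --out demo_curated
curation outputs written to demo_curated
$ head -4 demo_curated/ranked_genes.tsv
symbol	score	category	rank	families
G0027	13	1	1	CRL2_SR;CRL5_SR
G0029	13	1	2	CRL2_SR;CRL5_SR
G0001	11	1	3	CRL1_SR
```

The top score of 13 is one curator inclusion (+5) plus four distinct
evidence lines (+2 each) — here a BC-box-CUL2-box motif with CUL2, ELOB
and ELOC interactions. The shared elongin partners are why the gene is
listed under both CRL2 and CRL5 substrate receptors: family calls report
every rule the evidence satisfies. Category 1 marks curator-included
genes; rank orders by score with ties broken by category then symbol.
`demo_curated/family_tallies.json` holds the per-family high/low-confidence
split, which always sums to the family's input count.

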