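"""Variant-level association summarisation and filtering.

Two procedures operate on summary statistics only (no individual-level
data):

* PheWAS summarisation — keep genome-wide-significant records (p <= 1e-8),
  collapse multi-model duplicates of a variant-phenotype pair to the
  smallest p, and average effects per gene within each phenotype category
  (odds ratios for binary phenotypes, absolute effect sizes for continuous
  ones, never mixed).
* GWAS catalog cascade — keep p <= 5e-8, collapse multi-study duplicates of
  a gene-variant-phenotype key to the smallest p, keep variants uniquely
  mapped to one gene, keep high/moderate functional impact, and drop
  non-specific or absent parent trait categories (including the highly
  polygenic body-measurement traits).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

MODELS = ("genotypic_additive", "allelic", "dominant", "recessive")
#: Tie-break priority when two models report the same minimum p.
MODEL_PRIORITY = {m: i for i, m in enumerate(MODELS)}

IMPACTS = frozenset({"high", "moderate", "modifier", "low"})

DEFAULT_EXCLUDED_CATEGORIES = frozenset(
    {"Other trait", "Other disease", "NR", "Other measurement", "Body measurement"}
)


@dataclass(frozen=True)
class VariantAssociation:
    variant: str
    gene: str
    phenotype: str
    phenotype_category: str
    model: str
    p: float
    effect: float
    phenotype_type: str  # binary -> effect is an odds ratio; continuous -> beta

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.phenotype_type not in ("binary", "continuous"):
            raise ValueError(f"unknown phenotype_type {self.phenotype_type!r}")
        if self.phenotype_type == "binary" and self.effect <= 0:
            raise ValueError("odds ratio must be positive")


@dataclass(frozen=True)
class GenePhenotypeSummary:
    gene: str
    phenotype_category: str
    phenotype_type: str
    mean_effect: float
    n_associations: int

    def __post_init__(self):
        if self.n_associations < 1:
            raise ValueError("n_associations must be >= 1")


@dataclass(frozen=True)
class GwasRow:
    variant: str
    mapped_genes: frozenset[str]
    mapped_trait: str
    parent_category: str | None
    p: float
    impact: str | None
    study: str

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.impact is not None and self.impact not in IMPACTS:
            raise ValueError(f"unknown impact {self.impact!r}")


# --------------------------------------------------------------------------
# PheWAS side


def phewas_filter_significant(
    records: Iterable[VariantAssociation], alpha: float = 1e-8
) -> list[VariantAssociation]:
    """Keep records with p <= alpha (inclusive threshold)."""
    return [r for r in records if r.p <= alpha]


def phewas_dedup_models(
    records: Iterable[VariantAssociation],
) -> list[VariantAssociation]:
    """Per (variant, phenotype), keep the record with the smallest p.

    Exact p ties are broken by fixed model priority (genotypic/additive
    first), then lexicographically, so the result is order-independent.
    """
    best: dict[tuple[str, str], VariantAssociation] = {}
    for r in records:
        key = (r.variant, r.phenotype)
        cur = best.get(key)
        if cur is None or _dedup_sort_key(r) < _dedup_sort_key(cur):
            best[key] = r
    return list(best.values())


def _dedup_sort_key(r: VariantAssociation):
    return (r.p, MODEL_PRIORITY[r.model], r.gene, r.phenotype_category)


def phewas_gene_category_summary(
    records: Iterable[VariantAssociation],
    fold_protective: bool = False,
) -> list[GenePhenotypeSummary]:
    """Mean association effect per (gene, phenotype category).

    Binary phenotypes average odds ratios on the OR scale; continuous
    phenotypes average absolute effect sizes. The two phenotype types are
    summarised separately and never averaged together. With
    ``fold_protective`` protective odds ratios (< 1) are folded to 1/OR
    before averaging.
    """
    groups: dict[tuple[str, str, str], list[float]] = {}
    for r in records:
        if r.phenotype_type == "binary":
            eff = r.effect
            if fold_protective and eff < 1.0:
                eff = 1.0 / eff
        else:
            eff = abs(r.effect)
        groups.setdefault((r.gene, r.phenotype_category, r.phenotype_type), []).append(eff)
    return [
        GenePhenotypeSummary(g, cat, ptype, sum(vals) / len(vals), len(vals))
        for (g, cat, ptype), vals in sorted(groups.items())
    ]


def load_phewas_table(path: str | Path, sep: str = "\t") -> list[VariantAssociation]:
    """Read an AZPheWAS-style TSV: variant gene phenotype category model p effect type."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = ["variant", "gene", "phenotype", "category", "model", "p", "effect", "type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return [
        VariantAssociation(
            variant=row.variant,
            gene=row.gene,
            phenotype=row.phenotype,
            phenotype_category=row.category,
            model=row.model,
            p=float(row.p),
            effect=float(row.effect),
            phenotype_type=row.type,
        )
        for row in df.itertuples()
    ]


# --------------------------------------------------------------------------
# GWAS catalog side


def gwas_filter_pipeline(
    rows: Iterable[GwasRow],
    alpha: float = 5e-8,
    excluded_categories: frozenset[str] = DEFAULT_EXCLUDED_CATEGORIES,
    keep_impacts: frozenset[str] = frozenset({"high", "moderate"}),
) -> tuple[list[GwasRow], list[int]]:
    """Apply the five-stage filter cascade; returns survivors and stage log.

    Stages, in order: (1) p <= alpha; (2) per (mapped genes, variant,
    trait) keep the minimum-p row across studies; (3) keep rows uniquely
    mapped to a single gene; (4) keep rows with impact in ``keep_impacts``;
    (5) drop rows whose parent category is excluded or absent. The stage
    log records the survivor count after each stage and is non-increasing.
    """
    rows = list(rows)
    log: list[int] = []

    stage1 = [r for r in rows if r.p <= alpha]
    log.append(len(stage1))

    best: dict[tuple[frozenset[str], str, str], GwasRow] = {}
    for r in stage1:
        key = (r.mapped_genes, r.variant, r.mapped_trait)
        cur = best.get(key)
        if cur is None or (r.p, r.study) < (cur.p, cur.study):
            best[key] = r
    stage2 = [r for r in stage1 if best[(r.mapped_genes, r.variant, r.mapped_trait)] is r]
    log.append(len(stage2))

    stage3 = [r for r in stage2 if len(r.mapped_genes) == 1]
    log.append(len(stage3))

    stage4 = [r for r in stage3 if r.impact in keep_impacts]
    log.append(len(stage4))

    stage5 = [
        r for r in stage4
        if r.parent_category is not None and r.parent_category not in excluded_categories
    ]
    log.append(len(stage5))

    return stage5, log


#: Native GWAS Catalog headers -> internal fields.
GWAS_DEFAULT_COLUMN_MAP = {
    "variant": "SNPS",
    "mapped_genes": "MAPPED_GENE",
    "mapped_trait": "MAPPED_TRAIT",
    "p": "P-VALUE",
    "study": "STUDY ACCESSION",
    "impact": "IMPACT",
}


def load_gwas_table(
    path: str | Path,
    trait_parent_map: Mapping[str, str] | None = None,
    column_map: Mapping[str, str] = GWAS_DEFAULT_COLUMN_MAP,
    sep: str = "\t",
) -> list[GwasRow]:
    """Read a GWAS-Catalog-style TSV honouring the native column headers.

    ``MAPPED_GENE`` entries list multiple genes separated by commas, " - ",
    or semicolons (intergenic variants map to flanking genes). The parent
    trait category comes from the trait->parent mapping; traits absent from
    the mapping get ``None``.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in column_map.values() if c not in df.columns and c != "IMPACT"]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    trait_parent_map = trait_parent_map or {}
    rows = []
    for rec in df.to_dict("records"):
        genes = frozenset(
            g.strip().upper()
            for g in str(rec[column_map["mapped_genes"]])
            .replace(" - ", ";").replace(",", ";").split(";")
            if g.strip()
        )
        trait = str(rec[column_map["mapped_trait"]])
        impact_col = column_map.get("impact", "IMPACT")
        impact = rec.get(impact_col)
        impact = str(impact).strip().lower() if impact not in (None, "", float("nan")) else None
        if impact in ("nan", ""):
            impact = None
        rows.append(
            GwasRow(
                variant=str(rec[column_map["variant"]]),
                mapped_genes=genes,
                mapped_trait=trait,
                parent_category=trait_parent_map.get(trait),
                p=float(rec[column_map["p"]]),
                impact=impact,
                study=str(rec[column_map["study"]]),
            )
        )
    return rows


def load_trait_parent_map(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Two-column trait -> parent-category mapping file."""
    df = pd.read_csv(path, sep=sep, dtype=str, header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (trait, parent)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def summaries_to_frame(summaries: Sequence[GenePhenotypeSummary]) -> pd.DataFrame:
    """Gene x phenotype-category mean-effect matrix (binary and continuous
    phenotype types pivot into separate columns)."""
    df = pd.DataFrame(
        [
            {
                "gene": s.gene,
                "category": f"{s.phenotype_category} ({s.phenotype_type})",
                "mean_effect": s.mean_effect,
            }
            for s in summaries
        ]
    )
    if df.empty:
        return pd.DataFrame()
    return df.pivot(index="gene", columns="category", values="mean_effect")
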