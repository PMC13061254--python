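"""Confidence scoring, categorisation, and family classification of E3 candidates.

Scoring follows the census convention: a curator "yes" contributes +5, a
"no" contributes -5, and each distinct line of evidence (an InterPro-style
domain annotation, a BioGRID-style interaction, or a literature motif)
contributes +2. The score sum reflects confidence; categories partition
genes into curator-included (1), evidence-only (2), and neither (3).

Family classification is rule-driven: each family is defined by the domain,
motif, and interaction-partner claims that admit a gene (e.g. an F-box
domain and/or CUL1/SKP1 interactions admit a CRL1 substrate receptor).
Curator-only families (APC/C substrate receptors, atypical E3s, pseudo-E3s)
are entered through family-context votes alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .evidence import ANY_FAMILY, EvidenceLedger

CURATOR_ONLY_FAMILIES = frozenset({"APCC_SR", "atypical", "pseudo"})


@dataclass(frozen=True)
class ScoreWeights:
    """Additive weights for curator verdicts and evidence lines."""

    w_yes: int = 5
    w_no: int = -5
    w_evidence: int = 2

    def __post_init__(self):
        if not (self.w_yes > 0 and self.w_no < 0 and self.w_evidence > 0):
            raise ValueError("require w_yes > 0, w_no < 0, w_evidence > 0")


@dataclass(frozen=True)
class ConfidenceResult:
    gene: str
    score: int
    category: int
    rank: int | None = None

    def __post_init__(self):
        if self.category not in (1, 2, 3):
            raise ValueError("category must be 1, 2 or 3")


@dataclass(frozen=True)
class FamilyRule:
    """Claims admitting a gene into a family.

    A gene matches when any claim in any of the three sets appears among its
    evidence items. Curator-only families carry empty claim sets.
    """

    family: str
    domain_claims: frozenset[str] = frozenset()
    motif_claims: frozenset[str] = frozenset()
    partner_claims: frozenset[str] = frozenset()

    def __post_init__(self):
        if (
            self.family not in CURATOR_ONLY_FAMILIES
            and not (self.domain_claims or self.motif_claims or self.partner_claims)
        ):
            raise ValueError(
                f"family {self.family!r} needs at least one non-empty claim set"
            )

    @property
    def all_claims(self) -> frozenset[str]:
        return self.domain_claims | self.motif_claims | self.partner_claims


@dataclass(frozen=True)
class FamilyAssignment:
    gene: str
    family: str
    tier: str  # "high" iff category 1 in this family context
    support: Mapping[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class SankeyTally:
    """Stage-wise counts for one family's curation flow."""

    family: str
    stage_counts: Mapping[str, int]

    def __post_init__(self):
        sc = self.stage_counts
        if "input" in sc and "high" in sc and "low" in sc:
            if sc["high"] + sc["low"] != sc["input"]:
                raise ValueError("high + low must equal input")


def load_rules(path: str | Path | None = None) -> dict[str, FamilyRule]:
    """Load family rules from YAML; the packaged defaults when path is None."""
    if path is None:
        text = resources.files("e3ome.data").joinpath("family_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not raw:
        raise ValueError("empty rule set")
    rules = {}
    for family, body in raw.items():
        rules[family] = FamilyRule(
            family=family,
            domain_claims=frozenset(body.get("domains") or ()),
            motif_claims=frozenset(body.get("motifs") or ()),
            partner_claims=frozenset(body.get("partners") or ()),
        )
    return rules


def _vote_counts(ledger: EvidenceLedger, gene: str, family_context: str):
    votes = ledger.votes_for(gene, family_context)
    n_yes = sum(v.verdict == "yes" for v in votes)
    n_no = sum(v.verdict == "no" for v in votes)
    return n_yes, n_no


def _relevant_evidence(
    ledger: EvidenceLedger,
    gene: str,
    family_context: str,
    rules: Mapping[str, FamilyRule] | None,
) -> set[tuple[str, str]]:
    """Distinct (source, claim) pairs counting toward a gene's score.

    Under the "any" context (or without rules) every distinct pair counts;
    under a specific family only claims named by that family's rule count.
    """
    items = ledger.evidence_for(gene)
    pairs = {(e.source, e.claim) for e in items}
    if family_context == ANY_FAMILY or rules is None:
        return pairs
    rule = rules.get(family_context)
    if rule is None:
        raise KeyError(f"unknown family {family_context!r}")
    return {p for p in pairs if p[1] in rule.all_claims}


def score_gene(
    gene: str,
    ledger: EvidenceLedger,
    weights: ScoreWeights = ScoreWeights(),
    family_context: str = ANY_FAMILY,
    rules: Mapping[str, FamilyRule] | None = None,
) -> int:
    """Confidence score: w_yes*#yes + w_no*#no + w_evidence*#distinct evidence.

    Inconclusive and unassessed votes contribute nothing. Each distinct
    (source, claim) evidence pair counts once regardless of how many rows
    reported it.
    """
    n_yes, n_no = _vote_counts(ledger, gene, family_context)
    n_evid = len(_relevant_evidence(ledger, gene, family_context, rules))
    return weights.w_yes * n_yes + weights.w_no * n_no + weights.w_evidence * n_evid


def assign_category(
    gene: str,
    ledger: EvidenceLedger,
    family_context: str = ANY_FAMILY,
    rules: Mapping[str, FamilyRule] | None = None,
) -> int:
    """Category 1: >=1 curator yes; 2: no yes but some evidence; 3: neither."""
    n_yes, _ = _vote_counts(ledger, gene, family_context)
    if n_yes >= 1:
        return 1
    if _relevant_evidence(ledger, gene, ANY_FAMILY, None):
        return 2
    return 3


def rank_genes(results: Iterable[ConfidenceResult]) -> list[ConfidenceResult]:
    """Order by score descending; ties by category ascending then symbol."""
    ordered = sorted(results, key=lambda r: (-r.score, r.category, r.gene))
    return [
        ConfidenceResult(r.gene, r.score, r.category, rank=i + 1)
        for i, r in enumerate(ordered)
    ]


def score_ledger(
    ledger: EvidenceLedger,
    weights: ScoreWeights = ScoreWeights(),
) -> list[ConfidenceResult]:
    """Score, categorise and rank every gene in a ledger (context "any")."""
    results = [
        ConfidenceResult(
            g, score_gene(g, ledger, weights), assign_category(g, ledger)
        )
        for g in ledger.genes
    ]
    return rank_genes(results)


def classify_family(
    gene: str,
    ledger: EvidenceLedger,
    rules: Mapping[str, FamilyRule],
) -> list[FamilyAssignment]:
    """All family assignments a gene's evidence and votes support.

    A gene enters a family when any rule claim matches its evidence, or when
    it carries a yes/no curator vote in that family's context. A gene may
    hold several assignments (e.g. a dual F-box + helix-loop-helix receptor
    enters both CRL1_SR and CRL4_SR). Tier is "high" iff the gene is
    category 1 within the family context.
    """
    if not rules:
        raise ValueError("empty rule set")
    sym = ledger.resolve(gene)
    if sym is None:
        raise LookupError(f"unknown gene {gene!r}")
    claims_present = {e.claim for e in ledger.evidence_for(sym)}
    voted_families = {
        v.family_context
        for v in ledger.votes
        if v.gene == sym and v.verdict in ("yes", "no") and v.family_context != ANY_FAMILY
    }
    out = []
    for family, rule in sorted(rules.items()):
        matched = bool(rule.all_claims & claims_present)
        if not matched and family not in voted_families:
            continue
        support = {c: (c in claims_present) for c in sorted(rule.all_claims)}
        category = assign_category(sym, ledger, family_context=family)
        tier = "high" if category == 1 else "low"
        out.append(FamilyAssignment(sym, family, tier, support))
    return out


def enumerate_families(
    ledger: EvidenceLedger,
    rules: Mapping[str, FamilyRule],
) -> list[SankeyTally]:
    """Per-family stage tallies: input, per-claim evidence counts, high/low.

    Mirrors the curation flow of a Sankey diagram: candidates enter a family,
    each evidence claim is counted over them, and the high/low confidence
    split conserves the input count.
    """
    assignments: dict[str, list[FamilyAssignment]] = {}
    for gene in ledger.genes:
        for a in classify_family(gene, ledger, rules):
            assignments.setdefault(a.family, []).append(a)
    tallies = []
    for family in sorted(assignments):
        fam_assign = assignments[family]
        stage: dict[str, int] = {"input": len(fam_assign)}
        for claim in sorted(rules[family].all_claims):
            stage[claim] = sum(a.support.get(claim, False) for a in fam_assign)
        stage["high"] = sum(a.tier == "high" for a in fam_assign)
        stage["low"] = sum(a.tier == "low" for a in fam_assign)
        tallies.append(SankeyTally(family, stage))
    return tallies


def pairwise_overlap(gene_lists: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Row-normalised percentage overlap between named gene lists.

    cell(i, j) = 100 * |Li ∩ Lj| / |Li|; the diagonal is 100 and the matrix
    is asymmetric between lists of different sizes.
    """
    names = list(gene_lists)
    if len(names) < 2:
        raise ValueError("need at least two lists")
    sets = {n: set(gene_lists[n]) for n in names}
    for n, s in sets.items():
        if not s:
            raise ValueError(f"list {n!r} is empty")
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for i in names:
        for j in names:
            mat.loc[i, j] = 100.0 * len(sets[i] & sets[j]) / len(sets[i])
    return mat


def intersect_panel(
    panel: Iterable[str],
    external: Iterable[str],
    ledger: EvidenceLedger | None = None,
) -> set[str]:
    """Set intersection after optional alias resolution through a ledger."""
    def _resolve(tokens):
        out = set()
        for t in tokens:
            sym = ledger.resolve(t) if ledger is not None else None
            out.add(sym if sym is not None else str(t).strip().upper())
        return out

    return _resolve(panel) & _resolve(external)


def categories_from_workbook(table: pd.DataFrame) -> pd.Series:
    """Category counts from a compendium-style per-gene table.

    Deduplicates genes (a gene listed in several family sheets keeps its
    best, i.e. lowest, category) then counts genes per category.
    """
    best = table.groupby("symbol")["category"].min()
    return best.value_counts().sort_index()


def family_counts_from_workbook(
    table: pd.DataFrame, category: int = 1
) -> pd.Series:
    """Per-family gene counts at a given category from a compendium table."""
    sub = table[table["category"] == category]
    return sub.groupby("family")["symbol"].nunique().sort_index()
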