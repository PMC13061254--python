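"""Synthetic inputs with controllable ground truth for every pipeline stage.

Each generator is a pure function of its configuration (seed included);
sub-streams are derived per output kind so adding a generator does not shift
existing streams. Generators return in-memory objects plus a truth table
sufficient to compute recovery metrics, and writers emit the same file
formats the loaders read.

The statistical structure mirrors the real inputs: curator votes with a
configurable accuracy against the true family assignment, per-family
evidence claims emitted with a per-source sensitivity, variant associations
mixing uniform null p-values with strong signal keys, ontology annotations
with planted family-term enrichment over a protein-coding-sized universe,
and negative-binomial count matrices (variance mean + dispersion * mean^2)
with fold-change markers planted per cell class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import FamilyRule, load_rules
from .enrichment import OntologyTerm
from .evidence import ANY_FAMILY, CuratorVote, EvidenceItem, EvidenceLedger, GeneRecord
from .expression import CountMatrix, SampleMetadata

# Stream constants: each generator draws from default_rng([seed, STREAM_X]).
STREAM_EVIDENCE = 1
STREAM_PHEWAS = 2
STREAM_HPO = 3
STREAM_SC = 4
STREAM_TISSUE = 5

#: Source assigned to each kind of rule claim.
_CLAIM_SOURCE = {
    "domain": "interpro_domain",
    "motif": "literature_annotation",
    "partner": "biogrid_interaction",
}

PHENOTYPE_CATEGORIES = (
    "Cardiovascular", "Endocrine", "Gastrointestinal", "Haematology",
    "Musculoskeletal", "Neurology", "Renal", "Respiratory",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for all synthetic inputs."""

    seed: int = 0
    # evidence / curation
    n_genes: int = 120
    families: Mapping[str, int] = field(
        default_factory=lambda: {
            "RING": 30, "HECT": 10, "RBR": 6,
            "CRL1_SR": 12, "CRL3_SR": 14, "CRL5_SR": 8,
        }
    )
    curator_accuracy: float = 0.9
    evidence_sensitivity: float = 0.8
    # phewas
    n_variants_per_gene: int = 5
    signal_fraction: float = 0.1
    or_lognormal_params: tuple[float, float] = (0.3, 0.3)
    beta_sd: float = 0.4
    # hpo
    n_terms: int = 100
    hpo_universe_size: int = 19294
    background_annotation_prob: float = 0.02
    planted_annotation_prob: float = 0.5
    planted_family_term_pairs: tuple[tuple[str, str], ...] = ()
    hpo_family_size: int = 28
    ontology_depth: int = 5
    ontology_fan_in: int = 3
    # single-cell
    sc_n_genes: int = 500
    nb_mean: float = 2.0
    nb_dispersion: float = 0.5
    n_classes: int = 3
    cells_per_class: int = 100
    markers_per_class: int = 10
    marker_fold: float = 8.0
    # bulk metadata
    n_tissues: int = 31
    donors_per_tissue: int = 12
    max_samples_per_donor: int = 3

    def __post_init__(self):
        for p in (self.curator_accuracy, self.evidence_sensitivity,
                  self.signal_fraction, self.background_annotation_prob,
                  self.planted_annotation_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        for c in (self.n_genes, self.n_terms, self.sc_n_genes, self.n_classes,
                  self.cells_per_class, self.n_tissues, self.donors_per_tissue):
            if c <= 0:
                raise ValueError("counts must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# --------------------------------------------------------------------------
# Evidence / curation


def gen_evidence(
    config: GeneratorConfig,
    rules: Mapping[str, FamilyRule] | None = None,
) -> tuple[EvidenceLedger, dict]:
    """Synthetic evidence ledger with known family and category truth.

    Genes are assigned true families per ``config.families`` (the remainder
    are non-E3 background). For each true gene, each claim of its family's
    rule is emitted with probability ``evidence_sensitivity``. One curator
    votes per gene: true genes receive "yes" in their family context with
    probability ``curator_accuracy`` (else "no"); background genes receive
    "no" with that probability (else "yes").
    """
    rules = rules or load_rules()
    for fam in config.families:
        if fam not in rules:
            raise ValueError(f"family {fam!r} not in rule vocabulary")
    n_family = sum(config.families.values())
    if n_family > config.n_genes:
        raise ValueError("family counts exceed n_genes")

    rng = config.rng(STREAM_EVIDENCE)
    symbols = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    true_family: dict[str, str | None] = {}
    i = 0
    for fam in sorted(config.families):
        for _ in range(config.families[fam]):
            true_family[symbols[i]] = fam
            i += 1
    for sym in symbols[i:]:
        true_family[sym] = None

    genes = [GeneRecord(s, frozenset({f"ALIAS-{s}"})) for s in symbols]
    votes, items = [], []
    truth_rows = {}
    for sym in symbols:
        fam = true_family[sym]
        if fam is not None:
            rule = rules[fam]
            claim_kinds = (
                [("domain", c) for c in sorted(rule.domain_claims)]
                + [("motif", c) for c in sorted(rule.motif_claims)]
                + [("partner", c) for c in sorted(rule.partner_claims)]
            )
            n_evid = 0
            for kind, claim in claim_kinds:
                if rng.random() < config.evidence_sensitivity:
                    items.append(EvidenceItem(sym, _CLAIM_SOURCE[kind], claim))
                    n_evid += 1
            verdict = "yes" if rng.random() < config.curator_accuracy else "no"
            votes.append(CuratorVote(sym, "curator1", fam, verdict))
            category = 1 if verdict == "yes" else (2 if n_evid else 3)
        else:
            verdict = "no" if rng.random() < config.curator_accuracy else "yes"
            votes.append(CuratorVote(sym, "curator1", ANY_FAMILY, verdict))
            category = 1 if verdict == "yes" else 3
        truth_rows[sym] = {"family": fam, "category": category}

    truth = {"seed": config.seed, "genes": truth_rows}
    return EvidenceLedger(genes, votes, items), truth


# --------------------------------------------------------------------------
# PheWAS


def gen_phewas(config: GeneratorConfig) -> tuple[list, dict]:
    """Variant associations mixing null and signal keys across four models.

    Each gene gets ``n_variants_per_gene`` variants, each paired with one
    phenotype and reported under all four genetic models. A
    ``signal_fraction`` of (variant, phenotype) keys draws
    p = 10**(-Uniform(8, 15)) per model; the rest draw p ~ Uniform(0, 1).
    Binary effects are log-normal odds ratios; continuous effects normal
    betas.
    """
    from .associations import MODELS, VariantAssociation

    rng = config.rng(STREAM_PHEWAS)
    mu, sigma = config.or_lognormal_params
    records = []
    signal_keys = []
    symbols = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    v = 0
    for gene in symbols:
        for _ in range(config.n_variants_per_gene):
            v += 1
            variant = f"rs{v:07d}"
            cat = PHENOTYPE_CATEGORIES[rng.integers(len(PHENOTYPE_CATEGORIES))]
            ptype = "binary" if rng.random() < 0.5 else "continuous"
            phenotype = f"{cat} trait {v}"
            is_signal = rng.random() < config.signal_fraction
            if is_signal:
                signal_keys.append([variant, phenotype])
            for model in MODELS:
                if is_signal:
                    p = float(10.0 ** -rng.uniform(8.0, 15.0))
                else:
                    p = float(rng.uniform(np.nextafter(0, 1), 1.0))
                if ptype == "binary":
                    effect = float(rng.lognormal(mu, sigma))
                else:
                    effect = float(rng.normal(0.0, config.beta_sd))
                records.append(
                    VariantAssociation(variant, gene, phenotype, cat, model,
                                       p, effect, ptype)
                )
    truth = {"seed": config.seed, "signal_keys": signal_keys}
    return records, truth


# --------------------------------------------------------------------------
# HPO


def gen_hpo(
    config: GeneratorConfig,
) -> tuple[dict[str, OntologyTerm], dict[str, set[str]], dict[str, set[str]], dict]:
    """Random DAG ontology, gene-term annotations, and family gene sets.

    Depth is bounded by ``ontology_depth`` and each non-root term picks up to
    ``ontology_fan_in`` parents from the previous level. Every term annotates
    universe genes with ``background_annotation_prob``; planted
    (family, term) pairs annotate that family's genes at
    ``planted_annotation_prob`` instead.
    """
    rng = config.rng(STREAM_HPO)
    universe = [f"U{i:05d}" for i in range(1, config.hpo_universe_size + 1)]
    term_ids = [f"T:{i:04d}" for i in range(1, config.n_terms + 1)]

    levels = rng.integers(0, config.ontology_depth, size=config.n_terms)
    levels[0] = 0  # guarantee a root level exists
    terms: dict[str, OntologyTerm] = {}
    by_level: dict[int, list[str]] = {}
    for tid, lv in zip(term_ids, levels):
        by_level.setdefault(int(lv), []).append(tid)
    for tid, lv in zip(term_ids, levels):
        lv = int(lv)
        parents: frozenset[str] = frozenset()
        upper = [t for l in range(lv) for t in by_level.get(l, [])]
        if lv > 0 and upper:
            k = int(rng.integers(1, config.ontology_fan_in + 1))
            k = min(k, len(upper))
            idx = rng.choice(len(upper), size=k, replace=False)
            parents = frozenset(upper[j] for j in idx)
        terms[tid] = OntologyTerm(tid, f"synthetic term {tid}", parents)

    # family gene sets drawn from the universe, disjoint across families
    fam_names = sorted(config.families) or ["familyA"]
    n_fam_genes = config.hpo_family_size * len(fam_names)
    fam_idx = rng.choice(len(universe), size=n_fam_genes, replace=False)
    family_genes: dict[str, set[str]] = {}
    for j, fam in enumerate(fam_names):
        sel = fam_idx[j * config.hpo_family_size:(j + 1) * config.hpo_family_size]
        family_genes[fam] = {universe[i] for i in sel}

    planted = {(f, t) for f, t in config.planted_family_term_pairs}
    direct: dict[str, set[str]] = {}
    for tid in term_ids:
        n_bg = rng.binomial(len(universe), config.background_annotation_prob)
        idx = rng.choice(len(universe), size=n_bg, replace=False)
        genes = {universe[i] for i in idx}
        for fam in fam_names:
            if (fam, tid) in planted:
                mask = rng.random(config.hpo_family_size) < config.planted_annotation_prob
                genes |= {g for g, m in zip(sorted(family_genes[fam]), mask) if m}
        direct[tid] = genes

    truth = {
        "seed": config.seed,
        "planted_pairs": sorted(planted),
        "universe_size": len(universe),
    }
    return terms, direct, family_genes, truth


# --------------------------------------------------------------------------
# Single-cell counts


def gen_sc_counts(config: GeneratorConfig) -> tuple[CountMatrix, dict[str, str], dict]:
    """Negative-binomial count matrix with per-class planted markers.

    Per-gene base means are drawn log-normally around ``nb_mean``; counts are
    NB with variance mean + dispersion * mean^2. The first
    ``markers_per_class`` genes of each class's block have their in-class
    mean multiplied by ``marker_fold``.
    """
    rng = config.rng(STREAM_SC)
    g, k, cpk = config.sc_n_genes, config.n_classes, config.cells_per_class
    genes = [f"G{i:04d}" for i in range(1, g + 1)]
    cells = [f"cell{i:05d}" for i in range(1, k * cpk + 1)]
    labels = {c: f"class{j + 1}" for j, block in enumerate(
        (cells[i * cpk:(i + 1) * cpk] for i in range(k))) for c in block}

    base_mean = config.nb_mean * rng.lognormal(0.0, 0.5, size=g)
    mean_matrix = np.tile(base_mean[:, None], (1, k * cpk))
    marker_truth: dict[str, list[str]] = {}
    for j in range(k):
        marker_rows = range(j * config.markers_per_class,
                            (j + 1) * config.markers_per_class)
        marker_truth[f"class{j + 1}"] = [genes[r] for r in marker_rows]
        cols = slice(j * cpk, (j + 1) * cpk)
        for r in marker_rows:
            mean_matrix[r, cols] *= config.marker_fold

    r_param = 1.0 / config.nb_dispersion
    p_param = r_param / (r_param + mean_matrix)
    values = rng.negative_binomial(r_param, p_param).astype(float)
    matrix = CountMatrix(genes, cells, values, layer="raw")
    truth = {"seed": config.seed, "markers": marker_truth,
             "marker_fold": config.marker_fold}
    if config.marker_fold == 1.0:
        truth["markers"] = {c: [] for c in truth["markers"]}
    return matrix, labels, truth


# --------------------------------------------------------------------------
# Bulk tissue metadata


def gen_tissue_metadata(config: GeneratorConfig) -> list[SampleMetadata]:
    """Tissue/donor/sample metadata with donors unique across tissues and
    1 to ``max_samples_per_donor`` samples per donor."""
    rng = config.rng(STREAM_TISSUE)
    out = []
    d = 0
    for t in range(1, config.n_tissues + 1):
        tissue = f"tissue{t:02d}"
        for _ in range(config.donors_per_tissue):
            d += 1
            donor = f"D{d:04d}"
            n_samples = int(rng.integers(1, config.max_samples_per_donor + 1))
            for s in range(1, n_samples + 1):
                out.append(SampleMetadata(f"{donor}-S{s}", donor, tissue))
    return out


# --------------------------------------------------------------------------
# Writers (same formats the loaders read)


def write_evidence(ledger: EvidenceLedger, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_path = outdir / "genes.tsv"
    pd.DataFrame(
        [
            {
                "symbol": g.symbol,
                "aliases": "|".join(sorted(g.aliases)),
                "protein_coding": int(g.is_protein_coding),
            }
            for g in ledger.genes.values()
        ]
    ).to_csv(gene_path, sep="\t", index=False)
    vote_path = outdir / "votes.tsv"
    pd.DataFrame(
        [
            {"symbol": v.gene, "curator": v.curator, "family": v.family_context,
             "verdict": v.verdict}
            for v in ledger.votes
        ],
        columns=["symbol", "curator", "family", "verdict"],
    ).to_csv(vote_path, sep="\t", index=False)
    evid_path = outdir / "evidence.tsv"
    pd.DataFrame(
        [
            {"symbol": e.gene, "source": e.source, "claim": e.claim,
             "reference": e.reference or ""}
            for e in ledger.evidence
        ],
        columns=["symbol", "source", "claim", "reference"],
    ).to_csv(evid_path, sep="\t", index=False)
    return {"genes": gene_path, "votes": vote_path, "evidence": evid_path}


def write_phewas(records: Sequence, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {"variant": r.variant, "gene": r.gene, "phenotype": r.phenotype,
             "category": r.phenotype_category, "model": r.model,
             "p": repr(r.p), "effect": repr(r.effect), "type": r.phenotype_type}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
    return path


def write_obo(terms: Mapping[str, OntologyTerm], path: str | Path) -> Path:
    path = Path(path)
    lines = ["format-version: 1.2", ""]
    for tid in sorted(terms):
        t = terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {t.id}")
        lines.append(f"name: {t.name}")
        for p in sorted(t.parents):
            lines.append(f"is_a: {p}")
        lines.append("")
    path.write_text("\n".join(lines))
    return path


def write_annotations(direct: Mapping[str, set], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"gene": g, "term": t}
        for t in sorted(direct)
        for g in sorted(direct[t])
    ]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)
    return path


def write_counts(
    matrix: CountMatrix, labels: Mapping[str, str], outdir: str | Path
) -> dict[str, Path]:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mtx = outdir / "counts.mtx"
    mmwrite(mtx, csr_matrix(matrix.values))
    genes = outdir / "genes.txt"
    genes.write_text("\n".join(matrix.genes) + "\n")
    cells = outdir / "cells.txt"
    cells.write_text("\n".join(matrix.columns) + "\n")
    ann = outdir / "annotations.csv"
    pd.DataFrame(
        [{"cell": c, "broad_cell_class": labels[c]} for c in matrix.columns]
    ).to_csv(ann, index=False)
    return {"mtx": mtx, "genes": genes, "cells": cells, "annotations": ann}


def write_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"sample": m.sample, "donor": m.donor, "tissue": m.tissue}
         for m in metadata]
    ).to_csv(path, sep="\t", index=False)
    return path


def write_truth(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return path


def config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["families"] = dict(config.families)
    return d
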