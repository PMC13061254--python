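"""Evidence ledger: genes, curator votes, and typed evidence items.

The ledger is the substrate of confidence scoring and family classification.
Genes carry an HGNC-style symbol plus aliases; curator votes are one of four
verdicts recorded per (gene, curator, family context); evidence items are
claims of domain presence (InterPro-style), protein-protein interaction
(BioGRID-style), or literature-annotated motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VERDICTS = frozenset({"yes", "no", "inconclusive", "unassessed"})
EVIDENCE_SOURCES = frozenset(
    {"interpro_domain", "biogrid_interaction", "literature_annotation"}
)

ANY_FAMILY = "any"


class SchemaError(ValueError):
    """An input table is missing a required column."""


class AmbiguousSymbolError(LookupError):
    """A token matches more than one gene record."""

    def __init__(self, token: str, candidates: Sequence[str]):
        self.token = token
        self.candidates = sorted(candidates)
        super().__init__(
            f"token {token!r} is ambiguous: matches {', '.join(self.candidates)}"
        )


def canonicalize(token: str) -> str:
    """Uppercase and strip a symbol token (HGNC convention)."""
    return str(token).strip().upper()


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    aliases: frozenset[str] = frozenset()
    is_protein_coding: bool = True

    def __post_init__(self):
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.symbol in self.aliases:
            raise ValueError(
                f"symbol {self.symbol!r} must not appear in its own alias set"
            )


@dataclass(frozen=True)
class CuratorVote:
    gene: str
    curator: str
    family_context: str = ANY_FAMILY
    verdict: str = "unassessed"

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValueError(
                f"verdict {self.verdict!r} not in {sorted(VERDICTS)}"
            )


@dataclass(frozen=True)
class EvidenceItem:
    gene: str
    source: str
    claim: str
    reference: str | None = None

    def __post_init__(self):
        if self.source not in EVIDENCE_SOURCES:
            raise ValueError(
                f"source {self.source!r} not in {sorted(EVIDENCE_SOURCES)}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.gene, self.source, self.claim)


@dataclass
class RejectedRows:
    """Rows that could not be resolved against the gene table."""

    rows: list[dict] = field(default_factory=list)

    def add(self, table: str, row_number: int, reason: str, **extra):
        self.rows.append(
            {"table": table, "row": row_number, "reason": reason, **extra}
        )

    def __len__(self) -> int:
        return len(self.rows)


class EvidenceLedger:
    """Validated collection of genes, votes and evidence items.

    Equality is order-insensitive: two ledgers loaded from permuted input
    files compare equal.
    """

    def __init__(
        self,
        genes: Iterable[GeneRecord],
        votes: Iterable[CuratorVote] = (),
        evidence: Iterable[EvidenceItem] = (),
    ):
        self.genes: dict[str, GeneRecord] = {}
        # alias -> set of owning symbols; collisions surface as ambiguity
        # errors at resolve time, not at construction
        self._alias_index: dict[str, set[str]] = {}
        for g in genes:
            if g.symbol in self.genes:
                raise ValueError(f"duplicate gene symbol {g.symbol!r}")
            self.genes[g.symbol] = g
        for g in self.genes.values():
            for a in g.aliases:
                self._alias_index.setdefault(a, set()).add(g.symbol)

        self.votes: list[CuratorVote] = []
        seen_votes: set[tuple[str, str, str]] = set()
        for v in votes:
            gene = self._require(v.gene)
            v = CuratorVote(gene, v.curator, v.family_context, v.verdict)
            key = (v.gene, v.curator, v.family_context)
            if key in seen_votes:
                raise ValueError(f"duplicate vote for {key}")
            seen_votes.add(key)
            self.votes.append(v)

        self.evidence: list[EvidenceItem] = []
        self.n_duplicate_evidence = 0
        seen_items: set[tuple[str, str, str]] = set()
        for item in evidence:
            gene = self._require(item.gene)
            item = EvidenceItem(gene, item.source, item.claim, item.reference)
            if item.key in seen_items:
                self.n_duplicate_evidence += 1
                continue
            seen_items.add(item.key)
            self.evidence.append(item)
        if self.n_duplicate_evidence:
            logger.warning(
                "collapsed %d duplicate evidence row(s)", self.n_duplicate_evidence
            )

    def _require(self, token: str) -> str:
        sym = self.resolve(token)
        if sym is None:
            raise LookupError(f"unknown gene symbol {token!r}")
        return sym

    def resolve(self, token: str) -> str | None:
        """Resolve a token to a canonical symbol, or None.

        Matching is case-insensitive against symbols and aliases. A token
        matching two distinct genes raises :class:`AmbiguousSymbolError`.
        """
        tok = canonicalize(token)
        hits = set()
        if tok in self.genes:
            hits.add(tok)
        hits |= self._alias_index.get(tok, set())
        if len(hits) > 1:
            raise AmbiguousSymbolError(token, sorted(hits))
        return next(iter(hits)) if hits else None

    # -- per-gene views used by the scoring engine ---------------------------

    def votes_for(self, gene: str, family_context: str = ANY_FAMILY) -> list[CuratorVote]:
        """Votes applying to a gene in a family context.

        A vote recorded under "any" applies in every context; a vote recorded
        under a specific family applies only there (and under "any").
        """
        sym = self._require(gene)
        out = []
        for v in self.votes:
            if v.gene != sym:
                continue
            if (
                family_context == ANY_FAMILY
                or v.family_context == ANY_FAMILY
                or v.family_context == family_context
            ):
                out.append(v)
        return out

    def evidence_for(self, gene: str) -> list[EvidenceItem]:
        sym = self._require(gene)
        return [e for e in self.evidence if e.gene == sym]

    def __eq__(self, other) -> bool:
        if not isinstance(other, EvidenceLedger):
            return NotImplemented
        return (
            self.genes == other.genes
            and set(self.votes) == set(other.votes)
            and set(self.evidence) == set(other.evidence)
        )

    def __repr__(self) -> str:
        return (
            f"EvidenceLedger({len(self.genes)} genes, {len(self.votes)} votes, "
            f"{len(self.evidence)} evidence items)"
        )


# --------------------------------------------------------------------------
# Tabular ingestion


def _read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def load_ledger(
    gene_table: str | Path,
    vote_table: str | Path | None = None,
    evidence_tables: Iterable[str | Path] = (),
    sep: str = "\t",
) -> tuple[EvidenceLedger, RejectedRows]:
    """Load an evidence ledger from tabular files.

    gene_table columns: ``symbol``, ``aliases`` (pipe-delimited, may be
    empty), ``protein_coding`` (0/1). vote_table columns: ``symbol``,
    ``curator``, ``family``, ``verdict``. evidence tables: ``symbol``,
    ``source``, ``claim``, ``reference``.

    Unresolvable symbols in votes/evidence are collected into the returned
    :class:`RejectedRows` report rather than raising. Duplicate
    (gene, source, claim) rows are collapsed with a logged count.
    """
    rejected = RejectedRows()

    gdf = _read_table(gene_table, sep)
    _check_columns(gdf, ["symbol", "aliases", "protein_coding"], gene_table)
    genes = []
    for _, row in gdf.iterrows():
        sym = canonicalize(row["symbol"])
        aliases = frozenset(
            canonicalize(a) for a in str(row["aliases"]).split("|") if a.strip()
        ) - {sym}
        genes.append(
            GeneRecord(sym, aliases, str(row["protein_coding"]).strip() in ("1", "true", "True"))
        )
    skeleton = EvidenceLedger(genes)

    votes = []
    if vote_table is not None:
        vdf = _read_table(vote_table, sep)
        _check_columns(vdf, ["symbol", "curator", "verdict"], vote_table)
        for i, row in vdf.iterrows():
            verdict = str(row["verdict"]).strip().lower()
            if verdict not in VERDICTS:
                raise ValueError(
                    f"{vote_table} row {i + 2}: verdict {verdict!r} not in "
                    f"{sorted(VERDICTS)}"
                )
            sym = skeleton.resolve(row["symbol"])
            if sym is None:
                rejected.add(str(vote_table), i + 2, "unresolvable symbol",
                             symbol=str(row["symbol"]))
                continue
            family = str(row.get("family", ANY_FAMILY)).strip() or ANY_FAMILY
            votes.append(CuratorVote(sym, str(row["curator"]).strip(), family, verdict))

    items = []
    for path in evidence_tables:
        edf = _read_table(path, sep)
        _check_columns(edf, ["symbol", "source", "claim"], path)
        for i, row in edf.iterrows():
            sym = skeleton.resolve(row["symbol"])
            if sym is None:
                rejected.add(str(path), i + 2, "unresolvable symbol",
                             symbol=str(row["symbol"]))
                continue
            ref = str(row["reference"]).strip() if "reference" in edf.columns else ""
            items.append(
                EvidenceItem(sym, str(row["source"]).strip(),
                             str(row["claim"]).strip(), ref or None)
            )

    ledger = EvidenceLedger(skeleton.genes.values(), votes, items)
    if len(rejected):
        logger.warning("rejected %d unresolvable row(s)", len(rejected))
    return ledger, rejected


def resolve_symbol(token: str, ledger: EvidenceLedger) -> str | None:
    """Functional alias for :meth:`EvidenceLedger.resolve`."""
    return ledger.resolve(token)


# --------------------------------------------------------------------------
# Deposited-workbook ingestion

#: Candidate header names for the workbook reader, lowercased. The deposited
#: compendium layout is one sheet per family with per-source evidence flags;
#: headers vary across sheets, so matching is tolerant.
_WORKBOOK_COLUMN_SYNONYMS: Mapping[str, tuple[str, ...]] = {
    "symbol": ("symbol", "gene", "gene symbol", "gene_symbol", "hgnc symbol"),
    "category": ("category", "cat", "confidence category"),
    "score": ("score", "confidence score", "sum"),
}


def read_workbook(
    path: str | Path,
    sheet_families: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a curated-compendium workbook into a long per-gene table.

    One sheet per family; each sheet must expose a gene-symbol column and a
    category column (matched case-insensitively against known synonyms);
    any further columns are carried through as evidence flags. Returns a
    DataFrame with columns ``symbol``, ``family``, ``category`` plus the
    per-sheet extras.

    sheet_families optionally maps sheet names to family labels; by default
    each sheet name is used as the family label verbatim.
    """
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    frames = []
    for sheet in wb.sheetnames:
        ws = wb[sheet]
        rows = list(ws.iter_rows(values_only=True))
        if not rows:
            continue
        header = [str(h).strip() if h is not None else "" for h in rows[0]]
        lower = [h.lower() for h in header]
        colmap = {}
        for canon, synonyms in _WORKBOOK_COLUMN_SYNONYMS.items():
            for syn in synonyms:
                if syn in lower:
                    colmap[canon] = lower.index(syn)
                    break
        if "symbol" not in colmap or "category" not in colmap:
            logger.warning("sheet %r lacks symbol/category columns; skipped", sheet)
            continue
        family = (sheet_families or {}).get(sheet, sheet)
        extra_idx = [
            i for i, h in enumerate(header)
            if h and i not in colmap.values()
        ]
        for r in rows[1:]:
            if r is None or colmap["symbol"] >= len(r) or r[colmap["symbol"]] in (None, ""):
                continue
            rec = {
                "symbol": canonicalize(str(r[colmap["symbol"]])),
                "family": family,
                "category": int(r[colmap["category"]]),
            }
            for i in extra_idx:
                rec[header[i]] = r[i] if i < len(r) else None
            frames.append(rec)
    if not frames:
        raise SchemaError(f"{path}: no readable sheets with symbol/category columns")
    return pd.DataFrame(frames)
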