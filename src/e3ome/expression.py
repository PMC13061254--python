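"""Expression-side procedures: donor sampling, count scaling, normalisation,
one-vs-rest Wilcoxon marker detection, DE thresholding, and row Z-scores.

Bulk counts pass through a reproducible donor-sampling step (one sample per
donor, a fixed number of donors per tissue, donors exclusive to one tissue),
area-under-coverage scaling to a common library size, and restriction to a
predefined gene panel. Single-cell counts are normalised per cell to counts
per 10,000 (CP10K) with library-size clipping, optionally log1p-transformed,
and tested per cell class against the pooled rest with a Wilcoxon rank-sum
test, BH-adjusted within each class.

Matrices carry a layer tag (raw, auc_scaled, cp10k, log1p); each operation
refuses matrices tagged with the wrong layer so pipelines cannot silently
double-normalise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

LAYERS = ("raw", "auc_scaled", "cp10k", "log1p")

LOG2FC_EPS = 1e-9


class CapacityError(ValueError):
    """A tissue or class lacks the members a procedure requires."""


class LayerError(ValueError):
    """A matrix arrived with the wrong normalisation layer."""


@dataclass(frozen=True)
class SampleMetadata:
    sample: str
    donor: str
    tissue: str


@dataclass(frozen=True)
class MarkerResult:
    gene: str
    group: str
    statistic: float
    log2fc: float
    p: float
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class DECall:
    gene: str
    tissue: str
    log2fc: float
    fdr: float
    significant: bool


@dataclass
class CountMatrix:
    """Gene x sample/cell expression matrix with a normalisation-layer tag."""

    genes: list[str]
    columns: list[str]
    values: np.ndarray
    layer: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.columns)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.columns)} columns"
            )
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise ValueError("negative entries not allowed")

    def require_layer(self, *allowed: str) -> None:
        if self.layer not in allowed:
            raise LayerError(
                f"operation requires layer in {allowed}, got {self.layer!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.columns)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, layer: str = "raw") -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), layer)

    @classmethod
    def from_mtx(
        cls,
        mtx_path: str | Path,
        genes_path: str | Path,
        columns_path: str | Path,
        layer: str = "raw",
    ) -> "CountMatrix":
        from scipy.io import mmread

        values = np.asarray(mmread(mtx_path).todense(), dtype=float)
        genes = Path(genes_path).read_text().split()
        columns = Path(columns_path).read_text().split()
        return cls(genes, columns, values, layer)


# --------------------------------------------------------------------------
# Bulk side


def sample_donors(
    metadata: Iterable[SampleMetadata],
    per_tissue: int = 9,
    seed: int = 42,
) -> list[SampleMetadata]:
    """Retain one sample per donor and exactly ``per_tissue`` donors per tissue.

    Donors appearing in several tissues are assigned to their
    lexicographically first tissue (enforcing donor exclusivity); the
    retained sample for a donor is the lexicographically first of that
    donor's samples in the assigned tissue. Tissues are processed in sorted
    order and donor lists sorted before random selection, so the output is
    bit-identical for a fixed seed.
    """
    metadata = list(metadata)
    donor_tissues: dict[str, set[str]] = {}
    for m in metadata:
        donor_tissues.setdefault(m.donor, set()).add(m.tissue)
    donor_home = {d: min(ts) for d, ts in donor_tissues.items()}

    tissue_donors: dict[str, set[str]] = {}
    donor_sample: dict[str, str] = {}
    for m in sorted(metadata, key=lambda m: (m.tissue, m.donor, m.sample)):
        if donor_home[m.donor] != m.tissue:
            continue
        tissue_donors.setdefault(m.tissue, set()).add(m.donor)
        donor_sample.setdefault(m.donor, m.sample)

    rng = np.random.default_rng(seed)
    retained: list[SampleMetadata] = []
    for tissue in sorted(tissue_donors):
        eligible = sorted(tissue_donors[tissue])
        if len(eligible) < per_tissue:
            raise CapacityError(
                f"tissue {tissue!r} has {len(eligible)} eligible donors; "
                f"{per_tissue} required"
            )
        chosen = rng.choice(len(eligible), size=per_tissue, replace=False)
        for i in sorted(chosen):
            donor = eligible[i]
            retained.append(SampleMetadata(donor_sample[donor], donor, tissue))
    return retained


def auc_scale(
    matrix: CountMatrix,
    auc_per_sample: Mapping[str, float],
    target: float = 4e7,
) -> CountMatrix:
    """Scale each column by target / AUC, placing samples on a common
    library size. Values are not rounded."""
    matrix.require_layer("raw")
    factors = np.empty(len(matrix.columns))
    for j, col in enumerate(matrix.columns):
        auc = auc_per_sample[col]
        if auc <= 0:
            raise ValueError(f"AUC for {col!r} must be positive, got {auc}")
        factors[j] = target / auc
    return replace(matrix, values=matrix.values * factors, layer="auc_scaled")


def restrict_panel(
    matrix: CountMatrix, panel: Sequence[str]
) -> tuple[CountMatrix, list[str]]:
    """Row subset in panel order; panel genes absent from the matrix are
    reported, never invented."""
    index = {g: i for i, g in enumerate(matrix.genes)}
    present = [g for g in panel if g in index]
    missing = [g for g in panel if g not in index]
    if not present:
        raise ValueError("panel and matrix genes are disjoint")
    sub = matrix.values[[index[g] for g in present], :]
    return replace(matrix, genes=list(present), values=sub), missing


# --------------------------------------------------------------------------
# Single-cell side


def cp10k_normalize(matrix: CountMatrix, clip_min: float = 1e-12) -> CountMatrix:
    """Per-cell counts-per-10,000: non-finite entries zeroed, library sizes
    clipped to ``clip_min`` so all-zero cells normalise to all-zero columns."""
    matrix.require_layer("raw")
    values = np.where(np.isfinite(matrix.values), matrix.values, 0.0)
    libs = np.maximum(values.sum(axis=0), clip_min)
    return replace(matrix, values=values * (1e4 / libs), layer="cp10k")


def log1p_transform(matrix: CountMatrix) -> CountMatrix:
    """Natural-log ln(1 + x), elementwise."""
    matrix.require_layer("cp10k")
    if np.any(matrix.values < 0):
        raise ValueError("negative entries not allowed")
    return replace(matrix, values=np.log1p(matrix.values), layer="log1p")


def filter_classes(
    labels: Mapping[str, str], min_cells: int = 20
) -> list[str]:
    """Classes with at least ``min_cells`` members (inclusive)."""
    if not labels:
        raise ValueError("no cell labels given")
    counts = pd.Series(list(labels.values())).value_counts()
    survivors = sorted(counts[counts >= min_cells].index)
    if not survivors:
        raise CapacityError(
            f"no class reaches {min_cells} cells (largest: {counts.max()})"
        )
    return survivors


def _tie_terms(row_values: np.ndarray) -> float:
    """sum(t^3 - t) over tie groups of one gene's values."""
    _, counts = np.unique(row_values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def rank_sum_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact rank-sum p by enumeration of all group-1 subsets.

    p = P(|W' - mu| >= |W - mu|) over all equally likely assignments of the
    pooled ranks (midranks under ties) to a group of size len(x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = rankdata(pooled)
    mu = n1 * (n + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def rank_sum_normal_p(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided rank-sum (z, p) via the normal approximation with tie
    correction and no continuity correction; zero-variance data give p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    tie = _tie_terms(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return 0.0, 1.0
    z = (r1 - mu) / np.sqrt(var)
    return float(z), float(2.0 * norm.sf(abs(z)))


def wilcoxon_ovr(
    matrix: CountMatrix,
    labels: Mapping[str, str],
    alpha: float = 0.05,
    min_cells: int = 2,
    exact_max_n: int = 16,
) -> list[MarkerResult]:
    """One-vs-rest Wilcoxon rank-sum markers per gene per class.

    Each surviving class is tested against all remaining cells pooled,
    two-sided, with tie correction and no continuity correction; BH
    adjustment runs across genes within each class. Exact enumeration is
    used when the total cell count is at most ``exact_max_n``. Classes with
    fewer than ``min_cells`` members are skipped with a warning. Fold
    changes are log2((mean_in + eps) / (mean_out + eps)), eps = 1e-9.
    """
    import logging

    matrix.require_layer("cp10k", "log1p")
    logger = logging.getLogger(__name__)
    cols = matrix.columns
    groups = sorted({labels[c] for c in cols if c in labels})
    if len(groups) < 2:
        raise ValueError("need at least two classes")

    values = matrix.values
    n = len(cols)
    label_arr = np.array([labels.get(c, "") for c in cols])

    exact = n <= exact_max_n
    if not exact:
        # shared per-gene ranks over all cells; class rank sums by masking
        ranks = np.apply_along_axis(rankdata, 1, values)
        ties = np.array([_tie_terms(row) for row in values])

    results: list[MarkerResult] = []
    for group in groups:
        mask = label_arr == group
        n1 = int(mask.sum())
        n2 = n - n1
        if n1 < min_cells:
            logger.warning("class %r has %d cells (< %d); skipped", group, n1, min_cells)
            continue
        mean_in = values[:, mask].mean(axis=1)
        mean_out = values[:, ~mask].mean(axis=1)
        log2fc = np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS))

        if exact:
            stats = np.empty(values.shape[0])
            pvals = np.empty(values.shape[0])
            for i, row in enumerate(values):
                if np.ptp(row) == 0:
                    stats[i], pvals[i] = 0.0, 1.0
                else:
                    stats[i] = rankdata(row)[mask].sum()
                    pvals[i] = rank_sum_exact_p(row[mask], row[~mask])
        else:
            r1 = ranks[:, mask].sum(axis=1)
            mu = n1 * (n + 1) / 2.0
            var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(var > 0, (r1 - mu) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
            pvals = np.where(var > 0, 2.0 * norm.sf(np.abs(z)), 1.0)
            stats = z

        from .enrichment import bh_adjust

        padj = bh_adjust(pvals.tolist())
        for gene, s, lfc, p, pa in zip(matrix.genes, stats, log2fc, pvals, padj):
            results.append(
                MarkerResult(gene, group, float(s), float(lfc), float(p),
                             float(pa), bool(pa < alpha))
            )
    return results


def markers_to_frame(results: Sequence[MarkerResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "group": r.group,
                "statistic": r.statistic,
                "log2fc": r.log2fc,
                "p": r.p,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in results
        ]
    )


# --------------------------------------------------------------------------
# DE thresholding and visualisation transforms


def de_call(
    table: pd.DataFrame,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
) -> list[DECall]:
    """Threshold any engine's (fdr, log2fc) table.

    Significant iff fdr < fdr_max (strict) and |log2fc| >= lfc_min
    (inclusive). Required columns: gene, tissue, log2fc, fdr.
    """
    required = {"gene", "tissue", "log2fc", "fdr"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing column(s) {sorted(missing)}")
    return [
        DECall(
            gene=row.gene,
            tissue=row.tissue,
            log2fc=float(row.log2fc),
            fdr=float(row.fdr),
            significant=bool(row.fdr < fdr_max and abs(row.log2fc) >= lfc_min),
        )
        for row in table.itertuples()
    ]


def rowwise_zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row (x - mean) / sample SD (n-1 divisor); constant rows map to zeros."""
    if table.shape[1] < 2:
        raise ValueError("need at least two columns")
    values = table.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=table.index, columns=table.columns)
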