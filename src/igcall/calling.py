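"""Cell-level pipeline: QC, ASC selection, isotype calls, DP diagnostics.

The pipeline mirrors a standard droplet scRNA-seq workflow specialised to
antibody-secreting cells (ASCs):

1. four-step QC — drop high-mitochondrial cells, drop ribosomal genes, drop
   rarely-expressed genes, drop shallow cells;
2. ASC selection — cells with immunoglobulin expression above a fraction
   threshold (intersected across two references when both are analysed);
3. the isotype call — a cell is assigned the isotype holding more than a
   threshold share (default 85%) of its isotype-gene counts;
4. double-positive (DP) detection — a cell is DP for a gene pair when both
   genes exceed per-gene percent-of-total thresholds; genuine DP cells are
   doublets, and the library-size rank-sum diagnostic separates doublets
   (about twice the reads) from artifactual DPs caused by misassigned reads.

Thresholds for QC and DP are percent of raw per-cell total counts; the
log1p(y/L*1e4) transform is a display/export convenience only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import CountMatrix
from .stats import RankSumResult, rank_sum_test

UNASSIGNED = "unassigned"

DEFAULT_ISOTYPE_PATTERNS = (
    r"^IGHM$",
    r"^IGHD$",
    r"^IGHG[1-4]B?$",
    r"^IGHA[12]?$",
    r"^IGHE$",
)
DEFAULT_IG_PATTERNS = (r"^IGH", r"^IGK", r"^IGL")


@dataclass(frozen=True)
class QCParams:
    max_mito_fraction: float = 0.10
    min_reads: int = 1500
    min_genes: int = 450
    min_gene_prevalence: float = 0.005
    ribosomal_patterns: tuple[str, ...] = (r"^RPS", r"^RPL")
    mito_patterns: tuple[str, ...] = (r"^MT-",)
    ig_patterns: tuple[str, ...] = DEFAULT_IG_PATTERNS
    min_ig_fraction_for_asc: float = 0.10

    def __post_init__(self) -> None:
        for name in ("max_mito_fraction", "min_gene_prevalence", "min_ig_fraction_for_asc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_reads <= 0 or self.min_genes <= 0:
            raise ValueError("count thresholds must be positive")


@dataclass(frozen=True)
class DPThresholds:
    """Per gene pair, percent-of-total-count positivity thresholds."""

    thresholds: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("IGHG1", "IGHG2"): (0.5, 0.5),
            ("IGHG1", "IGHG3"): (0.5, 0.5),
            ("IGHA1", "IGHA2"): (0.8, 0.3),
        }
    )

    def __post_init__(self) -> None:
        for pair, (t1, t2) in self.thresholds.items():
            if t1 <= 0 or t2 <= 0:
                raise ValueError(f"thresholds for {pair} must be positive")


def qc_filter(matrix: CountMatrix, params: QCParams = QCParams()):
    """Four-step QC; returns (filtered matrix, step report).

    Steps in order: (i) drop cells over the mitochondrial fraction cap,
    (ii) drop ribosomal genes, (iii) drop genes expressed in fewer than
    ``min_gene_prevalence`` of the remaining cells, (iv) drop cells below
    the reads or detected-genes floors.
    """
    report = []
    m = matrix

    mito_mask = m.match_features(params.mito_patterns)
    if params.max_mito_fraction < 1.0 and not mito_mask.any():
        raise ValueError("matrix has no mitochondrial features; cannot apply mito QC")
    mito_frac = m.fraction_of(mito_mask)
    keep_cells = mito_frac <= params.max_mito_fraction
    report.append(("high_mito_cells_removed", int((~keep_cells).sum())))
    m = m.subset_cells(keep_cells)

    ribo_mask = m.match_features(params.ribosomal_patterns)
    report.append(("ribosomal_genes_removed", int(ribo_mask.sum())))
    m = m.subset_genes(~ribo_mask)

    prevalence = (m.counts > 0).mean(axis=0)
    keep_genes = prevalence >= params.min_gene_prevalence
    report.append(("low_prevalence_genes_removed", int((~keep_genes).sum())))
    m = m.subset_genes(keep_genes)

    totals = m.cell_totals()
    n_genes = (m.counts > 0).sum(axis=1)
    keep_cells = (totals >= params.min_reads) & (n_genes >= params.min_genes)
    report.append(("shallow_cells_removed", int((~keep_cells).sum())))
    m = m.subset_cells(keep_cells)

    rep = pd.DataFrame(report, columns=["step", "removed"])
    rep["order"] = np.arange(1, len(rep) + 1)
    return m, rep


def select_ascs(
    matrix: CountMatrix,
    ig_gene_patterns: tuple[str, ...] = DEFAULT_IG_PATTERNS,
    min_ig_fraction: float = 0.10,
    other: CountMatrix | None = None,
) -> np.ndarray:
    """Barcodes of cells with immunoglobulin expression above the threshold.

    With ``other`` given (the second reference's matrix), only barcodes
    passing in both are returned, preserving ``matrix``'s order.
    """
    mask = matrix.match_features(ig_gene_patterns)
    if not mask.any():
        raise ValueError("no features match the immunoglobulin patterns")
    frac = matrix.fraction_of(mask)
    selected = matrix.barcodes[frac > min_ig_fraction]
    if other is not None:
        other_sel = set(select_ascs(other, ig_gene_patterns, min_ig_fraction))
        selected = np.asarray([b for b in selected if b in other_sel])
    return selected


def expression_value(y, L, scale: float = 1e4, log: bool = True):
    """Normalised expression: log1p(y/L*scale), or y/L*scale (RPH at 1e2)."""
    y = np.asarray(y, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("cell total L must be positive")
    if np.any((y < 0) | (y > L)):
        raise ValueError("gene count y must satisfy 0 <= y <= L")
    v = y / L * scale
    return np.log1p(v) if log else v


def call_isotypes(
    matrix: CountMatrix,
    isotype_genes: list[str],
    call_threshold: float = 0.85,
) -> pd.DataFrame:
    """Per-cell isotype fractions and the >threshold call.

    Fractions are over isotype-gene counts only and sum to 1 whenever a cell
    has any isotype counts; a cell with none is ``unassigned`` with all-zero
    fractions (not an error).
    """
    missing = [g for g in isotype_genes if g not in matrix.features.index]
    if missing or not isotype_genes:
        raise ValueError(f"isotype genes absent from matrix: {missing}")
    cols = [matrix.gene_index(g) for g in isotype_genes]
    sub = matrix.counts[:, cols].astype(float)
    totals = sub.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals[:, None] > 0, sub / np.maximum(totals[:, None], 1), 0.0)
    best = np.argmax(frac, axis=1)
    best_frac = frac[np.arange(len(frac)), best]
    call = np.where(
        best_frac > call_threshold,
        np.asarray(isotype_genes, dtype=object)[best],
        UNASSIGNED,
    )
    out = pd.DataFrame(
        frac, columns=[f"fraction_{g}" for g in isotype_genes], index=matrix.barcodes
    )
    out.index.name = "barcode"
    out.insert(0, "call", call)
    out["isotype_total"] = totals.astype(np.int64)
    out["library_size"] = matrix.cell_totals()
    return out


def detect_dp(
    matrix: CountMatrix,
    thresholds: DPThresholds = DPThresholds(),
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Double-positive flags per configured gene pair.

    A cell is DP for (g1, g2) iff its percent-of-total counts exceed the
    pair's thresholds for both genes.  Returns (per-cell flags, pair counts).
    """
    pairs = pairs or [
        p for p in thresholds.thresholds if all(g in matrix.features.index for g in p)
    ]
    totals = matrix.cell_totals().astype(float)
    flags = pd.DataFrame(index=pd.Index(matrix.barcodes, name="barcode"))
    counts = []
    for g1, g2 in pairs:
        t1, t2 = thresholds.thresholds[(g1, g2)]
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = np.where(totals > 0, 100.0 * matrix.column(g1) / np.maximum(totals, 1), 0.0)
            p2 = np.where(totals > 0, 100.0 * matrix.column(g2) / np.maximum(totals, 1), 0.0)
        dp = (p1 > t1) & (p2 > t2)
        flags[f"DP_{g1}_{g2}"] = dp
        counts.append((g1, g2, t1, t2, int(dp.sum())))
    summary = pd.DataFrame(counts, columns=["gene1", "gene2", "threshold1", "threshold2", "n_dp"])
    return flags, summary


def dp_scatter_data(matrix: CountMatrix, pair: tuple[str, str]) -> pd.DataFrame:
    """Per-cell percent values for a gene pair (scatter-plot axes)."""
    totals = np.maximum(matrix.cell_totals().astype(float), 1)
    g1, g2 = pair
    return pd.DataFrame(
        {
            f"percent_{g1}": 100.0 * matrix.column(g1) / totals,
            f"percent_{g2}": 100.0 * matrix.column(g2) / totals,
        },
        index=pd.Index(matrix.barcodes, name="barcode"),
    )


def doublet_diagnostic(
    dp_flags: np.ndarray,
    library_sizes: np.ndarray,
    method: str = "auto",
    seed: int = 0,
) -> dict:
    """Rank-sum comparison of DP vs non-DP library sizes.

    Doublets carry roughly double the reads, so genuine DP cells show a
    significant library-size excess; artifactual DP cells do not.  Returns a
    dict with the statistic, two-sided p-value, group medians and direction;
    when either group is empty the diagnostic is skipped with a notice.
    """
    dp_flags = np.asarray(dp_flags, dtype=bool)
    library_sizes = np.asarray(library_sizes, dtype=float)
    x = library_sizes[dp_flags]
    y = library_sizes[~dp_flags]
    if x.size == 0 or y.size == 0:
        return {
            "skipped": True,
            "notice": "one group empty; doublet diagnostic not applicable",
            "n_dp": int(x.size),
            "n_other": int(y.size),
        }
    res: RankSumResult = rank_sum_test(x, y, method=method, seed=seed)
    med_dp, med_other = float(np.median(x)), float(np.median(y))
    return {
        "skipped": False,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "method": res.method,
        "n_dp": int(x.size),
        "n_other": int(y.size),
        "median_dp": med_dp,
        "median_other": med_other,
        "direction": "dp_larger" if med_dp > med_other else "dp_not_larger",
    }
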