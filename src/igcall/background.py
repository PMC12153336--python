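"""Synthetic non-immunoglobulin background counts for QC realism.

Tag reads are simulated for isotype genes only; the rest of a cell's
transcriptome (mitochondrial, ribosomal, marker and housekeeping genes) is
added directly at the count-matrix level from the cell truth table, so the
four-step QC, the ASC immunoglobulin-fraction rule and the percent-of-total
DP thresholds all operate on realistically composed totals.

Per cell, the final total T is set so that the observed isotype counts make
up ``1 - mito_fraction - background_gene_fraction`` of T; mitochondrial
counts are ``mito_fraction * T`` spread over the mitochondrial genes and the
remaining background is multinomial over ribosomal/marker/housekeeping genes
with Zipf-like weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import CountMatrix, make_features


def background_features(
    n_mito: int = 13, n_ribo: int = 80, n_housekeeping: int = 500
) -> pd.DataFrame:
    ids = (
        [f"MT-G{i:02d}" for i in range(1, n_mito + 1)]
        + [f"RPS{i:02d}" for i in range(1, n_ribo // 2 + 1)]
        + [f"RPL{i:02d}" for i in range(1, n_ribo - n_ribo // 2 + 1)]
        + ["JCHAIN", "XBP1"]
        + [f"BG{i:04d}" for i in range(1, n_housekeeping + 1)]
    )
    classes = (
        ["mito"] * n_mito + ["ribo"] * n_ribo + ["marker"] * 2 + ["background"] * n_housekeeping
    )
    return make_features(ids, feature_class=classes)


def add_background_counts(
    matrix: CountMatrix,
    cells: pd.DataFrame,
    seed: int = 0,
    n_mito: int = 13,
    n_ribo: int = 80,
    n_housekeeping: int = 500,
) -> CountMatrix:
    """Append background features to an isotype count matrix.

    ``cells`` must be the truth table whose barcodes cover the matrix rows;
    deterministic given ``seed`` and independent of which reference produced
    the isotype counts only through the observed isotype totals.
    """
    feats = background_features(n_mito, n_ribo, n_housekeeping)
    truth = cells.set_index("barcode").loc[matrix.barcodes]
    # size the background from the *truth* library, so both references see
    # the same non-isotype counts (the same underlying reads) regardless of
    # how many isotype reads each reference managed to assign
    lib = truth["library_size"].to_numpy().astype(float)
    m = truth["mito_fraction"].to_numpy()
    f = truth["background_gene_fraction"].to_numpy()
    iso_share = np.clip(1.0 - m - f, 0.05, None)
    mito_n = np.rint(lib * m / iso_share).astype(np.int64)
    bg_n = np.rint(lib * f / iso_share).astype(np.int64)

    rng = np.random.default_rng(seed)
    classes = feats["feature_class"].to_numpy()
    n_feats = len(feats)
    counts = np.zeros((matrix.n_cells, n_feats), dtype=np.int64)

    mito_cols = np.nonzero(classes == "mito")[0]
    other_cols = np.nonzero(classes != "mito")[0]
    w_mito = 1.0 / (np.arange(mito_cols.size) + 2.0)
    w_mito /= w_mito.sum()
    # markers get strong weight (plasma-cell markers are highly expressed);
    # a flat-ish Zipf tail keeps detected-gene counts realistic for the
    # min-genes QC threshold
    w_other = 1.0 / (np.arange(other_cols.size) + 1000.0)
    marker = classes[other_cols] == "marker"
    w_other[marker] = w_other.max() * 5
    w_other /= w_other.sum()
    for i in range(matrix.n_cells):
        if mito_n[i] > 0:
            counts[i, mito_cols] = rng.multinomial(mito_n[i], w_mito)
        if bg_n[i] > 0:
            counts[i, other_cols] = rng.multinomial(bg_n[i], w_other)

    extra = CountMatrix(counts, matrix.barcodes, feats)
    return matrix.concat_features(extra)
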