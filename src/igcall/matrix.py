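"""Cells x genes count matrix with barcode/feature registries.

The layout mirrors the Cell Ranger Matrix Market triple: ``matrix.mtx`` holds
genes x cells integer counts, ``features.tsv`` and ``barcodes.tsv`` the
registries.  Counts here are *effective* reads only; per-class read tallies
travel alongside the matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class CountMatrix:
    counts: np.ndarray  # (n_cells, n_genes) int64
    barcodes: np.ndarray  # cell barcodes, row order
    features: pd.DataFrame  # index gene_id; columns: symbol, feature_class
    tallies: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.barcodes = np.asarray(self.barcodes)
        if self.counts.shape != (self.barcodes.size, len(self.features)):
            raise ValueError("counts shape does not match registries")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(set(self.barcodes)) != self.barcodes.size:
            raise ValueError("duplicate barcodes")
        if self.features.index.duplicated().any():
            raise ValueError("duplicate feature ids")

    # -- registry helpers ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return int(self.barcodes.size)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.features.index)

    def gene_index(self, gene_id: str) -> int:
        return self.features.index.get_loc(gene_id)

    def match_features(self, patterns: list[str] | tuple[str, ...]) -> np.ndarray:
        """Boolean mask over features whose symbol matches any regex."""
        symbols = self.features["symbol"].astype(str)
        mask = np.zeros(len(self.features), dtype=bool)
        for pat in patterns:
            mask |= symbols.str.contains(pat, regex=True).to_numpy()
        return mask

    def column(self, gene_id: str) -> np.ndarray:
        return self.counts[:, self.gene_index(gene_id)]

    def cell_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def fraction_of(self, mask: np.ndarray) -> np.ndarray:
        """Per-cell fraction of total counts in the masked features (0 when
        the cell total is 0)."""
        totals = self.cell_totals()
        sub = self.counts[:, mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, sub / np.maximum(totals, 1), 0.0)
        return frac

    # -- subsetting ---------------------------------------------------------

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.nonzero(keep)[0]
        else:
            idx = keep
        return CountMatrix(self.counts[idx], self.barcodes[idx], self.features, self.tallies)

    def subset_barcodes(self, barcodes: np.ndarray) -> "CountMatrix":
        pos = {b: i for i, b in enumerate(self.barcodes)}
        idx = np.asarray([pos[b] for b in barcodes])
        return CountMatrix(self.counts[idx], np.asarray(barcodes), self.features, self.tallies)

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[:, mask], self.barcodes, self.features.loc[mask], self.tallies
        )

    def concat_features(self, other: "CountMatrix") -> "CountMatrix":
        if not np.array_equal(self.barcodes, other.barcodes):
            raise ValueError("feature concat requires identical barcode registries")
        feats = pd.concat([self.features, other.features])
        return CountMatrix(
            np.hstack([self.counts, other.counts]), self.barcodes, feats, self.tallies
        )

    # -- Matrix Market triple I/O -------------------------------------------

    def write_mtx(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mat = scipy.sparse.csc_matrix(self.counts.T)  # genes x cells
        scipy.io.mmwrite(str(out / "matrix.mtx"), mat, field="integer")
        feats = self.features.reset_index()
        feats.columns = ["gene_id", *feats.columns[1:]]
        feats.to_csv(out / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(self.barcodes).to_csv(out / "barcodes.tsv", header=False, index=False)

    @classmethod
    def read_mtx(cls, in_dir: str | Path) -> "CountMatrix":
        in_dir = Path(in_dir)
        mat = scipy.io.mmread(str(in_dir / "matrix.mtx")).tocsc()
        feats = pd.read_csv(in_dir / "features.tsv", sep="\t", header=None)
        cols = ["gene_id", "symbol", "feature_class"][: feats.shape[1]]
        feats.columns = cols + [f"extra{i}" for i in range(feats.shape[1] - len(cols))]
        feats = feats.set_index("gene_id")
        if "symbol" not in feats.columns:
            feats["symbol"] = feats.index
        barcodes = pd.read_csv(in_dir / "barcodes.tsv", header=None)[0].to_numpy()
        return cls(np.asarray(mat.T.todense(), dtype=np.int64), barcodes, feats)


def make_features(
    gene_ids: list[str],
    symbols: list[str] | None = None,
    feature_class: str | list[str] = "isotype",
) -> pd.DataFrame:
    feats = pd.DataFrame(
        {
            "symbol": symbols if symbols is not None else gene_ids,
            "feature_class": feature_class,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return feats


def is_pattern_match(values: pd.Index | pd.Series, patterns: tuple[str, ...]) -> np.ndarray:
    vals = pd.Series(values).astype(str)
    mask = np.zeros(len(vals), dtype=bool)
    for pat in patterns:
        mask |= vals.str.contains(pat, regex=True, flags=re.IGNORECASE).to_numpy()
    return mask
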