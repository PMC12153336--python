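"""Simulated cell populations with per-cell ground truth.

Each simulated cell is an antibody-secreting cell (ASC) expressing exactly one
isotype gene — the one-cell-one-antibody ground truth — unless it is a
doublet, in which case two cells share a barcode and the captured molecule
pool mixes two isotypes.  Library sizes are log-normal; a doublet's library
size is the sum of two independent draws, so doublets are stochastically
about twice as deep as singlets, which is what the library-size doublet
diagnostic exploits.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .util import kmer_strings

BARCODE_LENGTH = 16

#: Truth-table column names (one row per cell barcode).
CELL_COLUMNS = (
    "barcode",
    "true_isotype",
    "is_doublet",
    "second_isotype",
    "library_size",
    "library_size_primary",
    "library_size_secondary",
    "mito_fraction",
    "background_gene_fraction",
)


class EmptyTableError(ValueError):
    """Raised when a zero-cell table is requested."""


def _unique_barcodes(n: int, rng: np.random.Generator) -> np.ndarray:
    codes = np.empty(0, dtype=np.uint64)
    space = np.uint64(4**BARCODE_LENGTH)
    while codes.size < n:
        fresh = rng.integers(0, space, size=2 * (n - codes.size) + 16, dtype=np.uint64)
        codes = np.unique(np.concatenate([codes, fresh]))
    # keep deterministic but unordered-looking set
    codes = rng.permutation(codes)[:n]
    return kmer_strings(codes, BARCODE_LENGTH)


def simulate_cells(
    n_cells: int,
    isotype_proportions: Mapping[str, float],
    doublet_rate: float = 0.0,
    libsize_log_mean: float = 7.3,
    libsize_log_sd: float = 0.5,
    seed: int = 0,
    mito_beta: tuple[float, float] = (2.0, 38.0),
    background_beta: tuple[float, float] = (60.0, 50.0),
) -> pd.DataFrame:
    """Draw a cell truth table.

    Parameters
    ----------
    isotype_proportions
        Mixing proportions over isotype gene ids; must sum to 1 (±1e-9).
    doublet_rate
        Probability that a barcode captures two cells; must be in [0, 0.5].
        The second cell's isotype is drawn from the proportions restricted to
        the other genes, so a doublet always mixes two distinct isotypes.
    libsize_log_mean, libsize_log_sd
        Natural-log mean/sd of the per-cell isotype molecule count.
    mito_beta, background_beta
        Beta parameters for the per-cell mitochondrial fraction and for the
        fraction of total counts contributed by non-immunoglobulin background
        genes (both fractions of the cell's total count).
    """
    if n_cells <= 0:
        raise EmptyTableError("n_cells must be positive")
    genes = list(isotype_proportions)
    props = np.asarray([isotype_proportions[g] for g in genes], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"isotype proportions sum to {props.sum()}, not 1")
    if np.any(props < 0):
        raise ValueError("negative isotype proportion")
    if not 0.0 <= doublet_rate <= 0.5:
        raise ValueError("doublet_rate must be in [0, 0.5]")

    rng = np.random.default_rng(seed)
    barcodes = _unique_barcodes(n_cells, rng)
    primary_idx = rng.choice(len(genes), size=n_cells, p=props)
    is_doublet = rng.random(n_cells) < doublet_rate

    second_idx = np.full(n_cells, -1)
    for i in np.nonzero(is_doublet)[0]:
        p = props.copy()
        p[primary_idx[i]] = 0.0
        if p.sum() <= 0:
            raise ValueError("doublets need at least two isotypes with mass")
        second_idx[i] = rng.choice(len(genes), p=p / p.sum())

    def draw_libsize(size: int) -> np.ndarray:
        return np.maximum(1, np.rint(rng.lognormal(libsize_log_mean, libsize_log_sd, size))).astype(
            np.int64
        )

    lib_primary = draw_libsize(n_cells)
    lib_secondary = np.zeros(n_cells, dtype=np.int64)
    lib_secondary[is_doublet] = draw_libsize(int(is_doublet.sum()))

    mito = rng.beta(*mito_beta, size=n_cells)
    background = rng.beta(*background_beta, size=n_cells)

    gene_arr = np.asarray(genes, dtype=object)
    df = pd.DataFrame(
        {
            "barcode": barcodes,
            "true_isotype": gene_arr[primary_idx],
            "is_doublet": is_doublet,
            "second_isotype": np.where(is_doublet, gene_arr[np.maximum(second_idx, 0)], None),
            "library_size": lib_primary + lib_secondary,
            "library_size_primary": lib_primary,
            "library_size_secondary": lib_secondary,
            "mito_fraction": mito,
            "background_gene_fraction": background,
        }
    )
    validate_cells(df)
    return df


def validate_cells(cells: pd.DataFrame) -> None:
    if cells["barcode"].duplicated().any():
        raise ValueError("duplicate cell barcodes")
    if (cells["library_size"] < 1).any():
        raise ValueError("library sizes must be >= 1")
    for col in ("mito_fraction", "background_gene_fraction"):
        if ((cells[col] < 0) | (cells[col] > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    dbl = cells[cells["is_doublet"]]
    if (dbl["second_isotype"] == dbl["true_isotype"]).any():
        raise ValueError("doublet second isotype equals first")
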