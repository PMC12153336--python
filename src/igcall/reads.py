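"""3'-biased tag-read simulation over terminal constant-region exons.

The simulator emulates 10x Chromium 3' gene-expression reads: every cDNA read
is an ungapped window of the donor allele's terminal ("CH3-CHS") exon, read
starts concentrate near the 3' end, substitution sequencing errors are i.i.d.
per base, and each molecule may be sequenced multiple times through PCR
duplication (copy count 1 + Poisson(mean - 1)).  Reads are stored columnar
(numpy arrays per field) so that multi-million-read simulations stay cheap;
sequences are materialised on demand from (gene, offset, sparse errors).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panels import AllelePanel
from .util import kmer_strings, seq_to_u8

UMI_LENGTH = 12

POSITION_BIASES = ("uniform-over-exon", "3prime-geometric")


class ReadConfigError(ValueError):
    """Read-simulation configuration incompatible with the panel."""


class ReadSet:
    """Columnar container for simulated barcode/UMI-tagged reads."""

    def __init__(
        self,
        read_length: int,
        donor_reference: str,
        gene_ids: tuple[str, ...],
        allele_matrix: np.ndarray,
        cell_index: np.ndarray,
        cell_barcodes: np.ndarray,
        umi: np.ndarray,
        gene_codes: np.ndarray,
        offsets: np.ndarray,
        molecule_id: np.ndarray,
        is_pcr_copy: np.ndarray,
        error_read: np.ndarray | None = None,
        error_pos: np.ndarray | None = None,
        error_base: np.ndarray | None = None,
    ):
        self.read_length = int(read_length)
        self.donor_reference = donor_reference
        self.gene_ids = tuple(gene_ids)
        self.allele_matrix = allele_matrix  # (n_genes, exon_length) uint8
        self.cell_index = cell_index
        self.cell_barcodes = cell_barcodes  # per-cell, not per-read
        self.umi = umi
        self.gene_codes = gene_codes
        self.offsets = offsets
        self.molecule_id = molecule_id
        self.is_pcr_copy = is_pcr_copy
        empty = np.empty(0, dtype=np.int64)
        self.error_read = error_read if error_read is not None else empty
        self.error_pos = error_pos if error_pos is not None else empty.astype(np.int32)
        self.error_base = error_base if error_base is not None else empty.astype(np.uint8)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_reads(self) -> int:
        return int(self.cell_index.size)

    def read_ids(self, indices: np.ndarray | None = None) -> np.ndarray:
        idx = np.arange(self.n_reads) if indices is None else np.asarray(indices)
        return np.char.add("r", idx.astype(str))

    def read_barcodes(self, indices: np.ndarray | None = None) -> np.ndarray:
        idx = self.cell_index if indices is None else self.cell_index[indices]
        return self.cell_barcodes[idx]

    def umi_strings(self, indices: np.ndarray | None = None) -> np.ndarray:
        codes = self.umi if indices is None else self.umi[indices]
        return kmer_strings(codes, UMI_LENGTH)

    def has_errors(self) -> np.ndarray:
        mask = np.zeros(self.n_reads, dtype=bool)
        mask[self.error_read] = True
        return mask

    def true_gene_names(self, indices: np.ndarray | None = None) -> np.ndarray:
        codes = self.gene_codes if indices is None else self.gene_codes[indices]
        return np.asarray(self.gene_ids, dtype=object)[codes]

    # -- sequence materialisation -------------------------------------------

    def sequence_matrix(self, indices: np.ndarray | None = None) -> np.ndarray:
        """(n, read_length) uint8 ASCII matrix of cDNA sequences."""
        idx = np.arange(self.n_reads) if indices is None else np.asarray(indices)
        flat = self.allele_matrix.ravel()
        exon_len = self.allele_matrix.shape[1]
        base = self.gene_codes[idx].astype(np.int64) * exon_len + self.offsets[idx]
        mat = flat[base[:, None] + np.arange(self.read_length)]
        if self.error_read.size:
            # scatter errors belonging to the requested reads
            pos_of = np.full(self.n_reads, -1, dtype=np.int64)
            pos_of[idx] = np.arange(idx.size)
            rows = pos_of[self.error_read]
            keep = rows >= 0
            mat[rows[keep], self.error_pos[keep]] = self.error_base[keep]
        return mat

    def sequences(self, indices: np.ndarray | None = None) -> np.ndarray:
        mat = self.sequence_matrix(indices)
        return mat.view(f"S{self.read_length}").ravel().astype(str)

    def to_frame(self) -> pd.DataFrame:
        """Full per-read table (read_id, barcode, UMI, sequence, truth)."""
        return pd.DataFrame(
            {
                "read_id": self.read_ids(),
                "barcode": self.read_barcodes(),
                "umi": self.umi_strings(),
                "sequence": self.sequences(),
                "true_gene": self.true_gene_names(),
                "true_offset": self.offsets,
                "molecule_id": self.molecule_id,
                "is_pcr_copy": self.is_pcr_copy,
            }
        )

    def subset(self, indices: np.ndarray) -> "ReadSet":
        idx = np.asarray(indices)
        keep = np.zeros(self.n_reads, dtype=bool)
        keep[idx] = True
        err_keep = keep[self.error_read]
        remap = np.cumsum(keep) - 1
        return ReadSet(
            self.read_length,
            self.donor_reference,
            self.gene_ids,
            self.allele_matrix,
            self.cell_index[idx],
            self.cell_barcodes,
            self.umi[idx],
            self.gene_codes[idx],
            self.offsets[idx],
            self.molecule_id[idx],
            self.is_pcr_copy[idx],
            remap[self.error_read[err_keep]],
            self.error_pos[err_keep],
            self.error_base[err_keep],
        )


def _draw_offsets(
    n: int,
    max_start: int,
    position_bias: str,
    geometric_p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if position_bias == "uniform-over-exon":
        return rng.integers(0, max_start + 1, size=n).astype(np.int32)
    if position_bias == "3prime-geometric":
        # distance of the read start from the 3'-most valid start, truncated
        d = rng.geometric(geometric_p, size=n) - 1
        while True:
            bad = d > max_start
            if not bad.any():
                break
            d[bad] = rng.geometric(geometric_p, size=int(bad.sum())) - 1
        return (max_start - d).astype(np.int32)
    raise ReadConfigError(f"unknown position bias {position_bias!r}")


def offset_distribution(
    max_start: int, position_bias: str, geometric_p: float = 0.02
) -> np.ndarray:
    """Exact probability of each read-start offset under the bias model."""
    if position_bias == "uniform-over-exon":
        return np.full(max_start + 1, 1.0 / (max_start + 1))
    if position_bias == "3prime-geometric":
        d = np.arange(max_start + 1)
        w = geometric_p * (1 - geometric_p) ** d
        w /= w.sum()
        return w[::-1].copy()  # index by offset (0 = 5'-most)
    raise ReadConfigError(f"unknown position bias {position_bias!r}")


def simulate_reads(
    panel: AllelePanel,
    cells: pd.DataFrame,
    read_length: int = 90,
    error_rate: float = 0.0,
    position_bias: str = "3prime-geometric",
    geometric_p: float = 0.02,
    pcr_duplication_mean: float = 1.0,
    seed: int = 0,
) -> ReadSet:
    """Simulate tag reads for every cell from the donor panel's alleles.

    Molecules are drawn from the cell's true isotype (and, for doublets, its
    second isotype for the secondary library-size component); the total
    pre-duplication molecule count per cell equals its target library size.
    """
    if pcr_duplication_mean < 1.0:
        raise ReadConfigError("pcr_duplication_mean must be >= 1")
    if not 0.0 <= error_rate < 1.0:
        raise ReadConfigError("error_rate must be in [0, 1)")
    gene_ids = tuple(panel.gene_ids())
    exon_lens = {g: len(panel.terminal_seq(g)) for g in gene_ids}
    if read_length > min(exon_lens.values()):
        raise ReadConfigError(
            f"read_length {read_length} exceeds the shortest terminal exon "
            f"({min(exon_lens.values())} nt)"
        )
    if len(set(exon_lens.values())) != 1:
        raise ReadConfigError("panel terminal exons must share one length")
    exon_len = next(iter(exon_lens.values()))
    allele_matrix = np.vstack([seq_to_u8(panel.terminal_seq(g)) for g in gene_ids])
    code_of = {g: i for i, g in enumerate(gene_ids)}
    for g in pd.unique(cells["true_isotype"]):
        if g not in code_of:
            raise ReadConfigError(f"cell isotype {g!r} not in donor panel")

    rng = np.random.default_rng(seed)
    n_cells = len(cells)

    # molecule-level truth: primary component then secondary (doublets)
    prim_counts = cells["library_size_primary"].to_numpy()
    sec_counts = cells["library_size_secondary"].to_numpy()
    prim_genes = np.asarray([code_of[g] for g in cells["true_isotype"]], dtype=np.int16)
    sec_genes = np.asarray(
        [code_of[g] if g is not None else -1 for g in cells["second_isotype"]],
        dtype=np.int16,
    )
    mol_cell = np.concatenate(
        [
            np.repeat(np.arange(n_cells, dtype=np.int32), prim_counts),
            np.repeat(np.arange(n_cells, dtype=np.int32), sec_counts),
        ]
    )
    mol_gene = np.concatenate(
        [np.repeat(prim_genes, prim_counts), np.repeat(sec_genes, sec_counts)]
    )
    n_mol = mol_cell.size
    order = np.argsort(mol_cell, kind="stable")
    mol_cell = mol_cell[order]
    mol_gene = mol_gene[order]

    max_start = exon_len - read_length
    mol_offset = _draw_offsets(n_mol, max_start, position_bias, geometric_p, rng)
    mol_umi = rng.integers(0, 4**UMI_LENGTH, size=n_mol, dtype=np.uint64)

    if pcr_duplication_mean > 1.0:
        copies = 1 + rng.poisson(pcr_duplication_mean - 1.0, size=n_mol)
    else:
        copies = np.ones(n_mol, dtype=np.int64)
    read_mol = np.repeat(np.arange(n_mol, dtype=np.int64), copies)
    n_reads = read_mol.size
    first_of_mol = np.concatenate([[0], np.cumsum(copies)[:-1]])
    is_pcr = np.ones(n_reads, dtype=bool)
    is_pcr[first_of_mol] = False

    if error_rate > 0.0:
        n_err = rng.binomial(read_length, error_rate, size=n_reads)
        err_reads = np.nonzero(n_err)[0]
        err_read_list: list[np.ndarray] = []
        err_pos_list: list[np.ndarray] = []
        for r in err_reads:
            k = n_err[r]
            pos = rng.choice(read_length, size=k, replace=False)
            err_read_list.append(np.full(k, r, dtype=np.int64))
            err_pos_list.append(np.sort(pos).astype(np.int32))
        if err_read_list:
            error_read = np.concatenate(err_read_list)
            error_pos = np.concatenate(err_pos_list)
            orig = allele_matrix.ravel()[
                mol_gene[read_mol[error_read]].astype(np.int64) * exon_len
                + mol_offset[read_mol[error_read]]
                + error_pos
            ]
            # substitute with a uniformly random *different* base
            lookup = seq_to_u8("ACGT")
            orig_idx = np.searchsorted(np.sort(lookup), orig)
            shift = rng.integers(1, 4, size=error_read.size)
            error_base = lookup[(orig_idx + shift) % 4]
        else:
            error_read = error_pos = error_base = None
    else:
        error_read = error_pos = error_base = None

    return ReadSet(
        read_length=read_length,
        donor_reference=panel.reference_name,
        gene_ids=gene_ids,
        allele_matrix=allele_matrix,
        cell_index=mol_cell[read_mol],
        cell_barcodes=cells["barcode"].to_numpy(),
        umi=mol_umi[read_mol],
        gene_codes=mol_gene[read_mol],
        offsets=mol_offset[read_mol],
        molecule_id=read_mol,
        is_pcr_copy=is_pcr,
        error_read=error_read,
        error_pos=error_pos,
        error_base=error_base,
    )
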