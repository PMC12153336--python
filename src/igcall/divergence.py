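"""Variant inventories and ambiguity-region decomposition for paralog pairs.

Two questions drive the reference-ancestry analysis:

* where do two paralogous isotype genes differ *within* one reference
  (pair variants), and where does one gene differ *across* references
  (allele variants)?  -> :func:`enumerate_variants`, :func:`compare_references`
* from which read-start offsets is a tag read of length R *distinguishable*
  between the two paralogs, per reference?  -> :func:`decompose_regions`

A start offset is ambiguous in a reference iff the two paralogs' length-R
windows starting there are identical in that reference; such reads are
discarded as multi-mappers by the assignment model.  The four offset classes
(ambiguous in A only / in B only / in both / in neither) are the
blue/orange/red region scheme: for an (hg38-like, T2T-like) pair order, the
"blue" region is ambiguous in the T2T-like reference only, "orange" in the
hg38-like only, and "red" is distinguishable in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import AllelePanel
from .util import seq_to_u8

CLASS_NAMES = (
    "ambiguous_in_a_only",
    "ambiguous_in_b_only",
    "distinguishable_in_both",
    "ambiguous_in_both",
)

#: Colour aliases for the (hg38-like, T2T-like) pair order: blue = identical
#: in the T2T-like reference only, orange = identical in the hg38-like only.
COLOR_OF_CLASS = {
    "ambiguous_in_b_only": "blue",
    "ambiguous_in_a_only": "orange",
    "distinguishable_in_both": "red",
    "ambiguous_in_both": "grey",
}


# ---------------------------------------------------------------------------
# Pairwise global alignment (match 0, mismatch 1, gap 1)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    cost: int

    def columns(self) -> list[tuple[str | None, str | None]]:
        return [
            (a if a != "-" else None, b if b != "-" else None)
            for a, b in zip(self.aligned_a, self.aligned_b)
        ]

    @property
    def has_gaps(self) -> bool:
        return "-" in self.aligned_a or "-" in self.aligned_b


def align_pair(seq_a: str, seq_b: str) -> PairwiseAlignment:
    """Global alignment with unit mismatch and linear unit gap costs.

    Ties in the dynamic program are broken preferring the diagonal move, then
    the vertical (gap in B), then the horizontal (gap in A), so the traceback
    is deterministic.
    """
    if not seq_a or not seq_b:
        raise ValueError("align_pair requires non-empty sequences")
    a = seq_to_u8(seq_a)
    b = seq_to_u8(seq_b)
    n, m = a.size, b.size
    if n == m and np.array_equal(a, b):
        return PairwiseAlignment(seq_a, seq_b, 0)
    f = np.empty((n + 1, m + 1), dtype=np.int32)
    f[0] = np.arange(m + 1)
    j_idx = np.arange(m + 1)
    for i in range(1, n + 1):
        sub = (a[i - 1] != b).astype(np.int32)
        t = np.empty(m + 1, dtype=np.int32)
        t[0] = i
        t[1:] = np.minimum(f[i - 1, :-1] + sub, f[i - 1, 1:] + 1)
        # resolve the in-row (horizontal) dependency with a prefix scan:
        # f[i, j] = min_{k <= j} t[k] + (j - k)
        f[i] = np.minimum.accumulate(t - j_idx) + j_idx
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and f[i, j] == f[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and f[i, j] == f[i - 1, j] + 1:
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            j -= 1
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), int(f[n, m]))


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------


@dataclass
class VariantTable:
    """Mismatch inventory for an aligned sequence pair.

    ``rows`` has one record per mismatch column with 1-based positions in the
    alignment-column frame (equal to sequence position for gapless pairs);
    indels are inventoried separately and excluded from ``total_variants``.
    """

    pair_id: str
    rows: pd.DataFrame
    indels: pd.DataFrame
    frame: str  # "gapless" | "alignment_columns"
    coding_end: int | None = None

    @property
    def total_variants(self) -> int:
        return len(self.rows)

    @property
    def n_indel_columns(self) -> int:
        return len(self.indels)

    def compartment_counts(self) -> tuple[int, int]:
        """(coding, utr) mismatch counts; requires an annotated boundary."""
        if self.coding_end is None:
            raise ValueError("no coding/UTR boundary annotated")
        coding = int((self.rows["position"] <= self.coding_end).sum())
        return coding, self.total_variants - coding

    def validate(self) -> None:
        pos = self.rows["position"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError("variant positions must be strictly increasing")
        if (self.rows["base_left"] == self.rows["base_right"]).any():
            raise ValueError("variant rows must differ between sequences")


def enumerate_variants(
    seq_a: str,
    seq_b: str,
    pair_id: str = "pair",
    coding_end: int | None = None,
) -> VariantTable:
    """One row per mismatched alignment column; indel columns kept apart.

    ``coding_end``: 1-based position of the last coding base (stop-codon
    boundary) in the alignment-column frame, enabling coding/UTR attribution.
    """
    aln = align_pair(seq_a, seq_b)
    cols = aln.columns()
    mism = []
    indels = []
    for idx, (ca, cb) in enumerate(cols, start=1):
        if ca is None or cb is None:
            indels.append((idx, ca or "-", cb or "-"))
        elif ca != cb:
            mism.append((idx, ca, cb))
    rows = pd.DataFrame(mism, columns=["position", "base_left", "base_right"])
    ind = pd.DataFrame(indels, columns=["position", "base_left", "base_right"])
    frame = "gapless" if not aln.has_gaps else "alignment_columns"
    table = VariantTable(pair_id, rows, ind, frame, coding_end)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Region decomposition
# ---------------------------------------------------------------------------


@dataclass
class RegionDecomposition:
    pair: tuple[str, str]
    references: tuple[str, str]
    read_length: int
    labels: np.ndarray  # per start offset, values in CLASS_NAMES
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_offsets(self) -> int:
        return int(self.labels.size)

    def class_of(self, offset: int) -> str:
        return str(self.labels[offset])

    def class_lengths(self) -> dict[str, int]:
        return {c: int((self.labels == c).sum()) for c in CLASS_NAMES}

    def to_frame(self) -> pd.DataFrame:
        recs = [
            (cls, start, end, COLOR_OF_CLASS[cls])
            for cls, ivals in self.intervals.items()
            for start, end in ivals
        ]
        return pd.DataFrame(recs, columns=["class", "start", "end", "color"]).sort_values(
            "start", ignore_index=True
        )

    def to_bed(self, path: str | Path, chrom: str | None = None) -> None:
        chrom = chrom or "/".join(self.pair)
        with open(path, "w") as fh:
            for _, row in self.to_frame().iterrows():
                fh.write(f"{chrom}\t{row.start}\t{row.end}\t{row['class']}\n")

    def validate(self) -> None:
        covered = np.zeros(self.n_offsets, dtype=int)
        for cls, ivals in self.intervals.items():
            starts = [s for s, _ in ivals]
            if starts != sorted(starts):
                raise ValueError(f"{cls}: intervals not sorted")
            for s, e in ivals:
                covered[s:e] += 1
        if not np.all(covered == 1):
            raise ValueError("intervals do not partition the offsets")


def _run_length_intervals(labels: np.ndarray) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {c: [] for c in CLASS_NAMES}
    if labels.size == 0:
        return out
    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    for s, e in zip(starts, ends):
        out[str(labels[s])].append((int(s), int(e)))
    return out


def _ambiguous_offsets(seq_a: str, seq_b: str, read_length: int) -> np.ndarray:
    """ambiguous[o] == the two length-R windows starting at offset o agree.

    Offsets live in the frame of ``seq_a``.  Equal-length sequences use the
    direct base-by-base fast path; otherwise windows are projected through
    the global alignment and any mismatch or gap column inside the projected
    window marks the offset distinguishable.
    """
    n = len(seq_a)
    if read_length > n or read_length > len(seq_b):
        raise ValueError("read length exceeds exon length")
    n_off = n - read_length + 1
    if n == len(seq_b):
        diff = (seq_to_u8(seq_a) != seq_to_u8(seq_b)).astype(np.int32)
        csum = np.concatenate([[0], np.cumsum(diff)])
        window_diffs = csum[read_length:] - csum[:-read_length]
        return window_diffs == 0
    aln = align_pair(seq_a, seq_b)
    cols = aln.columns()
    bad = np.asarray(
        [ca is None or cb is None or ca != cb for ca, cb in cols], dtype=np.int32
    )
    csum = np.concatenate([[0], np.cumsum(bad)])
    first_col = np.full(n, -1, dtype=np.int64)
    ai = 0
    for c, (ca, _cb) in enumerate(cols):
        if ca is not None:
            first_col[ai] = c
            ai += 1
    amb = np.zeros(n_off, dtype=bool)
    for o in range(n_off):
        c0 = first_col[o]
        c1 = first_col[o + read_length - 1]
        amb[o] = (csum[c1 + 1] - csum[c0]) == 0
    return amb


def decompose_regions(
    panel_a: AllelePanel,
    panel_b: AllelePanel,
    gene_pair: tuple[str, str],
    read_length: int,
) -> RegionDecomposition:
    """Classify every valid read-start offset of a paralog pair.

    Classes partition the offsets: identical windows in both references
    (``ambiguous_in_both``), in one only, or in neither
    (``distinguishable_in_both``).
    """
    g1, g2 = gene_pair
    amb_a = _ambiguous_offsets(panel_a.terminal_seq(g1), panel_a.terminal_seq(g2), read_length)
    amb_b = _ambiguous_offsets(panel_b.terminal_seq(g1), panel_b.terminal_seq(g2), read_length)
    if amb_a.size != amb_b.size:
        n = min(amb_a.size, amb_b.size)
        amb_a, amb_b = amb_a[:n], amb_b[:n]
    labels = np.where(
        amb_a & amb_b,
        "ambiguous_in_both",
        np.where(
            amb_a,
            "ambiguous_in_a_only",
            np.where(amb_b, "ambiguous_in_b_only", "distinguishable_in_both"),
        ),
    ).astype(object)
    deco = RegionDecomposition(
        pair=gene_pair,
        references=(panel_a.reference_name, panel_b.reference_name),
        read_length=read_length,
        labels=labels,
        intervals=_run_length_intervals(labels),
    )
    deco.validate()
    return deco


# ---------------------------------------------------------------------------
# Cross-reference allele comparison
# ---------------------------------------------------------------------------


@dataclass
class CrossReferenceComparison:
    gene: str
    gene_id_a: str
    gene_id_b: str
    table: VariantTable
    duplicated: bool


def compare_references(
    panel_a: AllelePanel, panel_b: AllelePanel, gene: str
) -> list[CrossReferenceComparison]:
    """Variant tables for one gene symbol's alleles across two references.

    When a reference carries extra copies of the gene (duplication), one
    comparison is produced per copy pair and flagged.
    """
    copies_a = [g for g, r in panel_a.genes.items() if r.symbol == gene]
    copies_b = [g for g, r in panel_b.genes.items() if r.symbol == gene]
    if not copies_a or not copies_b:
        raise KeyError(f"gene {gene!r} missing from one of the panels")
    duplicated = len(copies_a) != len(copies_b) or len(copies_a) > 1
    out = []
    for ga in copies_a:
        for gb in copies_b:
            exon_a = panel_a.gene(ga).terminal_exon
            coding_end = exon_a.coding_end
            table = enumerate_variants(
                exon_a.seq,
                panel_b.terminal_seq(gb),
                pair_id=f"{ga}@{panel_a.reference_name}/{gb}@{panel_b.reference_name}",
                coding_end=coding_end,
            )
            out.append(CrossReferenceComparison(gene, ga, gb, table, duplicated))
    return out


def family_variant_columns(panel: AllelePanel, genes: list[str] | None = None) -> int:
    """Number of exon columns at which the panel's family sequences are not
    all identical (gene copies included) — the family variant inventory."""
    if genes is None:
        ids = panel.gene_ids()
    else:
        ids = [g for g, r in panel.genes.items() if r.symbol in genes or g in genes]
    seqs = [seq_to_u8(panel.terminal_seq(g)) for g in ids]
    lengths = {s.size for s in seqs}
    if len(lengths) != 1:
        raise ValueError("family variant counting requires equal-length exons")
    mat = np.vstack(seqs)
    return int((mat != mat[0]).any(axis=0).sum())
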