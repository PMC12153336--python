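"""Mismatch-based read assignment: the desk model of aligner behaviour.

Each read is placed ungapped at every offset of every candidate gene region;
placements with more than ``max_mismatch`` mismatches are dropped, the rest
are scored ``match_bonus*(R-mm) - mismatch_penalty*mm`` (an alignment-score
analogue, monotone in the mismatch count).  A read is assigned to the unique
best-scoring gene; a best-score tie across distinct genes is discarded as a
multi-mapper.  A tie whose placements all point at one gene id is kept when
``gene_level_rescue`` is on — this is the behaviour the exon-splitting rescue
annotation exploits: the shared terminal segment of two paralogs is annotated
to one merged gene, so reads wholly inside it stop being cross-gene ties.

UMI deduplication keeps one effective read per (barcode, UMI, gene) group and
marks the rest PCR duplicates; the four read classes (effective, duplicate,
discarded multi-mapper, unmapped) are exhaustive and exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import CountMatrix, make_features
from .panels import AllelePanel
from .reads import ReadSet
from .util import seq_to_u8

CLASSES = ("effective", "pcr_duplicate", "discarded_multimap", "unmapped")
EFFECTIVE, PCR_DUPLICATE, DISCARDED_MULTIMAP, UNMAPPED = range(4)


@dataclass(frozen=True)
class AssignmentPolicy:
    max_mismatch: int = 6
    match_bonus: int = 1
    mismatch_penalty: int = 2
    gene_level_rescue: bool = True


@dataclass(frozen=True)
class Region:
    """A candidate alignment region (one terminal exon, transcript strand).

    ``segments`` optionally splits the region into gene-attribution intervals
    ``(start, end, gene_id)`` — used by the rescue annotation, where the 3'
    shared segment belongs to a merged gene.  A placement is attributed to
    the gene of the segment containing its start; the sequence itself is
    never split, so placements spanning a boundary stay alignable and keep
    the original gene.
    """

    region_id: str
    gene_id: str
    seq: str
    segments: tuple[tuple[int, int, str], ...] | None = None

    def gene_at(self, start: int) -> str:
        if self.segments is None:
            return self.gene_id
        for s, e, gid in self.segments:
            if s <= start < e:
                return gid
        return self.gene_id


@dataclass(frozen=True)
class CandidateAlignment:
    gene_id: str
    region_id: str
    offset: int
    mismatches: int
    score: int


@dataclass(frozen=True)
class AssignmentResult:
    read_id: str
    read_class: str
    assigned_gene: str | None
    mismatches: int | None
    barcode: str | None = None
    umi: str | None = None


def panel_regions(panel: AllelePanel) -> list[Region]:
    """Terminal-exon regions of every gene in the panel."""
    return [
        Region(f"{g}:{rec.terminal_exon.exon_id}", g, rec.terminal_exon.seq)
        for g, rec in panel.genes.items()
    ]


# ---------------------------------------------------------------------------
# Per-read operations (the reference implementation; bulk path mirrors it)
# ---------------------------------------------------------------------------


def align_read(
    read_sequence: str,
    regions: list[Region],
    policy: AssignmentPolicy = AssignmentPolicy(),
) -> list[CandidateAlignment]:
    """All ungapped placements with at most ``max_mismatch`` mismatches,
    sorted by (score desc, gene id asc, offset asc)."""
    if not regions:
        raise ValueError("empty region set")
    r = len(read_sequence)
    q = seq_to_u8(read_sequence)
    out: list[CandidateAlignment] = []
    for region in regions:
        if len(region.seq) < r:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(seq_to_u8(region.seq), r)
        mism = (windows != q).sum(axis=1)
        for off in np.nonzero(mism <= policy.max_mismatch)[0]:
            mm = int(mism[off])
            score = policy.match_bonus * (r - mm) - policy.mismatch_penalty * mm
            out.append(
                CandidateAlignment(region.gene_at(int(off)), region.region_id, int(off), mm, score)
            )
    out.sort(key=lambda c: (-c.score, c.gene_id, c.offset))
    return out


def assign_read(
    alignments: list[CandidateAlignment],
    policy: AssignmentPolicy = AssignmentPolicy(),
    read_id: str = "read",
    barcode: str | None = None,
    umi: str | None = None,
) -> AssignmentResult:
    """Unique-best-gene assignment with multi-gene discard.

    No retained placement -> unmapped.  If the best score is reached by a
    single gene id the read is assigned there (smallest offset recorded);
    with ``gene_level_rescue`` off, a single-gene tie across several
    placements is discarded too.  Best score shared by two or more gene ids
    -> discarded multi-mapper.
    """
    if not alignments:
        return AssignmentResult(read_id, "unmapped", None, None, barcode, umi)
    best = max(a.score for a in alignments)
    tied = [a for a in alignments if a.score == best]
    genes = sorted({a.gene_id for a in tied})
    if len(genes) > 1 or (len(tied) > 1 and not policy.gene_level_rescue):
        return AssignmentResult(read_id, "discarded_multimap", None, None, barcode, umi)
    first = min(tied, key=lambda a: a.offset)
    return AssignmentResult(read_id, "effective", genes[0], first.mismatches, barcode, umi)


# ---------------------------------------------------------------------------
# Bulk path
# ---------------------------------------------------------------------------


@dataclass
class AssignmentTable:
    """Columnar per-read assignment outcome (xf/GN/AS/nM analogues)."""

    gene_ids: tuple[str, ...]
    read_class: np.ndarray  # uint8 codes into CLASSES
    gene_code: np.ndarray  # int16, -1 when unassigned
    mismatches: np.ndarray  # int16, -1 when unassigned
    cell_index: np.ndarray
    umi: np.ndarray
    policy: AssignmentPolicy = field(default_factory=AssignmentPolicy)
    read_length: int = 0

    @property
    def n_reads(self) -> int:
        return int(self.read_class.size)

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.read_class, minlength=4)
        return {name: int(counts[i]) for i, name in enumerate(CLASSES)}

    def assigned_gene_names(self) -> np.ndarray:
        names = np.asarray(self.gene_ids + ("",), dtype=object)
        return names[self.gene_code]

    def scores(self) -> np.ndarray:
        r, p = self.read_length, self.policy
        mm = self.mismatches
        return np.where(mm >= 0, p.match_bonus * (r - mm) - p.mismatch_penalty * mm, -1)

    def to_frame(self, reads: ReadSet) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": reads.read_ids(),
                "barcode": reads.read_barcodes(),
                "umi": reads.umi_strings(),
                "xf": np.asarray(CLASSES, dtype=object)[self.read_class],
                "GN": self.assigned_gene_names(),
                "AS": self.scores(),
                "nM": self.mismatches,
            }
        )


def _region_placements(regions: list[Region], read_length: int):
    """Stacked windows of all regions: (windows, gene codes, offsets, ids)."""
    gene_ids: list[str] = []
    gene_code_of: dict[str, int] = {}
    win_blocks = []
    gene_codes = []
    offsets = []
    for region in regions:
        if len(region.seq) < read_length:
            continue
        arr = seq_to_u8(region.seq)
        win = np.lib.stride_tricks.sliding_window_view(arr, read_length)
        win_blocks.append(win)
        offs = np.arange(win.shape[0])
        offsets.append(offs)
        codes = np.empty(win.shape[0], dtype=np.int16)
        for i, off in enumerate(offs):
            gid = region.gene_at(int(off))
            if gid not in gene_code_of:
                gene_code_of[gid] = len(gene_ids)
                gene_ids.append(gid)
            codes[i] = gene_code_of[gid]
        gene_codes.append(codes)
    if not win_blocks:
        raise ValueError("no region long enough for the read length")
    return (
        np.vstack(win_blocks),
        np.concatenate(gene_codes),
        np.concatenate(offsets),
        tuple(gene_ids),
    )


def _classify_unique(
    queries: np.ndarray,
    windows: np.ndarray,
    win_gene: np.ndarray,
    policy: AssignmentPolicy,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised unique-best-gene decision for unique read sequences.

    Returns (class code, gene code, mismatches) per query row.
    """
    n = queries.shape[0]
    cls = np.full(n, UNMAPPED, dtype=np.uint8)
    gene = np.full(n, -1, dtype=np.int16)
    mism = np.full(n, -1, dtype=np.int16)
    n_genes = int(win_gene.max()) + 1 if win_gene.size else 0
    big = np.int32(windows.shape[1] + 1)
    for lo in range(0, n, chunk):
        q = queries[lo : lo + chunk]
        mm = (q[:, None, :] != windows[None, :, :]).sum(axis=2, dtype=np.int32)
        mm[mm > policy.max_mismatch] = big
        best = mm.min(axis=1)
        for row in range(q.shape[0]):
            b = best[row]
            if b == big:
                continue
            tied_genes = win_gene[mm[row] == b]
            uniq = np.unique(tied_genes)
            if uniq.size > 1 or (tied_genes.size > 1 and not policy.gene_level_rescue):
                cls[lo + row] = DISCARDED_MULTIMAP
            else:
                cls[lo + row] = EFFECTIVE
                gene[lo + row] = uniq[0]
                mism[lo + row] = b
        del mm
    return cls, gene, mism


def assign_reads(
    reads: ReadSet,
    regions: list[Region] | AllelePanel,
    policy: AssignmentPolicy = AssignmentPolicy(),
) -> AssignmentTable:
    """Bulk assignment of a ReadSet against a panel or explicit regions.

    Identical in outcome to applying :func:`align_read` + :func:`assign_read`
    per read (oracle-tested); error-free reads are deduplicated by their
    (true gene, offset) source before alignment, which makes error-free
    simulations effectively free of redundant work.
    """
    if isinstance(regions, AllelePanel):
        regions = panel_regions(regions)
    windows, win_gene, _win_off, gene_ids = _region_placements(regions, reads.read_length)

    n = reads.n_reads
    cls = np.empty(n, dtype=np.uint8)
    gene = np.empty(n, dtype=np.int16)
    mism = np.empty(n, dtype=np.int16)

    err_mask = reads.has_errors()
    clean = np.nonzero(~err_mask)[0]
    errful = np.nonzero(err_mask)[0]

    if clean.size:
        exon_len = reads.allele_matrix.shape[1]
        key = reads.gene_codes[clean].astype(np.int64) * exon_len + reads.offsets[clean]
        uniq_key, inverse = np.unique(key, return_inverse=True)
        sorter = np.argsort(key, kind="stable")
        representatives = sorter[np.searchsorted(key, uniq_key, sorter=sorter)]
        uq = reads.sequence_matrix(clean[representatives])
        c, g, m = _classify_unique(uq, windows, win_gene, policy)
        cls[clean] = c[inverse]
        gene[clean] = g[inverse]
        mism[clean] = m[inverse]

    if errful.size:
        seqs = reads.sequence_matrix(errful)
        uq, inverse = np.unique(seqs, axis=0, return_inverse=True)
        c, g, m = _classify_unique(uq, windows, win_gene, policy)
        cls[errful] = c[inverse]
        gene[errful] = g[inverse]
        mism[errful] = m[inverse]

    return AssignmentTable(
        gene_ids=gene_ids,
        read_class=cls,
        gene_code=gene,
        mismatches=mism,
        cell_index=reads.cell_index.copy(),
        umi=reads.umi.copy(),
        policy=policy,
        read_length=reads.read_length,
    )


def dedup_umis(table: AssignmentTable) -> AssignmentTable:
    """Mark all but one read per (barcode, UMI, gene) group as PCR duplicates.

    The survivor is the lowest-mismatch, then first-seen read; unmapped and
    discarded reads are untouched.
    """
    cls = table.read_class.copy()
    assigned = np.nonzero((cls == EFFECTIVE) | (cls == PCR_DUPLICATE))[0]
    if assigned.size == 0:
        return replace(table, read_class=cls)
    key = (
        (table.cell_index[assigned].astype(np.uint64) << np.uint64(36))
        | (table.umi[assigned].astype(np.uint64) << np.uint64(12))
        | table.gene_code[assigned].astype(np.uint64)
    )
    order = np.lexsort((assigned, table.mismatches[assigned], key))
    sorted_key = key[order]
    first = np.concatenate([[True], sorted_key[1:] != sorted_key[:-1]])
    cls[assigned[order]] = np.where(first, EFFECTIVE, PCR_DUPLICATE).astype(np.uint8)
    return replace(table, read_class=cls)


def class_tallies(
    table: AssignmentTable, gene_subsets: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Per-class read counts, overall and restricted to gene subsets.

    A read belongs to a subset tally if its assigned gene is in the subset;
    unassigned classes are only tallied overall.
    """
    rows = {"all": table.class_counts()}
    if gene_subsets:
        names = np.asarray(table.gene_ids + ("",), dtype=object)
        assigned_names = names[table.gene_code]
        for label, genes in gene_subsets.items():
            in_set = np.isin(assigned_names, genes)
            sub = {}
            for code, cname in enumerate(CLASSES):
                mask = table.read_class == code
                if code in (EFFECTIVE, PCR_DUPLICATE):
                    sub[cname] = int((mask & in_set).sum())
                else:
                    sub[cname] = 0
            rows[label] = sub
    df = pd.DataFrame(rows).T
    df["total"] = df.sum(axis=1)
    return df


def quantify(
    table: AssignmentTable,
    whitelist: np.ndarray,
    barcodes_per_cell: np.ndarray,
    feature_order: list[str] | None = None,
) -> CountMatrix:
    """Effective-read counts per (whitelisted barcode, gene).

    ``barcodes_per_cell`` maps the table's cell indices to barcode strings;
    reads whose barcode is not whitelisted are tallied separately in the
    matrix's ``tallies`` attribute.
    """
    whitelist = np.asarray(whitelist)
    if whitelist.size == 0:
        raise ValueError("empty barcode whitelist")
    feature_order = feature_order or sorted(table.gene_ids)
    fcode = {g: i for i, g in enumerate(feature_order)}
    wl_row = {b: i for i, b in enumerate(whitelist)}
    cell_rows = np.asarray([wl_row.get(b, -1) for b in barcodes_per_cell], dtype=np.int64)

    eff = np.nonzero(table.read_class == EFFECTIVE)[0]
    rows = cell_rows[table.cell_index[eff]]
    in_wl = rows >= 0
    genes = np.asarray(
        [fcode[g] for g in np.asarray(table.gene_ids, dtype=object)[table.gene_code[eff]]],
        dtype=np.int64,
    )
    counts = np.zeros((whitelist.size, len(feature_order)), dtype=np.int64)
    np.add.at(counts, (rows[in_wl], genes[in_wl]), 1)

    tallies = pd.DataFrame(
        {
            "effective_whitelisted": [int(in_wl.sum())],
            "effective_other_barcode": [int((~in_wl).sum())],
            **{k: [v] for k, v in table.class_counts().items()},
        }
    )
    feats = make_features(feature_order, feature_class="isotype")
    return CountMatrix(counts, whitelist, feats, tallies)
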