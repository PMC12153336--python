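"""Synthetic allele panels for immunoglobulin isotype genes.

A panel holds, for one genome reference, the constant-region terminal exon
("CH3-CHS") of each isotype gene in transcript orientation.  Two panels built
from the same placement specs share gene structure but may carry different
alleles, emulating genome references of different ancestry (e.g. an
hg38-like and a T2T-like reference whose IGHG/IGHA alleles differ).

Variant placement is explicit: every difference between two paralogs within a
reference, and every difference between a gene's alleles across references,
is declared in a :class:`VariantPlacementSpec`.  The builder generates a
random background sequence per gene family and guarantees that declared
substitutions are present and no others, so downstream variant inventories
are exact by construction.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
TERMINAL_EXON_ID = "CH3-CHS"


class PlacementError(ValueError):
    """Inconsistent or out-of-range variant placement."""


class PanelError(ValueError):
    """Panel structure violates an invariant (duplicate ids, bad alphabet...)."""


@dataclass(frozen=True)
class Exon:
    """One exon, sequence in transcript orientation.

    ``coding_end`` is the 0-based exon offset at which the coding region ends
    (the stop-codon boundary); positions ``>= coding_end`` are 3'-UTR.  ``None``
    means no annotated boundary.
    """

    exon_id: str
    seq: str
    coding_end: int | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise PanelError(f"exon {self.exon_id}: empty sequence")
        if set(self.seq) - set(BASES):
            raise PanelError(f"exon {self.exon_id}: non-ACGT or lowercase characters")
        if self.coding_end is not None and not (0 <= self.coding_end <= len(self.seq)):
            raise PanelError(f"exon {self.exon_id}: coding_end outside exon")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    exons: tuple[Exon, ...]
    strand: str = "+"
    symbol: str | None = None
    allele_label: str = ""
    duplicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise PanelError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise PanelError(f"gene {self.gene_id}: no exons")
        object.__setattr__(self, "symbol", self.symbol or self.gene_id)

    @property
    def terminal_exon(self) -> Exon:
        """The 3'-most exon in transcript orientation (where 3' tag reads land)."""
        return self.exons[-1]


@dataclass
class AllelePanel:
    """Per-reference allele set with declared paralog pairs."""

    reference_name: str
    genes: dict[str, GeneRecord] = field(default_factory=dict)
    pairs: tuple[tuple[str, str], ...] = ()

    def validate(self) -> None:
        if len(self.genes) == 0:
            raise PanelError("empty panel")
        for gid, rec in self.genes.items():
            if gid != rec.gene_id:
                raise PanelError(f"gene key {gid!r} != record id {rec.gene_id!r}")
        for a, b in self.pairs:
            if a in self.genes and b in self.genes:
                if len(self.genes[a].exons) != len(self.genes[b].exons):
                    raise PanelError(f"paralog pair ({a},{b}): unequal exon counts")

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise PanelError(f"gene {gene_id!r} not in panel {self.reference_name!r}") from None

    def terminal_seq(self, gene_id: str) -> str:
        return self.gene(gene_id).terminal_exon.seq

    def gene_ids(self) -> list[str]:
        return list(self.genes)


@dataclass(frozen=True)
class VariantPlacementSpec:
    """Declared substitutions for one paralog pair.

    ``pair_variants`` maps a reference name to ``(position, base_in_gene_a,
    base_in_gene_b)`` rows; ``cross_variants`` maps a gene id to ``(position,
    base_in_ref_a, base_in_ref_b)`` rows.  A base of ``None`` means "the family
    background base at that position" — the builder chooses backgrounds so that
    a ``None`` never collides with an explicitly declared base at that column.
    """

    pair_id: str
    gene_a: str
    gene_b: str
    exon_id: str = TERMINAL_EXON_ID
    pair_variants: Mapping[str, Sequence[tuple[int, str | None, str | None]]] = field(
        default_factory=dict
    )
    cross_variants: Mapping[str, Sequence[tuple[int, str | None, str | None]]] = field(
        default_factory=dict
    )


@dataclass(frozen=True)
class DuplicationSpec:
    """An extra copy of a gene present in one reference only (IGHG4-style).

    ``substitutions`` are relative to the family background plus the source
    gene's constant (both-reference) columns.
    """

    gene: str
    reference: str
    copy_gene_id: str
    substitutions: Sequence[tuple[int, str]] = ()


def _families(
    specs: Sequence[VariantPlacementSpec], extra_genes: Sequence[str]
) -> list[list[str]]:
    """Connected components of the paralog-pair graph, insertion-ordered."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order: list[str] = []
    for sp in specs:
        for g in (sp.gene_a, sp.gene_b):
            if g not in parent:
                parent[g] = g
                order.append(g)
        ra, rb = find(sp.gene_a), find(sp.gene_b)
        if ra != rb:
            parent[rb] = ra
    for g in extra_genes:
        if g not in parent:
            parent[g] = g
            order.append(g)
    comps: dict[str, list[str]] = {}
    for g in order:
        comps.setdefault(find(g), []).append(g)
    return list(comps.values())


def build_allele_panel(
    specs: Sequence[VariantPlacementSpec],
    base_exon_length: int = 300,
    seed: int = 0,
    reference_names: tuple[str, str] = ("refA", "refB"),
    extra_genes: Sequence[str] = (),
    duplications: Sequence[DuplicationSpec] = (),
    coding_end: int | Mapping[str, int] | None = None,
    strands: Mapping[str, str] | None = None,
    allele_labels: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[AllelePanel, AllelePanel]:
    """Build a pair of panels realising the declared substitutions exactly.

    Returns ``(panel_a, panel_b)`` for ``reference_names``.  Deterministic given
    ``seed``: the family background sequences and nothing else are random.
    """
    ref_a, ref_b = reference_names
    families = _families(specs, extra_genes)
    gene_family = {g: i for i, fam in enumerate(families) for g in fam}

    # Resolve declared bases to per-(gene, reference, position) assignments.
    assigned: dict[tuple[str, str, int], str | None] = {}

    def put(gene: str, ref: str, pos: int, base: str | None) -> None:
        if base is not None and base not in BASES:
            raise PlacementError(f"base {base!r} at {gene}/{ref}:{pos} not in {BASES}")
        key = (gene, ref, pos)
        if key in assigned and assigned[key] != base:
            raise PlacementError(
                f"conflicting bases at {gene}/{ref} position {pos}: "
                f"{assigned[key]!r} vs {base!r}"
            )
        assigned[key] = base

    for sp in specs:
        for ref, rows in sp.pair_variants.items():
            if ref not in reference_names:
                raise PlacementError(f"unknown reference {ref!r} in spec {sp.pair_id}")
            for pos, ba, bb in rows:
                if not (0 <= pos < base_exon_length):
                    raise PlacementError(f"{sp.pair_id}: position {pos} outside exon")
                if ba == bb:
                    raise PlacementError(
                        f"{sp.pair_id}: pair variant at {pos} must differ between genes"
                    )
                put(sp.gene_a, ref, pos, ba)
                put(sp.gene_b, ref, pos, bb)
        for gene, rows in sp.cross_variants.items():
            for pos, bra, brb in rows:
                if not (0 <= pos < base_exon_length):
                    raise PlacementError(f"{sp.pair_id}: position {pos} outside exon")
                if bra == brb:
                    raise PlacementError(
                        f"{sp.pair_id}: cross-reference variant at {pos} must differ"
                    )
                put(gene, ref_a, pos, bra)
                put(gene, ref_b, pos, brb)

    dup_by_gene: dict[str, list[DuplicationSpec]] = {}
    for dup in duplications:
        if dup.reference not in reference_names:
            raise PlacementError(f"duplication of {dup.gene}: unknown reference")
        dup_by_gene.setdefault(dup.gene, []).append(dup)

    # Per family: background avoiding every explicitly declared base per column.
    backgrounds: dict[int, np.ndarray] = {}
    for fam_idx, fam in enumerate(families):
        rng = np.random.default_rng(np.random.SeedSequence([seed, fam_idx]))
        bg = rng.choice(list(BASES), size=base_exon_length)
        taken: dict[int, set[str]] = {}
        for (gene, _ref, pos), base in assigned.items():
            if gene in fam and base is not None:
                taken.setdefault(pos, set()).add(base)
        for dup in duplications:
            if dup.gene in fam:
                for pos, base in dup.substitutions:
                    taken.setdefault(pos, set()).add(base)
        for pos, bases in taken.items():
            if len(bases) >= len(BASES):
                raise PlacementError(f"position {pos}: all four bases declared")
            if bg[pos] in bases:
                choices = [b for b in BASES if b not in bases]
                bg[pos] = choices[rng.integers(len(choices))]
        backgrounds[fam_idx] = bg

    def coding_end_for(gene: str) -> int | None:
        if coding_end is None:
            return None
        if isinstance(coding_end, Mapping):
            return coding_end.get(gene)
        return int(coding_end)

    def build_seq(gene: str, ref: str) -> str:
        bg = backgrounds[gene_family[gene]].copy()
        for pos in range(base_exon_length):
            base = assigned.get((gene, ref, pos))
            if base is not None:
                bg[pos] = base
        return "".join(bg)

    def constant_columns(gene: str) -> dict[int, str]:
        cols: dict[int, str] = {}
        for pos in range(base_exon_length):
            a = assigned.get((gene, ref_a, pos))
            b = assigned.get((gene, ref_b, pos))
            if a is not None and a == b:
                cols[pos] = a
        return cols

    strands = strands or {}
    allele_labels = allele_labels or {}
    gene_order = [g for fam in families for g in fam]
    panels: list[AllelePanel] = []
    pair_list = tuple((sp.gene_a, sp.gene_b) for sp in specs)
    for ref in reference_names:
        genes: dict[str, GeneRecord] = {}
        for g in gene_order:
            exon = Exon(TERMINAL_EXON_ID, build_seq(g, ref), coding_end_for(g))
            genes[g] = GeneRecord(
                gene_id=g,
                exons=(exon,),
                strand=strands.get(g, "+"),
                allele_label=allele_labels.get(ref, {}).get(g, ""),
            )
            for dup in dup_by_gene.get(g, ()):
                if dup.reference != ref:
                    continue
                bg = backgrounds[gene_family[g]].copy()
                for pos, base in constant_columns(g).items():
                    bg[pos] = base
                for pos, base in dup.substitutions:
                    if not (0 <= pos < base_exon_length):
                        raise PlacementError(
                            f"duplication {dup.copy_gene_id}: position {pos} outside exon"
                        )
                    bg[pos] = base
                exon_d = Exon(TERMINAL_EXON_ID, "".join(bg), coding_end_for(g))
                genes[dup.copy_gene_id] = GeneRecord(
                    gene_id=dup.copy_gene_id,
                    exons=(exon_d,),
                    strand=strands.get(g, "+"),
                    symbol=g,
                    duplicate_of=g,
                )
        panel = AllelePanel(reference_name=ref, genes=genes, pairs=pair_list)
        panel.validate()
        panels.append(panel)
    return panels[0], panels[1]


# ---------------------------------------------------------------------------
# Default study panel: an hg38-like / T2T-like reference pair.
#
# The layout realises the variant inventories the divergence analysis expects:
#   * 28 family variant columns among the IGHG CH3-CHS exons in the hg38-like
#     reference and 34 in the T2T-like one (counting both IGHG4 copies);
#   * IGHG1 differing between references at 5 coding + 8 UTR columns,
#     IGHG2 at 1 + 3, IGHG3 at a single UTR column near the exon end;
#   * a duplicated IGHG4 in the T2T-like reference (copy 1: two coding
#     variants; copy 2: one coding + six UTR variants vs the hg38-like allele);
#   * an IGHA1/IGHA2 pair with nine hg38-only variants spread over the 3'
#     block (identical there in the T2T-like reference -> the "blue" region),
#     one T2T-only variant in the interior (the "orange" region) and three
#     constant variants at the 5' end (the "red" region);
#   * a designated 3' window of IGHG2 over which a donor read carrying the
#     T2T-like allele shows the (2, 1, 0, 7) mismatch pattern against
#     IGHG2-hg38like / IGHG1-hg38like / IGHG2-t2tlike / IGHG1-t2tlike.
# ---------------------------------------------------------------------------

REF_A = "hg38_like"
REF_B = "t2t_like"

EXON_LENGTH = 300
READ_LENGTH = 90

#: 0-based half-open start/end of the illustrative-read window in the IGHG
#: terminal exon (transcript coordinates).
WORKED_READ_WINDOW = (180, 270)

ISOTYPE_GENES = (
    "IGHM",
    "IGHD",
    "IGHG3",
    "IGHG1",
    "IGHG2",
    "IGHG4",
    "IGHE",
    "IGHA1",
    "IGHA2",
)

_G = {"coding_end": 150}


def default_panel_specs() -> dict:
    """Placement specs for the default hg38-like / T2T-like panel pair."""
    ighg12 = VariantPlacementSpec(
        pair_id="IGHG1/IGHG2",
        gene_a="IGHG1",
        gene_b="IGHG2",
        pair_variants={
            # one column where IGHG1 differs from IGHG2 in both references
            REF_A: [(250, "T", None)],
            REF_B: [(250, "T", None)],
        },
        cross_variants={
            # IGHG1: 5 coding + 8 UTR columns differ across references
            "IGHG1": [
                (20, "A", None),
                (40, "C", None),
                (60, "G", None),
                (80, "T", None),
                (120, "A", None),
                (155, "C", None),
                (170, "A", "G"),
                (190, None, "T"),
                (200, None, "A"),
                (210, None, "C"),
                (220, None, "G"),
                (230, None, "T"),
                (240, None, "A"),
            ],
            # IGHG2: 1 coding + 3 UTR columns differ across references
            "IGHG2": [
                (100, "G", None),
                (185, "C", None),
                (255, "A", None),
                (275, "T", None),
            ],
        },
    )
    ighg13 = VariantPlacementSpec(
        pair_id="IGHG1/IGHG3",
        gene_a="IGHG1",
        gene_b="IGHG3",
        pair_variants={
            # IGHG3 private columns, identical in both references
            ref: [
                (5, None, "T"),
                (35, None, "A"),
                (65, None, "C"),
                (95, None, "G"),
                (125, None, "T"),
                (158, None, "A"),
                (188, None, "C"),
                (248, None, "G"),
            ]
            for ref in (REF_A, REF_B)
        },
        cross_variants={
            # IGHG3: single UTR variant near the exon end
            "IGHG3": [(295, None, "G")],
        },
    )
    ighg14 = VariantPlacementSpec(
        pair_id="IGHG1/IGHG4",
        gene_a="IGHG1",
        gene_b="IGHG4",
        pair_variants={
            # IGHG4 private columns, identical in both references
            ref: [
                (12, None, "G"),
                (48, None, "T"),
                (112, None, "A"),
                (162, None, "C"),
                (205, None, "G"),
                (235, None, "T"),
                (265, None, "A"),
                (293, None, "C"),
            ]
            for ref in (REF_A, REF_B)
        },
        cross_variants={
            # IGHG4 copy 1: two coding variants in the T2T-like reference
            "IGHG4": [(10, None, "C"), (30, None, "G")],
        },
    )
    igha = VariantPlacementSpec(
        pair_id="IGHA1/IGHA2",
        gene_a="IGHA1",
        gene_b="IGHA2",
        pair_variants={
            # "red": three columns distinguishing the pair in both references
            ref: [(30, "C", None), (45, "G", None), (60, "T", None)]
            for ref in (REF_A, REF_B)
        },
        cross_variants={
            # nine hg38-only pair variants over the 3' block ("blue" when absent
            # in the T2T-like reference) + one T2T-only interior variant
            # ("orange")
            "IGHA2": [
                (170, "A", None),
                (183, "C", None),
                (196, "G", None),
                (209, "T", None),
                (222, "A", None),
                (235, "C", None),
                (248, "G", None),
                (261, "T", None),
                (285, "A", None),
                (100, None, "C"),
            ],
        },
    )
    duplications = (
        DuplicationSpec(
            gene="IGHG4",
            reference=REF_B,
            copy_gene_id="IGHG4B",
            # copy 2: one coding + six UTR variants vs the hg38-like allele
            substitutions=(
                (70, "A"),
                (160, "C"),
                (175, "G"),
                (260, "T"),
                (270, "A"),
                (280, "C"),
                (290, "G"),
            ),
        ),
    )
    return {
        "specs": (ighg12, ighg13, ighg14, igha),
        "duplications": duplications,
        "extra_genes": ("IGHM", "IGHD", "IGHE"),
        "coding_end": {
            "IGHG1": 150,
            "IGHG2": 150,
            "IGHG3": 150,
            "IGHG4": 150,
            "IGHA1": 190,
            "IGHA2": 190,
            "IGHM": 150,
            "IGHD": 150,
            "IGHE": 150,
        },
        # IGH constant-region genes lie on the minus strand of chromosome 14
        "strands": {g: "-" for g in ISOTYPE_GENES},
        "allele_labels": {
            REF_A: {
                "IGHG3": "IGHG3*01",
                "IGHG1": "IGHG1*02",
                "IGHG2": "IGHG2*06",
            },
            REF_B: {
                "IGHG3": "IGHG3*11",
                "IGHG1": "IGHG1*03",
                "IGHG2": "IGHG2*02",
            },
        },
    }


def default_reference_pair(seed: int = 0) -> tuple[AllelePanel, AllelePanel]:
    """The default hg38-like / T2T-like panel pair used across the pipeline."""
    kw = default_panel_specs()
    return build_allele_panel(
        kw.pop("specs"),
        base_exon_length=EXON_LENGTH,
        seed=seed,
        reference_names=(REF_A, REF_B),
        **kw,
    )


def illustrative_read(panel_b: AllelePanel, window: tuple[int, int] = WORKED_READ_WINDOW) -> str:
    """The worked-example read: the donor IGHG2 allele (T2T-like reference)
    over the designated 3' window of the CH3-CHS exon."""
    start, end = window
    return panel_b.terminal_seq("IGHG2")[start:end]
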