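"""Fixture emission and parsing: FASTA, GTF 2.2, FASTQ, TSV.

The on-disk layout mirrors a miniature Cell Ranger custom reference: one
FASTA record per gene region (genomic orientation) plus a GTF annotating the
terminal exon (1-based closed coordinates, attributes ``gene_id``,
``transcript_id``, ``exon_id``) and the coding segment as a CDS record.
Reads are emitted both as a TSV with truth columns and as 10x-style paired
FASTQ (R1 = barcode+UMI, R2 = cDNA, Phred+33 quality "I").  Writers and
readers are inverse bijections so fixtures round-trip bit-exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import AllelePanel, Exon, GeneRecord, TERMINAL_EXON_ID
from .reads import ReadSet
from .util import revcomp

FASTA_WIDTH = 60


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                records[name] = []
            elif name is not None and line:
                records[name].append(line)
    return {k: "".join(v) for k, v in records.items()}


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

GTF_COLUMNS = (
    "seqname",
    "source",
    "feature",
    "start",
    "end",
    "score",
    "strand",
    "frame",
    "attributes",
)


def _attrs(**kv: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items())


def panel_gtf_records(panel: AllelePanel) -> pd.DataFrame:
    """One exon record per gene exon plus a CDS record when a coding/UTR
    boundary is annotated.  Each gene region is its own contig named by the
    gene id; coordinates are genomic (minus-strand exons are stored
    reverse-complemented in the FASTA)."""
    rows = []
    for gid, rec in panel.genes.items():
        for exon in rec.exons:
            L = len(exon.seq)
            attrs = _attrs(
                gene_id=gid,
                transcript_id=f"{gid}.t1",
                exon_id=exon.exon_id,
                gene_symbol=rec.symbol,
            )
            rows.append((gid, "igcall", "exon", 1, L, ".", rec.strand, ".", attrs))
            if exon.coding_end is not None and exon.coding_end > 0:
                if rec.strand == "+":
                    c_start, c_end = 1, exon.coding_end
                else:
                    c_start, c_end = L - exon.coding_end + 1, L
                rows.append((gid, "igcall", "CDS", c_start, c_end, ".", rec.strand, "0", attrs))
    return pd.DataFrame(rows, columns=GTF_COLUMNS)


def write_gtf(path: str | Path, records: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for _, r in records.iterrows():
            fh.write("\t".join(str(r[c]) for c in GTF_COLUMNS) + "\n")


def read_gtf(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=GTF_COLUMNS, comment="#", dtype={"frame": str}
    )
    for key in ("gene_id", "transcript_id", "exon_id"):
        df[key] = df["attributes"].str.extract(rf'{key} "([^"]*)"')
    return df


def panel_fasta_records(panel: AllelePanel) -> dict[str, str]:
    """Genomic-orientation sequences: minus-strand genes reverse-complemented."""
    out = {}
    for gid, rec in panel.genes.items():
        seq = rec.terminal_exon.seq
        out[gid] = revcomp(seq) if rec.strand == "-" else seq
    return out


def panel_from_files(
    fasta_path: str | Path, gtf_path: str | Path, reference_name: str
) -> AllelePanel:
    """Rebuild a panel from its FASTA + GTF (transcript orientation restored)."""
    seqs = read_fasta(fasta_path)
    gtf = read_gtf(gtf_path)
    exons = gtf[gtf["feature"] == "exon"]
    cds = gtf[gtf["feature"] == "CDS"].set_index("gene_id")
    genes: dict[str, GeneRecord] = {}
    for _, row in exons.iterrows():
        gid = row["gene_id"]
        contig = seqs[row["seqname"]]
        genomic = contig[row["start"] - 1 : row["end"]]
        strand = row["strand"]
        transcript = revcomp(genomic) if strand == "-" else genomic
        coding_end = None
        if gid in cds.index:
            crow = cds.loc[gid]
            coding_end = int(crow["end"] - crow["start"] + 1)
        symbol = None
        m = pd.Series([row["attributes"]]).str.extract(r'gene_symbol "([^"]*)"')
        if not m.isna().iloc[0, 0]:
            symbol = m.iloc[0, 0]
        genes[gid] = GeneRecord(
            gene_id=gid,
            exons=(Exon(row["exon_id"] or TERMINAL_EXON_ID, transcript, coding_end),),
            strand=strand,
            symbol=symbol,
        )
    panel = AllelePanel(reference_name=reference_name, genes=genes)
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

READS_TSV_COLUMNS = (
    "read_id",
    "barcode",
    "umi",
    "sequence",
    "true_gene",
    "true_offset",
    "molecule_id",
    "is_pcr_copy",
)


def write_reads_tsv(path: str | Path, reads: ReadSet) -> None:
    reads.to_frame().to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"barcode": str, "umi": str, "sequence": str, "true_gene": str},
    )


def write_fastq_pair(r1_path: str | Path, r2_path: str | Path, reads: ReadSet) -> None:
    ids = reads.read_ids()
    barcodes = reads.read_barcodes()
    umis = reads.umi_strings()
    seqs = reads.sequences()
    q1 = "I" * (len(barcodes[0]) + len(umis[0])) if reads.n_reads else ""
    q2 = "I" * reads.read_length
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for i in range(reads.n_reads):
            f1.write(f"@{ids[i]}\n{barcodes[i]}{umis[i]}\n+\n{q1}\n")
            f2.write(f"@{ids[i]}\n{seqs[i]}\n+\n{q2}\n")


def read_fastq(path: str | Path) -> pd.DataFrame:
    names, seqs, quals = [], [], []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            names.append(header.rstrip("\n")[1:])
            seqs.append(fh.readline().rstrip("\n"))
            fh.readline()
            quals.append(fh.readline().rstrip("\n"))
    return pd.DataFrame({"read_id": names, "sequence": seqs, "quality": quals})


# ---------------------------------------------------------------------------
# Bundled fixture writer
# ---------------------------------------------------------------------------


def write_fixtures(
    panel_a: AllelePanel,
    panel_b: AllelePanel,
    cells: pd.DataFrame,
    reads: ReadSet,
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Emit the full fixture bundle; refuses a non-empty directory unless
    ``overwrite`` is set.  Returns the map of emitted paths."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for panel in (panel_a, panel_b):
        sub = out / f"ref_{panel.reference_name}"
        sub.mkdir(exist_ok=True)
        write_fasta(sub / "panel.fa", panel_fasta_records(panel))
        write_gtf(sub / "annotation.gtf", panel_gtf_records(panel))
        paths[f"fasta_{panel.reference_name}"] = sub / "panel.fa"
        paths[f"gtf_{panel.reference_name}"] = sub / "annotation.gtf"
    write_reads_tsv(out / "reads.tsv", reads)
    write_fastq_pair(out / "reads_R1.fastq", out / "reads_R2.fastq", reads)
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    paths.update(
        reads_tsv=out / "reads.tsv",
        reads_r1=out / "reads_R1.fastq",
        reads_r2=out / "reads_R2.fastq",
        cells_tsv=out / "cells.tsv",
    )
    return paths
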