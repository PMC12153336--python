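"""End-to-end experiment orchestration.

``run_experiment`` drives the full chain for a panel pair: simulate cells and
donor reads, map them under each reference, quantify, add background counts,
QC, select ASCs (intersection of references), call isotypes, detect DP cells
and run the doublet diagnostic, then emit a cross-reference comparison and a
versioned machine-readable summary.  All randomness is seeded per stage, so
re-running a config reproduces byte-identical summaries.

``expected_dp_count`` provides the closed-form companion to the simulated DP
artifact: from the deterministic per-offset assignment profile of error-free
donor reads and the read-position distribution it computes each ASC cell's
probability of crossing both DP thresholds, giving the analytic DP count the
simulation is checked against.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .assignment import (
    AssignmentPolicy,
    AssignmentTable,
    EFFECTIVE,
    Region,
    align_read,
    assign_read,
    assign_reads,
    class_tallies,
    dedup_umis,
    panel_regions,
    quantify,
)
from .background import add_background_counts
from .calling import (
    DPThresholds,
    QCParams,
    call_isotypes,
    detect_dp,
    doublet_diagnostic,
    qc_filter,
    select_ascs,
)
from .cells import simulate_cells
from .matrix import CountMatrix
from .panels import AllelePanel, REF_A, REF_B, default_reference_pair
from .reads import ReadSet, offset_distribution, simulate_reads

SUMMARY_SCHEMA_VERSION = 1

#: Default isotype mix: an IgG-dominated bone-marrow plasma-cell population.
DEFAULT_PROPORTIONS = {
    "IGHG1": 0.32,
    "IGHG2": 0.27,
    "IGHG3": 0.13,
    "IGHG4": 0.05,
    "IGHM": 0.09,
    "IGHD": 0.02,
    "IGHE": 0.01,
    "IGHA1": 0.06,
    "IGHA2": 0.05,
}


class ExperimentError(RuntimeError):
    pass


@dataclass
class ExperimentConfig:
    n_cells: int = 5000
    isotype_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    doublet_rate: float = 0.02
    libsize_log_mean: float = 7.3
    libsize_log_sd: float = 0.5
    read_length: int = 90
    error_rate: float = 0.0
    position_bias: str = "3prime-geometric"
    geometric_p: float = 0.02
    pcr_duplication_mean: float = 1.0
    donor_reference: str = REF_B
    max_mismatch: int = 6
    gene_level_rescue: bool = True
    call_threshold: float = 0.85
    qc: QCParams = field(default_factory=QCParams)
    dp_thresholds: DPThresholds = field(default_factory=DPThresholds)
    apply_qc: bool = True
    with_background: bool = True
    #: control mode: both references carry the donor's alleles, isolating the
    #: pipeline from any reference-mismatch effect
    identical_panels: bool = False
    panel_seed: int = 0
    cells_seed: int = 1
    reads_seed: int = 2
    background_seed: int = 3

    @property
    def policy(self) -> AssignmentPolicy:
        return AssignmentPolicy(
            max_mismatch=self.max_mismatch, gene_level_rescue=self.gene_level_rescue
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["qc"] = dataclasses.asdict(self.qc)
        d["dp_thresholds"] = [
            [g1, g2, t1, t2] for (g1, g2), (t1, t2) in self.dp_thresholds.thresholds.items()
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "qc" in d and isinstance(d["qc"], dict):
            qc = dict(d["qc"])
            for key in ("ribosomal_patterns", "mito_patterns", "ig_patterns"):
                if key in qc:
                    qc[key] = tuple(qc[key])
            d["qc"] = QCParams(**qc)
        if "dp_thresholds" in d and isinstance(d["dp_thresholds"], list):
            d["dp_thresholds"] = DPThresholds(
                {(g1, g2): (t1, t2) for g1, g2, t1, t2 in d["dp_thresholds"]}
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        s = sum(self.isotype_proportions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"isotype proportions sum to {s}")
        if self.donor_reference not in (REF_A, REF_B):
            raise ValueError(f"unknown donor reference {self.donor_reference!r}")


@dataclass
class ReferenceResult:
    reference: str
    assignment: AssignmentTable
    matrix: CountMatrix  # isotype + background counts, pre-QC
    matrix_qc: CountMatrix
    qc_report: pd.DataFrame
    tallies: pd.DataFrame
    call_table: pd.DataFrame | None = None
    dp_flags: pd.DataFrame | None = None
    dp_summary: pd.DataFrame | None = None
    diagnostics: dict | None = None


@dataclass
class ExperimentBundle:
    config: ExperimentConfig
    cells: pd.DataFrame
    reads: ReadSet
    panels: dict[str, AllelePanel]
    results: dict[str, ReferenceResult]
    asc_barcodes: np.ndarray
    comparison: dict | None
    summary: dict


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> ExperimentBundle:
    """Run the full simulate -> map(A,B) -> QC -> call -> DP/doublet chain."""
    config.validate()
    chash = config.config_hash()
    stage = "setup"

    def fail(exc: Exception):
        raise ExperimentError(f"stage {stage!r} failed (config {chash}): {exc}") from exc

    try:
        stage = "panels"
        panel_a, panel_b = default_reference_pair(config.panel_seed)
        panels = {panel_a.reference_name: panel_a, panel_b.reference_name: panel_b}
        if config.identical_panels:
            donor = panels[config.donor_reference]
            for name in list(panels):
                if name != config.donor_reference:
                    panels[name] = AllelePanel(name, donor.genes, donor.pairs)
        stage = "cells"
        cells = simulate_cells(
            config.n_cells,
            config.isotype_proportions,
            doublet_rate=config.doublet_rate,
            libsize_log_mean=config.libsize_log_mean,
            libsize_log_sd=config.libsize_log_sd,
            seed=config.cells_seed,
        )
        stage = "reads"
        reads = simulate_reads(
            panels[config.donor_reference],
            cells,
            read_length=config.read_length,
            error_rate=config.error_rate,
            position_bias=config.position_bias,
            geometric_p=config.geometric_p,
            pcr_duplication_mean=config.pcr_duplication_mean,
            seed=config.reads_seed,
        )
        results: dict[str, ReferenceResult] = {}
        for ref, panel in panels.items():
            stage = f"map[{ref}]"
            table = dedup_umis(assign_reads(reads, panel, config.policy))
            iso = quantify(
                table,
                whitelist=cells["barcode"].to_numpy(),
                barcodes_per_cell=cells["barcode"].to_numpy(),
                feature_order=list(panel.genes),
            )
            tall = class_tallies(
                table,
                gene_subsets={
                    "IGHG": [g for g in panel.genes if g.startswith("IGHG")],
                    "IGHA": [g for g in panel.genes if g.startswith("IGHA")],
                },
            )
            stage = f"background[{ref}]"
            mat = (
                add_background_counts(iso, cells, seed=config.background_seed)
                if config.with_background
                else iso
            )
            stage = f"qc[{ref}]"
            if config.apply_qc:
                mat_qc, report = qc_filter(mat, config.qc)
            else:
                mat_qc, report = mat, pd.DataFrame(columns=["step", "removed", "order"])
            results[ref] = ReferenceResult(
                reference=ref,
                assignment=table,
                matrix=mat,
                matrix_qc=mat_qc,
                qc_report=report,
                tallies=tall,
            )
        stage = "asc_selection"
        ra, rb = results[REF_A], results[REF_B]
        asc = select_ascs(
            ra.matrix_qc,
            config.qc.ig_patterns,
            config.qc.min_ig_fraction_for_asc,
            other=rb.matrix_qc,
        )
        stage = "isotype_calls"
        for ref, res in results.items():
            sub = res.matrix_qc.subset_barcodes(asc)
            isotype_genes = [
                g for g in res.matrix.features.index
                if res.matrix.features.loc[g, "feature_class"] == "isotype"
                and g in sub.features.index
            ]
            res.call_table = call_isotypes(sub, isotype_genes, config.call_threshold)
            flags, summary = detect_dp(sub, config.dp_thresholds)
            res.dp_flags, res.dp_summary = flags, summary
            res.diagnostics = {}
            lib = sub.cell_totals()
            for col in flags.columns:
                res.diagnostics[col] = doublet_diagnostic(
                    flags[col].to_numpy(), lib, seed=config.reads_seed
                )
        stage = "comparison"
        comparison = compare_outputs(ra, rb, asc)
        stage = "summary"
        summary = _build_summary(config, chash, cells, results, asc, comparison)
    except ExperimentError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        fail(exc)

    bundle = ExperimentBundle(
        config=config,
        cells=cells,
        reads=reads,
        panels=panels,
        results=results,
        asc_barcodes=asc,
        comparison=comparison,
        summary=summary,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _json_safe(obj.tolist())
    return obj


def _build_summary(config, chash, cells, results, asc, comparison) -> dict:
    per_ref = {}
    for ref, res in results.items():
        per_ref[ref] = {
            "class_counts": res.assignment.class_counts(),
            "qc_report": res.qc_report.set_index("step")["removed"].to_dict()
            if len(res.qc_report)
            else {},
            "n_cells_post_qc": res.matrix_qc.n_cells,
            "dp_counts": {
                f"{r.gene1}/{r.gene2}": int(r.n_dp) for r in res.dp_summary.itertuples()
            }
            if res.dp_summary is not None
            else {},
            "doublet_diagnostics": {
                k: {kk: vv for kk, vv in v.items() if kk != "skipped"}
                for k, v in (res.diagnostics or {}).items()
            },
            "call_counts": res.call_table["call"].value_counts().to_dict()
            if res.call_table is not None
            else {},
        }
    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "config_hash": chash,
        "seeds": {
            "panel": config.panel_seed,
            "cells": config.cells_seed,
            "reads": config.reads_seed,
            "background": config.background_seed,
        },
        "n_cells_simulated": int(len(cells)),
        "n_planted_doublets": int(cells["is_doublet"].sum()),
        "n_asc": int(len(asc)),
        "references": per_ref,
        "correlations": comparison.get("correlations", {}) if comparison else {},
    }
    return _json_safe(summary)


def validate_summary(summary: dict) -> None:
    """Minimal schema check for the versioned summary JSON."""
    required = {"schema_version", "config_hash", "seeds", "references", "n_asc"}
    missing = required - summary.keys()
    if missing:
        raise ValueError(f"summary missing keys: {sorted(missing)}")
    if summary["schema_version"] != SUMMARY_SCHEMA_VERSION:
        raise ValueError("unsupported summary schema version")


def write_bundle(bundle: ExperimentBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.config.to_yaml(out / "config.yaml")
    for ref, res in bundle.results.items():
        sub = out / ref
        res.matrix.write_mtx(sub / "matrix_raw")
        res.matrix_qc.write_mtx(sub / "matrix_qc")
        res.qc_report.to_csv(sub / "qc_report.tsv", sep="\t", index=False)
        res.tallies.to_csv(sub / "class_tallies.tsv", sep="\t")
        if res.call_table is not None:
            res.call_table.to_csv(sub / "isotype_calls.tsv", sep="\t")
        if res.dp_summary is not None:
            res.dp_summary.to_csv(sub / "dp_summary.tsv", sep="\t", index=False)
        if res.dp_flags is not None:
            res.dp_flags.to_csv(sub / "dp_flags.tsv", sep="\t")
    if bundle.comparison:
        for name, df in bundle.comparison.items():
            if isinstance(df, pd.DataFrame):
                df.to_csv(out / f"compare_{name}.tsv", sep="\t")
    with open(out / "summary.json", "w") as fh:
        json.dump(bundle.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Cross-reference comparison
# ---------------------------------------------------------------------------


def compare_outputs(res_a: ReferenceResult, res_b: ReferenceResult, asc: np.ndarray) -> dict:
    """Pair per-cell metrics across references over the shared ASC barcodes."""
    if len(asc) == 0:
        raise ValueError("empty barcode intersection")
    sub_a = res_a.matrix_qc.subset_barcodes(asc)
    sub_b = res_b.matrix_qc.subset_barcodes(asc)
    per_cell = pd.DataFrame(
        {
            "reads_a": sub_a.cell_totals(),
            "reads_b": sub_b.cell_totals(),
            "genes_a": (sub_a.counts > 0).sum(axis=1),
            "genes_b": (sub_b.counts > 0).sum(axis=1),
        },
        index=pd.Index(asc, name="barcode"),
    )
    shared_genes = [g for g in sub_a.features.index if g in set(sub_b.features.index)]
    tot_a = np.maximum(sub_a.cell_totals().astype(float), 1)
    tot_b = np.maximum(sub_b.cell_totals().astype(float), 1)
    gene_rows = {}
    for g in shared_genes:
        gene_rows[f"percent_{g}_a"] = 100.0 * sub_a.column(g) / tot_a
        gene_rows[f"percent_{g}_b"] = 100.0 * sub_b.column(g) / tot_b
    per_gene = pd.DataFrame(gene_rows, index=per_cell.index)
    correlations = {}
    for metric in ("reads", "genes"):
        x, y = per_cell[f"{metric}_a"], per_cell[f"{metric}_b"]
        if x.std() > 0 and y.std() > 0:
            correlations[f"{metric}_pearson"] = float(scipy.stats.pearsonr(x, y)[0])
            correlations[f"{metric}_spearman"] = float(scipy.stats.spearmanr(x, y)[0])
    marker_like = [
        g
        for g in sub_a.features.index
        if sub_a.features.loc[g, "feature_class"] in ("marker", "background")
        and g in set(sub_b.features.index)
    ]
    for g in marker_like[:2]:
        x = expressionless_percent(sub_a, g)
        y = expressionless_percent(sub_b, g)
        if x.std() > 0 and y.std() > 0:
            correlations[f"{g}_pearson"] = float(scipy.stats.pearsonr(x, y)[0])
    return {"per_cell": per_cell, "per_gene": per_gene, "correlations": correlations}


def expressionless_percent(matrix: CountMatrix, gene: str) -> np.ndarray:
    return 100.0 * matrix.column(gene) / np.maximum(matrix.cell_totals().astype(float), 1)


# ---------------------------------------------------------------------------
# Analytic DP expectation
# ---------------------------------------------------------------------------


def offset_assignment_profile(
    donor_panel: AllelePanel,
    ref_regions: list[Region] | AllelePanel,
    true_gene: str,
    read_length: int,
    policy: AssignmentPolicy = AssignmentPolicy(),
) -> pd.DataFrame:
    """Deterministic fate of an error-free donor read per start offset."""
    if isinstance(ref_regions, AllelePanel):
        ref_regions = panel_regions(ref_regions)
    seq = donor_panel.terminal_seq(true_gene)
    rows = []
    for off in range(len(seq) - read_length + 1):
        window = seq[off : off + read_length]
        res = assign_read(align_read(window, ref_regions, policy), policy)
        rows.append((off, res.read_class, res.assigned_gene))
    return pd.DataFrame(rows, columns=["offset", "read_class", "assigned_gene"])


def assignment_probabilities(
    donor_panel: AllelePanel,
    ref_regions: list[Region] | AllelePanel,
    genes: list[str],
    read_length: int,
    position_bias: str,
    geometric_p: float,
    policy: AssignmentPolicy = AssignmentPolicy(),
) -> dict[str, dict[str, float]]:
    """For each donor true gene, the probability that a read is assigned to
    each reference gene under the position distribution."""
    out: dict[str, dict[str, float]] = {}
    for g in genes:
        prof = offset_assignment_profile(donor_panel, ref_regions, g, read_length, policy)
        probs = offset_distribution(len(prof) - 1, position_bias, geometric_p)
        q: dict[str, float] = {}
        eff = prof["read_class"] == "effective"
        for gene, mass in zip(prof.loc[eff, "assigned_gene"], probs[prof.loc[eff, "offset"]]):
            q[gene] = q.get(gene, 0.0) + float(mass)
        out[g] = q
    return out


def _sf_sum_binom(k: int, parts: list[tuple[int, float]]) -> float:
    """P(sum of independent binomials > k), exact by convolution up to k."""
    parts = [(n, p) for n, p in parts if n > 0 and p > 0]
    if not parts:
        return 0.0
    if sum(n * p for n, p in parts) > 50 * (k + 1):
        return 1.0  # threshold is far below the mean; tail mass below it is negligible
    pmf = np.zeros(k + 1)
    pmf[0] = 1.0
    for n, p in parts:
        comp = scipy.stats.binom.pmf(np.arange(k + 1), n, p)
        pmf = np.convolve(pmf, comp)[: k + 1]
    return float(1.0 - pmf.sum())


def expected_dp_count(
    cells: pd.DataFrame,
    asc_barcodes: np.ndarray,
    totals: np.ndarray,
    q: dict[str, dict[str, float]],
    pair: tuple[str, str],
    thresholds: tuple[float, float],
) -> float:
    """Analytic expected number of DP cells for a gene pair among ASCs.

    For each ASC cell, molecule counts per truth component are binomially
    thinned by the assignment probabilities ``q[true_gene][assigned_gene]``
    and the probability that both genes' counts exceed their
    percent-of-total thresholds (computed against the realised cell totals
    ``totals``) is accumulated.
    """
    g1, g2 = pair
    t1, t2 = thresholds
    truth = cells.set_index("barcode").loc[asc_barcodes]
    expect = 0.0
    for (_, row), total in zip(truth.iterrows(), totals):
        comps = [(row["true_isotype"], int(row["library_size_primary"]))]
        if row["is_doublet"]:
            comps.append((row["second_isotype"], int(row["library_size_secondary"])))
        parts1 = [(n, q.get(g, {}).get(g1, 0.0)) for g, n in comps]
        parts2 = [(n, q.get(g, {}).get(g2, 0.0)) for g, n in comps]
        k1 = int(np.floor(t1 * total / 100.0))
        k2 = int(np.floor(t2 * total / 100.0))
        p1 = _sf_sum_binom(k1, parts1)
        p2 = _sf_sum_binom(k2, parts2)
        expect += p1 * p2
    return expect
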