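"""QC filtering, ASC selection, isotype calls and DP detection."""

import numpy as np
import pandas as pd
import pytest

from igcall import (
    DPThresholds,
    QCParams,
    call_isotypes,
    detect_dp,
    doublet_diagnostic,
    expression_value,
    qc_filter,
    select_ascs,
)
from igcall.matrix import CountMatrix, make_features


def build_matrix(counts, gene_ids, classes, barcodes=None):
    counts = np.asarray(counts, dtype=np.int64)
    barcodes = barcodes if barcodes is not None else np.array(
        [f"BC{i:04d}" for i in range(counts.shape[0])]
    )
    return CountMatrix(counts, barcodes, make_features(gene_ids, feature_class=classes))


@pytest.fixture()
def qc_matrix(rng):
    """2000 cells x (2 isotype + 1 mito + 2 ribo + 40 background) genes with
    planted QC violations."""
    n = 2000
    genes = ["IGHG1", "IGHG2", "MT-G01", "RPS01", "RPL01"] + [f"BG{i:03d}" for i in range(40)]
    classes = ["isotype"] * 2 + ["mito"] + ["ribo"] * 2 + ["background"] * 40
    counts = rng.poisson(40, size=(n, len(genes)))
    counts[:, 2] = rng.poisson(30, n)  # mito ~ a few % of ~1800 totals
    high_mito = rng.choice(n, 60, replace=False)
    counts[high_mito, 2] = 5000
    shallow = rng.choice(np.setdiff1d(np.arange(n), high_mito), 50, replace=False)
    counts[shallow] = 0
    counts[shallow, 0] = 5
    rare_gene = 5  # BG000 expressed in almost no cells
    counts[:, rare_gene] = 0
    counts[:3, rare_gene] = 1
    return build_matrix(counts, genes, classes)


class TestQCFilter:
    def test_permissive_params_change_nothing(self, qc_matrix):
        params = QCParams(max_mito_fraction=1.0, min_reads=1, min_genes=1, min_gene_prevalence=0.0,
                          ribosomal_patterns=("^NONE",))
        out, report = qc_filter(qc_matrix, params)
        assert out.counts.shape == qc_matrix.counts.shape
        assert report["removed"].sum() == 0

    def test_high_mito_cell_removed_first(self):
        counts = [[10, 10, 5], [10, 10, 0], [1, 1, 0], [10, 10, 1], [10, 10, 1]]
        m = build_matrix(counts, ["g1", "g2", "MT-G01"], ["isotype", "isotype", "mito"])
        out, report = qc_filter(m, QCParams(min_reads=5, min_genes=2, min_gene_prevalence=0.0))
        assert report.loc[report["step"] == "high_mito_cells_removed", "removed"].iloc[0] == 1
        assert "BC0000" not in out.barcodes  # the 20% mito cell

    def test_missing_mito_annotation_rejected(self):
        m = build_matrix([[5, 5]], ["g1", "g2"], ["isotype", "isotype"])
        with pytest.raises(ValueError):
            qc_filter(m, QCParams())

    def test_four_rules_match_independent_recomputation(self, qc_matrix):
        params = QCParams(max_mito_fraction=0.10, min_reads=1500, min_genes=30,
                          min_gene_prevalence=0.005)
        out, report = qc_filter(qc_matrix, params)
        # independent brute-force application of the four rules in order
        counts = qc_matrix.counts.copy()
        cells = np.arange(counts.shape[0])
        genes = list(qc_matrix.features.index)
        mito = [i for i, g in enumerate(genes) if g.startswith("MT-")]
        frac = counts[:, mito].sum(1) / np.maximum(counts.sum(1), 1)
        cells = cells[frac[cells] <= 0.10]
        keep_g = [i for i, g in enumerate(genes) if not (g.startswith("RPS") or g.startswith("RPL"))]
        prev = (counts[np.ix_(cells, keep_g)] > 0).mean(0)
        keep_g = [g for g, p in zip(keep_g, prev) if p >= 0.005]
        sub = counts[np.ix_(cells, keep_g)]
        ok = (sub.sum(1) >= 1500) & ((sub > 0).sum(1) >= 30)
        cells = cells[ok]
        assert list(out.barcodes) == [f"BC{i:04d}" for i in cells]
        assert out.counts.shape[1] == len(keep_g)
        assert list(report["order"]) == [1, 2, 3, 4]


class TestSelectASCs:
    def test_all_zero_ig_counts_empty(self):
        m = build_matrix([[0, 7], [0, 9]], ["IGHG1", "BG1"], ["isotype", "background"])
        assert select_ascs(m).size == 0

    def test_planted_fraction_recovered(self, rng):
        n = 300
        ig = rng.poisson(50, n)
        ig[: n // 3] = 0  # a third of the cells have no Ig at all
        bg = np.full(n, 100)
        m = build_matrix(np.column_stack([ig, bg]), ["IGHG1", "BG1"], ["isotype", "background"])
        got = set(select_ascs(m, min_ig_fraction=0.10))
        want = {f"BC{i:04d}" for i in range(n) if ig[i] / (ig[i] + 100) > 0.10}
        assert got == want

    def test_intersection_mode_drops_one_sided_cells(self):
        a = build_matrix([[50, 50], [50, 50]], ["IGHG1", "BG1"], ["isotype", "background"])
        b = build_matrix([[50, 50], [0, 100]], ["IGHG1", "BG1"], ["isotype", "background"])
        assert list(select_ascs(a, other=b)) == ["BC0000"]

    def test_no_matching_features_rejected(self):
        m = build_matrix([[1]], ["BG1"], ["background"])
        with pytest.raises(ValueError):
            select_ascs(m)


class TestExpressionValue:
    def test_closed_forms(self):
        assert expression_value(0, 100) == 0.0
        assert expression_value(100, 100) == pytest.approx(np.log1p(10000))
        assert expression_value(25, 5000) == pytest.approx(np.log1p(50))
        assert expression_value(25, 5000, scale=100, log=False) == pytest.approx(0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            expression_value(1, 0)
        with pytest.raises(ValueError):
            expression_value(10, 5)


class TestCallIsotypes:
    GENES = ["IGHG1", "IGHG2", "IGHA1"]

    def test_pure_cell_and_split_cell(self):
        m = build_matrix([[40, 0, 0], [20, 20, 0], [0, 0, 0]], self.GENES, "isotype")
        table = call_isotypes(m, self.GENES)
        assert table["call"].tolist() == ["IGHG1", "unassigned", "unassigned"]
        assert table.iloc[0]["fraction_IGHG1"] == 1.0
        np.testing.assert_allclose(
            table.filter(like="fraction_").sum(axis=1).to_numpy(), [1.0, 1.0, 0.0]
        )

    def test_threshold_edge(self):
        m = build_matrix([[86, 14, 0], [85, 15, 0]], self.GENES, "isotype")
        table = call_isotypes(m, self.GENES, call_threshold=0.85)
        assert table["call"].tolist() == ["IGHG1", "unassigned"]

    def test_invariant_to_uniform_rescaling(self):
        base = np.array([[30, 5, 5], [3, 90, 7]])
        t1 = call_isotypes(build_matrix(base, self.GENES, "isotype"), self.GENES)
        t2 = call_isotypes(build_matrix(base * 10, self.GENES, "isotype"), self.GENES)
        assert t1["call"].tolist() == t2["call"].tolist()
        np.testing.assert_allclose(
            t1.filter(like="fraction_").to_numpy(), t2.filter(like="fraction_").to_numpy()
        )

    def test_missing_gene_rejected(self):
        m = build_matrix([[1, 1, 1]], self.GENES, "isotype")
        with pytest.raises(ValueError):
            call_isotypes(m, ["IGHG1", "IGHZ"])


class TestDetectDP:
    def test_all_zero_matrix_no_dp(self):
        m = build_matrix(np.zeros((4, 2)), ["IGHG1", "IGHG2"], "isotype")
        flags, summary = detect_dp(m, DPThresholds({("IGHG1", "IGHG2"): (0.5, 0.5)}))
        assert summary["n_dp"].iloc[0] == 0

    def test_one_percent_each_crosses_half_percent_thresholds(self):
        counts = np.zeros((1, 3), dtype=int)
        counts[0] = [10, 10, 980]  # 1% IGHG1, 1% IGHG2 of the cell total
        m = build_matrix(counts, ["IGHG1", "IGHG2", "BG1"], ["isotype", "isotype", "background"])
        flags, summary = detect_dp(m, DPThresholds({("IGHG1", "IGHG2"): (0.5, 0.5)}))
        assert bool(flags["DP_IGHG1_IGHG2"].iloc[0])
        assert summary["n_dp"].iloc[0] == 1

    def test_asymmetric_igha_thresholds(self):
        counts = np.array([[7, 4, 989], [7, 2, 991]])  # 0.7%/0.4% and 0.7%/0.2%
        m = build_matrix(counts, ["IGHA1", "IGHA2", "BG1"], ["isotype", "isotype", "background"])
        flags, _ = detect_dp(m, DPThresholds({("IGHA1", "IGHA2"): (0.8, 0.3)}))
        assert not flags["DP_IGHA1_IGHA2"].any()  # 0.7% < 0.8% threshold on IGHA1
        counts2 = np.array([[9, 4, 987]])
        m2 = build_matrix(counts2, ["IGHA1", "IGHA2", "BG1"], ["isotype", "isotype", "background"])
        flags2, _ = detect_dp(m2, DPThresholds({("IGHA1", "IGHA2"): (0.8, 0.3)}))
        assert bool(flags2["DP_IGHA1_IGHA2"].iloc[0])


class TestDoubletDiagnostic:
    def test_identical_groups_p_one(self):
        flags = np.array([True] * 3 + [False] * 3)
        sizes = np.array([5.0, 6.0, 7.0, 5.0, 6.0, 7.0])
        res = doublet_diagnostic(flags, sizes, method="permutation")
        assert res["p_value"] == 1.0

    def test_separated_groups_toy_p(self):
        flags = np.array([True] * 3 + [False] * 3)
        sizes = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = doublet_diagnostic(flags, sizes, method="permutation")
        assert res["p_value"] == pytest.approx(0.1)
        assert res["direction"] == "dp_not_larger"

    def test_empty_group_skipped_with_notice(self):
        res = doublet_diagnostic(np.zeros(5, dtype=bool), np.arange(5.0))
        assert res["skipped"] and "notice" in res

    def test_doublet_excess_detected(self, rng):
        sizes = np.concatenate([rng.lognormal(8, 0.4, 200), rng.lognormal(8.7, 0.4, 30)])
        flags = np.concatenate([np.zeros(200, bool), np.ones(30, bool)])
        res = doublet_diagnostic(flags, sizes)
        assert res["p_value"] < 1e-6 and res["direction"] == "dp_larger"
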