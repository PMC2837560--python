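"""Replicate QC, dRn filtering, ddCT quantification and concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigrev import ddct_quantify, drn_outlier_filter, microarray_concordance, replicate_qc
from sigrev.ddct import CtTable, DdctResult, _pooled_t_test


def build_ct(entries, reference="REF", groups=None):
    """entries: list of (sample, gene, ct-values tuple[, drn])."""
    rows = []
    for e in entries:
        sample, gene, cts = e[0], e[1], e[2]
        drn = e[3] if len(e) > 3 else 1.0
        for i, ct in enumerate(cts, start=1):
            rows.append({"sample_id": sample, "gene": gene, "replicate": i,
                         "ct": ct, "delta_rn": drn})
    data = pd.DataFrame(rows)
    if groups is None:
        groups = pd.Series({s: ("case" if s.startswith("c") else "ctrl")
                            for s in data["sample_id"].unique()})
    return CtTable(data=data, reference_gene=reference, groups=groups)


def two_group_table(gene_ct_case, gene_ct_ctrl, ref_ct=12.0, gene="G"):
    entries = []
    for i, ct in enumerate(gene_ct_case):
        entries.append((f"c{i}", gene, (ct, ct, ct)))
        entries.append((f"c{i}", "REF", (ref_ct,) * 3))
    for i, ct in enumerate(gene_ct_ctrl):
        entries.append((f"n{i}", gene, (ct, ct, ct)))
        entries.append((f"n{i}", "REF", (ref_ct,) * 3))
    return build_ct(entries)


class TestCtTableValidation:
    def test_ct_over_forty_cycles_rejected(self):
        with pytest.raises(ValueError, match="CT values"):
            build_ct([("c0", "G", (41.0, 24.0, 24.0)), ("c0", "REF", (12.0,) * 3)])

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference gene"):
            build_ct([("c0", "G", (24.0,) * 3)])


class TestReplicateQc:
    def test_tight_triple_accepted_with_mean(self):
        t = build_ct([("c0", "G", (24.1, 24.2, 24.3)), ("c0", "REF", (12.0,) * 3)])
        qc = replicate_qc(t)
        row = qc.accepted.set_index(["sample_id", "gene"])
        assert row.loc[("c0", "G"), "ct"] == pytest.approx(24.2)
        assert qc.exclusions.empty

    def test_range_at_or_above_half_cycle_excluded(self):
        t = build_ct([("c0", "G", (24.0, 24.0, 24.6)), ("c0", "REF", (12.0,) * 3)])
        qc = replicate_qc(t)
        assert ("c0", "G") not in qc.accepted.set_index(["sample_id", "gene"]).index
        assert "range" in qc.exclusions.iloc[0]["reason"]
        # the gate is strict: exactly 0.5 fails too
        t2 = build_ct([("c0", "G", (24.0, 24.0, 24.5)), ("c0", "REF", (12.0,) * 3)])
        assert len(replicate_qc(t2).accepted.query("gene == 'G'")) == 0

    def test_identical_replicates_always_accepted(self):
        t = build_ct([("c0", "G", (30.0, 30.0, 30.0)), ("c0", "REF", (12.0,) * 3)])
        assert len(replicate_qc(t).accepted) == 2

    def test_undetermined_replicates_dropped_with_reason(self):
        t = build_ct([("c0", "G", (24.0, 24.1, np.nan)), ("c0", "REF", (12.0,) * 3)])
        qc = replicate_qc(t)
        assert qc.accepted.set_index(["sample_id", "gene"]).loc[("c0", "G"), "ct"] == pytest.approx(24.05)
        assert "undetermined" in qc.exclusions.iloc[0]["reason"]
        t2 = build_ct([("c0", "G", (np.nan,) * 3), ("c0", "REF", (12.0,) * 3)])
        qc2 = replicate_qc(t2)
        assert len(qc2.accepted.query("gene == 'G'")) == 0
        assert (qc2.exclusions["reason"] == "all replicates undetermined").any()


class TestDrnFilter:
    def test_uniform_drn_excludes_nothing(self):
        t = build_ct([("c0", "G", (24.0,) * 3), ("c0", "REF", (12.0,) * 3)])
        kept, excluded = drn_outlier_filter(t)
        assert excluded.empty
        assert len(kept.data) == len(t.data)

    def test_gross_outlier_excluded_at_three_sigma(self):
        n = 21
        entries = [(f"c{i}", "REF", (12.0,) * 3) for i in range(n)]
        entries += [(f"c{i}", "G", (24.0,) * 3, 1.0 + 0.01 * i) for i in range(n - 1)]
        base = [1.0 + 0.01 * i for i in range(n - 1)]
        outlier = np.mean(base) + 10 * np.std(base, ddof=1)
        entries.append((f"c{n - 1}", "G", (24.0,) * 3, outlier))
        t = build_ct(entries)
        # the outlier deviates from the contaminated per-gene mean by > 3 SD
        drn = t.data.query("gene == 'G'").groupby("sample_id")["delta_rn"].first()
        assert abs(outlier - drn.mean()) > 3 * drn.std(ddof=1)
        kept, excluded = drn_outlier_filter(t, k=3.0)
        assert set(excluded["sample_id"]) == {f"c{n - 1}"}
        assert not (kept.data.query("gene == 'G'")["sample_id"] == f"c{n - 1}").any()

    def test_missing_drn_column_passes_through(self):
        t = build_ct([("c0", "G", (24.0,) * 3), ("c0", "REF", (12.0,) * 3)])
        t.data = t.data.drop(columns=["delta_rn"])
        kept, excluded = drn_outlier_filter(t)
        assert excluded.empty
        pd.testing.assert_frame_equal(kept.data, t.data)


class TestQuantify:
    def test_zero_ddct_gives_unit_fold_change(self):
        t = two_group_table([24.0, 24.0], [24.0, 24.0])
        res = ddct_quantify(replicate_qc(t), t, "case", "ctrl")
        row = res.per_gene.iloc[0]
        assert row["ddct"] == pytest.approx(0.0)
        assert row["fold_change"] == pytest.approx(1.0)

    def test_ddct_of_3_32_gives_tenth_fold(self):
        t = two_group_table([27.32, 27.32], [24.0, 24.0])
        res = ddct_quantify(replicate_qc(t), t, "case", "ctrl")
        row = res.per_gene.iloc[0]
        assert row["fold_change"] == pytest.approx(2.0 ** -3.32, abs=1e-12)
        assert row["fold_change"] == pytest.approx(0.10, abs=0.001)

    def test_identical_groups_give_t_zero_p_one(self):
        t = two_group_table([24.0, 25.0], [24.0, 25.0])
        res = ddct_quantify(replicate_qc(t), t, "case", "ctrl")
        row = res.per_gene.iloc[0]
        assert row["t_stat"] == 0.0 and row["p_value"] == 1.0

    def test_shift_of_one_samples_cts_cancels_in_delta_ct(self):
        t = two_group_table([24.0, 25.0, 26.0], [23.0, 24.0, 22.5])
        res = ddct_quantify(replicate_qc(t), t, "case", "ctrl")
        shifted = two_group_table([24.0, 25.0, 26.0], [23.0, 24.0, 22.5])
        mask = shifted.data["sample_id"] == "c0"
        shifted.data.loc[mask, "ct"] += 3.0  # every CT of one sample, ref included
        res2 = ddct_quantify(replicate_qc(shifted), shifted, "case", "ctrl")
        pd.testing.assert_frame_equal(res.per_gene, res2.per_gene)

    def test_pooled_t_matches_textbook_formula(self):
        x = np.array([1.2, 1.9, 2.4, 1.7])
        y = np.array([2.8, 3.0, 2.2])
        tstat, p = _pooled_t_test(x, y)
        nx, ny = 4, 3
        sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (nx + ny - 2)
        expected_t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        expected_p = 2 * stats.t.sf(abs(expected_t), nx + ny - 2)
        assert tstat == pytest.approx(expected_t, abs=1e-12)
        assert p == pytest.approx(expected_p, abs=1e-12)
        ref = stats.ttest_ind(x, y)  # scipy as a second, independent check
        assert tstat == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_welch_option_relaxes_equal_variance(self):
        t = two_group_table([24.0, 25.0, 26.0, 27.0], [23.0, 23.1, 23.2])
        pooled = ddct_quantify(replicate_qc(t), t, "case", "ctrl")
        welch = ddct_quantify(replicate_qc(t), t, "case", "ctrl", welch=True)
        dct_case = np.array([12.0, 13.0, 14.0, 15.0])
        dct_ctrl = np.array([11.0, 11.1, 11.2])
        ref = stats.ttest_ind(dct_case, dct_ctrl, equal_var=False)
        assert welch.per_gene.iloc[0]["p_value"] == pytest.approx(ref.pvalue, abs=1e-12)
        assert welch.per_gene.iloc[0]["p_value"] != pooled.per_gene.iloc[0]["p_value"]

    def test_single_sample_group_gets_fc_but_no_test(self):
        t = two_group_table([24.0], [25.0, 25.5])
        res = ddct_quantify(replicate_qc(t), t, "case", "ctrl")
        row = res.per_gene.iloc[0]
        assert np.isfinite(row["fold_change"])
        assert np.isnan(row["p_value"])


class TestConcordance:
    def make_result(self, genes, fcs):
        per_gene = pd.DataFrame({"gene": genes, "ddct": 0.0, "fold_change": fcs,
                                 "t_stat": 0.0, "p_value": 0.5,
                                 "n_case": 3, "n_control": 3})
        return DdctResult(case_group="case", control_group="ctrl",
                          per_gene=per_gene, delta_ct=pd.DataFrame())

    def test_both_down_and_both_up_concordant_opposite_discordant(self):
        res = self.make_result(["ABCA8like", "IL8like", "disc"], [0.10, 148.06, 0.5])
        micro = pd.Series({"ABCA8like": 0.078, "IL8like": 20.20, "disc": 2.0})
        table, counts = microarray_concordance(res, micro)
        by_gene = table.set_index("gene")["same_direction"]
        assert by_gene["ABCA8like"] is True or by_gene["ABCA8like"] == True  # noqa: E712
        assert bool(by_gene["IL8like"])
        assert not bool(by_gene["disc"])
        assert counts == {"n_total": 3, "n_concordant": 2, "n_indeterminate": 0}

    def test_unit_fold_change_is_indeterminate(self):
        res = self.make_result(["g"], [1.0])
        table, counts = microarray_concordance(res, pd.Series({"g": 2.0}))
        assert table["same_direction"].isna().all()
        assert counts == {"n_total": 0, "n_concordant": 0, "n_indeterminate": 1}
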