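"""DE-set construction: FDR adjustment, the three-condition caller,
Tf2 aggregation, biotype exclusion, convergent fraction, qPCR ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genectx.de import (
    aggregate_tf2,
    bh_fdr,
    call_de,
    convergent_fraction,
    exclude_biotypes,
    qpcr_relative,
    recompute_statistics,
)
from genectx.io import GenomicInterval

from conftest import make_expression


def bh_brute_force(p):
    """Independent step-up oracle: adj_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = min(running, 1.0)
    return adj


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40))
    def test_agrees_with_brute_force(self, ps):
        assert bh_fdr(ps) == pytest.approx(bh_brute_force(ps), abs=1e-12)


class TestCallDe:
    def test_up_when_all_three_conditions_met(self):
        t = make_expression(
            [dict(gene_id="g", cond1=[10, 11], cond2=[16, 17], fold_change=1.6, fdr=0.01)]
        )
        up, down = call_de(t)
        assert "g" in up.members and not down.members

    def test_no_fold_change_means_no_call(self):
        t = make_expression(
            [dict(gene_id="g", cond1=[10, 10], cond2=[10, 10], fold_change=1.0, fdr=0.001)]
        )
        up, down = call_de(t)
        assert not up.members and not down.members

    def test_zero_replicate_in_higher_condition_blocks_call(self):
        t = make_expression(
            [dict(gene_id="g", cond1=[10, 10], cond2=[40, 0.0], fold_change=2.0, fdr=0.01)]
        )
        up, _ = call_de(t)
        assert not up.members

    def test_down_call_uses_inverse_threshold(self):
        t = make_expression(
            [dict(gene_id="g", cond1=[30, 30], cond2=[10, 10], fold_change=1 / 3, fdr=0.01)]
        )
        up, down = call_de(t)
        assert "g" in down.members and not up.members

    def test_degenerate_thresholds_return_universe(self):
        rows = [
            dict(gene_id=f"g{i}", cond1=[1 + i, 2 + i], cond2=[3 + i, 1 + i],
                 fold_change=fc, fdr=f)
            for i, (fc, f) in enumerate([(0.5, 0.9), (1.0, 1.0), (2.0, 0.5), (1.3, 0.2)])
        ]
        up, down = call_de(make_expression(rows), min_fc=1.0, max_fdr=1.0, expression_floor=0.0)
        assert up.members | down.members == up.universe

    def test_missing_replicate_rejected(self):
        t = make_expression([dict(gene_id="g", fold_change=2.0, fdr=0.01)])
        t.loc[0, "cond1_r1"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            call_de(t)


class TestAggregateTf2:
    def test_thirteen_copies_sum_to_thirteen(self):
        rows = [
            dict(gene_id=f"Tf2_{i}", biotype="retrotransposon",
                 cond1=[1.0, 1.0], cond2=[1.0, 1.0])
            for i in range(1, 14)
        ]
        merged = aggregate_tf2(make_expression(rows), [f"Tf2_{i}" for i in range(1, 14)])
        assert len(merged) == 1
        row = merged.iloc[0]
        assert row["gene_id"] == "Tf2" and row["biotype"] == "retrotransposon"
        for col in ("cond1_r1", "cond1_r2", "cond2_r1", "cond2_r2"):
            assert row[col] == pytest.approx(13.0)

    def test_single_id_keeps_values(self):
        rows = [dict(gene_id="Tf2_1", cond1=[3.0, 4.0], cond2=[6.0, 8.0])]
        merged = aggregate_tf2(make_expression(rows), ["Tf2_1"])
        assert merged.iloc[0]["cond1_r2"] == pytest.approx(4.0)

    def test_fold_change_is_ratio_of_summed_means(self):
        # oracle: recompute from sums, never average per-copy fold changes
        rows = [
            dict(gene_id="a", cond1=[10.0, 10.0], cond2=[10.0, 10.0], fold_change=1.0),
            dict(gene_id="b", cond1=[2.0, 2.0], cond2=[20.0, 20.0], fold_change=10.0),
        ]
        merged = aggregate_tf2(make_expression(rows), ["a", "b"], merged_id="m")
        expected = (10.0 + 20.0) / (10.0 + 2.0)
        assert merged.iloc[-1]["fold_change"] == pytest.approx(expected)
        assert merged.iloc[-1]["fold_change"] != pytest.approx((1.0 + 10.0) / 2)

    def test_missing_id_rejected(self):
        t = make_expression([dict(gene_id="a")])
        with pytest.raises(ValueError, match="absent"):
            aggregate_tf2(t, ["a", "ghost"])


class TestExcludeBiotypes:
    def test_removes_trna_and_rrna(self):
        rows = [dict(gene_id=f"g{i}", biotype=b) for i, b in enumerate(
            ["protein_coding"] * 4 + ["rRNA"] * 3 + ["tRNA"] * 2 + ["ncRNA"]
        )]
        out, counts = exclude_biotypes(make_expression(rows))
        assert len(out) == 5
        assert counts == {"rRNA": 3, "tRNA": 2}

    def test_identity_when_absent_or_empty_set(self):
        t = make_expression([dict(gene_id="g", biotype="ncRNA")])
        out, counts = exclude_biotypes(t)
        assert len(out) == 1 and counts == {}
        out2, _ = exclude_biotypes(t, excluded=set())
        assert len(out2) == 1


class TestConvergentFraction:
    @staticmethod
    def _pair(chrom, start, s1, s2, gap=100, length=500):
        a = GenomicInterval(chrom, start, start + length, s1, "gene", f"g{start}a")
        b = GenomicInterval(chrom, start + length + gap, start + 2 * length + gap, s2, "gene", f"g{start}b")
        return [a, b]

    def test_all_convergent_layout(self):
        genes, antisense = [], []
        for i in range(10):
            pair = self._pair("chr1", i * 5000, "+", "-")
            genes += pair
            antisense.append(GenomicInterval("chr1", pair[0].start, pair[0].end, "-", "antisense", f"as{i}"))
        assert convergent_fraction(antisense, genes) == pytest.approx(1.0)

    def test_tandem_only_layout(self):
        genes, antisense = [], []
        for i in range(10):
            pair = self._pair("chr1", i * 5000, "+", "+")
            genes += pair
            antisense.append(GenomicInterval("chr1", pair[0].start, pair[0].end, "-", "antisense", f"as{i}"))
        assert convergent_fraction(antisense, genes) == pytest.approx(0.0)

    def test_planted_half_convergent(self):
        # 100 convergent pairs and 100 tandem pairs; one antisense per pair,
        # anchored on the first gene -> exactly half map to convergent genes
        genes, antisense = [], []
        pos = 0
        for i in range(200):
            strands = ("+", "-") if i % 2 == 0 else ("+", "+")
            pair = self._pair("chr1", pos, *strands)
            genes += pair
            antisense.append(
                GenomicInterval("chr1", pair[0].start, pair[0].end, "-", "antisense", f"as{i}")
            )
            pos += 10_000
        assert convergent_fraction(antisense, genes) == pytest.approx(0.5, abs=0.05)

    def test_gap_cap_breaks_convergence(self):
        genes = self._pair("chr1", 0, "+", "-", gap=5000)
        antisense = [GenomicInterval("chr1", 0, 500, "-", "antisense", "as")]
        assert convergent_fraction(antisense, genes, max_gap=1000) == 0.0
        assert convergent_fraction(antisense, genes, max_gap=10_000) == 1.0

    def test_empty_antisense_rejected(self):
        with pytest.raises(ValueError):
            convergent_fraction([], self._pair("chr1", 0, "+", "-"))


class TestQpcr:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["gene", "condition", "ct"])

    def test_no_change_gives_one(self):
        t = self._table([
            ("act1", "control", 20), ("tbp1", "control", 22), ("x", "control", 25),
            ("act1", "mutant", 20), ("tbp1", "mutant", 22), ("x", "mutant", 25),
        ])
        assert qpcr_relative(t, control_condition="control")["x"] == pytest.approx(1.0)

    def test_one_cycle_lower_doubles(self):
        t = self._table([
            ("act1", "control", 20), ("tbp1", "control", 22), ("x", "control", 25),
            ("act1", "mutant", 20), ("tbp1", "mutant", 22), ("x", "mutant", 24),
        ])
        assert qpcr_relative(t, control_condition="control")["x"] == pytest.approx(2.0)

    def test_reference_shift_cancels(self):
        # references and target shift by the same cycle count -> level 1.0
        t = self._table([
            ("act1", "control", 20), ("tbp1", "control", 22), ("x", "control", 25),
            ("act1", "mutant", 21), ("tbp1", "mutant", 23), ("x", "mutant", 26),
        ])
        assert qpcr_relative(t, control_condition="control")["x"] == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        t = self._table([
            ("act1", "control", 20), ("x", "control", 25),
            ("act1", "mutant", 20), ("x", "mutant", 25),
        ])
        with pytest.raises(ValueError, match="tbp1"):
            qpcr_relative(t, control_condition="control")


def test_recompute_statistics_matches_replicates():
    rows = [
        dict(gene_id="g1", cond1=[100.0, 110.0], cond2=[400.0, 440.0]),
        dict(gene_id="g2", cond1=[50.0, 55.0], cond2=[52.0, 56.0]),
    ]
    out = recompute_statistics(make_expression(rows))
    m1 = (100 + 110) / 2 + 0.0
    assert out.loc[0, "fold_change"] == pytest.approx((420 + 0.5) / (105 + 0.5))
    assert 0 <= out.loc[1, "p_value"] <= 1
    assert (out["fdr"] >= out["p_value"] - 1e-12).all()
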