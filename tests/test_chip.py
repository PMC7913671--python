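"""H3K9me2/H3 log2 ratios, WT normalisation, domain calling, matched
random controls and anchored summaries."""

import numpy as np
import pytest

from genectx.chip import (
    anchored_summary,
    call_enriched_domains,
    matched_random_controls,
    normalize_to_wt,
    ratio_track,
)
from genectx.io import CoverageTrack, GenomeLayout, GenomicInterval

LAYOUT = GenomeLayout((("c", 100_000),))
BS = 50
NB = 100_000 // BS


def cov(values, layout=LAYOUT):
    return CoverageTrack(layout, BS, {c: np.asarray(v, dtype=float) for c, v in values.items()})


class TestRatioTrack:
    def test_equal_tracks_give_zero(self):
        t = cov({"c": np.full(NB, 10.0)})
        rt = ratio_track(t, t)
        assert np.allclose(rt.track.values["c"], 0.0)

    def test_fourfold_gives_two_log2(self):
        h3 = cov({"c": np.full(NB, 1000.0)})
        k9 = cov({"c": np.full(NB, 4000.0)})
        rt = ratio_track(k9, h3, pseudocount=1e-9)
        assert np.allclose(rt.track.values["c"], 2.0, atol=1e-6)

    def test_elementwise_formula(self, rng):
        h3 = cov({"c": rng.uniform(1, 100, NB)})
        k9 = cov({"c": rng.uniform(1, 100, NB)})
        pc = 1.0
        rt = ratio_track(k9, h3, pseudocount=pc)
        expected = np.log2((k9.values["c"] + pc) / (h3.values["c"] + pc))
        assert np.allclose(rt.track.values["c"], expected)
        assert np.all(np.isfinite(rt.track.values["c"]))

    def test_grid_mismatch_rejected(self):
        a = cov({"c": np.full(NB, 1.0)})
        b = CoverageTrack(LAYOUT, 100, {"c": np.full(1000, 1.0)})
        with pytest.raises(ValueError):
            ratio_track(a, b)

    def test_nonpositive_pseudocount_rejected(self):
        t = cov({"c": np.full(NB, 1.0)})
        with pytest.raises(ValueError):
            ratio_track(t, t, pseudocount=0.0)


class TestNormalizeToWt:
    def test_equal_ratios_give_zero(self):
        t = cov({"c": np.full(NB, 10.0)})
        rt = ratio_track(t, t, replicate="r1")
        out = normalize_to_wt(rt, rt)
        assert np.allclose(out.track.values["c"], 0.0)

    def test_planted_block_recovered_exactly(self):
        h3 = cov({"c": np.full(NB, 100.0)})
        k9_wt = cov({"c": np.full(NB, 100.0)})
        k9_vals = np.full(NB, 100.0)
        k9_vals[400:600] *= 2.0  # +1 log2 in a planted block
        k9_mut = cov({"c": k9_vals})
        wt = ratio_track(k9_wt, h3, pseudocount=1e-9, replicate="r1")
        mut = ratio_track(k9_mut, h3, pseudocount=1e-9, replicate="r1")
        out = normalize_to_wt(mut, wt)
        assert np.allclose(out.track.values["c"][400:600], 1.0, atol=1e-6)
        assert np.allclose(out.track.values["c"][:400], 0.0, atol=1e-6)

    def test_shift_invariance(self, rng):
        a = ratio_track(cov({"c": rng.uniform(1, 50, NB)}), cov({"c": rng.uniform(1, 50, NB)}),
                        replicate="r1")
        b = ratio_track(cov({"c": rng.uniform(1, 50, NB)}), cov({"c": rng.uniform(1, 50, NB)}),
                        replicate="r1")
        base = normalize_to_wt(a, b).track.values["c"]
        a.track.values["c"] += 0.7
        b.track.values["c"] += 0.7
        shifted = normalize_to_wt(a, b).track.values["c"]
        assert np.allclose(base, shifted)

    def test_replicate_pairing_enforced(self):
        t = cov({"c": np.full(NB, 10.0)})
        with pytest.raises(ValueError, match="pairing"):
            normalize_to_wt(ratio_track(t, t, replicate="r1"), ratio_track(t, t, replicate="r2"))

    def test_scaling_invariance_of_double_ratio(self, rng):
        # scaling a sample's coverage (both its antibody tracks jointly)
        # cancels in the double ratio when the pseudocount is negligible
        k9m, h3m = rng.uniform(10, 100, NB), rng.uniform(10, 100, NB)
        k9w, h3w = rng.uniform(10, 100, NB), rng.uniform(10, 100, NB)
        pc = 1e-12

        def double(s_mut, s_wt):
            mut = ratio_track(cov({"c": k9m * s_mut}), cov({"c": h3m * s_mut}), pc, replicate="r1")
            wt = ratio_track(cov({"c": k9w * s_wt}), cov({"c": h3w * s_wt}), pc, replicate="r1")
            return normalize_to_wt(mut, wt).track.values["c"]

        assert np.allclose(double(1, 1), double(3.7, 0.04), atol=1e-6)


class TestCallEnrichedDomains:
    def test_flat_track_yields_nothing(self):
        rt = ratio_track(cov({"c": np.full(NB, 10.0)}), cov({"c": np.full(NB, 10.0)}))
        with pytest.warns(UserWarning):
            domains = call_enriched_domains(rt)
        assert domains == []

    def test_planted_block_recovered_within_one_bin(self, rng):
        vals = rng.normal(0.0, 0.05, NB)
        vals[400:800] += 2.0  # 20 kb block
        rt = ratio_track(cov({"c": np.full(NB, 1.0)}), cov({"c": np.full(NB, 1.0)}))
        rt.track.values["c"] = vals
        domains = call_enriched_domains(rt, z_threshold=2.0, min_len=2000, merge_gap=1000)
        assert len(domains) == 1
        d = domains[0]
        assert abs(d.interval.start - 400 * BS) <= BS
        assert abs(d.interval.end - 800 * BS) <= BS
        assert d.mean_enrichment > d.threshold

    def test_invariant_to_constant_offset(self, rng):
        vals = rng.normal(0.0, 0.05, NB)
        vals[100:300] += 1.5
        rt = ratio_track(cov({"c": np.full(NB, 1.0)}), cov({"c": np.full(NB, 1.0)}))
        rt.track.values["c"] = vals
        a = call_enriched_domains(rt)
        rt.track.values["c"] = vals + 5.0
        b = call_enriched_domains(rt)
        assert [(d.interval.start, d.interval.end) for d in a] == [
            (d.interval.start, d.interval.end) for d in b
        ]

    def test_short_runs_discarded(self, rng):
        vals = np.zeros(NB)
        vals[500:510] = 3.0  # 500 bp, below min_len
        vals[:] += rng.normal(0, 0.05, NB)
        rt = ratio_track(cov({"c": np.full(NB, 1.0)}), cov({"c": np.full(NB, 1.0)}))
        rt.track.values["c"] = vals
        assert call_enriched_domains(rt, min_len=2000) == []


class TestMatchedRandomControls:
    FEATURES = [
        GenomicInterval("c", 10_000, 10_350, ".", "LTR", "L1"),
        GenomicInterval("c", 50_000, 50_500, ".", "LTR", "L2"),
        GenomicInterval("c", 80_000, 80_350, ".", "LTR", "L3"),
    ]

    def test_zero_features_zero_controls(self):
        assert matched_random_controls([], LAYOUT, seed=1) == []

    def test_length_multiset_matched(self):
        controls = matched_random_controls(self.FEATURES, LAYOUT, seed=7)
        assert sorted(len(c) for c in controls) == sorted(len(f) for f in self.FEATURES)
        assert all(c.chrom == f.chrom for c, f in zip(controls, self.FEATURES))

    def test_no_overlap_with_features_exclusions_or_each_other(self):
        exclusions = [GenomicInterval("c", 0, 30_000, label="dom")]
        for seed in range(100):
            controls = matched_random_controls(self.FEATURES, LAYOUT, exclusions, seed=seed)
            everything = self.FEATURES + exclusions
            for i, c in enumerate(controls):
                for other in everything + controls[:i]:
                    assert not c.overlaps(other)

    def test_deterministic_per_seed(self):
        a = matched_random_controls(self.FEATURES, LAYOUT, seed=5)
        b = matched_random_controls(self.FEATURES, LAYOUT, seed=5)
        assert [(c.start, c.end) for c in a] == [(c.start, c.end) for c in b]
        c = matched_random_controls(self.FEATURES, LAYOUT, seed=6)
        assert [(x.start, x.end) for x in a] != [(x.start, x.end) for x in c]

    def test_infeasible_placement_rejected(self):
        tiny = GenomeLayout((("c", 1000),))
        features = [GenomicInterval("c", 0, 900, ".", "LTR", "L1")]
        with pytest.raises(RuntimeError):
            matched_random_controls(features, tiny, seed=0, max_tries=50)


class TestAnchoredSummary:
    @staticmethod
    def _ratio_with(vals):
        rt = ratio_track(cov({"c": np.full(NB, 1.0)}), cov({"c": np.full(NB, 1.0)}))
        rt.track.values["c"] = np.asarray(vals, dtype=float)
        return rt

    FEATURES = [GenomicInterval("c", 10_000 + i * 8000, 10_400 + i * 8000, ".", "LTR", f"L{i}")
                for i in range(8)]
    CONTROLS = [GenomicInterval("c", 14_000 + i * 8000, 14_400 + i * 8000, ".", "ctrl", f"C{i}")
                for i in range(8)]

    def test_zero_track_gives_zero_excess(self):
        summ = anchored_summary(self._ratio_with(np.zeros(NB)), self.FEATURES, self.CONTROLS)
        assert summ.center_excess == pytest.approx(0.0)

    def test_planted_feature_signal_recovered(self):
        vals = np.zeros(NB)
        for f in self.FEATURES:
            vals[f.start // BS : (f.end - 1) // BS + 1] = 1.0
        summ = anchored_summary(self._ratio_with(vals), self.FEATURES, self.CONTROLS)
        assert summ.center_excess == pytest.approx(1.0, abs=0.01)

    def test_swapping_features_and_controls_negates_excess(self, rng):
        vals = rng.normal(0, 0.2, NB)
        a = anchored_summary(self._ratio_with(vals), self.FEATURES, self.CONTROLS)
        b = anchored_summary(self._ratio_with(vals), self.CONTROLS, self.FEATURES)
        assert a.center_excess == pytest.approx(-b.center_excess, abs=1e-12)

    def test_matrix_geometry(self):
        summ = anchored_summary(
            self._ratio_with(np.zeros(NB)), self.FEATURES, self.CONTROLS, flank=1000, body_bins=20
        )
        n_flank = 1000 // BS
        assert summ.feature_matrix.shape == (len(self.FEATURES), 2 * n_flank + 20)
        assert summ.body_columns == slice(n_flank, n_flank + 20)

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            anchored_summary(self._ratio_with(np.zeros(NB)), [], self.CONTROLS)
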