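import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import mimir
from mimir.enrichment import MarkerCall

from conftest import average_precision_oracle


class TestSegmentPseudotime:
    def test_balanced_no_fusion(self):
        pt = pd.Series(np.repeat(np.linspace(0.001, 0.999, 15), 100), index=range(1500))
        part = mimir.segment_pseudotime(pt)
        assert [s.n_cells for s in part.segments] == [100] * 15

    def test_three_deficient_bins_fuse_into_one(self):
        # bins 5,6,7 hold 20 cells each, all others 100; the evenest legal
        # plan fuses exactly those three into one 60-cell segment
        sizes = [100] * 5 + [20] * 3 + [100] * 7
        vals = np.concatenate(
            [np.full(n, (i + 0.5) / 15) for i, n in enumerate(sizes)]
        )
        part = mimir.segment_pseudotime(pd.Series(vals, index=range(len(vals))))
        assert [s.n_cells for s in part.segments] == [100] * 5 + [60] + [100] * 7

    def test_tiny_trajectory_single_segment(self):
        pt = pd.Series(np.linspace(0, 1, 40))
        part = mimir.segment_pseudotime(pt)
        assert len(part.segments) == 1
        assert part.segments[0].n_cells == 40

    def test_partition_valid_and_fusion_idempotent(self, marker_calls):
        segments, _, _ = marker_calls
        segments.validate()
        counts = [s.n_cells for s in segments.segments]
        assert min(counts) >= 60
        # re-segmenting an already valid partition's cells yields valid output
        assert sum(counts) == sum(len(s.cell_ids) for s in segments.segments)


class TestAucpr:
    def test_perfect_ranking(self):
        assert mimir.aucpr([3, 2, 1, 0], [1, 1, 0, 0]) == 1.0

    def test_interleaved_example(self):
        assert mimir.aucpr([3, 2, 1, 0], [1, 0, 1, 0]) == pytest.approx(5 / 6)

    def test_constant_scores_give_prevalence(self):
        assert mimir.aucpr([1, 1, 1, 1], [1, 0, 0, 1]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mimir.aucpr([1, 2], [1, 1])

    def test_exhaustive_oracle_agreement(self):
        """Matches a brute-force precision-recall integrator on every binary
        label vector of length <= 8 (distinct descending scores)."""
        for n in range(2, 9):
            scores = np.arange(n, 0, -1, dtype=float)
            for labels in itertools.product([0, 1], repeat=n):
                if len(set(labels)) < 2:
                    continue
                expect = average_precision_oracle(scores, labels)
                assert mimir.aucpr(scores, list(labels)) == pytest.approx(expect, abs=1e-12)

    def test_tied_blocks_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(4, 12)
            scores = rng.integers(0, 4, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max() or np.all(scores == scores[0]):
                continue
            assert mimir.aucpr(scores, labels) == pytest.approx(
                average_precision_oracle(scores, labels), abs=1e-12
            )

    def test_permuted_labels_concentrate_at_prevalence(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=400)
        labels = np.array([1] * 100 + [0] * 300)
        aps = []
        for _ in range(1000):
            aps.append(mimir.aucpr(scores, rng.permutation(labels)))
        assert np.mean(aps) == pytest.approx(0.25, abs=0.02)


class TestCallMarkers:
    def _toy(self, group_vals, back_vals):
        genes = ["g"]
        cells = [f"a{i}" for i in range(len(group_vals))] + [
            f"b{i}" for i in range(len(back_vals))
        ]
        values = np.array([list(group_vals) + list(back_vals)], dtype=float)
        meta = pd.DataFrame(index=cells)
        return (
            mimir.NormalizedMatrix(genes, cells, values, meta),
            [c for c in cells if c.startswith("a")],
            [c for c in cells if c.startswith("b")],
        )

    def test_perfect_marker_passes_both_modes(self):
        data, grp, bg = self._toy([5.0] * 10, [0.0] * 90)
        for mode in ("trajectory", "stage"):
            call = mimir.call_markers(data, grp, bg, mode=mode)[0]
            assert call.detect_frac == 1.0
            assert call.aucpr == 1.0
            assert call.passes

    def test_low_detection_fails_despite_aucpr(self):
        group = [6.0] + [0.0] * 19  # detected in 5% of group cells
        data, grp, bg = self._toy(group, [0.0] * 60)
        call = mimir.call_markers(data, grp, bg)[0]
        assert call.detect_frac == pytest.approx(0.05)
        assert not call.passes

    def test_small_logfc_fails(self):
        rng = np.random.default_rng(1)
        group = list(5.0 + rng.normal(0, 0.01, 20))
        back = list(4.8 + rng.normal(0, 0.01, 60))
        data, grp, bg = self._toy(group, back)
        call = mimir.call_markers(data, grp, bg)[0]
        assert call.aucpr_ratio > 2
        assert call.logfc < 0.3
        assert not call.passes

    def test_overlapping_sets_rejected(self):
        data, grp, bg = self._toy([1.0] * 5, [0.0] * 5)
        with pytest.raises(ValueError):
            mimir.call_markers(data, grp, grp)


def _call(gene, window, passes):
    return MarkerCall(gene, window, 1.0, 1.0, 5.0, 1.0, passes)


class TestDefineEnriched:
    @pytest.mark.parametrize(
        "pass_windows,mode,expected",
        [
            ([4], "trajectory", True),  # last segment alone suffices
            ([1, 3], "trajectory", True),  # two non-final segments suffice
            ([0], "trajectory", False),  # one non-final segment does not
            ([2], "stage", True),  # any stage window suffices
            ([], "stage", False),
        ],
    )
    def test_admission_rules(self, pass_windows, mode, expected):
        calls = [
            [_call("g", f"w{w}", w in pass_windows)] for w in range(5)
        ]
        enriched = mimir.define_enriched(calls, mode=mode)
        assert ("g" in enriched.genes) is expected

    def test_provenance_recorded(self):
        calls = [[_call("g", "w0", True)], [_call("g", "w1", True)]]
        enriched = mimir.define_enriched(calls, mode="trajectory")
        assert ">=2-segments" in enriched.provenance["g"]
        assert "last-segment" in enriched.provenance["g"]


class TestUnionEnriched:
    def test_union_and_identity(self):
        a = mimir.EnrichedGeneSet("noto", {"g1", "g2"}, {"g1": ["last-segment"]})
        b = mimir.EnrichedGeneSet("noto", {"g2", "g3"}, {"g2": ["any-stage"]})
        u = mimir.union_enriched(a, b)
        assert u.genes == {"g1", "g2", "g3"}
        empty = mimir.EnrichedGeneSet("noto", set(), {})
        assert mimir.union_enriched(empty, b).genes == b.genes

    def test_cell_type_mismatch_rejected(self):
        a = mimir.EnrichedGeneSet("noto", {"g1"}, {})
        b = mimir.EnrichedGeneSet("gland", {"g1"}, {})
        with pytest.raises(ValueError):
            mimir.union_enriched(a, b)


class TestFisherEnrichment:
    def test_hypergeometric_tail_value(self):
        # 10-gene module holding 5 of the 10 background carriers of term T,
        # background of 100: exact tail sum over the hypergeometric pmf
        background = {f"g{i}" for i in range(100)}
        module = {f"g{i}" for i in range(10)}
        carriers = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        amap = mimir.AnnotationMap("db", {g: frozenset({"T"}) for g in carriers})
        expected = sum(
            comb(10, i, exact=True) * comb(90, 10 - i, exact=True) for i in range(5, 11)
        ) / comb(100, 10, exact=True)
        res = mimir.fisher_enrichment(module, amap, background)
        assert res.loc["T", "p_value"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(6.7e-4, rel=0.01)

    def test_exclusive_term_is_top_hit(self):
        background = {f"g{i}" for i in range(50)}
        module = {f"g{i}" for i in range(8)}
        ann = {g: frozenset({"T:mod"}) for g in module}
        ann.update({f"g{i}": frozenset({"T:other"}) for i in range(8, 50)})
        res = mimir.fisher_enrichment(module, mimir.AnnotationMap("db", ann), background)
        assert res.index[0] == "T:mod"
        assert res.loc["T:mod", "p_value"] < res.loc["T:other", "p_value"]

    def test_term_absent_from_background_skipped(self):
        background = {"g1", "g2"}
        amap = mimir.AnnotationMap("db", {"outside": frozenset({"T:x"})})
        res = mimir.fisher_enrichment({"g1"}, amap, background)
        assert "T:x" not in res.index

    def test_genes_outside_background_rejected(self):
        amap = mimir.AnnotationMap("db", {})
        with pytest.raises(ValueError):
            mimir.fisher_enrichment({"g9"}, amap, {"g1"})
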