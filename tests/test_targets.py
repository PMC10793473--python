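import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import mimir
from mimir.modules import ModulePartition
from mimir.targets import DesignMatrix, TargetFit, TargetSets


def _design(n=200, seed=0, tf_names=("TF0",), injection=None, batch=None):
    rng = np.random.default_rng(seed)
    cols = {"const": np.ones(n)}
    for tf in tf_names:
        cols[tf] = rng.normal(3, 1, n)
    cols["injection"] = np.zeros(n) if injection is None else injection
    cols["batch"] = np.zeros(n) if batch is None else batch
    frame = pd.DataFrame(cols, index=[f"c{i}" for i in range(n)])
    return DesignMatrix(frame=frame, tf_names=list(tf_names))


class TestBuildDesign:
    def _inputs(self):
        cells = [f"c{i}" for i in range(6)]
        meta = pd.DataFrame(
            {
                "condition": ["ctrl", "ctrl", "ko1", "ko1", "quad", "quad"],
                "batch": ["0", "0", "1", "1", "1", "1"],
                "cell_type": "noto",
            },
            index=cells,
        )
        tfs = ["tfA", "tfB", "tfC", "tfD"]
        values = np.tile(np.arange(1.0, 7.0), (4, 1))
        tf_expr = mimir.NormalizedMatrix(tfs, cells, values, meta)
        komap = {
            "ctrl": set(),
            "ko1": {"tfA"},
            "quad": {"tfA", "tfB", "tfC", "tfD"},
        }
        return meta, tf_expr, komap

    def test_injection_coding_and_knockout_zeroing(self):
        meta, tf_expr, komap = self._inputs()
        design = mimir.build_design(meta, tf_expr, komap)
        f = design.frame
        assert list(f.loc[["c0", "c2", "c4"], "injection"]) == [0.0, 1.0, 1.5]
        assert np.all(f.loc[["c2", "c3"], "tfA"] == 0.0)
        assert np.all(f.loc[["c4", "c5"], ["tfA", "tfB", "tfC", "tfD"]].values == 0.0)
        assert f.loc["c0", "tfA"] == 1.0  # control untouched
        assert list(f.loc[:, "batch"]) == [0, 0, 1, 1, 1, 1]

    def test_missing_condition_rejected(self):
        meta, tf_expr, komap = self._inputs()
        del komap["quad"]
        with pytest.raises(ValueError, match="quad"):
            mimir.build_design(meta, tf_expr, komap)

    def test_injection_override_for_mis_expression(self):
        meta, tf_expr, komap = self._inputs()
        inj = {"ctrl": 0.0, "ko1": 1.0, "quad": 1.0}
        design = mimir.build_design(meta, tf_expr, komap, injection_map=inj)
        assert design.frame.loc["c4", "injection"] == 1.0


class TestFitRobust:
    def test_noiseless_identity(self):
        X = _design()
        y = 2.0 + 0.5 * X.frame["TF0"].values
        fit = mimir.fit_robust(y, X, gene="exact")
        assert fit.coef["TF0"] == pytest.approx(0.5, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response_degenerate(self):
        fit = mimir.fit_robust(np.full(200, 3.0), _design(), gene="const")
        assert fit.r2 == 0.0
        assert not (fit.pvalues < 1e-9).any()

    def test_outliers_hurt_ols_more_than_robust(self):
        """5% gross outliers: the robust coefficient stays within 0.05 of
        truth while an ordinary-least-squares oracle deviates by more."""
        rng = np.random.default_rng(42)
        X = _design(n=300, seed=1)
        tf = X.frame["TF0"].values
        y = 2.0 + 0.5 * tf + rng.normal(0, 0.1, 300)
        y[rng.random(300) < 0.05] += 10.0
        fit = mimir.fit_robust(y, X, gene="outl")
        ols = sm.OLS(y, X.frame[["const", "TF0"]].to_numpy()).fit()
        err_robust = abs(fit.coef["TF0"] - 0.5)
        err_ols = abs(ols.params[1] - 0.5)
        assert err_robust < 0.05
        assert err_ols > err_robust

    def test_zero_variance_predictors_dropped(self):
        X = _design()  # injection and batch constant at 0
        y = 1.0 + 0.3 * X.frame["TF0"].values
        fit = mimir.fit_robust(y, X, gene="g")
        assert "injection" in fit.dropped and "batch" in fit.dropped
        assert np.isnan(fit.coef["injection"])


class TestCallTargets:
    def _fit(self, gene, r2, coef, p):
        idx = ["const", "TF0", "injection", "batch"]
        return TargetFit(
            gene=gene,
            coef=pd.Series({**{c: 0.0 for c in idx}, "TF0": coef}),
            pvalues=pd.Series({**{c: 1.0 for c in idx}, "TF0": p}),
            r2=r2,
        )

    @pytest.mark.parametrize(
        "r2,coef,p,expected",
        [
            (0.2, 0.1, 1e-12, "positive"),  # all thresholds met
            (0.10, 0.3, 1e-20, None),  # r2 too low
            (0.3, -0.2, 1e-15, "negative"),  # symmetric negative rule
            (0.3, 0.04, 1e-15, None),  # coefficient below threshold
            (0.3, 0.2, 1e-8, None),  # p too large
        ],
    )
    def test_threshold_rules(self, r2, coef, p, expected):
        ts = mimir.call_targets([self._fit("g", r2, coef, p)], ["TF0"])
        if expected == "positive":
            assert "g" in ts.positive["TF0"]
        elif expected == "negative":
            assert "g" in ts.negative["TF0"]
        else:
            assert "g" not in ts.all_targets()

    def test_nonconverged_fit_excluded(self):
        fit = self._fit("g", 0.5, 0.5, 1e-20)
        fit.converged = False
        ts = mimir.call_targets([fit], ["TF0"])
        assert ts.all_targets() == set()


class TestInducedAndClassification:
    def test_induced_consensus_rule(self):
        def sets(ct, genes):
            return TargetSets(cell_type=ct, positive={"TF0": set(genes)})

        by_ct = [sets("a", ["g1", "g2"]), sets("b", ["g1"]), sets("c", ["g1", "g3"])]
        induced = mimir.call_induced_targets(by_ct, min_cell_types=2)
        assert induced["TF0"] == {"g1"}  # g2, g3 seen in only one cell type

    def test_classification_rules(self):
        enrichment = {"shared1": "noto", "a_only": "noto", "b_only": "gland", "stray": "gland"}
        classes = mimir.classify_targets(
            {"shared1", "a_only", "stray"},
            {"shared1", "b_only"},
            enrichment,
            cell_type_a="noto",
            cell_type_b="gland",
        )
        assert classes["shared"] == {"shared1"}
        assert classes["a_specific"] == {"a_only"}
        assert classes["b_specific"] == {"b_only"}
        assert classes["unclassified"] == {"stray"}

    def test_module_overlap_ranking(self):
        part = ModulePartition(
            assignments={**{f"a{i}": "mA" for i in range(10)}, **{f"b{i}": "mB" for i in range(4)}}
        )
        targets = {f"a{i}" for i in range(5)}
        df = mimir.target_module_overlap(targets, part)
        assert df.loc["mA", "target_pct"] == pytest.approx(50.0)
        assert df.loc["mB", "target_pct"] == 0.0
        assert list(df.index) == ["mA", "mB"]
        with pytest.raises(ValueError):
            mimir.target_module_overlap({"zz"}, part)


class TestRecoveryOnSimulatedData:
    def test_precision_recall_and_no_confound_leakage(self, perturbation_fit):
        """Planted targets recovered at the study thresholds; injection and
        batch confounds do not produce false calls among non-targets."""
        norm, design, results, truth = perturbation_fit
        ts = results.call_targets()
        called = {
            (tf, g)
            for tf, genes in {**ts.positive}.items()
            for g in genes
        } | {(tf, g) for tf, genes in ts.negative.items() for g in genes}
        truthset = set(truth.true_targets)
        tp = len(called & truthset)
        assert tp / max(len(called), 1) >= 0.9  # precision
        assert tp / len(truthset) >= 0.9  # recall
        # false-positive rate among non-target genes below 1%
        target_genes = {g for _, g in truthset}
        non_target_calls = {g for _, g in called - truthset if g not in target_genes}
        n_non_targets = len(results.fits) - len(target_genes)
        assert len(non_target_calls) / n_non_targets < 0.01

    def test_knockout_zeroing_matches_observed_zero(self, perturbation_sim):
        """Zeroing a knocked-out TF's predictor is equivalent to using its
        observed (near-zero) expression."""
        counts, truth, conditions = perturbation_sim
        norm = mimir.normalize_counts(counts)
        tfs = ["TF0", "TF1"]
        idx = [norm.gene_ids.index(t) for t in tfs]
        tf_expr = mimir.NormalizedMatrix(
            tfs, list(norm.cell_ids), norm.values[idx], norm.cell_meta, norm.scale_total
        )
        komap = {c.name: set(c.knockout) for c in conditions}
        inj = {c.name: c.injection for c in conditions}
        zeroed = mimir.build_design(norm.cell_meta, tf_expr, komap, injection_map=inj)
        observed = mimir.build_design(
            norm.cell_meta, tf_expr, {c.name: set() for c in conditions}, injection_map=inj
        )
        gidx = {g: i for i, g in enumerate(norm.gene_ids)}
        rng = np.random.default_rng(1)
        genes = rng.choice(sorted({g for _, g in truth.true_targets}), 8, replace=False)
        for g in genes:
            tf = next(tf for (tf, gg) in truth.true_targets if gg == g)
            c1 = mimir.fit_robust(norm.values[gidx[g]], zeroed, gene=g).coef[tf]
            c2 = mimir.fit_robust(norm.values[gidx[g]], observed, gene=g).coef[tf]
            assert c2 == pytest.approx(c1, rel=0.10)

    def test_summary_mentions_targets(self, perturbation_fit):
        _, _, results, _ = perturbation_fit
        text = results.summary()
        assert "TF0" in text and "positive" in text
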