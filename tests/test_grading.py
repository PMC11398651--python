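"""Grade tests, splitting, SMOTE, RFE and the boosted-tree model."""

import numpy as np
import pandas as pd
import pytest

from dcect_radiomics.grading import (
    wilcoxon_grade_test, split_train_test, smote_oversample,
    rfe_select_features, train_eval_boosted_trees, run_grading_pipeline,
    descriptive_statistics,
)
from _oracles import wilcoxon_exact_bruteforce


class TestWilcoxon:
    def test_fully_separated_small_groups(self):
        # (1,2,3) vs (4,5,6): most extreme of C(6,3)=20 orderings, doubled
        p = wilcoxon_grade_test([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        p = wilcoxon_grade_test([5, 5, 5, 5], [0, 0, 1, 1])
        assert p == 1.0

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 12)
        g = np.array([0] * 6 + [1] * 6)
        assert wilcoxon_grade_test(x, g) == pytest.approx(
            wilcoxon_grade_test(np.exp(3 * x), g), abs=1e-12)

    @pytest.mark.parametrize("seed", range(40))
    def test_exact_path_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 5))
        n2 = int(rng.integers(2, 11 - n1))
        vals = rng.integers(0, 6, n1 + n2).astype(float)  # ties likely
        groups = np.array([0] * n1 + [1] * n2)
        if len(np.unique(vals[:n1])) + len(np.unique(vals[n1:])) < 2:
            vals[0] += 0.5
        p = wilcoxon_grade_test(vals, groups)
        assert p == pytest.approx(wilcoxon_exact_bruteforce(vals, groups), abs=1e-12)

    def test_one_group_too_small(self):
        with pytest.raises(ValueError):
            wilcoxon_grade_test([1, 2, 3], [0, 1, 1])


def _cohort(n=39, n0=7, n_feat=4, seed=0, signal=2.0):
    rng = np.random.default_rng(seed)
    grades = pd.Series([0] * n0 + [1] * (n - n0),
                       index=[f"P{i:03d}" for i in range(n)])
    x = rng.normal(0, 1, (n, n_feat))
    x[:, 0] += signal * grades.values
    return pd.DataFrame(x, index=grades.index,
                        columns=[f"f{i}" for i in range(n_feat)]), grades


class TestSplit:
    def test_sizes_stratified_disjoint(self):
        x, g = _cohort()
        tr_x, tr_y, te_x, te_y = split_train_test(x, g, 29, 10, seed=1)
        assert len(tr_x) == 29 and len(te_x) == 10
        assert set(tr_x.index).isdisjoint(te_x.index)
        assert set(tr_x.index) | set(te_x.index) == set(x.index)
        assert tr_y.nunique() == te_y.nunique() == 2

    def test_deterministic(self):
        x, g = _cohort()
        a = split_train_test(x, g, 29, 10, seed=5)[2]
        b = split_train_test(x, g, 29, 10, seed=5)[2]
        assert list(a.index) == list(b.index)

    def test_wrong_total_raises(self):
        x, g = _cohort(n=20)
        with pytest.raises(ValueError):
            split_train_test(x, g, 29, 10)


class TestSmote:
    def test_balances_and_preserves_originals(self):
        x, g = _cohort(n=25, n0=5)
        bx, by = smote_oversample(x, g, seed=0)
        assert by.value_counts()[0] == by.value_counts()[1] == 20
        assert x.index.isin(bx.index).all()
        assert np.allclose(bx.loc[x.index].values, x.values)

    def test_synthetic_rows_on_minority_segments(self):
        x, g = _cohort(n=25, n0=5, n_feat=3)
        bx, by = smote_oversample(x, g, seed=1)
        minority = x[g == 0].values
        synth = bx.loc[[i for i in bx.index if str(i).startswith("synth")]].values
        for row in synth:
            # each synthetic point is a convex combination of two minority rows
            ok = False
            for a in range(len(minority)):
                for b in range(len(minority)):
                    if a == b:
                        continue
                    d = minority[b] - minority[a]
                    denom = (d ** 2).sum()
                    lam = ((row - minority[a]) @ d) / denom
                    if -1e-9 <= lam <= 1 + 1e-9 and np.allclose(
                            row, minority[a] + lam * d, atol=1e-9):
                        ok = True
            assert ok

    def test_balanced_input_noop(self):
        x, g = _cohort(n=20, n0=10)
        bx, by = smote_oversample(x, g, seed=0)
        assert bx.equals(x) and by.equals(g)

    def test_deterministic(self):
        x, g = _cohort(n=25, n0=5)
        a = smote_oversample(x, g, seed=9)[0]
        b = smote_oversample(x, g, seed=9)[0]
        assert a.equals(b)

    def test_minority_of_one_raises(self):
        x, g = _cohort(n=21, n0=1)
        with pytest.raises(ValueError):
            smote_oversample(x, g)


class TestRFE:
    def test_few_candidates_returned_unchanged(self):
        x, g = _cohort(n_feat=2)
        assert rfe_select_features(x, g, seed=0) == ["f0", "f1"]
        x3, _ = _cohort(n_feat=3)
        assert rfe_select_features(x3, g, seed=0) == ["f0", "f1", "f2"]

    def test_separating_feature_selected(self):
        x, g = _cohort(n_feat=10, signal=4.0, seed=2)
        sel = rfe_select_features(x, g, seed=0)
        assert "f0" in sel and len(sel) <= 3

    def test_cap_at_three(self):
        x, g = _cohort(n_feat=12, seed=3)
        assert len(rfe_select_features(x, g, seed=1)) <= 3

    def test_single_class_raises(self):
        x, g = _cohort()
        with pytest.raises(ValueError):
            rfe_select_features(x, pd.Series(1, index=x.index))


class TestBoostedTrees:
    def test_perfectly_separable(self):
        x, g = _cohort(signal=8.0, seed=4)
        tr_x, tr_y, te_x, te_y = split_train_test(x, g, 29, 10, seed=0)
        rep = train_eval_boosted_trees(tr_x, tr_y, te_x, te_y, ["f0"], seed=0)
        assert rep.auc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_confusion_arithmetic(self):
        # TP 3, FN 1, TN 5, FP 1 -> sens .75, spec 5/6, ppv .75, npv 5/6
        from dcect_radiomics.grading import ModelReport, _safe_div
        tp, fn, tn, fp = 3, 1, 5, 1
        assert _safe_div(tp, tp + fn) == 0.75
        assert _safe_div(tn, tn + fp) == pytest.approx(5 / 6)
        assert _safe_div(tp, tp + fp) == 0.75
        assert _safe_div(tn, tn + fn) == pytest.approx(5 / 6)

    def test_label_randomized_null_band(self):
        """Permuted grades give chance-level AUC on a 10-patient test set."""
        rng = np.random.default_rng(5)
        aucs = []
        for rep_i in range(20):
            x, g = _cohort(signal=3.0, seed=rep_i)
            g = pd.Series(rng.permutation(g.values), index=g.index)
            if min(g.value_counts()) < 4:
                continue
            try:
                rep = run_grading_pipeline(x, g, 29, 10, seed=rep_i)
            except ValueError:
                continue
            if rep.auc is not None:
                aucs.append(rep.auc)
        assert len(aucs) >= 10
        assert 0.2 <= float(np.median(aucs)) <= 0.8

    def test_single_class_test_set_warns(self):
        x, g = _cohort()
        tr_x, tr_y, te_x, te_y = split_train_test(x, g, 29, 10, seed=0)
        te_y1 = pd.Series(1, index=te_y.index)
        with pytest.warns(UserWarning, match="AUC"):
            rep = train_eval_boosted_trees(tr_x, tr_y, te_x, te_y1, ["f0"], seed=0)
        assert rep.auc is None


class TestPipelineStructure:
    def test_no_leakage_smote_and_rfe_see_only_training(self, monkeypatch):
        """Balancing and selection must never observe the held-out patients."""
        import dcect_radiomics.grading as gr
        x, g = _cohort()
        seen = {}
        orig_smote, orig_rfe = gr.smote_oversample, gr.rfe_select_features

        def spy_smote(f, l, **kw):
            seen["smote"] = set(f.index)
            return orig_smote(f, l, **kw)

        def spy_rfe(f, l, **kw):
            seen["rfe"] = set(f.index)
            return orig_rfe(f, l, **kw)

        monkeypatch.setattr(gr, "smote_oversample", spy_smote)
        monkeypatch.setattr(gr, "rfe_select_features", spy_rfe)
        rep = gr.run_grading_pipeline(x, g, 29, 10, seed=0)
        train_ids = {i for i in seen["smote"] if not str(i).startswith("synth")}
        test_ids = set(x.index) - train_ids
        assert len(test_ids) == 10
        assert seen["rfe"].isdisjoint(test_ids)
        # after SMOTE the training set is twice its majority-class count
        assert rep.train_size == 2 * g.loc[list(train_ids)].value_counts().max()

    def test_descriptive_statistics_layout(self):
        x, g = _cohort()
        df = descriptive_statistics(x, g)
        assert set(df.columns) == {"feature", "group0_mean", "group0_std",
                                   "group1_mean", "group1_std", "wilcoxon_p"}
        assert len(df) == x.shape[1]
        assert df.wilcoxon_p.between(0, 1).all()
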