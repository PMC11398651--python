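"""Lin's CCC, Dice, sequence selection, reproducibility reports, pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dcect_radiomics.concordance import (
    lin_ccc, dice_coefficient, select_phase_sequences,
    interobserver_reproducible, pairwise_sequence_matrix,
    intra_phase_reproducible, prune_correlated, PHASES,
)
from dcect_radiomics.tables import FeatureTable
from _oracles import ccc_bruteforce, prune_bruteforce


class TestLinCCC:
    def test_perfect_concordance(self):
        assert lin_ccc([3, 1, 4, 1, 5], [3, 1, 4, 1, 5]) == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        assert lin_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7, abs=1e-15)

    def test_perfect_reversed(self):
        x = np.array([-2.0, 0.0, 2.0])       # zero mean
        assert lin_ccc(x, -x) == pytest.approx(-1.0)

    def test_constant_vectors(self):
        assert lin_ccc([5, 5, 5], [5, 5, 5]) == 1.0
        assert lin_ccc([5, 5, 5], [7, 7, 7]) == 0.0
        assert lin_ccc([5, 5, 5], [1, 2, 3]) == 0.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            lin_ccc([1, 2], [1, 2])

    def test_matches_independent_formula_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n)
            y = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n)
            assert lin_ccc(x, y) == pytest.approx(ccc_bruteforce(x, y), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=25),
           st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=25))
    def test_bounded_symmetric_and_self_concordant(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        c = lin_ccc(x, y)
        assert -1.0 - 1e-9 <= c <= 1.0 + 1e-9
        assert c == pytest.approx(lin_ccc(y, x), abs=1e-12)
        assert lin_ccc(x, x) == pytest.approx(1.0)

    def test_lin_inequality_vs_pearson(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            x = rng.normal(0, 2, 20)
            y = 0.5 * x + rng.normal(1, 1, 20)
            r = np.corrcoef(x, y)[0, 1]
            assert abs(lin_ccc(x, y)) <= abs(r) + 1e-12


class TestDice:
    def _m(self, idx, shape=(1, 4, 4)):
        m = np.zeros(shape, bool)
        for i in idx:
            m[i] = True
        return m

    def test_identity_disjoint_half(self):
        a = self._m([(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1)])
        b = self._m([(0, 1, 0), (0, 1, 1), (0, 2, 0), (0, 2, 1)])
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, ~a & self._m([(0, 3, 3)])) == 0.0
        assert dice_coefficient(a, b) == 0.5

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random((2, 5, 5)) < 0.4
            b = rng.random((2, 5, 5)) < 0.4
            d = dice_coefficient(a, b)
            assert d == dice_coefficient(b, a)
            assert 0 <= d <= 1
            assert (d == 1.0) == bool(np.array_equal(a, b)) or not (a.any() or b.any())

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.ones((1, 2, 2), bool), np.ones((1, 3, 2), bool))

    def test_both_empty_defined_one(self):
        with pytest.warns(UserWarning):
            assert dice_coefficient(np.zeros((1, 2, 2), bool),
                                    np.zeros((1, 2, 2), bool)) == 1.0


class TestSelection:
    def test_exactly_seven_selects_all(self):
        sel = select_phase_sequences({"NCE": [0, 1], "L-AP": list(range(7)),
                                      "PVP": list(range(7))})
        assert sel.lap == tuple(range(7))
        assert sel.pvp == tuple(range(7))

    def test_eleven_sequence_rule(self):
        # 1-based 1..11 -> {1, 2, 5, 6, 7, 10, 11}
        sel = select_phase_sequences({"NCE": [1, 2], "L-AP": list(range(1, 12)),
                                      "PVP": list(range(1, 8))})
        assert sel.lap == (1, 2, 5, 6, 7, 10, 11)

    def test_nce_first_two_only(self):
        sel = select_phase_sequences({"NCE": [3, 1, 4, 2, 5],
                                      "L-AP": list(range(7)), "PVP": list(range(7))})
        assert sel.nce == (1, 2)

    def test_insufficient_names_phase(self):
        with pytest.raises(ValueError, match="PVP"):
            select_phase_sequences({"NCE": [0, 1], "L-AP": list(range(7)),
                                    "PVP": list(range(5))})


def _toy_table(n_pat=6, n_feat=5, seed=0, radiologist="R1", noise=0.0):
    """Small synthetic feature table over the 16-slot selected grid."""
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 1, (n_pat, n_feat))
    slots = ([("NCE", i) for i in range(2)] + [("L-AP", i) for i in range(2, 9)]
             + [("PVP", i) for i in range(9, 16)])
    rows = []
    for s, (phase, seq) in enumerate(slots):
        vals = base + noise * rng.normal(0, 1, base.shape)
        for p in range(n_pat):
            for f in range(n_feat):
                rows.append({"patient_id": f"P{p}", "radiologist": radiologist,
                             "phase": phase, "seq_index": seq,
                             "feature": f"f{f}", "value": vals[p, f]})
    return FeatureTable(pd.DataFrame(rows))


class TestInterobserver:
    def test_identical_tables_all_reproducible(self):
        t1 = _toy_table(radiologist="R1")
        t2 = FeatureTable(t1.df.assign(radiologist="R2"))
        for phase in PHASES:
            rep = interobserver_reproducible(t1, t2, phase)
            assert rep.reproducible.all()

    def test_noise_feature_not_reproducible(self):
        t1 = _toy_table(n_pat=39, seed=1)
        df2 = t1.df.assign(radiologist="R2").copy()
        rng = np.random.default_rng(2)
        sel = df2.feature == "f0"
        df2.loc[sel, "value"] = rng.normal(0, 1, int(sel.sum()))
        rep = interobserver_reproducible(t1, FeatureTable(df2), "PVP")
        assert not rep.reproducible["f0"]
        assert rep.reproducible.drop("f0").all()

    def test_invariant_to_feature_order(self):
        t1 = _toy_table(seed=3)
        t2 = FeatureTable(t1.df.assign(radiologist="R2"))
        shuffled = FeatureTable(t1.df.sample(frac=1, random_state=0)
                                .reset_index(drop=True))
        a = interobserver_reproducible(t1, t2, "L-AP").reproducible_features()
        b = interobserver_reproducible(shuffled, t2, "L-AP").reproducible_features()
        assert a == b


class TestPairwiseMatrix:
    def test_flat_noiseless_cohort_all_counts_full(self):
        """With no noise, drift, or enhancement differences the feature
        values are identical across sequences, so every off-diagonal count
        equals the feature total."""
        t = _toy_table(n_feat=7, noise=0.0)
        counts, _ = pairwise_sequence_matrix(t)
        off = counts.values[~np.eye(16, dtype=bool)]
        assert (off == 7).all()
        assert (np.diag(counts.values) == 7).all()

    def test_symmetry(self):
        t = _toy_table(noise=0.3, seed=5)
        counts, _ = pairwise_sequence_matrix(t)
        assert (counts.values == counts.values.T).all()

    def test_missing_patient_reported(self):
        t = _toy_table()
        df = t.df[~((t.df.patient_id == "P3") & (t.df.seq_index == 4))]
        with pytest.raises(ValueError, match="P3"):
            pairwise_sequence_matrix(FeatureTable(df.reset_index(drop=True)))


class TestIntraPhase:
    def test_noiseless_returns_all(self):
        t = _toy_table(n_feat=4)
        for phase in PHASES:
            assert intra_phase_reproducible(t, phase) == [f"f{i}" for i in range(4)]

    def test_degenerate_column_excluded(self):
        t = _toy_table(n_feat=3)
        df = t.df.copy()
        sel = (df.feature == "f1") & (df.seq_index == 9)
        df.loc[sel, "value"] = 42.0   # constant across patients in one sequence
        out = intra_phase_reproducible(FeatureTable(df), "PVP")
        assert "f1" not in out and "f0" in out

    def test_equals_intersection_of_pairwise_sets(self):
        t = _toy_table(n_feat=6, noise=0.25, seed=8)
        _, panel = pairwise_sequence_matrix(t)
        wide = t.wide()
        keys = sorted(wide.keys(), key=lambda k: (PHASES.index(k[0]), k[1]))
        lap_pos = [i for i, k in enumerate(keys) if k[0] == "L-AP"]
        expected = []
        for f, ccc in panel.items():
            sub = ccc[np.ix_(lap_pos, lap_pos)]
            iu = np.triu_indices(len(lap_pos), 1)
            if (sub[iu] >= 0.90).all():
                expected.append(f)
        assert intra_phase_reproducible(t, "L-AP") == sorted(expected)


class TestPrune:
    def _frame(self, cols, seed=0, n=20):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({c: rng.normal(0, 1, n) for c in cols})

    def test_duplicate_collapsed_independent_kept(self):
        df = self._frame(["a", "c"], seed=1)
        df["b"] = df["a"]
        kept = prune_correlated(df, 0.9)
        assert "c" in kept
        assert sum(f in kept for f in ("a", "b")) == 1

    def test_no_pair_above_threshold_is_noop(self):
        df = self._frame(["a", "b", "c"], seed=2)
        assert prune_correlated(df, 0.9) == ["a", "b", "c"]

    def test_retained_set_never_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            base = rng.normal(0, 1, (15, 3))
            mix = base @ rng.normal(0, 1, (3, 6))
            df = pd.DataFrame(mix, columns=list("abcdef"))
            kept = prune_correlated(df, 0.9)
            sub = df[kept].rank().corr().abs().values
            np.fill_diagonal(sub, 0)
            assert sub.max() <= 0.9 + 1e-12

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_stepwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 7))
        base = rng.normal(0, 1, (12, max(2, k - 2)))
        mix = base @ rng.normal(0, 1, (base.shape[1], k)) + 0.3 * rng.normal(0, 1, (12, k))
        df = pd.DataFrame(mix, columns=[f"f{i}" for i in range(k)])
        assert prune_correlated(df, 0.9) == prune_bruteforce(df, 0.9)

    def test_constant_column_warns(self):
        df = self._frame(["a", "b"], seed=4)
        df["c"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            kept = prune_correlated(df, 0.9)
        assert "c" in kept
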