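import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mc5 import (
    GeneSet,
    GeneSetCollection,
    TisWeights,
    compare_groups,
    correlate_score,
    immunity_cycle_activity,
    ssgsea,
    tis,
)

from conftest import make_expr


def ssgsea_oracle(col, genes, set_genes, alpha):
    """Loop-based Barbie running sum written independently of the package."""
    n = len(col)
    ranks = stats.rankdata(col)
    order = sorted(range(n), key=lambda i: (-col[i], i))
    in_set = [genes[i] in set_genes for i in range(n)]
    sum_in = sum(ranks[i] ** alpha for i in order if in_set[i])
    n_out = n - sum(in_set)
    es, p_in, p_out = 0.0, 0.0, 0.0
    for i in order:
        if in_set[i]:
            p_in += ranks[i] ** alpha / sum_in
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


def _sets(**kw):
    return GeneSetCollection({k: GeneSet(frozenset(v)) for k, v in kw.items()})


class TestSsgsea:
    def test_matches_independent_oracle(self, rng):
        g, n = 40, 6
        x = rng.normal(5, 2, size=(g, n))
        genes = [f"g{i}" for i in range(g)]
        set_genes = {"g3", "g7", "g11", "g20", "g33"}
        expr = make_expr(x)
        scores = ssgsea(expr, _sets(sig=set_genes), normalize=False)
        for j in range(n):
            assert scores.iloc[0, j] == pytest.approx(
                ssgsea_oracle(x[:, j], genes, set_genes, 0.25), abs=1e-10
            )

    def test_tied_expression_matches_oracle(self, rng):
        x = rng.integers(0, 4, size=(25, 4)).astype(float)  # many ties
        genes = [f"g{i}" for i in range(25)]
        set_genes = {"g1", "g5", "g9"}
        scores = ssgsea(make_expr(x), _sets(sig=set_genes), normalize=False)
        for j in range(4):
            assert scores.iloc[0, j] == pytest.approx(
                ssgsea_oracle(x[:, j], genes, set_genes, 0.25), abs=1e-10
            )

    def test_high_set_expression_scores_higher(self, rng):
        x = rng.normal(5, 1, size=(50, 20))
        set_idx = np.arange(8)
        x[np.ix_(set_idx, np.arange(10))] += 3.0  # first 10 samples enriched
        scores = ssgsea(make_expr(x), _sets(sig={f"g{i}" for i in set_idx}))
        assert scores.iloc[0, :10].min() > scores.iloc[0, 10:].max()

    def test_normalization_divides_by_global_range(self, rng):
        x = rng.normal(size=(30, 8))
        sets = _sets(a={"g0", "g1", "g2"}, b={"g10", "g11"})
        raw = ssgsea(make_expr(x), sets, normalize=False)
        norm = ssgsea(make_expr(x), sets, normalize=True)
        rng_ = raw.to_numpy().max() - raw.to_numpy().min()
        assert np.allclose(norm.to_numpy(), raw.to_numpy() / rng_)

    def test_no_overlap_set_skipped_all_missing_raises(self, rng):
        x = rng.normal(size=(10, 4))
        scores = ssgsea(make_expr(x), _sets(ok={"g0", "g1"}, gone={"NOPE"}))
        assert list(scores.index) == ["ok"]
        with pytest.raises(ValueError, match="no signature"):
            ssgsea(make_expr(x), _sets(gone={"NOPE"}))

    def test_empty_collection_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            ssgsea(make_expr(rng.normal(size=(5, 3))), GeneSetCollection({}))


class TestTis:
    def _weights(self):
        return TisWeights({f"T{i}": 0.1 * (i + 1) for i in range(18)})

    def test_weighted_sum_oracle(self, rng):
        w = self._weights()
        x = rng.normal(5, 1, size=(18, 6))
        expr = make_expr(x, genes=list(w.weights))
        s = tis(expr, w)
        oracle = np.array(list(w.weights.values())) @ x
        assert np.allclose(s.to_numpy(), oracle, atol=1e-12)

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError, match="18"):
            TisWeights({"A": 1.0})

    def test_missing_genes_contribute_zero(self, rng):
        w = self._weights()
        x = rng.normal(5, 1, size=(10, 4))
        expr = make_expr(x, genes=[f"T{i}" for i in range(10)])
        s = tis(expr, w)
        oracle = np.array([0.1 * (i + 1) for i in range(10)]) @ x
        assert np.allclose(s.to_numpy(), oracle, atol=1e-12)

    def test_all_missing_rejected(self, rng):
        with pytest.raises(ValueError, match="none"):
            tis(make_expr(rng.normal(size=(3, 2))), self._weights())

    def test_from_tsv_round_trip(self, tmp_path):
        p = tmp_path / "tis.tsv"
        p.write_text("".join(f"T{i}\t{0.5 * i}\n" for i in range(18)))
        w = TisWeights.from_tsv(p)
        assert w.weights["T4"] == pytest.approx(2.0)


class TestImmunityCycle:
    def test_signed_step_is_pos_minus_neg(self, rng):
        x = rng.normal(5, 1, size=(30, 10))
        expr = make_expr(x)
        pos, neg = {"g0", "g1", "g2"}, {"g10", "g11"}
        signed = GeneSetCollection(
            {
                "step1": GeneSet(
                    frozenset(pos | neg),
                    weights={**{g: +1 for g in pos}, **{g: -1 for g in neg}},
                )
            }
        )
        out = immunity_cycle_activity(expr, signed, normalize=False)
        p = ssgsea(expr, _sets(step1=pos), normalize=False)
        n = ssgsea(expr, _sets(step1=neg), normalize=False)
        assert np.allclose(out.to_numpy(), (p - n).to_numpy(), atol=1e-10)

    def test_unsigned_step_equals_plain_ssgsea(self, rng):
        x = rng.normal(size=(20, 5))
        expr = make_expr(x)
        sets = _sets(step={"g0", "g3", "g7"})
        out = immunity_cycle_activity(expr, sets, normalize=False)
        ref = ssgsea(expr, sets, normalize=False)
        assert np.allclose(out.to_numpy(), ref.to_numpy())


class TestCorrelateScore:
    def test_matches_scipy(self, rng):
        n = 50
        s = pd.Series(rng.normal(size=n), index=[f"s{j}" for j in range(n)])
        feats = pd.DataFrame(
            rng.normal(size=(4, n)),
            index=list("abcd"),
            columns=s.index,
        )
        out = correlate_score(s, feats)
        for f in feats.index:
            r, p = stats.spearmanr(s.to_numpy(), feats.loc[f].to_numpy())
            assert out.loc[f, "coefficient"] == pytest.approx(r, abs=1e-12)
            assert out.loc[f, "p"] == pytest.approx(p, rel=1e-10)

    def test_constant_feature_flagged(self, rng):
        n = 20
        s = pd.Series(rng.normal(size=n), index=[f"s{j}" for j in range(n)])
        feats = pd.DataFrame(
            np.vstack([np.ones(n), rng.normal(size=n)]), index=["flat", "ok"], columns=s.index
        )
        out = correlate_score(s, feats)
        assert out.loc["flat", "constant"] and np.isnan(out.loc["flat", "coefficient"])
        assert not out.loc["ok", "constant"]

    def test_pearson_option_and_bad_method(self, rng):
        n = 30
        s = pd.Series(rng.normal(size=n), index=[f"s{j}" for j in range(n)])
        feats = pd.DataFrame(rng.normal(size=(1, n)), index=["a"], columns=s.index)
        out = correlate_score(s, feats, method="pearson")
        r, _ = stats.pearsonr(s.to_numpy(), feats.loc["a"].to_numpy())
        assert out.loc["a", "coefficient"] == pytest.approx(r, abs=1e-12)
        with pytest.raises(ValueError):
            correlate_score(s, feats, method="kendall")


class TestCompareGroups:
    def _frame(self, rows, samples):
        return pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))], columns=samples)

    def test_forced_tests_match_scipy(self, rng):
        n = 40
        samples = [f"s{j}" for j in range(n)]
        g = pd.Series(np.repeat(["a", "b"], n // 2), index=samples)
        y = rng.normal(size=n)
        y[n // 2:] += 1.0
        feats = self._frame([y], samples)
        out_t = compare_groups(feats, g, test="t")
        _, p_t = stats.ttest_ind(y[: n // 2], y[n // 2:], equal_var=False)
        assert out_t.loc["f0", "p"] == pytest.approx(p_t, rel=1e-10)
        out_u = compare_groups(feats, g, test="mwu")
        _, p_u = stats.mannwhitneyu(
            y[: n // 2], y[n // 2:], alternative="two-sided", method="asymptotic"
        )
        assert out_u.loc["f0", "p"] == pytest.approx(p_u, rel=1e-10)
        assert out_t.loc["f0", "direction"] > 0

    def test_binary_feature_uses_fisher(self, rng):
        n = 60
        samples = [f"s{j}" for j in range(n)]
        g = pd.Series(np.repeat(["a", "b"], n // 2), index=samples)
        y = np.r_[rng.binomial(1, 0.8, n // 2), rng.binomial(1, 0.2, n // 2)].astype(float)
        out = compare_groups(self._frame([y], samples), g, test="auto")
        assert out.loc["f0", "test"] == "fisher"
        table = [
            [int(y[: n // 2].sum()), int(n // 2 - y[: n // 2].sum())],
            [int(y[n // 2:].sum()), int(n // 2 - y[n // 2:].sum())],
        ]
        _, p = stats.fisher_exact(table)
        assert out.loc["f0", "p"] == pytest.approx(p, rel=1e-12)

    def test_auto_picks_mwu_for_skewed(self, rng):
        n = 60
        samples = [f"s{j}" for j in range(n)]
        g = pd.Series(np.repeat(["a", "b"], n // 2), index=samples)
        y = rng.exponential(1.0, n) ** 3  # heavily non-normal
        out = compare_groups(self._frame([y], samples), g, test="auto")
        assert out.loc["f0", "test"] == "mwu"

    def test_not_two_groups_rejected(self, rng):
        samples = [f"s{j}" for j in range(6)]
        g = pd.Series(["a"] * 6, index=samples)
        with pytest.raises(ValueError, match="two groups"):
            compare_groups(self._frame([np.arange(6.0)], samples), g)
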