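import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from genewalk.benchmark import (
    auroc,
    clamp_padj,
    kendall_tau_vs_truth,
    lr_uniformity_test,
    mgsa_convert,
    parental_enhance,
    random_baseline,
    relevance_score,
)
from .conftest import make_ontology


def tau_b_oracle(x, y):
    """All-pairs concordant/discordant count with tie correction."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = len(x) * (len(x) - 1) / 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom if denom > 0 else np.nan


class TestClamp:
    @pytest.mark.parametrize(
        "padj,expected", [(0.05, 0.05), (0.0999, 0.0999), (0.10, 1.0),
                          (0.9999, 1.0), (1.0, 1.0)]
    )
    def test_threshold_rule(self, padj, expected):
        assert clamp_padj(padj) == expected


class TestKendallTau:
    def test_all_insignificant_gives_zero(self):
        pred = {"t1": 1.0, "t2": 1.0, "t3": 1.0}
        truth = {"t1": True, "t2": False, "t3": False}
        assert kendall_tau_vs_truth(pred, truth) == 0.0

    def test_all_relevant_all_significant_tied_gives_one(self):
        pred = {"t1": 0.01, "t2": 0.01, "t3": 0.01}
        truth = {"t1": True, "t2": True, "t3": True}
        assert kendall_tau_vs_truth(pred, truth) == 1.0

    def test_all_relevant_but_insignificant_gives_zero(self):
        pred = {"t1": 1.0, "t2": 1.0}
        truth = {"t1": True, "t2": True}
        assert kendall_tau_vs_truth(pred, truth) == 0.0

    def test_explicit_three_term_example(self):
        pred = {"t1": 0.01, "t2": 0.05, "t3": 1.0}
        truth = {"t1": True, "t2": False, "t3": False}
        expected = tau_b_oracle([0.01, 0.05, 1.0], [1, 2, 2])
        assert kendall_tau_vs_truth(pred, truth) == pytest.approx(expected)

    def test_matches_all_pairs_oracle(self, rng):
        checked = 0
        while checked < 200:
            n = int(rng.integers(2, 9))
            padj = rng.choice([0.01, 0.03, 0.07, 0.5, 1.0], size=n)
            rel = rng.random(n) < 0.5
            if not rel.any():
                continue
            keys = [f"t{i}" for i in range(n)]
            pred = dict(zip(keys, padj))
            truth = dict(zip(keys, rel))
            clamped = [clamp_padj(p) for p in padj]
            ranks = [1 if r else 2 for r in rel]
            expected = tau_b_oracle(clamped, ranks)
            got = kendall_tau_vs_truth(pred, truth)
            if np.isnan(expected):
                assert got in (0.0, 1.0)
            else:
                assert got == pytest.approx(expected)
            checked += 1

    def test_mismatched_sets_error(self):
        with pytest.raises(ValueError):
            kendall_tau_vs_truth({"a": 0.5}, {"b": True})


class TestMgsa:
    @pytest.mark.parametrize(
        "ppost,expected", [(0.8, 0.92), (0.5, 1.0), (1.0, 0.9), (0.51, 0.949)]
    )
    def test_conversion(self, ppost, expected):
        assert mgsa_convert(ppost) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            mgsa_convert(1.2)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([True, True, False, False], [0.01, 0.02, 0.9, 1.0]) == 1.0

    def test_all_scores_equal(self):
        assert auroc([True, False], [0.5, 0.5]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([True, True], [0.1, 0.2])

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 15))
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            padj = rng.choice([0.01, 0.05, 0.2, 1.0], size=n)
            score = relevance_score(padj)
            pos = score[labels]
            neg = score[~labels]
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            )
            assert auroc(labels, padj) == pytest.approx(
                wins / (len(pos) * len(neg))
            )


class TestRandomBaseline:
    @staticmethod
    def benchmark(rng, n_genes=20, n_ann=10):
        truth = {}
        for g in range(n_genes):
            rel = rng.permutation([True] * (n_ann // 2)
                                  + [False] * (n_ann - n_ann // 2))
            truth[f"g{g}"] = {f"t{i}": bool(r) for i, r in enumerate(rel)}
        return truth

    def test_auroc_near_half(self, rng):
        truth = self.benchmark(rng)
        _, mean_auroc = random_baseline(truth, n_samples=100, seed=1)
        assert mean_auroc == pytest.approx(0.5, abs=0.05)

    def test_tau_bounds_for_all_relevant_gene(self):
        truth = {"g": {f"t{i}": True for i in range(6)}}
        # pooled AUROC is undefined when every pooled label is positive
        with pytest.raises(ValueError):
            random_baseline(truth, n_samples=5, seed=0)
        truth["h"] = {"t0": True, "t1": False}
        taus, _ = random_baseline(truth, n_samples=20, seed=0)
        assert 0.0 <= taus["g"] <= 1.0

    def test_seeded_determinism(self, rng):
        truth = self.benchmark(rng, n_genes=5)
        out1 = random_baseline(truth, n_samples=3, seed=9)
        out2 = random_baseline(truth, n_samples=3, seed=9)
        assert out1 == out2


class TestParentalEnhance:
    ontology = staticmethod(lambda: make_ontology(
        [("leaf", "mid"), ("mid", "root"), ("leaf2", "root")]
    ))

    def test_insignificant_child_takes_ancestor_value(self):
        preds = {("g", "leaf"): 0.5, ("g", "mid"): 0.02, ("g", "root"): 0.9}
        out = parental_enhance(preds, self.ontology())
        assert out[("g", "leaf")] == 0.02

    def test_significant_child_unchanged(self):
        preds = {("g", "leaf"): 0.05, ("g", "mid"): 0.01}
        out = parental_enhance(preds, self.ontology())
        assert out[("g", "leaf")] == 0.05

    def test_minimum_of_multiple_significant_ancestors(self):
        preds = {("g", "leaf"): 0.5, ("g", "mid"): 0.04, ("g", "root"): 0.01}
        out = parental_enhance(preds, self.ontology())
        assert out[("g", "leaf")] == 0.01

    def test_indirect_ancestor_reached(self):
        preds = {("g", "leaf"): 0.5, ("g", "root"): 0.03}
        out = parental_enhance(preds, self.ontology())
        assert out[("g", "leaf")] == 0.03

    def test_idempotent_and_never_increases(self, rng):
        onto = self.ontology()
        terms = list(onto)
        for _ in range(20):
            preds = {
                ("g", t): float(rng.choice([0.01, 0.05, 0.3, 1.0]))
                for t in terms
            }
            once = parental_enhance(preds, onto)
            twice = parental_enhance(once, onto)
            assert once == twice
            assert all(once[k] <= preds[k] for k in preds)

    def test_unknown_term_errors(self):
        with pytest.raises(KeyError):
            parental_enhance({("g", "nope"): 0.5}, self.ontology())


def lr_oracle(observations):
    """Direct multinomial likelihoods under both hypotheses."""
    from collections import Counter

    counts = Counter((y, x) for x, y in observations)
    totals = Counter()
    for (y, x), n in counts.items():
        totals[x] += n
    ll0 = sum(n * math.log(1.0 / (x + 1)) for (y, x), n in counts.items())
    ll1 = sum(n * math.log(n / totals[x]) for (y, x), n in counts.items())
    return -2.0 * (ll0 - ll1)


class TestLrUniformity:
    def test_even_split_statistic_zero(self):
        obs = [(1, 0)] * 5 + [(1, 1)] * 5
        res = lr_uniformity_test(obs)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_df_formula(self):
        res = lr_uniformity_test([(2, 0), (2, 1), (1, 0)])
        assert res.x_max == 2
        assert res.df == 5  # x_max (x_max + 3) / 2
        strict = lr_uniformity_test([(2, 0), (2, 1), (1, 0)],
                                    df_mode="constrained")
        assert strict.df == 3

    def test_small_table_matches_direct_likelihood(self):
        obs = [(2, 0)] * 3 + [(2, 1)] * 3 + [(2, 2)] * 3
        res = lr_uniformity_test(obs)
        assert res.statistic == pytest.approx(lr_oracle(obs), abs=1e-9)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_random_tables_match_direct_likelihood(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 60))
            xs = rng.integers(1, 6, size=n)
            ys = np.array([rng.integers(0, x + 1) for x in xs])
            obs = list(zip(xs.tolist(), ys.tolist()))
            res = lr_uniformity_test(obs)
            assert res.statistic == pytest.approx(lr_oracle(obs), abs=1e-9)
            assert res.statistic >= -1e-9
            assert sum(res.totals.values()) == n

    def test_validation(self):
        with pytest.raises(ValueError):
            lr_uniformity_test([])
        with pytest.raises(ValueError):
            lr_uniformity_test([(2, 3)])
        with pytest.raises(ValueError):
            lr_uniformity_test([(0, 0)])

    def test_power_under_extreme_alternative(self, rng):
        xs = rng.integers(1, 6, size=500)
        obs = [(int(x), int(x)) for x in xs]  # y = x always
        res = lr_uniformity_test(obs)
        assert res.p_value < 1e-6

    def test_audit_counts(self):
        res = lr_uniformity_test([(1, 0), (1, 0), (1, 1), (3, 2)])
        assert res.counts[(0, 1)] == 2
        assert res.totals == {1: 3, 3: 1}
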