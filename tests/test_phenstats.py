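"""Fisher/chi-square association tests, the pair matrix and the network.

Oracles are independent of the implementation path: exhaustive
hypergeometric enumeration for Fisher, and the Sum((O-E)^2/E) closed form
with the chi-square(1) survival function for the pair statistic.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist

from cnvcohort.phenstats import (
    ContingencyTable2x2,
    PairAssociationMatrix,
    ZeroMarginError,
    build_network,
    chi_square_2x2,
    feature_vs_pcnv,
    fisher_exact_2x2,
    pair_matrix,
)
from cnvcohort.simulate import GeneratorParams, generate


def fisher_enumeration(table: ContingencyTable2x2) -> float:
    """Sum hypergeometric probabilities <= that of the observed table."""
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x) * math.comb(n - col1, row1 - x) / math.comb(n, row1)
        )

    p_obs = prob(a)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def chi_square_oracle(table: ContingencyTable2x2) -> tuple[float, float]:
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    return stat, float(chi2_dist.sf(stat, df=1))


def frame(carrier, **features) -> pd.DataFrame:
    data = {"pcnv": np.asarray(carrier, dtype=bool)}
    for name, vals in features.items():
        data[f"ph_{name}"] = np.asarray(vals, dtype=float)
    return pd.DataFrame(data)


class TestFisher:
    def test_balanced_table_is_null(self):
        orr, p = fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert orr == 1.0 and p == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        t = ContingencyTable2x2(3, 1, 1, 3)
        _, p = fisher_exact_2x2(t)
        assert p == pytest.approx(fisher_enumeration(t), rel=1e-12)

    def test_severe_obesity_sex_imbalance_is_significant(self):
        # 105 of 160 severely obese vs 55 of 85... sex split among severity
        _, p = fisher_exact_2x2(ContingencyTable2x2(105, 18, 55, 30))
        assert p < 0.01

    def test_zero_margin_is_undefined(self):
        with pytest.raises(ZeroMarginError):
            fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4))

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 200:
            a, b, c, d = rng.integers(0, 11, size=4)
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            if 0 in t.margins():
                continue
            _, p = fisher_exact_2x2(t)
            assert p == pytest.approx(fisher_enumeration(t), rel=1e-9)
            checked += 1

    def test_infinite_odds_ratio(self):
        orr, _ = fisher_exact_2x2(ContingencyTable2x2(3, 1, 0, 4))
        assert orr == math.inf


class TestFeatureVsPcnv:
    def test_exactly_proportional_feature_gives_p_one(self):
        # feature rate identical in carriers (5/10) and non-carriers (20/40)
        carrier = [True] * 10 + [False] * 40
        feature = [1] * 5 + [0] * 5 + [1] * 20 + [0] * 20
        table, p = feature_vs_pcnv(frame(carrier, x=feature), "x")
        assert p == pytest.approx(1.0)
        assert table.odds_ratio == pytest.approx(1.0)

    def test_unknowns_excluded_from_both_margins(self):
        carrier = [True] * 3 + [False] * 5
        feature = [1, None, 0, 1, None, None, 0, 0]
        vals = [float("nan") if v is None else float(v) for v in feature]
        table, _ = feature_vs_pcnv(frame(carrier, x=vals), "x")
        assert table.n == 5  # three unknowns dropped

    def test_carrier_only_feature_has_infinite_or(self):
        carrier = [True] * 3 + [False] * 6
        feature = [1, 1, 1, 0, 0, 0, 0, 0, 0]
        table, _ = feature_vs_pcnv(frame(carrier, x=feature), "x")
        assert table.odds_ratio == math.inf

    def test_unknown_feature_name_raises(self):
        with pytest.raises(KeyError):
            feature_vs_pcnv(frame([True, False], x=[1, 0]), "nope")


class TestChiSquare:
    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 100:
            cells = rng.integers(1, 40, size=4)
            t = ContingencyTable2x2(*map(int, cells))
            stat, p = chi_square_2x2(t)
            ostat, op = chi_square_oracle(t)
            assert stat == pytest.approx(ostat, rel=1e-12)
            assert p == pytest.approx(op, rel=1e-12)
            checked += 1


class TestPairMatrix:
    def test_identical_distribution_gives_zero_statistic(self):
        carrier = [True] * 10 + [False] * 20
        a = [1] * 5 + [0] * 5 + [1] * 10 + [0] * 10
        b = [1] * 5 + [0] * 5 + [1] * 10 + [0] * 10
        m = pair_matrix(frame(carrier, a=a, b=b), ["a", "b"])
        assert m.statistic[0, 1] == pytest.approx(0.0)
        assert m.p[0, 1] == pytest.approx(1.0)

    def test_pair_count_bound(self):
        rng = np.random.default_rng(0)
        carrier = rng.random(200) < 0.3
        features = {f"f{k}": rng.random(200) < 0.5 for k in range(15)}
        m = pair_matrix(frame(carrier, **features), sorted(features))
        assert m.n_evaluable() <= 105

    def test_zero_margin_pairs_marked_non_evaluable(self):
        carrier = [True] * 5 + [False] * 5
        a = [0] * 10  # never present: co-occurrence margin is zero
        b = [1] * 5 + [0] * 5
        m = pair_matrix(frame(carrier, a=a, b=b), ["a", "b"])
        assert not m.evaluable[0, 1]
        assert math.isnan(m.p[0, 1])

    def test_planted_pair_effect_detected_with_high_power(self):
        # carrier-enriched features whose co-occurrence has odds ratio 4
        # inside carriers, n=1000: the pair signal should be detected in
        # nearly every replicate
        params = dict(
            n_patients=1000,
            pcnv_prevalence=0.22,
            missing_anthro_rate=1.0,
            phenotype_base_rates={"a": 0.35, "b": 0.35},
            phenotype_carrier_log_or={"a": 0.8, "b": 0.8},
            pair_effects=[("a", "b", math.log(4.0))],
        )
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            cohort = generate(GeneratorParams(seed=seed, **params))
            m = pair_matrix(cohort.frame, ["a", "b"])
            if m.evaluable[0, 1] and m.p[0, 1] < 0.05:
                hits += 1
        assert hits / n_seeds >= 0.90

    def test_matrix_invariant_under_feature_reordering(self):
        rng = np.random.default_rng(3)
        carrier = rng.random(300) < 0.25
        features = {f"f{k}": rng.random(300) < 0.4 for k in range(6)}
        df = frame(carrier, **features)
        names = sorted(features)
        m1 = pair_matrix(df, names)
        shuffled = list(reversed(names))
        m2 = pair_matrix(df, shuffled)
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                b = names[j]
                assert m1.pair_p(a, b) == pytest.approx(m2.pair_p(a, b), nan_ok=True)

    def test_three_level_coding_available(self):
        carrier = [True] * 20 + [False] * 30
        rng = np.random.default_rng(9)
        a = rng.random(50) < 0.5
        b = rng.random(50) < 0.5
        m = pair_matrix(frame(carrier, a=a, b=b), ["a", "b"], coding="three_level")
        assert m.evaluable[0, 1]


def synthetic_matrix(features, sig_pairs, p_sig=0.01, p_null=0.5):
    k = len(features)
    p = np.full((k, k), p_null)
    stat = np.zeros((k, k))
    ev = np.ones((k, k), dtype=bool)
    np.fill_diagonal(ev, False)
    np.fill_diagonal(p, np.nan)
    idx = {f: i for i, f in enumerate(features)}
    for a, b in sig_pairs:
        p[idx[a], idx[b]] = p[idx[b], idx[a]] = p_sig
    return PairAssociationMatrix(features=list(features), p=p, statistic=stat,
                                 evaluable=ev)


class TestNetwork:
    def test_twelve_significant_pairs_over_18_features(self):
        features = [f"f{k:02d}" for k in range(18)]
        # 12 edges concentrated on the first 10 features
        pairs = [
            (features[i], features[j])
            for i, j in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 4), (2, 5),
                         (3, 6), (4, 7), (5, 8), (6, 9), (7, 9), (8, 9)]
        ]
        net = build_network(synthetic_matrix(features, pairs), alpha=0.05)
        assert len(net.edges) == 12
        assert len(net.connected_features) == 10
        assert len(net.isolated_features) == 8

    def test_alpha_zero_gives_empty_edge_set(self):
        features = ["a", "b", "c"]
        net = build_network(
            synthetic_matrix(features, [("a", "b")]), alpha=0.0
        )
        assert net.edges == []

    @pytest.mark.parametrize("rule", ["max_degree_quartile", "top_k"])
    def test_star_graph_core_is_the_hub(self, rule):
        features = ["hub", "s1", "s2", "s3", "s4"]
        pairs = [("hub", s) for s in features[1:]]
        net = build_network(
            synthetic_matrix(features, pairs), core_rule=rule, top_k=1
        )
        assert net.core == ["hub"]
        assert net.degree("hub") == 4

    def test_core_degrees_dominate_non_core(self):
        features = [f"f{k}" for k in range(8)]
        pairs = [("f0", "f1"), ("f0", "f2"), ("f0", "f3"), ("f1", "f2"),
                 ("f4", "f5")]
        net = build_network(synthetic_matrix(features, pairs))
        if net.core:
            core_min = min(net.degree(n) for n in net.core)
            rest = [net.degree(n) for n in net.nodes if n not in net.core]
            assert all(core_min >= d for d in rest)
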