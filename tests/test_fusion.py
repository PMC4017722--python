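"""Diversity rank/score machinery, combination enumeration, and leaderboard.

The leaderboard is cross-checked against an independent brute-force
recomputation (explicit loops, its own Pearson formula, no shared code).
"""

import math
from itertools import combinations as itercombos

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarfusion import (
    ActivityTable,
    CombinationSpec,
    CombinatorialFusion,
    CoverageError,
    InhibitorRecord,
    ScoreTable,
    SystemPerformance,
    all_pair_profiles,
    combine_scores,
    diversity_profile,
    diversity_score,
    enumerate_combinations,
    evaluate_system,
    leaderboard,
    recommend_pairs,
    select_systems,
    simulate_study,
    SimulationConfig,
)


def _toy_table(n=5):
    return ActivityTable(
        name="toy", records=[InhibitorRecord(f"C{i}", float(10 ** (i % 4) + i)) for i in range(n)]
    )


def _toy_system(label, table, shift):
    return ScoreTable(
        label=label, scores={r.id: r.ic50_nM * (1 + shift) for r in table.records}
    )


score_dicts = st.dictionaries(
    st.text(alphabet="ABCDE", min_size=1, max_size=3),
    st.floats(0.1, 1e5, allow_nan=False),
    min_size=1,
    max_size=10,
)


class TestDiversityScore:
    def test_printed_estimates_log_scale(self, table2):
        _, systems = table2
        by = {s.label: s for s in systems}
        value = diversity_score(by["BB"], by["FF"], "CHEMBL195177", scale="log10")
        assert value == pytest.approx(abs(math.log10(3.9) - math.log10(6.2)), abs=1e-12)
        assert value == pytest.approx(0.2013, abs=5e-5)

    def test_printed_estimates_raw_scale(self, table2):
        _, systems = table2
        by = {s.label: s for s in systems}
        assert diversity_score(by["BB"], by["FF"], "CHEMBL195177", scale="raw") == pytest.approx(2.3)

    def test_missing_id(self, table2):
        _, systems = table2
        with pytest.raises(CoverageError):
            diversity_score(systems[0], systems[1], "NOPE")

    @given(scores=score_dicts, shift=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_nonnegativity(self, scores, shift):
        a = ScoreTable("A", scores)
        b = ScoreTable("B", {k: v * shift for k, v in scores.items()})
        for compound in scores:
            d_ab = diversity_score(a, b, compound)
            assert d_ab >= 0
            assert d_ab == pytest.approx(diversity_score(b, a, compound), abs=1e-14)
            assert diversity_score(a, a, compound) == 0.0


class TestDiversityProfile:
    def test_self_pair_is_flat_zero(self, table2):
        table, systems = table2
        profile = diversity_profile(systems[0], systems[0], table)
        assert profile.aggregate == 0.0
        assert np.all(profile.f == 0)

    def test_f_is_nonincreasing_rearrangement(self, table2):
        table, systems = table2
        profile = diversity_profile(systems[0], systems[4], table)
        assert profile.t == 133
        assert np.all(np.diff(profile.f) <= 0)
        assert sorted(profile.f) == sorted(profile.scores.values())
        assert profile.aggregate == pytest.approx(sum(profile.scores.values()))
        assert profile.f[0] == max(profile.scores.values())
        assert profile.f[-1] == min(profile.scores.values())

    def test_single_disagreement(self):
        table = _toy_table(4)
        a = _toy_system("A", table, 0.0)
        scores = dict(a.scores)
        scores["C2"] *= 10
        b = ScoreTable("B", scores)
        profile = diversity_profile(a, b, table)
        assert profile.f[0] == pytest.approx(1.0)  # one decade apart
        assert np.all(profile.f[1:] == 0)
        assert profile.rank_order[0] == "C2"

    @pytest.mark.parametrize("q,expected", [(2, 1), (4, 6), (6, 15)])
    def test_pair_counts(self, q, expected):
        table = _toy_table(4)
        systems = [_toy_system(f"S{i}", table, 0.1 * i) for i in range(q)]
        profiles = all_pair_profiles(systems, table)
        assert len(profiles) == expected == q * (q - 1) // 2

    def test_needs_two_systems(self):
        table = _toy_table(3)
        with pytest.raises(ValueError):
            all_pair_profiles([_toy_system("A", table, 0)], table)


class TestEnumeration:
    @pytest.mark.parametrize("m,expected", [(1, 1), (3, 7), (6, 63)])
    def test_counts(self, m, expected):
        assert len(enumerate_combinations([f"S{i}" for i in range(m)])) == expected

    def test_matches_brute_force_subsets(self):
        for m in range(1, 11):
            labels = [f"S{i}" for i in range(m)]
            specs = enumerate_combinations(labels)
            brute = set()
            for mask in range(1, 2 ** m):
                brute.add(frozenset(labels[j] for j in range(m) if mask >> j & 1))
            assert {frozenset(s.members) for s in specs} == brute
            assert len(specs) == len(brute) == 2 ** m - 1

    def test_deterministic_order(self):
        specs = enumerate_combinations(["B", "A"])
        assert [s.members for s in specs] == [("A",), ("B",), ("A", "B")]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            enumerate_combinations(["A", "A"])
        with pytest.raises(ValueError):
            CombinationSpec(members=("A", "A"))
        with pytest.raises(ValueError):
            CombinationSpec(members=())


class TestCombineScores:
    def test_geometric_mean_of_printed_values(self, table2):
        table, systems = table2
        spec = CombinationSpec(members=("BB", "FF"))
        merged = combine_scores(spec, systems, table)
        assert merged["CHEMBL195177"] == pytest.approx(math.sqrt(3.9 * 6.2), rel=1e-12)
        assert merged["CHEMBL195177"] == pytest.approx(4.917, abs=5e-4)

    def test_raw_mean(self, table2):
        table, systems = table2
        spec = CombinationSpec(members=("BB", "FF"), rule="mean_raw")
        assert combine_scores(spec, systems, table)["CHEMBL195177"] == pytest.approx(5.05)

    def test_singleton_identity(self, table2):
        table, systems = table2
        merged = combine_scores(CombinationSpec(members=("BB",)), systems, table)
        bb = next(s for s in systems if s.label == "BB")
        for i in table.ids:
            assert merged[i] == pytest.approx(bb[i], rel=1e-14)

    def test_unknown_member(self, table2):
        table, systems = table2
        with pytest.raises(LookupError):
            combine_scores(CombinationSpec(members=("XX",)), systems, table)


# --- independent brute-force oracle (no shared code with the package) ------

def _brute_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def _brute_leaderboard(truth, system_scores):
    labels = sorted(system_scores)
    ids = list(truth)
    out = {}
    for mask in range(1, 2 ** len(labels)):
        members = tuple(labels[j] for j in range(len(labels)) if mask >> j & 1)
        r_values = []
        for i in ids:
            logs = [math.log10(system_scores[m][i]) for m in members]
            r_values.append(sum(logs) / len(logs))
        x = [math.log10(truth[i]) for i in ids]
        out[frozenset(members)] = _brute_pearson(x, r_values)
    return out


class TestLeaderboard:
    def test_top_pair_is_bb_ff(self, table2):
        table, systems = table2
        entries = leaderboard(systems, table)
        assert len(entries) == 63
        pairs = [e for e in entries if len(e.combination.members) == 2]
        assert pairs[0].combination.members == ("BB", "FF")
        assert pairs[0].r_test == pytest.approx(0.816, abs=0.005)

    def test_singletons_match_individual_evaluation(self, table2):
        table, systems = table2
        entries = {e.combination.members: e for e in leaderboard(systems, table)}
        for system in systems:
            expected = evaluate_system(system, table).r
            assert entries[(system.label,)].r_test == pytest.approx(expected, abs=1e-14)

    def test_duplicate_systems_fuse_to_same_r(self, table2):
        table, systems = table2
        bb = next(s for s in systems if s.label == "BB")
        clone = ScoreTable("BB2", dict(bb.scores))
        entries = {e.combination.members: e for e in leaderboard([bb, clone], table)}
        assert entries[("BB", "BB2")].r_test == pytest.approx(
            entries[("BB",)].r_test, abs=1e-14
        )

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_oracle_equivalence_on_synthetic_systems(self, m):
        _, test, systems = simulate_study(
            SimulationConfig(n_train=0, n_test=40, m=m, noise_sd=0.4, seed=m)
        )
        truth = test.activities
        scores = {s.label: {i: s[i] for i in test.ids} for s in systems}
        oracle = _brute_leaderboard(truth, scores)
        for entry in leaderboard(systems, test):
            key = frozenset(entry.combination.members)
            assert entry.r_test == pytest.approx(oracle[key], abs=1e-12)

    def test_sorted_descending(self, table2):
        table, systems = table2
        entries = leaderboard(systems, table)
        rs = [e.r_test for e in entries]
        assert rs == sorted(rs, reverse=True)


class TestSelection:
    def _perf(self, label, r):
        return SystemPerformance(label=label, n=25, r=r)

    def test_low_performer_dropped(self):
        perfs = [
            self._perf("Best", 0.955),
            self._perf("Fast", 0.840),
            self._perf("Caesar", 0.238),
        ]
        assert select_systems(perfs) == ["Best", "Fast"]

    def test_all_equal_all_kept(self):
        perfs = [self._perf(l, 0.7) for l in "ABC"]
        assert select_systems(perfs) == ["A", "B", "C"]

    def test_fraction_one_keeps_argmax(self):
        perfs = [self._perf("A", 0.9), self._perf("B", 0.8), self._perf("C", 0.9)]
        assert select_systems(perfs, drop_fraction=1.0) == ["A", "C"]

    def test_empty_input(self):
        with pytest.raises(ValueError):
            select_systems([])


class TestRecommendPairs:
    def test_order_matches_aggregate(self, table2):
        table, systems = table2
        profiles = all_pair_profiles(systems, table)
        ranked = recommend_pairs(profiles, len(profiles))
        aggs = [p.aggregate for p in ranked]
        assert aggs == sorted(aggs, reverse=True)
        top = ranked[0]
        assert top.pair == max(profiles, key=lambda p: p.aggregate).pair

    def test_low_diversity_pairs_rank_below_high(self, table2):
        table, systems = table2
        profiles = all_pair_profiles(systems, table)
        position = {tuple(sorted(p.pair)): i for i, p in enumerate(recommend_pairs(profiles, 15))}
        for low in [("BB", "BC"), ("BB", "BF")]:
            for high in [("BB", "FF"), ("BB", "FC"), ("BF", "FF")]:
                assert position[low] > position[high]

    def test_k_too_large(self, table2):
        table, systems = table2
        profiles = all_pair_profiles(systems[:2], table)
        with pytest.raises(ValueError):
            recommend_pairs(profiles, 2)


class TestModelSurface:
    def test_fit_with_selection(self, table1):
        table, systems = table1
        results = CombinatorialFusion(table, systems).fit(drop_fraction=0.5)
        assert results.selected == ["Best_train", "Fast_train"]
        assert len(results.entries) == 3  # 2^2 - 1
        assert len(results.performances) == 3  # dropped system still reported

    def test_from_dataframe(self, table2):
        import pandas as pd

        table, systems = table2
        frame = pd.DataFrame(
            {
                "id": table.ids,
                "ic50": [table.activities[i] for i in table.ids],
                "BB": [systems[0][i] for i in table.ids],
                "FF": [systems[4][i] for i in table.ids],
            }
        )
        model = CombinatorialFusion.from_dataframe(
            frame, activity_col="ic50", system_cols=["BB", "FF"]
        )
        results = model.fit()
        assert results.best.combination.members == ("BB", "FF")
        assert results.best.r_test == pytest.approx(0.814, abs=5e-4)

    def test_summary_mentions_best_combination(self, table2):
        table, systems = table2
        results = CombinatorialFusion(table, systems).fit()
        text = results.summary()
        assert "BB+FF" in text or results.best.combination.label in text
        assert "133" in text and "63" in text

    def test_rank_score_plot(self, table2):
        import matplotlib

        matplotlib.use("Agg")
        table, systems = table2
        results = CombinatorialFusion(table, systems).fit()
        ax = results.plot_rank_score(pairs=[("BB", "FF"), ("BB", "BC")])
        assert len(ax.lines) == 2
        xdata = ax.lines[0].get_xdata()
        assert len(xdata) == 133
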