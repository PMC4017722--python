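"""Combinatorial fusion of prediction systems.

Given m scoring systems (each a score function s_A assigning every inhibitor
an estimated activity) and an experimental activity table, this module

* measures how *distinctively* any two systems predict, via the per-inhibitor
  diversity score d_i(A,B) = |s_A(p_i) - s_B(p_i)| and its descending
  rearrangement, the diversity rank/score function f_(A,B)(j), j = 1…t
  (whose plot is the diversity rank/score graph);
* enumerates all 2^m - 1 non-empty subsets of systems, combines each subset
  by score (unweighted mean in log-activity space by default, i.e. the
  geometric mean of the IC50 estimates), and ranks the combinations by their
  test-set correlation r_test;
* implements the two selection heuristics used to prune the search: keep
  only systems of relatively high individual performance, and prefer pairs
  with large aggregate diversity.

The guiding principle is that fusing systems helps only when each system
performs relatively well *and* the systems are diverse; both quantities are
computed here so the heuristics can be applied or audited.

The statsmodels-style surface is :class:`CombinatorialFusion` (the model,
built from data) and :class:`FusionResults` (returned by ``fit()``; carries
the per-system performances, diversity profiles, the full leaderboard and a
``summary()`` table).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError
from .evaluate import SystemPerformance, evaluate_system, pearson_r, to_log_activity
from .io import ActivityTable, ScoreTable

__all__ = [
    "DiversityProfile",
    "CombinationSpec",
    "LeaderboardEntry",
    "diversity_score",
    "diversity_profile",
    "all_pair_profiles",
    "enumerate_combinations",
    "combine_scores",
    "leaderboard",
    "select_systems",
    "recommend_pairs",
    "CombinatorialFusion",
    "FusionResults",
]

COMBINATION_RULES = ("mean_log", "mean_raw")


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityProfile:
    """Diversity of a pair of systems across the whole inhibitor set.

    ``scores`` holds d_i(A,B) per inhibitor id; ``rank_order`` is the ids
    sorted by descending diversity (ties broken lexicographically by id);
    ``f`` is the rank-indexed score sequence f_(A,B)(j) for j = 1…t, i.e. the
    non-increasing rearrangement of the scores; ``aggregate`` is their sum,
    the scalar used to rank pairs (the area under the rank/score graph).
    """

    pair: tuple[str, str]
    scores: dict[str, float]
    rank_order: list[str]
    f: np.ndarray
    aggregate: float

    @property
    def t(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        """Two-column frame (rank j, f(j)) — the rank/score graph as data."""
        return pd.DataFrame(
            {"rank": np.arange(1, self.t + 1), "score": self.f}
        )


def _score_on_scale(table: ScoreTable, compound_id: str, scale: str) -> float:
    value = table[compound_id]
    return to_log_activity(value) if scale == "log10" else value


def _check_scale(scale: str) -> None:
    if scale not in ("log10", "raw"):
        raise ValueError(f"unknown scale {scale!r}")


def diversity_score(
    a: ScoreTable, b: ScoreTable, compound_id: str, scale: str = "log10"
) -> float:
    """d_i(A,B): absolute difference of two systems' scores for one inhibitor.

    Symmetric in (a, b); zero iff the systems agree on this compound.
    """
    _check_scale(scale)
    for table in (a, b):
        if compound_id not in table.scores:
            raise CoverageError(
                f"id {compound_id!r} missing from system {table.label!r}",
                missing=[compound_id],
            )
    return abs(_score_on_scale(a, compound_id, scale) - _score_on_scale(b, compound_id, scale))


def diversity_profile(
    a: ScoreTable, b: ScoreTable, table: ActivityTable, scale: str = "log10"
) -> DiversityProfile:
    """Diversity scores of the pair (a, b) over a table, sorted into f_(A,B).

    The sort is stable and descending, with ties broken by id so the profile
    is reproducible.
    """
    _check_scale(scale)
    for system in (a, b):
        absent = system.covers(table.ids)
        if absent:
            raise CoverageError(
                f"system {system.label!r} is missing ids: {absent[:10]}",
                missing=absent,
            )
    scores = {i: diversity_score(a, b, i, scale) for i in table.ids}
    rank_order = sorted(scores, key=lambda i: (-scores[i], i))
    f = np.array([scores[i] for i in rank_order])
    return DiversityProfile(
        pair=(a.label, b.label),
        scores=scores,
        rank_order=rank_order,
        f=f,
        aggregate=float(f.sum()),
    )


def all_pair_profiles(
    systems: Sequence[ScoreTable], table: ActivityTable, scale: str = "log10"
) -> list[DiversityProfile]:
    """Diversity profiles for all q(q-1)/2 unordered pairs of q systems.

    Pairs are emitted in lexicographic order of (label_A, label_B).
    """
    if len(systems) < 2:
        raise ValueError("need at least 2 systems for pairwise diversity")
    by_label = sorted(systems, key=lambda s: s.label)
    return [
        diversity_profile(a, b, table, scale)
        for a, b in _combinations(by_label, 2)
    ]


# ---------------------------------------------------------------------------
# Combinations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinationSpec:
    """A non-empty subset of system labels plus the score-combination rule."""

    members: tuple[str, ...]
    rule: str = "mean_log"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("combination must have at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in combination: {self.members}")
        if self.rule not in COMBINATION_RULES:
            raise ValueError(f"unknown rule {self.rule!r}; use one of {COMBINATION_RULES}")

    @property
    def label(self) -> str:
        return "+".join(self.members)


@dataclass(frozen=True)
class LeaderboardEntry:
    """One evaluated combination: the subset and its test correlation."""

    combination: CombinationSpec
    r_test: float
    n: int


def enumerate_combinations(
    labels: Sequence[str], rule: str = "mean_log"
) -> list[CombinationSpec]:
    """All 2^m - 1 non-empty subsets of m system labels.

    Ordered by subset size, then lexicographically; members within a spec are
    sorted. Duplicate labels are rejected.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("need at least one system label")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate system labels: {labels}")
    ordered = sorted(labels)
    return [
        CombinationSpec(members=subset, rule=rule)
        for k in range(1, len(ordered) + 1)
        for subset in _combinations(ordered, k)
    ]


def combine_scores(
    spec: CombinationSpec,
    systems: Sequence[ScoreTable],
    table: ActivityTable,
) -> ScoreTable:
    """Combine the member systems' scores into a single prediction.

    ``mean_log`` averages log10 activities and re-expresses the mean as an
    activity in nM — the geometric mean of the members' IC50 estimates.
    ``mean_raw`` is the arithmetic mean of the nM values. A singleton
    combination returns the member's scores unchanged.
    """
    by_label = {s.label: s for s in systems}
    unknown = [m for m in spec.members if m not in by_label]
    if unknown:
        raise LookupError(f"unknown system labels: {unknown}")
    members = [by_label[m] for m in spec.members]
    for system in members:
        absent = system.covers(table.ids)
        if absent:
            raise CoverageError(
                f"system {system.label!r} is missing ids: {absent[:10]}",
                missing=absent,
            )
    combined = {}
    for i in table.ids:
        values = np.array([s[i] for s in members])
        if spec.rule == "mean_log":
            combined[i] = float(10 ** np.mean(np.log10(values)))
        else:
            combined[i] = float(np.mean(values))
    return ScoreTable(label=spec.label, scores=combined)


def leaderboard(
    systems: Sequence[ScoreTable],
    exptl: ActivityTable,
    rule: str = "mean_log",
    scale: str = "log10",
) -> list[LeaderboardEntry]:
    """Evaluate every non-empty combination of systems by its r_test.

    Entries are sorted by r_test descending; ties go to the smaller subset,
    then lexicographically by member labels. Singleton entries coincide with
    :func:`~qsarfusion.evaluate.evaluate_system`.
    """
    entries = []
    for spec in enumerate_combinations([s.label for s in systems], rule=rule):
        merged = combine_scores(spec, systems, exptl)
        perf = evaluate_system(merged, exptl, scale=scale)
        entries.append(LeaderboardEntry(combination=spec, r_test=perf.r, n=perf.n))
    return sorted(
        entries,
        key=lambda e: (-e.r_test, len(e.combination.members), e.combination.members),
    )


# ---------------------------------------------------------------------------
# Selection heuristics
# ---------------------------------------------------------------------------

def select_systems(
    perfs: Sequence[SystemPerformance], drop_fraction: float = 0.5
) -> list[str]:
    """Keep systems whose r is at least ``drop_fraction`` of the best r.

    Operationalizes "drop systems whose performance is far below the rest":
    with training correlations (0.955, 0.840, 0.238) and the default 0.5
    threshold, the third system is dropped. ``drop_fraction=1.0`` keeps only
    the argmax (and exact ties). Input order is preserved.
    """
    if not perfs:
        raise ValueError("need at least one system performance")
    if not 0 < drop_fraction <= 1:
        raise ValueError("drop_fraction must be in (0, 1]")
    best = max(p.r for p in perfs)
    return [p.label for p in perfs if p.r >= drop_fraction * best]


def recommend_pairs(
    profiles: Sequence[DiversityProfile], k: int
) -> list[DiversityProfile]:
    """Top-k pairs by aggregate diversity (descending; ties by pair label)."""
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the {len(profiles)} available profiles")
    ranked = sorted(profiles, key=lambda p: (-p.aggregate, p.pair))
    return list(ranked[:k])


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class CombinatorialFusion:
    """Exhaustive score-combination analysis of m prediction systems.

    Parameters
    ----------
    exptl
        Experimental activities (the inhibitor set the systems are judged on).
    systems
        The m candidate scoring systems; each must cover every id of
        ``exptl``.
    scale
        ``"log10"`` (default) or ``"raw"`` — the space in which correlations
        and diversity scores are computed.
    rule
        Score-combination rule, ``"mean_log"`` (default) or ``"mean_raw"``.

    Examples
    --------
    >>> from qsarfusion import CombinatorialFusion
    >>> table, systems = load_fixture("table2")          # doctest: +SKIP
    >>> res = CombinatorialFusion(table, systems).fit()  # doctest: +SKIP
    >>> res.best.combination.label                       # doctest: +SKIP
    'BB+FF'
    """

    def __init__(
        self,
        exptl: ActivityTable,
        systems: Sequence[ScoreTable],
        scale: str = "log10",
        rule: str = "mean_log",
    ):
        if not systems:
            raise ValueError("need at least one scoring system")
        _check_scale(scale)
        if rule not in COMBINATION_RULES:
            raise ValueError(f"unknown rule {rule!r}")
        self.exptl = exptl
        self.systems = list(systems)
        self.scale = scale
        self.rule = rule

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        activity_col: str,
        system_cols: Sequence[str],
        id_col: str = "id",
        name: str = "frame",
        **kwargs,
    ) -> "CombinatorialFusion":
        """Build the model from a tidy frame with one column per system."""
        from .io import ActivityTable, InhibitorRecord

        records = [
            InhibitorRecord(id=str(row[id_col]), ic50_nM=float(row[activity_col]))
            for _, row in frame.iterrows()
        ]
        table = ActivityTable(name=name, records=records)
        systems = [
            ScoreTable(
                label=col,
                scores={str(r[id_col]): float(r[col]) for _, r in frame.iterrows()},
            )
            for col in system_cols
        ]
        return cls(table, systems, **kwargs)

    def fit(self, drop_fraction: float | None = None) -> "FusionResults":
        """Run the full analysis and return a :class:`FusionResults`.

        If ``drop_fraction`` is given, low-performing systems are removed by
        :func:`select_systems` before enumeration; otherwise all systems
        enter the leaderboard.
        """
        performances = [
            evaluate_system(s, self.exptl, scale=self.scale) for s in self.systems
        ]
        if drop_fraction is not None:
            kept = set(select_systems(performances, drop_fraction))
            active = [s for s in self.systems if s.label in kept]
        else:
            active = self.systems
        profiles = (
            all_pair_profiles(active, self.exptl, self.scale)
            if len(active) >= 2
            else []
        )
        entries = leaderboard(active, self.exptl, rule=self.rule, scale=self.scale)
        return FusionResults(
            model=self,
            performances=performances,
            selected=[s.label for s in active],
            profiles=profiles,
            entries=entries,
        )


class FusionResults:
    """Fitted combinatorial-fusion analysis.

    Attributes
    ----------
    performances : list[SystemPerformance]
        Individual r for every input system (including dropped ones).
    selected : list[str]
        Labels that entered the enumeration.
    profiles : list[DiversityProfile]
        All pairwise diversity profiles of the selected systems.
    entries : list[LeaderboardEntry]
        The full leaderboard, best combination first.
    """

    def __init__(self, model, performances, selected, profiles, entries):
        self.model = model
        self.performances = performances
        self.selected = selected
        self.profiles = profiles
        self.entries = entries

    @property
    def best(self) -> LeaderboardEntry:
        """The top combination overall."""
        return self.entries[0]

    def best_of_size(self, k: int) -> LeaderboardEntry:
        """The top combination with exactly k members."""
        for entry in self.entries:
            if len(entry.combination.members) == k:
                return entry
        raise ValueError(f"no combination of size {k}")

    def leaderboard_frame(self) -> pd.DataFrame:
        """The leaderboard as a DataFrame (members, size, rule, r_test, n)."""
        return pd.DataFrame(
            {
                "members": [e.combination.label for e in self.entries],
                "size": [len(e.combination.members) for e in self.entries],
                "rule": [e.combination.rule for e in self.entries],
                "r_test": [e.r_test for e in self.entries],
                "n": [e.n for e in self.entries],
            }
        )

    def diversity_frame(self) -> pd.DataFrame:
        """Aggregate diversity per pair, descending."""
        ranked = sorted(self.profiles, key=lambda p: (-p.aggregate, p.pair))
        return pd.DataFrame(
            {
                "pair": [f"{a}+{b}" for a, b in (p.pair for p in ranked)],
                "aggregate_diversity": [p.aggregate for p in ranked],
                "t": [p.t for p in ranked],
            }
        )

    def summary(self, top: int = 10) -> str:
        """Human-readable report: systems, selection, top combinations."""
        model = self.model
        lines = [
            "Combinatorial Fusion Results",
            "=" * 60,
            f"Inhibitors (t):        {model.exptl.t}",
            f"Systems (m):           {len(model.systems)}",
            f"Selected for fusion:   {', '.join(self.selected)}",
            f"Scale:                 {model.scale}",
            f"Combination rule:      {model.rule}",
            f"Combinations scored:   {len(self.entries)}",
            f"Pairwise profiles:     {len(self.profiles)}",
            "",
            "Individual systems",
            "-" * 60,
            f"{'system':<20}{'n':>6}{'r':>10}",
        ]
        for p in self.performances:
            flag = "" if p.label in self.selected else "  (dropped)"
            lines.append(f"{p.label:<20}{p.n:>6}{p.r:>10.3f}{flag}")
        lines += [
            "",
            f"Top {min(top, len(self.entries))} combinations",
            "-" * 60,
            f"{'members':<28}{'size':>5}{'r_test':>10}",
        ]
        for e in self.entries[:top]:
            lines.append(
                f"{e.combination.label:<28}{len(e.combination.members):>5}{e.r_test:>10.3f}"
            )
        return "\n".join(lines)

    def plot_rank_score(self, pairs=None, ax=None):
        """Plot diversity rank/score graphs (one line per pair).

        ``pairs`` restricts to the given (label_A, label_B) tuples; default
        is every profile. Returns the matplotlib axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        wanted = set(map(tuple, pairs)) if pairs is not None else None
        for profile in self.profiles:
            if wanted is not None and tuple(profile.pair) not in wanted:
                continue
            ax.plot(
                np.arange(1, profile.t + 1),
                profile.f,
                label="+".join(profile.pair),
            )
        ax.set_xlabel("diversity rank j")
        ax.set_ylabel("diversity score f(j)")
        ax.legend(fontsize="small", ncol=2)
        return ax
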