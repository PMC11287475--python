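"""Wrightian relative fitness, stepwise competitiveness, community summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rankcast.coculture import (
    CoCultureError,
    community_counts_summary,
    fitness_table,
    relative_fitness,
    stepwise_competitiveness,
)


def pair_df(means: dict[tuple[str, str], float]) -> pd.DataFrame:
    """Fitness table with one record per ordered pair at the given log10 value."""
    rows = [
        {"species1": a, "species2": b, "log10_rel_fitness": v}
        for (a, b), v in means.items()
    ]
    return pd.DataFrame(rows)


def stepwise_oracle(species: list[str], signed) -> dict[str, float]:
    """Explicit enumeration of the stepwise bookkeeping: walk species from
    weakest (mean pairwise log fitness) upward; each species sums its own
    perspective for every pair, pairs already visited re-use the recorded
    value with opposite sign instead of being re-estimated."""
    prov = {s: np.mean([signed(s, o) for o in species if o != s]) for s in species}
    order = sorted(species, key=lambda s: (prov[s], s))
    recorded: dict[frozenset, tuple[str, float]] = {}
    scores = {}
    for s in order:
        total = 0.0
        for o in species:
            if o == s:
                continue
            key = frozenset((s, o))
            if key in recorded:
                owner, val = recorded[key]
                total += -val  # reciprocal of the already-counted perspective
            else:
                val = signed(s, o)
                recorded[key] = (s, val)
                total += val
        scores[s] = total
    return scores


class TestRelativeFitness:
    def test_symmetric_outcome(self):
        w, lw = relative_fitness(5e4, 5e4, 1e8, 1e8)
        assert w == 1.0 and lw == 0.0

    def test_printed_formula(self):
        w, lw = relative_fitness(5e4, 5e4, 2e8, 5e7)
        assert w == pytest.approx(4.0)
        assert lw == pytest.approx(np.log10(4.0))

    @settings(deadline=None, max_examples=50)
    @given(st.tuples(*[st.floats(1e2, 1e9) for _ in range(4)]))
    def test_role_swap_is_reciprocal(self, cfu):
        s1, s2, e1, e2 = cfu
        w12, l12 = relative_fitness(s1, s2, e1, e2)
        w21, l21 = relative_fitness(s2, s1, e2, e1)
        assert w12 * w21 == pytest.approx(1.0)
        assert l12 == pytest.approx(-l21)

    def test_zero_count_rejected_with_record_name(self):
        df = pd.DataFrame(
            [
                {
                    "species1": "A", "species2": "B",
                    "start_cfu1": 5e4, "start_cfu2": 5e4,
                    "end_cfu1": 0.0, "end_cfu2": 1e8,
                    "replicate": 1, "medium": "GIM",
                }
            ]
        )
        with pytest.raises(CoCultureError, match="A vs B"):
            fitness_table(df)

    def test_detection_limit_imputation(self):
        df = pd.DataFrame(
            [
                {
                    "species1": "A", "species2": "B",
                    "start_cfu1": 5e4, "start_cfu2": 5e4,
                    "end_cfu1": 10.0, "end_cfu2": 1e8,
                    "replicate": 1, "medium": "GIM",
                }
            ]
        )
        out = fitness_table(df, detection_limit=1e3)
        assert out.loc[0, "end_cfu1"] == 1e3
        assert bool(out.loc[0, "end_cfu1_censored"])


class TestStepwiseCompetitiveness:
    def test_all_zero_fitness_gives_zero_scores(self):
        df = pair_df({("A", "B"): 0.0, ("A", "C"): 0.0, ("B", "C"): 0.0})
        scores = stepwise_competitiveness(df)
        assert [s.score for s in scores] == [0.0, 0.0, 0.0]
        # deterministic (lexicographic) order on ties
        assert [s.species for s in scores] == ["A", "B", "C"]

    def test_single_pair(self):
        scores = {s.species: s.score for s in stepwise_competitiveness(pair_df({("A", "B"): 0.5}))}
        assert scores == pytest.approx({"A": 0.5, "B": -0.5})

    def test_three_species_matches_enumeration_oracle(self):
        means = {("A", "B"): 0.3, ("A", "C"): 0.2, ("B", "C"): -0.4}

        def signed(a, b):
            if (a, b) in means:
                return means[(a, b)]
            return -means[(b, a)]

        expected = stepwise_oracle(["A", "B", "C"], signed)
        got = {s.species: s.score for s in stepwise_competitiveness(pair_df(means))}
        assert got == pytest.approx(expected)
        assert got == pytest.approx({"B": -0.7, "C": 0.2, "A": 0.5})

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(-2, 2), min_size=6, max_size=6))
    def test_sum_zero_with_reciprocal_pairs(self, vals):
        species = ["A", "B", "C", "D"]
        pairs = [(a, b) for i, a in enumerate(species) for b in species[i + 1 :]]
        df = pair_df(dict(zip(pairs, vals)))
        total = sum(s.score for s in stepwise_competitiveness(df))
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_replicate_ordering(self):
        rng = np.random.default_rng(3)
        rows = []
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            for _ in range(5):
                rows.append({"species1": a, "species2": b,
                             "log10_rel_fitness": rng.normal(0, 0.5)})
        df = pd.DataFrame(rows)
        shuffled = df.sample(frac=1.0, random_state=9)
        s1 = {s.species: s.score for s in stepwise_competitiveness(df)}
        s2 = {s.species: s.score for s in stepwise_competitiveness(shuffled)}
        assert s1 == pytest.approx(s2)

    def test_missing_pair_rejected(self):
        with pytest.raises(CoCultureError, match="missing pairwise"):
            stepwise_competitiveness(pair_df({("A", "B"): 0.1, ("A", "C"): 0.2}))


def counts_df(levels: dict[str, float], n=9, sd=0.0, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n + 1):
        for s, lvl in levels.items():
            rows.append({"species": s, "replicate": rep,
                         "end_cfu": 10 ** (lvl + rng.normal(0, sd))})
    return pd.DataFrame(rows)


class TestCommunitySummary:
    def test_identical_counts_single_group(self):
        out = community_counts_summary(counts_df({"A": 7, "B": 7, "C": 7}))
        assert set(out["group"]) == {out["group"].iloc[0]}

    def test_tenfold_separation_recovers_order(self):
        out = community_counts_summary(
            counts_df({"A": 6, "B": 7, "C": 8, "D": 9}, n=9, sd=0.1, seed=4)
        )
        assert out["species"].tolist() == ["A", "B", "C", "D"]
        # all pairs significant -> no shared letters
        letters = out["group"].tolist()
        assert all(set(a).isdisjoint(b) for i, a in enumerate(letters) for b in letters[i + 1 :])

    def test_detection_limit_species_ranked_last_and_flagged(self):
        df = counts_df({"A": 3, "B": 7, "C": 8}, n=6, sd=0.05, seed=1)
        df["censored"] = df["species"] == "A"
        out = community_counts_summary(df)
        assert out["species"].iloc[0] == "A"
        assert bool(out.loc[out["species"] == "A", "censored"].iloc[0])

    def test_unequal_pairing_rejected(self):
        df = counts_df({"A": 7, "B": 8}, n=6)
        df = df.drop(df[(df["species"] == "A") & (df["replicate"] == 3)].index)
        with pytest.raises(CoCultureError, match="pairing"):
            community_counts_summary(df)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(CoCultureError, match="replicates"):
            community_counts_summary(counts_df({"A": 7, "B": 8}, n=4))
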