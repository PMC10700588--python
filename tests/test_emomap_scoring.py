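"""Landscape embedding and transitivity scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import affectmap as am
from affectmap import cohort as ch
from affectmap import emomap, task_design as td


def _similarity_table(dissim: dict) -> pd.DataFrame:
    rows = [
        {"image_id_a": a, "image_id_b": b, "similarity": 10.0 - d}
        for (a, b), d in dissim.items()
    ]
    return pd.DataFrame(rows)


class TestEmbedding:
    def test_exact_planar_configuration_recovered(self):
        # equilateral triangle with side 1 is exactly realizable in the plane
        table = _similarity_table({("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0})
        emb = emomap.embed_landscape(table, seed=0)
        for pair in (("a", "b"), ("a", "c"), ("b", "c")):
            assert emb.distance(*pair) == pytest.approx(1.0, abs=1e-6)
        assert emb.stress < 1e-8

    def test_equal_dissimilarities_give_equal_distances(self):
        # a regular tetrahedron needs three dimensions
        images = ["a", "b", "c", "d"]
        table = _similarity_table(
            {p: 4.0 for p in itertools.combinations(images, 2)}
        )
        emb = emomap.embed_landscape(table, n_dimensions=3, seed=1)
        dists = [emb.distance(*p) for p in itertools.combinations(images, 2)]
        assert max(dists) - min(dists) < 1e-4 * max(dists)

    def test_stress_beats_classical_scaling_start(self):
        # oracle: classical (Torgerson) scaling computed independently here
        rng = np.random.default_rng(5)
        images = [f"i{k}" for k in range(6)]
        dissim = {
            p: float(rng.uniform(1, 9)) for p in itertools.combinations(images, 2)
        }
        table = _similarity_table(dissim)
        delta = np.zeros((6, 6))
        for (a, b), d in dissim.items():
            i, j = images.index(a), images.index(b)
            delta[i, j] = delta[j, i] = d
        centering = np.eye(6) - np.ones((6, 6)) / 6
        b_mat = -0.5 * centering @ (delta**2) @ centering
        vals, vecs = np.linalg.eigh(b_mat)
        order = np.argsort(vals)[::-1][:2]
        x0 = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
        d0 = np.linalg.norm(x0[:, None, :] - x0[None, :, :], axis=-1)
        classical_stress = ((d0 - delta) ** 2).sum() / 2.0

        emb = emomap.embed_landscape(table, seed=0)
        assert emb.raw_stress <= classical_stress + 1e-9

    def test_missing_pair_rejected(self):
        table = _similarity_table({("a", "b"): 1.0, ("a", "c"): 1.0})
        with pytest.raises(ValueError, match="cover all image pairs"):
            emomap.embed_landscape(table)

    def test_out_of_range_rating_rejected(self):
        table = _similarity_table({("a", "b"): -2.0, ("a", "c"): 1.0, ("b", "c"): 1.0})
        with pytest.raises(ValueError, match="outside"):
            emomap.embed_landscape(table)


class TestClusterDistances:
    def _embedding_from_points(self, points: dict) -> emomap.LandscapeEmbedding:
        coords = pd.DataFrame(points).T
        coords.index.name = "image_id"
        coords.columns = ["dim_1", "dim_2"]
        return emomap.LandscapeEmbedding(coords, 0.0, 0.0, 2)

    def test_collapsed_cluster_has_zero_within(self):
        design = td.build_emopair_design()
        rng = np.random.default_rng(0)
        points = {img: rng.normal(size=2) for img in td.pair_images()}
        for img in [f"anger_{i:02d}" for i in range(1, 6)]:
            points[img] = np.array([1.0, 1.0])
        dist = emomap.cluster_distances(self._embedding_from_points(points), design)
        assert dist.within["anger"] == pytest.approx(0.0)

    def test_three_tight_clusters_at_distance_ten(self):
        centres = {
            "anger": np.array([0.0, 0.0]),
            "happiness": np.array([10.0, 0.0]),
            "sadness": np.array([5.0, 5.0 * np.sqrt(3)]),
        }
        points = {
            img: centres[td.image_category(img)] for img in td.pair_images()
        }
        dist = emomap.cluster_distances(
            self._embedding_from_points(points), td.build_emopair_design()
        )
        assert dist.mean_within == pytest.approx(0.0)
        for v in dist.between.values():
            assert v == pytest.approx(10.0)

    def test_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(3)
        points = {img: rng.normal(size=2) for img in td.pair_images()}
        design = td.build_emopair_design()
        dist = emomap.cluster_distances(self._embedding_from_points(points), design)
        # oracle: loop over explicitly enumerated pairs
        from collections import defaultdict

        sums = defaultdict(list)
        for a, b in itertools.combinations(td.pair_images(), 2):
            d = float(np.linalg.norm(points[a] - points[b]))
            ca, cb = td.image_category(a), td.image_category(b)
            key = ("within", ca) if ca == cb else ("between",) + tuple(sorted((ca, cb)))
            sums[key].append(d)
        for emo in td.EMOTIONS:
            assert dist.within[emo] == pytest.approx(np.mean(sums[("within", emo)]))
        for pair, v in dist.between.items():
            assert v == pytest.approx(np.mean(sums[("between",) + pair]))


def _choices_from_order(items, order_key) -> pd.DataFrame:
    """Choice table where preferences follow a strict total order."""
    rows = []
    for a, b in itertools.combinations(items, 2):
        rows.append(
            {
                "target_a": a,
                "target_b": b,
                "chosen": a if order_key(a) > order_key(b) else b,
            }
        )
    return pd.DataFrame(rows)


def _brute_force_score(table: pd.DataFrame) -> int:
    """Independent scorer: explicit counting loops, no shared code path."""
    counts: dict = {}
    for _, row in table.iterrows():
        counts.setdefault(row["target_a"], 0)
        counts.setdefault(row["target_b"], 0)
        counts[row["chosen"]] += 1
    total = 0
    for _, row in table.iterrows():
        unchosen = row["target_b"] if row["chosen"] == row["target_a"] else row["target_a"]
        total += counts[row["chosen"]] - counts[unchosen]
    return total


class TestConsistencyScore:
    def test_fully_transitive_eleven_items_scores_220(self):
        items = [f"img{k:02d}" for k in range(11)]
        table = _choices_from_order(items, order_key=lambda s: s)
        cs = emomap.consistency_score(table)
        assert cs.score == 220 == cs.max_score
        assert sorted(cs.rank_scores.values(), reverse=True) == list(range(10, -1, -1))

    def test_three_item_toy(self):
        table = pd.DataFrame(
            {
                "target_a": ["A", "B", "A"],
                "target_b": ["B", "C", "C"],
                "chosen": ["A", "B", "A"],
            }
        )
        cs = emomap.consistency_score(table)
        assert cs.rank_scores == {"A": 2, "B": 1, "C": 0}
        assert cs.score == 4

    def test_three_item_circular_toy(self):
        table = pd.DataFrame(
            {
                "target_a": ["A", "B", "A"],
                "target_b": ["B", "C", "C"],
                "chosen": ["A", "B", "C"],
            }
        )
        cs = emomap.consistency_score(table)
        assert cs.rank_scores == {"A": 1, "B": 1, "C": 1}
        assert cs.score == 0

    def test_all_patterns_match_brute_force_oracle(self):
        items = ["A", "B", "C", "D"]
        pairs = list(itertools.combinations(items, 2))
        for pattern in itertools.product((0, 1), repeat=len(pairs)):
            table = pd.DataFrame(
                {
                    "target_a": [p[0] for p in pairs],
                    "target_b": [p[1] for p in pairs],
                    "chosen": [p[bit] for p, bit in zip(pairs, pattern)],
                }
            )
            assert emomap.consistency_score(table).score == _brute_force_score(table)

    def test_rank_scores_sum_to_trial_count(self):
        rng = np.random.default_rng(0)
        items = [f"t{k}" for k in range(11)]
        pairs = list(itertools.combinations(items, 2))
        table = pd.DataFrame(
            {
                "target_a": [p[0] for p in pairs],
                "target_b": [p[1] for p in pairs],
                "chosen": [p[rng.integers(2)] for p in pairs],
            }
        )
        cs = emomap.consistency_score(table)
        assert sum(cs.rank_scores.values()) == 55

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        flip=st.integers(min_value=0, max_value=14),
        perm=st.permutations(list("ABCDEF")),
    )
    def test_single_swap_never_helps_and_hurts_unless_adjacent(self, flip, perm):
        # Swapping the choice of two *adjacent* items in the preference order
        # yields another perfectly transitive order, so the score can stay at
        # the ceiling; every other single swap strictly decreases it.
        order = {item: k for k, item in enumerate(perm)}
        table = _choices_from_order(list("ABCDEF"), order_key=lambda s: order[s])
        perfect = emomap.consistency_score(table).score
        assert perfect == emomap.consistency_score(table).max_score
        flipped = table.copy()
        row = flipped.iloc[flip]
        other = row["target_b"] if row["chosen"] == row["target_a"] else row["target_a"]
        flipped.loc[flipped.index[flip], "chosen"] = other
        swapped_score = emomap.consistency_score(flipped).score
        adjacent = abs(order[row["target_a"]] - order[row["target_b"]]) == 1
        if adjacent:
            assert swapped_score == perfect
        else:
            assert swapped_score < perfect

    def test_wrong_trial_count_rejected(self):
        table = pd.DataFrame(
            {"target_a": ["A", "B"], "target_b": ["B", "C"], "chosen": ["A", "B"]}
        )
        with pytest.raises(ValueError, match="expected 3 trials"):
            emomap.consistency_score(table)

    def test_choice_outside_pair_rejected(self):
        table = pd.DataFrame(
            {
                "target_a": ["A", "B", "A"],
                "target_b": ["B", "C", "C"],
                "chosen": ["A", "B", "B"],
            }
        )
        with pytest.raises(ValueError, match="not in trial pair"):
            emomap.consistency_score(table)

    def test_lapses_are_counted(self):
        table = pd.DataFrame(
            {
                "target_a": ["A", "B", "A"],
                "target_b": ["B", "C", "C"],
                "chosen": ["A", "B", "A"],
                "n_lapses": [1, 0, 2],
            }
        )
        assert emomap.consistency_score(table).n_lapses == 3


def test_cohort_scorer_agrees_with_reference_scorer(fixture_cohort):
    _, responses = fixture_cohort
    choices = responses["choices"]
    fast = emomap.consistency_scores_cohort(choices).set_index(
        ["participant_id", "condition"]
    )
    for (pid, condition), group in choices.groupby(["participant_id", "condition"]):
        ref = emomap.consistency_score(group, condition=condition)
        assert fast.loc[(pid, condition), "score"] == ref.score
        assert fast.loc[(pid, condition), "n_lapses"] == ref.n_lapses


class TestParticipantScores:
    def test_complete_participant_row_schema(self, fixture_cohort):
        _, responses = fixture_cohort
        scores = emomap.emomap_participant_scores(
            responses["similarity"], responses["choices"], n_init=1, max_iter=100
        )
        expected = {
            "consistency_anger", "consistency_happiness", "consistency_sadness",
            "color_control_consistency", "mean_between", "mean_within", "stress",
        }
        assert expected <= set(scores.columns)
        assert scores["complete"].all()

    def test_noiseless_participant_hits_ceiling(self, fixture_cohort):
        _, responses = fixture_cohort
        scores = emomap.emomap_participant_scores(
            responses["similarity"], responses["choices"], skip_embedding=True
        )
        row = scores[scores["participant_id"] == "p0001"].iloc[0]
        for emo in td.EMOTIONS:
            assert row[f"consistency_{emo}"] == 220

    def test_partial_data_flagged_incomplete(self, fixture_cohort):
        _, responses = fixture_cohort
        choices = responses["choices"]
        truncated = choices[
            ~(
                (choices["participant_id"] == "p0003")
                & (choices["condition"] == "anger")
            )
        ]
        scores = emomap.emomap_participant_scores(
            responses["similarity"], truncated, skip_embedding=True
        )
        row = scores[scores["participant_id"] == "p0003"].iloc[0]
        assert not row["complete"]
        assert np.isnan(row["consistency_anger"])

    def test_consistency_decreases_with_experience_noise(self):
        cfg = ch.CohortConfig(n_participants=120, seed=31)
        cohort = ch.generate_profiles(cfg)
        designs = td.build_all_designs(seed=31)
        choices = ch.simulate_choices(cohort, designs)
        scores = emomap.emomap_participant_scores(
            pd.DataFrame(columns=["participant_id", "image_id_a", "image_id_b", "similarity"]),
            choices,
            skip_embedding=True,
        )
        merged = scores.merge(cohort.profiles, on="participant_id")
        from scipy import stats as sps

        rho, _ = sps.spearmanr(merged["sigma_exp"], merged["emotional_consistency"])
        assert rho < -0.5

    def test_between_distance_recovers_modularity(self):
        designs = td.build_all_designs(seed=41)
        means = []
        for m in (2.0, 6.0, 12.0):
            cfg = ch.CohortConfig(
                n_participants=25, seed=41, modularity_mean=m, modularity_sd=0.0,
                tas_modularity_beta=0.0,
            )
            cohort = ch.generate_profiles(cfg)
            sim = ch.simulate_similarity(cohort, designs)
            scores = emomap.emomap_participant_scores(
                sim,
                pd.DataFrame(columns=["participant_id", "condition", "target_a", "target_b", "chosen"]),
                n_init=1,
                max_iter=100,
            )
            means.append(scores["mean_between"].mean())
        assert means[0] < means[1] < means[2]
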