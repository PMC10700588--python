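"""Scoring of EmoMap responses.

Part 1: similarity ratings (0-10) are converted to dissimilarities
(10 - rating) and embedded into a low-dimensional landscape by metric
least-squares multidimensional scaling (SMACOF stress majorization, classical
scaling start plus seeded random restarts). Mean embedded Euclidean distances
within each emotion's 10 image pairs and between each emotion pair's 25 cross
pairs index the differentiation of emotional experience.

Part 2: triplet choices are scored for logical (transitive) consistency.
Each image's rank score is the number of times it was chosen across the 55
trials; per trial the unchosen rank is subtracted from the chosen rank, and
these item differences are summed. A fully transitive participant's sorted
ranks are exactly 10, 9, ..., 0 and their score is 220.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import smacof

from . import task_design as td

RATING_MAX = 10.0
PERFECT_SCORE = 220  # attained iff 55 choices over 11 images are transitive


@dataclass
class LandscapeEmbedding:
    """A fitted MDS landscape: per-image coordinates plus stress."""

    coordinates: pd.DataFrame  # index image_id, columns dim_1..dim_k
    stress: float  # normalized (Kruskal-type) stress
    raw_stress: float  # sum of squared distance-dissimilarity residuals
    n_dimensions: int

    def distance(self, image_a: str, image_b: str) -> float:
        xa = self.coordinates.loc[image_a].to_numpy()
        xb = self.coordinates.loc[image_b].to_numpy()
        return float(np.linalg.norm(xa - xb))


@dataclass
class ClusterDistances:
    within: dict  # emotion -> mean within-cluster distance
    between: dict  # (emotion_a, emotion_b) -> mean between-cluster distance
    mean_within: float
    mean_between: float


@dataclass
class ConsistencyScore:
    condition: str
    rank_scores: dict  # image_id -> times chosen
    score: int
    n_lapses: int
    max_score: int


def classical_scaling(delta: np.ndarray, n_dimensions: int = 2) -> np.ndarray:
    """Torgerson classical scaling of a dissimilarity matrix.

    Used as the deterministic initial configuration for stress majorization.
    Negative eigenvalues (non-Euclidean input) are truncated at zero.
    """
    n = delta.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (delta**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dimensions]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def dissimilarity_matrix(
    similarity: pd.DataFrame, images: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Symmetric dissimilarity matrix (10 - rating) from a similarity table.

    Requires exactly one in-range rating per unordered image pair.
    """
    if images is None:
        images = sorted(
            set(similarity["image_id_a"]) | set(similarity["image_id_b"])
        )
    index = {img: i for i, img in enumerate(images)}
    n = len(images)
    delta = np.full((n, n), np.nan)
    np.fill_diagonal(delta, 0.0)
    for a, b, s in similarity[["image_id_a", "image_id_b", "similarity"]].itertuples(
        index=False
    ):
        if not 0.0 <= s <= RATING_MAX:
            raise ValueError(f"similarity rating {s} outside [0, {RATING_MAX}]")
        if a not in index or b not in index:
            raise ValueError(f"unknown image in similarity table: {a!r}/{b!r}")
        i, jx = index[a], index[b]
        if not np.isnan(delta[i, jx]):
            raise ValueError(f"duplicate rating for pair ({a}, {b})")
        delta[i, jx] = delta[jx, i] = RATING_MAX - s
    if np.isnan(delta).any():
        raise ValueError("similarity table does not cover all image pairs")
    return delta, images


def embed_landscape(
    similarity: pd.DataFrame,
    n_dimensions: int = 2,
    seed: int = 0,
    n_init: int = 8,
    max_iter: int = 300,
    eps: float = 1e-10,
) -> LandscapeEmbedding:
    """Metric MDS embedding of one participant's similarity ratings.

    Runs SMACOF from the classical-scaling configuration and from
    ``n_init - 1`` seeded random starts, keeping the lowest-stress solution.
    The reported stress is normalized: sqrt(raw / sum of squared
    dissimilarities over pairs).
    """
    delta, images = dissimilarity_matrix(similarity)
    inits: list[np.ndarray | None] = [classical_scaling(delta, n_dimensions)]
    inits += [None] * max(0, n_init - 1)
    best_x, best_stress = None, np.inf
    ss = np.random.SeedSequence(seed)
    for init, child in zip(inits, ss.spawn(len(inits))):
        x, raw = smacof(
            delta,
            metric=True,
            n_components=n_dimensions,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=eps,
            random_state=np.random.RandomState(child.generate_state(1)[0] % (2**31)),
            normalized_stress=False,
        )
        if raw < best_stress:
            best_x, best_stress = x, raw
    denom = (delta**2).sum() / 2.0
    norm_stress = float(np.sqrt(max(best_stress, 0.0) / denom)) if denom > 0 else 0.0
    coords = pd.DataFrame(
        best_x,
        index=pd.Index(images, name="image_id"),
        columns=[f"dim_{k + 1}" for k in range(n_dimensions)],
    )
    return LandscapeEmbedding(coords, norm_stress, float(best_stress), n_dimensions)


def cluster_distances(
    embedding: LandscapeEmbedding, design: pd.DataFrame
) -> ClusterDistances:
    """Mean embedded distances within and between emotion clusters."""
    missing = set(design["image_id_a"]) | set(design["image_id_b"])
    missing -= set(embedding.coordinates.index)
    if missing:
        raise ValueError(f"design images missing from embedding: {sorted(missing)}")
    coords = embedding.coordinates
    xa = coords.loc[design["image_id_a"]].to_numpy()
    xb = coords.loc[design["image_id_b"]].to_numpy()
    d = np.linalg.norm(xa - xb, axis=1)
    table = design.assign(distance=d)
    within = {
        emo: float(g["distance"].mean())
        for emo, g in table[table["pair_type"] == "within"].groupby("category_a")
    }
    between = {}
    bet = table[table["pair_type"] == "between"]
    for (a, b), g in bet.groupby(["category_a", "category_b"]):
        between[tuple(sorted((a, b)))] = float(g["distance"].mean())
    return ClusterDistances(
        within=within,
        between=between,
        mean_within=float(np.mean(list(within.values()))),
        mean_between=float(np.mean(list(between.values()))),
    )


def consistency_score(
    choices: pd.DataFrame, condition: str | None = None
) -> ConsistencyScore:
    """Transitivity-based consistency score of one choice set.

    ``choices`` holds one row per trial with columns ``target_a``,
    ``target_b``, ``chosen`` (and optionally ``condition`` and ``n_lapses``).
    The trial set must present every unordered pair of the condition's
    targets exactly once; lapses (trap selections, already retried in-task)
    are counted for QC but never enter the ranks.
    """
    if condition is not None:
        if "condition" in choices.columns:
            choices = choices[choices["condition"] == condition]
    elif "condition" in choices.columns:
        conds = choices["condition"].unique()
        if len(conds) != 1:
            raise ValueError("choice table mixes conditions; pass condition=")
        condition = conds[0]

    if len(choices) == 0:
        raise ValueError(f"no trials for condition {condition!r}")
    items = sorted(set(choices["target_a"]) | set(choices["target_b"]))
    n_items = len(items)
    expected = n_items * (n_items - 1) // 2
    if len(choices) != expected:
        raise ValueError(
            f"expected {expected} trials for {n_items} items, got {len(choices)}"
        )
    seen = set()
    for a, b in choices[["target_a", "target_b"]].itertuples(index=False):
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"pair ({a}, {b}) appears more than once")
        seen.add(key)

    bad = ~(
        (choices["chosen"] == choices["target_a"])
        | (choices["chosen"] == choices["target_b"])
    )
    if bad.any():
        row = choices[bad].iloc[0]
        raise ValueError(
            f"chosen image {row['chosen']!r} is not in trial pair "
            f"({row['target_a']!r}, {row['target_b']!r})"
        )

    ranks = {item: 0 for item in items}
    for c in choices["chosen"]:
        ranks[c] += 1
    diffs = [
        ranks[c] - (ranks[b] if c == a else ranks[a])
        for a, b, c in choices[["target_a", "target_b", "chosen"]].itertuples(index=False)
    ]
    n_lapses = int(choices["n_lapses"].sum()) if "n_lapses" in choices.columns else 0
    # maximum: sum of |i-j| over all rank pairs of a strict total order
    max_score = sum(j - i for i, j in itertools.combinations(range(n_items), 2))
    return ConsistencyScore(
        condition=condition if condition is not None else "unlabelled",
        rank_scores=ranks,
        score=int(sum(diffs)),
        n_lapses=n_lapses,
        max_score=max_score,
    )


def consistency_scores_cohort(choices: pd.DataFrame) -> pd.DataFrame:
    """Vectorized consistency scores for a whole cohort's choice table.

    One row per participant x condition with the score, trial count and
    lapse count. Groups whose trial count differs from the standard
    55-pair design are flagged invalid (score NaN). Agrees with
    :func:`consistency_score` row for row on complete data.
    """
    df = choices.copy()
    bad = ~((df["chosen"] == df["target_a"]) | (df["chosen"] == df["target_b"]))
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(
            f"chosen image {row['chosen']!r} is not in trial pair "
            f"({row['target_a']!r}, {row['target_b']!r})"
        )
    df["unchosen"] = np.where(
        df["chosen"] == df["target_a"], df["target_b"], df["target_a"]
    )
    keys = ["participant_id", "condition"]
    ranks = df.groupby(keys + ["chosen"]).size()
    rank_chosen = ranks.reindex(
        pd.MultiIndex.from_frame(df[keys + ["chosen"]])
    ).fillna(0).to_numpy()
    rank_unchosen = ranks.reindex(
        pd.MultiIndex.from_frame(df[keys + ["unchosen"]].rename(columns={"unchosen": "chosen"}))
    ).fillna(0).to_numpy()
    df["item_diff"] = rank_chosen - rank_unchosen
    agg = df.groupby(keys).agg(
        score=("item_diff", "sum"), n_trials=("item_diff", "size")
    )
    agg["n_lapses"] = (
        df.groupby(keys)["n_lapses"].sum() if "n_lapses" in df.columns else 0
    )
    expected = td.N_TARGETS * (td.N_TARGETS - 1) // 2
    agg.loc[agg["n_trials"] != expected, "score"] = np.nan
    return agg.reset_index()


def emomap_participant_scores(
    similarity: pd.DataFrame,
    choices: pd.DataFrame,
    pair_design: pd.DataFrame | None = None,
    n_dimensions: int = 2,
    seed: int = 0,
    n_init: int = 8,
    max_iter: int = 300,
    skip_embedding: bool = False,
) -> pd.DataFrame:
    """One row per participant: cluster distances plus consistency scores.

    Participants with partial data are kept but flagged ``complete=False``
    (their missing scores are NaN). ``skip_embedding`` drops the MDS stage
    for analyses that only need the consistency scores.
    """
    if pair_design is None:
        pair_design = td.build_emopair_design()
    pids = sorted(
        set(similarity["participant_id"]) | set(choices["participant_id"])
    )
    sim_groups = dict(tuple(similarity.groupby("participant_id")))
    cons = (
        consistency_scores_cohort(choices)
        if len(choices)
        else pd.DataFrame(columns=["participant_id", "condition", "score", "n_lapses"])
    )
    cons_groups = {
        (pid, condition): row
        for pid, condition, row in zip(
            cons["participant_id"], cons["condition"], cons.itertuples(index=False)
        )
    }
    rows = []
    for pid in pids:
        row: dict = {"participant_id": pid, "complete": True}
        sim = sim_groups.get(pid)
        if not skip_embedding:
            try:
                if sim is None:
                    raise ValueError("no similarity data")
                emb = embed_landscape(
                    sim, n_dimensions=n_dimensions, seed=seed,
                    n_init=n_init, max_iter=max_iter,
                )
                dist = cluster_distances(emb, pair_design)
                row["stress"] = emb.stress
                for emo, v in dist.within.items():
                    row[f"within_{emo}"] = v
                for (a, b), v in dist.between.items():
                    row[f"between_{a}_{b}"] = v
                row["mean_within"] = dist.mean_within
                row["mean_between"] = dist.mean_between
            except ValueError:
                row["complete"] = False
        emo_scores = []
        n_lapses = 0
        for condition in td.TRIPLET_CONDITIONS:
            key = (
                "color_control_consistency"
                if condition == "color_control"
                else f"consistency_{condition}"
            )
            entry = cons_groups.get((pid, condition))
            score = entry.score if entry is not None else np.nan
            row[key] = score
            if np.isnan(score):
                row["complete"] = False
            else:
                n_lapses += int(entry.n_lapses)
                if condition != "color_control":
                    emo_scores.append(score)
        row["emotional_consistency"] = (
            float(np.mean(emo_scores)) if len(emo_scores) == 3 else np.nan
        )
        row["n_lapses"] = n_lapses
        rows.append(row)
    return pd.DataFrame(rows)
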