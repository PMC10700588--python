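"""Scoring of ExpressionMap, Visual Matching and PLF recognition responses.

Representational consistency is -1 x the sample standard deviation of the
true speeds (pixels/frame) attributed to the four repetitions of one actor's
expression, averaged over actors within an emotion and then over emotions;
0 is perfect consistency. Representation distances are absolute differences
of mean attributed speeds between emotion pairs. Matching difficulty is the
mean absolute percent deviation from the reference speed; recognition
accuracy is the correct-emotion rating minus the mean of the two incorrect
ratings (range -10..10). The representation-matching composite multiplies
each emotion's representational consistency with its matching difficulty.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import task_design as td

EMOTION_PAIRS = tuple(itertools.combinations(td.EMOTIONS, 2))


def true_speed(percent_attributed: float, base_speed: float) -> float:
    """Attributed speed in pixels/frame: (percent / 100) x recorded speed.

    E.g. 200% attributed to a face moving at 2.5 pixels/frame -> 5 pixels/frame.
    """
    percent = np.asarray(percent_attributed, dtype=float)
    if np.any(percent < td.DIAL_MIN_PCT) or np.any(percent > td.DIAL_MAX_PCT):
        raise ValueError(
            f"attributed percent outside dial bounds "
            f"[{td.DIAL_MIN_PCT}, {td.DIAL_MAX_PCT}]"
        )
    base = np.asarray(base_speed, dtype=float)
    if np.any(base <= 0):
        raise ValueError("base speed must be positive")
    out = percent / 100.0 * base
    return float(out) if out.ndim == 0 else out


def consistency_from_speeds(speeds, ddof: int = 1) -> float:
    """-1 x sample SD of the speeds attributed to one expression.

    0 iff all attributions are identical; e.g. attributed speeds of 119, 120
    and 121 (percent at a 1 pixel/frame base) give an SD of 1 and a
    consistency of -1.
    """
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size < 2:
        raise ValueError("need at least two repetitions")
    return -float(np.std(speeds, ddof=ddof))


def representational_consistency(
    expression: pd.DataFrame, scale: str = "speed", ddof: int = 1
) -> pd.DataFrame:
    """Per-participant representational consistency and mean speeds.

    Expects the ExpressionMap response table (4 repetitions per actor x
    emotion, with ``attributed_pct`` and ``base_speed``). The SD is taken per
    actor x emotion over repetitions on converted speeds (``scale="speed"``,
    the default) or on raw percentages (``scale="percent"``), multiplied by
    -1, then averaged over actors within emotion and over emotions.
    """
    if scale not in ("speed", "percent"):
        raise ValueError("scale must be 'speed' or 'percent'")
    expression = expression.copy()
    expression["attributed_speed"] = true_speed(
        expression["attributed_pct"].to_numpy(), expression["base_speed"].to_numpy()
    )
    value_col = "attributed_speed" if scale == "speed" else "attributed_pct"

    counts = expression.groupby(["participant_id", "actor", "emotion"]).size()
    if (counts != len(td.REPETITIONS)).any():
        bad = counts[counts != len(td.REPETITIONS)].index[0]
        raise ValueError(f"expected 4 repetitions per actor x emotion, got {bad}")

    cell = expression.groupby(["participant_id", "actor", "emotion"])[value_col].agg(
        ["std", "mean"]
    )
    cell["std"] = expression.groupby(["participant_id", "actor", "emotion"])[
        value_col
    ].std(ddof=ddof)
    per_emotion = cell.groupby(["participant_id", "emotion"]).mean()
    rows = []
    speed_means = expression.groupby(["participant_id", "emotion"])[
        "attributed_speed"
    ].mean()
    for pid, g in per_emotion.groupby("participant_id"):
        row = {"participant_id": pid}
        cons = {}
        for emo in td.EMOTIONS:
            cons[emo] = -float(g.loc[(pid, emo), "std"])
            row[f"rep_consistency_{emo}"] = cons[emo]
            row[f"rep_speed_{emo}"] = float(speed_means.loc[(pid, emo)])
        row["rep_consistency"] = float(np.mean(list(cons.values())))
        dists = representation_distances(
            {emo: row[f"rep_speed_{emo}"] for emo in td.EMOTIONS}
        )
        for key, v in dists.items():
            if len(key) == 2:
                row[f"rep_distance_{key[0]}_{key[1]}"] = v
        row["rep_distance"] = dists[("mean",)]
        rows.append(row)
    return pd.DataFrame(rows)


def representation_distances(mean_speeds: dict) -> dict:
    """Absolute pairwise differences of per-emotion mean speeds, plus mean.

    Keys are sorted emotion pairs; the overall mean is under ``("mean",)``.
    """
    missing = [e for e in td.EMOTIONS if e not in mean_speeds]
    if missing:
        raise ValueError(f"missing emotion means: {missing}")
    out = {
        (a, b): float(abs(mean_speeds[a] - mean_speeds[b])) for a, b in EMOTION_PAIRS
    }
    out[("mean",)] = float(np.mean(list(out.values())))
    return out


def matching_scores(matching: pd.DataFrame, split: bool = True) -> pd.DataFrame:
    """Per-participant matching difficulty (mean absolute percent deviation).

    Expects the Visual Matching response table (48 trials per participant
    with ``attributed_pct`` and ``target_pct``). With ``split=True`` a
    cohort-median split on overall deviation labels each participant
    ``high_matching`` (deviation <= median, i.e. better matching; ties go
    high) or ``low_matching``.
    """
    counts = matching.groupby("participant_id").size()
    n_expected = len(td.ACTORS) * len(td.REPETITIONS) * len(td.EMOTIONS)
    if (counts != n_expected).any():
        bad = counts[counts != n_expected]
        raise ValueError(
            f"expected {n_expected} matching trials per participant; "
            f"offending participants: {list(bad.index[:3])}"
        )
    matching = matching.copy()
    matching["deviation"] = (
        matching["attributed_pct"] - matching["target_pct"]
    ).abs()
    per_emotion = (
        matching.groupby(["participant_id", "emotion"])["deviation"]
        .mean()
        .unstack("emotion")
        .rename(columns={e: f"matching_difficulty_{e}" for e in td.EMOTIONS})
    )
    overall = matching.groupby("participant_id")["deviation"].mean()
    out = per_emotion.assign(matching_difficulty=overall).reset_index()
    if split:
        median = out["matching_difficulty"].median()
        out["matching_group"] = np.where(
            out["matching_difficulty"] <= median, "high_matching", "low_matching"
        )
        out["matching_median"] = median
    return out


def recognition_accuracy(recognition: pd.DataFrame) -> pd.DataFrame:
    """Per-participant recognition accuracy (overall and per emotion).

    Trial accuracy = correct-emotion rating minus the mean of the two
    incorrect ratings; the overall mean is taken over all 108 trials.
    """
    rating_cols = [f"rating_{e}" for e in td.EMOTIONS]
    missing = [c for c in rating_cols if c not in recognition.columns]
    if missing:
        raise ValueError(f"missing rating scales: {missing}")
    ratings = recognition[rating_cols].to_numpy()
    if np.any((ratings < 0) | (ratings > 10)):
        raise ValueError("ratings must lie in [0, 10]")
    correct_idx = np.array(
        [td.EMOTIONS.index(e) for e in recognition["emotion"]]
    )
    rows = np.arange(len(recognition))
    correct = ratings[rows, correct_idx]
    incorrect_mean = (ratings.sum(axis=1) - correct) / (len(td.EMOTIONS) - 1)
    table = recognition[["participant_id", "emotion"]].copy()
    table["accuracy"] = correct - incorrect_mean
    per_emotion = (
        table.groupby(["participant_id", "emotion"])["accuracy"]
        .mean()
        .unstack("emotion")
        .rename(columns={e: f"accuracy_{e}" for e in td.EMOTIONS})
    )
    overall = table.groupby("participant_id")["accuracy"].mean()
    return per_emotion.assign(accuracy=overall).reset_index()


def representation_matching(
    rep: pd.DataFrame, matching: pd.DataFrame, standardized: bool = False
) -> pd.DataFrame:
    """Composite of representational consistency and matching difficulty.

    Per emotion the composite is the raw product
    rep_consistency_e x matching_difficulty_e (<= 0, higher is better);
    ``standardized=True`` z-scores both factors across the cohort first.
    """
    merged = rep.merge(matching, on="participant_id", validate="one_to_one")
    out = merged[["participant_id"]].copy()
    comps = []
    for emo in td.EMOTIONS:
        c = merged[f"rep_consistency_{emo}"]
        d = merged[f"matching_difficulty_{emo}"]
        if standardized:
            c = (c - c.mean()) / c.std(ddof=1)
            d = (d - d.mean()) / d.std(ddof=1)
        comp = c * d
        out[f"representation_matching_{emo}"] = comp
        comps.append(comp)
    out["representation_matching"] = np.mean(comps, axis=0)
    return out


def expression_participant_scores(
    expression: pd.DataFrame,
    matching: pd.DataFrame,
    recognition: pd.DataFrame,
    scale: str = "speed",
    standardized_composite: bool = False,
) -> pd.DataFrame:
    """Participant-level wide table of every ExpressionMap-battery measure."""
    rep = representational_consistency(expression, scale=scale)
    match = matching_scores(matching)
    acc = recognition_accuracy(recognition)
    comp = representation_matching(rep, match, standardized=standardized_composite)
    out = rep.merge(match, on="participant_id").merge(acc, on="participant_id")
    return out.merge(comp, on="participant_id")
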