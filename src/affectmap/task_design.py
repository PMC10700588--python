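"""Deterministic enumeration of the five behavioural task designs.

The whole pipeline — simulators, scorers, validators — shares these tables as
the single ground truth for which trials exist:

* EmoMap part 1: pairwise similarity ratings over 15 affect-inducing images
  (5 each for anger, happiness, sadness) -> 105 unordered pairs.
* EmoMap part 2: triplet choices. Per condition (anger / happiness / sadness /
  color_control) the 11 target images appear in every unordered pair (55
  trials), each trial carrying one "trap" image drawn from the opposing
  category pool (a grayscale image in the color-control condition).
* ExpressionMap and Visual Matching: speed-dial tasks over 4 actors x
  3 emotions x 4 repetitions = 48 trials, dial bounded at 25%-300% of the
  recorded speed. Matching start speeds form the 50..200%-in-10%-steps grid
  (16 per emotion); ExpressionMap start speeds are seeded-uniform in the dial
  range.
* PLF emotion recognition: full crossing of 4 actors x 3 emotions x 3 spatial
  levels x 3 kinematic levels = 108 trials (12 per spatial x kinematic cell).

Image identifiers are synthetic stable strings (category + index); the real
stimulus-set image numbers are irrelevant to any scoring operation.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pandas as pd

EMOTIONS: tuple[str, ...] = ("anger", "happiness", "sadness")
TRIPLET_CONDITIONS: tuple[str, ...] = EMOTIONS + ("color_control",)

N_PAIR_IMAGES_PER_EMOTION = 5
N_TARGETS = 11
N_TRAP_IMAGES_CONTROL = 5

ACTORS: tuple[int, ...] = (1, 2, 3, 4)
REPETITIONS: tuple[int, ...] = (1, 2, 3, 4)
DIAL_MIN_PCT = 25.0
DIAL_MAX_PCT = 300.0
MATCHING_START_GRID: tuple[int, ...] = tuple(range(50, 201, 10))
MATCHING_TARGET_PCT = 100.0

SPATIAL_LEVELS: tuple[int, ...] = (50, 100, 150)
KINEMATIC_LEVELS: tuple[int, ...] = (50, 100, 150)


def pair_images() -> list[str]:
    """The 15 similarity-rating images, 5 per emotion category."""
    return [
        f"{emo}_{i:02d}"
        for emo in EMOTIONS
        for i in range(1, N_PAIR_IMAGES_PER_EMOTION + 1)
    ]


def image_category(image_id: str) -> str:
    return image_id.rsplit("_", 1)[0]


def build_emopair_design() -> pd.DataFrame:
    """All 105 unordered pairs of the 15 images with category annotations.

    30 pairs are within-category (10 per emotion) and 75 between-category
    (25 per emotion pair).
    """
    rows = []
    for a, b in itertools.combinations(pair_images(), 2):
        cat_a, cat_b = image_category(a), image_category(b)
        rows.append(
            {
                "image_id_a": a,
                "image_id_b": b,
                "category_a": cat_a,
                "category_b": cat_b,
                "pair_type": "within" if cat_a == cat_b else "between",
            }
        )
    return pd.DataFrame(rows)


def target_images(condition: str) -> list[str]:
    """The 11 target (non-trap) images of one triplet condition."""
    _check_condition(condition)
    stem = "neutral" if condition == "color_control" else condition
    return [f"{stem}_t{i:02d}" for i in range(1, N_TARGETS + 1)]


def trap_pool(condition: str) -> list[str]:
    """Images eligible as the trial's attention-check trap.

    Emotional conditions draw traps from the two opposing emotions' target
    pools; the color-control condition draws from a small grayscale pool.
    """
    _check_condition(condition)
    if condition == "color_control":
        return [f"gray_{i:02d}" for i in range(1, N_TRAP_IMAGES_CONTROL + 1)]
    others = [e for e in EMOTIONS if e != condition]
    return [img for e in others for img in target_images(e)]


def build_triplet_design(condition: str, seed: int = 0) -> pd.DataFrame:
    """55 triplet trials: every unordered target pair once, plus one trap.

    Trap assignment is seeded-random over the opposing-category pool; traps
    may repeat across trials. Each target image appears in exactly 10 trials.
    """
    _check_condition(condition)
    targets = target_images(condition)
    pool = trap_pool(condition)
    rng = np.random.default_rng([seed, TRIPLET_CONDITIONS.index(condition)])
    rows = []
    for a, b in itertools.combinations(targets, 2):
        trap = pool[rng.integers(len(pool))]
        rows.append(
            {
                "condition": condition,
                "target_a": a,
                "target_b": b,
                "trap_image": trap,
                "trap_category": (
                    "grayscale" if condition == "color_control" else image_category(trap)
                ),
            }
        )
    return pd.DataFrame(rows)


def build_speed_design(task: str, seed: int = 0) -> pd.DataFrame:
    """48 speed-dial trials (4 actors x 3 emotions x 4 repetitions).

    ``task`` is ``"expressionmap"`` (start speed seeded-uniform within dial
    bounds) or ``"matching"`` (the 16 actor x repetition cells of each emotion
    carry the 50..200% step-10 start grid in seeded order, and the reference
    video plays at the recorded speed, i.e. a 100% target).
    """
    if task not in ("expressionmap", "matching"):
        raise ValueError(f"unknown speed task {task!r}")
    rng = np.random.default_rng([seed, 0 if task == "expressionmap" else 1])
    rows = []
    for emotion in EMOTIONS:
        cells = [(a, r) for a in ACTORS for r in REPETITIONS]
        if task == "matching":
            starts = rng.permutation(np.array(MATCHING_START_GRID, dtype=float))
        else:
            starts = rng.uniform(DIAL_MIN_PCT, DIAL_MAX_PCT, size=len(cells))
        for (actor, rep), start in zip(cells, starts):
            rows.append(
                {
                    "task": task,
                    "actor": actor,
                    "emotion": emotion,
                    "repetition": rep,
                    "start_speed_pct": float(start),
                    "dial_min_pct": DIAL_MIN_PCT,
                    "dial_max_pct": DIAL_MAX_PCT,
                    "target_pct": MATCHING_TARGET_PCT if task == "matching" else np.nan,
                }
            )
    return pd.DataFrame(rows)


def build_recognition_design() -> pd.DataFrame:
    """108 recognition trials: actors x emotions x spatial x kinematic levels."""
    rows = [
        {
            "actor": actor,
            "emotion": emotion,
            "spatial_level": spatial,
            "kinematic_level": kinematic,
        }
        for actor in ACTORS
        for emotion in EMOTIONS
        for spatial in SPATIAL_LEVELS
        for kinematic in KINEMATIC_LEVELS
    ]
    return pd.DataFrame(rows)


def build_all_designs(seed: int = 0) -> dict[str, pd.DataFrame]:
    """Every design table keyed by a short name; shared by the pipeline."""
    designs: dict[str, pd.DataFrame] = {"emopair": build_emopair_design()}
    for condition in TRIPLET_CONDITIONS:
        designs[f"triplet_{condition}"] = build_triplet_design(condition, seed=seed)
    designs["expressionmap"] = build_speed_design("expressionmap", seed=seed)
    designs["matching"] = build_speed_design("matching", seed=seed)
    designs["recognition"] = build_recognition_design()
    return designs


def write_designs(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write one CSV per design table; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in build_all_designs(seed=seed).items():
        path = outdir / f"design_{name}.csv"
        table.to_csv(path, index=False)
        paths[name] = path
    return paths


def _check_condition(condition: str) -> None:
    if condition not in TRIPLET_CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {TRIPLET_CONDITIONS}"
        )
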