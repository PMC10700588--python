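"""Synthetic cohorts with the generative structure the analysis assumes.

Each simulated participant carries a latent profile:

* a 2-D affect plane (axes interpretable as valence/arousal) with one cluster
  centre per emotion at radius ``modularity`` — anger and sadness centres are
  placed closer to each other than either is to happiness, echoing the greater
  anger-sadness overlap seen empirically;
* trial-to-trial experience noise ``sigma_exp`` perturbing affect-plane
  positions and evoked intensities;
* a latent representation speed per emotion (pixels/frame) with
  representational noise ``sigma_rep``;
* visual matching noise ``sigma_match`` (percent points) and a trap-selecting
  lapse probability;
* trait covariates AQ (0-50), TAS (20-100) and non-verbal reasoning (percent).

The experience-representation link is injected through a Gaussian copula correlating
1/sigma_exp with 1/sigma_rep across participants (``rho_cons``), and through
the recognition model: ratings arise from a Gaussian tuning kernel comparing
the perceived stimulus speed (corrupted by matching noise) with the sampled
representation speed, so recognition accuracy genuinely depends on both the
consistency of the stored template and the ability to match it to input.

All distributional choices are artifact decisions isolated in
:class:`CohortConfig`; defaults for the per-emotion representation speeds are
the empirically reported means (angry 3.85, happy 2.80, sad 1.63 pixels/frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import task_design as td

# Cluster-centre angles (degrees) on the affect plane. With equal radii the
# chord ratios reproduce the observed asymmetry: the anger-sadness separation
# is ~0.69 of the anger-happiness / happiness-sadness separations.
CLUSTER_ANGLES_DEG = {"happiness": 90.0, "anger": 229.3, "sadness": -49.3}


@dataclass
class CohortConfig:
    """Distributions and ranges for every latent participant parameter."""

    n_participants: int = 193
    seed: int = 0

    # cross-participant correlation between 1/sigma_exp and 1/sigma_rep
    rho_cons: float = 0.6

    # affect-plane geometry
    modularity_mean: float = 6.0
    modularity_sd: float = 1.5
    modularity_min: float = 0.5
    within_cluster_sd: float = 1.5
    similarity_lambda: float = 5.0  # similarity = 10 * exp(-distance / lambda)

    # experience noise (log-normal marginal), affect-plane units
    sigma_exp_log_mu: float = 0.0
    sigma_exp_log_sd: float = 0.6
    # representational noise (log-normal marginal), pixels/frame
    sigma_rep_log_mu: float = float(np.log(0.5))
    sigma_rep_log_sd: float = 0.6
    # matching noise (log-normal), percent points
    sigma_match_log_mu: float = float(np.log(30.0))
    sigma_match_log_sd: float = 0.4
    # colorfulness-judgment noise for the control condition (independent)
    sigma_ctrl_log_mu: float = 0.0
    sigma_ctrl_log_sd: float = 0.6
    # attention lapses (Beta prior, mean ~3%)
    lapse_beta_a: float = 1.0
    lapse_beta_b: float = 30.0

    # latent representation speeds, pixels/frame
    rep_speed_means: dict = field(
        default_factory=lambda: {"anger": 3.85, "happiness": 2.80, "sadness": 1.63}
    )
    rep_speed_sd: float = 0.45
    # recorded actor speeds: v0(actor, emotion) = factor[actor] * emotion mean
    actor_speed_factors: tuple = (0.9, 1.0, 1.1, 1.2)

    # evoked-intensity distribution for triplet target images
    intensity_mean: float = 3.5
    intensity_sd: float = 0.8

    # recognition model
    rating_kernel_width: float = 1.0  # tau, pixels/frame
    rating_noise_sd: float = 0.5
    match_weight: float = 1.5  # scales matching noise into perceived-speed noise

    # trait covariates
    aq_mean: float = 19.0
    aq_sd: float = 6.8
    tas_mean: float = 48.0
    tas_sd: float = 11.6
    nvr_mean: float = 61.0
    nvr_sd: float = 15.0
    # alexithymia -> less modular landscape (per-SD shift of modularity)
    tas_modularity_beta: float = -0.25

    def base_speeds(self) -> pd.DataFrame:
        """v0(actor, emotion) in pixels/frame for the recorded PLF videos."""
        rows = [
            {
                "actor": actor,
                "emotion": emotion,
                "base_speed": self.actor_speed_factors[i] * self.rep_speed_means[emotion],
            }
            for i, actor in enumerate(td.ACTORS)
            for emotion in td.EMOTIONS
        ]
        return pd.DataFrame(rows)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["actor_speed_factors"] = list(self.actor_speed_factors)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "actor_speed_factors" in data:
            data["actor_speed_factors"] = tuple(data["actor_speed_factors"])
        return cls(**data)


@dataclass
class Cohort:
    """Latent state of a generated cohort.

    ``profiles`` has one row per participant (noise scales, speeds, traits);
    ``image_positions`` the per-participant affect-plane coordinates of the 15
    similarity images; ``intensities`` the per-participant evoked intensity of
    every triplet target image.
    """

    config: CohortConfig
    profiles: pd.DataFrame
    image_positions: pd.DataFrame
    intensities: pd.DataFrame

    @property
    def participant_ids(self) -> list[str]:
        return list(self.profiles["participant_id"])


def generate_profiles(config: CohortConfig) -> Cohort:
    """Draw a cohort of latent participant profiles.

    The (1/sigma_exp, 1/sigma_rep) pair realises rank correlation
    ``rho_cons`` through a Gaussian copula with log-normal marginals.
    """
    if config.n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if not -1.0 <= config.rho_cons <= 1.0:
        raise ValueError("rho_cons must lie in [-1, 1]")
    for name in ("modularity_sd", "within_cluster_sd", "sigma_exp_log_sd",
                 "sigma_rep_log_sd", "sigma_match_log_sd", "rep_speed_sd"):
        if getattr(config, name) < 0:
            raise ValueError(f"{name} must be >= 0")
    n = config.n_participants
    rng = np.random.default_rng(config.seed)

    # copula: z2 = rho*z1 + sqrt(1-rho^2)*w correlates the precisions
    z1 = rng.standard_normal(n)
    w = rng.standard_normal(n)
    rho = config.rho_cons
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * w
    # high z -> high precision -> low noise
    sigma_exp = np.exp(config.sigma_exp_log_mu - config.sigma_exp_log_sd * z1)
    sigma_rep = np.exp(config.sigma_rep_log_mu - config.sigma_rep_log_sd * z2)

    sigma_match = np.exp(
        config.sigma_match_log_mu + config.sigma_match_log_sd * rng.standard_normal(n)
    )
    sigma_ctrl = np.exp(
        config.sigma_ctrl_log_mu + config.sigma_ctrl_log_sd * rng.standard_normal(n)
    )
    lapse_prob = rng.beta(config.lapse_beta_a, config.lapse_beta_b, size=n)

    aq = np.clip(rng.normal(config.aq_mean, config.aq_sd, n), 0, 50)
    tas = np.clip(rng.normal(config.tas_mean, config.tas_sd, n), 20, 100)
    nvr = np.clip(rng.normal(config.nvr_mean, config.nvr_sd, n), 0, 100)

    z_tas = (tas - config.tas_mean) / max(config.tas_sd, 1e-12)
    modularity = np.maximum(
        config.modularity_min,
        rng.normal(
            config.modularity_mean + config.tas_modularity_beta * z_tas,
            config.modularity_sd,
        ),
    )

    speeds = {
        emo: rng.normal(config.rep_speed_means[emo], config.rep_speed_sd, n)
        for emo in td.EMOTIONS
    }

    ids = [f"p{i + 1:04d}" for i in range(n)]
    profiles = pd.DataFrame(
        {
            "participant_id": ids,
            "modularity": modularity,
            "sigma_exp": sigma_exp,
            "sigma_rep": sigma_rep,
            "sigma_match": sigma_match,
            "sigma_ctrl": sigma_ctrl,
            "lapse_prob": lapse_prob,
            "s_anger": speeds["anger"],
            "s_happiness": speeds["happiness"],
            "s_sadness": speeds["sadness"],
            "aq": aq,
            "tas": tas,
            "nvr": nvr,
        }
    )

    # affect-plane image positions: cluster centre + per-image offset
    images = td.pair_images()
    cats = np.array([td.image_category(img) for img in images])
    angles = np.deg2rad([CLUSTER_ANGLES_DEG[c] for c in cats])
    units = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (15, 2)
    offsets = rng.normal(0.0, config.within_cluster_sd, size=(n, len(images), 2))
    centres = modularity[:, None, None] * units[None, :, :]
    pos = centres + offsets
    image_positions = pd.DataFrame(
        {
            "participant_id": np.repeat(ids, len(images)),
            "image_id": np.tile(images, n),
            "x": pos[:, :, 0].ravel(),
            "y": pos[:, :, 1].ravel(),
        }
    )

    # evoked intensities of triplet targets, fixed per participant
    rows = []
    for condition in td.TRIPLET_CONDITIONS:
        targets = td.target_images(condition)
        mu = rng.normal(config.intensity_mean, config.intensity_sd, size=(n, len(targets)))
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(ids, len(targets)),
                    "condition": condition,
                    "image_id": np.tile(targets, n),
                    "intensity": mu.ravel(),
                }
            )
        )
    intensities = pd.concat(rows, ignore_index=True)

    return Cohort(config, profiles, image_positions, intensities)


# alias matching the pipeline vocabulary
generate_cohort = generate_profiles


def _participant_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, index, stream])


def simulate_similarity(
    cohort: Cohort, designs: dict[str, pd.DataFrame], seed: int = 0
) -> pd.DataFrame:
    """EmoMap part-1 similarity ratings for a cohort.

    Each image's affect-plane position is perturbed by N(0, sigma_exp^2 I)
    per trial; similarity = 10*exp(-d/lambda), rounded to the task's
    4-decimal resolution.
    """
    pair_design = designs["emopair"]
    lam = cohort.config.similarity_lambda
    cfg_seed = cohort.config.seed
    ids = cohort.participant_ids
    n = len(ids)

    images = td.pair_images()
    img_index = {img: i for i, img in enumerate(images)}
    # (n, 15, 2) positions in generation order
    pos = (
        cohort.image_positions.set_index(["participant_id", "image_id"])
        .loc[[(p, i) for p in ids for i in images], ["x", "y"]]
        .to_numpy()
        .reshape(n, len(images), 2)
    )
    ai = np.array([img_index[i] for i in pair_design["image_id_a"]])
    bi = np.array([img_index[i] for i in pair_design["image_id_b"]])
    m = len(pair_design)
    sigma_exp = cohort.profiles["sigma_exp"].to_numpy()

    sims = np.empty((n, m))
    for idx in range(n):
        rng = _participant_rng(cfg_seed + seed, idx, 0)
        noise = rng.normal(0.0, sigma_exp[idx], size=(m, 4))
        pa = pos[idx, ai] + noise[:, :2]
        pb = pos[idx, bi] + noise[:, 2:]
        d = np.hypot(pa[:, 0] - pb[:, 0], pa[:, 1] - pb[:, 1])
        sims[idx] = np.round(np.clip(10.0 * np.exp(-d / lam), 0.0, 10.0), 4)
    return pd.DataFrame(
        {
            "participant_id": np.repeat(ids, m),
            "image_id_a": np.tile(pair_design["image_id_a"].to_numpy(), n),
            "image_id_b": np.tile(pair_design["image_id_b"].to_numpy(), n),
            "similarity": sims.ravel(),
        }
    )


def simulate_choices(
    cohort: Cohort, designs: dict[str, pd.DataFrame], seed: int = 0
) -> pd.DataFrame:
    """EmoMap part-2 triplet choices for a cohort.

    Chosen image = argmax of evoked intensity plus N(0, sigma_exp) noise over
    the two targets (sigma_ctrl in the color-control condition); with
    probability ``lapse_prob`` the trap is selected first (counted as a
    lapse) and the trial retried with fresh noise, so final choices are
    always among the targets.
    """
    cfg_seed = cohort.config.seed
    ids = cohort.participant_ids
    n = len(ids)
    lapse_prob = cohort.profiles["lapse_prob"].to_numpy()
    sigma_exp = cohort.profiles["sigma_exp"].to_numpy()
    sigma_ctrl = cohort.profiles["sigma_ctrl"].to_numpy()

    # intensities as (n, n_targets) arrays per condition, in generation order
    mu_by_cond = {}
    for condition in td.TRIPLET_CONDITIONS:
        targets = td.target_images(condition)
        sub = cohort.intensities[cohort.intensities["condition"] == condition]
        mu_by_cond[condition] = (
            sub.set_index(["participant_id", "image_id"])["intensity"]
            .loc[[(p, t) for p in ids for t in targets]]
            .to_numpy()
            .reshape(n, len(targets))
        )

    frames = []
    for idx, pid in enumerate(ids):
        rng = _participant_rng(cfg_seed + seed, idx, 1)
        for condition in td.TRIPLET_CONDITIONS:
            trip = designs[f"triplet_{condition}"]
            targets = td.target_images(condition)
            t_index = {t: i for i, t in enumerate(targets)}
            a = trip["target_a"].to_numpy()
            b = trip["target_b"].to_numpy()
            mu = mu_by_cond[condition][idx]
            mu_a = mu[[t_index[t] for t in a]]
            mu_b = mu[[t_index[t] for t in b]]
            m = len(trip)
            noise_sd = sigma_ctrl[idx] if condition == "color_control" else sigma_exp[idx]
            lapses = rng.random(m) < lapse_prob[idx]
            ea = rng.normal(0.0, noise_sd, m)
            eb = rng.normal(0.0, noise_sd, m)
            # retried trials get fresh experience noise
            ea2 = rng.normal(0.0, noise_sd, m)
            eb2 = rng.normal(0.0, noise_sd, m)
            ea = np.where(lapses, ea2, ea)
            eb = np.where(lapses, eb2, eb)
            chosen = np.where(mu_a + ea > mu_b + eb, a, b)
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "condition": condition,
                        "target_a": a,
                        "target_b": b,
                        "trap_image": trip["trap_image"].to_numpy(),
                        "chosen": chosen,
                        "n_lapses": lapses.astype(int),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_emomap(
    cohort: Cohort, designs: dict[str, pd.DataFrame], seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Similarity-rating and triplet-choice response tables for a cohort."""
    return (
        simulate_similarity(cohort, designs, seed=seed),
        simulate_choices(cohort, designs, seed=seed),
    )


def simulate_expression_and_matching(
    cohort: Cohort, designs: dict[str, pd.DataFrame], seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ExpressionMap and Visual Matching speed-attribution tables.

    ExpressionMap: attributed true speed ~ N(s_emotion, sigma_rep), converted
    to a dial percentage against the actor's recorded speed and clipped to the
    dial bounds. Matching: attributed percent ~ N(target percent, sigma_match)
    clipped to the bounds (start speed does not bias the response).
    """
    base = cohort.config.base_speeds().set_index(["actor", "emotion"])["base_speed"]
    cfg_seed = cohort.config.seed
    out = {}
    for task in ("expressionmap", "matching"):
        design = designs[task]
        actors = design["actor"].to_numpy()
        emotions = design["emotion"].to_numpy()
        v0 = base[list(zip(actors, emotions))].to_numpy()
        frames = []
        for idx, pid in enumerate(cohort.participant_ids):
            prof = cohort.profiles.iloc[idx]
            rng = _participant_rng(cfg_seed + seed, idx, 2 if task == "expressionmap" else 3)
            m = len(design)
            if task == "expressionmap":
                s_e = np.array([prof[f"s_{e}"] for e in emotions])
                s_rep = float(prof["sigma_rep"])
                true = s_e + (rng.normal(0.0, s_rep, m) if s_rep > 0 else 0.0)
                pct = np.clip(100.0 * true / v0, td.DIAL_MIN_PCT, td.DIAL_MAX_PCT)
            else:
                s_match = float(prof["sigma_match"])
                target = design["target_pct"].to_numpy()
                pct = np.clip(
                    target + (rng.normal(0.0, s_match, m) if s_match > 0 else 0.0),
                    td.DIAL_MIN_PCT,
                    td.DIAL_MAX_PCT,
                )
            frame = design.copy()
            frame.insert(0, "participant_id", pid)
            frame["base_speed"] = v0
            frame["attributed_pct"] = np.round(pct, 4)
            frames.append(frame)
        out[task] = pd.concat(frames, ignore_index=True)
    return out["expressionmap"], out["matching"]


def simulate_recognition(
    cohort: Cohort, designs: dict[str, pd.DataFrame], seed: int = 0
) -> pd.DataFrame:
    """PLF-recognition rating table (three 0-10 scales per trial).

    Rating on scale e = 10 * exp(-(v_hat - s_hat_e)^2 / (2 tau^2)) + noise,
    where s_hat_e ~ N(s_e, sigma_rep) is the trial's sampled representation
    and v_hat is the stimulus speed perceived through the participant's
    matching noise. Ratings are clipped to [0, 10] at 3-decimal resolution.
    """
    design = designs["recognition"]
    cfg = cohort.config
    base = cfg.base_speeds().set_index(["actor", "emotion"])["base_speed"]
    actors = design["actor"].to_numpy()
    emotions = design["emotion"].to_numpy()
    kin = design["kinematic_level"].to_numpy(dtype=float)
    v0 = base[list(zip(actors, emotions))].to_numpy()
    v_stim = v0 * kin / 100.0
    tau = cfg.rating_kernel_width
    frames = []
    for idx, pid in enumerate(cohort.participant_ids):
        prof = cohort.profiles.iloc[idx]
        rng = _participant_rng(cfg.seed + seed, idx, 4)
        m = len(design)
        s_rep = float(prof["sigma_rep"])
        s_match = float(prof["sigma_match"])
        stim_noise_sd = cfg.match_weight * s_match / 100.0 * v0
        ratings = {}
        for scale in td.EMOTIONS:
            # each scale is a separate matching operation against its template
            v_hat = v_stim + rng.normal(0.0, 1.0, m) * stim_noise_sd
            s_hat = prof[f"s_{scale}"] + (
                rng.normal(0.0, s_rep, m) if s_rep > 0 else 0.0
            )
            r = 10.0 * np.exp(-((v_hat - s_hat) ** 2) / (2.0 * tau**2))
            if cfg.rating_noise_sd > 0:
                r = r + rng.normal(0.0, cfg.rating_noise_sd, m)
            ratings[f"rating_{scale}"] = np.round(np.clip(r, 0.0, 10.0), 3)
        frame = design.copy()
        frame.insert(0, "participant_id", pid)
        for k, v in ratings.items():
            frame[k] = v
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def simulate_responses(
    cohort: Cohort, designs: dict[str, pd.DataFrame] | None = None, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """All five response tables for a cohort, keyed by task name."""
    if designs is None:
        designs = td.build_all_designs(seed=cohort.config.seed)
    similarity, choices = simulate_emomap(cohort, designs, seed=seed)
    expression, matching = simulate_expression_and_matching(cohort, designs, seed=seed)
    recognition = simulate_recognition(cohort, designs, seed=seed)
    return {
        "similarity": similarity,
        "choices": choices,
        "expressionmap": expression,
        "matching": matching,
        "recognition": recognition,
    }
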