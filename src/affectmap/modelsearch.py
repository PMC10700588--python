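"""Model search: importance screening, sequential building, path reversal.

The search mirrors a four-step procedure: (1) shadow-feature (Boruta-style)
importance screening of candidate predictors of emotion-recognition accuracy
with a random-forest backend; (2) sequential structural-model building —
confirmed candidates enter in descending importance and are kept while the
nested likelihood-ratio test shows a significant improvement; (3) systematic
reversal of every structural path with BIC comparison (dBIC 2-6 positive,
>6 strong evidence; |dBIC| < 2 is a tie — covariance-equivalent reversals,
e.g. any two-variable model, land here and retain the original direction);
(4) a final refit assembling the retained directions, which must not lose to
any single-reversal variant by more than the strong-evidence margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .sem import ModelSpec, PathModel, fit_path_model, lrt

DEFAULT_CANDIDATES = (
    "emotional_consistency",
    "mean_between",
    "mean_within",
    "rep_consistency",
    "rep_distance",
    "matching_difficulty",
    "representation_matching",
    "color_control_consistency",
    "aq",
    "tas",
    "nvr",
)


@dataclass
class BorutaScreen:
    """Shadow-feature relevance screen with a random-forest backend.

    Each iteration appends a permuted (shadow) copy of every candidate
    column, fits a random-forest regressor on the augmented matrix and
    computes permutation importances; a candidate scores a *hit* when it
    beats the best shadow. Hits over iterations are classified by a
    two-sided binomial test against chance (p = 1/2): significantly many ->
    confirmed, significantly few -> rejected, otherwise tentative.
    """

    n_iter: int = 100
    alpha: float = 0.01
    n_estimators: int = 100
    n_repeats: int = 3
    max_depth: int | None = None
    importance: str = "permutation"  # or "impurity" (faster, classic flavour)
    seed: int = 0

    def fit(self, x: pd.DataFrame, y: pd.Series) -> "BorutaScreen":
        x = x.copy()
        if x.shape[0] < 20:
            raise ValueError("too few rows for a stable forest screen")
        constant = [c for c in x.columns if x[c].nunique() <= 1]
        if constant:
            raise ValueError(f"constant candidate columns: {constant}")
        rng = np.random.default_rng(self.seed)
        cols = list(x.columns)
        hits = pd.Series(0, index=cols, dtype=int)
        history, shadow_max = [], []
        xv = x.to_numpy(dtype=float)
        yv = np.asarray(y, dtype=float)
        for it in range(self.n_iter):
            shadows = np.column_stack(
                [rng.permutation(xv[:, k]) for k in range(xv.shape[1])]
            )
            aug = np.hstack([xv, shadows])
            forest = RandomForestRegressor(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            ).fit(aug, yv)
            if self.importance == "impurity":
                imp = forest.feature_importances_
            elif self.importance == "permutation":
                imp = permutation_importance(
                    forest,
                    aug,
                    yv,
                    n_repeats=self.n_repeats,
                    random_state=int(rng.integers(2**31 - 1)),
                    n_jobs=1,
                ).importances_mean
            else:
                raise ValueError("importance must be 'permutation' or 'impurity'")
            real, shadow = imp[: len(cols)], imp[len(cols):]
            threshold = shadow.max()
            hits[np.array(cols)[real > threshold]] += 1
            history.append(real)
            shadow_max.append(threshold)
        self.hits_ = hits
        self.importance_history_ = pd.DataFrame(history, columns=cols)
        self.shadow_max_history_ = np.array(shadow_max)
        self.mean_importance_ = self.importance_history_.mean()

        decisions = {}
        for col in cols:
            p = stats.binomtest(int(hits[col]), self.n_iter, 0.5).pvalue
            if p < self.alpha and hits[col] > self.n_iter / 2:
                decisions[col] = "confirmed"
            elif p < self.alpha and hits[col] < self.n_iter / 2:
                decisions[col] = "rejected"
            else:
                decisions[col] = "tentative"
        self.decisions_ = pd.Series(decisions)
        self.support_ = self.decisions_ == "confirmed"
        return self

    def report(self) -> pd.DataFrame:
        order = self.mean_importance_.sort_values(ascending=False).index
        return pd.DataFrame(
            {
                "variable": order,
                "decision": self.decisions_[order].to_numpy(),
                "hits": self.hits_[order].to_numpy(),
                "n_iter": self.n_iter,
                "mean_importance": self.mean_importance_[order].to_numpy(),
                "mean_shadow_max": float(self.shadow_max_history_.mean()),
            }
        ).reset_index(drop=True)


@dataclass
class ImportanceReport:
    table: pd.DataFrame
    outcome: str
    screen: BorutaScreen = field(repr=False, default=None)

    def confirmed(self) -> list[str]:
        t = self.table
        return list(t.loc[t["decision"] == "confirmed", "variable"])


def screen_importance(
    scores: pd.DataFrame,
    outcome: str = "accuracy",
    candidates: tuple | None = None,
    seed: int = 0,
    **screen_kwargs,
) -> ImportanceReport:
    """Rank and classify candidate predictors of ``outcome``."""
    if candidates is None:
        candidates = [c for c in DEFAULT_CANDIDATES if c in scores.columns]
    missing = [c for c in list(candidates) + [outcome] if c not in scores.columns]
    if missing:
        raise ValueError(f"score table lacks columns: {missing}")
    complete = scores[list(candidates) + [outcome]].dropna()
    screen = BorutaScreen(seed=seed, **screen_kwargs).fit(
        complete[list(candidates)], complete[outcome]
    )
    return ImportanceReport(screen.report(), outcome, screen)


def sequential_build(
    report: ImportanceReport | list[str],
    scores: pd.DataFrame,
    outcome: str = "accuracy",
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[PathModel, pd.DataFrame]:
    """Add confirmed variables as predictors of ``outcome`` one at a time.

    All confirmed candidates stay in the covariance model throughout (free
    exogenous covariances), so successive models are nested: step k frees the
    k-th most important candidate's path into the outcome and is kept iff the
    likelihood-ratio test against the previous model has p < ``alpha``. The
    build stops at the first rejected addition.
    """
    if isinstance(report, ImportanceReport):
        t = report.table
        ordered = [
            v for v in t.sort_values("mean_importance", ascending=False)["variable"]
            if t.set_index("variable").loc[v, "decision"] == "confirmed"
        ]
    else:
        ordered = list(report)
    fit_kwargs.setdefault("compute_se", False)
    # outcome starts isolated (zero covariance with every candidate); each
    # accepted step frees exactly one path into it, so models are nested
    base_spec = ModelSpec(
        extra_variables=tuple(ordered) + (outcome,), isolate=(outcome,)
    )
    model = fit_path_model(base_spec, scores, **fit_kwargs)
    log_rows = []
    for var in ordered:
        candidate_spec = model.spec.with_edge((var, outcome))
        new_model = fit_path_model(candidate_spec, scores, **fit_kwargs)
        test = lrt(model, new_model)
        accepted = test["p"] < alpha
        log_rows.append(
            {
                "variable": var,
                "lrt_statistic": test["statistic"],
                "lrt_df": test["df"],
                "lrt_p": test["p"],
                "accepted": accepted,
                "bic_before": model.bic_,
                "bic_after": new_model.bic_,
            }
        )
        if not accepted:
            break
        model = new_model
    return model, pd.DataFrame(log_rows)


def reverse_path_search(
    model: PathModel,
    scores: pd.DataFrame,
    tie_threshold: float = 2.0,
    strong_threshold: float = 6.0,
    **fit_kwargs,
) -> tuple[pd.DataFrame, PathModel]:
    """Systematically reverse each structural path and compare BICs.

    dBIC = BIC(reversed) - BIC(original); positive values favour the
    original direction. Evidence categories follow the conventional BIC
    scale (|dBIC| < 2 tie, 2-6 positive, > 6 strong). The reversed direction
    is retained only when it wins by more than the tie threshold. The final
    model refits the retained directions and is checked against every
    single-reversal variant of itself.
    """
    fit_kwargs.setdefault("compute_se", False)
    rows = []
    retained = []
    for edge in model.spec.edges:
        try:
            rev_spec = model.spec.reverse_edge(edge)
            rev = fit_path_model(rev_spec, scores, **fit_kwargs)
            delta = rev.bic_ - model.bic_
            comparable = True
        except (ValueError, RuntimeError) as exc:
            delta, rev, comparable = np.nan, None, False
            note = str(exc)
        if comparable:
            if abs(delta) < tie_threshold:
                category, keep = "tie", edge
            elif delta > 0:
                category = "strong" if delta > strong_threshold else "positive"
                keep = edge
            else:
                category = (
                    "strong_reversed" if delta < -strong_threshold else "positive_reversed"
                )
                keep = (edge[1], edge[0])
            note = ""
        else:
            category, keep = "not_comparable", edge
        retained.append(keep)
        rows.append(
            {
                "edge": f"{edge[0]} -> {edge[1]}",
                "bic_original": model.bic_,
                "bic_reversed": rev.bic_ if rev is not None else np.nan,
                "delta_bic": delta,
                "evidence": category,
                "retained": f"{keep[0]} -> {keep[1]}",
                "note": note,
            }
        )
    report = pd.DataFrame(rows)
    final_spec = ModelSpec(
        tuple(retained), model.spec.latents, model.spec.extra_variables
    )
    final = fit_path_model(final_spec, scores, **fit_kwargs)
    # admissibility check: no single reversal of the final model should win
    # by more than the strong-evidence margin
    worst = 0.0
    for edge in final.spec.edges:
        try:
            rev = fit_path_model(final.spec.reverse_edge(edge), scores, **fit_kwargs)
            worst = min(worst, rev.bic_ - final.bic_)
        except (ValueError, RuntimeError):
            continue
    final.reversal_margin_ = worst  # <= 0 would mean a reversal still wins
    return report, final


def association_screen(
    scores: pd.DataFrame, formulas: list[str] | None = None
) -> pd.DataFrame:
    """Participant-level least-squares association screen.

    Ordinary least-squares stand-ins for the battery's headline associations
    (consistency of experience -> consistency of representation, etc.), each
    with the usual trait covariates. Returns a tidy coefficient table.
    """
    if formulas is None:
        formulas = [
            "rep_consistency ~ emotional_consistency + aq + tas + nvr"
            " + color_control_consistency",
            "rep_distance ~ mean_between + aq + tas + nvr"
            " + color_control_consistency",
            "accuracy ~ rep_consistency + rep_distance + aq + tas + nvr",
        ]
    rows = []
    for formula in formulas:
        cols = [
            c for c in scores.columns
            if c in formula.replace("~", "+").replace(" ", "").split("+")
        ]
        data = scores[cols].dropna()
        fit = smf.ols(formula, data=data).fit()
        if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
            raise ValueError(f"rank-deficient design for {formula!r}")
        for term in fit.params.index:
            rows.append(
                {
                    "model": formula,
                    "term": term,
                    "coef": float(fit.params[term]),
                    "se": float(fit.bse[term]),
                    "t": float(fit.tvalues[term]),
                    "p": float(fit.pvalues[term]),
                    "n": int(fit.nobs),
                }
            )
    return pd.DataFrame(rows)
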