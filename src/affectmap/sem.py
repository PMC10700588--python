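"""Maximum-likelihood structural models in the RAM parameterization.

A model is a set of directed structural edges among variables that are
either manifest (observed columns) or latent with observed indicators.
With ``A`` collecting directed coefficients (structural paths and loadings),
``S`` the symmetric residual variance/covariance matrix, and ``F`` the
filter onto observed variables, the implied covariance is

    Sigma = F (I - A)^{-1} S (I - A)^{-T} F^T

which supports nonrecursive (feedback) loops whenever ``I - A`` is
invertible. Free parameters are estimated by minimizing the normal-theory ML
discrepancy; standard errors come from the numerical Hessian of the
log-likelihood, indirect effects are path products with delta-method (Sobel)
standard errors, and model comparison uses BIC = -2 logL + k log N with N
the number of participants.

Conventions: latent scales are set by fixing the first loading to 1;
variables are z-scored before fitting; residual variances are free for every
variable and covariances are free between every pair of exogenous structural
variables (those without an incoming structural edge).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["ModelSpec", "PathModel", "fit_path_model", "saturated_spec", "lrt"]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative structural-model specification.

    ``edges`` are directed structural paths (source, destination) among
    structural variables; ``latents`` maps a latent name to its observed
    indicators; ``extra_variables`` enter the model without any structural
    edge (free exogenous covariances only); ``isolate`` lists variables
    withheld from the automatic exogenous covariances (their covariance with
    every other variable is fixed at zero until a path frees it) — this is
    what keeps sequentially built models nested.
    """

    edges: tuple = ()
    latents: tuple = ()  # ((latent, (ind1, ind2, ...)), ...)
    extra_variables: tuple = ()
    isolate: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "edges", tuple((str(a), str(b)) for a, b in self.edges))
        object.__setattr__(
            self,
            "latents",
            tuple((str(name), tuple(inds)) for name, inds in dict(self.latents).items()),
        )
        object.__setattr__(self, "extra_variables", tuple(self.extra_variables))
        object.__setattr__(self, "isolate", tuple(self.isolate))
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop {a!r} not allowed")
            if (a, b) in seen:
                raise ValueError(f"duplicate edge {(a, b)}")
            seen.add((a, b))

    @property
    def latent_map(self) -> dict:
        return {name: list(inds) for name, inds in self.latents}

    def structural_variables(self) -> list[str]:
        ordered: list[str] = []
        for a, b in self.edges:
            for v in (a, b):
                if v not in ordered:
                    ordered.append(v)
        for v in self.extra_variables:
            if v not in ordered:
                ordered.append(v)
        for name, _ in self.latents:
            if name not in ordered:
                ordered.append(name)
        return ordered

    def observed_variables(self) -> list[str]:
        latent_names = set(self.latent_map)
        out = [v for v in self.structural_variables() if v not in latent_names]
        for _, inds in self.latents:
            for i in inds:
                if i not in out:
                    out.append(i)
        return out

    def exogenous(self) -> list[str]:
        endo = {b for _, b in self.edges}
        return [v for v in self.structural_variables() if v not in endo]

    def reverse_edge(self, edge: tuple) -> "ModelSpec":
        """A copy of the spec with one structural edge reversed."""
        if tuple(edge) not in self.edges:
            raise ValueError(f"edge {edge} not in model")
        a, b = edge
        new_edges = tuple((b, a) if (x, y) == (a, b) else (x, y) for x, y in self.edges)
        if len(set(new_edges)) != len(new_edges):
            raise ValueError(f"reversing {edge} duplicates an existing edge")
        return ModelSpec(new_edges, self.latents, self.extra_variables, self.isolate)

    def with_edge(self, edge: tuple) -> "ModelSpec":
        return ModelSpec(
            self.edges + (tuple(edge),), self.latents, self.extra_variables, self.isolate
        )

    def to_dict(self) -> dict:
        return {
            "edges": [list(e) for e in self.edges],
            "latents": {name: list(inds) for name, inds in self.latents},
            "extra_variables": list(self.extra_variables),
            "isolate": list(self.isolate),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        return cls(
            tuple(tuple(e) for e in data.get("edges", ())),
            tuple((k, tuple(v)) for k, v in data.get("latents", {}).items()),
            tuple(data.get("extra_variables", ())),
            tuple(data.get("isolate", ())),
        )


def saturated_spec(variables) -> ModelSpec:
    """All variables exogenous with free covariances: the saturated model."""
    return ModelSpec(extra_variables=tuple(variables))


class _Parameterization:
    """Index bookkeeping for the free entries of A and S."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        latent_map = spec.latent_map
        self.observed = spec.observed_variables()
        self.latent_names = list(latent_map)
        self.variables = self.observed + self.latent_names
        self.index = {v: i for i, v in enumerate(self.variables)}
        self.n_obs = len(self.observed)
        self.n_all = len(self.variables)

        self.free: list[tuple[str, int, int]] = []  # (kind, row, col)
        self.fixed_loadings: list[tuple[int, int]] = []
        for a, b in spec.edges:
            self.free.append(("beta", self.index[b], self.index[a]))
        for name, inds in latent_map.items():
            j = self.index[name]
            for k, ind in enumerate(inds):
                i = self.index[ind]
                if k == 0:
                    self.fixed_loadings.append((i, j))
                else:
                    self.free.append(("loading", i, j))
        for v in self.variables:
            i = self.index[v]
            self.free.append(("var", i, i))
        exog = [v for v in spec.exogenous() if v not in spec.isolate]
        for a, b in itertools.combinations(exog, 2):
            self.free.append(("cov", self.index[a], self.index[b]))
        self.n_params = len(self.free)

    def start_values(self, rng: np.random.Generator | None = None) -> np.ndarray:
        theta = np.empty(self.n_params)
        for k, (kind, _, _) in enumerate(self.free):
            theta[k] = {"beta": 0.0, "loading": 0.8, "var": 1.0, "cov": 0.0}[kind]
        if rng is not None:
            theta = theta + rng.uniform(-0.3, 0.3, self.n_params)
            for k, (kind, _, _) in enumerate(self.free):
                if kind == "var":
                    theta[k] = max(theta[k], 0.05)
        return theta

    def bounds(self) -> list[tuple]:
        return [
            (1e-8, None) if kind == "var" else (None, None)
            for kind, _, _ in self.free
        ]

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_all
        a = np.zeros((n, n))
        s = np.zeros((n, n))
        for (i, j) in self.fixed_loadings:
            a[i, j] = 1.0
        for value, (kind, i, j) in zip(theta, self.free):
            if kind in ("beta", "loading"):
                a[i, j] = value
            elif kind == "var":
                s[i, i] = value
            else:
                s[i, j] = s[j, i] = value
        return a, s


@dataclass
class PathModel:
    """Estimator-style ML fitter for a :class:`ModelSpec`.

    After :meth:`fit`: ``loglik_``, ``bic_``, ``k_``, ``params_`` (tidy table
    with estimates, SEs, z, p and standardized betas), ``effects_`` (direct
    and indirect effects), ``implied_cov_``, ``converged_``.
    """

    spec: ModelSpec
    n_restarts: int = 5
    tol: float = 1e-8
    max_iter: int = 2000
    seed: int = 0
    compute_se: bool = True
    standardize: bool = True
    _par: _Parameterization = field(init=False, repr=False, default=None)

    def fit(self, data: pd.DataFrame) -> "PathModel":
        par = _Parameterization(self.spec)
        self._par = par
        missing = [v for v in par.observed if v not in data.columns]
        if missing:
            raise ValueError(f"data lacks model variables: {missing}")
        x = data[par.observed].dropna().to_numpy(dtype=float)
        n = x.shape[0]
        if n <= len(par.observed):
            raise ValueError("too few complete rows to fit the model")
        if self.standardize:
            sd = x.std(axis=0, ddof=1)
            if np.any(sd == 0):
                bad = [par.observed[i] for i in np.where(sd == 0)[0]]
                raise ValueError(f"constant columns cannot be modelled: {bad}")
            x = (x - x.mean(axis=0)) / sd
        c = np.cov(x.T, ddof=0).reshape(len(par.observed), len(par.observed))
        self.n_ = n
        self.sample_cov_ = c
        sign, logdet_c = np.linalg.slogdet(c)
        if sign <= 0:
            raise ValueError("sample covariance is singular")
        p = len(par.observed)
        obs_idx = [par.index[v] for v in par.observed]

        def discrepancy(theta: np.ndarray) -> float:
            a, s = par.matrices(theta)
            try:
                m = np.linalg.inv(np.eye(par.n_all) - a)
            except np.linalg.LinAlgError:
                return 1e10
            v = m @ s @ m.T
            sigma = v[np.ix_(obs_idx, obs_idx)]
            try:
                cho = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                return 1e10
            logdet = 2.0 * np.log(np.diag(cho)).sum()
            inv_sigma = np.linalg.inv(sigma)
            f = logdet + np.trace(c @ inv_sigma) - logdet_c - p
            return f if np.isfinite(f) else 1e10

        rng = np.random.default_rng(self.seed)
        best = None
        for r in range(max(1, self.n_restarts)):
            theta0 = par.start_values(rng if r > 0 else None)
            res = optimize.minimize(
                discrepancy,
                theta0,
                method="L-BFGS-B",
                bounds=par.bounds(),
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e9:
            raise RuntimeError("path model failed to converge")
        self.converged_ = bool(best.success or best.fun < 1e9)
        self.theta_ = best.x
        self.discrepancy_ = float(best.fun)
        self.loglik_ = float(
            -0.5 * n * (p * np.log(2 * np.pi) + self.discrepancy_ + logdet_c + p)
        )
        self.k_ = par.n_params
        self.bic_ = float(-2 * self.loglik_ + self.k_ * np.log(n))

        a, s = par.matrices(self.theta_)
        m = np.linalg.inv(np.eye(par.n_all) - a)
        v_all = m @ s @ m.T
        self.implied_cov_ = pd.DataFrame(
            v_all[np.ix_(obs_idx, obs_idx)], index=par.observed, columns=par.observed
        )
        self._v_all = v_all

        if self.compute_se:
            self.param_cov_ = self._parameter_covariance(discrepancy, n)
        else:
            self.param_cov_ = np.full((par.n_params, par.n_params), np.nan)
        self.params_ = self._param_table(v_all)
        self.effects_ = self._effect_table()
        return self

    # -- internals ---------------------------------------------------------

    def _parameter_covariance(self, discrepancy, n: int) -> np.ndarray:
        # Hessian of -logL = (n/2) * Hessian of the discrepancy
        theta = self.theta_
        k = len(theta)
        h = np.empty((k, k))
        step = 1e-4 * np.maximum(1.0, np.abs(theta))
        f0 = discrepancy(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = step[i]
                ej = np.zeros(k); ej[j] = step[j]
                if i == j:
                    val = (
                        discrepancy(theta + ei) - 2 * f0 + discrepancy(theta - ei)
                    ) / step[i] ** 2
                else:
                    val = (
                        discrepancy(theta + ei + ej)
                        - discrepancy(theta + ei - ej)
                        - discrepancy(theta - ei + ej)
                        + discrepancy(theta - ei - ej)
                    ) / (4 * step[i] * step[j])
                h[i, j] = h[j, i] = val
        h *= n / 2.0
        try:
            return np.linalg.inv(h)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(h)

    def _std_coef(self, kind: str, i: int, j: int, value: float, v_all) -> float:
        if kind in ("beta", "loading"):
            denom = v_all[i, i]
            if denom <= 0:
                return np.nan
            return value * np.sqrt(v_all[j, j] / denom)
        if kind == "cov":
            denom = np.sqrt(v_all[i, i] * v_all[j, j])
            return value / denom if denom > 0 else np.nan
        return np.nan

    def _param_table(self, v_all) -> pd.DataFrame:
        par = self._par
        rows = []
        diag = np.sqrt(np.clip(np.diag(self.param_cov_), 0.0, None))
        for k, ((kind, i, j), est) in enumerate(zip(par.free, self.theta_)):
            se = float(diag[k]) if np.isfinite(diag[k]) else np.nan
            z = est / se if se and se > 0 else np.nan
            rows.append(
                {
                    "kind": kind,
                    # regression convention: lhs ~ rhs (destination ~ source)
                    "lhs": par.variables[i],
                    "rhs": par.variables[j],
                    "estimate": float(est),
                    "se": se,
                    "z": float(z) if np.isfinite(z) else np.nan,
                    "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                    "std": self._std_coef(kind, i, j, est, v_all),
                }
            )
        return pd.DataFrame(rows)

    def edge_estimate(self, edge: tuple) -> pd.Series:
        """Tidy row for the structural edge (source, destination)."""
        a, b = edge
        t = self.params_
        row = t[(t["kind"] == "beta") & (t["lhs"] == b) & (t["rhs"] == a)]
        if row.empty:
            raise KeyError(f"edge {edge} not in model")
        return row.iloc[0]

    def _effect_table(self) -> pd.DataFrame:
        par = self._par
        rows = []
        edge_pos = {}
        for k, (kind, i, j) in enumerate(par.free):
            if kind == "beta":
                edge_pos[(par.variables[j], par.variables[i])] = k
        for (a, b), k in edge_pos.items():
            est = self.theta_[k]
            se = float(np.sqrt(max(self.param_cov_[k, k], 0.0)))
            z = est / se if se > 0 else np.nan
            rows.append(
                {
                    "path": f"{a} -> {b}",
                    "type": "direct",
                    "estimate": float(est),
                    "se": se,
                    "z": float(z) if np.isfinite(z) else np.nan,
                    "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                    "std": self._std_coef(
                        "beta", par.index[b], par.index[a], est, self._v_all
                    ),
                }
            )
        graph = nx.DiGraph(list(edge_pos))
        for a, b in itertools.permutations(graph.nodes, 2):
            paths = [
                p for p in nx.all_simple_paths(graph, a, b) if len(p) >= 3
            ] if nx.has_path(graph, a, b) else []
            if not paths:
                continue
            total, grad = 0.0, np.zeros(par.n_params)
            std_total = 0.0
            for p_nodes in paths:
                ks = [edge_pos[(x, y)] for x, y in zip(p_nodes[:-1], p_nodes[1:])]
                prod = float(np.prod([self.theta_[k] for k in ks]))
                total += prod
                std_total += float(
                    np.prod(
                        [
                            self._std_coef(
                                "beta",
                                par.index[y],
                                par.index[x],
                                self.theta_[edge_pos[(x, y)]],
                                self._v_all,
                            )
                            for x, y in zip(p_nodes[:-1], p_nodes[1:])
                        ]
                    )
                )
                for k in ks:
                    others = prod / self.theta_[k] if self.theta_[k] != 0 else np.prod(
                        [self.theta_[q] for q in ks if q != k]
                    )
                    grad[k] += others
            var = float(grad @ self.param_cov_ @ grad)
            se = np.sqrt(max(var, 0.0))
            z = total / se if se > 0 else np.nan
            rows.append(
                {
                    "path": " -> ".join(paths[0]) if len(paths) == 1 else f"{a} => {b}",
                    "type": "indirect",
                    "estimate": total,
                    "se": float(se),
                    "z": float(z) if np.isfinite(z) else np.nan,
                    "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                    "std": std_total,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "spec": self.spec.to_dict(),
            "n": int(self.n_),
            "loglik": self.loglik_,
            "k": self.k_,
            "bic": self.bic_,
            "converged": self.converged_,
            "params": self.params_.to_dict(orient="records"),
            "effects": self.effects_.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def fit_path_model(spec: ModelSpec, data: pd.DataFrame, **kwargs) -> PathModel:
    """Fit ``spec`` to ``data`` by maximum likelihood (thin wrapper)."""
    return PathModel(spec, **kwargs).fit(data)


def lrt(smaller: PathModel, bigger: PathModel) -> dict:
    """Likelihood-ratio test of nested fitted models (same observed set)."""
    if set(smaller._par.observed) != set(bigger._par.observed):
        raise ValueError("LRT requires models over the same observed variables")
    df = bigger.k_ - smaller.k_
    if df <= 0:
        raise ValueError("bigger model must have more free parameters")
    statistic = max(0.0, 2.0 * (bigger.loglik_ - smaller.loglik_))
    return {
        "statistic": statistic,
        "df": df,
        "p": float(stats.chi2.sf(statistic, df)),
    }
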