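"""Normative lifespan trajectory models (location-scale-shape).

For one metric at one scale, the observed values are modelled with a
four-parameter distribution family whose every parameter may depend
smoothly on age through a P-spline (cubic B-spline basis, second-order
difference penalty).  Acquisition site enters as ridge-shrunk additive
offsets on the location and log-scale predictors (a shrinkage stand-in for
mean/variance random effects), and sex as offsets on location, log-scale
and skew.  Fitting is penalized maximum likelihood by cyclic backfitting
over the distribution parameters: each inner step is a penalized weighted
least-squares update on one parameter's coefficients, with score and
curvature obtained numerically from the per-observation log-likelihood, and
step-halving guaranteeing the penalized deviance never increases.

The fitted model yields population quantile bands (sexes marginalized by
averaging the sex-specific parameter sets with cohort proportions, site
offsets at zero) and per-subject deviation scores
``z = Phi^{-1}(F(y | age, sex, site))``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import norm

from .families import FAMILIES, apply_link

PARAMS = ("mu", "sigma", "nu", "tau")


class ConvergenceWarning(UserWarning):
    pass


def bspline_design(x: np.ndarray, lo: float, hi: float, n_bases: int, degree: int = 3):
    """B-spline design matrix with equally spaced knots spanning [lo, hi]."""
    x = np.asarray(x, dtype=float)
    inner = np.linspace(lo, hi, n_bases - degree + 1)
    t = np.concatenate(
        [np.full(degree, lo), inner, np.full(degree, hi)]
    )
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, t, degree, extrapolate=False).toarray(), t


def difference_penalty(n_bases: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(n_bases), n=order, axis=0)
    return D.T @ D


@dataclass
class TrajectoryConfig:
    family: str = "bcpe"
    n_bases: int = 20
    degree: int = 3
    penalty_order: int = 2
    age_range: tuple[float, float] = (6.0, 88.0)
    # smoothing parameter per distribution parameter; None -> GAIC grid (mu only)
    smoothing: dict = field(
        default_factory=lambda: {"mu": None, "sigma": 50.0, "nu": 200.0, "tau": 200.0}
    )
    gaic_grid: tuple = (0.1, 1.0, 10.0, 100.0, 1e3, 1e4, 1e5)
    gaic_k: float | None = None  # GAIC dof penalty; None -> log(n) (SBC-like)
    ridge: float = 1.0  # shrinkage on site/sex offsets
    transform: str = "none"  # or "log10"
    tol: float = 1e-3
    max_iter: int = 200
    site_on: tuple = ("mu", "sigma")
    sex_on: tuple = ("mu", "sigma", "nu")


@dataclass
class NormativeModel:
    """Fitted coefficient set for one (structure, scale, metric)."""

    family_name: str
    config: TrajectoryConfig
    knots: np.ndarray
    coefs: dict[str, np.ndarray]  # spline coefficients per parameter
    site_offsets: dict[str, dict[str, float]]  # param -> site -> offset
    sex_offsets: dict[str, float]  # param -> coefficient on the +-0.5 code
    sites: list[str]
    sex_props: dict[str, float]
    deviance_path: list[float] = field(default_factory=list)
    converged: bool = True
    metric_id: str = ""

    @property
    def family(self):
        return FAMILIES[self.family_name]

    # -- linear predictors -------------------------------------------------
    def _spline_eta(self, param: str, ages: np.ndarray) -> np.ndarray:
        lo, hi = self.config.age_range
        B, _ = bspline_design(ages, lo, hi, self.config.n_bases, self.config.degree)
        return B @ self.coefs[param]

    def _eta(self, param: str, ages, sex=None, site=None) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        eta = self._spline_eta(param, ages)
        if param in self.sex_offsets and sex is not None:
            code = np.where(np.asarray(sex) == "m", 0.5, -0.5)
            eta = eta + self.sex_offsets[param] * code
        if site is not None and param in self.site_offsets:
            offs = self.site_offsets[param]
            site_arr = np.broadcast_to(np.asarray(site), ages.shape)
            eta = eta + np.array([offs.get(s, 0.0) for s in site_arr])
        return eta

    def parameter_values(self, ages, sex=None, site=None) -> dict[str, np.ndarray]:
        """Distribution parameters at given covariates.

        ``sex=None`` marginalizes by averaging the two sex-specific
        parameter sets with the training-cohort proportions; ``site=None``
        uses zero site offsets (the harmonized population).
        """
        out = {}
        for p in PARAMS:
            if p not in self.coefs:
                continue
            if sex is None:
                em = self._eta(p, ages, sex="m", site=site)
                ef = self._eta(p, ages, sex="f", site=site)
                pm = self.sex_props.get("m", 0.5)
                val = pm * apply_link(self.family.links[p], em) + (1 - pm) * apply_link(
                    self.family.links[p], ef
                )
            else:
                val = apply_link(self.family.links[p], self._eta(p, ages, sex=sex, site=site))
            out[p] = val
        for p in PARAMS:
            out.setdefault(p, np.zeros_like(np.atleast_1d(np.asarray(ages, float))))
        return out

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        d = {
            "family": self.family_name,
            "metric_id": self.metric_id,
            "age_range": list(self.config.age_range),
            "n_bases": self.config.n_bases,
            "degree": self.config.degree,
            "transform": self.config.transform,
            "knots": self.knots.tolist(),
            "coefs": {p: c.tolist() for p, c in self.coefs.items()},
            "site_offsets": self.site_offsets,
            "sex_offsets": self.sex_offsets,
            "sites": self.sites,
            "sex_props": self.sex_props,
            "converged": self.converged,
            "deviance_path": self.deviance_path,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NormativeModel":
        d = json.loads(text)
        cfg = TrajectoryConfig(
            family=d["family"],
            n_bases=d["n_bases"],
            degree=d["degree"],
            age_range=tuple(d["age_range"]),
            transform=d["transform"],
        )
        return cls(
            family_name=d["family"],
            config=cfg,
            knots=np.asarray(d["knots"]),
            coefs={p: np.asarray(c) for p, c in d["coefs"].items()},
            site_offsets=d["site_offsets"],
            sex_offsets=d["sex_offsets"],
            sites=d["sites"],
            sex_props=d["sex_props"],
            converged=d["converged"],
            deviance_path=d["deviance_path"],
            metric_id=d["metric_id"],
        )


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def _design(param, ages, sex_code, site_onehot, sites, config):
    """Design matrix and penalty for one distribution parameter."""
    lo, hi = config.age_range
    B, knots = bspline_design(ages, lo, hi, config.n_bases, config.degree)
    blocks = [B]
    pen_diag = []
    lam = config.smoothing.get(param, 100.0)
    P_spl = (lam if lam is not None else 1.0) * difference_penalty(
        config.n_bases, config.penalty_order
    )
    if param in config.site_on:
        blocks.append(site_onehot)
        pen_diag.append(config.ridge * np.eye(site_onehot.shape[1]))
    if param in config.sex_on:
        blocks.append(sex_code[:, None])
        pen_diag.append(config.ridge * np.eye(1))
    X = np.hstack(blocks)
    P = np.zeros((X.shape[1], X.shape[1]))
    P[: config.n_bases, : config.n_bases] = P_spl
    ofs = config.n_bases
    for blk in pen_diag:
        k = blk.shape[0]
        P[ofs : ofs + k, ofs : ofs + k] = blk
        ofs += k
    return X, P, knots


def _loglik_eta(family, y, etas):
    vals = {p: apply_link(family.links[p], etas[p]) for p in PARAMS}
    with np.errstate(over="ignore", invalid="ignore"):
        ll = family.loglik(y, vals["mu"], vals["sigma"], vals["nu"], vals["tau"])
    return np.where(np.isfinite(ll), ll, -1e10)


def _fit_once(y, ages, sex_code, site_onehot, sites, config):
    family = FAMILIES[config.family]
    active = list(family.params)
    X, P, knots, beta, etas = {}, {}, None, {}, {}
    start = family.default_eta(y)
    for p in active:
        X[p], P[p], knots = _design(p, ages, sex_code, site_onehot, sites, config)
        beta[p] = np.zeros(X[p].shape[1])
        # start the spline block flat at the family's moment-matched value
        beta[p][: config.n_bases] = start.get(p, 0.0)
        etas[p] = X[p] @ beta[p]
    for p in PARAMS:
        if p not in active:
            etas[p] = np.full(len(y), {"nu": 1.0, "tau": np.log(2.0)}[p] if p in ("nu", "tau") else 0.0)

    def pen_dev(etas_now, beta_now):
        ll = _loglik_eta(family, y, etas_now).sum()
        pen = sum(beta_now[p] @ P[p] @ beta_now[p] for p in active)
        return -2.0 * ll + pen

    dev = pen_dev(etas, beta)
    path = [dev]
    converged = False
    for _ in range(config.max_iter):
        for p in active:
            eta0 = etas[p]
            h = 1e-4 * np.maximum(1.0, np.abs(eta0))
            lp = _loglik_eta(family, y, {**etas, p: eta0 + h})
            lm = _loglik_eta(family, y, {**etas, p: eta0 - h})
            l0 = _loglik_eta(family, y, etas)
            u = (lp - lm) / (2.0 * h)
            w = -(lp - 2.0 * l0 + lm) / h**2
            bad = ~(w > 1e-8)
            w = np.where(bad, np.maximum(u * u, 1e-8), w)
            z = eta0 + u / w
            A = X[p].T @ (w[:, None] * X[p]) + P[p]
            b = X[p].T @ (w * z)
            try:
                beta_new = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
            # step-halving on the penalized deviance
            step = 1.0
            for _half in range(12):
                trial_beta = {**beta, p: beta[p] + step * (beta_new - beta[p])}
                trial_etas = {**etas, p: X[p] @ trial_beta[p]}
                if pen_dev(trial_etas, trial_beta) <= dev + 1e-9:
                    beta, etas = trial_beta, trial_etas
                    dev = pen_dev(etas, beta)
                    break
                step *= 0.5
        path.append(dev)
        if abs(path[-2] - path[-1]) < config.tol:
            converged = True
            break
    return family, X, P, knots, beta, etas, path, converged


def fit_normative_model(
    table: pd.DataFrame,
    value_col: str,
    config: TrajectoryConfig | None = None,
    metric_id: str | None = None,
) -> NormativeModel:
    """Fit a normative location-scale-shape model of ``value_col`` vs age.

    ``table`` needs columns ``age``, ``sex`` ('m'/'f'), ``site`` and the
    metric column.  Deterministic given data and config.
    """
    if config is None:
        config = TrajectoryConfig()
    df = table.dropna(subset=["age", "sex", "site", value_col])
    if len(df) < 50:
        raise ValueError(f"need >= 50 observations, got {len(df)}")
    y = df[value_col].to_numpy(dtype=float)
    if config.transform == "log10":
        if np.any(y <= 0):
            raise ValueError("log10 transform requested but values are not all positive")
        y = np.log10(y)
    elif config.transform != "none":
        raise ValueError(f"unknown transform {config.transform!r}")
    if config.family == "bcpe" and np.any(y <= 0):
        raise ValueError("bcpe family requires positive (transformed) values")
    ages = df["age"].to_numpy(dtype=float)
    sex_code = np.where(df["sex"].to_numpy() == "m", 0.5, -0.5)
    sites = sorted(df["site"].unique().tolist())
    site_onehot = np.column_stack(
        [(df["site"].to_numpy() == s).astype(float) for s in sites]
    )

    smoothings = [config.smoothing.get("mu")]
    if smoothings[0] is None:  # GAIC grid over the mu smoothing parameter
        gaic_k = config.gaic_k if config.gaic_k is not None else float(np.log(len(y)))
        best = None
        for lam in config.gaic_grid:
            cfg = TrajectoryConfig(**{**config.__dict__})
            cfg.smoothing = {**config.smoothing, "mu": lam}
            fam, X, P, knots, beta, etas, path, conv = _fit_once(
                y, ages, sex_code, site_onehot, sites, cfg
            )
            W = np.ones(len(y))
            A = X["mu"].T @ (W[:, None] * X["mu"]) + P["mu"]
            edf = float(np.trace(np.linalg.solve(A, X["mu"].T @ (W[:, None] * X["mu"]))))
            ll = _loglik_eta(fam, y, etas).sum()
            gaic = -2 * ll + gaic_k * edf
            if best is None or gaic < best[0]:
                best = (gaic, lam)
        config = TrajectoryConfig(**{**config.__dict__})
        config.smoothing = {**config.smoothing, "mu": best[1]}

    family, X, P, knots, beta, etas, path, converged = _fit_once(
        y, ages, sex_code, site_onehot, sites, config
    )
    if not converged:
        warnings.warn(
            f"normative fit for {metric_id or value_col} did not converge "
            f"in {config.max_iter} iterations (deviance path recorded)",
            ConvergenceWarning,
        )

    def unpack(p):
        spl = beta[p][: config.n_bases]
        ofs = config.n_bases
        site_off = {}
        if p in config.site_on:
            for i, s in enumerate(sites):
                site_off[s] = float(beta[p][ofs + i])
            ofs += len(sites)
        sex_off = float(beta[p][ofs]) if p in config.sex_on else None
        return spl, site_off, sex_off

    coefs, site_offsets, sex_offsets = {}, {}, {}
    for p in family.params:
        spl, site_off, sex_off = unpack(p)
        coefs[p] = spl
        if site_off:
            site_offsets[p] = site_off
        if sex_off is not None:
            sex_offsets[p] = sex_off
    pm = float((df["sex"] == "m").mean())
    model = NormativeModel(
        family_name=config.family,
        config=config,
        knots=knots,
        coefs=coefs,
        site_offsets=site_offsets,
        sex_offsets=sex_offsets,
        sites=sites,
        sex_props={"m": pm, "f": 1.0 - pm},
        deviance_path=[float(v) for v in path],
        converged=converged,
        metric_id=metric_id or value_col,
    )
    # sanity: sigma must be positive across the fitted age range
    grid = np.linspace(*config.age_range, 50)
    if np.any(model.parameter_values(grid)["sigma"] <= 0):
        raise RuntimeError("fitted sigma non-positive on the age range")
    return model


# ----------------------------------------------------------------------
# prediction and scoring
# ----------------------------------------------------------------------

@dataclass
class TrajectoryBand:
    ages: np.ndarray
    center: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def predict_quantiles(model: NormativeModel, ages, q: float) -> np.ndarray:
    """Population quantile curve (sexes marginalized, site offsets zero)."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    lo, hi = model.config.age_range
    if ages.min() < lo - 1e-9 or ages.max() > hi + 1e-9:
        warnings.warn("ages outside the fitted range: extrapolating", UserWarning)
    pv = model.parameter_values(ages)
    return model.family.ppf(q, pv["mu"], pv["sigma"], pv["nu"], pv["tau"])


def trajectory_band(
    model: NormativeModel, ages, q_low: float = 0.25, q_high: float = 0.75
) -> TrajectoryBand:
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    return TrajectoryBand(
        ages=ages,
        center=predict_quantiles(model, ages, 0.5),
        lower=predict_quantiles(model, ages, q_low),
        upper=predict_quantiles(model, ages, q_high),
    )


def deviation_score(model: NormativeModel, rows: pd.DataFrame, value_col: str) -> np.ndarray:
    """Quantile-residual z-score ``Phi^{-1}(F(y))`` per subject row."""
    ages = rows["age"].to_numpy(dtype=float)
    y = rows[value_col].to_numpy(dtype=float)
    if model.config.transform == "log10":
        y = np.log10(y)
    unseen = ~rows["site"].isin(model.sites)
    if unseen.any():
        warnings.warn(
            f"{int(unseen.sum())} rows from sites unseen in training: "
            "scored with zero site offset",
            UserWarning,
        )
    out = np.empty(len(rows))
    for sex in ("m", "f"):
        sel = (rows["sex"] == sex).to_numpy()
        if not sel.any():
            continue
        pv = model.parameter_values(
            ages[sel], sex=sex, site=rows["site"].to_numpy()[sel]
        )
        F = model.family.cdf(y[sel], pv["mu"], pv["sigma"], pv["nu"], pv["tau"])
        out[sel] = norm.ppf(np.clip(F, 1e-12, 1 - 1e-12))
    return out


def estimated_site_contrast(
    model: NormativeModel, site_a: str, site_b: str, ages=None
) -> float:
    """Mean difference of fitted location between two sites (response scale)."""
    if ages is None:
        ages = np.linspace(*model.config.age_range, 100)
    mu_a = model.parameter_values(ages, site=site_a)["mu"]
    mu_b = model.parameter_values(ages, site=site_b)["mu"]
    return float(np.mean(mu_a - mu_b))
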