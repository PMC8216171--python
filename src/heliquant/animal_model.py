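"""REML animal models for variance-component estimation.

The core model for an n-vector of phenotypes y is

    y = X b + sum_k u_k + e,     u_k ~ N(0, sigma2_k * K_k),   e ~ N(0, sigma2_R * I)

where each K_k is a known n x n covariance structure: the additive
relationship matrix A for the individual genetic effect ("animal"),
or an incidence-based block structure for maternal identity or brood.
Variance components are estimated by maximizing the restricted
log-likelihood; standard errors come from the observed information of
that criterion.

Model 1 of the toxicity analysis is ``random_effects=("animal",)`` with
fixed effects of sex and larval feeding treatment; Model 2 adds
``"maternal_identity"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "AnimalModelFit",
    "fit_animal_model",
    "restricted_loglik",
    "lrt_variance_component",
    "fixed_effect_variance",
    "boundary_lrt_pvalue",
]

_RANDOM_NAMES = ("animal", "maternal_identity", "brood")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one animal-model fit."""

    trait: str = "total"
    fixed_effects: tuple = ("sex", "treatment")
    random_effects: tuple = ("animal",)
    constrain_nonnegative: bool = True

    def __post_init__(self):
        object.__setattr__(self, "fixed_effects", tuple(self.fixed_effects))
        object.__setattr__(self, "random_effects", tuple(self.random_effects))
        for r in self.random_effects:
            if r not in _RANDOM_NAMES:
                raise ValueError(f"unknown random effect {r!r}")
        for f in self.fixed_effects:
            if f not in ("sex", "treatment"):
                raise ValueError(f"unknown fixed effect {f!r}")


@dataclass
class VarianceComponents:
    """Variance decomposition for one trait, on the squared trait scale.

    ``V_sex`` and ``V_trm`` are fixed-effect variances (variance across
    observations of the fitted sex / treatment contributions); the rest
    are REML variance components.  ``V_P`` is their sum.
    """

    V_G: float = 0.0
    V_mat: float = 0.0
    V_sex: float = 0.0
    V_trm: float = 0.0
    V_R: float = 0.0
    V_brood: float = 0.0

    @property
    def V_P(self) -> float:
        return self.V_G + self.V_mat + self.V_sex + self.V_trm + self.V_R + self.V_brood

    def as_dict(self) -> dict:
        return {
            "V_G": self.V_G,
            "V_mat": self.V_mat,
            "V_sex": self.V_sex,
            "V_trm": self.V_trm,
            "V_R": self.V_R,
            "V_brood": self.V_brood,
            "V_P": self.V_P,
        }


@dataclass
class AnimalModelFit:
    spec: ModelSpec
    components: VarianceComponents
    component_SEs: dict
    random_variances: dict
    fixed_coefficients: pd.DataFrame
    restricted_loglik: float
    converged: bool
    degenerate: bool
    n_obs: int
    n_broods: int
    _X: np.ndarray = field(repr=False, default=None)
    _col_effects: list = field(repr=False, default=None)
    _beta: np.ndarray = field(repr=False, default=None)

    def report(self) -> dict:
        """Plain-dict fit report (JSON-serializable)."""
        vp = self.components.V_P
        comp = self.components.as_dict()
        return {
            "trait": self.spec.trait,
            "fixed_effects": list(self.spec.fixed_effects),
            "random_effects": list(self.spec.random_effects),
            "n_obs": self.n_obs,
            "n_broods": self.n_broods,
            "converged": bool(self.converged),
            "degenerate": bool(self.degenerate),
            "restricted_loglik": self.restricted_loglik,
            "components": comp,
            "component_SEs": dict(self.component_SEs),
            "ratios_to_V_P": {
                k: (v / vp if vp > 0 else float("nan"))
                for k, v in comp.items()
                if k not in ("V_P",)
            },
            "fixed_coefficients": self.fixed_coefficients.to_dict("records"),
        }


# ---------------------------------------------------------------------------
# design construction


def _fixed_design(phenos: pd.DataFrame, fixed_effects: Sequence[str]):
    n = len(phenos)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    effects = ["intercept"]
    for eff in fixed_effects:
        if eff not in phenos.columns:
            raise ValueError(f"fixed effect {eff!r} not a phenotype column")
        levels = phenos[eff].fillna("std").astype(str)
        uniq = sorted(levels.unique())
        for lev in uniq[1:]:  # first level is the reference
            cols.append((levels == lev).to_numpy(float))
            names.append(f"{eff}[{lev}]")
            effects.append(eff)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is singular after dropping empty levels")
    return X, names, effects


def _incidence_K(labels: pd.Series) -> np.ndarray:
    """K = Z Z' for a grouping factor; rows with missing labels each get
    a private level (block of size one)."""
    lab = labels.astype(object).where(labels.notna(), None).tolist()
    keys = []
    priv = 0
    for v in lab:
        if v is None:
            keys.append(("__private__", priv))
            priv += 1
        else:
            keys.append(("lvl", str(v)))
    arr = pd.factorize(pd.Series(keys))[0]
    return (arr[:, None] == arr[None, :]).astype(float)


def _random_structures(
    phenos: pd.DataFrame, A: RelationshipMatrix | None, random_effects: Sequence[str]
):
    Ks = []
    for name in random_effects:
        if name == "animal":
            if A is None:
                raise ValueError("'animal' random effect requires a RelationshipMatrix")
            missing = [i for i in phenos["id"] if i not in A._index]
            if missing:
                raise ValueError(
                    f"{len(missing)} phenotyped individuals missing from A, e.g. {missing[:3]}"
                )
            Ks.append((name, A.submatrix(list(phenos["id"]))))
        elif name == "maternal_identity":
            if "dam" not in phenos.columns:
                raise ValueError("'maternal_identity' requires a dam column")
            Ks.append((name, _incidence_K(phenos["dam"])))
        elif name == "brood":
            if "brood" not in phenos.columns:
                raise ValueError("'brood' requires a brood column")
            Ks.append((name, _incidence_K(phenos["brood"])))
    return Ks


# ---------------------------------------------------------------------------
# REML criterion


def _reml_loglik_core(y, X, Kmats, variances) -> float:
    """Restricted log-likelihood (with constants) at the given components.

    ``variances`` lists one variance per K followed by the residual.
    """
    n, p = X.shape
    V = variances[-1] * np.eye(n)
    for v, K in zip(variances[:-1], Kmats):
        V += v * K
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    XtViX = X.T @ Vi_X
    sign, logdetXVX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    return -0.5 * (logdetV + logdetXVX + yPy + (n - p) * np.log(2.0 * np.pi))


def restricted_loglik(
    phenos: pd.DataFrame,
    A: RelationshipMatrix | None,
    spec: ModelSpec,
    components: Mapping[str, float],
) -> float:
    """Evaluate the REML criterion at given variance components.

    ``components`` maps each name in ``spec.random_effects`` plus
    ``"residual"`` to a nonnegative variance.
    """
    y = phenos[spec.trait].to_numpy(float)
    X, _, _ = _fixed_design(phenos, spec.fixed_effects)
    Ks = _random_structures(phenos, A, spec.random_effects)
    variances = [float(components[name]) for name, _ in Ks]
    variances.append(float(components["residual"]))
    if any(v < 0 for v in variances):
        raise ValueError("variance components must be nonnegative")
    return _reml_loglik_core(y, X, [K for _, K in Ks], np.asarray(variances))


# ---------------------------------------------------------------------------
# fitting


def _optimize_single_K(y, X, K):
    """Fast path for one structured component plus residual: rotate into
    the eigenbasis of K, where V is diagonal, and profile the REML
    criterion down to a 1-D search in the variance ratio."""
    n, p = X.shape
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def crit(gamma):
        w = 1.0 / (1.0 + gamma * d)
        XtWiX = Xt.T @ (Xt * w[:, None])
        XtWiy = Xt.T @ (w * yt)
        sign, logdetXWX = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return -np.inf, None, None
        beta = np.linalg.solve(XtWiX, XtWiy)
        rss = float(yt @ (w * yt) - XtWiy @ beta)
        if rss <= 0:
            return -np.inf, None, None
        s2e = rss / (n - p)
        ll = -0.5 * (
            -float(np.sum(np.log(w)))
            + (n - p) * (np.log(s2e) + 1.0 + np.log(2.0 * np.pi))
            + logdetXWX
        )
        return ll, beta, s2e

    res = optimize.minimize_scalar(
        lambda lg: -crit(np.exp(lg))[0], bounds=(-18.0, 18.0), method="bounded",
        options={"xatol": 1e-12},
    )
    gamma = float(np.exp(res.x))
    ll, _, s2e = crit(gamma)
    ll0, _, s2e0 = crit(0.0)
    if ll0 >= ll:
        return np.array([0.0, s2e0]), ll0, True
    return np.array([gamma * s2e, s2e]), ll, True


def _profiled_crit(gammas, y, X, Kmats):
    """REML criterion with the residual variance profiled out; ``gammas``
    are the component-to-residual variance ratios."""
    n, p = X.shape
    W = np.eye(n)
    for g, K in zip(gammas, Kmats):
        W += g * K
    try:
        L = np.linalg.cholesky(W)
    except np.linalg.LinAlgError:
        return -np.inf, None
    logdetW = 2.0 * np.sum(np.log(np.diag(L)))
    Wi_X = np.linalg.solve(W, X)
    Wi_y = np.linalg.solve(W, y)
    XtWiX = X.T @ Wi_X
    sign, logdetXWX = np.linalg.slogdet(XtWiX)
    if sign <= 0:
        return -np.inf, None
    beta = np.linalg.solve(XtWiX, X.T @ Wi_y)
    rss = float(y @ Wi_y - (X.T @ Wi_y) @ beta)
    if rss <= 0:
        return -np.inf, None
    s2e = rss / (n - p)
    ll = -0.5 * (
        logdetW + (n - p) * (np.log(s2e) + 1.0 + np.log(2.0 * np.pi)) + logdetXWX
    )
    return ll, s2e


def _optimize_reml(y, X, Kmats, vy):
    """Maximize the REML criterion over variance ratios (residual scale
    profiled out) with restarts and boundary (component = 0) candidates.
    Returns (variances, loglik, ok)."""
    if len(Kmats) == 1:
        return _optimize_single_K(y, X, Kmats[0])
    m = len(Kmats) + 1
    nk = m - 1
    lo, hi = -18.0, 18.0

    def neg(theta):
        return -_profiled_crit(np.exp(np.clip(theta, lo, hi)), y, X, Kmats)[0]

    starts = [
        np.full(nk, np.log(0.3 / nk)),
        np.full(nk, np.log(2.0)),
        np.full(nk, np.log(0.02)),
    ]

    best_v, best_ll, ok = None, -np.inf, False
    for s in starts:
        res = optimize.minimize(
            neg, s, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 2000},
        )
        gam = np.exp(np.clip(res.x, lo, hi))
        ll, s2e = _profiled_crit(gam, y, X, Kmats)
        if ll > best_ll and s2e is not None:
            best_v = np.append(gam * s2e, s2e)
            best_ll, ok = ll, bool(res.success)

    # boundary candidates: force each non-residual component to zero
    snap = 1e-6 * vy
    for k in range(m - 1):
        if best_v[k] > snap * 10:
            continue
        sub = [K for j, K in enumerate(Kmats) if j != k]
        if sub:
            v_sub, ll_sub, _ = _optimize_reml(y, X, sub, vy)
            cand = np.insert(v_sub, k, 0.0)
        else:
            # residual-only REML has a closed form
            p = X.shape[1]
            r = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            cand = np.array([0.0, float(r @ r) / (len(y) - p)])
        ll_cand = _reml_loglik_core(y, X, Kmats, np.maximum(cand, 0.0))
        if ll_cand >= best_ll - 1e-9:
            best_v = np.maximum(cand, 0.0)
            best_ll = ll_cand
            ok = True
    best_v = np.where(best_v < snap, 0.0, best_v)
    best_ll = _reml_loglik_core(y, X, Kmats, best_v)
    return best_v, best_ll, ok


def _component_ses(y, X, Kmats, v_hat, vy):
    """Asymptotic SEs from the observed information (numerical Hessian of
    the REML criterion on the variance scale); NaN at the boundary."""
    m = len(v_hat)
    H = np.full((m, m), np.nan)
    h = np.maximum(1e-4 * np.abs(v_hat), 1e-7 * vy)

    def ll(v):
        if np.any(v < 0):
            return np.nan
        return _reml_loglik_core(y, X, Kmats, v)

    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            fpp = ll(v_hat + ei + ej)
            fpm = ll(v_hat + ei - ej)
            fmp = ll(v_hat - ei + ej)
            fmm = ll(v_hat - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    ses = np.full(m, np.nan)
    try:
        cov = np.linalg.inv(-H)
        d = np.diag(cov)
        ses = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
    except np.linalg.LinAlgError:
        pass
    ses[v_hat == 0.0] = np.nan
    return ses


def fit_animal_model(
    phenos: pd.DataFrame,
    A: RelationshipMatrix | None,
    spec: ModelSpec,
) -> AnimalModelFit:
    """Fit a mixed model by REML and assemble the variance decomposition.

    Parameters
    ----------
    phenos : DataFrame
        One row per phenotyped individual; must contain ``id``, the trait
        column named by ``spec.trait``, and whatever columns the fixed
        and random effects in ``spec`` require (``sex``, ``treatment``,
        ``dam``, ``brood``).
    A : RelationshipMatrix or None
        Required when ``"animal"`` is among the random effects.
    spec : ModelSpec
    """
    phenos = phenos.reset_index(drop=True)
    y = phenos[spec.trait].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise ValueError("trait column contains non-finite values")
    n = len(y)
    n_broods = phenos["brood"].nunique() if "brood" in phenos.columns else 0

    X, names, effects = _fixed_design(phenos, spec.fixed_effects)
    Ks = _random_structures(phenos, A, spec.random_effects)
    Kmats = [K for _, K in Ks]
    vy = float(np.var(y, ddof=1)) if n > 1 else 0.0

    if vy <= 0.0:
        comp = VarianceComponents()
        coef = pd.DataFrame(
            {"term": names, "effect": effects,
             "estimate": [float(np.mean(y))] + [0.0] * (len(names) - 1),
             "SE": [np.nan] * len(names)}
        )
        return AnimalModelFit(
            spec=spec, components=comp,
            component_SEs={nm: np.nan for nm, _ in Ks} | {"residual": np.nan},
            random_variances={nm: 0.0 for nm, _ in Ks} | {"residual": 0.0},
            fixed_coefficients=coef, restricted_loglik=np.nan,
            converged=True, degenerate=True, n_obs=n, n_broods=n_broods,
            _X=X, _col_effects=effects, _beta=np.zeros(X.shape[1]),
        )

    v_hat, ll, ok = _optimize_reml(y, X, Kmats, vy)
    ses = _component_ses(y, X, Kmats, v_hat, vy)

    # GLS fixed-effect solutions at the REML estimates
    V = v_hat[-1] * np.eye(n)
    for v, K in zip(v_hat[:-1], Kmats):
        V += v * K
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, Vi_X.T @ y)
    beta_cov = np.linalg.inv(XtViX)
    coef = pd.DataFrame(
        {"term": names, "effect": effects, "estimate": beta,
         "SE": np.sqrt(np.diag(beta_cov))}
    )

    rand = {nm: float(v) for (nm, _), v in zip(Ks, v_hat[:-1])}
    rand["residual"] = float(v_hat[-1])
    se_map = {nm: float(s) for (nm, _), s in zip(Ks, ses[:-1])}
    se_map["residual"] = float(ses[-1])

    fit = AnimalModelFit(
        spec=spec,
        components=VarianceComponents(),  # filled below
        component_SEs=se_map,
        random_variances=rand,
        fixed_coefficients=coef,
        restricted_loglik=float(ll),
        converged=ok,
        degenerate=False,
        n_obs=n,
        n_broods=n_broods,
        _X=X,
        _col_effects=effects,
        _beta=beta,
    )
    fit.components = VarianceComponents(
        V_G=rand.get("animal", 0.0),
        V_mat=rand.get("maternal_identity", 0.0),
        V_brood=rand.get("brood", 0.0),
        V_sex=fixed_effect_variance(fit, "sex") if "sex" in spec.fixed_effects else 0.0,
        V_trm=fixed_effect_variance(fit, "treatment")
        if "treatment" in spec.fixed_effects
        else 0.0,
        V_R=rand["residual"],
    )
    return fit


def fixed_effect_variance(fit: AnimalModelFit, effect: str) -> float:
    """Variance across observations of the fitted contribution of one
    fixed effect (the linear predictor restricted to that effect's
    columns), the standard way of expressing a fixed effect on the
    variance-component scale."""
    if effect not in fit._col_effects:
        raise ValueError(f"effect {effect!r} not in the fitted design")
    mask = np.array([e == effect for e in fit._col_effects])
    contrib = fit._X[:, mask] @ fit._beta[mask]
    return float(np.var(contrib))  # population variance over observations


def boundary_lrt_pvalue(delta_loglik: float) -> float:
    """P-value for dropping one variance component, using the 50:50
    mixture of a point mass at zero and chi-square(1) appropriate for a
    null on the boundary of the parameter space."""
    stat = max(2.0 * delta_loglik, 0.0)
    return float(0.5 * stats.chi2.sf(stat, df=1))


def lrt_variance_component(full: AnimalModelFit, reduced: AnimalModelFit) -> float:
    """Boundary-corrected likelihood-ratio test between two REML fits that
    differ by exactly one random effect (same trait and fixed effects)."""
    if full.spec.trait != reduced.spec.trait or set(full.spec.fixed_effects) != set(
        reduced.spec.fixed_effects
    ):
        raise ValueError("models must share trait and fixed effects for a REML LRT")
    extra = set(full.spec.random_effects) - set(reduced.spec.random_effects)
    if len(extra) != 1 or not set(reduced.spec.random_effects) <= set(
        full.spec.random_effects
    ):
        raise ValueError("reduced model must be nested with one fewer random effect")
    return boundary_lrt_pvalue(full.restricted_loglik - reduced.restricted_loglik)
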