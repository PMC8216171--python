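"""Derived quantitative-genetic metrics.

Heritability and evolvability summarize the variance decomposition of
the animal model; repeatability (the intra-class correlation among
full-sib broods) and the parent-offspring regressions provide
complementary, model-light views of the same among-brood variance; the
maternal-effect coefficient m = beta_mo - beta_fo follows Falconer's
dilution model, in which an offspring phenotype depends linearly on the
maternal phenotype beyond transmitted genes; and the response
projections translate a per-generation evolvability (and optionally m)
into multi-generation change in the trait mean.

Random-intercept models (one grouping factor, a small fixed design) are
fitted by a dedicated profiled REML that exploits the block-diagonal
covariance, making the 1000-replicate parametric bootstraps cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .animal_model import VarianceComponents, boundary_lrt_pvalue

__all__ = [
    "EvolvabilityReport",
    "RepeatabilityEstimate",
    "RegressionEstimate",
    "MaternalEffectEstimate",
    "ResponseProjection",
    "broad_sense_heritability",
    "mean_scaled_evolvability",
    "evolvability_report",
    "estimate_repeatability",
    "parent_offspring_regression",
    "maternal_effect_coefficient",
    "estimate_maternal_effect",
    "project_compound_response",
    "falconer_response_trajectory",
]


# ---------------------------------------------------------------------------
# heritability and evolvability


def broad_sense_heritability(
    components: VarianceComponents, denominator: str = "text-convention"
) -> float:
    """Broad-sense heritability H2 = V_G / V_P.

    ``denominator="text-convention"`` (default) includes the sex variance
    in V_P but excludes the treatment variance, on the grounds that an
    experimentally imposed diet contrast does not represent natural
    phenotypic variance.  ``denominator="full"`` uses the sum of all
    components.
    """
    if denominator == "text-convention":
        vp = (
            components.V_G
            + components.V_mat
            + components.V_sex
            + components.V_R
            + components.V_brood
        )
    elif denominator == "full":
        vp = components.V_P
    else:
        raise ValueError("denominator must be 'text-convention' or 'full'")
    if vp <= 0:
        raise ZeroDivisionError("total phenotypic variance is zero")
    return components.V_G / vp


def mean_scaled_evolvability(V_G: float, mu: float) -> float:
    """Mean-scaled evolvability e_mu = 100 * V_G / mu**2, in percent.

    This is the expected percent change in the trait mean per generation
    under unit-strength selection (selection on the trait as strong as
    selection on fitness itself).
    """
    if mu <= 0:
        raise ValueError("trait mean must be positive for mean-scaling")
    if V_G < 0:
        raise ValueError("V_G must be nonnegative")
    return 100.0 * V_G / mu**2


@dataclass
class EvolvabilityReport:
    mu: float
    V_G: float
    H2: float
    e_mu: float
    H2_SE: float = float("nan")
    e_mu_SE: float = float("nan")


def evolvability_report(
    components: VarianceComponents,
    mu: float,
    V_G_SE: float = float("nan"),
    denominator: str = "text-convention",
) -> EvolvabilityReport:
    """Bundle H2 and e_mu for one trait; delta-method SEs from the SE of
    V_G, holding the other components and the mean fixed."""
    h2 = broad_sense_heritability(components, denominator=denominator)
    emu = mean_scaled_evolvability(components.V_G, mu)
    vp = components.V_G / h2 if h2 > 0 else components.V_P
    h2_se = float("nan")
    emu_se = float("nan")
    if np.isfinite(V_G_SE):
        # d(V_G/(V_G+rest))/dV_G = rest / vp^2
        rest = vp - components.V_G
        h2_se = abs(rest) / vp**2 * V_G_SE
        emu_se = 100.0 / mu**2 * V_G_SE
    return EvolvabilityReport(mu=mu, V_G=components.V_G, H2=h2, e_mu=emu,
                              H2_SE=h2_se, e_mu_SE=emu_se)


# ---------------------------------------------------------------------------
# fast random-intercept REML
#
# y = X b + Z u + e with u one intercept per group.  With gamma =
# sigma2_u / sigma2_e, each group's covariance block is
# sigma2_e (I + gamma J), whose inverse and determinant are closed-form,
# so the restricted likelihood profiles down to a 1-D search in gamma.


@dataclass
class _RIFit:
    beta: np.ndarray
    beta_se: np.ndarray
    sigma2_group: float
    sigma2_resid: float
    loglik: float          # restricted log-likelihood, with constants
    loglik_null: float     # same criterion at sigma2_group = 0
    n: int
    p: int
    n_groups: int
    group_labels: np.ndarray
    group_means_blup: np.ndarray


def _ri_profile(y, X, groups):
    """Precompute per-group sufficient statistics."""
    labels, inv = np.unique(groups, return_inverse=True)
    q = len(labels)
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    S = np.zeros((q, p))   # per-group column sums of X
    t = np.zeros(q)        # per-group sums of y
    nj = np.zeros(q)
    np.add.at(S, inv, X)
    np.add.at(t, inv, y)
    np.add.at(nj, inv, 1.0)
    return labels, inv, q, n, p, XtX, Xty, yty, S, t, nj


def _ri_criterion(gamma, n, p, XtX, Xty, yty, S, t, nj):
    """Profiled restricted log-likelihood at variance ratio gamma >= 0."""
    c = gamma / (1.0 + nj * gamma)                     # per-group shrinkage
    XtWiX = XtX - (S * c[:, None]).T @ S
    XtWiy = Xty - S.T @ (c * t)
    ytWiy = yty - float(c @ t**2)
    sign, logdetXWX = np.linalg.slogdet(XtWiX)
    if sign <= 0:
        return -np.inf, None, None, None
    beta = np.linalg.solve(XtWiX, XtWiy)
    rss = ytWiy - float(XtWiy @ beta)
    # exact-fit data (rss == 0 up to roundoff) gets a tiny floor so the
    # criterion stays finite and the slope is still reported
    rss = max(rss, 1e-12 * max(yty, 1.0))
    s2e = rss / (n - p)
    ll = -0.5 * (
        float(np.sum(np.log1p(nj * gamma)))
        + (n - p) * (np.log(s2e) + 1.0 + np.log(2.0 * np.pi))
        + logdetXWX
    )
    return ll, beta, s2e, XtWiX


def _fit_random_intercept(y, X, groups) -> _RIFit:
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    labels, inv, q, n, p, XtX, Xty, yty, S, t, nj = _ri_profile(y, X, groups)

    def neg(log_gamma):
        ll, *_ = _ri_criterion(np.exp(log_gamma), n, p, XtX, Xty, yty, S, t, nj)
        return -ll

    res = optimize.minimize_scalar(neg, bounds=(-16.0, 16.0), method="bounded",
                                   options={"xatol": 1e-10})
    gamma = float(np.exp(res.x))
    ll, beta, s2e, XtWiX = _ri_criterion(gamma, n, p, XtX, Xty, yty, S, t, nj)
    ll0, beta0, s2e0, XtWiX0 = _ri_criterion(0.0, n, p, XtX, Xty, yty, S, t, nj)
    if ll0 >= ll:  # boundary solution
        gamma, ll, beta, s2e, XtWiX = 0.0, ll0, beta0, s2e0, XtWiX0
    beta_se = np.sqrt(np.diag(s2e * np.linalg.inv(XtWiX)))
    # BLUPs of the group effects, used by the parametric bootstrap
    resid_group = t - S @ beta
    blup = gamma * resid_group / (1.0 + nj * gamma)
    return _RIFit(
        beta=beta, beta_se=beta_se,
        sigma2_group=gamma * s2e, sigma2_resid=s2e,
        loglik=ll, loglik_null=ll0,
        n=n, p=p, n_groups=q, group_labels=labels, group_means_blup=blup,
    )


# ---------------------------------------------------------------------------
# repeatability (ICC among broods)


@dataclass
class RepeatabilityEstimate:
    R: float
    SE: float
    CI: tuple
    p: float
    n_boot: int
    seed: int
    sigma2_group: float
    sigma2_resid: float
    boot_values: np.ndarray = None


def estimate_repeatability(
    phenos: pd.DataFrame,
    trait: str = "total",
    group: str = "brood",
    n_boot: int = 1000,
    seed: int = 0,
) -> RepeatabilityEstimate:
    """Repeatability R = V_group / (V_group + V_resid) from a Gaussian
    random-intercept model with ``group`` as the grouping factor.

    Uncertainty comes from ``n_boot`` parametric bootstraps: new data are
    simulated from the fitted model (fresh group effects and residuals)
    and the model refitted to each; the SE is the bootstrap standard
    deviation and the CI the 2.5/97.5 percentile interval.  The p-value
    is a boundary-corrected likelihood-ratio test of V_group = 0.
    ``n_boot=0`` skips the bootstrap (point estimate and p-value only).
    """
    df = phenos.dropna(subset=[trait, group])
    counts = df.groupby(group).size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 groups with at least 2 members each")
    y = df[trait].to_numpy(float)
    g = df[group].to_numpy()
    X = np.ones((len(y), 1))
    fit = _fit_random_intercept(y, X, g)
    tot = fit.sigma2_group + fit.sigma2_resid
    R = fit.sigma2_group / tot if tot > 0 else 0.0
    p = boundary_lrt_pvalue(fit.loglik - fit.loglik_null)

    se, ci, boots = float("nan"), (float("nan"), float("nan")), None
    if n_boot:
        if n_boot < 2:
            raise ValueError("n_boot must be 0 or >= 2")
        rng = np.random.default_rng(seed)
        _, inv = np.unique(g, return_inverse=True)
        q = fit.n_groups
        mu = float(fit.beta[0])
        boots = np.empty(n_boot)
        for b in range(n_boot):
            u = rng.normal(0.0, np.sqrt(fit.sigma2_group), size=q)
            yb = mu + u[inv] + rng.normal(0.0, np.sqrt(fit.sigma2_resid), size=len(y))
            fb = _fit_random_intercept(yb, X, g)
            tb = fb.sigma2_group + fb.sigma2_resid
            boots[b] = fb.sigma2_group / tb if tb > 0 else 0.0
        se = float(np.std(boots, ddof=1))
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (float(max(lo, 0.0)), float(min(hi, 1.0)))
    return RepeatabilityEstimate(
        R=float(R), SE=se, CI=ci, p=float(p), n_boot=n_boot, seed=seed,
        sigma2_group=fit.sigma2_group, sigma2_resid=fit.sigma2_resid,
        boot_values=boots,
    )


# ---------------------------------------------------------------------------
# parent-offspring regressions and the maternal-effect coefficient


@dataclass
class RegressionEstimate:
    slope: float
    SE: float
    t: float
    p: float
    intercept: float
    n: int
    n_families: int
    parent: str


def _parent_offspring_frame(
    phenos: pd.DataFrame, trait: str, parent: str
) -> pd.DataFrame:
    """Offspring rows paired with the chosen parent's phenotype."""
    if parent not in ("mother", "father", "midparent"):
        raise ValueError("parent must be 'mother', 'father' or 'midparent'")
    ph = phenos.set_index("id")
    off = phenos[phenos["brood"].notna()].copy()
    off = off[off["dam"].notna()]  # offspring only (parents have no dam row here)

    def look(ids):
        return ids.map(lambda i: ph[trait].get(i) if pd.notna(i) else np.nan)

    mo = look(off["dam"])
    fo = look(off["sire"]) if "sire" in off.columns else pd.Series(np.nan, index=off.index)
    if parent == "mother":
        off["parent_value"] = mo
    elif parent == "father":
        off["parent_value"] = fo
    else:
        off["parent_value"] = (mo + fo) / 2.0
    out = off.dropna(subset=["parent_value", trait])
    return out


def parent_offspring_regression(
    phenos: pd.DataFrame, trait: str = "total", parent: str = "mother"
) -> RegressionEstimate:
    """Regression of offspring phenotype on a parent phenotype, fitted as
    a random-intercept mixed model with brood (family) as the grouping
    factor.  Slope inference uses a t statistic on residual degrees of
    freedom (n - 2).

    Under purely additive inheritance the mother-offspring and
    father-offspring slopes each estimate h2 / 2; the midparent slope
    estimates h2.
    """
    df = _parent_offspring_frame(phenos, trait, parent)
    fams = df["brood"].nunique()
    if fams < 3:
        raise ValueError("need parent phenotypes for at least 3 families")
    x = df["parent_value"].to_numpy(float)
    if np.var(x) <= 0:
        raise ValueError("zero variance in parent phenotype")
    y = df[trait].to_numpy(float)
    X = np.column_stack([np.ones(len(y)), x])
    fit = _fit_random_intercept(y, X, df["brood"].to_numpy())
    slope, se = float(fit.beta[1]), float(fit.beta_se[1])
    df_resid = fit.n - fit.p
    tval = slope / se
    pval = 2.0 * stats.t.sf(abs(tval), df_resid)
    return RegressionEstimate(
        slope=slope, SE=se, t=float(tval), p=float(pval),
        intercept=float(fit.beta[0]), n=fit.n, n_families=fams, parent=parent,
    )


def maternal_effect_coefficient(beta_mo: float, beta_fo: float) -> float:
    """Falconer maternal-effect coefficient m = beta_mo - beta_fo."""
    return beta_mo - beta_fo


@dataclass
class MaternalEffectEstimate:
    beta_mo: RegressionEstimate
    beta_fo: RegressionEstimate
    beta_mid: RegressionEstimate
    m: float
    m_CI: tuple
    n_boot: int
    seed: int


def estimate_maternal_effect(
    phenos: pd.DataFrame,
    trait: str = "total",
    n_boot: int = 1000,
    seed: int = 0,
) -> MaternalEffectEstimate:
    """Estimate m = beta_mo - beta_fo with a brood-level (cluster)
    bootstrap percentile CI.

    The mother-offspring regression uses every brood with a phenotyped
    dam; the father-offspring and midparent regressions are restricted
    to broods whose sire was identified and phenotyped, so the two
    slopes may rest on different subsets of broods.  Each bootstrap
    replicate resamples broods with replacement and refits both
    regressions jointly on the resampled broods.
    """
    b_mo = parent_offspring_regression(phenos, trait, "mother")
    b_fo = parent_offspring_regression(phenos, trait, "father")
    b_mid = parent_offspring_regression(phenos, trait, "midparent")
    m = maternal_effect_coefficient(b_mo.slope, b_fo.slope)

    ci = (float("nan"), float("nan"))
    if n_boot:
        rng = np.random.default_rng(seed)
        mo_df = _parent_offspring_frame(phenos, trait, "mother")
        fo_df = _parent_offspring_frame(phenos, trait, "father")
        broods = np.array(sorted(set(mo_df["brood"]) | set(fo_df["brood"])))

        def arrays(df):
            return {
                b: (d["parent_value"].to_numpy(float), d[trait].to_numpy(float))
                for b, d in df.groupby("brood")
            }

        mo_by, fo_by = arrays(mo_df), arrays(fo_df)
        ms = []
        for _ in range(n_boot):
            chosen = rng.choice(broods, size=len(broods), replace=True)
            try:
                ms.append(_boot_m(chosen, mo_by) - _boot_m(chosen, fo_by))
            except (ValueError, np.linalg.LinAlgError):
                continue  # degenerate resample (e.g. a single brood drawn)
        if len(ms) >= 2:
            lo, hi = np.percentile(ms, [2.5, 97.5])
            ci = (float(lo), float(hi))
    return MaternalEffectEstimate(
        beta_mo=b_mo, beta_fo=b_fo, beta_mid=b_mid, m=float(m),
        m_CI=ci, n_boot=n_boot, seed=seed,
    )


def _boot_m(chosen, by_brood) -> float:
    """Slope of the random-intercept regression on a cluster resample;
    each drawn brood becomes its own group even if drawn repeatedly."""
    xs, ys, gs = [], [], []
    for k, b in enumerate(chosen):
        if b not in by_brood:
            continue
        x, y = by_brood[b]
        xs.append(x)
        ys.append(y)
        gs.append(np.full(len(x), k))
    if len(xs) < 3:
        raise ValueError("degenerate bootstrap resample")
    x = np.concatenate(xs)
    if np.var(x) <= 0:
        raise ValueError("degenerate bootstrap resample")
    X = np.column_stack([np.ones(len(x)), x])
    return float(
        _fit_random_intercept(np.concatenate(ys), X, np.concatenate(gs)).beta[1]
    )


# ---------------------------------------------------------------------------
# selection-response projections


def project_compound_response(e_mu: float, beta_mu: float, g: int) -> float:
    """Cumulative percent change in the trait mean after ``g`` generations
    of compounded proportional response: 100 * ((1 + e_mu/100 * beta_mu)**g - 1).

    ``e_mu`` is the per-generation mean-scaled evolvability in percent and
    ``beta_mu`` the mean-scaled selection strength as a proportion
    (1.0 = selection as strong as selection on fitness itself).
    """
    if g < 0:
        raise ValueError("g must be nonnegative")
    return 100.0 * ((1.0 + e_mu / 100.0 * beta_mu) ** g - 1.0)


@dataclass
class ResponseProjection:
    h2: float
    m: float
    beta: float
    generations: int
    trajectory: np.ndarray        # per-generation responses R_t
    cumulative_change: float      # sum of the trajectory
    ratio_to_no_maternal: float   # cumulative, relative to m = 0
    asymptotic_ratio: float       # per-generation limit 1 / (1 - m)


def falconer_response_trajectory(
    h2: float, m: float, beta: float, g: int, recursion=None
) -> ResponseProjection:
    """Cumulative selection response over ``g`` generations when the
    maternal phenotype feeds into the offspring phenotype with
    coefficient ``m`` (constant heritability, constant selection).

    The default per-generation recursion is the minimal
    phenotype-transmission form R_t = h2 * beta + m * R_{t-1}; a custom
    ``recursion(t, prev, h2, m, beta) -> R_t`` may be supplied to explore
    variants that carry additional maternal-additive covariance terms.
    For 0 < m < 1 the per-generation response approaches
    h2 * beta / (1 - m), i.e. an asymptotic excess of 1/(1-m) over the
    plain breeder's-equation response.
    """
    if abs(m) >= 1:
        raise ValueError("|m| must be < 1 for a convergent recursion")
    if g < 0:
        raise ValueError("g must be nonnegative")
    if recursion is None:
        def recursion(t, prev, h2, m, beta):
            return h2 * beta + m * prev

    traj = np.zeros(g)
    prev = 0.0
    for t in range(g):
        prev = recursion(t, prev, h2, m, beta)
        traj[t] = prev
    cum = float(np.sum(traj))
    base = h2 * beta * g
    return ResponseProjection(
        h2=h2, m=m, beta=beta, generations=g,
        trajectory=traj, cumulative_change=cum,
        ratio_to_no_maternal=(cum / base if base != 0 else float("nan")),
        asymptotic_ratio=1.0 / (1.0 - m),
    )
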