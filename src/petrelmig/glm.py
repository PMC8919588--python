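"""Generalised linear models for the similarity and phenology analyses.

Families/links used by the pipeline: gamma with identity link (EMD "effort"
values — continuous, non-negative, right-skewed, with effects expected to be
additive in km), gamma with log link (within-individual date ranges),
binomial with log link (Bhattacharyya affinities in [0, 1]), plus Gaussian.

Fitting is iteratively reweighted least squares to relative deviance
tolerance 1e-8; the identity-link gamma is guarded by step-halving so
fitted means stay positive. The gamma dispersion is the Pearson estimator.
Model reduction follows backwards stepwise deletion with ANOVA tests
(F with estimated dispersion for gamma/gaussian, χ² for binomial),
respecting marginality (interactions leave before their main effects).
Pairwise level comparisons use estimated marginal means with Tukey
adjustment via the studentized range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class GLMError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# families and links
# ---------------------------------------------------------------------------


class _Family:
    name = ""
    estimate_dispersion = True

    def variance(self, mu):
        raise NotImplementedError

    def deviance(self, y, mu):
        raise NotImplementedError

    def valid_mu(self, mu):
        return np.all(np.isfinite(mu))

    def loglik(self, y, mu, scale):
        raise NotImplementedError


class Gaussian(_Family):
    name = "gaussian"

    def variance(self, mu):
        return np.ones_like(mu)

    def deviance(self, y, mu):
        return float(np.sum((y - mu) ** 2))

    def loglik(self, y, mu, scale):
        return float(np.sum(sps.norm.logpdf(y, mu, np.sqrt(scale))))


class Gamma(_Family):
    name = "gamma"

    def variance(self, mu):
        return mu**2

    def deviance(self, y, mu):
        return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))

    def valid_mu(self, mu):
        return np.all(np.isfinite(mu)) and np.all(mu > 0)

    def loglik(self, y, mu, scale):
        shape = 1.0 / scale
        return float(np.sum(sps.gamma.logpdf(y, a=shape, scale=mu / shape)))


class Binomial(_Family):
    name = "binomial"
    estimate_dispersion = False

    def variance(self, mu):
        return mu * (1.0 - mu)

    def deviance(self, y, mu):
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
        return float(2.0 * np.sum(t1 + t2))

    def valid_mu(self, mu):
        return np.all(np.isfinite(mu)) and np.all((mu > 0) & (mu < 1))

    def loglik(self, y, mu, scale):
        return float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))


class _Link:
    name = ""

    def __call__(self, mu):
        raise NotImplementedError

    def inverse(self, eta):
        raise NotImplementedError

    def deta_dmu(self, mu):
        raise NotImplementedError


class Identity(_Link):
    name = "identity"

    def __call__(self, mu):
        return mu

    def inverse(self, eta):
        return eta

    def deta_dmu(self, mu):
        return np.ones_like(mu)


class Log(_Link):
    name = "log"

    def __call__(self, mu):
        return np.log(mu)

    def inverse(self, eta):
        return np.exp(np.clip(eta, -700, 700))

    def deta_dmu(self, mu):
        return 1.0 / mu


class Logit(_Link):
    name = "logit"

    def __call__(self, mu):
        return np.log(mu / (1 - mu))

    def inverse(self, eta):
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))

    def deta_dmu(self, mu):
        return 1.0 / (mu * (1.0 - mu))


_FAMILIES = {"gaussian": Gaussian, "gamma": Gamma, "binomial": Binomial}
_LINKS = {"identity": Identity, "log": Log, "logit": Logit}


# ---------------------------------------------------------------------------
# design matrices from term lists
# ---------------------------------------------------------------------------


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool


def _term_vars(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


@dataclass
class Design:
    """Treatment-coded design matrix built from a term list."""

    terms: list[str]
    X: np.ndarray
    columns: list[str]
    term_slices: dict[str, list[int]]
    levels: dict[str, list] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


def build_design(table: pd.DataFrame, terms: list[str]) -> Design:
    """Intercept + main effects + ':'-interactions, treatment coding."""
    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]
    slices: dict[str, list[int]] = {}
    levels: dict[str, list] = {}

    def var_columns(v: str) -> list[tuple[str, np.ndarray]]:
        s = table[v]
        if _is_categorical(s):
            lv = levels.setdefault(v, sorted(pd.unique(s.astype(str))))
            return [(f"{v}[{l}]", (s.astype(str) == l).to_numpy(dtype=float)) for l in lv[1:]]
        return [(v, s.to_numpy(dtype=float))]

    for term in terms:
        idxs = []
        parts = [var_columns(v) for v in _term_vars(term)]
        combos = [([], np.ones(n))]
        for p in parts:
            combos = [
                (nm + [pn], col * pc) for nm, col in combos for pn, pc in p
            ]
        for nm, col in combos:
            names.append(":".join(nm))
            cols.append(col)
            idxs.append(len(cols) - 1)
        slices[term] = idxs
    X = np.column_stack(cols)
    return Design(terms=list(terms), X=X, columns=names, term_slices=slices, levels=levels)


# ---------------------------------------------------------------------------
# the fit
# ---------------------------------------------------------------------------


@dataclass
class GLMFit:
    family: str
    link: str
    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    cov_params: np.ndarray
    dispersion: float
    deviance: float
    null_deviance: float
    df_resid: int
    columns: list[str]
    design: Design
    table: pd.DataFrame
    response: str
    fitted: np.ndarray
    loglik: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "stat": self.tvalues,
                "p": self.pvalues,
            },
            index=self.columns,
        )

    def term_pvalues(self, alpha_via_anova=True) -> dict[str, float]:
        """ANOVA (deletion-test) p-value per removable term."""
        out = {}
        for term in removable_terms(self.terms):
            out[term] = anova_drop(self, term)
        return out


def _irls(X, y, family: _Family, link: _Link, max_iter=200, tol=1e-8):
    n, p = X.shape
    # starting values: mu from adjusted response
    if family.name == "binomial":
        mu0 = float(np.clip(np.mean(y), 0.02, 0.98))
    elif family.name == "gamma":
        mu0 = float(np.mean(y))
    else:
        mu0 = float(np.mean(y))
    # valid intercept-only start so step-halving always has a feasible anchor
    beta = np.zeros(p)
    beta[0] = float(link(np.asarray([mu0]))[0])
    eta = X @ beta
    mu = link.inverse(eta)
    dev = family.deviance(y, mu)
    for it in range(max_iter):
        gprime = link.deta_dmu(mu)
        w = 1.0 / (family.variance(mu) * gprime**2)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise GLMError("non-finite IRLS weights; model/link unsuitable for data")
        z = eta + (y - mu) * gprime
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        # step-halving: keep fitted means inside the family support
        # step-halving keeps fitted means in the family support and enforces
        # deviance non-increase (oscillation guard for non-canonical links)
        step = 1.0
        for half in range(40):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand
            mu_c = link.inverse(eta_c)
            if family.valid_mu(mu_c):
                dev_c = family.deviance(y, mu_c)
                if np.isfinite(dev_c) and (dev_c <= dev * (1 + 1e-9) + 1e-12 or step < 1e-6):
                    break
            step /= 2.0
        else:
            raise GLMError(
                "could not keep fitted means in the family support; try a log link"
            )
        param_change = float(np.max(np.abs(cand - beta) / (np.abs(beta) + 1.0))) if it > 0 else np.inf
        beta, eta, mu = cand, eta_c, mu_c
        dev_new = family.deviance(y, mu)
        if param_change < 1e-11 or (
            abs(dev_new - dev) <= tol * (abs(dev) + 0.1) and param_change < 1e-9
        ):
            dev = dev_new
            break
        dev = dev_new
    else:
        raise GLMError(f"IRLS did not converge in {max_iter} iterations (deviance {dev:.4g})")
    gprime = link.deta_dmu(mu)
    w = 1.0 / (family.variance(mu) * gprime**2)
    return beta, mu, dev, w


def fit_glm(
    table: pd.DataFrame,
    response: str,
    terms: list[str],
    family: str = "gaussian",
    link: str = "identity",
) -> GLMFit:
    """Fit a GLM of `response` on `terms` (strings, ':' for interactions)."""
    fam = _FAMILIES[family]()
    lnk = _LINKS[link]()
    y = table[response].to_numpy(dtype=float)
    if family == "gamma" and np.any(y <= 0):
        raise GLMError("gamma family requires strictly positive response")
    if family == "binomial" and np.any((y < 0) | (y > 1)):
        raise GLMError("binomial family requires response in [0, 1]")
    design = build_design(table, terms)
    X = design.X
    if X.shape[1] >= X.shape[0]:
        raise GLMError("design matrix is rank deficient (saturated: p >= n)")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise GLMError("design matrix is rank deficient")
    beta, mu, dev, w = _irls(X, y, fam, lnk)
    n, p = X.shape
    df_resid = n - p
    pearson = float(np.sum((y - mu) ** 2 / fam.variance(mu)))
    dispersion = pearson / df_resid if fam.estimate_dispersion else 1.0
    XtWX = (X * w[:, None]).T @ X
    cov = np.linalg.inv(XtWX) * dispersion
    bse = np.sqrt(np.diag(cov))
    tval = beta / bse
    if fam.estimate_dispersion:
        pval = 2.0 * sps.t.sf(np.abs(tval), df_resid)
    else:
        pval = 2.0 * sps.norm.sf(np.abs(tval))
    null_design = build_design(table, [])
    try:
        _, mu0, dev0, _ = _irls(null_design.X, y, fam, lnk)
    except GLMError:
        dev0 = np.nan
    ll = fam.loglik(y, mu, dispersion if fam.estimate_dispersion else 1.0)
    return GLMFit(
        family=family,
        link=link,
        terms=list(terms),
        params=beta,
        bse=bse,
        tvalues=tval,
        pvalues=pval,
        cov_params=cov,
        dispersion=dispersion,
        deviance=dev,
        null_deviance=float(dev0),
        df_resid=df_resid,
        columns=design.columns,
        design=design,
        table=table,
        response=response,
        fitted=mu,
        loglik=ll,
    )


# ---------------------------------------------------------------------------
# stepwise deletion with marginality
# ---------------------------------------------------------------------------


def removable_terms(terms: list[str]) -> list[str]:
    """Terms not contained in any retained higher-order interaction."""
    out = []
    for t in terms:
        tv = set(_term_vars(t))
        contained = any(
            t != u and tv.issubset(set(_term_vars(u))) for u in terms
        )
        if not contained:
            out.append(t)
    return out


def anova_drop(fit: GLMFit, term: str) -> float:
    """Deletion-test p-value for removing `term` from the fitted model."""
    reduced_terms = [t for t in fit.terms if t != term]
    reduced = fit_glm(fit.table, fit.response, reduced_terms, fit.family, fit.link)
    ddf = fit.design.n_params - reduced.design.n_params
    ddev = reduced.deviance - fit.deviance
    if _FAMILIES[fit.family]().estimate_dispersion:
        F = (ddev / ddf) / fit.dispersion
        return float(sps.f.sf(max(F, 0.0), ddf, fit.df_resid))
    return float(sps.chi2.sf(max(ddev, 0.0), ddf))


def stepwise_backward(fit: GLMFit, alpha: float = 0.05) -> tuple[GLMFit, list[dict]]:
    """Backwards stepwise deletion of non-significant terms (marginality-safe).

    Repeatedly removes the least significant removable term with p >= alpha;
    returns the minimum adequate model and a deletion log.
    """
    log: list[dict] = []
    current = fit
    while True:
        cands = removable_terms(current.terms)
        if not cands:
            break
        pvals = {t: anova_drop(current, t) for t in cands}
        worst = max(pvals, key=lambda t: pvals[t])
        if pvals[worst] < alpha:
            break
        log.append({"dropped": worst, "p": pvals[worst]})
        current = fit_glm(
            current.table,
            current.response,
            [t for t in current.terms if t != worst],
            current.family,
            current.link,
        )
    return current, log


# ---------------------------------------------------------------------------
# estimated marginal means with Tukey adjustment
# ---------------------------------------------------------------------------


def emmeans_tukey(
    fit: GLMFit,
    factor: str,
    covariate_values: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Pairwise contrasts of estimated marginal means for `factor` levels.

    Marginal means are evaluated on the link scale at covariates fixed at
    their observed means (overridable via `covariate_values`, e.g. a median),
    with other factors averaged over their levels with equal weights. The
    familywise adjustment uses the studentized range distribution.
    """
    if factor not in fit.design.levels:
        raise GLMError(f"{factor!r} is not a categorical term of the model")
    levels = fit.design.levels[factor]
    cov_vals = covariate_values or {}

    # reference rows: one synthetic data row per level (other factors averaged)
    def grid_x(level: str) -> np.ndarray:
        rows = []
        other_factors = [v for v in fit.design.levels if v != factor]
        combos = [[]]
        for of in other_factors:
            combos = [c + [(of, l)] for c in combos for l in fit.design.levels[of]]
        for combo in combos:
            rec = {}
            for col in fit.table.columns:
                s = fit.table[col]
                if col == factor:
                    rec[col] = level
                elif any(col == of for of, _ in combo):
                    rec[col] = dict(combo)[col]
                elif _is_categorical(s):
                    rec[col] = s.astype(str).iloc[0]
                else:
                    rec[col] = cov_vals.get(col, float(s.mean()))
            rows.append(rec)
        grid = pd.DataFrame(rows)
        Xg = _design_for_new(fit.design, grid)
        return Xg.mean(axis=0)

    xs = {l: grid_x(l) for l in levels}
    k = len(levels)
    df = fit.df_resid
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = xs[levels[i]] - xs[levels[j]]
            est = float(d @ fit.params)
            se = float(np.sqrt(d @ fit.cov_params @ d))
            t = est / se
            if _FAMILIES[fit.family]().estimate_dispersion:
                raw = 2.0 * float(sps.t.sf(abs(t), df))
            else:
                raw = 2.0 * float(sps.norm.sf(abs(t)))
            if k == 2:
                adj = raw
            else:
                adj = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
            rows.append(
                {
                    "contrast": f"{levels[i]} - {levels[j]}",
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p_raw": raw,
                    "p_adjusted": float(min(max(adj, raw), 1.0)),
                }
            )
    return pd.DataFrame(rows)


def _design_for_new(design: Design, new: pd.DataFrame) -> np.ndarray:
    """Design matrix for new data using the stored levels/terms."""
    n = len(new)
    cols = [np.ones(n)]

    def var_columns(v: str) -> list[np.ndarray]:
        s = new[v]
        if v in design.levels:
            lv = design.levels[v]
            return [(s.astype(str) == l).to_numpy(dtype=float) for l in lv[1:]]
        return [s.to_numpy(dtype=float)]

    for term in design.terms:
        parts = [var_columns(v) for v in _term_vars(term)]
        combos = [np.ones(n)]
        for p in parts:
            combos = [c * pc for c in combos for pc in p]
        cols.extend(combos)
    return np.column_stack(cols)
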