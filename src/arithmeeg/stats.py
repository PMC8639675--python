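"""Mixed-effects inference: inverse-Gaussian GLMM for response times,
binomial GLMM for accuracy, Gaussian LMMs for ERD/ERS, estimated marginal
means and Tukey-corrected pairwise contrasts.

All models share the same structure: sum-to-zero coded fixed experimental
factors (so main effects stay interpretable under interactions, Type-III
style) plus a random intercept per participant.

statsmodels provides the Gaussian linear mixed model (``MixedLM``) but no
frequentist GLMM for inverse-Gaussian or binomial families, so those two are
fit here by maximizing the marginal likelihood with Gauss-Hermite quadrature
over the random intercept.  Per-term tests are likelihood-ratio chi-square
tests (each term removed from the full model in turn).  The linear models
report per-term Wald F statistics with denominator degrees of freedom
``n - p - (g - 1)`` (observations minus fixed-effect columns minus
participant degrees of freedom), the standard small-sample approximation for
balanced within-participant designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import optimize, special
from scipy import stats as sps

__all__ = [
    "FittedModel",
    "ModelError",
    "fit_rt_model",
    "fit_accuracy_model",
    "fit_erders_model",
    "pairwise_posthoc",
]


class ModelError(RuntimeError):
    """Model fitting failed beyond recovery; carries diagnostics."""


@dataclass
class FittedModel:
    """Fixed-effect estimates plus what post-hoc contrasts need."""

    kind: str  # "ig_glmm" | "binomial_glmm" | "lognormal_lmm" | "lmm"
    formula: str
    params: np.ndarray
    cov: np.ndarray
    design_info: "patsy.DesignInfo"
    data: pd.DataFrame
    factors: tuple[str, ...]
    df_denom: float
    loglik: float | None = None
    extra: dict = field(default_factory=dict)


def _sum_formula(response: str, factors: Sequence[str], max_order: int | None = None) -> str:
    terms = [f"C({f}, Sum)" for f in factors]
    if max_order is None or max_order >= len(factors):
        return f"{response} ~ " + " * ".join(terms)
    return f"{response} ~ (" + " + ".join(terms) + f") ** {max_order}"


# ---------------------------------------------------------------------------
# GLMM machinery (Gauss-Hermite quadrature over the participant intercept)

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(20)
_LOG_GH_W = np.log(_GH_WEIGHTS) - 0.5 * np.log(np.pi)


def _group_index(groups: pd.Series) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(groups, sort=True)
    return codes, len(uniques)


def _glmm_negloglik(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    family: str,
) -> float:
    p = X.shape[1]
    beta = theta[:p]
    sigma = np.exp(theta[-1])
    eta = X @ beta
    b = np.sqrt(2.0) * sigma * _GH_NODES  # (K,)
    lin = eta[:, None] + b[None, :]  # (n, K)

    if family == "binomial":
        # logit link
        ll_obs = y[:, None] * lin - np.logaddexp(0.0, lin)
        penalty = 0.0
    elif family == "inverse_gaussian":
        # identity link; lam is the IG shape parameter
        lam = np.exp(theta[p])
        mu = lin
        floor = 1e-3
        penalty = 1e4 * np.sum(np.clip(floor - mu, 0.0, None) ** 2)
        mu = np.maximum(mu, floor)
        yc = y[:, None]
        ll_obs = (
            0.5 * (np.log(lam) - np.log(2 * np.pi) - 3 * np.log(yc))
            - lam * (yc - mu) ** 2 / (2 * mu**2 * yc)
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown family {family}")

    ll_group = np.zeros((n_groups, ll_obs.shape[1]))
    np.add.at(ll_group, gidx, ll_obs)
    ll = special.logsumexp(ll_group + _LOG_GH_W[None, :], axis=1).sum()
    if not np.isfinite(ll):
        return 1e12
    return -(ll) + penalty


def _fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    family: str,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (theta_hat, cov_beta, loglik). Raises ModelError on failure."""
    p = X.shape[1]
    # starting values
    if family == "binomial":
        pbar = np.clip(y.mean(), 1e-3, 1 - 1e-3)
        beta0 = np.zeros(p)
        beta0[0] = np.log(pbar / (1 - pbar))
        theta0 = np.concatenate([beta0, [np.log(0.5)]])
    else:
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        mu0 = np.maximum(X @ beta0, 1e-2)
        lam0 = 1.0 / np.mean((y - mu0) ** 2 / (mu0**2 * y))
        theta0 = np.concatenate([beta0, [np.log(max(lam0, 1e-3)), np.log(0.5)]])

    res = optimize.minimize(
        _glmm_negloglik,
        theta0,
        args=(y, X, gidx, n_groups, family),
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    if not np.all(np.isfinite(res.x)):
        raise ModelError(f"GLMM ({family}) optimization diverged: {res.message}")
    # observed-information covariance for the fixed effects
    try:
        hess = _numeric_hessian(
            lambda th: _glmm_negloglik(th, y, X, gidx, n_groups, family), res.x
        )
        cov_all = np.linalg.inv(hess)
        cov_beta = cov_all[:p, :p]
        if not np.all(np.isfinite(cov_beta)) or np.any(np.diag(cov_beta) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov_beta = np.full((p, p), np.nan)
    return res.x, cov_beta, -res.fun


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    h = np.zeros((n, n))
    f0 = f(x)
    steps = eps * np.maximum(np.abs(x), 1.0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fij = f(x + ei + ej)
            fi = f(x + ei)
            fj = f(x + ej)
            h[i, j] = h[j, i] = (fij - fi - fj + f0) / (steps[i] * steps[j])
    return h


def _check_factorial(data: pd.DataFrame, factors: Sequence[str]) -> None:
    if data["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels present")


def _glmm_effect_table(
    data: pd.DataFrame,
    response: str,
    family: str,
    model_id: str,
) -> tuple[pd.DataFrame, FittedModel]:
    factors = ("strategy", "operation")
    _check_factorial(data, factors)
    formula = _sum_formula(response, factors)
    y_dm, X_dm = patsy.dmatrices(formula, data, return_type="dataframe")
    X = np.asarray(X_dm)
    y = np.asarray(y_dm).ravel()
    design_info = X_dm.design_info
    gidx, n_groups = _group_index(data["participant"])

    model_warnings: list[str] = []
    if family == "binomial" and (y.min() == y.max()):
        model_warnings.append(
            "complete separation: the response has no variation; "
            "coefficients are not identifiable"
        )

    theta, cov_beta, ll_full = _fit_glmm(y, X, gidx, n_groups, family)
    p = X.shape[1]
    beta = theta[:p]
    if family == "binomial" and np.any(np.abs(beta) > 10):
        model_warnings.append(
            "possible (quasi-)separation: |coefficient| > 10 on the logit scale"
        )

    rows = []
    for term in design_info.term_names:
        if term == "Intercept":
            continue
        cols = []
        for name, sl in design_info.term_name_slices.items():
            if name != term:
                cols.extend(range(sl.start, sl.stop))
        X_red = X[:, cols]
        df_term = p - len(cols)
        try:
            _, _, ll_red = _fit_glmm(y, X_red, gidx, n_groups, family)
            chi2 = max(2.0 * (ll_full - ll_red), 0.0)
            pval = float(sps.chi2.sf(chi2, df_term))
        except ModelError as err:
            model_warnings.append(f"reduced model without {term} failed: {err}")
            chi2, pval = np.nan, np.nan
        rows.append(
            {
                "model": model_id,
                "term": _pretty_term(term),
                "stat_kind": "chi2",
                "statistic": chi2,
                "df1": df_term,
                "df2": np.nan,
                "p": pval,
            }
        )
    effects = pd.DataFrame(rows)
    fitted = FittedModel(
        kind=f"{'ig' if family == 'inverse_gaussian' else family}_glmm",
        formula=formula,
        params=beta,
        cov=cov_beta,
        design_info=design_info,
        data=data,
        factors=factors,
        df_denom=np.inf,
        loglik=ll_full,
        extra={
            "theta": theta,
            "sigma_participant": float(np.exp(theta[-1])),
            "warnings": model_warnings,
        },
    )
    for w in model_warnings:
        warnings.warn(w)
    return effects, fitted


def _pretty_term(term: str) -> str:
    return (
        term.replace("C(", "")
        .replace(", Sum)", "")
        .replace(":", " x ")
    )


def fit_rt_model(trials: pd.DataFrame) -> tuple[pd.DataFrame, FittedModel]:
    """Inverse-Gaussian GLMM (identity link) for trial-level response times.

    ``trials`` needs columns participant, strategy, operation, rt and should
    contain correct, consistency-retained trials only.  Fixed effects:
    strategy, operation, and their interaction; random intercept per
    participant; per-term likelihood-ratio chi-square tests.  If the
    inverse-Gaussian fit fails, falls back (with a warning) to a Gaussian
    mixed model on log RT as a location-scale surrogate.
    """
    data = trials.copy()
    if (data["rt"] <= 0).any():
        raise ValueError("response times must be positive")
    try:
        return _glmm_effect_table(data, "rt", "inverse_gaussian", "rt")
    except ModelError as err:
        warnings.warn(f"inverse-Gaussian GLMM failed ({err}); falling back to log-RT LMM")
        data = data.assign(log_rt=np.log(data["rt"]))
        try:
            effects, fitted = _lmm_effect_table(
                data, "log_rt", ("strategy", "operation"), "rt", use_lrt=True
            )
        except Exception as err2:  # noqa: BLE001
            raise ModelError(
                f"both the inverse-Gaussian GLMM ({err}) and the log-RT "
                f"fallback ({err2}) failed"
            ) from err2
        fitted.extra.setdefault("warnings", []).append("log-RT fallback used")
        return effects, fitted


def fit_accuracy_model(trials: pd.DataFrame) -> tuple[pd.DataFrame, FittedModel]:
    """Binomial (logit link) GLMM for trial-level correctness.

    Same fixed/random structure as the RT model.  Complete or quasi-complete
    separation is reported in the fitted model's warnings, never silently
    dropped.
    """
    data = trials.copy()
    data["correct"] = data["correct"].astype(float)
    return _glmm_effect_table(data, "correct", "binomial", "accuracy")


# ---------------------------------------------------------------------------
# Gaussian linear mixed models (ERD/ERS)


def _fit_mixedlm(model, reml: bool):
    """Fit a MixedLM, falling back to a derivative-free optimizer.

    The default L-BFGS path can hit singular working matrices when the
    random-intercept variance collapses to the boundary; Powell does not
    evaluate the analytic score and is robust there.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return model.fit(reml=reml)
        except (np.linalg.LinAlgError, ValueError):
            return model.fit(reml=reml, method="powell")


def _lmm_effect_table(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    model_id: str,
    *,
    max_order: int | None = None,
    use_lrt: bool = False,
) -> tuple[pd.DataFrame, FittedModel]:
    formula = _sum_formula(response, factors, max_order)
    model = smf.mixedlm(formula, data, groups=data["participant"])
    result = _fit_mixedlm(model, reml=not use_lrt)
    design_info = model.data.design_info
    p = len(result.fe_params)
    n = len(data)
    g = data["participant"].nunique()
    df_denom = float(n - p - (g - 1))
    params = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[:p, :p]

    rows = []
    for term in design_info.term_names:
        if term == "Intercept":
            continue
        sl = design_info.term_name_slices[term]
        idx = np.arange(sl.start, sl.stop)
        q = idx.size
        if use_lrt:
            from statsmodels.regression.mixed_linear_model import MixedLM

            cols = [i for i in range(p) if i not in set(idx)]
            X_full = np.asarray(patsy.build_design_matrices([design_info], data)[0])
            red_model = MixedLM(
                np.asarray(data[response]), X_full[:, cols], groups=data["participant"]
            )
            red_res = _fit_mixedlm(red_model, reml=False)
            chi2 = max(2.0 * (result.llf - red_res.llf), 0.0)
            rows.append(
                {
                    "model": model_id,
                    "term": _pretty_term(term),
                    "stat_kind": "chi2",
                    "statistic": chi2,
                    "df1": q,
                    "df2": np.nan,
                    "p": float(sps.chi2.sf(chi2, q)),
                }
            )
        else:
            b = params[idx]
            V = cov[np.ix_(idx, idx)]
            try:
                fstat = float(b @ np.linalg.solve(V, b) / q)
            except np.linalg.LinAlgError:
                fstat = np.nan
            rows.append(
                {
                    "model": model_id,
                    "term": _pretty_term(term),
                    "stat_kind": "F",
                    "statistic": fstat,
                    "df1": q,
                    "df2": df_denom,
                    "p": float(sps.f.sf(fstat, q, df_denom)) if np.isfinite(fstat) else np.nan,
                }
            )

    fitted = FittedModel(
        kind="lmm" if not use_lrt else "lognormal_lmm",
        formula=formula,
        params=params,
        cov=cov,
        design_info=design_info,
        data=data,
        factors=tuple(factors),
        df_denom=df_denom,
        loglik=float(result.llf),
        extra={
            "sigma_participant": float(np.sqrt(result.cov_re.iloc[0, 0])),
            "sigma_resid": float(np.sqrt(result.scale)),
            "converged": bool(result.converged),
            "warnings": [],
        },
    )
    return pd.DataFrame(rows), fitted


def fit_erders_model(records: pd.DataFrame) -> tuple[pd.DataFrame, FittedModel]:
    """Linear mixed model for one band's ERD/ERS records.

    Full-factorial fixed effects (operation, strategy, ROI, hemisphere, all
    interactions up to the four-way), random intercept per participant, and
    per-term Wald F tests.  A singular fit triggers a logged refit without
    the four-way interaction.
    """
    if records["band"].nunique() != 1:
        raise ValueError("fit_erders_model expects records from a single band")
    factors = ("operation", "strategy", "roi", "hemisphere")
    _check_factorial(records, factors)
    band = records["band"].iloc[0]
    effects, fitted = _lmm_effect_table(records, "value", factors, f"erders_{band}")
    # a boundary variance estimate (sigma_participant -> 0) and a strict
    # optimizer convergence flag tripping at that boundary are legitimate
    # REML outcomes; the reduced model is only for an unusable fit
    singular = (
        not np.all(np.isfinite(fitted.cov))
        or np.any(np.diag(fitted.cov) <= 0)
        or not np.isfinite(effects["statistic"]).all()
    )
    if not fitted.extra["converged"] and not singular:
        fitted.extra["warnings"].append(
            "optimizer convergence flag not set (boundary variance); "
            "fit accepted on finite covariance"
        )
    if singular:
        warnings.warn(
            f"singular or non-converged fit for band {band}; refitting "
            "without the four-way interaction"
        )
        try:
            effects, fitted = _lmm_effect_table(
                records, "value", factors, f"erders_{band}", max_order=3
            )
            fitted.extra["warnings"].append(
                "four-way interaction dropped (singular fit)"
            )
        except (np.linalg.LinAlgError, ValueError) as err:
            warnings.warn(
                f"reduced model for band {band} also failed ({err}); "
                "keeping the full-model fit"
            )
            fitted.extra["warnings"].append("reduced-model refit failed")
    return effects, fitted


# ---------------------------------------------------------------------------
# estimated marginal means and Tukey-corrected pairwise contrasts


def pairwise_posthoc(
    fitted: FittedModel, factors: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimated marginal means for the cells of ``factors`` plus all
    pairwise contrasts with Tukey-family adjustment.

    EMMs average model predictions over the levels of the remaining factors
    (balanced grid).  The Tukey adjustment uses the studentized-range
    distribution with the model's denominator df (infinite for the GLMMs,
    where Wald z statistics are used).  For the binomial model the means are
    on the logit scale.  Returns (contrasts, emmeans).
    """
    unknown = [f for f in factors if f not in fitted.factors]
    if unknown:
        raise ValueError(f"factors {unknown} not in model ({fitted.factors})")
    levels = {f: sorted(fitted.data[f].unique()) for f in fitted.factors}
    sub = [f for f in factors]
    rest = [f for f in fitted.factors if f not in sub]

    cells = list(product(*(levels[f] for f in sub)))
    L = np.zeros((len(cells), fitted.params.size))
    for ci, cell in enumerate(cells):
        grid = pd.DataFrame(
            [
                dict(zip(sub, cell)) | dict(zip(rest, others))
                for others in product(*(levels[f] for f in rest))
            ]
            or [dict(zip(sub, cell))]
        )
        X_cell = np.asarray(
            patsy.build_design_matrices([fitted.design_info], grid)[0]
        )
        L[ci] = X_cell.mean(axis=0)

    est = L @ fitted.params
    V = L @ fitted.cov @ L.T
    se = np.sqrt(np.diag(V))
    df = fitted.df_denom
    tcrit = sps.t.ppf(0.975, df) if np.isfinite(df) else sps.norm.ppf(0.975)

    emm_rows = []
    for cell, e, s in zip(cells, est, se):
        row = dict(zip(sub, cell))
        row.update(
            emmean=e, se=s, ci_low=e - tcrit * s, ci_high=e + tcrit * s
        )
        emm_rows.append(row)
    emmeans = pd.DataFrame(emm_rows)

    k = len(cells)
    sr_df = df if np.isfinite(df) else 1e9
    con_rows = []
    for i, j in combinations(range(k), 2):
        diff = est[i] - est[j]
        se_d = np.sqrt(V[i, i] + V[j, j] - 2 * V[i, j])
        if not np.isfinite(se_d) or se_d <= 0:
            warnings.warn(f"contrast {cells[i]} - {cells[j]} dropped (no variance)")
            continue
        t = diff / se_d
        p_unadj = float(
            2 * (sps.t.sf(abs(t), df) if np.isfinite(df) else sps.norm.sf(abs(t)))
        )
        p_tukey = float(sps.studentized_range.sf(np.sqrt(2.0) * abs(t), k, sr_df))
        con_rows.append(
            {
                "cell_a": " / ".join(map(str, cells[i])),
                "cell_b": " / ".join(map(str, cells[j])),
                "estimate": diff,
                "se": se_d,
                "statistic": t,
                "p_unadjusted": p_unadj,
                "p_tukey": min(max(p_tukey, p_unadj), 1.0),
            }
        )
    return pd.DataFrame(con_rows), emmeans
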