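"""Day/night log-activity mixed models with all-subsets AIC averaging.

Per subject-day mean activity counts in each stratum (daytime,
nighttime) are log-transformed (log(x + offset)) and modelled as a
Gaussian linear mixed model with fixed effects of day type, age, sex
and body mass and a random intercept per subject for the repeated daily
measures:

    log(activity + 1) ~ day_type + age + sex + mass + (1 | subject)

All 2^k subsets of the fixed terms are fitted by maximum likelihood
(ML, not REML, so AICs are comparable across fixed-effect sets), ranked
by AIC, and the models within delta_max of the best are averaged.
Reported coefficients are the conditional (natural) averages — each
term averaged only over retained models containing it, with Akaike
weights renormalized over those models — with unconditional standard
errors that include the between-model variance component. Continuous
predictors are standardized (mean 0, SD 1) before fitting so estimates
are comparable across terms.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

DEFAULT_TERMS = ("day_type", "age", "sex", "mass")
DEFAULT_LOG_OFFSET = 1.0
DEFAULT_DELTA_MAX = 10.0

#: Pretty labels matching the reporting convention for dummy-coded terms.
TERM_LABELS = {
    "day_type": "Day type (weekend)",
    "age": "Age",
    "sex": "Sex (male)",
    "mass": "Body mass",
}


class ModelError(ValueError):
    pass


def build_summary_table(
    summaries: pd.DataFrame,
    metadata: pd.DataFrame,
    stratum: str = "daytime",
    log_offset: float = DEFAULT_LOG_OFFSET,
) -> pd.DataFrame:
    """Long modelling table for one response stratum.

    One row per subject-day with log-transformed mean activity, raw
    covariates and standardized copies (``age_z``, ``mass_z``; sex and
    day type stay 0/1 dummies). Rows whose stratum summary is missing
    are dropped.
    """
    if log_offset <= 0:
        raise ModelError("log offset must be positive")
    col = {"daytime": "daytime_mean_count", "nighttime": "nighttime_mean_count"}.get(stratum)
    if col is None:
        raise ModelError(f"unknown stratum {stratum!r}")
    df = summaries.merge(metadata.rename(columns={"id": "subject_id"}), on="subject_id")
    df = df[np.isfinite(df[col])].copy()
    if df.empty:
        raise ModelError(f"no usable {stratum} summaries")
    df["log_activity"] = np.log(df[col] + log_offset)
    df["day_type_dummy"] = (df["day_type"] == "weekend").astype(float)
    df["sex_dummy"] = (df["sex"] == "M").astype(float)
    for name in ("age", "mass"):
        x = df[name].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        df[f"{name}_z"] = (x - x.mean()) / sd if sd > 0 else 0.0
    df["stratum"] = stratum
    return df.reset_index(drop=True)


_TERM_COLUMNS = {
    "day_type": "day_type_dummy",
    "age": "age_z",
    "sex": "sex_dummy",
    "mass": "mass_z",
}


@dataclass
class FittedLMM:
    """One random-intercept model fit (ML)."""

    terms: tuple
    params: pd.Series  # fixed effects incl. intercept
    bse: pd.Series
    llf: float
    aic: float
    n_obs: int
    group_var: float
    resid_var: float
    boundary: bool  # random-intercept variance at (or near) zero
    converged: bool


def fit_random_intercept_model(
    table: pd.DataFrame, fixed_terms: tuple = DEFAULT_TERMS, response: str = "log_activity"
) -> FittedLMM:
    """Fit log-activity ~ fixed_terms + (1 | subject) by maximum likelihood.

    AIC = -2*llf + 2*(k_fixed + 2), counting the random-intercept and
    residual variances. A singular fit (zero intercept variance) is
    returned with ``boundary=True`` rather than raised.
    """
    if table["subject_id"].nunique() < 2:
        raise ModelError("need at least 2 subjects")
    cols = [_TERM_COLUMNS[t] for t in fixed_terms]
    X = pd.DataFrame({"intercept": np.ones(len(table))})
    for t, c in zip(fixed_terms, cols):
        col = table[c].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            raise ModelError(f"predictor {t!r} is constant in this table")
        X[t] = col
    y = table[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ModelError("non-finite response values")

    model = MixedLM(y, X.to_numpy(), groups=table["subject_id"].to_numpy())
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for method in ("bfgs", "nm", "powell"):
            try:
                fit = model.fit(reml=False, method=method, maxiter=500)
                break
            except np.linalg.LinAlgError:
                continue
    if fit is None:
        raise ModelError("mixed-model fit failed for every optimizer")
    k_fixed = X.shape[1]
    llf = float(fit.llf)
    group_var = float(np.squeeze(fit.cov_re))  # already on the response scale
    resid_var = float(fit.scale)
    names = list(X.columns)
    return FittedLMM(
        terms=tuple(fixed_terms),
        params=pd.Series(np.asarray(fit.fe_params), index=names),
        bse=pd.Series(np.asarray(fit.bse_fe), index=names),
        llf=llf,
        aic=-2.0 * llf + 2.0 * (k_fixed + 2),
        n_obs=len(table),
        group_var=group_var,
        resid_var=resid_var,
        boundary=group_var <= 1e-3 * max(resid_var, 1e-12),
        converged=bool(fit.converged),
    )


@dataclass
class ModelAveragedResult:
    """Conditional model-averaged coefficients plus the candidate table."""

    response: str  # 'daytime' | 'nighttime'
    terms_table: pd.DataFrame  # per predictor: estimate, SE, z, p, CI
    candidates: pd.DataFrame  # per model: terms, AIC, delta, weight
    delta_max: float

    def table1_style(self) -> pd.DataFrame:
        """Coefficient table in the conventional reporting layout."""
        t = self.terms_table
        return pd.DataFrame(
            {
                "Predictor variable": t["label"],
                "Estimate (SE)": [
                    f"{e:.3f} ({s:.3f})" for e, s in zip(t["estimate"], t["se"])
                ],
                "z-value": [f"{z:.3f}" for z in t["z"]],
                "p value": [("< 0.001" if p < 0.001 else f"{p:.3f}") for p in t["p"]],
                "95% CI": [
                    f"{lo:.3f}, {hi:.3f}" for lo, hi in zip(t["ci_low"], t["ci_high"])
                ],
            }
        )


def simulate_summary_table(
    n_subjects: int = 42,
    n_days: int = 14,
    coefs: dict | None = None,
    intercept: float = 4.0,
    random_intercept_sd: float = 0.3,
    resid_sd: float = 0.25,
    seed: int = 0,
    stratum: str = "daytime",
) -> pd.DataFrame:
    """Summary table drawn from the mixed-model generative process itself.

    ``coefs`` maps terms to true coefficients on the *standardized*
    predictor scale (z-scored age and mass, 0/1 dummies for weekend and
    male), so recovered standardized estimates target them directly.
    Days run from a Monday, giving 10 weekdays + 4 weekend days per
    fortnight. Used for parameter-recovery checks of the averaging
    machinery with known truth.
    """
    coefs = dict(coefs or {})
    rng = np.random.default_rng(seed)
    sex = rng.permutation(np.array(["F", "M"] * ((n_subjects + 1) // 2))[:n_subjects])
    subjects = pd.DataFrame(
        {
            "subject_id": [f"dog{i + 1:03d}" for i in range(n_subjects)],
            "age": rng.uniform(2.0, 9.0, n_subjects),
            "sex": sex,
            "mass": rng.uniform(2.7, 45.4, n_subjects),
            "b": rng.normal(0.0, random_intercept_sd, n_subjects),
        }
    )
    dates = pd.date_range("2020-01-06", periods=n_days, freq="D")
    df = subjects.merge(pd.DataFrame({"date": dates}), how="cross")
    df["day_type"] = np.where(df["date"].dt.weekday >= 5, "weekend", "weekday")
    df["day_type_dummy"] = (df["day_type"] == "weekend").astype(float)
    df["sex_dummy"] = (df["sex"] == "M").astype(float)
    for name in ("age", "mass"):
        x = df[name].to_numpy()
        df[f"{name}_z"] = (x - x.mean()) / x.std(ddof=1)
    eta = np.full(len(df), intercept) + df["b"].to_numpy()
    for term, beta in coefs.items():
        eta = eta + beta * df[_TERM_COLUMNS[term]].to_numpy()
    df["log_activity"] = eta + rng.normal(0.0, resid_sd, len(df))
    df["stratum"] = stratum
    return df.drop(columns=["b"])


def conditional_average(betas, ses, weights) -> tuple:
    """Weighted coefficient average with between-model variance.

    ``weights`` are renormalized internally; returns (estimate, SE) with
    SE = sqrt(sum_m w_m (se_m^2 + (beta_m - estimate)^2)).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    w = np.asarray(weights, dtype=float)
    if betas.size == 0:
        raise ModelError("no models contain the term")
    w = w / w.sum()
    est = float(np.sum(w * betas))
    se = float(np.sqrt(np.sum(w * (ses**2 + (betas - est) ** 2))))
    return est, se


def dredge_and_average(
    table: pd.DataFrame,
    full_terms: tuple = DEFAULT_TERMS,
    delta_max: float = DEFAULT_DELTA_MAX,
    response_label: str = "",
) -> ModelAveragedResult:
    """All-subsets candidate generation and conditional model averaging.

    Fits all 2^k subsets of ``full_terms`` (each with the random
    intercept), retains models with delta AIC < ``delta_max``, computes
    Akaike weights w ~ exp(-delta/2) renormalized over the retained set,
    and averages each term over the retained models containing it with
    weights renormalized over those models. The unconditional SE
    includes between-model variance:
    SE = sqrt(sum_m w'_m (se_m^2 + (beta_m - avg)^2)). A full
    (zero-substituted) average over every retained model is also
    reported in the terms table.
    """
    if delta_max <= 0:
        raise ModelError("delta_max must be positive")
    fits = []
    for r in range(len(full_terms) + 1):
        for combo in itertools.combinations(full_terms, r):
            fits.append(fit_random_intercept_model(table, combo))

    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    keep = delta < delta_max
    if not keep.any():  # unreachable with delta_max > 0; defensive
        raise ModelError("empty retained model set")
    retained = [f for f, k in zip(fits, keep) if k]
    delta_r = delta[keep]
    w = np.exp(-delta_r / 2.0)
    w = w / w.sum()

    candidates = pd.DataFrame(
        {
            "terms": [" + ".join(f.terms) or "(intercept only)" for f in fits],
            "k": [len(f.terms) + 3 for f in fits],  # + intercept + 2 variances
            "logLik": [f.llf for f in fits],
            "AIC": aics,
            "delta_AIC": delta,
            "retained": keep,
        }
    ).sort_values("AIC", ignore_index=True)
    weight_map = {
        " + ".join(f.terms) or "(intercept only)": wi for f, wi in zip(retained, w)
    }
    candidates["weight"] = [
        weight_map.get(t, 0.0) if r else 0.0
        for t, r in zip(candidates["terms"], candidates["retained"])
    ]

    rows = []
    for term in full_terms:
        has = np.array([term in f.terms for f in retained])
        betas = np.array([f.params[term] if term in f.terms else 0.0 for f in retained])
        ses = np.array([f.bse[term] if term in f.terms else 0.0 for f in retained])
        # conditional (natural) average over models containing the term
        est, se = conditional_average(betas[has], ses[has], w[has])
        # full average: absent models contribute a zero coefficient
        est_full = float(np.sum(w * betas))
        z = abs(est) / se if se > 0 else np.inf
        p = 2.0 * stats.norm.sf(z)
        rows.append(
            {
                "term": term,
                "label": TERM_LABELS.get(term, term),
                "estimate": est,
                "se": se,
                "z": z,
                "p": p,
                "ci_low": est - 1.96 * se,
                "ci_high": est + 1.96 * se,
                "estimate_full_average": est_full,
                "weight_containing": float(w[has].sum()),
            }
        )
    return ModelAveragedResult(
        response=response_label,
        terms_table=pd.DataFrame(rows),
        candidates=candidates,
        delta_max=delta_max,
    )


def fit_both_strata(
    summaries: pd.DataFrame,
    metadata: pd.DataFrame,
    full_terms: tuple = DEFAULT_TERMS,
    delta_max: float = DEFAULT_DELTA_MAX,
    log_offset: float = DEFAULT_LOG_OFFSET,
) -> dict:
    """Daytime and nighttime model-averaged results from cohort summaries."""
    out = {}
    for stratum in ("daytime", "nighttime"):
        table = build_summary_table(summaries, metadata, stratum, log_offset)
        out[stratum] = dredge_and_average(table, full_terms, delta_max, response_label=stratum)
    return out
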