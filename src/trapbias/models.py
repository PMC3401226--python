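"""The five competing analyses of seasonal trap-catch data.

=====  =========================================================================
id     model
=====  =========================================================================
M1     traditional standardization: ln(catch/100 trap-days + 1) ~ Treatment,
       Gaussian errors, fitted at the replicate level.
M2     known seasonality, Gaussian: ln(abundance + 1) ~ Treatment
       + offset(ln seasonal %) + offset(ln surviving traps), at the
       replicate x interval level.
M3     unknown seasonality, Gaussian: ln(abundance + 1) ~ Treatment
       + Interval factor + offset(ln surviving traps).
M4     known seasonality, negative binomial GLM (log link): abundance ~
       Treatment + offset(ln seasonal %) + offset(ln surviving traps).
M5     unknown seasonality, negative binomial GLM: abundance ~ Treatment
       + Interval factor + offset(ln surviving traps).
=====  =========================================================================

All five return per-treatment predictions normalized to the same scale —
the expected catch per 100 trap-days of a full-effort replicate — so their
biases are directly comparable.  For M2–M5 the linear predictor is
evaluated per interval at the full trap count, back-transformed per
interval (``exp(eta) - 1`` for the Gaussian ln(x+1) models, ``exp(eta)``
for the NB models), summed over the season and divided by the number of
traps.

The NB dispersion ("size", theta; variance mu + mu^2/theta) is estimated
by alternating between the GLM regression coefficients at fixed theta and
the maximum-likelihood theta at fixed means, until theta stabilises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .simulate import Dataset, SeasonalProfile
from .standardize import summarize_replicates

__all__ = [
    "MODEL_IDS",
    "ModelFit",
    "ModelFitError",
    "build_analysis_table",
    "fit_m1",
    "fit_m2",
    "fit_m3",
    "fit_m4",
    "fit_m5",
    "fit_all",
    "fit_negbin_glm",
]

MODEL_IDS = (
    "M1_trad_normal",
    "M2_offset_normal",
    "M3_factor_normal",
    "M4_offset_negbin",
    "M5_factor_negbin",
)

THETA_MIN = 1e-3
THETA_MAX = 1e6
PRED_FLOOR = 1e-12


class ModelFitError(RuntimeError):
    """A model cannot be fitted to the (loss-manipulated) data at hand."""


@dataclass
class ModelFit:
    """Result of one analysis on one dataset.

    ``log_predictions`` holds one value per treatment on the log scale,
    normalized to the common season scale (catch per 100 trap-days of a
    full-effort replicate).  ``treatment_effects`` are the raw fitted
    treatment coefficients on the model's own scale; ``interval_effects``
    the interval-factor coefficients (first interval as reference) for the
    factor models, ``None`` otherwise.  ``dispersion`` is the NB size
    parameter where applicable.
    """

    model_id: str
    log_predictions: np.ndarray
    treatment_effects: np.ndarray
    interval_effects: np.ndarray | None = None
    converged: bool = True
    dispersion: float | None = None
    n_dropped: int = 0
    flags: tuple[str, ...] = ()


def build_analysis_table(dataset: Dataset, profile: SeasonalProfile | None = None) -> pd.DataFrame:
    """Aggregate a dataset to the replicate x interval grain used by M2–M5.

    ``abundance`` is the count summed over the surviving traps of the
    replicate in that interval and ``n_traps`` the number of surviving traps
    (0–4); combinations where every trap was lost are absent from the table
    (their log-traps offset is undefined) and counted in ``attrs['n_dropped']``.
    ``seasonal_pct`` carries the profile percentage of the interval.
    """
    p = dataset.params
    profile = profile or p.seasonal_profile
    alive = dataset.surviving()
    table = alive.groupby(["treatment", "replicate", "interval"], as_index=False).agg(
        abundance=("count", "sum"), n_traps=("count", "size")
    )
    pct = {i + 1: 100.0 * prop for i, prop in enumerate(profile.proportions)}
    table["seasonal_pct"] = table["interval"].map(pct)
    table.attrs["n_dropped"] = p.n_treatments * p.n_replicates * p.n_intervals - len(table)
    table.attrs["n_traps_full"] = p.n_traps
    table.attrs["percents"] = profile.percents
    table.attrs["n_treatments"] = p.n_treatments
    return table


# ---------------------------------------------------------------------------
# shared helpers


def _treatments(table: pd.DataFrame) -> np.ndarray:
    n_treat = table.attrs.get("n_treatments", int(table["treatment"].max()))
    present = set(table["treatment"])
    missing = set(range(1, n_treat + 1)) - present
    if missing:
        raise ModelFitError(f"treatments {sorted(missing)} have no surviving observations")
    return np.arange(1, n_treat + 1)

def _percents(table: pd.DataFrame) -> np.ndarray:
    pcts = table.attrs.get("percents")
    if pcts is None:  # reconstruct from the rows if every interval is present
        by_interval = table.drop_duplicates("interval").set_index("interval")["seasonal_pct"]
        if len(by_interval) != 5:
            raise ModelFitError("cannot reconstruct the seasonal profile from the table")
        pcts = by_interval.sort_index().to_numpy()
    pcts = np.asarray(pcts, dtype=float)
    if np.any(pcts <= 0):
        raise ModelFitError("seasonal offsets require strictly positive profile percentages")
    return pcts


def _dummies(labels: np.ndarray, levels: np.ndarray) -> np.ndarray:
    return (labels[:, None] == levels[None, :]).astype(float)


def _season_log_predictions(eta: np.ndarray, n_traps_full: int, gaussian: bool) -> tuple[np.ndarray, tuple[str, ...]]:
    """Collapse the full-effort linear predictor eta[treatment, interval] to
    one log prediction per treatment on the per-100-trap-day scale."""
    per_interval = np.expm1(eta) if gaussian else np.exp(eta)
    season = per_interval.sum(axis=1) / n_traps_full
    flags = tuple(f"floored_treatment_{t + 1}" for t in np.nonzero(season <= PRED_FLOOR)[0])
    return np.log(np.maximum(season, PRED_FLOOR)), flags


# ---------------------------------------------------------------------------
# M1: traditional standardization


def fit_m1(replicates: pd.DataFrame) -> ModelFit:
    """Gaussian linear model of ln(standardized catch + 1) on the treatment
    factor, fitted to the per-replicate standardized catches.

    The fitted treatment mean mu is back-transformed as exp(mu) - 1; a
    non-positive back-transform is floored at a machine-small value and
    flagged.
    """
    y = np.log1p(replicates["standardized_catch"].to_numpy(dtype=float))
    levels = np.sort(replicates["treatment"].unique())
    X = _dummies(replicates["treatment"].to_numpy(), levels)
    res = sm.OLS(y, X).fit()
    mu = np.asarray(res.params, dtype=float)
    pred = np.expm1(mu)
    flags = tuple(f"floored_treatment_{t}" for t in levels[pred <= PRED_FLOOR])
    return ModelFit(
        model_id="M1_trad_normal",
        log_predictions=np.log(np.maximum(pred, PRED_FLOOR)),
        treatment_effects=mu,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# M2 / M3: Gaussian models at the replicate x interval grain


def fit_m2(table: pd.DataFrame, profile: SeasonalProfile | None = None) -> ModelFit:
    """Known-seasonality Gaussian model: ln(abundance + 1) on the treatment
    factor with ln(seasonal %) and ln(surviving traps) as offsets.

    Offsets enter with coefficient one, so they are subtracted from the
    response before ordinary least squares — the exact Gaussian treatment.
    """
    levels = _treatments(table)
    pcts = np.asarray(profile.percents, float) if profile else _percents(table)
    if np.any(table["seasonal_pct"].to_numpy() <= 0):
        raise ModelFitError("seasonal offsets require strictly positive profile percentages")
    offset = np.log(table["seasonal_pct"].to_numpy(float)) + np.log(table["n_traps"].to_numpy(float))
    y = np.log1p(table["abundance"].to_numpy(float)) - offset
    X = _dummies(table["treatment"].to_numpy(), levels)
    alpha = np.asarray(sm.OLS(y, X).fit().params, dtype=float)
    nfull = table.attrs.get("n_traps_full", 4)
    eta = alpha[:, None] + np.log(pcts)[None, :] + np.log(nfull)
    log_pred, flags = _season_log_predictions(eta, nfull, gaussian=True)
    return ModelFit(
        model_id="M2_offset_normal",
        log_predictions=log_pred,
        treatment_effects=alpha,
        n_dropped=table.attrs.get("n_dropped", 0),
        flags=flags,
    )


def fit_m3(table: pd.DataFrame) -> ModelFit:
    """Unknown-seasonality Gaussian model: ln(abundance + 1) on treatment and
    a five-level interval factor, with ln(surviving traps) as offset.

    Season-scale predictions aggregate the estimated interval effects: the
    linear predictor is evaluated per interval at full effort, each interval
    back-transformed, and the season summed.
    """
    levels = _treatments(table)
    intervals = np.arange(1, 6)
    if set(table["interval"]) != set(intervals):
        raise ModelFitError("an interval level has no surviving observations")
    offset = np.log(table["n_traps"].to_numpy(float))
    y = np.log1p(table["abundance"].to_numpy(float)) - offset
    Xt = _dummies(table["treatment"].to_numpy(), levels)
    Xi = _dummies(table["interval"].to_numpy(), intervals[1:])  # interval 1 = reference
    coefs = np.asarray(sm.OLS(y, np.hstack([Xt, Xi])).fit().params, dtype=float)
    alpha, gamma = coefs[: len(levels)], np.concatenate([[0.0], coefs[len(levels):]])
    nfull = table.attrs.get("n_traps_full", 4)
    eta = alpha[:, None] + gamma[None, :] + np.log(nfull)
    log_pred, flags = _season_log_predictions(eta, nfull, gaussian=True)
    return ModelFit(
        model_id="M3_factor_normal",
        log_predictions=log_pred,
        treatment_effects=alpha,
        interval_effects=gamma,
        n_dropped=table.attrs.get("n_dropped", 0),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# negative binomial GLM with alternating theta estimation


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(stats.nbinom.logpmf(y, theta, theta / (theta + mu)).sum())


def _theta_score(y: np.ndarray, mu: np.ndarray, th: float) -> float:
    return float(
        np.sum(
            special.digamma(y + th)
            - special.digamma(th)
            + np.log(th)
            - np.log(th + mu)
            + 1.0
            - (y + th) / (th + mu)
        )
    )


def _ml_theta(y: np.ndarray, mu: np.ndarray, theta0: float | None = None) -> float:
    """Maximum-likelihood NB size parameter at fixed means.

    A positive score at the cap (data no more dispersed than Poisson) returns
    THETA_MAX; otherwise Newton's method on the score equation, seeded from
    ``theta0`` or a coarse bounded search, polished to near machine precision.
    """
    if _theta_score(y, mu, THETA_MAX) >= 0.0:
        return THETA_MAX
    if _theta_score(y, mu, THETA_MIN) <= 0.0:
        return THETA_MIN
    if theta0 is None or not THETA_MIN < theta0 < THETA_MAX:
        res = optimize.minimize_scalar(
            lambda lt: -_nb_loglik(y, mu, np.exp(lt)),
            bounds=(np.log(THETA_MIN), np.log(THETA_MAX)),
            method="bounded",
            options={"xatol": 1e-3},
        )
        theta0 = float(np.exp(res.x))
    th = theta0
    for _ in range(100):
        score = _theta_score(y, mu, th)
        info = float(
            np.sum(
                special.polygamma(1, y + th)
                - special.polygamma(1, th)
                + 1.0 / th
                - 2.0 / (th + mu)
                + (y + th) / (th + mu) ** 2
            )
        )
        new = th - score / info if info != 0.0 else th
        if not np.isfinite(new) or new <= 0.0:
            new = th / 2.0
        new = min(max(new, THETA_MIN), THETA_MAX)
        if abs(new - th) < 1e-12 * max(1.0, th):
            return new
        th = new
    return th


def fit_negbin_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    theta_tol: float = 1e-8,
    max_outer: int = 50,
) -> tuple[np.ndarray, float, bool, tuple[str, ...]]:
    """Negative binomial GLM (log link) with the size parameter estimated by
    maximum likelihood.

    Starting from the Poisson fit, the algorithm alternates between (a) the
    GLM coefficients at fixed theta and (b) the ML theta at fixed fitted
    means, until theta changes by less than ``theta_tol`` (relative for
    theta > 1) or ``max_outer`` iterations.  Near-Poisson data drive theta to
    the cap of 1e6, which is flagged but treated as converged.

    Returns (coefficients, theta, converged, flags).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ModelFitError("negative binomial response must be non-negative integers")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        beta, mu = np.asarray(pois.params), np.asarray(pois.mu)
        theta = _ml_theta(y, mu)
        converged = False
        for _ in range(max_outer):
            fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
            res = sm.GLM(y, X, family=fam, offset=offset).fit(
                start_params=beta, tol=1e-10, maxiter=200
            )
            beta, mu = np.asarray(res.params), np.asarray(res.mu)
            theta_new = _ml_theta(y, mu, theta0=theta)
            if abs(theta_new - theta) < theta_tol * max(1.0, theta):
                theta = theta_new
                converged = True
                break
            theta = theta_new
    flags: tuple[str, ...] = ()
    if theta >= THETA_MAX * (1.0 - 1e-6):
        theta = THETA_MAX
        flags = ("theta_capped",)
        converged = True
    if not np.all(np.isfinite(beta)):
        raise ModelFitError("negative binomial coefficients diverged")
    return beta, theta, converged, flags


def fit_m4(table: pd.DataFrame, profile: SeasonalProfile | None = None) -> ModelFit:
    """Known-seasonality negative binomial GLM: abundance on the treatment
    factor with ln(seasonal %) and ln(surviving traps) offsets."""
    levels = _treatments(table)
    if (table.groupby("treatment")["abundance"].sum() == 0).any():
        raise ModelFitError("a treatment caught no individuals; NB mean is degenerate")
    pcts = np.asarray(profile.percents, float) if profile else _percents(table)
    if np.any(table["seasonal_pct"].to_numpy() <= 0):
        raise ModelFitError("seasonal offsets require strictly positive profile percentages")
    offset = np.log(table["seasonal_pct"].to_numpy(float)) + np.log(table["n_traps"].to_numpy(float))
    X = _dummies(table["treatment"].to_numpy(), levels)
    alpha, theta, conv, flags = fit_negbin_glm(table["abundance"].to_numpy(float), X, offset)
    nfull = table.attrs.get("n_traps_full", 4)
    eta = alpha[:, None] + np.log(pcts)[None, :] + np.log(nfull)
    log_pred, pred_flags = _season_log_predictions(eta, nfull, gaussian=False)
    return ModelFit(
        model_id="M4_offset_negbin",
        log_predictions=log_pred,
        treatment_effects=alpha,
        converged=conv,
        dispersion=theta,
        n_dropped=table.attrs.get("n_dropped", 0),
        flags=flags + pred_flags,
    )


def fit_m5(table: pd.DataFrame) -> ModelFit:
    """Unknown-seasonality negative binomial GLM: abundance on treatment and
    a five-level interval factor, with ln(surviving traps) offset."""
    levels = _treatments(table)
    intervals = np.arange(1, 6)
    if set(table["interval"]) != set(intervals):
        raise ModelFitError("an interval level has no surviving observations")
    if (table.groupby("treatment")["abundance"].sum() == 0).any():
        raise ModelFitError("a treatment caught no individuals; NB mean is degenerate")
    offset = np.log(table["n_traps"].to_numpy(float))
    Xt = _dummies(table["treatment"].to_numpy(), levels)
    Xi = _dummies(table["interval"].to_numpy(), intervals[1:])
    coefs, theta, conv, flags = fit_negbin_glm(
        table["abundance"].to_numpy(float), np.hstack([Xt, Xi]), offset
    )
    alpha, gamma = coefs[: len(levels)], np.concatenate([[0.0], coefs[len(levels):]])
    nfull = table.attrs.get("n_traps_full", 4)
    eta = alpha[:, None] + gamma[None, :] + np.log(nfull)
    log_pred, pred_flags = _season_log_predictions(eta, nfull, gaussian=False)
    return ModelFit(
        model_id="M5_factor_negbin",
        log_predictions=log_pred,
        treatment_effects=alpha,
        interval_effects=gamma,
        converged=conv,
        dispersion=theta,
        n_dropped=table.attrs.get("n_dropped", 0),
        flags=flags + pred_flags,
    )


def fit_all(dataset: Dataset, models: tuple[str, ...] = MODEL_IDS) -> dict[str, ModelFit]:
    """Fit the requested analyses to one (possibly loss-manipulated) dataset.

    Raises :class:`ModelFitError` from the individual fits; callers running
    simulation grids catch it and record the replicate as failed.
    """
    fits: dict[str, ModelFit] = {}
    if "M1_trad_normal" in models:
        fits["M1_trad_normal"] = fit_m1(summarize_replicates(dataset))
    if set(models) - {"M1_trad_normal"}:
        table = build_analysis_table(dataset)
        dispatch = {
            "M2_offset_normal": fit_m2,
            "M3_factor_normal": fit_m3,
            "M4_offset_negbin": fit_m4,
            "M5_factor_negbin": fit_m5,
        }
        for mid in models:
            if mid in dispatch:
                fits[mid] = dispatch[mid](table)
    return fits
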