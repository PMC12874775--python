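"""Goodness-of-fit panel: likelihood criteria and predictive skill scores.

AIC = −2·ℓ + 2k and BIC = −2·ℓ + k·log(n) with ℓ the log-likelihood; RMSE
and Nash–Sutcliffe efficiency (NSE = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²) plus their
scale-free companions NRMSE = RMSE/SD(y) and MAE/SD.  Edge-level
predictions are conditional means ŷ = E[V | U = u] computed from the
fitted copula's h-function on the pseudo-observation scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .copula_core import CopulaParams, get_family

__all__ = ["FitMetrics", "information_criteria", "predict_edge",
           "prediction_metrics", "edge_fit_metrics"]


@dataclass(frozen=True)
class FitMetrics:
    loglik: float = float("nan")
    aic: float = float("nan")
    bic: float = float("nan")
    rmse: float = float("nan")
    nse: float = float("nan")
    nrmse: float = float("nan")
    mae_sd: float = float("nan")
    n: int = 0
    k: int = 0


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """(AIC, BIC) from a log-likelihood, parameter count and sample size."""
    if n < 1:
        raise ValueError("n must be >= 1")
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * math.log(n)
    return aic, bic


def predict_edge(pseudo_u, params: CopulaParams, n_grid: int = 64) -> np.ndarray:
    """Conditional-mean prediction v̂ = E[V | U = u] for each pseudo-value u.

    Uses E[V|u] = 1 − ∫₀¹ h(v|u) dv evaluated by Gauss–Legendre quadrature
    of the conditional CDF (h-function); outputs lie in (0, 1).
    """
    fam = get_family(params.family)
    u = np.asarray(pseudo_u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("pseudo_u must be interior to (0,1)")
    nodes, wts = np.polynomial.legendre.leggauss(n_grid)
    v = 0.5 * (nodes + 1.0)  # map [-1,1] -> (0,1)
    w = 0.5 * wts
    H = fam.hfunc(v[None, :], u[:, None], params.theta)  # (n, n_grid)
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("conditional CDF returned non-finite values")
    pred = 1.0 - H @ w
    return np.clip(pred, 1e-12, 1.0 - 1e-12)


def prediction_metrics(observed, predicted) -> FitMetrics:
    """RMSE, NSE, NRMSE = RMSE/SD, MAE/SD for a prediction vector.

    SD uses the n−1 denominator.  NSE = 1 at perfect prediction, 0 for the
    mean predictor; constant observed vectors are rejected (NSE undefined).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("observed and predicted must be equal-length vectors (n >= 2)")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("degenerate input: constant observed vector (NSE undefined)")
    err = y - yhat
    rmse = float(np.sqrt(np.mean(err ** 2)))
    nse = 1.0 - float(np.sum(err ** 2)) / ss_tot
    sd = float(np.std(y, ddof=1))
    return FitMetrics(
        rmse=rmse,
        nse=nse,
        nrmse=rmse / sd,
        mae_sd=float(np.mean(np.abs(err))) / sd,
        n=len(y),
    )


def edge_fit_metrics(pseudo_u, pseudo_v, params: CopulaParams) -> FitMetrics:
    """Full metric panel for one fitted edge: likelihood criteria for the
    copula plus predictive skill of the conditional-mean rule."""
    from .parameter_learning import edge_loglik

    u = np.clip(np.asarray(pseudo_u, dtype=float), 1e-10, 1 - 1e-10)
    v = np.clip(np.asarray(pseudo_v, dtype=float), 1e-10, 1 - 1e-10)
    fam = get_family(params.family)
    ll = edge_loglik(u, v, params)
    aic, bic = information_criteria(ll, fam.n_params, len(u))
    pred = predict_edge(u, params)
    pm = prediction_metrics(v, pred)
    return FitMetrics(loglik=ll, aic=aic, bic=bic, rmse=pm.rmse, nse=pm.nse,
                      nrmse=pm.nrmse, mae_sd=pm.mae_sd, n=len(u),
                      k=fam.n_params)
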