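"""Hierarchical-Bayes view of linear stacking.

Each of the ``T`` trees of a random forest yields a prediction
``Z_j ~ Normal(beta * mu, sigma2)`` of the target ``mu = E(Y | x)``, where
``beta`` is the multiplicative finite-sample bias (``beta > 1``:
overprediction; ``0 < beta < 1``: underprediction).  A second model supplies
the prior ``mu ~ Normal(mu_m, tau2)``.  Conditionally on the variance
parameters the posterior of ``mu`` is Normal with

    nu2    = (1/tau2 + T beta^2 / sigma2)^(-1)
    lambda = [T beta tau2 / (sigma2 + T beta^2 tau2)] Zbar
             + [sigma2 / (sigma2 + T beta^2 tau2)] mu_m

so the Bayes estimate under squared-error loss is itself a linear
combination of the forest mean ``Zbar`` and the other model's output — the
linear stacking estimator.  The debiasing behaviour depends on the variance
condition ``sigma2 << tau2`` and on ``C = T tau2 / sigma2``:

* ``sigma2 << tau2`` and ``beta > 1``: lambda ~= Zbar / beta — the stack
  downweights an overpredicting forest;
* ``sigma2 << tau2`` and ``beta < 1`` with ``C beta <= 1``: the stack
  underweights the forest and mixes in a non-trivial fraction of ``mu_m``
  (as ``beta -> 0`` the prediction is ``mu_m`` alone);
* ``sigma2 << tau2`` and ``beta < 1`` with ``C beta >> 1``: the stack
  upweights the forest with minimal ``mu_m`` contribution;
* ``sigma2`` comparable to or larger than ``tau2``: the debiasing effect is
  ambiguous.

The additive bias ``alpha`` is kept as a field (default 0, the assumption
under which the closed forms hold); in the regression view of stacking the
fitted intercept estimates the average additive bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BayesStackParams",
    "PosteriorSummary",
    "posterior",
    "posterior_quadrature",
    "regime_report",
    "RegimeReport",
]


@dataclass(frozen=True)
class BayesStackParams:
    """Parameters of the hierarchical stacking model."""

    T: int
    beta: float
    sigma2: float
    tau2: float
    Zbar: float
    mu_m: float
    alpha: float = 0.0

    def validate(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.sigma2 <= 0 or self.tau2 <= 0:
            raise ValueError("sigma2 and tau2 must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.alpha != 0.0:
            raise NotImplementedError(
                "closed-form posterior implemented for alpha = 0 only"
            )


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean/variance of mu and the mixing weights.

    ``weight_rf`` multiplies ``Zbar`` and ``weight_prior`` multiplies
    ``mu_m`` in the posterior mean; the two sum to 1 exactly when
    ``beta = 1``.
    """

    lam: float
    nu2: float
    weight_rf: float
    weight_prior: float


def posterior(params: BayesStackParams) -> PosteriorSummary:
    """Closed-form conjugate posterior of the target given forest and prior."""
    params.validate()
    T, b, s2, t2 = params.T, params.beta, params.sigma2, params.tau2
    nu2 = 1.0 / (1.0 / t2 + T * b * b / s2)
    denom = s2 + T * b * b * t2
    w_rf = T * b * t2 / denom
    w_prior = s2 / denom
    lam = w_rf * params.Zbar + w_prior * params.mu_m
    return PosteriorSummary(lam=lam, nu2=nu2, weight_rf=w_rf, weight_prior=w_prior)


def posterior_quadrature(
    params: BayesStackParams, n_grid: int = 40001, span_sds: float = 12.0
) -> PosteriorSummary:
    """Numeric posterior of mu by dense grid quadrature.

    An independent check of :func:`posterior`: the unnormalized posterior
    density ``exp(-T (Zbar - beta mu)^2 / (2 sigma2)) *
    exp(-(mu - mu_m)^2 / (2 tau2))`` is evaluated on a grid spanning both
    plausible centers (``Zbar/beta`` and ``mu_m``) padded by ``span_sds``
    standard deviations of the wider of the two components, then normalized
    to yield the posterior mean and variance.
    """
    params.validate()
    T, b, s2, t2 = params.T, params.beta, params.sigma2, params.tau2
    like_sd = np.sqrt(s2 / (T * b * b))
    sd = max(like_sd, np.sqrt(t2))
    lo = min(params.Zbar / b, params.mu_m) - span_sds * sd
    hi = max(params.Zbar / b, params.mu_m) + span_sds * sd
    mu = np.linspace(lo, hi, n_grid)
    log_post = (
        -T * (params.Zbar - b * mu) ** 2 / (2.0 * s2)
        - (mu - params.mu_m) ** 2 / (2.0 * t2)
    )
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    lam = float(np.sum(w * mu))
    nu2 = float(np.sum(w * (mu - lam) ** 2))
    post = posterior(params)
    return PosteriorSummary(lam=lam, nu2=nu2, weight_rf=post.weight_rf, weight_prior=post.weight_prior)


@dataclass(frozen=True)
class RegimeReport:
    """Qualitative debiasing regime and the posterior mixing weights."""

    label: str
    C: float  # T tau2 / sigma2
    weight_rf: float
    weight_prior: float


def regime_report(
    params: BayesStackParams,
    variance_ratio_threshold: float = 100.0,
    large_C_beta: float = 10.0,
) -> RegimeReport:
    """Classify the stacking regime implied by the parameters.

    The variance condition ``sigma2 << tau2`` is operationalized as
    ``tau2 / sigma2 >= variance_ratio_threshold``; within it the sign of
    ``beta - 1`` and the size of ``C beta`` distinguish the regimes
    described in the module docstring.
    """
    params.validate()
    post = posterior(params)
    C = params.T * params.tau2 / params.sigma2
    ratio = params.tau2 / params.sigma2
    if ratio < variance_ratio_threshold:
        label = "ambiguous"
    elif params.beta > 1.0:
        label = "overprediction-downweight"
    elif params.beta == 1.0:
        label = "unbiased-shrinkage"
    elif C * params.beta <= 1.0:
        label = "underprediction-prior-weighted"
    elif C * params.beta >= large_C_beta:
        label = "underprediction-rf-weighted"
    else:
        label = "underprediction-intermediate"
    return RegimeReport(
        label=label, C=C, weight_rf=post.weight_rf, weight_prior=post.weight_prior
    )
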