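"""Core task mathematics for the probability-estimation task.

This module holds the pieces that everything else is built on: the discrete
slider response grid, the logit transform and the additive (log-odds) form of
Bayes' theorem for two hypotheses, and the binarized quadratic scoring rule
together with its expected-value algebra.

The scoring rule works as follows.  A participant reports a probability
``pi`` that a questioned hidden state is true.  One trial is later selected
for payout; the participant keeps an endowment ``N`` unless they lose a
penalty ``W``, and the probability of losing is the squared report error
``(I - pi)**2`` where ``I`` indicates whether the questioned state was true.
Because the loss *probability* (not the loss amount) is quadratic in the
error, reporting the true posterior probability maximizes expected value
regardless of risk attitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SliderGrid",
    "make_slider_grid",
    "logit",
    "inv_logit",
    "likelihood_from_theta",
    "objective_posterior",
    "p_loss",
    "trial_ev",
    "ideal_ev",
    "subjective_ev",
    "snap_to_grid",
]


@dataclass(frozen=True)
class SliderGrid:
    """The discrete response scale: 33 probabilities from 0.02 to 0.98 in steps of 0.03.

    The grid deliberately excludes 0 and 1 (keeping every report's logit
    finite) and avoids "round" values that would invite anchoring.
    """

    values: np.ndarray = field(repr=False)
    step: float = 0.03
    lo: float = 0.02
    hi: float = 0.98

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != 33:
            raise ValueError("slider grid must have exactly 33 values")
        if not np.allclose(np.diff(v), self.step, atol=1e-12):
            raise ValueError("slider grid must be evenly spaced")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


def make_slider_grid() -> SliderGrid:
    """Build the response grid: ``values[k] = 0.02 + 0.03 * k`` for k = 0..32."""
    values = 0.02 + 0.03 * np.arange(33)
    return SliderGrid(values=values)


def logit(p):
    """Log odds ``ln(p / (1 - p))``; defined only on the open interval (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)) or np.any(np.isnan(p)):
        raise ValueError("logit requires 0 < p < 1")
    out = np.log(p) - np.log1p(-p)
    return out if out.ndim else float(out)

def inv_logit(z):
    """Exact inverse of :func:`logit`; maps the real line onto (0, 1)."""
    z = np.asarray(z, dtype=float)
    out = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))
    return out if out.ndim else float(out)


def likelihood_from_theta(theta, concordant):
    """Likelihood of the observed sample conditional on the questioned state.

    ``theta`` is the evidence strength (majority:minority picture ratio as a
    probability, 0.5 < theta < 1).  The likelihood is ``theta`` when the
    sample signals the questioned gallery (``concordant``) and ``1 - theta``
    otherwise.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta <= 0.5) | (theta >= 1.0)) or np.any(np.isnan(theta)):
        raise ValueError("evidence strength theta must lie in (0.5, 1)")
    concordant = np.asarray(concordant, dtype=bool)
    out = np.where(concordant, theta, 1.0 - theta)
    return out if out.ndim else float(out)


def objective_posterior(prior_q, likelihood_q):
    """Bayes' theorem for two complementary hypotheses.

    ``Pr(Q|x) = Pr(Q) Pr(x|Q) / (Pr(Q) Pr(x|Q) + (1-Pr(Q)) (1-Pr(x|Q)))``,
    equivalently ``inv_logit(logit(prior) + logit(likelihood))``: in log-odds
    space the posterior is simply the sum of prior and likelihood terms.
    """
    p = np.asarray(prior_q, dtype=float)
    l = np.asarray(likelihood_q, dtype=float)
    if np.any((p <= 0) | (p >= 1)) or np.any((l <= 0) | (l >= 1)):
        raise ValueError("objective_posterior requires arguments in (0, 1)")
    num = p * l
    out = num / (num + (1.0 - p) * (1.0 - l))
    return out if out.ndim else float(out)


def p_loss(outcome_I, report_pi):
    """Probability of losing the penalty: the squared report error ``(I - pi)**2``."""
    I = np.asarray(outcome_I, dtype=float)
    pi = np.asarray(report_pi, dtype=float)
    if np.any((I != 0) & (I != 1)):
        raise ValueError("outcome indicator must be 0 or 1")
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("report must lie in [0, 1]")
    out = (I - pi) ** 2
    return out if out.ndim else float(out)


def _check_money(endowment_N, penalty_W) -> None:
    if np.any(np.asarray(penalty_W, dtype=float) > np.asarray(endowment_N, dtype=float)):
        raise ValueError("penalty W must not exceed endowment N")


def trial_ev(report_pi, posterior_pr, endowment_N, penalty_W):
    """Expected trial value ``N - W (Pr - 2 Pr pi + pi**2)`` for report ``pi``.

    Equals the outcome enumeration ``sum_I P(I) (N - W (I - pi)**2)`` with
    ``P(I=1) = Pr``; maximized (over the reals) at ``pi = Pr``.
    """
    pi = np.asarray(report_pi, dtype=float)
    pr = np.asarray(posterior_pr, dtype=float)
    if np.any((pi < 0) | (pi > 1)) or np.any((pr < 0) | (pr > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    _check_money(endowment_N, penalty_W)
    out = endowment_N - penalty_W * (pr - 2.0 * pr * pi + pi**2)
    return out if np.ndim(out) else float(out)


def ideal_ev(posterior_pr, endowment_N, penalty_W):
    """Expected value when reporting the exact posterior: ``N - W Pr (1 - Pr)``."""
    pr = np.asarray(posterior_pr, dtype=float)
    if np.any((pr < 0) | (pr > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    _check_money(endowment_N, penalty_W)
    out = endowment_N - penalty_W * pr * (1.0 - pr)
    return out if np.ndim(out) else float(out)


def subjective_ev(report_pi, endowment_N, penalty_W):
    """Expected value a reporter assigns to their own report: ``N - W pi (1 - pi)``.

    Same functional form as :func:`ideal_ev` with the report standing in for
    the objective posterior.
    """
    return ideal_ev(report_pi, endowment_N, penalty_W)


def snap_to_grid(p, grid: SliderGrid):
    """Discretize a probability onto the response grid.

    Nearest grid value wins; exact midpoints round upward; values outside the
    grid range clamp to its endpoints.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probability must lie in [0, 1]")
    # floor(x + 0.5) rounds .5 up, unlike banker's rounding
    k = np.floor((p - grid.lo) / grid.step + 0.5).astype(int)
    k = np.clip(k, 0, grid.n - 1)
    out = grid.values[k]
    return out if p.ndim else float(out)
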