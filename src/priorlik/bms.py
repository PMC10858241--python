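"""Random-effects Bayesian model selection over per-participant log-evidences.

The population is modeled as a mixture over models: each participant's data
were generated by one model, drawn from unknown population frequencies ``r``
with a Dirichlet prior.  A variational scheme yields the Dirichlet posterior
``Dir(alpha)``; the exceedance probability (xp) of a model is the posterior
probability that it is the most frequent, estimated by Monte-Carlo sampling
of the Dirichlet.  The protected exceedance probability (pxp) blends xp with
chance through the Bayesian omnibus risk (bor), the posterior probability
that all models are equally frequent:

    pxp_k = xp_k * (1 - bor) + bor / K

Family-level comparison splits the prior mass equally across families and
equally within each family (so large families are not favored a priori) and
sums sampled frequencies within families.  Because the mean-field update is
unreliable for sub-unit Dirichlet counts (flat evidence then drifts toward
the smallest family), the family posterior is sampled exactly by a seeded
Gibbs sampler alternating model assignments and frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

__all__ = ["BMSResult", "bms", "family_xp"]


@dataclass
class BMSResult:
    models: list[str]
    alpha: np.ndarray
    expected_freq: np.ndarray
    xp: np.ndarray
    pxp: np.ndarray
    bor: float
    mc_samples: int
    seed: int
    prior_alpha: np.ndarray = field(repr=False, default=None)
    posterior_assignments: np.ndarray = field(repr=False, default=None)
    family_map: dict | None = None
    families: list[str] | None = None
    family_xp: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = dict(models=self.models, alpha=self.alpha.tolist(),
                 expected_freq=self.expected_freq.tolist(),
                 xp=self.xp.tolist(), pxp=self.pxp.tolist(), bor=self.bor,
                 mc_samples=self.mc_samples, seed=self.seed)
        if self.family_xp is not None:
            d.update(families=self.families, family_map=self.family_map,
                     family_xp=self.family_xp.tolist())
        return d


def _variational_dirichlet(log_ev: np.ndarray, alpha0: np.ndarray,
                           tol: float = 1e-6, max_iter: int = 10_000):
    """Variational updates for the Dirichlet posterior over model frequencies.

    Returns (alpha, g) where g[n, k] is the posterior probability that
    participant n's data came from model k.
    """
    n, K = log_ev.shape
    alpha = alpha0.astype(float).copy()
    g = np.full((n, K), 1.0 / K)
    for _ in range(max_iter):
        log_u = log_ev + (digamma(alpha) - digamma(alpha.sum()))
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, g


def _free_energy(log_ev: np.ndarray, alpha0: np.ndarray,
                 alpha: np.ndarray, g: np.ndarray) -> float:
    """Variational free energy of the random-effects (mixture) model."""
    E_log_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.nansum(g * np.log(np.where(g > 0, g, 1.0)))
    term_data = float(np.sum(g * log_ev))
    term_assign = float(np.sum(g * E_log_r))
    ln_B = lambda a: float(gammaln(a).sum() - gammaln(a.sum()))
    # E_q[ln p(r)] - E_q[ln q(r)]
    term_prior = -ln_B(alpha0) + float((alpha0 - 1) @ E_log_r)
    term_q = -ln_B(alpha) + float((alpha - 1) @ E_log_r)
    return term_data + term_assign + entropy + term_prior - term_q


def _f0_null(log_ev: np.ndarray) -> float:
    """Evidence of the null: all models equally frequent (r fixed at 1/K)."""
    K = log_ev.shape[1]
    return float(np.sum(logsumexp(log_ev, axis=1) - np.log(K)))


def _exceedance_mc(alpha: np.ndarray, mc_samples: int,
                   rng: np.random.Generator,
                   groups: np.ndarray | None = None) -> np.ndarray:
    """Monte-Carlo argmax frequencies of Dirichlet draws (optionally summed
    over model groups first).  Chunked to bound memory."""
    K = alpha.size
    n_out = K if groups is None else int(groups.max()) + 1
    counts = np.zeros(n_out)
    remaining = mc_samples
    while remaining > 0:
        m = min(remaining, 500_000)
        draws = rng.dirichlet(alpha, size=m)
        if groups is not None:
            summed = np.zeros((m, n_out))
            for k in range(K):
                summed[:, groups[k]] += draws[:, k]
            draws = summed
        idx, c = np.unique(np.argmax(draws, axis=1), return_counts=True)
        counts[idx] += c
        remaining -= m
    return counts / mc_samples


def _gibbs_frequency_samples(log_ev: np.ndarray, alpha0: np.ndarray,
                             n_samples: int, burn: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Exact posterior samples of model frequencies r by Gibbs sampling,
    alternating per-participant model assignments and Dir(alpha0 + counts)."""
    n, K = log_ev.shape
    L = log_ev - logsumexp(log_ev, axis=1, keepdims=True)
    m = np.argmax(log_ev, axis=1)
    draws = np.empty((n_samples, K))
    for t in range(burn + n_samples):
        counts = np.bincount(m, minlength=K)
        r = rng.dirichlet(alpha0 + counts)
        with np.errstate(divide="ignore"):
            logp = L + np.log(r)
        p = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
        m = (np.cumsum(p, axis=1) < rng.random(n)[:, None]).sum(axis=1)
        if t >= burn:
            draws[t - burn] = r
    return draws


def _as_matrix(evidence) -> tuple[np.ndarray, list[str]]:
    if isinstance(evidence, pd.DataFrame):
        return evidence.to_numpy(dtype=float), [str(c) for c in evidence.columns]
    arr = np.asarray(evidence, dtype=float)
    return arr, [f"m{k}" for k in range(arr.shape[1])]


def bms(evidence, prior_alpha: float | np.ndarray = 1.0,
        mc_samples: int = 1_000_000, seed: int = 0) -> BMSResult:
    """Random-effects Bayesian model selection.

    ``evidence``: participants x models array or DataFrame of log-evidences
    (e.g., -AIC/2 or -BIC/2).  Returns Dirichlet posterior parameters,
    expected model frequencies, exceedance and protected exceedance
    probabilities, and the Bayesian omnibus risk.
    """
    log_ev, models = _as_matrix(evidence)
    if log_ev.ndim != 2 or log_ev.shape[0] < 1 or log_ev.shape[1] < 2:
        raise ValueError("need >= 1 participant and >= 2 models")
    if not np.all(np.isfinite(log_ev)):
        raise ValueError("log-evidences must be finite")
    if mc_samples < 10_000:
        warnings.warn("fewer than 1e4 Monte-Carlo samples: exceedance "
                      "probabilities will be imprecise")
    K = log_ev.shape[1]
    alpha0 = np.full(K, float(prior_alpha)) if np.isscalar(prior_alpha) \
        else np.asarray(prior_alpha, dtype=float)

    alpha, g = _variational_dirichlet(log_ev, alpha0)
    rng = np.random.default_rng(seed)
    xp = _exceedance_mc(alpha, mc_samples, rng)

    f1 = _free_energy(log_ev, alpha0, alpha, g)
    f0 = _f0_null(log_ev)
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = xp * (1.0 - bor) + bor / K

    return BMSResult(
        models=models, alpha=alpha, expected_freq=alpha / alpha.sum(),
        xp=xp, pxp=pxp, bor=bor, mc_samples=mc_samples, seed=seed,
        prior_alpha=alpha0, posterior_assignments=g,
    )


def family_xp(evidence, partition: dict[str, str],
              mc_samples: int = 1_000_000, seed: int = 0,
              gibbs_samples: int = 10_000, gibbs_burn: int = 1_000) -> BMSResult:
    """Family-wise exceedance probabilities over a partition of model space.

    ``partition`` maps every model name to a family label.  The Dirichlet
    prior puts equal mass on each family, split equally among its members
    (total prior mass 1 per family), correcting for family size rather than
    simply adding member exceedance probabilities.  Frequencies are sampled
    from the exact posterior under that prior (Gibbs) and summed within
    families before taking the argmax.  Model-level xp/pxp/bor in the result
    come from the standard unit-prior variational analysis.
    """
    log_ev, models = _as_matrix(evidence)
    missing = [m for m in models if m not in partition]
    if missing:
        raise ValueError(f"partition does not cover models: {missing}")
    families = sorted(set(partition[m] for m in models))
    if len(families) < 2:
        raise ValueError("need at least 2 families")
    sizes = {f: sum(1 for m in models if partition[m] == f) for f in families}
    if min(sizes.values()) == 0:
        raise ValueError("empty family")
    groups = np.array([families.index(partition[m]) for m in models])
    alpha0 = np.array([1.0 / (len(families) * sizes[partition[m]]) for m in models])
    alpha0 *= len(models)  # total prior mass K, one unit-equivalent per model

    rng = np.random.default_rng(seed)
    draws = _gibbs_frequency_samples(log_ev, alpha0, gibbs_samples, gibbs_burn, rng)
    fam_sums = np.zeros((draws.shape[0], len(families)))
    for k in range(len(models)):
        fam_sums[:, groups[k]] += draws[:, k]
    counts = np.bincount(np.argmax(fam_sums, axis=1), minlength=len(families))
    fam_xp_ = counts / counts.sum()

    base = bms(evidence, prior_alpha=1.0, mc_samples=mc_samples, seed=seed)
    return BMSResult(
        models=models, alpha=base.alpha, expected_freq=base.expected_freq,
        xp=base.xp, pxp=base.pxp, bor=base.bor, mc_samples=mc_samples, seed=seed,
        prior_alpha=alpha0, posterior_assignments=base.posterior_assignments,
        family_map=dict(partition), families=families, family_xp=fam_xp_,
    )
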