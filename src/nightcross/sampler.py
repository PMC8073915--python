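"""Adaptive MCMC for the mixed-effects logistic crossing model.

The posterior is sampled with Metropolis-within-Gibbs in a non-centred
parameterisation: fixed effects and log sigma move jointly under an
adapted multivariate normal proposal (Haario-style covariance adaptation
with a global scale tuned toward ~25% acceptance), and the per-bird
standardised intercepts z_b move in parallel with independent per-bird
accept/reject steps (their full conditionals factorise over birds),
tuned toward ~44% acceptance.  Adaptation runs only during warmup, so
the retained chains are draws from a fixed Markov kernel.

Priors: coefficients Normal(0, 5^2) (weakly informative; wide enough to
be inert at these effect sizes yet proper under the near-separation
that small route-choice datasets invite), random-effect scale
half-Student-t(3, 0, 2.5).  A flat-coefficient variant is available as
a prior-sensitivity diagnostic.
"""

from __future__ import annotations

import math

import numpy as np

COEF_PRIOR_SD = 5.0
SIGMA_T_DF = 3.0
SIGMA_T_SCALE = 2.5


def _log1pexp(x):
    # stable log(1 + e^x)
    return np.logaddexp(0.0, x)


def _loglik_terms(y, eta):
    return y * eta - _log1pexp(eta)


def _log_prior_sigma(log_sigma: float) -> float:
    sigma = math.exp(log_sigma)
    # half-t density on sigma plus the log|d sigma / d log sigma| Jacobian
    return (
        -0.5 * (SIGMA_T_DF + 1.0)
        * math.log1p((sigma / SIGMA_T_SCALE) ** 2 / SIGMA_T_DF)
        + log_sigma
    )


def sample_logistic_mixed(
    y: np.ndarray,
    X: np.ndarray,
    bird_idx: np.ndarray,
    n_birds: int,
    chains: int = 4,
    iterations: int = 2000,
    seed: int | None = None,
    flat_priors: bool = False,
):
    """Posterior draws for logit P(y=1) = X beta + sigma * z[bird].

    ``iterations`` counts total per-chain iterations; the first half is
    warmup/adaptation and is discarded.  Returns a dict of arrays shaped
    (chains, kept, ...): ``beta``, ``sigma``, ``u`` (= sigma * z) plus
    the acceptance rates for diagnostics.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    bird_idx = np.asarray(bird_idx, int)
    n, p = X.shape
    if iterations < 20:
        raise ValueError("iterations too small to adapt and sample")
    warmup = iterations // 2
    keep = iterations - warmup
    rng = np.random.default_rng(seed)

    beta_out = np.empty((chains, keep, p))
    sigma_out = np.empty((chains, keep))
    u_out = np.empty((chains, keep, n_birds))
    acc_beta = np.zeros(chains)
    acc_z = np.zeros(chains)

    for c in range(chains):
        beta = rng.normal(0.0, 1.0, p)
        log_sigma = math.log(0.5) + rng.normal(0.0, 0.3)
        z = rng.normal(0.0, 0.5, n_birds)

        d = p + 1
        prop_cov = np.eye(d) * 0.1
        log_scale = 0.0
        step_ls = 0.5
        step_z = np.full(n_birds, 0.5)
        hist = np.zeros((warmup, d))
        n_acc_b = n_try_b = n_acc_z = n_try_z = 0

        def _joint_parts(beta, log_sigma, z):
            eta = X @ beta + math.exp(log_sigma) * z[bird_idx]
            ll = _loglik_terms(y, eta)
            lp = _log_prior_sigma(log_sigma)
            if not flat_priors:
                lp += -0.5 * float(beta @ beta) / COEF_PRIOR_SD**2
            return ll, lp

        ll, lp = _joint_parts(beta, log_sigma, z)
        ll_sum = float(ll.sum())

        for it in range(iterations):
            # --- block 1: (beta, log sigma) jointly --------------------
            theta = np.concatenate([beta, [log_sigma]])
            prop = theta + math.exp(log_scale) * rng.multivariate_normal(
                np.zeros(d), prop_cov
            )
            beta_p, log_sigma_p = prop[:p], float(prop[p])
            ll_p, lp_p = _joint_parts(beta_p, log_sigma_p, z)
            ll_p_sum = float(ll_p.sum())
            log_alpha = (ll_p_sum + lp_p) - (ll_sum + lp)
            accept = math.log(rng.uniform()) < log_alpha
            if accept:
                beta, log_sigma, ll, ll_sum, lp = beta_p, log_sigma_p, ll_p, ll_p_sum, lp_p
            n_try_b += 1
            n_acc_b += accept

            # --- block 1b: single-site log sigma (helps sigma mixing) --
            ls_p = log_sigma + step_ls * rng.normal()
            ll_p, lp_p = _joint_parts(beta, ls_p, z)
            ll_p_sum = float(ll_p.sum())
            acc_ls = math.log(rng.uniform()) < (ll_p_sum + lp_p) - (ll_sum + lp)
            if acc_ls:
                log_sigma, ll, ll_sum, lp = ls_p, ll_p, ll_p_sum, lp_p

            # --- block 2: all z_b in parallel --------------------------
            sigma = math.exp(log_sigma)
            z_p = z + step_z * rng.normal(0.0, 1.0, n_birds)
            eta_base = X @ beta
            ll_cur = _loglik_terms(y, eta_base + sigma * z[bird_idx])
            ll_new = _loglik_terms(y, eta_base + sigma * z_p[bird_idx])
            d_ll = np.bincount(bird_idx, weights=ll_new - ll_cur, minlength=n_birds)
            d_prior = -0.5 * (z_p**2 - z**2)
            acc_mask = np.log(rng.uniform(size=n_birds)) < d_ll + d_prior
            z = np.where(acc_mask, z_p, z)
            n_try_z += n_birds
            n_acc_z += int(acc_mask.sum())
            ll = _loglik_terms(y, eta_base + sigma * z[bird_idx])
            ll_sum = float(ll.sum())

            # --- adaptation (warmup only) ------------------------------
            if it < warmup:
                hist[it] = np.concatenate([beta, [log_sigma]])
                gamma = (it + 1) ** -0.6
                log_scale += gamma * ((1.0 if accept else 0.0) - 0.25)
                step_ls *= math.exp(gamma * ((1.0 if acc_ls else 0.0) - 0.44))
                step_z *= np.exp(gamma * (acc_mask.astype(float) - 0.44))
                if it >= 50 and (it + 1) % 25 == 0:
                    emp = np.cov(hist[: it + 1].T)
                    prop_cov = (2.38**2 / d) * (emp + 1e-6 * np.eye(d))
            else:
                k = it - warmup
                beta_out[c, k] = beta
                sigma_out[c, k] = math.exp(log_sigma)
                u_out[c, k] = math.exp(log_sigma) * z

        acc_beta[c] = n_acc_b / max(n_try_b, 1)
        acc_z[c] = n_acc_z / max(n_try_z, 1)

    return {
        "beta": beta_out,
        "sigma": sigma_out,
        "u": u_out,
        "accept_beta": acc_beta,
        "accept_z": acc_z,
    }
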