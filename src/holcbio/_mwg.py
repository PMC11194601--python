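"""Adaptive Metropolis-within-Gibbs kernel for the richness model.

Operates on a flat parameter vector in the sampler's working
parameterization: city effects are non-centered (standard-normal deviations
``z`` scaled by ``sigma``) and random-effect SDs are sampled on the log
scale with the change-of-variable Jacobian included, so the stationary
distribution is exactly the model posterior re-expressed in (z, log sigma).

Layout for C cities (P = 9 + 4C):
  theta[0]              global intercept b0
  theta[1:4]            grade effects b_B, b_C, b_D  (grade A is reference)
  theta[4]              impervious slope b_imp
  theta[5 + g*C + c]    deviation z for effect group g (0 = intercept,
                        1..3 = grade slope) and city c
  theta[5 + 4C + j]     log sigma_j for group j in 0..3
"""

import math

import numpy as np
from numba import njit

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@njit(cache=False)
def log_posterior_flat(
    theta, y, grade, city, x, offset, lgam, C,
    prior_sd, gamma_shape, gamma_rate, sig_mask, sig_val,
):
    """Unnormalized log posterior in the working parameterization."""
    b0 = theta[0]
    bimp = theta[4]

    sig = np.empty(4)
    lp = 0.0
    for j in range(4):
        if sig_mask[j]:
            sig[j] = sig_val[j]
        else:
            s = theta[5 + 4 * C + j]
            if s > 50.0:  # exp would overflow; reject
                return -np.inf
            sig[j] = math.exp(s)
            # Gamma(shape, rate) prior on sigma plus log-Jacobian d sigma/d s
            lp += (
                gamma_shape * math.log(gamma_rate)
                - math.lgamma(gamma_shape)
                + (gamma_shape - 1.0) * s
                - gamma_rate * sig[j]
                + s
            )

    for j in range(5):  # Normal(0, prior_sd) on the fixed effects
        lp += (
            -0.5 * (theta[j] / prior_sd) ** 2
            - math.log(prior_sd)
            - _LOG_SQRT_2PI
        )
    for j in range(5, 5 + 4 * C):  # standard-normal deviations
        lp += -0.5 * theta[j] * theta[j] - _LOG_SQRT_2PI

    ll = 0.0
    for i in range(y.shape[0]):
        g = grade[i]
        c = city[i]
        eta = offset[i] + b0 + sig[0] * theta[5 + c] + bimp * x[i]
        if g > 0:
            eta += theta[g] + sig[g] * theta[5 + g * C + c]
        if eta > 500.0:
            return -np.inf
        ll += y[i] * eta - math.exp(eta) - lgam[i]
    return lp + ll


@njit(cache=False)
def run_chain(
    theta0, n_burn, n_samp, seed,
    y, grade, city, x, offset, lgam, C,
    prior_sd, gamma_shape, gamma_rate, sig_mask, sig_val, update_mask,
    blk_mean0, blk_cov0,
):
    """One MCMC chain: single-site random-walk updates plus likelihood-
    invariant interweaving moves, with Robbins-Monro scale adaptation during
    burn-in (target acceptance 0.44), frozen afterwards.

    The interweaving moves handle the near-nonidentified directions of the
    hierarchical posterior: a joint translation of an effect and its city
    deviations (b -> b + d, z -> z - d/sigma leaves every eta unchanged) and
    a joint rescaling of a deviation SD and its deviations
    (log sigma -> log sigma + d, z -> z exp(-d)), which decorrelates the
    sigma-z funnel. Both have acceptance ratios involving only the priors
    (and, for the rescaling, the proposal Jacobian exp(-C d)).

    Returns (samples, scales, acceptance_rates).
    """
    np.random.seed(seed)
    P = theta0.shape[0]
    theta = theta0.copy()
    scales = np.full(P, 0.2)
    # interweaving move scales: 4 translation + 4 rescaling (one per group)
    iw_scales = np.full(8, 0.3)
    iw_acc = np.zeros(8)
    # adaptive-Metropolis block for the 5 fixed effects (impervious surface
    # is grade-structured, so b_imp and the grade effects are collinear and
    # need a correlated joint proposal). The moments are seeded with a
    # Laplace-approximation covariance so the weakly identified direction is
    # proposed correctly from the start.
    blk_pseudo = 1000
    blk_mean = blk_mean0.copy()
    blk_m2 = blk_cov0 * (blk_pseudo - 1.0)
    blk_seen = blk_pseudo
    blk_L = np.linalg.cholesky((2.38**2 / 5.0) * blk_cov0)
    blk_scale = 1.0
    blk_acc = 0.0
    lp = log_posterior_flat(
        theta, y, grade, city, x, offset, lgam, C,
        prior_sd, gamma_shape, gamma_rate, sig_mask, sig_val,
    )
    samples = np.empty((n_samp, P))
    acc_batch = np.zeros(P)
    acc_total = np.zeros(P)
    n_kept = 0
    batch_len = 50
    n_batches = 0
    for it in range(n_burn + n_samp):
        for j in range(P):
            if not update_mask[j]:
                continue
            old = theta[j]
            theta[j] = old + scales[j] * np.random.normal()
            lp_new = log_posterior_flat(
                theta, y, grade, city, x, offset, lgam, C,
                prior_sd, gamma_shape, gamma_rate, sig_mask, sig_val,
            )
            if math.log(np.random.random()) < lp_new - lp:
                lp = lp_new
                acc_batch[j] += 1.0
                if it >= n_burn:
                    acc_total[j] += 1.0
            else:
                theta[j] = old

        # --- joint updates of the fixed-effect block ---
        for _rep in range(20):
            old_block = theta[0:5].copy()
            step = np.empty(5)
            for j in range(5):
                step[j] = np.random.normal()
            theta[0:5] = old_block + blk_scale * (blk_L @ step)
            lp_new = log_posterior_flat(
                theta, y, grade, city, x, offset, lgam, C,
                prior_sd, gamma_shape, gamma_rate, sig_mask, sig_val,
            )
            if math.log(np.random.random()) < lp_new - lp:
                lp = lp_new
                blk_acc += 0.05
            else:
                theta[0:5] = old_block
        if it < n_burn:
            # running moments of the block for the adapted covariance
            blk_seen += 1
            delta_v = theta[0:5] - blk_mean
            blk_mean += delta_v / blk_seen
            blk_m2 += np.outer(delta_v, theta[0:5] - blk_mean)

        # --- interweaving moves (skip groups with pinned sigma) ---
        for g in range(4):
            if sig_mask[g]:
                continue
            sidx = 5 + 4 * C + g
            bidx = 0 if g == 0 else g
            sig_g = math.exp(theta[sidx])

            # translation: b += d, z -= d / sigma (eta invariant)
            d = iw_scales[g] * np.random.normal()
            b_old = theta[bidx]
            b_new = b_old + d
            dz = d / sig_g
            dlp = -0.5 * ((b_new / prior_sd) ** 2 - (b_old / prior_sd) ** 2)
            for c in range(C):
                z_old = theta[5 + g * C + c]
                z_new = z_old - dz
                dlp += -0.5 * (z_new * z_new - z_old * z_old)
            if math.log(np.random.random()) < dlp:
                theta[bidx] = b_new
                for c in range(C):
                    theta[5 + g * C + c] -= dz
                lp += dlp
                iw_acc[g] += 1.0

            # rescaling: log sigma += d, z *= exp(-d) (eta invariant)
            d = iw_scales[4 + g] * np.random.normal()
            s_old = theta[sidx]
            s_new = s_old + d
            if s_new < 50.0:
                scale = math.exp(-d)
                dlp = (
                    (gamma_shape - 1.0) * d
                    - gamma_rate * (math.exp(s_new) - math.exp(s_old))
                    + d  # Jacobian of the sigma -> log sigma prior transform
                    - C * d  # proposal Jacobian of rescaling C deviations
                )
                for c in range(C):
                    z_old = theta[5 + g * C + c]
                    z_new = z_old * scale
                    dlp += -0.5 * (z_new * z_new - z_old * z_old)
                if math.log(np.random.random()) < dlp:
                    theta[sidx] = s_new
                    for c in range(C):
                        theta[5 + g * C + c] *= scale
                    lp += dlp
                    iw_acc[4 + g] += 1.0

        if it < n_burn:
            if (it + 1) % batch_len == 0:
                n_batches += 1
                delta = min(0.3, 3.0 / math.sqrt(n_batches))
                for j in range(P):
                    rate = acc_batch[j] / batch_len
                    scales[j] *= math.exp(delta * (rate - 0.44))
                    acc_batch[j] = 0.0
                for j in range(8):
                    rate = iw_acc[j] / batch_len
                    iw_scales[j] *= math.exp(delta * (rate - 0.44))
                    iw_acc[j] = 0.0
                blk_scale *= math.exp(delta * (blk_acc / batch_len - 0.3))
                blk_acc = 0.0
                cov = blk_m2 / (blk_seen - 1)
                for j in range(5):
                    cov[j, j] += 1e-8
                blk_L = np.linalg.cholesky((2.38**2 / 5.0) * cov)
        else:
            samples[n_kept] = theta
            n_kept += 1
    denom = max(n_samp, 1)
    return samples, scales, acc_total / denom
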