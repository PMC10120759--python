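"""Independent oracles for the shrinkage posterior.

Deterministic grid integration of the joint density

    p(beta, sigma^2, delta, lambda | beta_hat)
      ∝ (sigma^2)^{-(N+M)/2 - 1} |Psi|^{-1/2}
        exp(-N/(2 sigma^2) [1 - 2 b'bhat + b'(D + Psi^{-1}) b])
        * prod C+(0,1) densities of delta and each lambda_j,

with beta and sigma^2 integrated analytically given the scales (Gaussian and
inverse-gamma marginals), leaving a low-dimensional quadrature over the
half-Cauchy scales via the CDF substitution delta = tan(pi*u/2) (which makes
the prior weight uniform in u). Entirely independent of the Gibbs code path.
"""

import numpy as np


def _weights_and_moments(beta_hat, D, n, psi_flat):
    """Marginal weight and conditional beta moments for each scale point.

    psi_flat: (npts, M) array of per-variant prior-variance products.
    Returns (logw, means (npts, M), covs (npts, M, M) scaled by sigma2/N
    expectation).
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    D = np.asarray(D, dtype=float)
    m = beta_hat.size
    npts = psi_flat.shape[0]
    A = np.broadcast_to(D, (npts, m, m)).copy()
    idx = np.arange(m)
    A[:, idx, idx] += 1.0 / psi_flat
    A_inv = np.linalg.inv(A)
    mean = np.einsum("pij,j->pi", A_inv, beta_hat)
    c = 1.0 - np.einsum("i,pi->p", beta_hat, mean)
    sign, logdet_A = np.linalg.slogdet(A)
    logw = (-0.5 * np.sum(np.log(psi_flat), axis=1)
            - 0.5 * logdet_A
            - 0.5 * n * np.log(c))
    e_sigma2 = (n * c / 2.0) / (n / 2.0 - 1.0)
    return logw, mean, A_inv, e_sigma2


def grid_posterior_1snp(beta_hat, n, ngrid=400):
    """Posterior mean/variance of beta for one SNP, one group (D = [1])."""
    u = (np.arange(ngrid) + 0.5) / ngrid
    scales = np.tan(np.pi * u / 2.0)
    d2, l2 = np.meshgrid(scales**2, scales**2, indexing="ij")
    psi = (d2 * l2).reshape(-1, 1)
    logw, mean, A_inv, e_s2 = _weights_and_moments(
        np.atleast_1d(beta_hat), np.eye(1), n, psi)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    e_beta = float(w @ mean[:, 0])
    e_beta2 = float(w @ (mean[:, 0]**2 + e_s2 * A_inv[:, 0, 0] / n))
    return e_beta, e_beta2 - e_beta**2


def grid_posterior_2snp(beta_hat, D, n, ngrid=60):
    """Posterior mean/variance of beta for two SNPs in one group.

    Quadrature over (delta, lambda_1, lambda_2)."""
    u = (np.arange(ngrid) + 0.5) / ngrid
    s = np.tan(np.pi * u / 2.0)
    d2, l2a, l2b = np.meshgrid(s**2, s**2, s**2, indexing="ij")
    psi = np.stack([(d2 * l2a).ravel(), (d2 * l2b).ravel()], axis=1)
    logw, mean, A_inv, e_s2 = _weights_and_moments(beta_hat, D, n, psi)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    e_beta = w @ mean
    var = np.empty(2)
    for j in range(2):
        e_b2 = w @ (mean[:, j]**2 + e_s2 * A_inv[:, j, j] / n)
        var[j] = e_b2 - e_beta[j]**2
    return e_beta, var
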