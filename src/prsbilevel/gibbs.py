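"""Bilevel continuous-shrinkage Gibbs sampler on GWAS summary statistics.

Model (standardized genotypes G, standardized phenotype y, N individuals):

    y | G, beta, sigma^2    ~  MVN(G beta, sigma^2 I)
    beta_j | sigma^2, ...   ~  N(0, sigma^2/N * delta^2_{A_j} * lambda^2_j)
    delta_k, lambda_j       ~  C+(0, 1)        p(sigma^2) ∝ sigma^-2

where A_j is the annotation group of copy j. With the LD matrix
D = G^T G / N and marginal effects beta_hat = G^T y / N from a GWAS, the
full conditionals depend on the data only through (beta_hat, D, N), so the
sampler runs from summary statistics alone. Each half-Cauchy scale is
decomposed as a scale mixture of inverse gammas,

    x^2 | a ~ IG(1/2, 1/a),   a ~ IG(1/2, 1)   =>   x ~ C+(0, 1),

giving conjugate inverse-gamma updates for delta^2_k (with auxiliary t_k)
and lambda^2_j (with auxiliary c_j). A variant in several annotation groups
is expanded into one copy per group; copies share the variant's row/column
of D and its beta_hat entry, and the variant's total effect is the sum of
its copies.

With a single group (K=1) the model reduces to the fully Bayesian
continuous-shrinkage PRS with a global half-Cauchy scale (the PRS-CS-auto
special case at gamma-gamma hyper-parameters a0 = 0.5, b0 = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.stats
from sklearn.base import BaseEstimator

from .annotation import assign_sentinel, expand_overlap
from .datatypes import (
    AnnotationMap,
    ExpandedDesign,
    LDBlock,
    PosteriorSummary,
    SummaryStats,
    ValidationError,
)

_PSI_FLOOR = 1e-30  # keeps 1/psi finite; far below any statistically relevant scale


@dataclass
class GibbsConfig:
    """Chain settings for the Gibbs sampler.

    ``shrink_cap`` clips the per-copy prior-variance product
    delta^2 * lambda^2 before the beta update (standard practice for
    summary-statistic horseshoe samplers; 1.0 bounds the prior variance of a
    standardized effect by sigma^2/N). ``lambda_conditional`` selects between
    the self-consistent conditionals ("derived", default) and the literal
    published forms ("as_printed"); see sample_lambda2/sample_delta2.
    """

    n_iter: int = 1000
    n_burnin: int = 500
    thin: int = 5
    seed: int = 0
    shrink_cap: float = 1.0
    lambda_conditional: str = "derived"

    def validate(self) -> None:
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValidationError("need n_iter > n_burnin >= 0")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.shrink_cap <= 0:
            raise ValidationError("shrink_cap must be positive")
        if self.lambda_conditional not in ("derived", "as_printed"):
            raise ValidationError(
                f"unknown lambda_conditional {self.lambda_conditional!r}")


def _inv_gamma(rng: np.random.Generator, shape, rate):
    """Draw from IG(shape, rate): density ∝ x^{-shape-1} exp(-rate/x)."""
    rate = np.asarray(rate, dtype=float)
    return rate / rng.standard_gamma(shape, size=rate.shape)


# ---------------------------------------------------------------------------
# full conditionals
# ---------------------------------------------------------------------------

def beta_conditional_moments(D, beta_hat, psi, sigma2, n):
    """Mean and covariance of beta | rest within one LD block.

    beta | .  ~  MVN( A^{-1} beta_hat,  sigma^2/N * A^{-1} ),
    A = D + diag(1/psi), psi the per-copy product delta^2 * lambda^2.
    """
    psi = np.maximum(np.asarray(psi, dtype=float), _PSI_FLOOR)
    A = np.asarray(D, dtype=float) + np.diag(1.0 / psi)
    A_inv = np.linalg.inv(A)
    mean = A_inv @ np.asarray(beta_hat, dtype=float)
    return mean, (sigma2 / n) * A_inv


def sample_beta_block(D, beta_hat, psi, sigma2, n, rng):
    """One MVN draw of the beta copies in an LD block (Cholesky based)."""
    psi = np.maximum(np.asarray(psi, dtype=float), _PSI_FLOOR)
    A = np.array(D, dtype=float)
    idx = np.arange(A.shape[0])
    A[idx, idx] += 1.0 / psi
    try:
        L, low = sla.cho_factor(A, lower=True, check_finite=False)
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise RuntimeError(
            "Cholesky factorization of D + diag(1/psi) failed; "
            "consider the LD ridge-repair flag") from err
    mean = sla.cho_solve((L, low), np.asarray(beta_hat, dtype=float),
                         check_finite=False)
    z = rng.standard_normal(A.shape[0])
    noise = sla.solve_triangular(L, z, lower=True, trans="T",
                                 check_finite=False)
    return mean + np.sqrt(sigma2 / n) * noise


def sigma2_rate(beta, beta_hat, D_beta, psi, n):
    """Rate of the sigma^2 conditional, N/2 * {1 - 2 b'bhat + b'[D+Psi^{-1}]b}."""
    beta = np.asarray(beta, dtype=float)
    psi = np.maximum(np.asarray(psi, dtype=float), _PSI_FLOOR)
    quad = float(beta @ np.asarray(D_beta, dtype=float)
                 + np.sum(beta * beta / psi))
    return 0.5 * n * (1.0 - 2.0 * float(beta @ np.asarray(beta_hat, float))
                      + quad)


def sample_sigma2(beta, beta_hat, D_beta, psi, n, m_prime, rng):
    """sigma^2 | .  ~  IG( (N + M')/2, rate ).

    The nominal rate N/2 * {1 - 2 b'bhat + b'[D+Psi^{-1}]b} can go negative
    when M' > N (the summary-statistic residual term overfits); it is floored
    at the prior quadratic term N/2 * sum(beta^2/psi) — the convention of
    summary-statistic continuous-shrinkage samplers — and at 1e-12.
    """
    beta_arr = np.asarray(beta, dtype=float)
    psi_arr = np.maximum(np.asarray(psi, dtype=float), _PSI_FLOOR)
    floor = 0.5 * n * float(np.sum(beta_arr * beta_arr / psi_arr))
    rate = max(sigma2_rate(beta, beta_hat, D_beta, psi, n), floor, 1e-12)
    return float(_inv_gamma(rng, 0.5 * (n + m_prime), np.array(rate)))


def sample_delta2(beta_copies_k, lambda2_copies_k, sigma2, t_k, n, rng,
                  mode: str = "derived"):
    """Group-level shrinkage delta^2_k | . ~ IG((M_k + 1)/2, rate).

    rate = sum_j N beta_j^2 / (2 sigma^2 lambda_j^2) + 1/t_k in mode
    "derived" (the full conditional implied by the auxiliary
    t_k | delta_k^2 ~ IG(1, delta_k^{-2} + 1)); mode "as_printed" adds t_k
    itself, as published.
    """
    beta = np.asarray(beta_copies_k, dtype=float)
    lam2 = np.asarray(lambda2_copies_k, dtype=float)
    m_k = beta.size
    ssum = float(np.sum(n * beta * beta / (2.0 * sigma2 * lam2))) if m_k else 0.0
    aux = 1.0 / t_k if mode == "derived" else t_k
    return float(_inv_gamma(rng, 0.5 * (m_k + 1), np.array(ssum + aux)))


def sample_t(delta2_k, rng):
    """Auxiliary t_k | delta_k^2 ~ IG(1, delta_k^{-2} + 1)."""
    rate = 1.0 / np.asarray(delta2_k, dtype=float) + 1.0
    return _inv_gamma(rng, 1.0, rate)


def sample_lambda2(beta_copy, sigma2, delta2_group, c_copy, n, rng,
                   mode: str = "derived"):
    """Local shrinkage lambda^2_j | . ~ IG(1, rate).

    mode "derived": rate = N beta_j^2 / (2 sigma^2 delta^2_{A_j}) + 1/c_j
    (full conditional of the stated joint prior); mode "as_printed":
    rate = N beta_j^2 / (2 sigma^2) + c_j, exactly as published.
    """
    beta = np.asarray(beta_copy, dtype=float)
    if mode == "derived":
        rate = n * beta * beta / (2.0 * sigma2 * np.asarray(delta2_group, float)) \
            + 1.0 / np.asarray(c_copy, dtype=float)
    else:
        rate = n * beta * beta / (2.0 * sigma2) + np.asarray(c_copy, dtype=float)
    return _inv_gamma(rng, 1.0, rate)


def sample_c(lambda2_copy, rng):
    """Auxiliary c_j | lambda_j^2 ~ IG(1, lambda_j^{-2} + 1)."""
    rate = 1.0 / np.asarray(lambda2_copy, dtype=float) + 1.0
    return _inv_gamma(rng, 1.0, rate)


def sample_delta2_interweave(psi_k, c_k, t_k, rng):
    """Resample delta^2_k along the non-identified scale direction.

    The likelihood constrains only the products psi_j = delta^2_k *
    lambda^2_j, so the delta/lambda split mixes poorly under the plain scan.
    Holding the products (and auxiliaries) fixed, the exact conditional of
    delta^2_k in the (delta^2, psi) parametrization is generalized inverse
    Gaussian:

        p(d) ∝ d^{(M_k-1)/2 - 1} exp(-S d - R / d),
        S = sum_j 1/(c_j psi_j),  R = 1/t_k,

    after which each lambda^2_j is deterministically psi_j / delta^2_k. This
    is a valid reparametrized Gibbs step: it leaves the joint posterior (and
    in particular beta) unchanged while making the group scale identifiable
    in finite chains.
    """
    psi_k = np.asarray(psi_k, dtype=float)
    c_k = np.asarray(c_k, dtype=float)
    s = float(np.sum(1.0 / (c_k * psi_k)))
    r = 1.0 / float(t_k)
    p = 0.5 * (psi_k.size - 1)
    # GIG(p, a=2S, b=2R) -> scipy geninvgauss(p, sqrt(ab), scale=sqrt(b/a))
    return float(scipy.stats.geninvgauss.rvs(
        p, 2.0 * np.sqrt(s * r), scale=np.sqrt(r / s), random_state=rng))


def half_cauchy_mixture_draws(n_draws: int, rng: np.random.Generator):
    """Draw x with x^2 | a ~ IG(1/2, 1/a), a ~ IG(1/2, 1); x ~ C+(0, 1)."""
    a = _inv_gamma(rng, 0.5, np.ones(n_draws))
    x2 = _inv_gamma(rng, 0.5, 1.0 / a)
    return np.sqrt(x2)


def half_cauchy_mixture_check(n_draws: int = 100_000, seed: int = 0) -> float:
    """KS distance of the inverse-gamma scale mixture against C+(0, 1).

    The half-Cauchy CDF is (2/pi) arctan(x).
    """
    if n_draws < 10_000:
        raise ValidationError("need n_draws >= 1e4 for a stable KS distance")
    rng = np.random.default_rng(seed)
    x = half_cauchy_mixture_draws(n_draws, rng)
    return float(scipy.stats.kstest(x, scipy.stats.halfcauchy.cdf).statistic)


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------

def _effective_sample_size(trace: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS estimate."""
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1:] / (np.arange(n, 0, -1) * x.var())
    tau = 1.0
    for lag in range(1, n // 2):
        if acf[lag] <= 0:
            break
        tau += 2.0 * acf[lag]
    return float(n / tau)


def _block_layout(ss: SummaryStats, blocks: list[LDBlock],
                  design: ExpandedDesign):
    """Precompute, per block, the copy slice and expanded LD matrix."""
    offset = 0
    copy_starts = np.concatenate(
        [[0], np.cumsum(np.bincount(design.copy_variant,
                                    minlength=design.n_variants))])
    ss_ids = ss.variant_ids
    layout = []
    for block in blocks:
        m_b = len(block)
        v_lo, v_hi = offset, offset + m_b
        if ss_ids[v_lo:v_hi] != block.variant_ids:
            raise ValidationError(
                "summary statistics are not ordered to match the LD blocks; "
                "run align_alleles first")
        c_lo, c_hi = int(copy_starts[v_lo]), int(copy_starts[v_hi])
        local_v = design.copy_variant[c_lo:c_hi] - v_lo
        D_exp = block.D[np.ix_(local_v, local_v)]
        layout.append({
            "copies": slice(c_lo, c_hi),
            "D_exp": D_exp,
            "beta_hat": ss.beta_hat[v_lo:v_hi][local_v],
        })
        offset = v_hi
    if offset != len(ss):
        raise ValidationError("LD blocks do not cover all summary-stat variants")
    return layout


def run_gibbs(ss: SummaryStats, blocks: list[LDBlock],
              design: ExpandedDesign, cfg: GibbsConfig) -> PosteriorSummary:
    """Run the bilevel shrinkage chain and return posterior-mean effects.

    Systematic scan per iteration: beta (block by block) -> sigma^2 ->
    lambda^2, c -> delta^2, t. Posterior means are taken over post-burn-in
    draws at the configured thinning. Fully reproducible given cfg.seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    layout = _block_layout(ss, blocks, design)

    m_prime = design.m_prime
    k_groups = design.n_groups
    n = ss.n_gwas
    group = design.copy_group
    group_sizes = design.group_sizes
    group_members = [np.flatnonzero(group == k) for k in range(k_groups)]

    beta = np.zeros(m_prime)
    sigma2 = 1.0
    lambda2 = np.ones(m_prime)
    c = np.ones(m_prime)
    delta2 = np.ones(k_groups)
    t = np.ones(k_groups)
    mode = cfg.lambda_conditional

    n_kept = 0
    beta_sum = np.zeros(m_prime)
    beta_sq_sum = np.zeros(m_prime)
    delta2_sum = np.zeros(k_groups)
    sigma2_sum = 0.0
    sigma2_trace: list[float] = []
    delta2_trace: list[np.ndarray] = []

    for it in range(cfg.n_iter):
        psi = np.minimum(delta2[group] * lambda2, cfg.shrink_cap)
        D_beta = np.empty(m_prime)
        for blk in layout:
            sl = blk["copies"]
            beta[sl] = sample_beta_block(blk["D_exp"], blk["beta_hat"],
                                         psi[sl], sigma2, n, rng)
            D_beta[sl] = blk["D_exp"] @ beta[sl]
        beta_hat_full = np.concatenate([blk["beta_hat"] for blk in layout]) \
            if len(layout) > 1 else layout[0]["beta_hat"]
        sigma2 = sample_sigma2(beta, beta_hat_full, D_beta, psi, n, m_prime, rng)

        lambda2 = sample_lambda2(beta, sigma2, delta2[group], c, n, rng, mode)
        c = sample_c(lambda2, rng)

        sq = n * beta * beta / (2.0 * sigma2 * lambda2)
        group_ss = np.bincount(group, weights=sq, minlength=k_groups)
        aux = 1.0 / t if mode == "derived" else t
        delta2 = _inv_gamma(rng, 0.5 * (group_sizes + 1), group_ss + aux)
        t = sample_t(delta2, rng)

        if mode == "derived":
            # interweaving: re-split the delta/lambda products per group
            products = delta2[group] * lambda2
            for k in range(k_groups):
                in_k = group_members[k]
                if in_k.size == 0:
                    continue
                d_new = sample_delta2_interweave(products[in_k], c[in_k],
                                                 t[k], rng)
                lambda2[in_k] = products[in_k] / d_new
                delta2[k] = d_new

        # truncate the stored product at the cap (scaling lambda^2 down) so
        # every conditional sees the same state, as in the reference sampler
        over = delta2[group] * lambda2 > cfg.shrink_cap
        if over.any():
            lambda2[over] = cfg.shrink_cap / delta2[group[over]]

        if not (np.all(np.isfinite(beta)) and np.isfinite(sigma2)):
            raise RuntimeError(f"non-finite Gibbs state at iteration {it}")

        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
            n_kept += 1
            beta_sum += beta
            beta_sq_sum += beta * beta
            delta2_sum += delta2
            sigma2_sum += sigma2
            sigma2_trace.append(sigma2)
            delta2_trace.append(delta2.copy())

    beta_tilde = beta_sum / n_kept
    diagnostics = {
        "beta_var_copies": beta_sq_sum / n_kept - beta_tilde**2,
        "n_kept": n_kept,
        "sigma2_trace": np.array(sigma2_trace),
        "delta2_trace": np.array(delta2_trace),
        "ess_sigma2": _effective_sample_size(np.array(sigma2_trace)),
    }
    return PosteriorSummary(
        design=design,
        beta_tilde_copies=beta_tilde,
        beta_tilde_variant=design.collapse_to_variants(beta_tilde),
        delta2_mean=delta2_sum / n_kept,
        sigma2_mean=sigma2_sum / n_kept,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class BilevelShrinkagePRS(BaseEstimator):
    """Polygenic score with a bilevel (group + variant) half-Cauchy prior.

    Fit from GWAS summary statistics plus an LD reference; no individual-level
    training data is needed. After fitting, ``beta_tilde_`` holds per-variant
    posterior-mean effects (sums over annotation copies) and ``predict``
    scores a standardized genotype matrix.

    Parameters
    ----------
    n_iter, n_burnin, thin
        Chain length, burn-in, and thinning for the posterior means.
    shrink_cap
        Upper clip for the per-copy products delta^2 * lambda^2 before the
        beta update (numerical guard against ill-conditioning).
    lambda_conditional
        "derived" (default, self-consistent conditionals) or "as_printed".
    random_state
        Seed for the single chain RNG.

    Examples
    --------
    >>> model = BilevelShrinkagePRS(random_state=7)
    >>> model.fit(sumstats, ld_blocks, annotations)   # doctest: +SKIP
    >>> prs = model.predict(G_test)                   # doctest: +SKIP
    """

    def __init__(self, n_iter: int = 1000, n_burnin: int = 500, thin: int = 5,
                 shrink_cap: float = 1.0, lambda_conditional: str = "derived",
                 random_state: int | None = None):
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.thin = thin
        self.shrink_cap = shrink_cap
        self.lambda_conditional = lambda_conditional
        self.random_state = random_state

    def _config(self) -> GibbsConfig:
        seed = 0 if self.random_state is None else int(self.random_state)
        return GibbsConfig(n_iter=self.n_iter, n_burnin=self.n_burnin,
                           thin=self.thin, seed=seed,
                           shrink_cap=self.shrink_cap,
                           lambda_conditional=self.lambda_conditional)

    def _make_design(self, sumstats: SummaryStats,
                     annotations: AnnotationMap | None) -> ExpandedDesign:
        if annotations is None:
            annotations = AnnotationMap(
                groups=["all"],
                assignment={v: ("all",) for v in sumstats.variant_ids})
        else:
            annotations = assign_sentinel(annotations, sumstats.variant_ids)
        return expand_overlap(annotations, sumstats)

    def fit(self, sumstats: SummaryStats, ld_blocks: list[LDBlock],
            annotations: AnnotationMap | None = None):
        """Run the Gibbs chain; inputs must already be allele-aligned."""
        design = self._make_design(sumstats, annotations)
        post = run_gibbs(sumstats, ld_blocks, design, self._config())
        self.design_ = design
        self.posterior_ = post
        self.beta_tilde_copies_ = post.beta_tilde_copies
        self.beta_tilde_ = post.beta_tilde_variant
        self.delta2_mean_ = post.delta2_mean
        self.sigma2_mean_ = post.sigma2_mean
        self.diagnostics_ = post.diagnostics
        self.variant_ids_ = list(sumstats.variant_ids)
        return self

    def predict(self, G: np.ndarray) -> np.ndarray:
        """Total PRS of each individual (columns of G aligned to variants)."""
        if not hasattr(self, "beta_tilde_"):
            raise ValidationError("estimator is not fitted")
        G = np.asarray(G, dtype=float)
        if G.shape[1] != len(self.variant_ids_):
            raise ValidationError(
                f"G has {G.shape[1]} columns, expected {len(self.variant_ids_)}")
        return G @ self.beta_tilde_
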