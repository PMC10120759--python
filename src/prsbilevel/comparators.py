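"""Reference methods for comparison: the single-group continuous-shrinkage
PRS (PRS-CS-auto special case) and a closed-form functional-prior posterior
with bin-wise reweighting (LDpred-funct style)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import LDBlock, SummaryStats, ValidationError
from .gibbs import BilevelShrinkagePRS, GibbsConfig
from .scoring import GroupScores

logger = logging.getLogger(__name__)


class PRSCSAuto(BilevelShrinkagePRS):
    """Fully Bayesian continuous-shrinkage PRS with a single global scale.

    This is exactly the bilevel model with K = 1 (all variants in one group),
    i.e. the gamma-gamma prior at a0 = 0.5, b0 = 1; fitting runs the same
    Gibbs code path and is bitwise reproducible against it at equal seed.
    """

    def fit(self, sumstats: SummaryStats, ld_blocks: list[LDBlock],
            annotations=None):
        if annotations is not None:
            logger.info("PRSCSAuto ignores annotations (single global group)")
        return super().fit(sumstats, ld_blocks, annotations=None)


def prscs_auto(ss: SummaryStats, blocks: list[LDBlock],
               cfg: GibbsConfig | None = None):
    """Functional entry point; returns the same PosteriorSummary as a K=1
    bilevel run with the same seed."""
    cfg = cfg if cfg is not None else GibbsConfig()
    model = PRSCSAuto(n_iter=cfg.n_iter, n_burnin=cfg.n_burnin, thin=cfg.thin,
                      shrink_cap=cfg.shrink_cap,
                      lambda_conditional=cfg.lambda_conditional,
                      random_state=cfg.seed)
    model.fit(ss, blocks)
    return model.posterior_


@dataclass
class PerSnpHeritability:
    """Per-SNP heritabilities sigma_j^2 and the prior normalizing constant c.

    The prior is beta_j ~ N(0, c * sigma_j^2); c is chosen so that the total
    prior genetic variance sum_j c*sigma_j^2 equals the trait heritability.
    """

    sigma_j2: np.ndarray
    c: float

    def __post_init__(self) -> None:
        self.sigma_j2 = np.asarray(self.sigma_j2, dtype=float)
        if np.any(self.sigma_j2 < 0):
            raise ValidationError("per-SNP heritabilities must be >= 0")
        if not np.any(self.sigma_j2 > 0):
            raise ValidationError("at least one sigma_j^2 must be positive")

    @classmethod
    def from_total(cls, sigma_j2: np.ndarray, h2: float) -> "PerSnpHeritability":
        """Normalize so sum_j c*sigma_j^2 = h2."""
        sigma_j2 = np.asarray(sigma_j2, dtype=float)
        total = float(sigma_j2.sum())
        if total <= 0:
            raise ValidationError("total per-SNP heritability must be positive")
        return cls(sigma_j2=sigma_j2, c=h2 / total)


def ldpred_funct_posterior(ss: SummaryStats, blocks: list[LDBlock],
                           h: PerSnpHeritability,
                           n: int | None = None) -> np.ndarray:
    """Closed-form posterior mean E[beta|.] = W^{-1} N beta_hat per block,
    with W = N D + (1/c) diag(1/sigma_j^2).

    Variants with sigma_j^2 = 0 get a zero posterior effect (infinite-penalty
    limit) and are excluded from the solve with a warning.
    """
    n = int(n if n is not None else ss.n_gwas)
    if len(h.sigma_j2) != len(ss):
        raise ValidationError("sigma_j2 length != number of variants")
    beta_hat = ss.beta_hat
    out = np.zeros(len(ss))
    n_zero = int(np.sum(h.sigma_j2 == 0))
    if n_zero:
        logger.warning("%d zero-heritability variants set to zero effect", n_zero)
    offset = 0
    for block in blocks:
        m_b = len(block)
        sl = slice(offset, offset + m_b)
        s2 = h.sigma_j2[sl]
        keep = np.flatnonzero(s2 > 0)
        if keep.size:
            W = n * block.D[np.ix_(keep, keep)] \
                + np.diag(1.0 / (h.c * s2[keep]))
            try:
                sol = np.linalg.solve(W, n * beta_hat[sl][keep])
            except np.linalg.LinAlgError as err:
                raise RuntimeError(
                    "singular W in LDpred-funct solve; consider the LD "
                    "ridge-repair flag") from err
            tmp = np.zeros(m_b)
            tmp[keep] = sol
            out[sl] = tmp
        offset += m_b
    if offset != len(ss):
        raise ValidationError("LD blocks do not cover all variants")
    return out


def bin_by_posterior(effects: np.ndarray, L: int = 40) -> np.ndarray:
    """Partition SNPs into L bins of approximately equal sum of squared
    posterior-mean effects.

    SNPs are ranked by |effect| descending and assigned greedily: the current
    bin closes once its cumulative sum of squares reaches the per-bin target,
    which is re-computed from the remaining mass after each bin. Returns a
    0-based bin index per SNP (every SNP assigned exactly once, every bin
    non-empty).
    """
    effects = np.asarray(effects, dtype=float)
    if effects.size == 0:
        raise ValidationError("effects must be non-empty")
    if L < 1:
        raise ValidationError("L must be >= 1")
    n_nonzero = int(np.sum(effects != 0))
    if L > max(n_nonzero, 1):
        logger.warning("reducing L from %d to %d (number of nonzero effects)",
                       L, max(n_nonzero, 1))
        L = max(n_nonzero, 1)
    order = np.argsort(-np.abs(effects), kind="stable")
    sq = effects[order] ** 2
    remaining = float(sq.sum())
    bins = np.zeros(effects.size, dtype=int)
    current, acc = 0, 0.0
    # target re-computed per bin from the remaining mass so that a few very
    # large effects cannot starve the later bins
    target = remaining / L
    for rank, idx in enumerate(order):
        bins[idx] = current
        acc += sq[rank]
        remaining -= sq[rank]
        items_left = effects.size - rank - 1
        bins_left = L - current - 1
        if bins_left > 0 and items_left > 0 and (
                acc >= target * (1 - 1e-12) or items_left == bins_left):
            current += 1
            acc = 0.0
            target = remaining / bins_left
    return bins


class LDpredFunct:
    """Functional-prior PRS comparator with closed-form posterior and L-bin
    cross-validated reweighting.

    Parameters
    ----------
    L : number of posterior-effect bins (40 in the reference protocol).
    """

    def __init__(self, L: int = 40):
        self.L = L

    def fit(self, sumstats: SummaryStats, ld_blocks: list[LDBlock],
            per_snp_h2: PerSnpHeritability):
        self.effects_ = ldpred_funct_posterior(sumstats, ld_blocks, per_snp_h2)
        self.bins_ = bin_by_posterior(self.effects_, self.L)
        self.n_bins_ = int(self.bins_.max()) + 1
        self.variant_ids_ = list(sumstats.variant_ids)
        return self

    def bin_scores(self, G: np.ndarray) -> GroupScores:
        """Per-bin partial PRS matrix, ready for the same alpha-CV machinery
        used for annotation groups."""
        if not hasattr(self, "effects_"):
            raise ValidationError("estimator is not fitted")
        G = np.asarray(G, dtype=float)
        if G.shape[1] != len(self.effects_):
            raise ValidationError("G columns do not match fitted variants")
        cols = np.zeros((len(self.effects_), self.n_bins_))
        cols[np.arange(len(self.effects_)), self.bins_] = self.effects_
        return GroupScores(G @ cols, [f"bin{b}" for b in range(self.n_bins_)])

    def predict(self, G: np.ndarray) -> np.ndarray:
        """Unweighted total PRS, G @ E[beta|.]."""
        if not hasattr(self, "effects_"):
            raise ValidationError("estimator is not fitted")
        return np.asarray(G, dtype=float) @ self.effects_
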